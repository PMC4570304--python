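"""Calibration/validation accuracy metrics and per-site reports.

Metrics follow standard chemometric usage: R^2 = 1 - SSres/SStot with SStot
about the observed mean of the evaluated split, RMSE in the target's units
(mg/kg for total nitrogen), and MRE as the mean absolute relative error in
percent (which is why targets must be strictly positive).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np


def metrics(y_obs, y_pred) -> Dict[str, float]:
    """R^2, RMSE and MRE(%) of predictions against observations."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_obs.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(y_obs <= 0):
        raise ValueError("observed values must be strictly positive (MRE divides by them)")
    res = y_pred - y_obs
    rmse = float(np.sqrt(np.mean(res**2)))
    mre = float(100.0 * np.mean(np.abs(res) / y_obs))
    sstot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = float("nan") if sstot == 0 else float(1.0 - np.sum(res**2) / sstot)
    return {"r2": r2, "rmse": rmse, "mre": mre, "n": int(y_obs.size)}


@dataclasses.dataclass
class EvaluationReport:
    """Per-split, per-site metric blocks plus model metadata.

    ``splits`` maps split name (calibration/validation) to a dict mapping
    site label ("overall" plus each site) to a metrics dict.  Sites with
    fewer than 2 samples are reported with n only and NaN metrics.
    """

    splits: Dict[str, Dict[str, Dict[str, float]]]
    metadata: Dict[str, object] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"splits": self.splits, "metadata": self.metadata}

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(splits=d["splits"], metadata=d.get("metadata", {}))

    def metric(self, split: str, name: str, site: str = "overall") -> float:
        return self.splits[split][site][name]


def split_block(
    y_obs, y_pred, sites: Optional[Sequence[str]] = None
) -> Dict[str, Dict[str, float]]:
    """Overall + per-site metric blocks for one split."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0:
        return {"overall": {"r2": float("nan"), "rmse": float("nan"), "mre": float("nan"), "n": 0}}
    block = {"overall": metrics(y_obs, y_pred)}
    if sites is not None:
        sites = np.asarray(list(sites))
        if sites.size != y_obs.size:
            raise ValueError("site labels must cover all samples")
        for s in sorted(set(sites.tolist())):
            m = sites == s
            if m.sum() >= 2:
                block[s] = metrics(y_obs[m], y_pred[m])
            else:
                block[s] = {
                    "r2": float("nan"),
                    "rmse": float("nan"),
                    "mre": float("nan"),
                    "n": int(m.sum()),
                }
    return block


def split_report(
    y_cal, yhat_cal, y_val, yhat_val,
    sites_cal: Optional[Sequence[str]] = None,
    sites_val: Optional[Sequence[str]] = None,
    metadata: Optional[dict] = None,
) -> EvaluationReport:
    """Assemble the full calibration + validation report."""
    return EvaluationReport(
        splits={
            "calibration": split_block(y_cal, yhat_cal, sites_cal),
            "validation": split_block(y_val, yhat_val, sites_val),
        },
        metadata=metadata or {},
    )
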