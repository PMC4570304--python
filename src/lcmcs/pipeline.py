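"""End-to-end calibration pipelines: PLS, LCM, CS and LCMCS.

The four methods share one skeleton — spectral transform, denoising, band
selection, PLS — and differ in two switches: how spectra are denoised
(fixed-level wavelet smoothing vs the correlation-maximizing optimal
spectrum) and whether the PLS latent scores feed a Takagi-Sugeno fuzzy
regressor (the "complementary superiority" step) or PLS predicts directly:

=======  ==================  ================
method   denoising           regressor
=======  ==================  ================
PLS      fixed-level         PLS
LCM      optimal spectrum    PLS
CS       fixed-level         PLS scores -> ANFIS
LCMCS    optimal spectrum    PLS scores -> ANFIS
=======  ==================  ================

All learned state (level map, band mask, PLS model, ANFIS) is fit on the
calibration split only and applied frozen to validation spectra.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import transforms
from .anfis import ANFISRegressor
from .band_selection import CorrelationBandSelector
from .evaluation import EvaluationReport, split_report
from .lcm import LCMDenoiser, smooth_to_level
from .pls import PLSRegression, choose_components
from .spectra_io import SpectrumSet, TargetVector, save_report

#: per-site calibration counts of the standard three-site study design
_STUDY_CAL_COUNTS = {"C": (100, 55), "R": (95, 50), "F": (85, 45)}
_STUDY_CAL_FRACTION = 150 / 280


@dataclasses.dataclass
class ANFISConfig:
    mfs_per_input: int = 2
    epochs: int = 60
    learning_rate: float = 0.01
    patience: int = 20
    consequent_penalty: float = 0.05


@dataclasses.dataclass
class MethodConfig:
    """Configuration of one calibration pipeline."""

    method: str = "LCMCS"                     # PLS | LCM | CS | LCMCS
    transform: str = "FDR_LOG_INV"            # REF | FDR | LOG_INV | FDR_LOG_INV
    denoise: str = "lcm_osp"                  # "lcm_osp" or "fixed_level:K"
    selection: str = "p<0.01"                 # band-selection criterion
    lvs: Union[int, str] = 5                  # latent variables, or "auto"
    anfis: Optional[ANFISConfig] = None
    wavelet: str = "sym8"
    max_level: int = 5
    split_seed: int = 0
    leaky_occ: bool = False                   # learn the level map on all samples

    def __post_init__(self):
        if self.method not in ("PLS", "LCM", "CS", "LCMCS"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("CS", "LCMCS") and self.anfis is None:
            self.anfis = ANFISConfig()
        if self.method in ("PLS", "LCM") and self.anfis is not None:
            raise ValueError(f"{self.method} does not use an ANFIS stage")
        if self.method in ("LCM", "LCMCS") and self.denoise != "lcm_osp":
            raise ValueError(f"{self.method} requires denoise='lcm_osp'")
        if self.denoise != "lcm_osp" and not self.denoise.startswith("fixed_level"):
            raise ValueError(f"unknown denoise setting {self.denoise!r}")

    @property
    def fixed_level(self) -> int:
        """Smoothing depth for fixed_level denoising (0 = none)."""
        if self.denoise == "lcm_osp":
            raise ValueError("not a fixed-level config")
        if ":" in self.denoise:
            return int(self.denoise.split(":", 1)[1])
        return 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def preset(name: str, split_seed: int = 0, anfis_seed: int = 0) -> MethodConfig:
    """Named pipeline presets matching the four comparison models:
    derivative-of-log(1/R) spectra throughout, level-5 or level-4 fixed
    smoothing for the non-LCM models, the optimal spectrum for the LCM ones,
    per-band significance or |r|>0.40 selection, and 8 or 5 latent variables.
    """
    presets = {
        "study_pls": MethodConfig(
            method="PLS", transform="FDR_LOG_INV", denoise="fixed_level:5",
            selection="p<0.01", lvs=8, split_seed=split_seed,
        ),
        "study_lcm": MethodConfig(
            method="LCM", transform="FDR_LOG_INV", denoise="lcm_osp",
            selection="p<0.01", lvs=8, split_seed=split_seed,
        ),
        "study_cs": MethodConfig(
            method="CS", transform="FDR_LOG_INV", denoise="fixed_level:4",
            selection="|r|>0.40", lvs=5, anfis=ANFISConfig(), split_seed=split_seed,
        ),
        "study_lcmcs": MethodConfig(
            method="LCMCS", transform="FDR_LOG_INV", denoise="lcm_osp",
            selection="p<0.01", lvs=5, anfis=ANFISConfig(), split_seed=split_seed,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# Calibration / validation split


def calibration_split(
    spectra: SpectrumSet, seed: int = 0, cal_fraction: float = _STUDY_CAL_FRACTION
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic calibration/validation index split.

    With site labels, the split is stratified per site; when per-site sizes
    match the standard 100/95/85 three-site design, the calibration counts
    are exactly 55/50/45 (validation 45/45/40).  Without labels, a plain
    seeded shuffle at ``cal_fraction``.
    """
    rng = np.random.default_rng(seed)
    n = spectra.n_samples
    if spectra.site is None:
        idx = rng.permutation(n)
        n_cal = int(round(cal_fraction * n))
        return np.sort(idx[:n_cal]), np.sort(idx[n_cal:])
    sites = np.asarray(spectra.site)
    cal_idx, val_idx = [], []
    for s in sorted(set(sites.tolist())):
        where = np.nonzero(sites == s)[0]
        n_site = where.size
        target = _STUDY_CAL_COUNTS.get(s)
        if target is not None and target[0] == n_site:
            n_cal = target[1]
        else:
            n_cal = int(round(cal_fraction * n_site))
        perm = rng.permutation(n_site)
        cal_idx.append(where[perm[:n_cal]])
        val_idx.append(where[perm[n_cal:]])
    return np.sort(np.concatenate(cal_idx)), np.sort(np.concatenate(val_idx))


# ---------------------------------------------------------------------------
# Fitted pipeline


@dataclasses.dataclass
class FittedMethod:
    """All frozen state of one fitted pipeline, reusable on new spectra."""

    config: MethodConfig
    denoiser: Optional[LCMDenoiser]
    selector: CorrelationBandSelector
    pls: PLSRegression
    anfis: Optional[ANFISRegressor]
    n_components: int

    def _denoise(self, values: np.ndarray) -> np.ndarray:
        if self.denoiser is not None:
            return self.denoiser.transform(values)
        k = self.config.fixed_level
        return smooth_to_level(values, k, self.config.wavelet) if k else values

    def predict_values(self, transformed_values: np.ndarray) -> np.ndarray:
        """Predict TN from already-transformed spectra on the training grid."""
        X = self.selector.transform(self._denoise(transformed_values))
        if self.anfis is not None:
            return self.anfis.predict(self.pls.transform(X))
        return self.pls.predict(X)

    def predict(self, spectra: SpectrumSet) -> np.ndarray:
        """Predict TN from original reflectance spectra."""
        t = transforms.apply_transform(spectra, self.config.transform)
        return self.predict_values(t.values)


def fit_method(
    spectra: SpectrumSet,
    y: TargetVector,
    cfg: MethodConfig,
    cal_idx: np.ndarray,
) -> FittedMethod:
    """Fit one pipeline on the calibration rows of ``spectra``."""
    t = transforms.apply_transform(spectra, cfg.transform)
    yv = y.aligned_to(spectra)
    X_all, y_all = t.values, yv
    X_cal, y_cal = X_all[cal_idx], y_all[cal_idx]

    denoiser = None
    if cfg.denoise == "lcm_osp":
        denoiser = LCMDenoiser(wavelet=cfg.wavelet, max_level=cfg.max_level)
        if cfg.leaky_occ:
            denoiser.fit(X_all, y_all)
        else:
            denoiser.fit(X_cal, y_cal)
        Xd_cal = denoiser.transform(X_cal)
    else:
        k = cfg.fixed_level
        Xd_cal = smooth_to_level(X_cal, k, cfg.wavelet) if k else X_cal

    selector = CorrelationBandSelector(criterion=cfg.selection).fit(Xd_cal, y_cal)
    if not selector.mask_.any():
        raise ValueError(
            f"band selection {cfg.selection!r} is empty "
            f"(max |r| = {np.abs(selector.r_).max():.4f})"
        )
    Xs_cal = selector.transform(Xd_cal)

    if cfg.lvs == "auto":
        n_comp = choose_components(Xs_cal, y_cal, max_components=min(15, Xs_cal.shape[1]))
    else:
        n_comp = int(cfg.lvs)
    n_comp = min(n_comp, Xs_cal.shape[1], Xs_cal.shape[0] - 1)
    pls = PLSRegression(n_components=n_comp).fit(Xs_cal, y_cal)

    anfis_model = None
    if cfg.anfis is not None:
        S_cal = pls.transform(Xs_cal)
        anfis_model = ANFISRegressor(
            mfs_per_input=cfg.anfis.mfs_per_input,
            epochs=cfg.anfis.epochs,
            learning_rate=cfg.anfis.learning_rate,
            patience=cfg.anfis.patience,
            consequent_penalty=cfg.anfis.consequent_penalty,
            random_state=cfg.split_seed,
        ).fit(S_cal, y_cal)

    return FittedMethod(
        config=cfg, denoiser=denoiser, selector=selector,
        pls=pls, anfis=anfis_model, n_components=n_comp,
    )


def run_method(
    spectra: SpectrumSet,
    y: TargetVector,
    cfg: MethodConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> EvaluationReport:
    """Split, fit and evaluate one pipeline; optionally persist artifacts."""
    cal_idx, val_idx = calibration_split(spectra, seed=cfg.split_seed)
    fitted = fit_method(spectra, y, cfg, cal_idx)
    t = transforms.apply_transform(spectra, cfg.transform)
    yv = y.aligned_to(spectra)
    yhat_cal = fitted.predict_values(t.values[cal_idx])
    yhat_val = fitted.predict_values(t.values[val_idx])
    sites = None if spectra.site is None else np.asarray(spectra.site)
    report = split_report(
        yv[cal_idx], yhat_cal, yv[val_idx], yhat_val,
        sites_cal=None if sites is None else sites[cal_idx],
        sites_val=None if sites is None else sites[val_idx],
        metadata={
            "method": cfg.method,
            "transform": cfg.transform,
            "denoise": cfg.denoise,
            "selection": cfg.selection,
            "lvs": fitted.n_components,
            "n_bands_selected": int(fitted.selector.mask_.sum()),
            "split_seed": cfg.split_seed,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_report(report, out_dir / "report.json")
        _save_artifacts(fitted, spectra, out_dir)
    return report


def _save_artifacts(fitted: FittedMethod, spectra: SpectrumSet, out_dir: Path) -> None:
    wl = spectra.wavelengths
    sel = pd.DataFrame({"wavelength": wl, "selected": fitted.selector.mask_.astype(int),
                        "r": fitted.selector.r_})
    sel.to_csv(out_dir / "band_selection.csv", index=False)
    if fitted.denoiser is not None:
        occ = pd.DataFrame({"wavelength": wl, "level": fitted.denoiser.level_map_,
                            "occ_r": fitted.denoiser.occ_r_})
        occ.to_csv(out_dir / "occ.csv", index=False)
    fitted.pls.save(out_dir / "pls_model.json")
    if fitted.anfis is not None:
        fitted.anfis.save(out_dir / "anfis_model.json")
    (out_dir / "config.json").write_text(json.dumps(fitted.config.to_dict(), indent=2) + "\n")


def compare_methods(
    spectra: SpectrumSet,
    y: TargetVector,
    configs: List[MethodConfig],
    out_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Run several pipelines and tabulate their metrics, best first.

    Per-method failures become rows with an ``error`` column instead of
    aborting the comparison.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to compare")
    rows = []
    for cfg in configs:
        row = {"method": cfg.method, "transform": cfg.transform,
               "denoise": cfg.denoise, "selection": cfg.selection}
        try:
            sub = None if out_dir is None else Path(out_dir) / cfg.method
            rep = run_method(spectra, y, cfg, out_dir=sub)
            row["lvs"] = rep.metadata["lvs"]
            for split, tag in (("calibration", "cal"), ("validation", "val")):
                m = rep.splits[split]["overall"]
                row[f"r2_{tag}"] = m["r2"]
                row[f"rmse_{tag}"] = m["rmse"]
                row[f"mre_{tag}"] = m["mre"]
            row["error"] = ""
        except Exception as exc:  # recorded, not raised
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "r2_val" in df.columns:
        df = df.sort_values("r2_val", ascending=False, na_position="last").reset_index(drop=True)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "comparison.csv", index=False)
    return df
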