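"""Containers and CSV I/O for vis-NIR spectra, target vectors and reports.

A :class:`SpectrumSet` holds a samples x bands matrix on a strictly uniform
wavelength grid (the package convention is 350-2500 nm at 1 nm, i.e. 2151
bands, but any uniform grid is accepted).  Reflectance spectra carry the
``REF`` tag and must lie in (0, 1]; transformed spectra carry the tag of the
transform that produced them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Recognised transform tags: original reflectance, first derivative,
#: reciprocal logarithm, and first derivative of the reciprocal logarithm.
TRANSFORM_TAGS = ("REF", "FDR", "LOG_INV", "FDR_LOG_INV")

_GRID_TOL = 1e-9


@dataclasses.dataclass
class SpectrumSet:
    """Sample x band spectral matrix with an explicit wavelength axis.

    Parameters
    ----------
    wavelengths : array of float, shape (n_bands,)
        Strictly increasing uniform grid, in nm.
    values : array of float, shape (n_samples, n_bands)
        Reflectance in (0, 1] when ``transform_tag == "REF"``, otherwise a
        transform of reflectance (unconstrained sign).
    sample_ids : sequence of str
        One id per row; alignment with targets is by id, never by position.
    site : sequence of str, optional
        Per-sample site label (e.g. C/R/F for the three study areas).
    transform_tag : str
        One of ``REF``, ``FDR``, ``LOG_INV``, ``FDR_LOG_INV``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: Sequence[str]
    site: Optional[Sequence[str]] = None
    transform_tag: str = "REF"
    #: cleared on processed copies: smoothing can legitimately overshoot (0, 1]
    check_range: bool = dataclasses.field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.site is not None:
            self.site = list(map(str, self.site))
            if len(self.site) != self.values.shape[0]:
                raise ValueError("site labels must match the sample count")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValueError(
                f"unknown transform_tag {self.transform_tag!r}; "
                f"expected one of {TRANSFORM_TAGS}"
            )
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"value matrix has {self.values.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids must match the number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        d = np.diff(self.wavelengths)
        if self.wavelengths.size >= 2:
            if np.any(d <= 0):
                bad = np.nonzero(d <= 0)[0]
                raise ValueError(
                    f"wavelengths not strictly increasing at indices {bad[:10].tolist()}"
                )
            if np.any(np.abs(d - d[0]) > _GRID_TOL):
                bad = np.nonzero(np.abs(d - d[0]) > _GRID_TOL)[0]
                raise ValueError(
                    f"non-uniform wavelength grid at indices {bad[:10].tolist()}"
                )
        if self.transform_tag == "REF" and self.check_range:
            if np.any(~np.isfinite(self.values)):
                raise ValueError("non-finite reflectance values")
            if np.any(self.values <= 0) or np.any(self.values > 1):
                i, j = np.unravel_index(
                    int(np.argmax((self.values <= 0) | (self.values > 1))),
                    self.values.shape,
                )
                raise ValueError(
                    f"reflectance out of (0, 1] for sample "
                    f"{self.sample_ids[i]!r} at {self.wavelengths[j]:g} nm"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def spacing(self) -> float:
        """Grid step in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def with_values(self, values: np.ndarray, transform_tag: Optional[str] = None) -> "SpectrumSet":
        """Copy carrying new (processed) values; the raw-reflectance range
        check is not re-applied."""
        return SpectrumSet(
            wavelengths=self.wavelengths.copy(),
            values=np.asarray(values, dtype=float),
            sample_ids=list(self.sample_ids),
            site=None if self.site is None else list(self.site),
            transform_tag=self.transform_tag if transform_tag is None else transform_tag,
            check_range=False,
        )

    def subset(self, idx: np.ndarray) -> "SpectrumSet":
        """Row subset by integer index array."""
        idx = np.asarray(idx)
        return SpectrumSet(
            wavelengths=self.wavelengths.copy(),
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            site=None if self.site is None else [self.site[i] for i in idx],
            transform_tag=self.transform_tag,
            check_range=self.check_range,
        )


@dataclasses.dataclass
class TargetVector:
    """Per-sample target property (total nitrogen, mg/kg; strictly positive)."""

    values: np.ndarray
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.size != len(self.sample_ids):
            raise ValueError("sample_ids must match the number of values")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("target values must be finite and strictly positive")

    def aligned_to(self, spectra: SpectrumSet) -> np.ndarray:
        """Target values reordered to the spectra's sample order.

        Alignment is by sample_id; any mismatch is a hard error.
        """
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in spectra.sample_ids if sid not in pos]
        if missing:
            raise ValueError(f"targets missing for sample_ids {missing[:10]}")
        return self.values[[pos[sid] for sid in spectra.sample_ids]]

    def subset(self, idx: np.ndarray) -> "TargetVector":
        idx = np.asarray(idx)
        return TargetVector(self.values[idx], [self.sample_ids[i] for i in idx])


# ---------------------------------------------------------------------------
# CSV loading / saving


def load_spectra(path, layout: str = "wide", transform_tag: str = "REF") -> SpectrumSet:
    """Load a spectra table from CSV.

    Wide layout: header ``sample_id,350,351,...``; one row per sample.
    Long layout: columns ``sample_id,wavelength,value`` (plus optional
    ``site``).  Row order of first appearance is preserved.
    """
    path = Path(path)
    if layout == "wide":
        # pandas silently renames duplicate headers, so check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate wavelength columns: {dups}")
        df = pd.read_csv(path, dtype={"sample_id": str})
        if "sample_id" not in df.columns:
            raise ValueError("wide CSV must have a 'sample_id' column")
        site = None
        if "site" in df.columns:
            site = df.pop("site").tolist()
        sample_ids = df.pop("sample_id").tolist()
        try:
            wavelengths = np.array([float(c) for c in df.columns])
        except ValueError as exc:
            raise ValueError(f"non-numeric wavelength column header: {exc}") from exc
        if np.unique(wavelengths).size != wavelengths.size:
            raise ValueError("duplicate wavelength columns")
        values = df.to_numpy(dtype=float)
    elif layout == "long":
        df = pd.read_csv(path, dtype={"sample_id": str})
        for col in ("sample_id", "wavelength", "value"):
            if col not in df.columns:
                raise ValueError(f"long CSV missing column {col!r}")
        wide = df.pivot(index="sample_id", columns="wavelength", values="value")
        # preserve order of first appearance
        order = list(dict.fromkeys(df["sample_id"]))
        wide = wide.loc[order]
        if wide.isna().any().any():
            raise ValueError("long CSV is not a complete sample x wavelength grid")
        wavelengths = wide.columns.to_numpy(dtype=float)
        sample_ids = wide.index.tolist()
        values = wide.to_numpy(dtype=float)
        site = None
        if "site" in df.columns:
            site_map = df.drop_duplicates("sample_id").set_index("sample_id")["site"]
            site = [str(site_map[sid]) for sid in sample_ids]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if np.any(~np.isfinite(values)):
        i, j = np.unravel_index(int(np.argmax(~np.isfinite(values))), values.shape)
        raise ValueError(f"non-numeric cell at row {i}, band column {j}")
    return SpectrumSet(wavelengths, values, sample_ids, site=site, transform_tag=transform_tag)


def save_spectra(s: SpectrumSet, path) -> None:
    """Write a SpectrumSet as a wide CSV (full float precision)."""
    path = Path(path)
    cols = {"sample_id": s.sample_ids}
    if s.site is not None:
        cols["site"] = s.site
    df = pd.DataFrame(cols)
    wl_cols = [format(w, ".10g") for w in s.wavelengths]
    df = pd.concat([df, pd.DataFrame(s.values, columns=wl_cols)], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")


def load_targets(path) -> TargetVector:
    """Load a target CSV with columns ``sample_id,tn``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    col = "tn" if "tn" in df.columns else df.columns[1]
    return TargetVector(df[col].to_numpy(dtype=float), df["sample_id"].tolist())


def save_targets(t: TargetVector, path) -> None:
    pd.DataFrame({"sample_id": t.sample_ids, "tn": t.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Evaluation report I/O (the report object itself lives in lcmcs.evaluation)


def save_report(report, path) -> None:
    """Write an EvaluationReport as JSON (lossless) and a CSV summary.

    ``path`` is the JSON file; a sibling ``<stem>.csv`` table is written next
    to it.  Round trip through :func:`load_report` preserves metric values to
    better than 1e-12 (repr-round-trip floats).
    """
    path = Path(path)
    d = report.to_dict()
    path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    rows = []
    for split, blocks in d["splits"].items():
        for site, m in blocks.items():
            rows.append({"split": split, "site": site, **m})
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")


def load_report(path):
    from .evaluation import EvaluationReport

    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))
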