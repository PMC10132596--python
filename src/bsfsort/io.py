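"""CSV/JSON input and output for fingerprints, boundaries and reports.

Fingerprint CSVs carry one row per sample: a ``sample_id`` column, one
absorbance column per wavelength named ``a<nm>`` (e.g. ``a240``), and optional
``substance`` and ``truth`` columns.  The wavelength grid is inferred from the
headers and sorted ascending, so fingerprints for other medications on other
grids parse unchanged.  Truth values are case-insensitive; the shorthand
``A`` / ``LQ/C`` aliases used in laboratory record sheets are accepted.

Boundary CSVs carry one row per wavelength with ``wavelength``, ``lower`` and
``upper`` columns.  Result reports are written either as a CSV mirroring the
laboratory record layout (absorbances, sorted category, verdict, reason) or
as a JSON document that additionally records the credibility values, the full
parameter set, the seed and the package version.  Output bytes are
deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .fingerprint import ClassificationResult, ConfusionCounts, Verdict
from .outranking import (
    ABSORBANCE_MAX,
    ABSORBANCE_MIN,
    AbsorbanceRangeError,
    CategorySystem,
    SpectralFingerprint,
    ThresholdSet,
)

__all__ = [
    "RunConfig",
    "read_category_system_csv",
    "read_fingerprints_csv",
    "write_category_system_csv",
    "write_fingerprints_csv",
    "write_results",
]

_ABS_COLUMN = re.compile(r"^a(\d+(?:\.\d+)?)$")

_TRUTH_ALIASES = {
    "authentic": "authentic",
    "a": "authentic",
    "lqc": "lqc",
    "lq/c": "lqc",
    "lq": "lqc",
    "c": "lqc",
    "unknown": "unknown",
    "": None,
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one command-line run."""

    samples_path: Optional[str] = None
    boundaries_path: Optional[str] = None
    use_reference: bool = False
    lam: Optional[float] = None
    q: Optional[float] = None
    p: Optional[float] = None
    v: Optional[float] = None
    widen_fraction: float = 0.0
    strict: bool = True
    output_format: str = "csv"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam is not None and not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam override must be in [0, 1], got {self.lam}")
        if self.output_format not in ("csv", "json"):
            raise ValueError(f"output format must be csv or json, got "
                             f"{self.output_format!r}")


def _normalize_truth(raw) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    key = str(raw).strip().lower()
    if key in _TRUTH_ALIASES:
        return _TRUTH_ALIASES[key]
    raise ValueError(f"unrecognized truth label {raw!r}")


def read_fingerprints_csv(path: Union[str, Path],
                          strict: bool = True) -> list[SpectralFingerprint]:
    """Parse a fingerprint CSV into validated :class:`SpectralFingerprint`s.

    In strict mode (default) absorbances outside the [0, 2] instrument scale
    are rejected with the offending row and column named; in lenient mode
    they are clipped with a warning, matching a saturating instrument.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no fingerprint rows")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    abs_cols = [(float(m.group(1)), c) for c in df.columns
                if (m := _ABS_COLUMN.match(str(c)))]
    if not abs_cols:
        raise ValueError(f"{path}: no absorbance columns (expected names like 'a240')")
    abs_cols.sort()
    wavelengths = tuple(wl for wl, _ in abs_cols)
    columns = [c for _, c in abs_cols]

    fingerprints = []
    for idx, row in df.iterrows():
        values = []
        for col in columns:
            try:
                val = float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path} row {idx + 2}, column {col}: non-numeric "
                    f"absorbance {row[col]!r}") from None
            if not (ABSORBANCE_MIN <= val <= ABSORBANCE_MAX):
                if strict:
                    raise AbsorbanceRangeError(
                        f"{path} row {idx + 2}, column {col}: absorbance "
                        f"{val} outside [0, 2] (use lenient mode to clip)")
                warnings.warn(
                    f"{path} row {idx + 2}, column {col}: clipping absorbance "
                    f"{val} to the [0, 2] scale", stacklevel=2)
                val = min(max(val, ABSORBANCE_MIN), ABSORBANCE_MAX)
            values.append(val)
        substance = row.get("substance")
        if isinstance(substance, float) and np.isnan(substance):
            substance = None
        fingerprints.append(SpectralFingerprint(
            sample_id=str(row["sample_id"]),
            wavelengths=wavelengths,
            absorbances=tuple(values),
            substance=None if substance is None else str(substance),
            truth_label=_normalize_truth(row.get("truth")),
        ))
    return fingerprints


def _abs_header(wavelengths: Sequence[float]) -> list[str]:
    return [f"a{wl:g}" for wl in wavelengths]


def write_fingerprints_csv(fingerprints: Sequence[SpectralFingerprint],
                           path: Union[str, Path]) -> None:
    """Write fingerprints in the same layout :func:`read_fingerprints_csv` parses."""
    if len(fingerprints) == 0:
        raise ValueError("no fingerprints to write")
    grid = fingerprints[0].wavelengths
    records = []
    for fp in fingerprints:
        rec = {"sample_id": fp.sample_id}
        rec.update(dict(zip(_abs_header(grid), fp.absorbances)))
        rec["substance"] = fp.substance
        rec["truth"] = fp.truth_label
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, lineterminator="\n")


def read_category_system_csv(path: Union[str, Path]) -> CategorySystem:
    """Parse a boundary-profile CSV (columns wavelength, lower, upper)."""
    df = pd.read_csv(path)
    missing = {"wavelength", "lower", "upper"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("wavelength")
    return CategorySystem(
        wavelengths=tuple(df["wavelength"].astype(float)),
        lower_boundary=tuple(df["lower"].astype(float)),
        upper_boundary=tuple(df["upper"].astype(float)),
    )


def write_category_system_csv(system: CategorySystem,
                              path: Union[str, Path]) -> None:
    pd.DataFrame({
        "wavelength": system.wavelengths,
        "lower": system.lower_boundary,
        "upper": system.upper_boundary,
    }).to_csv(path, index=False, lineterminator="\n")


def _sorted_category(result: ClassificationResult) -> str:
    return "A" if result.verdict == Verdict.AUTHENTIC else "LQ/C"


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Tabular view of classification results (record-sheet layout)."""
    grid = results[0].wavelengths
    records = []
    for res in results:
        rec = {"sample_id": res.sample_id}
        rec.update(dict(zip(_abs_header(grid), res.absorbances)))
        rec["sorted_category"] = _sorted_category(res)
        rec["verdict"] = res.verdict.value
        rec["reason"] = res.reason.value
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_results(results: Sequence[ClassificationResult],
                  path: Union[str, Path],
                  counts: Optional[ConfusionCounts] = None,
                  thresholds: Optional[ThresholdSet] = None,
                  output_format: str = "csv",
                  seed: Optional[int] = None) -> None:
    """Write a classification report as CSV or JSON.

    The CSV mirrors the laboratory record layout; the JSON report adds the
    credibility values per boundary and direction, the parameter set, the
    seed and the package version.  Byte output is deterministic for fixed
    inputs.
    """
    if len(results) == 0:
        raise ValueError("no results to write")
    if output_format == "csv":
        results_frame(results).to_csv(path, index=False, lineterminator="\n")
        return
    if output_format != "json":
        raise ValueError(f"unknown output format {output_format!r}")

    doc = {
        "version": __version__,
        "seed": seed,
        "parameters": None if thresholds is None else {
            "q": thresholds.q,
            "p": thresholds.p,
            "v": thresholds.v,
            "lam": thresholds.lam,
            "weights": ("equal" if thresholds.weights is None
                        else list(thresholds.weights)),
        },
        "counts": None if counts is None else {
            "tp": counts.tp, "tn": counts.tn,
            "fp": counts.fp, "fn": counts.fn,
            "n_total": counts.n_total,
        },
        "results": [
            {
                "sample_id": res.sample_id,
                "wavelengths": list(res.wavelengths),
                "absorbances": list(res.absorbances),
                "pessimistic": res.pessimistic.value,
                "optimistic": res.optimistic.value,
                "relation_lower": res.relation_lower.value,
                "relation_upper": res.relation_upper.value,
                "sigma_ab_lower": res.sigma_ab_lower,
                "sigma_ba_lower": res.sigma_ba_lower,
                "sigma_ab_upper": res.sigma_ab_upper,
                "sigma_ba_upper": res.sigma_ba_upper,
                "sorted_category": _sorted_category(res),
                "verdict": res.verdict.value,
                "reason": res.reason.value,
                "truth": res.truth_label,
            }
            for res in results
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
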