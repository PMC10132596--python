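"""Threshold calibration and credibility-cut sensitivity analysis.

The preference and veto thresholds (p, v) are trained on a labeled set of
authentic and proxy low-quality/counterfeit fingerprints by exhaustive grid
search, minimizing the (optionally weighted) number of misclassifications.
The credibility cut level lambda is deliberately not part of that search — it
encodes how much evidence the operator demands — and is instead explored by a
sweep that maps false-positive/false-negative counts across lambda values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprint import ConfusionCounts, classify_batch, confusion
from .outranking import CategorySystem, SpectralFingerprint, ThresholdSet

__all__ = [
    "CalibrationGrid",
    "LambdaBand",
    "LambdaSweepRow",
    "calibrate_thresholds",
    "find_breakpoints",
    "lambda_sweep",
]

logger = logging.getLogger(__name__)


def _default_p_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 0.20 + 1e-9, 0.01), 2))


def _default_v_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.01, 0.30 + 1e-9, 0.01), 2))


@dataclass(frozen=True)
class CalibrationGrid:
    """Candidate (p, v) pairs for the threshold search.

    Only admissible pairs with v > p >= q_fixed are evaluated.  The defaults
    span 0–0.20 AU for p and 0.01–0.30 AU for v in 0.01 steps, bracketing
    typical preparation variability on the 0–2 absorbance scale.
    """

    p_values: tuple[float, ...] = field(default_factory=_default_p_grid)
    v_values: tuple[float, ...] = field(default_factory=_default_v_grid)
    q_fixed: float = 0.0

    def __post_init__(self) -> None:
        for name, vals in (("p_values", self.p_values), ("v_values", self.v_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if arr.min() < 0:
                raise ValueError(f"{name} must be >= 0")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        if self.q_fixed < 0:
            raise ValueError("q_fixed must be >= 0")

    def admissible_pairs(self) -> list[tuple[float, float]]:
        return [(p, v) for p in self.p_values if p >= self.q_fixed
                for v in self.v_values if v > p]


@dataclass(frozen=True)
class LambdaSweepRow:
    """False-positive/false-negative counts at one credibility cut level."""

    lam: float
    fp: int
    fn: int


@dataclass(frozen=True)
class LambdaBand:
    """Maximal run of consecutive sweep values with identical (fp, fn)."""

    lam_min: float
    lam_max: float
    fp: int
    fn: int


def _require_both_classes(labeled: Sequence[SpectralFingerprint]) -> None:
    labels = {fp.truth_label for fp in labeled}
    if not {"authentic", "lqc"} <= labels:
        raise ValueError(
            "calibration requires both authentic and lqc truth labels, "
            f"got {sorted(l for l in labels if l)}")


def calibrate_thresholds(
    labeled: Sequence[SpectralFingerprint],
    system: CategorySystem,
    grid: Optional[CalibrationGrid] = None,
    lam: float = 0.85,
    *,
    weights: Optional[tuple[float, ...]] = None,
    fp_weight: float = 1.0,
    fn_weight: float = 1.0,
) -> tuple[ThresholdSet, ConfusionCounts]:
    """Grid-search (p, v) minimizing weighted misclassifications.

    Evaluates every admissible pair by classifying the labeled set and
    counting errors.  Ties on the objective are broken toward the smaller
    veto threshold, then the smaller preference threshold — the strictest
    admissible system.  Deterministic: identical inputs give identical
    outputs.

    Returns the winning :class:`ThresholdSet` (with ``lam`` and ``weights``
    as supplied) together with the confusion counts it achieves.
    """
    if grid is None:
        grid = CalibrationGrid()
    _require_both_classes(labeled)
    pairs = grid.admissible_pairs()
    if not pairs:
        raise ValueError("calibration grid contains no admissible (p, v) pair")

    best: Optional[tuple[float, float, float, ConfusionCounts]] = None
    for p, v in pairs:
        ts = ThresholdSet(q=grid.q_fixed, p=p, v=v, weights=weights, lam=lam)
        counts = confusion(classify_batch(labeled, system, ts))
        objective = fp_weight * counts.fp + fn_weight * counts.fn
        key = (objective, v, p)
        if best is None or key < (best[0], best[1], best[2]):
            best = (objective, v, p, counts)
    objective, v, p, counts = best
    logger.info("calibrated thresholds: p=%.4g v=%.4g (objective=%.4g, "
                "fp=%d fn=%d of %d)", p, v, objective, counts.fp, counts.fn,
                counts.n_total)
    return ThresholdSet(q=grid.q_fixed, p=p, v=v, weights=weights, lam=lam), counts


def lambda_sweep(
    labeled: Sequence[SpectralFingerprint],
    system: CategorySystem,
    thresholds: ThresholdSet,
    lam_grid: Optional[Sequence[float]] = None,
) -> list[LambdaSweepRow]:
    """Reclassify the labeled set at each lambda and record fp/fn counts.

    All other parameters are held fixed.  The default grid runs from 0 to 1
    in steps of 0.01.  Warnings about lam <= 0.5 are suppressed here: sweeping
    the full range on purpose is the point of the analysis.
    """
    if lam_grid is None:
        lam_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    lam_arr = np.asarray(lam_grid, dtype=float)
    if lam_arr.size == 0:
        raise ValueError("lam_grid must be nonempty")
    if np.any(np.diff(lam_arr) <= 0):
        raise ValueError("lam_grid must be strictly ascending")
    rows = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="credibility cut")
        for lam in lam_arr:
            ts = thresholds.replace(lam=float(lam))
            counts = confusion(classify_batch(labeled, system, ts))
            rows.append(LambdaSweepRow(lam=float(lam), fp=counts.fp, fn=counts.fn))
    return rows


def find_breakpoints(rows: Sequence[LambdaSweepRow]) -> list[LambdaBand]:
    """Group a sweep into maximal bands of constant (fp, fn).

    Band edges are the evaluated grid values themselves (closed intervals);
    the true breakpoints lie between adjacent bands at the grid resolution.
    """
    if len(rows) == 0:
        raise ValueError("cannot summarize an empty sweep")
    bands: list[LambdaBand] = []
    start = rows[0]
    prev = rows[0]
    for row in rows[1:]:
        if (row.fp, row.fn) != (prev.fp, prev.fn):
            bands.append(LambdaBand(start.lam, prev.lam, prev.fp, prev.fn))
            start = row
        prev = row
    bands.append(LambdaBand(start.lam, prev.lam, prev.fp, prev.fn))
    return bands
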