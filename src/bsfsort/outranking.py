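"""ELECTRE TRI-B outranking engine for spectral-fingerprint sorting.

A medication sample is represented by its UV absorbance at a small set of
wavelengths (its spectral fingerprint); each wavelength acts as one criterion
in a multicriteria sorting problem.  Two boundary profiles — the lower and
upper edges of the authentic band — delimit three ordered categories::

    CAT-B  <  CAT-A (authentic band)  <  CAT-C

The engine computes, per criterion, a partial concordance (degree to which one
profile is at least as good as another, softened between the indifference
threshold ``q`` and the preference threshold ``p``) and a partial discordance
(opposition to that claim, reaching a full veto at deficit ``v``).  Weighted
partial concordances aggregate into a global concordance, which discordances
discount into a credibility index sigma in [0, 1].  The outranking relation
"a outranks b" holds when sigma(a, b) >= lambda, the credibility cut level.

Category assignment follows the two standard ELECTRE TRI-B procedures:
pessimistic (scan boundary profiles downward; assign the highest category
whose lower profile the sample outranks) and optimistic (scan upward; assign
the category below the first profile that strictly outranks the sample).
Samples on which the two procedures disagree are incomparable to the system.

All thresholds are scalars broadcast over every criterion and both boundary
profiles; absorbance is treated as a maximizing criterion throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ABSORBANCE_MAX",
    "ABSORBANCE_MIN",
    "AbsorbanceRangeError",
    "Category",
    "CategorySystem",
    "GridMismatchError",
    "OutrankingResult",
    "Relation",
    "SpectralFingerprint",
    "ThresholdError",
    "ThresholdSet",
    "assign_optimistic",
    "assign_pessimistic",
    "credibility",
    "credibility_pair",
    "global_concordance",
    "partial_concordance",
    "partial_discordance",
    "relation",
]

#: Instrument absorbance scale: 0 = fully transparent, 2 = opaque/saturated.
ABSORBANCE_MIN = 0.0
ABSORBANCE_MAX = 2.0

TRUTH_LABELS = ("authentic", "lqc", "unknown")


class ThresholdError(ValueError):
    """Raised for inadmissible threshold configurations (e.g. p < q or v <= p)."""


class GridMismatchError(ValueError):
    """Raised when two objects do not share the same wavelength grid."""


class AbsorbanceRangeError(ValueError):
    """Raised for absorbance values outside the [0, 2] instrument scale."""


class Category(str, Enum):
    """Ordered sorting categories; CAT-A is the authentic band."""

    CAT_B = "CAT-B"
    CAT_A = "CAT-A"
    CAT_C = "CAT-C"

    @property
    def rank(self) -> int:
        return {"CAT-B": 0, "CAT-A": 1, "CAT-C": 2}[self.value]


class Relation(str, Enum):
    """Outranking relation between a sample and one boundary profile."""

    SAMPLE_PREFERRED = "sample_preferred"
    BOUNDARY_PREFERRED = "boundary_preferred"
    INDIFFERENT = "indifferent"
    INCOMPARABLE = "incomparable"


def _as_float_tuple(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(x) for x in values)


def _check_absorbances(values: Sequence[float], *, context: str) -> None:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{context}: empty absorbance vector")
    if not np.all(np.isfinite(arr)):
        raise AbsorbanceRangeError(f"{context}: non-finite absorbance value")
    if arr.min() < ABSORBANCE_MIN or arr.max() > ABSORBANCE_MAX:
        raise AbsorbanceRangeError(
            f"{context}: absorbance outside [{ABSORBANCE_MIN}, {ABSORBANCE_MAX}]"
        )


def _check_wavelengths(wavelengths: Sequence[float], *, context: str) -> None:
    arr = np.asarray(wavelengths, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{context}: empty wavelength grid")
    if np.any(np.diff(arr) <= 0):
        raise ValueError(f"{context}: wavelengths must be strictly increasing")


@dataclass(frozen=True)
class SpectralFingerprint:
    """One sample's absorbance vector over an ordered wavelength grid.

    Parameters
    ----------
    sample_id:
        Free-text identifier of the physical sample.
    wavelengths:
        Strictly increasing wavelengths in nm.
    absorbances:
        Absorbance in AU at each wavelength, on the saturating 0–2 scale.
    substance:
        Optional description of the (claimed or factual) substance.
    truth_label:
        Optional ground truth, one of ``authentic``, ``lqc``, ``unknown``.
    """

    sample_id: str
    wavelengths: tuple[float, ...]
    absorbances: tuple[float, ...]
    substance: Optional[str] = None
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _as_float_tuple(self.wavelengths))
        object.__setattr__(self, "absorbances", _as_float_tuple(self.absorbances))
        ctx = f"fingerprint {self.sample_id!r}"
        _check_wavelengths(self.wavelengths, context=ctx)
        if len(self.absorbances) != len(self.wavelengths):
            raise ValueError(f"{ctx}: {len(self.absorbances)} absorbances for "
                             f"{len(self.wavelengths)} wavelengths")
        _check_absorbances(self.absorbances, context=ctx)
        if self.truth_label is not None and self.truth_label not in TRUTH_LABELS:
            raise ValueError(f"{ctx}: truth_label must be one of {TRUTH_LABELS}")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.absorbances, dtype=float)


@dataclass(frozen=True)
class CategorySystem:
    """Lower/upper boundary profiles of the authentic band (CAT-A).

    The lower boundary separates CAT-B from CAT-A; the upper boundary
    separates CAT-A from CAT-C.  Both profiles live on the same wavelength
    grid as the fingerprints they sort and must satisfy lower < upper
    elementwise.
    """

    wavelengths: tuple[float, ...]
    lower_boundary: tuple[float, ...]
    upper_boundary: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _as_float_tuple(self.wavelengths))
        object.__setattr__(self, "lower_boundary", _as_float_tuple(self.lower_boundary))
        object.__setattr__(self, "upper_boundary", _as_float_tuple(self.upper_boundary))
        _check_wavelengths(self.wavelengths, context="category system")
        for name, vec in (("lower", self.lower_boundary), ("upper", self.upper_boundary)):
            if len(vec) != len(self.wavelengths):
                raise ValueError(f"category system: {name} boundary length mismatch")
            _check_absorbances(vec, context=f"category system {name} boundary")
        lo = np.asarray(self.lower_boundary)
        hi = np.asarray(self.upper_boundary)
        if np.any(lo >= hi):
            raise ValueError("category system: lower boundary must be strictly "
                             "below upper boundary at every wavelength")

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.lower_boundary, dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.upper_boundary, dtype=float)


@dataclass(frozen=True)
class ThresholdSet:
    """Uncertainty parameters of the sorting system.

    ``q`` (indifference), ``p`` (preference) and ``v`` (veto) are absorbance
    deficits in AU, applied identically to every criterion and both boundary
    profiles; they must satisfy 0 <= q <= p < v.  ``weights`` are positive
    per-criterion weights summing to one (``None`` means equal weights,
    resolved against the wavelength grid at evaluation time).  ``lam`` is the
    credibility cut level: the outranking relation holds iff sigma >= lam.
    Values of lam at or below 0.5 are admitted for sensitivity sweeps but a
    warning is emitted, since an outranking supported by less than half the
    evidence is not meaningful.
    """

    q: float = 0.0
    p: float = 0.05
    v: float = 0.10
    weights: Optional[tuple[float, ...]] = None
    lam: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= self.p):
            raise ThresholdError(f"need 0 <= q <= p, got q={self.q}, p={self.p}")
        if not (self.p < self.v):
            raise ThresholdError(f"need p < v, got p={self.p}, v={self.v}")
        if not (0.0 <= self.lam <= 1.0):
            raise ThresholdError(f"lam must be in [0, 1], got {self.lam}")
        if self.lam <= 0.5:
            warnings.warn(
                f"credibility cut lam={self.lam} <= 0.5: outranking at or below "
                "half credibility is not meaningful", stacklevel=2)
        if self.weights is not None:
            w = _as_float_tuple(self.weights)
            object.__setattr__(self, "weights", w)
            arr = np.asarray(w)
            if np.any(arr <= 0):
                raise ThresholdError("weights must be strictly positive")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ThresholdError(f"weights must sum to 1, got {arr.sum()}")

    def resolve_weights(self, n_criteria: int) -> np.ndarray:
        if self.weights is None:
            return np.full(n_criteria, 1.0 / n_criteria)
        if len(self.weights) != n_criteria:
            raise ThresholdError(
                f"{len(self.weights)} weights for {n_criteria} criteria")
        return np.asarray(self.weights, dtype=float)

    def replace(self, **changes) -> "ThresholdSet":
        from dataclasses import replace as _replace
        return _replace(self, **changes)


@dataclass(frozen=True)
class OutrankingResult:
    """Credibilities in both directions and the resulting relation."""

    sigma_ab: float
    sigma_ba: float
    relation: Relation


# ---------------------------------------------------------------------------
# index computations

def _concordance_array(values: np.ndarray, references: np.ndarray,
                       q: float, p: float) -> np.ndarray:
    """Vectorized partial concordance of `values` outranking `references`."""
    deficit = references - values
    if p == q:  # degenerate: step function at deficit == q
        return np.where(deficit <= q, 1.0, 0.0)
    with np.errstate(over="ignore"):  # near-degenerate p - q; clip absorbs inf
        return np.clip((p - deficit) / (p - q), 0.0, 1.0)


def _discordance_array(values: np.ndarray, references: np.ndarray,
                       p: float, v: float) -> np.ndarray:
    """Vectorized partial discordance against `values` outranking `references`."""
    deficit = references - values
    with np.errstate(over="ignore"):
        return np.clip((deficit - p) / (v - p), 0.0, 1.0)


def partial_concordance(value: float, reference: float, q: float, p: float) -> float:
    """Degree (0–1) to which ``value`` is at least as good as ``reference``.

    Full concordance when the deficit ``reference - value`` is within the
    indifference threshold ``q``; zero once the deficit reaches the preference
    threshold ``p``; linear in between.  With p == q the interpolation
    degenerates to a step at deficit q.
    """
    if p < q or q < 0:
        raise ThresholdError(f"need 0 <= q <= p, got q={q}, p={p}")
    return float(_concordance_array(np.float64(value), np.float64(reference), q, p))


def partial_discordance(value: float, reference: float, p: float, v: float) -> float:
    """Degree (0–1) of opposition to ``value`` outranking ``reference``.

    Zero while the deficit is within the preference threshold ``p``; reaches a
    full veto (1) once the deficit meets the veto threshold ``v``; linear in
    between.  A deficit of exactly ``v`` vetoes.
    """
    if v <= p:
        raise ThresholdError(f"need p < v, got p={p}, v={v}")
    return float(_discordance_array(np.float64(value), np.float64(reference), p, v))


def global_concordance(partials: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted aggregation of per-criterion concordances."""
    c = np.asarray(partials, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.shape != w.shape:
        raise ValueError(f"{c.size} partial scores but {w.size} weights")
    return float(np.dot(c, w))


def credibility(global_c: float, discordances: Sequence[float]) -> float:
    """Credibility sigma: global concordance discounted by strong discordances.

    Only discordances strictly exceeding the global concordance discount it;
    each contributes a factor (1 - d_j) / (1 - C).  Any discordance of exactly
    1 (a veto) annihilates the credibility.  Always sigma <= C.
    """
    d = np.asarray(discordances, dtype=float)
    if np.any(d >= 1.0):
        return 0.0
    mask = d > global_c
    if not np.any(mask):
        return float(global_c)
    return float(global_c * np.prod((1.0 - d[mask]) / (1.0 - global_c)))


def _sigma(values: np.ndarray, references: np.ndarray, t: ThresholdSet,
           weights: np.ndarray) -> float:
    c = _concordance_array(values, references, t.q, t.p)
    d = _discordance_array(values, references, t.p, t.v)
    return credibility(float(np.dot(c, weights)), d)


def credibility_pair(sample: SpectralFingerprint,
                     boundary: Sequence[float],
                     thresholds: ThresholdSet) -> tuple[float, float]:
    """Credibility that the sample outranks the boundary, and vice versa.

    The forward direction answers "is the sample at least as good as the
    boundary at every wavelength"; the reverse swaps the roles.  Both use the
    same scalar thresholds and weights.
    """
    b = np.asarray(boundary, dtype=float)
    a = sample.values
    if b.shape != a.shape:
        raise GridMismatchError(
            f"boundary has {b.size} values but fingerprint "
            f"{sample.sample_id!r} has {a.size}")
    w = thresholds.resolve_weights(a.size)
    return _sigma(a, b, thresholds, w), _sigma(b, a, thresholds, w)


def relation(sigma_ab: float, sigma_ba: float, lam: float) -> Relation:
    """Outranking relation implied by the two credibilities at cut level lam."""
    a_out = sigma_ab >= lam
    b_out = sigma_ba >= lam
    if a_out and b_out:
        return Relation.INDIFFERENT
    if a_out:
        return Relation.SAMPLE_PREFERRED
    if b_out:
        return Relation.BOUNDARY_PREFERRED
    return Relation.INCOMPARABLE


def outranking_result(sigma_ab: float, sigma_ba: float, lam: float) -> OutrankingResult:
    return OutrankingResult(sigma_ab, sigma_ba, relation(sigma_ab, sigma_ba, lam))


# ---------------------------------------------------------------------------
# category assignment

def _check_grids(sample: SpectralFingerprint, system: CategorySystem) -> None:
    if sample.wavelengths != system.wavelengths:
        raise GridMismatchError(
            f"fingerprint {sample.sample_id!r} grid {sample.wavelengths} does "
            f"not match system grid {system.wavelengths}")


def pessimistic_from_sigmas(sigma_ab_lower: float, sigma_ab_upper: float,
                            lam: float) -> Category:
    """Downward scan: highest category whose lower profile the sample outranks."""
    if sigma_ab_upper >= lam:
        return Category.CAT_C
    if sigma_ab_lower >= lam:
        return Category.CAT_A
    return Category.CAT_B


def optimistic_from_sigmas(sigma_ab_lower: float, sigma_ba_lower: float,
                           sigma_ab_upper: float, sigma_ba_upper: float,
                           lam: float) -> Category:
    """Upward scan: category below the first profile strictly preferred to the sample."""
    if sigma_ba_lower >= lam and sigma_ab_lower < lam:
        return Category.CAT_B
    if sigma_ba_upper >= lam and sigma_ab_upper < lam:
        return Category.CAT_A
    return Category.CAT_C


def assign_pessimistic(sample: SpectralFingerprint, system: CategorySystem,
                       thresholds: ThresholdSet) -> Category:
    """Pessimistic (conservative) ELECTRE TRI-B category assignment."""
    _check_grids(sample, system)
    sab_u, _ = credibility_pair(sample, system.upper, thresholds)
    sab_l, _ = credibility_pair(sample, system.lower, thresholds)
    return pessimistic_from_sigmas(sab_l, sab_u, thresholds.lam)


def assign_optimistic(sample: SpectralFingerprint, system: CategorySystem,
                      thresholds: ThresholdSet) -> Category:
    """Optimistic ELECTRE TRI-B category assignment."""
    _check_grids(sample, system)
    sab_l, sba_l = credibility_pair(sample, system.lower, thresholds)
    sab_u, sba_u = credibility_pair(sample, system.upper, thresholds)
    return optimistic_from_sigmas(sab_l, sba_l, sab_u, sba_u, thresholds.lam)
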