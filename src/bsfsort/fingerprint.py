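"""Authenticity layer: learn the authentic band and map sorting to a verdict.

The authentic band (CAT-A) is learned from replicate fingerprints of a known
good medication: the elementwise minimum and maximum over replicates become
the lower and upper boundary profiles, optionally widened by a fixed fraction
to form intrinsic boundaries.

A sample is declared Authentic only when both ELECTRE TRI-B assignment
procedures place it in CAT-A and it is not indifferent to either boundary.
Every other outcome — CAT-B, CAT-C, indifference to a boundary, or
incomparability (the two procedures disagree) — yields a Low-Quality/
Counterfeit (LQC) verdict: a sample that cannot be sorted cleanly into the
authentic band is by definition suspect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .outranking import (
    ABSORBANCE_MAX,
    Category,
    CategorySystem,
    GridMismatchError,
    Relation,
    SpectralFingerprint,
    ThresholdSet,
    credibility_pair,
    optimistic_from_sigmas,
    pessimistic_from_sigmas,
    relation,
)

__all__ = [
    "ClassificationResult",
    "ConfusionCounts",
    "Reason",
    "Verdict",
    "build_category_system",
    "classify",
    "classify_batch",
    "confusion",
]

logger = logging.getLogger(__name__)


class Verdict(str, Enum):
    AUTHENTIC = "Authentic"
    LQC = "LQC"


class Reason(str, Enum):
    """Why a sample received its verdict."""

    IN_CAT_A = "in_cat_a"
    CAT_B = "cat_b"
    CAT_C = "cat_c"
    INDIFFERENT_BOUNDARY = "indifferent_boundary"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class ClassificationResult:
    """Full sorting outcome for one sample.

    Carries the two category assignments, the outranking relation and both
    credibility directions at each boundary, the final verdict, and a reason
    code explaining any LQC verdict.  The fingerprint's grid, absorbances and
    truth label are echoed for reporting.
    """

    sample_id: str
    wavelengths: tuple[float, ...]
    absorbances: tuple[float, ...]
    pessimistic: Category
    optimistic: Category
    relation_lower: Relation
    relation_upper: Relation
    sigma_ab_lower: float
    sigma_ba_lower: float
    sigma_ab_upper: float
    sigma_ba_upper: float
    verdict: Verdict
    reason: Reason
    truth_label: Optional[str] = None
    substance: Optional[str] = None


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion totals for a labeled batch (Authentic is the positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def errors(self) -> int:
        return self.fp + self.fn


def build_category_system(replicates: Sequence[SpectralFingerprint],
                          widen_fraction: float = 0.0) -> CategorySystem:
    """Learn CAT-A boundaries from replicate authentic fingerprints.

    The lower boundary is the elementwise minimum over replicates scaled by
    (1 - widen_fraction); the upper boundary is the elementwise maximum scaled
    by (1 + widen_fraction), capped at the saturating absorbance of 2.  A
    widen_fraction of 0.10 reproduces the intrinsic-range convention of taking
    10% below the lowest and 10% above the highest observed value.

    Replicate counts need not be statistically large — the goal is to span
    preparation variability — but fewer than 5 replicates triggers a warning.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate fingerprint")
    if widen_fraction < 0:
        raise ValueError(f"widen_fraction must be >= 0, got {widen_fraction}")
    grid = replicates[0].wavelengths
    for fp in replicates[1:]:
        if fp.wavelengths != grid:
            raise GridMismatchError(
                f"replicate {fp.sample_id!r} is on a different wavelength grid")
    if len(replicates) < 5:
        warnings.warn(
            f"building boundaries from only {len(replicates)} replicate(s); "
            "preparation variability may be under-sampled", stacklevel=2)
    stack = np.vstack([fp.values for fp in replicates])
    lower = (1.0 - widen_fraction) * stack.min(axis=0)
    upper = np.minimum((1.0 + widen_fraction) * stack.max(axis=0), ABSORBANCE_MAX)
    if np.any(lower >= upper):
        raise ValueError(
            "degenerate boundaries: lower >= upper at some wavelength "
            "(identical replicates with widen_fraction=0?)")
    return CategorySystem(grid, tuple(lower), tuple(upper))


def classify(sample: SpectralFingerprint, system: CategorySystem,
             thresholds: ThresholdSet) -> ClassificationResult:
    """Sort one fingerprint and derive the Authentic/LQC verdict.

    Authentic requires agreement of the pessimistic and optimistic procedures
    on CAT-A with no indifference to either boundary.  Reason precedence for
    LQC verdicts: incomparability (procedure disagreement), then boundary
    indifference, then the agreed non-authentic category.
    """
    if sample.wavelengths != system.wavelengths:
        raise GridMismatchError(
            f"fingerprint {sample.sample_id!r} grid does not match system grid")
    lam = thresholds.lam
    sab_l, sba_l = credibility_pair(sample, system.lower, thresholds)
    sab_u, sba_u = credibility_pair(sample, system.upper, thresholds)
    pess = pessimistic_from_sigmas(sab_l, sab_u, lam)
    opti = optimistic_from_sigmas(sab_l, sba_l, sab_u, sba_u, lam)
    rel_l = relation(sab_l, sba_l, lam)
    rel_u = relation(sab_u, sba_u, lam)

    if pess != opti:
        reason = Reason.INCOMPARABLE
    elif Relation.INDIFFERENT in (rel_l, rel_u):
        reason = Reason.INDIFFERENT_BOUNDARY
    elif pess == Category.CAT_A:
        reason = Reason.IN_CAT_A
    elif pess == Category.CAT_B:
        reason = Reason.CAT_B
    else:
        reason = Reason.CAT_C
    verdict = Verdict.AUTHENTIC if reason == Reason.IN_CAT_A else Verdict.LQC

    return ClassificationResult(
        sample_id=sample.sample_id,
        wavelengths=sample.wavelengths,
        absorbances=sample.absorbances,
        pessimistic=pess,
        optimistic=opti,
        relation_lower=rel_l,
        relation_upper=rel_u,
        sigma_ab_lower=sab_l,
        sigma_ba_lower=sba_l,
        sigma_ab_upper=sab_u,
        sigma_ba_upper=sba_u,
        verdict=verdict,
        reason=reason,
        truth_label=sample.truth_label,
        substance=sample.substance,
    )


def classify_batch(samples: Sequence[SpectralFingerprint], system: CategorySystem,
                   thresholds: ThresholdSet) -> list[ClassificationResult]:
    """Order-preserving classification of a batch sharing one wavelength grid."""
    if len(samples) == 0:
        raise ValueError("classify_batch requires at least one fingerprint")
    results = []
    for fp in samples:
        try:
            results.append(classify(fp, system, thresholds))
        except Exception as exc:
            raise type(exc)(f"sample {fp.sample_id!r}: {exc}") from exc
    return results


def confusion(results: Sequence[ClassificationResult],
              truth: Optional[Mapping[str, str]] = None) -> ConfusionCounts:
    """Confusion counts against ground truth (Authentic = positive class).

    ``truth`` maps sample_id to ``authentic``/``lqc``; when omitted, the truth
    labels carried on the results are used.  Samples with unknown or missing
    truth are excluded from the totals.
    """
    tp = tn = fp_ = fn = 0
    for res in results:
        if truth is not None:
            if res.sample_id not in truth:
                raise ValueError(f"no truth label for sample {res.sample_id!r}")
            label = truth[res.sample_id]
        else:
            label = res.truth_label
        if label not in ("authentic", "lqc"):
            continue
        positive = res.verdict == Verdict.AUTHENTIC
        if label == "authentic":
            tp, fn = tp + positive, fn + (not positive)
        else:
            fp_, tn = fp_ + positive, tn + (not positive)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp_, fn=fn)
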