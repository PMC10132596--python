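"""Tests for boundary learning and the Authentic/LQC verdict layer."""

import numpy as np
import pytest

from bsfsort import (
    Category,
    Reason,
    Relation,
    SpectralFingerprint,
    ThresholdSet,
    Verdict,
    build_category_system,
    classify,
    classify_batch,
    confusion,
)
from bsfsort.fingerprint import ConfusionCounts
from bsfsort.outranking import GridMismatchError

GRID2 = (240.0, 250.0)
GRID4 = (240.0, 250.0, 260.0, 270.0)


def fp(values, sid="s", grid=GRID4, truth=None):
    return SpectralFingerprint(sid, grid, values, truth_label=truth)


class TestBuildCategorySystem:
    def test_elementwise_min_max(self):
        reps = [fp(v, grid=GRID2) for v in
                ([1.0, 0.6], [0.9, 0.7], [1.1, 0.65])]
        with pytest.warns(UserWarning, match="replicate"):
            system = build_category_system(reps)
        assert system.lower_boundary == (0.9, 0.6)
        assert system.upper_boundary == (1.1, 0.7)

    def test_widening_applies_intrinsic_range(self):
        reps = [fp(v, grid=GRID2) for v in
                ([1.0, 0.6], [0.9, 0.7], [1.1, 0.65])]
        with pytest.warns(UserWarning):
            system = build_category_system(reps, widen_fraction=0.10)
        assert system.lower_boundary == pytest.approx((0.81, 0.54))
        assert system.upper_boundary == pytest.approx((1.21, 0.77))

    def test_upper_capped_at_saturation(self):
        reps = [fp([1.9, 0.6], grid=GRID2), fp([1.95, 0.7], grid=GRID2),
                fp([1.8, 0.5], grid=GRID2), fp([1.85, 0.55], grid=GRID2),
                fp([1.99, 0.65], grid=GRID2)]
        system = build_category_system(reps, widen_fraction=0.10)
        assert system.upper_boundary[0] == 2.0

    def test_single_replicate_is_degenerate(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError,
                                                      match="degenerate"):
            build_category_system([fp([1.0, 0.6], grid=GRID2)])

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_category_system([])
        reps = [fp([1.0, 0.6], grid=GRID2), fp([1.0, 0.6, 0.5, 0.4])]
        with pytest.raises(GridMismatchError):
            build_category_system(reps)


class TestClassify:
    def test_sample_inside_band_is_authentic(self, ref_system, ref_thresholds):
        res = classify(fp([0.907, 0.584, 0.56, 0.478], "3"), ref_system,
                       ref_thresholds)
        assert res.verdict == Verdict.AUTHENTIC
        assert res.reason == Reason.IN_CAT_A
        assert res.pessimistic == res.optimistic == Category.CAT_A

    def test_flat_low_sample_is_lqc(self, ref_system, ref_thresholds):
        res = classify(fp([0.15, 0.099, 0.083, 0.077], "25"), ref_system,
                       ref_thresholds)
        assert res.verdict == Verdict.LQC
        assert res.reason == Reason.CAT_B

    def test_boundary_indifference_blocks_authentic_at_low_cut(
            self, ref_system, ref_thresholds):
        """A borderline authentic sample becomes indifferent to the lower
        boundary once the cut drops below its reverse credibility (0.80)."""
        sample = fp([0.714, 0.45, 0.474, 0.412], "13")
        res = classify(sample, ref_system, ref_thresholds.replace(lam=0.75))
        assert res.pessimistic == res.optimistic == Category.CAT_A
        assert res.relation_lower == Relation.INDIFFERENT
        assert res.verdict == Verdict.LQC
        assert res.reason == Reason.INDIFFERENT_BOUNDARY

    def test_disagreeing_procedures_mean_incomparable(self, ref_system,
                                                      ref_thresholds):
        res = classify(fp([0.776, 0.532, 0.439, 0.365], "1"), ref_system,
                       ref_thresholds)
        assert res.pessimistic != res.optimistic
        assert res.reason == Reason.INCOMPARABLE
        assert res.verdict == Verdict.LQC

    def test_grid_mismatch_rejected(self, ref_system, ref_thresholds):
        with pytest.raises(GridMismatchError):
            classify(fp([1.0, 0.6], grid=GRID2), ref_system, ref_thresholds)


class TestClassifyBatch:
    def test_validation_batch_counts(self, validation_set, ref_system,
                                     ref_thresholds):
        results = classify_batch(validation_set, ref_system, ref_thresholds)
        verdicts = [r.verdict for r in results]
        assert verdicts.count(Verdict.AUTHENTIC) == 4
        assert verdicts.count(Verdict.LQC) == 46

    def test_calibration_batch_counts(self, calibration_set, ref_system,
                                      ref_thresholds):
        results = classify_batch(calibration_set, ref_system, ref_thresholds)
        verdicts = [r.verdict for r in results]
        assert verdicts.count(Verdict.AUTHENTIC) == 4
        assert verdicts.count(Verdict.LQC) == 21

    def test_empty_batch_rejected(self, ref_system, ref_thresholds):
        with pytest.raises(ValueError):
            classify_batch([], ref_system, ref_thresholds)

    def test_errors_carry_sample_context(self, ref_system, ref_thresholds):
        batch = [fp([0.9, 0.6, 0.6, 0.5], "ok"),
                 fp([1.0, 0.6], sid="bad-grid", grid=GRID2)]
        with pytest.raises(GridMismatchError, match="bad-grid"):
            classify_batch(batch, ref_system, ref_thresholds)


class TestConfusion:
    def test_counts_against_explicit_truth(self, validation_set, ref_system,
                                           ref_thresholds):
        results = classify_batch(validation_set, ref_system, ref_thresholds)
        truth = {r.sample_id: r.truth_label for r in results}
        counts = confusion(results, truth)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (4, 46, 0, 0)
        assert counts.n_total == 50

    def test_single_misclassified_authentic_counts_as_fn(
            self, validation_set, ref_system, ref_thresholds):
        results = classify_batch(validation_set, ref_system,
                                 ref_thresholds.replace(lam=0.75))
        counts = confusion(results)
        assert (counts.fp, counts.fn) == (0, 1)

    def test_unknown_truth_excluded(self, ref_system, ref_thresholds):
        batch = [fp([0.9, 0.6, 0.6, 0.5], "a", truth="authentic"),
                 fp([0.9, 0.6, 0.6, 0.5], "b", truth="unknown"),
                 fp([0.9, 0.6, 0.6, 0.5], "c")]
        counts = confusion(classify_batch(batch, ref_system, ref_thresholds))
        assert counts.n_total == 1

    def test_missing_truth_id_rejected(self, ref_system, ref_thresholds):
        results = classify_batch([fp([0.9, 0.6, 0.6, 0.5], "a")],
                                 ref_system, ref_thresholds)
        with pytest.raises(ValueError, match="truth"):
            confusion(results, {"other": "authentic"})

    def test_empty_results_all_zero(self):
        counts = confusion([])
        assert counts == ConfusionCounts(0, 0, 0, 0)
        assert counts.n_total == 0


class TestVerdictInvariants:
    def test_authentic_requires_both_procedures_cat_a(
            self, validation_set, ref_system, ref_thresholds):
        for lam in (0.6, 0.75, 0.85, 0.95):
            results = classify_batch(validation_set, ref_system,
                                     ref_thresholds.replace(lam=lam))
            for res in results:
                if res.verdict == Verdict.AUTHENTIC:
                    assert res.pessimistic == res.optimistic == Category.CAT_A
                    assert Relation.INDIFFERENT not in (res.relation_lower,
                                                        res.relation_upper)
                if res.pessimistic != res.optimistic:
                    assert res.reason == Reason.INCOMPARABLE

    def test_verdicts_invariant_under_criterion_permutation(
            self, validation_set, ref_system, ref_thresholds):
        """Relabeling which column carries which wavelength (sample, boundaries
        and weights permuted together) cannot change any verdict."""
        perm = [2, 0, 3, 1]
        system = type(ref_system)(
            ref_system.wavelengths,
            tuple(ref_system.lower_boundary[i] for i in perm),
            tuple(ref_system.upper_boundary[i] for i in perm))
        baseline = classify_batch(validation_set, ref_system, ref_thresholds)
        permuted_batch = [
            SpectralFingerprint(s.sample_id, s.wavelengths,
                                tuple(s.absorbances[i] for i in perm),
                                truth_label=s.truth_label)
            for s in validation_set]
        permuted = classify_batch(permuted_batch, system, ref_thresholds)
        assert [r.verdict for r in baseline] == [r.verdict for r in permuted]

    def test_raising_veto_never_flips_interior_authentic_to_lqc(
            self, ref_system, ref_thresholds):
        rng = np.random.default_rng(7)
        lo, hi = np.asarray(ref_system.lower), np.asarray(ref_system.upper)
        p = ref_thresholds.p
        for _ in range(50):
            values = rng.uniform(lo + p, hi - p)
            sample = fp(values, "interior")
            small = classify(sample, ref_system, ref_thresholds)
            assert small.verdict == Verdict.AUTHENTIC
            for v in (0.15, 0.3, 0.8):
                bigger = classify(sample, ref_system,
                                  ref_thresholds.replace(v=v))
                assert bigger.verdict == Verdict.AUTHENTIC
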