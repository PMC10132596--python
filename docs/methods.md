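# Methods

## Model

A medication sample is represented by its spectral fingerprint: transmitted
UV absorbance (AU, on a saturating 0–2 instrument scale; 0 = transparent,
2 = opaque) at an ordered grid of wavelengths. For the bundled Praziquantel
data the grid is 240/250/260/270 nm — the stretch of the drug's UV response
reachable with inexpensive, long-lived LEDs. Each wavelength is one criterion
of an ELECTRE TRI-B sorting problem with two boundary profiles delimiting
three ordered categories, CAT-B < CAT-A < CAT-C, of which CAT-A is the
authentic band.

The indices follow the canonical ELECTRE TRI-B definitions. For alternative
*a* and reference *b* with absorbance *g_j*:

- partial concordance
  `c_j = 1` if `g_j(a) ≥ g_j(b) − q`, `0` if `g_j(a) ≤ g_j(b) − p`, else
  `(g_j(a) − (g_j(b) − p)) / (p − q)`;
- partial discordance
  `d_j = 0` if deficit ≤ p, `1` if deficit ≥ v, else `(deficit − p)/(v − p)`;
- global concordance `C = Σ w_j c_j` with positive weights summing to 1;
- credibility `σ = C · Π_{j: d_j > C} (1 − d_j)/(1 − C)`; any `d_j = 1`
  forces `σ = 0`, and σ ≤ C always.

Outranking is non-strict: it holds iff σ ≥ λ. The pessimistic procedure
scans profiles downward (outrank the upper profile → CAT-C; else the lower →
CAT-A; else CAT-B); the optimistic procedure scans upward (first profile that
strictly outranks the sample caps its category). Absorbance is maximizing for
both profiles; deviations below the lower and above the upper boundary are
handled symmetrically by the two profiles.

**Verdict mapping.** Authentic ⇔ both procedures assign CAT-A *and* the
sample is indifferent to neither boundary. Incomparability (procedure
disagreement) and indifference both map to LQ/C. Indifference must block the
Authentic verdict: a borderline genuine sample just above the lower boundary
has σ(sample, lower) = 1 but σ(lower, sample) = 0.80, so once λ drops to or
below 0.80 the boundary *also* outranks the sample and the verdict flips to
LQ/C — exactly the observed low-cut false negative. Reason codes record
incomparability first, then indifference, then the agreed category.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| q (AU) | indifference threshold | 0 | learned min/max boundaries already absorb replicate noise |
| p (AU) | preference threshold | 0.05 | calibrated on the 25-sample labeled batch |
| v (AU) | veto threshold | 0.10 | calibrated; a single deficit ≥ v annihilates credibility |
| λ | credibility cut | 0.85 | operator-chosen evidence requirement; not calibrated |
| w_j | criterion weights | equal (1/k) | no wavelength is privileged |
| widen_fraction | intrinsic-range widening | 0 | 0.10 reproduces the ±10% intrinsic-boundary convention |

Thresholds are scalars broadcast to every criterion and both profiles.
λ ≤ 0.5 is admitted (the sensitivity sweep covers [0, 1]) but warns, since an
outranking supported by less than half the weighted evidence is not
meaningful. Calibration searches p ∈ {0, 0.01, …, 0.20} ×
v ∈ {0.01, …, 0.30} by default, keeping only admissible pairs v > p ≥ q,
minimizing fp + fn (weights configurable), ties broken toward smaller v then
smaller p — the strictest zero-error system. On the bundled calibration batch
that strictest optimum is (p=0, v=0.01); the operating pair (0.05, 0.10) also
achieves zero errors and tolerates more preparation variability.

## Numerical conventions

- Equality conventions: with q = 0, a sample exactly on a boundary value has
  full concordance (`value ≥ reference − q`); a deficit of exactly v vetoes.
  Both are the continuous limits of the interpolants.
- Degenerate p = q: concordance becomes a step at deficit q.
- σ ≥ λ uses exact floating-point comparison, no epsilon — reproducible, but
  knife-edge λ values (e.g. λ exactly equal to a sample's σ) behave exactly
  as written.
- Input absorbances are used as recorded, without rounding; values outside
  [0, 2] are rejected (strict mode) or clipped with a warning (lenient mode),
  matching a saturating instrument.
- All scores are clipped to [0, 1]; near-degenerate threshold gaps divide to
  ±inf before clipping, which is silenced deliberately.

## Synthetic data

`generate_authentic` draws replicate fingerprints around a mean profile with
per-wavelength spread, either uniform (mean ± half-range) or truncated
normal, clipped to [0, 2]; the default spec uses the recorded Praziquantel
replicate mean with half-ranges equal to mean − lower boundary, so the
elementwise min/max of a large sample converge to the recorded boundary
profiles. This emulates the *concentration* variability of field-prepared
solutions — independent draws per wavelength — not the strong inter-wavelength
correlation a single dilution error would induce, nor instrument drift or
stray-light artifacts. `generate_contaminant` draws random convex mixtures of
monotone exponential decays and single Gaussian peaks, a synthetic stand-in
for physical proxy substances spanning flat-low (salts), saturating and
peaked spectral shapes; it makes no attempt at chromophore-level realism.
Passing end-to-end tests on these data therefore demonstrate the sorting
machinery and calibration logic, not real-world spectral coverage.

Generation is a pure function of (spec, n, seed); every synthetic batch
records its seed.

## Problem sizes and determinism

Everything outside `generate_*` is deterministic. The test suite uses 1000
randomized instances for the engine-vs-oracle equivalence check (tolerance
1e-12), 200 randomized samples for the veto property, 40 interior samples ×
15 cut levels for the sandwich property, and an end-to-end synthetic run with
300 boundary replicates plus 50-per-class calibration and held-out batches —
sizes chosen to exercise the extremes of the generator while keeping the
suite fast.

## Known limitations

- Two profiles / three categories only; a separate "low-quality" band between
  CAT-B and CAT-A (to distinguish adulterated from outright counterfeit
  product) is not modeled, though the indifference reason code already
  identifies those samples.
- Per-criterion or per-profile threshold vectors are not supported; the
  scalar broadcast mirrors how the reference study operated.
- The recorded boundary profiles are rounded to two decimals; with them, the
  borderline authentic sample outranks the lower boundary with σ = 1 exactly,
  so no false negative can appear at high λ < 1. A high-cut flip would
  require unrounded boundary values lying above some of the sample's
  absorbances; the package documents rather than simulates this.
- No concentration estimation (Beer–Lambert), mixture deconvolution, ROC
  analysis or threshold confidence intervals.
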