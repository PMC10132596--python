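"""Bundled Praziquantel reference data and a synthetic fingerprint generator.

The reference data come from a laboratory proof-of-concept on Praziquantel,
an anthelmintic essential for treating neglected tropical diseases: CAT-A
boundary profiles learned from 15 replicate authentic preparations, the
calibrated uncertainty thresholds, a 25-sample labeled calibration batch, and
a 50-sample blinded validation batch of authentic, proxy low-quality, and
counterfeit preparations measured at 240/250/260/270 nm.  Values are embedded
exactly as recorded.

The synthetic generator emulates two things the reference data cannot ship:
the raw replicate fingerprints behind the learned boundaries (only their
min/mean/max survive), and an open-ended family of contaminant spectra.
Authentic replicates are drawn around a mean profile with per-wavelength
spread (uniform half-range or truncated normal), mimicking the concentration
variability of field-prepared solutions.  Contaminants are synthetic stand-ins
for physical proxy substances: random mixtures of monotone exponential decays
and single Gaussian peaks, spanning the qualitative shapes seen in practice
(flat-low salts, saturating aromatics, peaked absorbers).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .outranking import (
    ABSORBANCE_MAX,
    ABSORBANCE_MIN,
    CategorySystem,
    GridMismatchError,
    SpectralFingerprint,
    ThresholdSet,
)

__all__ = [
    "REFERENCE_WAVELENGTHS",
    "SyntheticSpec",
    "default_authentic_spec",
    "generate_authentic",
    "generate_contaminant",
    "generate_mixture",
    "reference_dataset",
    "validation_reported_verdicts",
]

#: Wavelength grid (nm) of the Praziquantel reference fingerprints.
REFERENCE_WAVELENGTHS: tuple[float, ...] = (240.0, 250.0, 260.0, 270.0)

# Boundary profiles of the authentic band: elementwise min (lower) and max
# (upper) over 15 replicate authentic preparations; the mean is informational.
_REF_LOWER = (0.71, 0.44, 0.46, 0.40)
_REF_MEAN = (0.97, 0.62, 0.63, 0.54)
_REF_UPPER = (1.22, 0.79, 0.80, 0.68)

# Calibrated uncertainty parameters (shared across criteria and boundaries).
_REF_Q, _REF_P, _REF_V, _REF_LAM = 0.0, 0.05, 0.10, 0.85

# 25-sample calibration batch: (id, a240, a250, a260, a270, substance).
# Pure Praziquantel rows are authentic; everything else (including
# adulterated mixtures) is low-quality/counterfeit.
_CALIBRATION_ROWS = (
    ("1", 0.471, 0.91, 1.779, 1.485, "Phenylboronic Acid"),
    ("2", 0.558, 0.379, 0.373, 0.318, "Azithromycin & Praziquantel"),
    ("3", 1.51, 0.324, 0.153, 0.136, "Sodium Nitrate"),
    ("4", 0.714, 0.45, 0.474, 0.412, "Praziquantel"),
    ("5", 0.15, 0.099, 0.083, 0.077, "Myristic Acid"),
    ("6", 0.61, 0.611, 0.904, 0.889, "4-chlorobenzyl Alcohol"),
    ("7", 2.0, 2.0, 2.0, 2.0, "4-biphenyl methanol"),
    ("8", 0.393, 0.331, 0.227, 0.173, "Sodium Sulfite"),
    ("9", 0.322, 0.246, 0.163, 0.135, "Sodium Chloride"),
    ("10", 0.339, 0.252, 0.164, 0.142, "Sodium Bicarbonate"),
    ("11", 0.776, 0.532, 0.439, 0.365, "Praziquantel & Ivermectin"),
    ("12", 0.447, 0.328, 0.183, 0.16, "Magnesium Sulfate"),
    ("13", 2.0, 1.688, 2.0, 2.0, "methyl-triphenylphosphonium bromide"),
    ("14", 0.862, 0.565, 0.522, 0.448, "Praziquantel"),
    ("15", 0.393, 0.278, 0.147, 0.123, "Sodium Sulfate"),
    ("16", 0.357, 0.194, 0.203, 0.205, "Sweet n' Low"),
    ("17", 0.423, 0.294, 0.152, 0.129, "Sugar"),
    ("18", 0.414, 0.288, 0.143, 0.12, "Splenda"),
    ("19", 0.887, 0.566, 0.516, 0.439, "Praziquantel"),
    ("20", 0.472, 0.321, 0.199, 0.198, "Coffee"),
    ("21", 0.434, 0.287, 0.128, 0.104, "Sugar"),
    ("22", 0.678, 0.317, 0.349, 0.364, "Sweet n' Low"),
    ("23", 0.43, 0.281, 0.136, 0.114, "Splenda"),
    ("24", 1.253, 1.153, 1.059, 0.972, "Pepper"),
    ("25", 0.907, 0.584, 0.56, 0.478, "Praziquantel"),
)

# 50-sample blinded validation batch:
# (id, a240, a250, a260, a270, substance, reported verdict "A"/"LQ/C").
_VALIDATION_ROWS = (
    ("1", 0.776, 0.532, 0.439, 0.365, "Praziquantel & Ivermectin (proxy LQ)", "LQ/C"),
    ("2", 0.339, 0.252, 0.164, 0.142, "Sodium Bicarbonate", "LQ/C"),
    ("3", 0.907, 0.584, 0.56, 0.478, "Praziquantel", "A"),
    ("4", 0.393, 0.278, 0.147, 0.123, "Sodium Sulfate", "LQ/C"),
    ("5", 0.43, 0.281, 0.136, 0.114, "Splenda", "LQ/C"),
    ("6", 0.322, 0.246, 0.163, 0.135, "Sodium Chloride", "LQ/C"),
    ("7", 0.862, 0.565, 0.522, 0.448, "Praziquantel", "A"),
    ("8", 0.678, 0.317, 0.349, 0.364, "Sweet n' Low", "LQ/C"),
    ("9", 0.43, 0.281, 0.136, 0.114, "Splenda", "LQ/C"),
    ("10", 2.0, 2.0, 2.0, 2.0, "4-biphenyl methanol", "LQ/C"),
    ("11", 0.678, 0.317, 0.349, 0.364, "Sweet n' Low", "LQ/C"),
    ("12", 1.253, 1.153, 1.059, 0.972, "Pepper", "LQ/C"),
    ("13", 0.714, 0.45, 0.474, 0.412, "Praziquantel", "A"),
    ("14", 0.393, 0.278, 0.147, 0.123, "Sodium Sulfate", "LQ/C"),
    ("15", 2.0, 1.688, 2.0, 2.0, "methyl-triphenylphosphonium bromide", "LQ/C"),
    ("16", 0.322, 0.246, 0.163, 0.135, "Sodium Chloride", "LQ/C"),
    ("17", 0.357, 0.194, 0.203, 0.205, "Sweet n' Low", "LQ/C"),
    ("18", 0.887, 0.566, 0.516, 0.439, "Praziquantel", "A"),
    ("19", 0.434, 0.287, 0.128, 0.104, "Sugar", "LQ/C"),
    ("20", 0.471, 0.91, 1.779, 1.485, "Phenylboronic Acid", "LQ/C"),
    ("21", 0.423, 0.294, 0.152, 0.129, "Sugar", "LQ/C"),
    ("22", 1.12, 0.838, 0.272, 0.135, "Ivermectin", "LQ/C"),
    ("23", 0.888, 0.667, 0.238, 0.132, "Ivermectin", "LQ/C"),
    ("24", 1.51, 0.324, 0.153, 0.136, "Sodium Nitrate", "LQ/C"),
    ("25", 0.15, 0.099, 0.083, 0.077, "Myristic Acid", "LQ/C"),
    ("26", 0.15, 0.099, 0.083, 0.077, "Myristic Acid", "LQ/C"),
    ("27", 0.61, 0.611, 0.904, 0.889, "4-chlorobenzyl Alcohol", "LQ/C"),
    ("28", 0.447, 0.328, 0.183, 0.16, "Magnesium Sulfate", "LQ/C"),
    ("29", 0.423, 0.294, 0.152, 0.129, "Sugar", "LQ/C"),
    ("30", 0.472, 0.321, 0.199, 0.198, "Coffee", "LQ/C"),
    ("31", 0.414, 0.288, 0.143, 0.12, "Splenda", "LQ/C"),
    ("32", 0.357, 0.194, 0.203, 0.205, "Sweet n' Low", "LQ/C"),
    ("33", 1.245, 0.921, 0.273, 0.117, "Ivermectin", "LQ/C"),
    ("34", 1.253, 1.153, 1.059, 0.972, "Pepper", "LQ/C"),
    ("35", 2.0, 1.688, 2.0, 2.0, "methyl-triphenylphosphonium bromide", "LQ/C"),
    ("36", 1.51, 0.324, 0.153, 0.136, "Sodium Nitrate", "LQ/C"),
    ("37", 0.471, 0.91, 1.779, 1.485, "Phenylboronic Acid", "LQ/C"),
    ("38", 0.414, 0.288, 0.143, 0.12, "Splenda", "LQ/C"),
    ("39", 1.68, 1.839, 1.282, 0.747, "Ivermectin", "LQ/C"),
    ("40", 2.0, 2.0, 2.0, 2.0, "4-biphenyl methanol", "LQ/C"),
    ("41", 0.393, 0.331, 0.227, 0.173, "Sodium Sulfite", "LQ/C"),
    ("42", 0.393, 0.331, 0.227, 0.173, "Sodium Sulfite", "LQ/C"),
    ("43", 0.434, 0.287, 0.128, 0.104, "Sugar", "LQ/C"),
    ("44", 0.472, 0.321, 0.199, 0.198, "Coffee", "LQ/C"),
    ("45", 0.558, 0.379, 0.373, 0.318, "Azithromycin & Praziquantel (Proxy LQ)", "LQ/C"),
    ("46", 0.776, 0.532, 0.439, 0.365, "Praziquantel & Ivermectin (proxy LQ)", "LQ/C"),
    ("47", 0.61, 0.611, 0.904, 0.889, "4-chlorobenzyl Alcohol", "LQ/C"),
    ("48", 0.339, 0.252, 0.164, 0.142, "Sodium Bicarbonate", "LQ/C"),
    ("49", 1.101, 0.829, 0.259, 0.124, "Ivermectin", "LQ/C"),
    ("50", 0.447, 0.328, 0.183, 0.16, "Magnesium Sulfate", "LQ/C"),
)


def _truth_from_substance(substance: str) -> str:
    # Only a pure Praziquantel preparation is authentic; mixtures are proxy LQ.
    return "authentic" if substance == "Praziquantel" else "lqc"


def _rows_to_fingerprints(rows) -> list[SpectralFingerprint]:
    out = []
    for row in rows:
        sid, a240, a250, a260, a270, substance = row[:6]
        out.append(SpectralFingerprint(
            sample_id=sid,
            wavelengths=REFERENCE_WAVELENGTHS,
            absorbances=(a240, a250, a260, a270),
            substance=substance,
            truth_label=_truth_from_substance(substance),
        ))
    return out


def reference_dataset(name: str):
    """Return one of the bundled Praziquantel reference objects.

    ``boundaries``
        :class:`CategorySystem` with the learned lower/upper CAT-A profiles.
    ``thresholds``
        :class:`ThresholdSet` with q=0, p=0.05, v=0.10, lam=0.85 and equal
        criterion weights.
    ``calibration_set``
        The 25 labeled fingerprints used to train (p, v).
    ``validation_set``
        The 50 labeled fingerprints of the blinded validation batch.
    """
    if name == "boundaries":
        return CategorySystem(REFERENCE_WAVELENGTHS, _REF_LOWER, _REF_UPPER)
    if name == "thresholds":
        return ThresholdSet(q=_REF_Q, p=_REF_P, v=_REF_V, lam=_REF_LAM)
    if name == "calibration_set":
        return _rows_to_fingerprints(_CALIBRATION_ROWS)
    if name == "validation_set":
        return _rows_to_fingerprints(_VALIDATION_ROWS)
    raise KeyError(
        f"unknown reference dataset {name!r}; expected one of "
        "'boundaries', 'thresholds', 'calibration_set', 'validation_set'")


def reference_mean_profile() -> tuple[float, ...]:
    """Mean absorbance of the 15 replicate authentic preparations."""
    return _REF_MEAN


def validation_reported_verdicts() -> dict[str, str]:
    """Recorded sorted category ("A" or "LQ/C") per validation sample id."""
    return {row[0]: row[6] for row in _VALIDATION_ROWS}


# ---------------------------------------------------------------------------
# synthetic generation

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for synthetic authentic replicate fingerprints.

    ``spread`` is the per-wavelength half-range (uniform model) or standard
    deviation (truncated-normal model) in AU; a scalar is broadcast over the
    grid.  Generation is a pure function of (spec, n): the seed lives in the
    spec, and all draws are clipped to the [0, 2] instrument scale.
    """

    wavelengths: tuple[float, ...]
    mean_profile: tuple[float, ...]
    spread: Union[float, tuple[float, ...]]
    noise_model: str = "uniform_range"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths",
                           tuple(float(x) for x in self.wavelengths))
        object.__setattr__(self, "mean_profile",
                           tuple(float(x) for x in self.mean_profile))
        if len(self.mean_profile) != len(self.wavelengths):
            raise ValueError("mean_profile length must match wavelengths")
        mean = np.asarray(self.mean_profile)
        if mean.min() < ABSORBANCE_MIN or mean.max() > ABSORBANCE_MAX:
            raise ValueError("mean_profile must lie within [0, 2]")
        spread = np.broadcast_to(np.asarray(self.spread, dtype=float),
                                 mean.shape)
        if np.any(spread < 0):
            raise ValueError("spread must be >= 0")
        if self.noise_model not in ("uniform_range", "truncated_normal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def spread_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.spread, dtype=float),
            (len(self.wavelengths),)).copy()


def default_authentic_spec(seed: int = 0) -> SyntheticSpec:
    """Spec emulating the replicate Praziquantel preparations.

    The mean profile is the recorded replicate mean; the uniform half-ranges
    are mean minus lower boundary, so elementwise min/max of a large sample
    converge to the recorded boundary profiles.
    """
    spread = tuple(round(m - lo, 6) for m, lo in zip(_REF_MEAN, _REF_LOWER))
    return SyntheticSpec(
        wavelengths=REFERENCE_WAVELENGTHS,
        mean_profile=_REF_MEAN,
        spread=spread,
        noise_model="uniform_range",
        seed=seed,
    )


def generate_authentic(spec: SyntheticSpec, n: int) -> list[SpectralFingerprint]:
    """Draw ``n`` synthetic authentic replicate fingerprints.

    Uniform model: mean ± spread per wavelength.  Truncated-normal model:
    Gaussian with sd = spread, clipped to the instrument scale.  Output is
    deterministic given the spec (including its seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(spec.seed)
    mean = np.asarray(spec.mean_profile)
    spread = spec.spread_array
    if spec.noise_model == "uniform_range":
        draws = rng.uniform(mean - spread, mean + spread, size=(n, mean.size))
    else:
        draws = rng.normal(mean, spread, size=(n, mean.size))
    draws = np.clip(draws, ABSORBANCE_MIN, ABSORBANCE_MAX)
    return [
        SpectralFingerprint(
            sample_id=f"auth-{i + 1:04d}",
            wavelengths=spec.wavelengths,
            absorbances=tuple(draws[i]),
            substance="synthetic authentic",
            truth_label="authentic",
        )
        for i in range(n)
    ]


def generate_contaminant(wavelengths: Sequence[float], n: int,
                         seed: int = 0) -> list[SpectralFingerprint]:
    """Draw ``n`` synthetic contaminant fingerprints.

    Each curve is a random convex mixture of a monotone exponential decay and
    a single Gaussian peak over the grid, clipped to [0, 2] — a synthetic
    stand-in for the physical proxy substances used in laboratory calibration.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be a strictly increasing grid of >= 2 points")
    span = wl[-1] - wl[0]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        amplitude = rng.uniform(0.05, 2.0)
        rate = rng.uniform(0.0, 6.0)
        decay = amplitude * np.exp(-rate * (wl - wl[0]) / span)
        height = rng.uniform(0.0, 2.0)
        center = rng.uniform(wl[0] - 0.5 * span, wl[-1] + 0.5 * span)
        width = rng.uniform(span / 8.0, span / 2.0)
        peak = height * np.exp(-0.5 * ((wl - center) / width) ** 2)
        mix = rng.uniform(0.0, 1.0)
        curve = np.clip(mix * decay + (1.0 - mix) * peak,
                        ABSORBANCE_MIN, ABSORBANCE_MAX)
        out.append(SpectralFingerprint(
            sample_id=f"cont-{i + 1:04d}",
            wavelengths=tuple(wl),
            absorbances=tuple(curve),
            substance="synthetic contaminant",
            truth_label="lqc",
        ))
    return out


def generate_mixture(base: SpectralFingerprint, contaminant: SpectralFingerprint,
                     fraction: float) -> SpectralFingerprint:
    """Adulterate ``base`` with ``contaminant`` at the given mass fraction.

    Elementwise convex combination of the two fingerprints; any nonzero
    fraction makes the product low-quality by definition.
    """
    if base.wavelengths != contaminant.wavelengths:
        raise GridMismatchError("mixture components must share a wavelength grid")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    mixed = (1.0 - fraction) * base.values + fraction * contaminant.values
    return SpectralFingerprint(
        sample_id=f"{base.sample_id}+{contaminant.sample_id}@{fraction:g}",
        wavelengths=base.wavelengths,
        absorbances=tuple(mixed),
        substance=f"{base.substance} + {contaminant.substance} ({fraction:g})",
        truth_label="lqc" if fraction > 0 else base.truth_label,
    )
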