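"""Reproducible synthetic SERS datasets for four tumor-cell-line classes.

Real SERS spectra of cell lysates mixed with aggregated silver
nanoparticles are proprietary to the measuring lab; this module emulates
their statistical structure so every downstream stage (preprocessing,
PCA, SVM, batch-wise validation) can be exercised and tested:

* four spectral classes built from a common table of Lorentzian bands at
  literature positions for cellular biomolecules (adenine ring modes at
  723 and 1339 cm^-1, carboxylate at 660 cm^-1, protein CN/amide bands,
  carbohydrate bands near 1000-1100 cm^-1, CH2/CH3 stretches at
  2923/2952 cm^-1);
* per-class multiplicative amplitude profiles that differ chiefly at
  660, 723, 900 and 1339 cm^-1 and in the CH-stretch/fingerprint balance
  — the classes remain highly similar overall, as real cell lysate
  spectra are;
* six independently prepared batches per class, with a per-(batch, band)
  log-normal amplitude factor emulating preparation-to-preparation
  enhancement variability;
* a per-spectrum random cubic background (residual excitation light),
  a shared dark level + slow drift, and additive Gaussian detector
  noise. The matching dark spectrum is returned alongside the data.

Random streams are split hierarchically (dataset -> class -> batch ->
spectrum) with :class:`numpy.random.SeedSequence`, so the same config and
seed reproduce the dataset bit for bit and changing ``n_per_batch`` does
not reshuffle other batches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .spectral_io import Spectrum, SpectrumSet

__all__ = [
    "BandTemplate",
    "GeneratorConfig",
    "default_class_templates",
    "generate_dataset",
    "chance_level_dataset",
    "DEFAULT_CLASS_LABELS",
]

DEFAULT_CLASS_LABELS = ("Capan-1", "HepG2", "MCF-7", "SK-Hep1")

# (center cm^-1, HWHM cm^-1, base amplitude in counts)
# Fingerprint bands use 10 cm^-1 HWHM, the broader CH-stretch envelope 20.
_DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (660.0, 10.0, 60.0),   # carboxylate
    (723.0, 10.0, 80.0),   # adenine ring breathing
    (800.0, 10.0, 45.0),   # CN stretch
    (900.0, 10.0, 55.0),   # protein
    (960.0, 10.0, 50.0),   # CN stretch
    (1030.0, 10.0, 55.0),  # carbohydrate
    (1080.0, 10.0, 65.0),  # carbohydrate
    (1289.0, 10.0, 50.0),  # amide III
    (1339.0, 10.0, 75.0),  # adenine
    (1450.0, 10.0, 85.0),  # CH2 deformation
    (1660.0, 10.0, 95.0),  # amide I
    (2923.0, 20.0, 120.0),  # CH2 stretch
    (2952.0, 20.0, 100.0),  # CH3 stretch
)

# Per-class multiplicative factors on the base amplitudes, one row per
# class in DEFAULT_CLASS_LABELS order, one column per band above.
# Contrasts are concentrated where the loading structure of the real data
# puts them: 660/900 up for Capan-1, adenine bands (723, 1339) down for
# HepG2, the CH/fingerprint balance down for MCF-7 (the class a first
# principal component separates), and 660/900 slightly down with 960 up
# for SK-Hep1. All other bands are shared, keeping the classes similar.
_DEFAULT_CLASS_AMPLITUDE = (
    (1.15, 1.00, 1.00, 1.12, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.05, 1.05),
    (1.00, 0.85, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 0.85, 1.00, 1.00, 1.00, 1.00),
    (1.05, 1.05, 1.05, 1.05, 1.05, 1.05, 1.05, 1.00, 1.05, 1.00, 1.00, 0.75, 0.75),
    (0.90, 1.00, 1.00, 0.95, 1.10, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
)


@dataclass(frozen=True)
class BandTemplate:
    """One Lorentzian band: center (cm^-1), HWHM (cm^-1), base amplitude."""

    center: float
    width: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError(f"band at {self.center}: width must be > 0")
        if self.base_amplitude < 0:
            raise ValidationError(
                f"band at {self.center}: base amplitude must be >= 0"
            )

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-height Lorentzian evaluated on the axis."""
        return 1.0 / (1.0 + ((wavenumbers - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one reproducible synthetic dataset.

    ``class_amplitude[k, m]`` multiplies band ``m``'s base amplitude for
    class ``k``. ``batch_amp_sd`` is the relative standard deviation of a
    mean-one log-normal factor drawn per (batch, band).
    ``baseline_coeffs_sd`` are the standard deviations of the random
    polynomial background coefficients (constant..cubic, counts, on an
    axis normalized to [0, 1]). ``dark_level`` / ``dark_drift_sd`` set
    the shared dark signal, ``noise_sd`` the per-channel Gaussian noise.
    """

    axis_start: float = 400.0
    axis_stop: float = 3100.0
    axis_step: float = 2.0
    bands: tuple[BandTemplate, ...] = tuple(
        BandTemplate(*b) for b in _DEFAULT_BANDS
    )
    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS
    class_amplitude: tuple[tuple[float, ...], ...] = _DEFAULT_CLASS_AMPLITUDE
    n_batches: int = 6
    n_per_batch: int = 16
    batch_amp_sd: float = 0.03
    baseline_coeffs_sd: tuple[float, float, float, float] = (30.0, 30.0, 30.0, 30.0)
    dark_level: float = 100.0
    dark_drift_sd: float = 5.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.axis_start < self.axis_stop and self.axis_step > 0):
            raise ValidationError("axis must satisfy start < stop with step > 0")
        bands = tuple(
            b if isinstance(b, BandTemplate) else BandTemplate(*b)
            for b in self.bands
        )
        object.__setattr__(self, "bands", bands)
        amp = tuple(tuple(float(a) for a in row) for row in self.class_amplitude)
        object.__setattr__(self, "class_amplitude", amp)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if len(amp) != len(self.class_labels):
            raise ValidationError(
                "class_amplitude must have one row per class label"
            )
        for row in amp:
            if len(row) != len(bands):
                raise ValidationError(
                    "class_amplitude rows must have one entry per band"
                )
            if any(a < 0 for a in row):
                raise ValidationError("class_amplitude entries must be >= 0")
        if self.n_batches < 2:
            raise ValidationError("n_batches must be >= 2")
        if self.n_per_batch < 1:
            raise ValidationError("n_per_batch must be >= 1")
        for name in ("batch_amp_sd", "dark_drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        sds = tuple(float(s) for s in self.baseline_coeffs_sd)
        if len(sds) > 4 or any(s < 0 for s in sds):
            raise ValidationError(
                "baseline_coeffs_sd must be <= 4 non-negative values (degree <= 3)"
            )
        object.__setattr__(self, "baseline_coeffs_sd", sds)
        for b in bands:
            if not (self.axis_start <= b.center <= self.axis_stop):
                raise ValidationError(
                    f"band center {b.center} cm^-1 lies outside the axis "
                    f"[{self.axis_start}, {self.axis_stop}]"
                )

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def axis(self) -> np.ndarray:
        n = int(np.floor((self.axis_stop - self.axis_start) / self.axis_step + 0.5)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


def default_class_templates() -> GeneratorConfig:
    """Default four-class configuration.

    The four amplitude rows are distinct and differ chiefly at 660, 723,
    900 and 1339 cm^-1 and in the CH-stretch-to-fingerprint balance;
    the "MCF-7" row is the extreme of the four in CH/fingerprint area
    ratio, mirroring the contrast that a first principal component of
    such data captures.
    """
    return GeneratorConfig()


def _lognormal_factors(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Mean-one log-normal factors with relative standard deviation ``sd``."""
    if sd == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(sd * sd))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _random_polynomial(
    rng: np.random.Generator, t: np.ndarray, coeff_sds: Sequence[float]
) -> np.ndarray:
    coeffs = np.array([rng.normal(0.0, s) if s > 0 else 0.0 for s in coeff_sds])
    return sum(c * t**k for k, c in enumerate(coeffs))


def generate_dataset(config: GeneratorConfig) -> tuple[SpectrumSet, Spectrum]:
    """Generate the labeled dataset plus its matching dark spectrum.

    Each spectrum is ``sum_m A[k, m] * g[k, b, m] * L_m(nu) + poly_j(nu)
    + dark_level + drift(nu) + eps`` with ``L_m`` a unit-height
    Lorentzian, ``g`` the per-(batch, band) log-normal factor, ``poly_j``
    a per-spectrum random cubic background and ``eps`` i.i.d. Gaussian
    noise. The dark spectrum shares ``dark_level`` and ``drift`` but has
    its own noise draw, emulating one dark acquisition per session.
    """
    axis = config.axis()
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    profiles = np.vstack([b.profile(axis) for b in config.bands])
    base_amp = np.array([b.base_amplitude for b in config.bands])
    class_amp = np.asarray(config.class_amplitude, dtype=float)

    root = np.random.SeedSequence(config.seed)
    data_ss, dark_ss = root.spawn(2)

    dark_rng = np.random.default_rng(dark_ss)
    drift = _random_polynomial(dark_rng, t, (config.dark_drift_sd,) * 4)
    dark_noise = dark_rng.normal(0.0, config.noise_sd, axis.size) if config.noise_sd else 0.0
    dark = Spectrum(
        wavenumbers=axis,
        intensities=config.dark_level + drift + dark_noise,
        sample_id="dark",
    )

    spectra: list[Spectrum] = []
    class_streams = data_ss.spawn(config.n_classes)
    for k, label in enumerate(config.class_labels):
        batch_streams = class_streams[k].spawn(config.n_batches)
        for b in range(config.n_batches):
            children = batch_streams[b].spawn(config.n_per_batch + 1)
            batch_rng = np.random.default_rng(children[0])
            g = _lognormal_factors(batch_rng, config.batch_amp_sd, len(config.bands))
            band_signal = (class_amp[k] * base_amp * g) @ profiles
            for j in range(config.n_per_batch):
                rng = np.random.default_rng(children[j + 1])
                background = _random_polynomial(rng, t, config.baseline_coeffs_sd)
                noise = (
                    rng.normal(0.0, config.noise_sd, axis.size)
                    if config.noise_sd
                    else 0.0
                )
                spectra.append(
                    Spectrum(
                        wavenumbers=axis,
                        intensities=band_signal
                        + background
                        + config.dark_level
                        + drift
                        + noise,
                        sample_id=f"{label}_b{b + 1}_s{j + 1}",
                        cell_line=label,
                        batch=b + 1,
                    )
                )
    return SpectrumSet(spectra, axis), dark


def chance_level_dataset(config: GeneratorConfig) -> tuple[SpectrumSet, Spectrum]:
    """Negative control: identical generation but with no class signal.

    Every class amplitude row is replaced by the across-class mean row,
    so labels carry no information and any downstream classifier should
    perform at chance (1/K).
    """
    amp = np.asarray(config.class_amplitude, dtype=float)
    mean_row = tuple(float(a) for a in amp.mean(axis=0))
    null_config = replace(
        config, class_amplitude=tuple(mean_row for _ in config.class_labels)
    )
    return generate_dataset(null_config)
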