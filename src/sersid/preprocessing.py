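"""Spectral preprocessing chain for SERS spectra.

The chain applied to every spectrum, in order:

1. **Dark subtraction** — subtract a Whittaker-smoothed dark spectrum,
   removing dark current and the constant detector bias.
2. **Background correction** — estimate the slowly varying background
   (residual excitation light / fluorescence) by asymmetric least
   squares: iterated Whittaker smoothing in which points above the
   current fit get a small weight ``p`` and points below get ``1 - p``,
   so the fit tracks the lower envelope beneath the Raman bands.
3. **Cropping** — keep the fingerprint region [500, 1800] cm^-1 and the
   CH-stretch region [2828, 3028] cm^-1 (closed intervals) and
   concatenate them.
4. **Area normalization** — divide by the integrated absolute intensity
   (trapezoidal channel widths, computed per region so the gap between
   regions carries no weight), making the retained area exactly 1 and
   the result invariant to laser-power / collection-efficiency scaling.

The Whittaker smoother minimizes ``sum_i w_i (y_i - z_i)^2 +
lambda * sum (D^d z)^2`` with ``D^d`` the d-th order finite difference;
the normal equations ``(W + lambda D'D) z = W y`` are symmetric positive
definite and banded with bandwidth ``d``, solved with a banded Cholesky
factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sparse

from .errors import NumericalError, ValidationError
from .spectral_io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "whittaker_smooth",
    "estimate_baseline",
    "subtract_dark",
    "crop_and_combine",
    "area_normalize",
    "preprocess_set",
    "trapezoid_weights",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    lambda_baseline
        Whittaker penalty for the baseline estimate; larger = stiffer
        baseline. Dimensionless (scales with intensity^0 but with the
        channel grid). Default 1e5 for a ~2 cm^-1 grid.
    asymmetry_p
        Weight assigned to points above the current baseline fit,
        0 < p < 0.5. Small p pushes the fit under the peaks.
    diff_order_d
        Order of the finite-difference penalty (1-3). d=2 leaves straight
        lines unpenalized.
    max_iter, tol
        Reweighting iteration cap and the maximum absolute change in the
        weight vector accepted as converged (0 = exact fixpoint).
    lambda_dark
        Penalty used to smooth the dark spectrum (symmetric weights; a
        dark spectrum has no peaks to protect, so it can be much stiffer
        than the baseline penalty — the default suppresses dark shot
        noise by more than an order of magnitude).
    low_region, high_region
        Closed wavenumber intervals retained by cropping, in cm^-1.
    """

    lambda_baseline: float = 1e5
    asymmetry_p: float = 0.01
    diff_order_d: int = 2
    max_iter: int = 20
    tol: float = 0.0
    lambda_dark: float = 1e7
    low_region: tuple[float, float] = (500.0, 1800.0)
    high_region: tuple[float, float] = (2828.0, 3028.0)

    def __post_init__(self) -> None:
        if not self.lambda_baseline > 0:
            raise ValidationError("lambda_baseline must be > 0")
        if not 0 < self.asymmetry_p < 0.5:
            raise ValidationError("asymmetry_p must lie in (0, 0.5)")
        if self.diff_order_d not in (1, 2, 3):
            raise ValidationError("diff_order_d must be 1, 2 or 3")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValidationError("tol must be >= 0")
        if not self.lambda_dark > 0:
            raise ValidationError("lambda_dark must be > 0")
        lo, hi = self.low_region, self.high_region
        if not (lo[0] < lo[1] and hi[0] < hi[1] and lo[1] < hi[0]):
            raise ValidationError(
                "crop regions must be ordered, non-empty and non-overlapping"
            )


_PENALTY_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _penalty_upper_bands(n: int, d: int) -> np.ndarray:
    """Upper banded storage (scipy ``solveh_banded`` layout) of D'D."""
    key = (n, d)
    cached = _PENALTY_CACHE.get(key)
    if cached is not None:
        return cached
    D = sparse.identity(n, format="csr")
    for _ in range(d):
        D = D[1:] - D[:-1]
    P = (D.T @ D).todia()
    ab = np.zeros((d + 1, n))
    for k, off in enumerate(P.offsets):
        if off >= 0:
            ab[d - off, :] = P.data[k, :]
    _PENALTY_CACHE[key] = ab
    return ab


def whittaker_smooth(
    y: np.ndarray,
    weights: np.ndarray | None = None,
    lam: float = 1e5,
    d: int = 2,
) -> np.ndarray:
    """Penalized-least-squares (Whittaker) smoother.

    Returns the minimizer of ``sum w_i (y_i - z_i)^2 + lam * sum (D^d z)^2``
    via the banded SPD system ``(W + lam D'D) z = W y``. With ``lam = 0``
    and unit weights this is the identity; with very large ``lam`` and
    ``d = 2`` the result approaches the weighted least-squares line.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if d not in (1, 2, 3):
        raise ValidationError("difference order d must be 1, 2 or 3")
    if n < d + 2:
        raise ValidationError(f"need at least {d + 2} points for order-{d} penalty")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValidationError("weights must match y in length")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if not np.any(w > 0):
            raise NumericalError(
                "all smoothing weights are zero: the penalized system is singular"
            )
    if lam < 0:
        raise ValidationError("penalty lambda must be >= 0")
    ab = lam * _penalty_upper_bands(n, d)
    ab = np.array(ab)  # copy before adding the weight diagonal
    ab[d, :] += w
    try:
        return scipy.linalg.solveh_banded(ab, w * y, lower=False)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"singular or indefinite penalized system (lam={lam}, d={d}): {exc}"
        ) from None


def estimate_baseline(y: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate.

    Starts from unit weights, then iterates: smooth, set the weight of
    every channel above the fit to ``p`` and below to ``1 - p``, and
    re-solve, until the weight vector stops changing (or ``max_iter``).
    The returned vector is the baseline; subtract it from ``y`` to get
    the background-corrected spectrum.
    """
    y = np.asarray(y, dtype=float)
    p = config.asymmetry_p
    w = np.ones(y.size)
    z = y
    for _ in range(config.max_iter):
        z = whittaker_smooth(y, w, config.lambda_baseline, config.diff_order_d)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.max(np.abs(w_new - w)) <= config.tol:
            break
        w = w_new
    return z


def subtract_dark(y: Spectrum, dark: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Subtract a Whittaker-smoothed dark spectrum from ``y``.

    Smoothing the dark trace (symmetric unit weights) removes its shot
    noise so the subtraction does not inject extra noise while still
    removing the dark current and constant bias.
    """
    if y.wavenumbers.size != dark.wavenumbers.size or not np.array_equal(
        y.wavenumbers, dark.wavenumbers
    ):
        raise ValidationError(
            f"spectrum '{y.sample_id}' and dark spectrum are on different axes"
        )
    smoothed = whittaker_smooth(
        dark.intensities, None, config.lambda_dark, config.diff_order_d
    )
    return y.with_intensities(y.intensities - smoothed)


def crop_and_combine(s: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Crop to the fingerprint and CH regions and concatenate them.

    Both interval bounds are inclusive. The output records the two block
    lengths in ``segments`` so later integration treats them separately.
    """
    wn = s.wavenumbers
    low = (wn >= config.low_region[0]) & (wn <= config.low_region[1])
    high = (wn >= config.high_region[0]) & (wn <= config.high_region[1])
    if not low.any():
        raise ValidationError(
            f"spectrum '{s.sample_id}': no channels in the low-wavenumber "
            f"region {config.low_region}"
        )
    if not high.any():
        raise ValidationError(
            f"spectrum '{s.sample_id}': no channels in the high-wavenumber "
            f"region {config.high_region}"
        )
    n_low, n_high = int(low.sum()), int(high.sum())
    return replace(
        s,
        wavenumbers=np.concatenate([wn[low], wn[high]]),
        intensities=np.concatenate([s.intensities[low], s.intensities[high]]),
        segments=(n_low, n_high),
    )


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Channel integration widths so that ``sum(y * w) == trapezoid(y, x)``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two channels to integrate")
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    if x.size > 2:
        w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


def area_normalize_arrays(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    segments: Sequence[int] | None = None,
) -> np.ndarray:
    """Divide intensities by the total absolute trapezoidal area.

    When ``segments`` is given, integration weights are computed per
    contiguous block so the artificial jump between cropped regions
    contributes nothing.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    it = np.asarray(intensities, dtype=float)
    if segments is None:
        segments = (wn.size,)
    weights = np.concatenate(
        [trapezoid_weights(wn[lo:hi]) for lo, hi in Spectrum._segment_bounds(segments)]
    )
    area = float(np.sum(np.abs(it) * weights))
    if area <= 0.0:
        raise ValidationError("cannot area-normalize an all-zero spectrum")
    return it / area


def area_normalize(s: Spectrum) -> Spectrum:
    """L1 area normalization: total absolute area over the axis becomes 1."""
    try:
        out = area_normalize_arrays(s.wavenumbers, s.intensities, s.segments)
    except ValidationError as exc:
        raise ValidationError(f"spectrum '{s.sample_id}': {exc}") from None
    return s.with_intensities(out)


def preprocess_set(
    sset: SpectrumSet,
    dark: Spectrum | None,
    config: PreprocessConfig | None = None,
) -> SpectrumSet:
    """Run the full chain on every spectrum, preserving labels and order."""
    config = config or PreprocessConfig()
    out: list[Spectrum] = []
    axis: np.ndarray | None = None
    for s in sset:
        try:
            if dark is not None:
                s = subtract_dark(s, dark, config)
            baseline = estimate_baseline(s.intensities, config)
            s = s.with_intensities(s.intensities - baseline)
            s = crop_and_combine(s, config)
            s = area_normalize(s)
        except (ValidationError, NumericalError) as exc:
            msg = str(exc)
            if s.sample_id and s.sample_id not in msg:
                msg = f"spectrum '{s.sample_id}': {msg}"
            raise type(exc)(msg) from exc
        if axis is None:
            axis = s.wavenumbers
        out.append(s)
    return SpectrumSet(out, axis if axis is not None else sset.axis)
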