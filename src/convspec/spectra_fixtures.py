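"""Synthetic incident spectra for testing and benchmarking.

The generators mirror the kinds of inputs used to characterize a
reconstructive spectrometer: discrete Gaussian peak sets with controlled
position/FWHM/amplitude, random smooth broadband waveforms, and series of
gradually dipping / rising / shifting peaks.  Everything is deterministic
under a seed.

The default window mirrors the characterization band of the reference
device class: 6,250-6,670 cm^-1 (1,500-1,600 nm), N = 200, step 2.1 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .device_model import WavenumberGrid
from .measurement import Spectrum

__all__ = [
    "PeakSpec",
    "default_grid",
    "gaussian_peaks",
    "random_broadband",
    "varying_series",
    "FWHM_TO_SIGMA",
]

#: Gaussian FWHM = 2 sqrt(2 ln 2) sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548...


def default_grid() -> WavenumberGrid:
    """One composite-FSR window of the default device: 6,250 cm^-1 start,
    2.1 cm^-1 step, 200 points (span 420 cm^-1)."""
    return WavenumberGrid(nu_start=6250.0, delta_nu=2.1, n_points=200)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian peak: center (cm^-1), FWHM (cm^-1), relative amplitude
    in (0, 1]."""

    center: float
    fwhm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in (0, 1]")


def gaussian_peaks(grid: WavenumberGrid, peaks: Sequence[PeakSpec]) -> Spectrum:
    """Sum of Gaussian peaks, max-normalized to the largest amplitude.

    Every center must lie inside the half-open window
    ``[nu_start, nu_start + span)``; a peak outside would wrap around the
    composite-FSR window and alias.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    lo, hi = grid.nu_start, grid.nu_start + grid.span
    for pk in peaks:
        if not lo <= pk.center < hi:
            raise ValueError(
                f"peak center {pk.center} outside window [{lo}, {hi})"
            )
    vals = np.zeros(grid.n_points)
    for pk in peaks:
        sigma = pk.fwhm * FWHM_TO_SIGMA
        vals += pk.amplitude * np.exp(-0.5 * ((grid.nu - pk.center) / sigma) ** 2)
    vals *= max(pk.amplitude for pk in peaks) / vals.max()
    return Spectrum(grid, vals)


def random_broadband(
    grid: WavenumberGrid,
    n_components: Optional[int] = None,
    smoothness: float = 10.0,
    seed: Optional[int] = None,
) -> Spectrum:
    """Random smooth broadband waveform, max-normalized to 1.

    Built as a sum of Gaussians with seeded random centers, widths and
    amplitudes.  ``smoothness`` is the minimum component width (Gaussian
    sigma, cm^-1) and acts as the waveform's correlation length: widths are
    drawn uniformly from [smoothness, 3*smoothness], so spectral content is
    confined to low DFT indices (predominantly below the default device's
    ``k_max``).  Component centers stay 2.5 sigma inside the window so no
    sharp truncation edges leak high frequencies.

    ``n_components`` defaults to a seeded draw from 5..10.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = int(rng.integers(5, 11))
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    lo, hi = grid.nu_start, grid.nu_start + grid.span
    vals = np.zeros(grid.n_points)
    for _ in range(n_components):
        sigma = rng.uniform(smoothness, 3.0 * smoothness)
        margin = min(2.5 * sigma, 0.45 * grid.span)
        center = rng.uniform(lo + margin, hi - margin)
        amp = rng.uniform(0.2, 1.0)
        vals += amp * np.exp(-0.5 * ((grid.nu - center) / sigma) ** 2)
    return Spectrum(grid, vals / vals.max())


def varying_series(
    grid: WavenumberGrid,
    peaks: Sequence[PeakSpec],
    mode: str,
    n_frames: int,
    magnitude: float,
    target: int = 0,
) -> list[Spectrum]:
    """Series of spectra with one peak gradually varying.

    The base spectrum is given by its Gaussian peak composition (frame 0 is
    exactly ``gaussian_peaks(grid, peaks)``).  Across ``n_frames`` frames
    the ``target`` peak's amplitude decreases (``"dip"``) or increases
    (``"rise"``) by ``magnitude`` in total, or its center translates by
    ``magnitude`` cm^-1 in total (``"shift"``), all linearly frame to frame.

    A shift pushing the peak out of the window, or a dip/rise leaving the
    (0, 1] amplitude range, raises at the offending frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if mode not in ("dip", "rise", "shift"):
        raise ValueError(f"mode must be dip|rise|shift, got {mode!r}")
    peaks = list(peaks)
    base = peaks[target]
    frames = []
    for f in range(n_frames):
        frac = f / (n_frames - 1)
        if mode == "dip":
            pk = replace(base, amplitude=base.amplitude - magnitude * frac)
        elif mode == "rise":
            pk = replace(base, amplitude=base.amplitude + magnitude * frac)
        else:
            pk = replace(base, center=base.center + magnitude * frac)
        varied = list(peaks)
        varied[target] = pk
        frames.append(gaussian_peaks(grid, varied))
    return frames
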