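"""Photodetector trace simulation: the physical circular convolution.

At each schedule step the detector integrates the incident spectrum against
the (shifted) overlaid response.  On an ``N``-point grid with rectangle-rule
weight ``delta_nu`` the noiseless trace is

    p[t] = delta_nu * sum_j x[j] * r_sys[(j - t) mod N],   t = 0 .. N-1,

i.e. a discrete circular cross-correlation between spectrum and response.
The index direction is a fixed package convention, chosen so that the DFT
relation

    DFT(p)[k] = delta_nu * conj(R_sys[k]) * X[k]

holds exactly for real sequences, making spectrum recovery a plain division
(see :mod:`convspec.reconstruction`).  Physically it corresponds to running
the proportional phase drive so the waveform slides one grid sample per step
toward decreasing wavenumber; the opposite drive direction would recover the
mirror image of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .device_model import (
    CascadeDesign,
    SystemResponse,
    WavenumberGrid,
    evaluate_response_values,
    system_response,
)
from .exceptions import DispersionError, WindowMismatchError
from .modulation import PhaseSchedule, phase_schedule

__all__ = [
    "Spectrum",
    "MeasurementTrace",
    "DispersionModel",
    "simulate_trace",
    "apply_dispersion",
]


@dataclass
class Spectrum:
    """Incident (or recovered) spectrum sampled on a wavenumber grid.

    Intensities are linear power units, typically max-normalized to 1.
    Physical inputs to the forward model must be nonnegative (enforced at
    the simulation and file-reading boundaries); recovered spectra may carry
    small negative noise excursions and are not clipped by default.
    """

    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensities must have shape ({self.grid.n_points},), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        self.intensities = arr

    @property
    def is_nonnegative(self) -> bool:
        return bool(self.intensities.min() >= 0.0)

    def normalized(self) -> "Spectrum":
        """Max-normalized copy (peak intensity 1)."""
        peak = float(np.max(np.abs(self.intensities)))
        if peak == 0.0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.grid, self.intensities / peak)

    @classmethod
    def impulse(cls, grid: WavenumberGrid, index: int, amplitude: float = 1.0) -> "Spectrum":
        x = np.zeros(grid.n_points)
        x[index] = amplitude
        return cls(grid, x)


@dataclass
class MeasurementTrace:
    """Simulated detector sequence ``p[t]`` with noise metadata."""

    values: np.ndarray
    grid: WavenumberGrid
    noise_sigma: float = 0.0
    seed: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (self.grid.n_points,):
            raise ValueError("trace length must equal the grid size")
        self.values = arr


@dataclass(frozen=True)
class DispersionModel:
    """Linear group-index dispersion ``n(nu) = n_g0 + slope * (nu - anchor)``.

    The stage phase argument becomes ``2 pi n_eff delta_L * (alpha(nu) nu)``
    with warp factor ``alpha(nu) = n(nu) / n_g0``, stretching the FSR periods
    across the window.  ``slope`` is d(n_g)/d(nu) per cm^-1.
    """

    n_g0: float
    slope: float = 0.0
    anchor_nu: float = 0.0

    def index(self, nu: np.ndarray) -> np.ndarray:
        return self.n_g0 + self.slope * (np.asarray(nu, dtype=float) - self.anchor_nu)

    def warp_factor(self, nu: np.ndarray) -> np.ndarray:
        return self.index(nu) / self.n_g0

    def warp(self, nu: np.ndarray) -> np.ndarray:
        """Phase-equivalent wavenumber map ``nu -> n(nu) * nu / n_g0``."""
        return self.warp_factor(nu) * np.asarray(nu, dtype=float)

    def validate_over(self, grid: WavenumberGrid) -> None:
        if self.n_g0 <= 0 or np.any(self.index(grid.nu) <= 0):
            raise DispersionError("group index must stay positive over the grid")


def _resolve_response(
    x: Spectrum, system: Union[CascadeDesign, SystemResponse]
) -> SystemResponse:
    if isinstance(system, SystemResponse):
        if system.grid != x.grid:
            raise WindowMismatchError("spectrum and response grids differ")
        return system
    if isinstance(system, CascadeDesign):
        return system_response(system, x.grid)
    raise TypeError("system must be a CascadeDesign or SystemResponse")


def simulate_trace(
    x: Spectrum,
    system: Union[CascadeDesign, SystemResponse],
    schedule: Optional[PhaseSchedule] = None,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    dispersion: Optional[DispersionModel] = None,
) -> MeasurementTrace:
    """Simulate the detector trace of spectrum ``x`` through the device.

    Noiseless values are ``p[t] = delta_nu * sum_j x[j] r_sys[(j - t) % N]``
    (see module docstring for the sign convention).  ``noise_sigma`` adds
    zero-mean white Gaussian noise with standard deviation
    ``noise_sigma * max(p)``, reproducible under ``seed``.

    A ``schedule`` must be grid-aligned (``n_steps == N``); its integer
    origin offset ``t0`` (thermal drift stand-in) delays the trace
    circularly.  With a ``dispersion`` model the response no longer shifts
    rigidly on the wavenumber grid, so each step is evaluated from the
    cascade directly (this requires cascade provenance).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not x.is_nonnegative:
        raise ValueError("incident spectrum must be nonnegative")
    grid = x.grid
    n = grid.n_points
    response = _resolve_response(x, system)

    if schedule is None:
        t0 = 0
        if dispersion is not None or response.cascade is not None:
            cascade = response.cascade
            if cascade is not None:
                schedule = phase_schedule(cascade, n)
    else:
        if schedule.n_steps != n:
            raise WindowMismatchError(
                f"schedule must be grid-aligned: n_steps {schedule.n_steps} != N {n}"
            )
        if not np.isclose(schedule.delta_nu, grid.delta_nu):
            raise WindowMismatchError("schedule footstep differs from grid step")
        t0 = schedule.t0
        if float(t0) != int(t0):
            raise ValueError("only integer origin offsets t0 are supported")
        t0 = int(t0)

    if dispersion is None:
        base = response.values
        # C[t, j] = base[(j - t + t0) % N]
        idx = (np.arange(n)[None, :] - np.arange(n)[:, None] + t0) % n
        p = grid.delta_nu * (base[idx] @ x.intensities)
    else:
        cascade = response.cascade
        if cascade is None or schedule is None:
            raise ValueError(
                "dispersion simulation needs a cascade-backed response and schedule"
            )
        dispersion.validate_over(grid)
        alpha = dispersion.warp_factor(grid.nu)
        p = np.empty(n)
        inc = np.asarray(schedule.increments)
        for t in range(n):
            vals = evaluate_response_values(
                cascade, grid, inc * (t0 - t), warp_factor=alpha
            )
            p[t] = grid.delta_nu * float(vals @ x.intensities)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sigma * p.max(), size=n)

    return MeasurementTrace(
        values=p,
        grid=grid,
        noise_sigma=noise_sigma,
        seed=seed,
        provenance={
            "t0": t0,
            "dispersion": None if dispersion is None else dispersion,
            "tabulated": response.cascade is None,
        },
    )


def apply_dispersion(response: SystemResponse, model: DispersionModel) -> SystemResponse:
    """Static response under group-index dispersion.

    Re-evaluates the cascade with phase argument
    ``2 pi n_eff delta_L * (alpha(nu) nu)``, which stretches the oscillation
    periods across the window (more periods where the index is larger).
    ``slope = 0`` with ``n_g0`` equal to the stage index is the identity.
    Requires cascade provenance (a tabulated response cannot be
    re-evaluated).
    """
    if response.cascade is None:
        raise ValueError("apply_dispersion needs a cascade-backed response")
    model.validate_over(response.grid)
    phases = response.phases
    if phases is None:
        phases = np.zeros(response.cascade.n_stages)
    values = evaluate_response_values(
        response.cascade,
        response.grid,
        phases,
        warp_factor=model.warp_factor(response.grid.nu),
    )
    return SystemResponse(
        response.grid,
        values,
        tau=response.tau,
        cascade=response.cascade,
        phases=phases,
        dispersion=model,
    )
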