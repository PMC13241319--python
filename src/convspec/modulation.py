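"""Proportional phase schedules and circular waveform shifting.

Driving every stage with a per-step phase increment proportional to its arm
length difference — ``delta_phi_i = 2 pi m_i / n_steps`` for FSR ratio
``m_i`` — translates the *overlaid* response rigidly along the wavenumber
axis, modulo the composite FSR.  One full cycle of ``n_steps`` advances
stage ``i`` by exactly ``2 pi m_i``, returning the response to its start.

When ``n_steps`` equals the grid size ``N``, each step moves the response by
exactly one grid sample, so time-domain phase stepping becomes an exact
circular index shift of the sampled response: the identity the measurement
model is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .device_model import CascadeDesign, WavenumberGrid, system_response
from .exceptions import MisalignmentError, WindowMismatchError

__all__ = ["PhaseSchedule", "phase_schedule", "shifted_response", "wrap_phase"]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phases into (-pi, pi] for numerical hygiene."""
    return -((np.pi - np.asarray(phi)) % (2.0 * np.pi)) + np.pi


@dataclass(frozen=True)
class PhaseSchedule:
    """Discretized proportional phase drive for one cascade.

    ``increments[i] = 2 pi m_i / n_steps`` radians per step; the shifting
    footstep in wavenumber is ``delta_nu = fsr_comp / n_steps``.  ``t0`` is
    an optional origin offset (in steps) modelling slow drift, e.g. the
    thermally induced waveform shift; it is estimated and removed
    algorithmically downstream (circular re-registration), never by
    re-calibrating the device.
    """

    n_steps: int
    increments: tuple[float, ...]
    fsr_comp: float
    ratios: tuple[int, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if len(self.increments) != len(self.ratios):
            raise ValueError("one increment per stage required")

    @property
    def delta_nu(self) -> float:
        """Shifting footstep ``fsr_comp / n_steps`` in cm^-1."""
        return self.fsr_comp / self.n_steps

    def phases_at(self, t: float) -> np.ndarray:
        """Stage phases at (possibly fractional) step ``t``, wrapped to
        (-pi, pi]."""
        raw = np.asarray(self.increments) * (t + self.t0)
        return wrap_phase(raw)


def phase_schedule(
    cascade: CascadeDesign, n_steps: int, t0: float = 0.0
) -> PhaseSchedule:
    """Proportional schedule for ``cascade`` with ``n_steps`` steps per
    composite-FSR cycle.

    The increments satisfy the proportionality condition
    ``delta_phi_1 : ... : delta_phi_n = m_1 : ... : m_n`` (equivalently
    ``1/FSR_1 : ... : 1/FSR_n``, i.e. the arm length differences) exactly,
    by construction from the integer ratios.
    """
    increments = tuple(2.0 * np.pi * m / n_steps for m in cascade.ratios)
    return PhaseSchedule(
        n_steps=int(n_steps),
        increments=increments,
        fsr_comp=cascade.fsr_comp,
        ratios=cascade.ratios,
        t0=t0,
    )


def shifted_response(
    cascade: CascadeDesign,
    grid: WavenumberGrid,
    schedule: PhaseSchedule,
    t: int,
) -> np.ndarray:
    """Overlaid response at schedule step ``t``.

    With a grid-aligned schedule (``n_steps == N``) this equals the exact
    circular shift of the step-0 response: ``shifted[j] = base[(j + t) % N]``
    — increasing ``t`` moves the waveform toward increasing wavenumber.
    Raises :class:`MisalignmentError` if the schedule is not grid-aligned,
    since only then is the shift grid-exact.
    """
    if schedule.ratios != cascade.ratios or not np.isclose(
        schedule.fsr_comp, cascade.fsr_comp
    ):
        raise ValueError("schedule was not generated for this cascade")
    if not grid.matches_fsr(cascade.fsr_comp):
        raise WindowMismatchError(
            f"grid span {grid.span} != composite FSR {cascade.fsr_comp}"
        )
    if schedule.n_steps != grid.n_points:
        raise MisalignmentError(
            f"grid-exact shifting needs n_steps == N "
            f"({schedule.n_steps} != {grid.n_points})"
        )
    return system_response(cascade, grid, phases=schedule.phases_at(t)).values
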