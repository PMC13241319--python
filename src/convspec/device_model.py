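"""Cascaded unbalanced-interferometer device model.

An unbalanced Mach-Zehnder interferometer (MZI) with arm length difference
``delta_L`` has a sinusoidal spectral transmittance whose period in
wavenumber, the free spectral range, is ``FSR = 1 / (n_g * delta_L)``.
Cascading stages multiplies their transmittances, producing an overlaid
response whose period is the least common multiple of the stage FSRs (the
*composite* FSR) and whose discrete Fourier spectrum contains components at
every index reachable as ``|sum(eps_i * m_i)|`` with ``eps_i in {-1, 0, +1}``,
where ``m_i = FSR_comp / FSR_i`` are the integer FSR ratios.

The largest *contiguously* covered frequency index sets the spectrometer
resolution: ``resolution = FSR_comp / k_max``.  A geometric ("ternary")
ratio ladder ``m_i = 3**(i-1)`` maximizes contiguous coverage for a product
of offset cosines, reaching ``(3**n - 1) / 2`` with ``n`` stages.

Conventions used throughout the package:

* wavenumbers ``nu`` in cm^-1, arm length differences in micrometres,
  indices ``n_eff``/``n_g`` dimensionless;
* forward DFT with negative exponent and no normalization
  (``numpy.fft.fft``); the inverse carries ``1/N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    DegenerateStageError,
    IncommensurableFSRError,
    WindowMismatchError,
)

__all__ = [
    "WavenumberGrid",
    "MZIStage",
    "CascadeDesign",
    "SystemResponse",
    "stage_response",
    "system_response",
    "composite_fsr",
    "ratios_from_delta_L",
    "k_max_estimate",
    "resolution",
    "coverage_enumerate",
    "design_cascade",
    "design_resolution",
    "comb_response",
    "DEFAULT_KMAX_TAU",
]

#: Relative magnitude threshold below which a DFT bin of the system response
#: counts as zero.  "Non-zero term" is numerically ill-posed for a
#: floating-point DFT, so significance is judged relative to the largest bin.
DEFAULT_KMAX_TAU = 1e-3

_UM_TO_CM = 1e-4


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform discretization of one composite-FSR window.

    Samples are ``nu_start + j * delta_nu`` for ``j = 0 .. n_points - 1``
    (left-closed, half-open window).  When paired with a cascade the span
    ``n_points * delta_nu`` must equal the composite FSR exactly, so that
    circular index arithmetic on the grid is circular arithmetic on the
    physical response.
    """

    nu_start: float
    delta_nu: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.delta_nu > 0:
            raise ValueError(f"delta_nu must be > 0, got {self.delta_nu}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")

    @property
    def span(self) -> float:
        """Window width ``n_points * delta_nu`` in cm^-1."""
        return self.n_points * self.delta_nu

    @cached_property
    def nu(self) -> np.ndarray:
        """Grid sample positions in cm^-1 (length ``n_points``)."""
        arr = self.nu_start + self.delta_nu * np.arange(self.n_points)
        arr.setflags(write=False)
        return arr

    @classmethod
    def from_span(cls, nu_start: float, span: float, n_points: int) -> "WavenumberGrid":
        return cls(nu_start, span / n_points, n_points)

    def matches_fsr(self, fsr_comp: float, rel_tol: float = 1e-9) -> bool:
        return math.isclose(self.span, fsr_comp, rel_tol=rel_tol)


@dataclass(frozen=True)
class MZIStage:
    """One unbalanced MZI stage.

    Parameters
    ----------
    delta_L:
        Arm length difference in micrometres.
    n_eff, n_g:
        Effective and group indices.  ``n_eff`` enters the oscillating phase
        term, ``n_g`` the FSR; they are equal in the dispersionless default.
    rho:
        Coupler power splitting ratio, strictly inside (0, 1).  ``rho`` in
        {0, 1} is rejected: the interference term vanishes and the stage no
        longer modulates.
    phi0:
        Static phase offset in radians.
    """

    delta_L: float
    n_eff: float = 2.0
    n_g: float = 2.0
    rho: float = 0.5
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise DegenerateStageError(
                f"rho must lie strictly inside (0, 1), got {self.rho}"
            )
        if self.delta_L <= 0 or self.n_g <= 0 or self.n_eff <= 0:
            raise ValueError("delta_L, n_eff and n_g must be positive")

    @property
    def fsr(self) -> float:
        """Free spectral range ``1 / (n_g * delta_L)`` in cm^-1."""
        return 1.0 / (self.n_g * self.delta_L * _UM_TO_CM)

    @property
    def gamma1(self) -> float:
        """Modulation scale ``2 rho (1 - rho)``, in (0, 0.5]."""
        return 2.0 * self.rho * (1.0 - self.rho)

    @property
    def gamma2(self) -> float:
        """Offset ``(rho^2 + (1-rho)^2) / (2 rho (1-rho))`` >= 1."""
        return (self.rho**2 + (1.0 - self.rho) ** 2) / self.gamma1


def stage_response(
    stage: MZIStage, grid: WavenumberGrid, phi: float = 0.0
) -> np.ndarray:
    """Periodic transmittance of one stage on the grid.

    ``r_i(nu) = rho^2 + (1-rho)^2 + 2 rho (1-rho) cos(2 pi n_eff nu delta_L
    + phi0 + phi)``, bounded within ``[(1 - 2 rho)^2, 1]``.
    """
    arg = (
        2.0 * np.pi * stage.n_eff * (stage.delta_L * _UM_TO_CM) * grid.nu
        + stage.phi0
        + phi
    )
    r = stage.rho**2 + (1.0 - stage.rho) ** 2 + stage.gamma1 * np.cos(arg)
    return r


@dataclass(frozen=True)
class CascadeDesign:
    """Ordered cascade of MZI stages with exact integer FSR ratios.

    Stage FSRs are represented as ``FSR_i = fsr_comp / m_i`` through the
    integer ratio sequence ``m_i``, so least-common-multiple arithmetic is
    exact.  The canonical form requires ``gcd(m_1..m_n) = 1``; otherwise
    ``fsr_comp`` would not be the *least* common multiple of the stage FSRs.
    """

    stages: tuple[MZIStage, ...]
    fsr_comp: float
    ratios: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("cascade needs at least one stage")
        if len(self.stages) != len(self.ratios):
            raise ValueError("one ratio per stage required")
        if any(m < 1 for m in self.ratios):
            raise ValueError(f"all ratios must be >= 1, got {self.ratios}")
        if math.gcd(*self.ratios) != 1:
            raise ValueError(
                f"gcd of FSR ratios must be 1 (canonical LCM form), got {self.ratios}"
            )
        if self.fsr_comp <= 0:
            raise ValueError("fsr_comp must be positive")
        for st, m in zip(self.stages, self.ratios):
            if not math.isclose(st.fsr * m, self.fsr_comp, rel_tol=1e-9):
                raise ValueError(
                    f"stage FSR {st.fsr} inconsistent with ratio {m} and "
                    f"composite FSR {self.fsr_comp}"
                )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @classmethod
    def from_ratios(
        cls,
        ratios: Sequence[int],
        fsr_comp: float,
        rho: float | Sequence[float] = 0.5,
        phi0: float | Sequence[float] = 0.0,
        n_eff: float = 2.0,
        n_g: float | None = None,
    ) -> "CascadeDesign":
        """Build a cascade from integer FSR ratios and a composite FSR.

        Arm length differences follow from ``FSR_i = fsr_comp / m_i`` and
        ``delta_L_i = 1 / (n_g * FSR_i)``.  ``n_g`` defaults to ``n_eff``
        (dispersionless model).
        """
        if n_g is None:
            n_g = n_eff
        n = len(ratios)
        rhos = [rho] * n if np.isscalar(rho) else list(rho)
        phis = [phi0] * n if np.isscalar(phi0) else list(phi0)
        stages = tuple(
            MZIStage(
                delta_L=m / (n_g * fsr_comp) / _UM_TO_CM,
                n_eff=n_eff,
                n_g=n_g,
                rho=r,
                phi0=p,
            )
            for m, r, p in zip(ratios, rhos, phis)
        )
        return cls(stages=stages, fsr_comp=float(fsr_comp), ratios=tuple(int(m) for m in ratios))

    @classmethod
    def from_fsrs(
        cls, fsr_list: Sequence[float], rel_tol: float = 1e-6, **kwargs
    ) -> "CascadeDesign":
        """Build a cascade from raw stage FSRs (cm^-1).

        The FSRs are rationalized against each other (tolerance ``rel_tol``)
        and snapped to the exact integer-ratio lattice of the detected
        composite FSR.
        """
        fsr_comp, ratios = composite_fsr(fsr_list, rel_tol=rel_tol)
        return cls.from_ratios(ratios, fsr_comp, **kwargs)


def composite_fsr(
    fsr_list: Sequence[float], rel_tol: float = 1e-6, max_denominator: int = 1000
) -> tuple[float, tuple[int, ...]]:
    """Least common multiple of stage FSRs and canonical integer ratios.

    Each FSR is expressed as a rational multiple of the first (continued-
    fraction rationalization via :meth:`fractions.Fraction.limit_denominator`,
    denominators bounded by ``max_denominator`` — FSR ratio sets of real
    cascades are small integers); the LCM of those fractions is the composite
    FSR.  Raises :class:`IncommensurableFSRError` if any ratio has no such
    rational approximation within ``rel_tol`` (no finite composite FSR
    exists at a practical ratio scale).

    Returns ``(fsr_comp, ratios)`` with ``ratios[i] = fsr_comp / fsr_list[i]``
    and ``gcd(ratios) == 1``.
    """
    fsrs = [float(f) for f in fsr_list]
    if not fsrs or any(f <= 0 for f in fsrs):
        raise ValueError("FSR list must be non-empty and positive")
    base = fsrs[0]
    fracs: list[Fraction] = []
    for f in fsrs:
        q = Fraction(f / base).limit_denominator(max_denominator)
        if q == 0 or abs(float(q) * base - f) > rel_tol * f:
            raise IncommensurableFSRError(
                f"FSR {f} is not a rational multiple of {base} within "
                f"relative tolerance {rel_tol}"
            )
        fracs.append(q)
    # LCM of fractions: lcm of numerators over gcd of denominators.
    num = math.lcm(*(q.numerator for q in fracs))
    den = math.gcd(*(q.denominator for q in fracs))
    lcm_frac = Fraction(num, den)
    ratios = tuple(int(lcm_frac / q) for q in fracs)
    assert math.gcd(*ratios) == 1
    return float(base * lcm_frac), ratios


def ratios_from_delta_L(
    delta_L_um: Sequence[float], n_g: float = 2.0, rel_tol: float = 1e-6
) -> tuple[float, tuple[int, ...]]:
    """Convenience converter from physical arm length differences (um) to a
    composite FSR and canonical integer ratios."""
    fsrs = [1.0 / (n_g * dl * _UM_TO_CM) for dl in delta_L_um]
    return composite_fsr(fsrs, rel_tol=rel_tol)


class SystemResponse:
    """Sampled overlaid response of a cascade over one composite-FSR window.

    Holds the nonnegative transmittance samples ``values`` (length ``N``),
    their forward DFT and the largest significant frequency index ``k_max``.
    Instances may come from an analytic cascade evaluation
    (:func:`system_response`) or from tabulated/measured data (constructed
    directly), in which case ``cascade``/``phases`` provenance is ``None``.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        values: np.ndarray,
        tau: float = DEFAULT_KMAX_TAU,
        cascade: Optional[CascadeDesign] = None,
        phases: Optional[np.ndarray] = None,
        dispersion=None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (grid.n_points,):
            raise ValueError(
                f"values must have shape ({grid.n_points},), got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("response values must be finite")
        floor = -1e-9 * max(float(values.max(initial=0.0)), 1.0)
        if values.min() < floor:
            raise ValueError("response values must be nonnegative")
        self.grid = grid
        self.values = np.clip(values, 0.0, None)
        self.values.setflags(write=False)
        self.tau = float(tau)
        self.cascade = cascade
        self.phases = None if phases is None else np.asarray(phases, dtype=float)
        self.dispersion = dispersion

    @cached_property
    def dft(self) -> np.ndarray:
        """Forward DFT of the samples (negative exponent, unnormalized)."""
        out = np.fft.fft(self.values)
        out.setflags(write=False)
        return out

    @cached_property
    def k_max(self) -> int:
        """Largest significant frequency index, at the instance's ``tau``."""
        return k_max_estimate(self, self.tau)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SystemResponse(N={self.grid.n_points}, span={self.grid.span:g} cm^-1, "
            f"k_max={self.k_max})"
        )


def system_response(
    cascade: CascadeDesign,
    grid: WavenumberGrid,
    phases: Optional[Sequence[float]] = None,
    tau: float = DEFAULT_KMAX_TAU,
) -> SystemResponse:
    """Overlaid response: element-wise product of all stage responses.

    ``phases`` gives one extra phase (radians) per stage on top of each
    stage's static offset.  The grid span must equal the composite FSR, or
    the circular-convolution identity would break
    (:class:`WindowMismatchError`).
    """
    if not grid.matches_fsr(cascade.fsr_comp):
        raise WindowMismatchError(
            f"grid span {grid.span} cm^-1 != composite FSR {cascade.fsr_comp} cm^-1"
        )
    if phases is None:
        phases = np.zeros(cascade.n_stages)
    phases = np.asarray(phases, dtype=float)
    if phases.shape != (cascade.n_stages,):
        raise ValueError("need one phase per stage")
    values = np.ones(grid.n_points)
    for st, phi in zip(cascade.stages, phases):
        values = values * stage_response(st, grid, phi)
    return SystemResponse(grid, values, tau=tau, cascade=cascade, phases=phases)


def evaluate_response_values(
    cascade: CascadeDesign,
    grid: WavenumberGrid,
    phases: Sequence[float],
    warp_factor: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Raw response samples, optionally with a wavenumber warp.

    ``warp_factor`` is a per-sample multiplicative factor ``alpha(nu)`` on the
    phase argument's wavenumber (``nu -> alpha(nu) * nu``), used by the
    dispersion model where the index becomes wavenumber dependent.
    """
    nu = grid.nu if warp_factor is None else grid.nu * np.asarray(warp_factor)
    values = np.ones(grid.n_points)
    for st, phi in zip(cascade.stages, np.asarray(phases, dtype=float)):
        arg = 2.0 * np.pi * st.n_eff * (st.delta_L * _UM_TO_CM) * nu + st.phi0 + phi
        values = values * (
            st.rho**2 + (1.0 - st.rho) ** 2 + st.gamma1 * np.cos(arg)
        )
    return values


def k_max_estimate(response: "SystemResponse | np.ndarray", tau: float = DEFAULT_KMAX_TAU) -> int:
    """Largest ``k <= N/2`` with ``|R[k]| > tau * max_k |R[k]|``.

    Accepts a :class:`SystemResponse` or a raw complex DFT array.  Raises on
    an all-zero response and on ``tau`` outside (0, 1).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    dft = response.dft if isinstance(response, SystemResponse) else np.asarray(response)
    mag = np.abs(dft)
    peak = mag.max()
    if peak == 0.0:
        raise ValueError("all-zero response has no frequency content")
    n = len(mag)
    half = n // 2
    significant = np.nonzero(mag[: half + 1] > tau * peak)[0]
    return int(significant.max(initial=0))


def resolution(fsr_comp: float, k_max: int) -> float:
    """Resolution law: ``FSR_comp / k_max`` (cm^-1).

    ``k_max = 0`` means the response carries only DC and nothing is
    resolvable.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1 (DC-only response resolves nothing)")
    return fsr_comp / k_max


def coverage_enumerate(ratios: Sequence[int]) -> tuple[frozenset[int], int]:
    """Achievable frequency indices of a product of offset cosines.

    Returns ``({ |sum(eps_i * m_i)| : eps_i in {-1, 0, +1} }, L)`` where ``L``
    is the largest index such that ``0..L`` is fully covered (the contiguous
    prefix that sets the usable resolution).
    """
    ratios = [int(m) for m in ratios]
    if any(m < 1 for m in ratios):
        raise ValueError("ratios must be positive integers")
    sums = {0}
    for m in ratios:
        sums = {s + e * m for s in sums for e in (-1, 0, 1)}
    achievable = frozenset(abs(s) for s in sums)
    prefix = 0
    while prefix + 1 in achievable:
        prefix += 1
    return achievable, prefix


def design_cascade(
    n_stages: int,
    fsr_comp: float,
    scheme: str = "ternary",
    ratios: Optional[Sequence[int]] = None,
    rho: float | Sequence[float] = 0.5,
    phi0: float | Sequence[float] = 0.0,
    n_eff: float = 2.0,
    n_g: float | None = None,
) -> CascadeDesign:
    """Design a cascade maximizing contiguous frequency coverage.

    The ``ternary`` scheme uses ``m_i = 3**(i-1)``: balanced-ternary
    representability makes the contiguous coverage grow as ``(3**n - 1)/2``,
    i.e. exponentially in the stage count.  ``custom`` takes an explicit
    ratio sequence.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if scheme == "ternary":
        ratios = [3**i for i in range(n_stages)]
    elif scheme == "custom":
        if ratios is None:
            raise ValueError("custom scheme requires explicit ratios")
        if len(ratios) != n_stages:
            raise ValueError("len(ratios) must equal n_stages")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return CascadeDesign.from_ratios(
        ratios, fsr_comp, rho=rho, phi0=phi0, n_eff=n_eff, n_g=n_g
    )


def design_resolution(design: CascadeDesign) -> float:
    """Resolution reached by a design: ``fsr_comp`` over its contiguous
    coverage prefix."""
    _, prefix = coverage_enumerate(design.ratios)
    return resolution(design.fsr_comp, prefix)


def comb_response(
    grid: WavenumberGrid,
    k_max: int,
    amplitudes: Optional[Sequence[float]] = None,
    tau: float = DEFAULT_KMAX_TAU,
) -> SystemResponse:
    """Synthetic tabulated response with a flat comb of components 1..k_max.

    Emulates a measured response with rich, contiguous harmonic content (as
    fabricated cascades exhibit once coupler imperfections and dispersion
    populate extra mixing products).  Cosines with Schroeder phases
    ``theta_k = pi k (k+1) / (k_max + 1)`` keep the crest factor low; the
    smallest DC pedestal making the waveform nonnegative is then added and
    the result is scaled to peak transmittance 1.

    No cascade provenance is attached: this is a tabulated response.
    """
    n = grid.n_points
    if not 1 <= k_max <= n // 2:
        raise ValueError(f"k_max must lie in [1, N/2], got {k_max}")
    if amplitudes is None:
        amplitudes = np.ones(k_max)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (k_max,):
        raise ValueError("need one amplitude per component 1..k_max")
    j = np.arange(n)
    values = np.zeros(n)
    for k in range(1, k_max + 1):
        theta = np.pi * k * (k + 1) / (k_max + 1)
        values += amplitudes[k - 1] * np.cos(2.0 * np.pi * k * j / n + theta)
    values -= values.min()  # minimal DC pedestal for nonnegativity
    values /= values.max()
    return SystemResponse(grid, values, tau=tau)
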