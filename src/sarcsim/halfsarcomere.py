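"""Mechanics and cross-bridge kinetics of a single half-sarcomere.

A half-sarcomere is modelled as a population of myosin heads cycling
through three states -- detached (D), attached pre-powerstroke (A1) and
attached post-powerstroke (A2) -- with strain-dependent transition rates,
in the tradition of Huxley-style distribution models.  Attached heads are
resolved over a discrete cross-bridge strain axis; the detached pool is a
single number.  Total force is the sum of the cross-bridge (active)
contribution and an exponential passive elasticity representing titin and
other parallel structures.

The number of heads that may participate at all is

    N_i(l, t) = n0 * zeta_i * psi(t) * phi(l)

where ``n0`` is the head density per cross-sectional area, ``zeta_i`` a
per-unit strength multiplier (the source of active heterogeneity),
``psi`` the imposed activation trace and ``phi`` the piecewise-linear
thick/thin filament overlap fraction.

All lengths and strains are in nanometres, forces are stresses in N m^-2,
rates in s^-1 and times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidInputError",
    "StepSizeError",
    "AxisRangeError",
    "StructureError",
    "StrainAxis",
    "RateLaws",
    "RateTables",
    "OverlapGeometry",
    "HalfSarcomereParams",
    "XbDistribution",
    "HalfSarcomereState",
    "overlap_fraction",
    "n_available",
    "passive_force",
    "passive_stiffness",
    "active_force",
    "set_available",
    "kinetics_step",
    "shift_distribution",
    "instantaneous_stiffness",
    "total_force",
    "isometric_steady_state",
]


class InvalidInputError(ValueError):
    """Raised for non-finite or out-of-range scalar inputs."""


class StepSizeError(RuntimeError):
    """Raised when dt violates the explicit-update stability guard."""


class AxisRangeError(RuntimeError):
    """Raised when a strain shift would push bound mass off the axis."""


class StructureError(RuntimeError):
    """Raised on mismatched array shapes between distribution and axis."""


# ---------------------------------------------------------------------------
# strain axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainAxis:
    """Uniform discretization of cross-bridge strain (nm).

    The range must bracket zero and be wide enough that essentially no
    bound mass reaches the boundary bins during a protocol; runs monitor
    boundary occupancy and report it in their diagnostics.
    """

    x_min: float = -12.0
    x_max: float = 12.0
    n_bins: int = 97

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_min) and np.isfinite(self.x_max)):
            raise InvalidInputError("strain axis limits must be finite")
        if not (self.x_min < 0.0 < self.x_max):
            raise InvalidInputError("strain axis must bracket zero")
        if self.n_bins < 5:
            raise InvalidInputError("strain axis needs at least 5 bins")

    @property
    def bin_width(self) -> float:
        return (self.x_max - self.x_min) / (self.n_bins - 1)

    def centers(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_bins)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateLaws:
    """Coefficients of the strain-dependent transition rates (s^-1, nm).

    D -> A1   attachment at total rate ``f0``, deposited over strain bins
              with Gaussian weights of width ``sigma_f`` centred at zero
              (heads bind near their unstrained position).
    A1 -> A2  powerstroke, sigmoidal in strain: negligible for
              x << -x_ps, approaching ``k3_0`` for x >> -x_ps (the stroke
              is energetically favourable once it does positive work).
    A2 -> A1  slow constant reversal ``k_minus3``.
    A1 -> D   slow constant detachment ``g_a1`` plus the shared
              strain-sensitive term.
    A2 -> D   detachment ``g0`` plus the shared strain-sensitive term.

    The shared strain-sensitive detachment applies to both attached
    states and has two parts, capped at ``g_cap`` to preserve
    explicit-update stability:

    * a steep detachment barrier ``g_det * (x / x_det)**8`` -- heads
      dragged to extreme strain of either sign are torn off rapidly.
      The eighth power makes the barrier negligible at working strains
      (below ~6 nm) but overwhelming within a few nm of the strain-axis
      ends, so stretching first raises force (heads bear more strain)
      before detachment wins;
    * a "slip" term ``g_slip`` switched on (sigmoidally, width
      ``w_slip``) for strains below ``x_slip`` -- compressed heads that
      oppose shortening release quickly.  This is the classic
      detachment asymmetry of Huxley-type schemes; it gives the unit a
      realistic maximal shortening velocity while leaving the slowly
      cycling positive-strain heads (the strain-energy store behind
      force enhancement) untouched.
    """

    f0: float = 8.0
    sigma_f: float = 0.7
    k3_0: float = 75.0
    x_k3: float = 1.0
    k_minus3: float = 5.0
    g_a1: float = 8.0
    g0: float = 10.0
    g_det: float = 30.0
    x_det: float = 6.0
    g_slip: float = 850.0
    x_slip: float = -0.3
    w_slip: float = 0.3
    g_cap: float = 900.0
    x_ps: float = 10.0  # powerstroke displacement (nm)

    def tables(self, axis: StrainAxis) -> "RateTables":
        x = axis.centers()
        w = np.exp(-0.5 * (x / self.sigma_f) ** 2)
        w /= w.sum()
        k3 = self.k3_0 / (1.0 + np.exp(-(x + self.x_ps) / self.x_k3))
        slip = self.g_slip / (1.0 + np.exp((x - self.x_slip) / self.w_slip))
        barrier = self.g_det * (x / self.x_det) ** 8
        strain_det = np.minimum(barrier + slip, self.g_cap)
        g1x = self.g_a1 + strain_det
        g2 = self.g0 + strain_det
        exit1 = k3 + g1x
        exit2 = g2 + self.k_minus3
        max_exit = float(max(self.f0, exit1.max(), exit2.max()))
        return RateTables(
            x=x, attach_w=w, k3=k3, g1x=g1x, g2=g2, exit1=exit1, exit2=exit2,
            f0=self.f0, k_minus3=self.k_minus3,
            x_ps=self.x_ps, max_exit=max_exit,
        )


class RateTables(NamedTuple):
    """Rate laws evaluated on a strain axis (precomputed for speed)."""

    x: np.ndarray
    attach_w: np.ndarray
    k3: np.ndarray
    g1x: np.ndarray
    g2: np.ndarray
    exit1: np.ndarray
    exit2: np.ndarray
    f0: float
    k_minus3: float
    x_ps: float
    max_exit: float


# ---------------------------------------------------------------------------
# geometry and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapGeometry:
    """Breakpoints (nm) of the piecewise-linear filament overlap fraction.

    Zero below ``ascending_zero``, rising linearly to 1 at ``plateau_lo``,
    flat to ``plateau_hi``, falling linearly to 0 at ``descending_zero``.
    """

    ascending_zero: float = 800.0
    plateau_lo: float = 1150.0
    plateau_hi: float = 1300.0
    descending_zero: float = 1700.0

    def __post_init__(self) -> None:
        bp = (self.ascending_zero, self.plateau_lo,
              self.plateau_hi, self.descending_zero)
        if not all(b < c for b, c in zip(bp, bp[1:])):
            raise InvalidInputError("overlap breakpoints must be increasing")

    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([self.ascending_zero, self.plateau_lo,
                         self.plateau_hi, self.descending_zero])


@dataclass(frozen=True)
class HalfSarcomereParams:
    """Parameters of one half-sarcomere.

    ``zeta`` scales the available head count (active strength multiplier,
    drawn with SD alpha across units); ``xi`` scales the passive stress
    (drawn with SD beta).  Passive stress follows

        F_pass(l) = xi * sigma_p * (exp((l - l0)/lambda) - 1)   l >= l0

    with a linear continuation of matched slope below ``l0`` so that
    passive stiffness is positive everywhere.  ``k_cb`` is the elastic
    force per head per nm of strain.
    """

    n0_density: float = 1.15e17
    zeta: float = 1.0
    xi: float = 1.0
    passive_sigma: float = 112.0
    passive_offset: float = 625.0
    passive_lambda: float = 136.0
    overlap: OverlapGeometry = field(default_factory=OverlapGeometry)
    k_cb: float = 1.0e-12
    rates: RateLaws = field(default_factory=RateLaws)
    axis: StrainAxis = field(default_factory=StrainAxis)

    def __post_init__(self) -> None:
        if self.n0_density <= 0 or self.zeta <= 0 or self.xi <= 0:
            raise InvalidInputError("n0_density, zeta and xi must be > 0")
        if self.passive_lambda <= 0:
            raise InvalidInputError("passive_lambda must be > 0")

    @property
    def x_ps(self) -> float:
        return self.rates.x_ps


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class XbDistribution:
    """Bound cross-bridge populations over the strain axis plus a
    detached pool.

    ``a1`` and ``a2`` are number densities per strain bin (heads m^-2),
    with arbitrary leading batch dimensions; ``d`` is the detached pool
    with the matching batch shape.
    """

    a1: np.ndarray
    a2: np.ndarray
    d: np.ndarray | float

    @classmethod
    def all_detached(cls, axis: StrainAxis, n: float | np.ndarray = 0.0,
                     batch_shape: tuple[int, ...] = ()) -> "XbDistribution":
        shape = batch_shape + (axis.n_bins,)
        d = np.broadcast_to(np.asarray(n, dtype=float), batch_shape).copy() \
            if batch_shape else float(n)
        return cls(a1=np.zeros(shape), a2=np.zeros(shape), d=d)

    def total_bound(self) -> np.ndarray | float:
        return self.a1.sum(axis=-1) + self.a2.sum(axis=-1)

    def total(self) -> np.ndarray | float:
        return self.d + self.total_bound()

    def copy(self) -> "XbDistribution":
        d = self.d.copy() if isinstance(self.d, np.ndarray) else self.d
        return XbDistribution(self.a1.copy(), self.a2.copy(), d)


@dataclass
class HalfSarcomereState:
    """Length plus cross-bridge distribution of one half-sarcomere, with
    cached force components (force_total = force_active + force_passive)."""

    length: float
    dist: XbDistribution
    force_active: float = 0.0
    force_passive: float = 0.0

    @property
    def force_total(self) -> float:
        return self.force_active + self.force_passive


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def overlap_fraction(length, geometry: OverlapGeometry):
    """Fraction of heads available at a given half-sarcomere length.

    Piecewise linear: 1 on the plateau, 0 beyond the no-overlap lengths,
    continuous everywhere.
    """
    arr = np.asarray(length, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("length must be finite")
    if np.any(arr <= 0):
        raise InvalidInputError("length must be > 0")
    out = np.interp(arr, geometry.breakpoints, [0.0, 1.0, 1.0, 0.0],
                    left=0.0, right=0.0)
    return float(out) if np.isscalar(length) else out


def n_available(length, activation, params: HalfSarcomereParams,
                zeta=None):
    """Available head density N(l, t) = n0 * zeta * psi * phi(l)."""
    act = np.asarray(activation, dtype=float)
    if np.any(act < 0) or np.any(act > 1) or not np.all(np.isfinite(act)):
        raise InvalidInputError("activation must lie in [0, 1]")
    z = params.zeta if zeta is None else zeta
    out = params.n0_density * z * act * overlap_fraction(length, params.overlap)
    return float(out) if np.isscalar(length) and np.isscalar(activation) else out


def passive_force(length, params: HalfSarcomereParams, xi=None):
    """Passive (titin-like) stress at a given length.

    Exponential above the slack offset, linear continuation with matched
    slope below it; strictly increasing everywhere and zero at the offset.
    """
    arr = np.asarray(length, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("length must be finite")
    x = xi if xi is not None else params.xi
    u = (arr - params.passive_offset) / params.passive_lambda
    out = np.where(u >= 0.0, np.expm1(np.minimum(u, 50.0)), u)
    out = x * params.passive_sigma * out
    return float(out) if np.isscalar(length) else out


def passive_stiffness(length, params: HalfSarcomereParams, xi=None):
    """d(passive stress)/d(length); positive everywhere."""
    arr = np.asarray(length, dtype=float)
    x = xi if xi is not None else params.xi
    u = (arr - params.passive_offset) / params.passive_lambda
    out = x * params.passive_sigma / params.passive_lambda * \
        np.where(u >= 0.0, np.exp(np.minimum(u, 50.0)), 1.0)
    return float(out) if np.isscalar(length) else out


def active_force(dist: XbDistribution, params: HalfSarcomereParams):
    """Cross-bridge stress: k_cb * (sum a1*x + sum a2*(x + x_ps)).

    Positive = tensile.  Pre-powerstroke heads bear only their strain;
    post-powerstroke heads additionally bear the stroke displacement.
    """
    x = params.axis.centers()
    if dist.a1.shape[-1] != x.shape[0]:
        raise StructureError("distribution does not match params.axis")
    out = params.k_cb * (dist.a1 @ x + dist.a2 @ (x + params.x_ps))
    return float(out) if dist.a1.ndim == 1 else out


def total_force(state: HalfSarcomereState, params: HalfSarcomereParams) -> float:
    """Active plus passive stress; also refreshes the caches on *state*."""
    state.force_active = active_force(state.dist, params)
    state.force_passive = passive_force(state.length, params)
    return state.force_total


def set_available(dist: XbDistribution, n_new) -> XbDistribution:
    """Rescale the pools so that d + sum(a1) + sum(a2) equals ``n_new``.

    The closure when the available-head count changes (activation ramp or
    overlap change): all pools are scaled proportionally.  Starting from a
    fully empty distribution, new mass enters the detached pool.
    """
    tot = np.asarray(dist.total(), dtype=float)
    n_new = np.asarray(n_new, dtype=float)
    scale = np.where(tot > 0.0, n_new / np.where(tot > 0.0, tot, 1.0), 0.0)
    a1 = dist.a1 * scale[..., None]
    a2 = dist.a2 * scale[..., None]
    d = dist.d * scale + np.where(tot > 0.0, 0.0, n_new)
    if a1.ndim == 1:
        d = float(d)
    return XbDistribution(a1=a1, a2=a2, d=d)


def kinetics_step(dist: XbDistribution, dt: float,
                  tables: RateTables) -> XbDistribution:
    """One forward-Euler step of the D/A1/A2 kinetic exchange.

    Conserves total mass exactly (each outgoing flux reappears in the
    destination state).  The stability guard requires
    dt * (largest total exit rate over bins) < 1, which also guarantees
    non-negative occupancies; any residual negatives from round-off are
    clipped with the mass returned to D.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if dt * tables.max_exit >= 1.0:
        raise StepSizeError(
            f"dt={dt} violates stability guard: dt*max_rate="
            f"{dt * tables.max_exit:.3f} >= 1; reduce dt")
    a1, a2 = dist.a1, dist.a2
    d = np.asarray(dist.d, dtype=float)
    attach = (tables.f0 * dt) * d[..., None] * tables.attach_w
    a1_new = a1 * (1.0 - dt * tables.exit1) + attach + (dt * tables.k_minus3) * a2
    a2_new = a2 * (1.0 - dt * tables.exit2) + (dt * tables.k3) * a1
    d_new = d + dt * ((tables.g1x * a1).sum(axis=-1)
                      + (tables.g2 * a2).sum(axis=-1)) - tables.f0 * dt * d
    # round-off guard: clip negatives back into the detached pool
    neg = np.minimum(a1_new, 0.0).sum(axis=-1) + np.minimum(a2_new, 0.0).sum(axis=-1)
    if np.any(neg < 0.0):
        d_new = d_new + neg
        a1_new = np.maximum(a1_new, 0.0)
        a2_new = np.maximum(a2_new, 0.0)
    if a1_new.ndim == 1:
        d_new = float(d_new)
    return XbDistribution(a1=a1_new, a2=a2_new, d=d_new)


def shift_distribution(dist: XbDistribution, delta_length,
                       axis: StrainAxis,
                       max_leak_frac: float = 1e-6) -> XbDistribution:
    """Advect bound profiles by ``delta_length`` along the strain axis.

    When the half-sarcomere lengthens by ``delta``, every bound head's
    elastic strain grows by ``delta``; the a1/a2 profiles translate
    rigidly.  Conservative linear interpolation is used, which preserves
    both the total bound number and the first strain moment exactly for
    mass that stays on the axis.  Mass pushed past the axis ends is
    returned to the detached pool; if it exceeds ``max_leak_frac`` of the
    bound total an :class:`AxisRangeError` is raised (the axis was too
    narrow for the protocol).
    """
    delta = np.asarray(delta_length, dtype=float)
    half_range = 0.5 * (axis.x_max - axis.x_min)
    if np.any(np.abs(delta) >= half_range):
        raise AxisRangeError(
            f"shift {np.max(np.abs(delta)):.2f} nm exceeds half the axis range")
    batch = dist.a1.shape[:-1]
    nb = axis.n_bins
    a1 = dist.a1.reshape(-1, nb)
    a2 = dist.a2.reshape(-1, nb)
    s = (np.broadcast_to(delta, batch).reshape(-1)
         if batch else np.full(1, float(delta))) / axis.bin_width
    k = np.floor(s).astype(int)
    frac = s - k

    j = np.arange(nb)[None, :]
    src1 = j - k[:, None]        # contributes with weight (1 - frac)
    src2 = src1 - 1              # contributes with weight frac
    ok1 = (src1 >= 0) & (src1 < nb)
    ok2 = (src2 >= 0) & (src2 < nb)
    c1 = np.clip(src1, 0, nb - 1)
    c2 = np.clip(src2, 0, nb - 1)
    w1 = (1.0 - frac)[:, None]
    w2 = frac[:, None]

    def move(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = w1 * np.where(ok1, np.take_along_axis(a, c1, axis=1), 0.0) \
            + w2 * np.where(ok2, np.take_along_axis(a, c2, axis=1), 0.0)
        return out, a.sum(axis=1) - out.sum(axis=1)

    a1_new, leak1 = move(a1)
    a2_new, leak2 = move(a2)
    leak = leak1 + leak2
    bound_total = a1.sum() + a2.sum()
    rel = leak.sum() / bound_total if bound_total > 0 else 0.0
    if rel > max_leak_frac:
        raise AxisRangeError(
            f"{rel:.2e} of bound mass left the strain axis; widen it")
    d_new = np.asarray(dist.d, dtype=float).reshape(-1) + leak
    if batch:
        return XbDistribution(a1=a1_new.reshape(batch + (nb,)),
                              a2=a2_new.reshape(batch + (nb,)),
                              d=d_new.reshape(batch))
    return XbDistribution(a1=a1_new[0], a2=a2_new[0], d=float(d_new[0]))


def instantaneous_stiffness(state: HalfSarcomereState,
                            params: HalfSarcomereParams) -> float:
    """d(total force)/d(length) with the bound population frozen.

    A length change of dl shifts every bound head's strain by dl, so the
    cross-bridge term is k_cb * (bound head count); the passive term is
    the local slope of the passive curve.  Strictly positive.
    """
    return float(params.k_cb * np.asarray(state.dist.total_bound())
                 + passive_stiffness(state.length, params))


def hs_kinetics_step(state: HalfSarcomereState, activation: float, dt: float,
                     params: HalfSarcomereParams,
                     tables: RateTables | None = None) -> XbDistribution:
    """Convenience wrapper: refresh the available pool for the current
    (length, activation), then advance the kinetics by one step."""
    tb = tables if tables is not None else params.rates.tables(params.axis)
    n = n_available(state.length, activation, params)
    return kinetics_step(set_available(state.dist, n), dt, tb)


# ---------------------------------------------------------------------------
# closed-form isometric steady state (used as oracle and reference scale)
# ---------------------------------------------------------------------------

def isometric_steady_state(params: HalfSarcomereParams, length: float,
                           activation: float = 1.0) -> XbDistribution:
    """Steady-state distribution at fixed length and activation.

    At fixed length the kinetic exchange is linear in the occupancies, so
    the stationary point solves per strain bin:

        0 = f0*w(x)*d + k_minus3*a2 - (k3 + g_a1)*a1
        0 = k3*a1 - (k_minus3 + g2)*a2

    normalised so that d + sum(a1) + sum(a2) = N(l, psi).
    """
    tb = params.rates.tables(params.axis)
    n = n_available(length, activation, params)
    denom = tb.exit1 - tb.k_minus3 * tb.k3 / tb.exit2
    a1_hat = tb.f0 * tb.attach_w / denom          # per unit detached pool
    a2_hat = tb.k3 * a1_hat / tb.exit2
    d = n / (1.0 + a1_hat.sum() + a2_hat.sum())
    return XbDistribution(a1=a1_hat * d, a2=a2_hat * d, d=float(d))
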