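"""Activation/length protocols, paired stretch-vs-isometric trials and
the residual force enhancement (RFE) statistic.

The standard protocol activates the fiber linearly over 1 s, holds it
isometric for another second, stretches it at constant velocity to the
final length, and holds.  The isometric companion is activated at the
final length and held there throughout.  RFE is the percentage by which
the ramp-and-hold tension exceeds the isometric companion's tension,
evaluated ``t_ss`` = 6 s after the end of the length change:

    RFE = 100 * (F_stretch(t_ss) - F_iso(t_ss)) / F_iso(t_ss)

Stretch magnitude and velocity are expressed relative to the *final*
length; the equivalent initial-length fractions are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .halfsarcomere import (HalfSarcomereParams, InvalidInputError,
                            isometric_steady_state, active_force,
                            passive_force, overlap_fraction)
from .heterogeneity import HeterogeneitySpec, make_ensemble, sample_multipliers
from .network import Network, SimulationResult, Topology, run_simulation

__all__ = ["Protocol", "RfeResult", "PairResult", "EnsembleResult",
           "activation_trace", "length_trace", "run_protocol_pair",
           "run_ensemble", "steady_state_length_tension", "T_SS_DEFAULT"]

T_SS_DEFAULT = 6.0


@dataclass(frozen=True)
class Protocol:
    """Timing and geometry of one ramp-and-hold / isometric trial pair.

    ``stretch_magnitude`` is the length change as a fraction of the final
    length; ``stretch_velocity`` is in final lengths per second.  The
    imposed trace is per mean half-sarcomere; the network multiplies by
    its series count.
    """

    stretch_magnitude: float = 0.08
    stretch_velocity: float = 0.1
    activation_ramp_duration: float = 1.0
    pre_stretch_hold: float = 1.0
    post_stretch_hold: float = 6.5
    dt: float = 1.0e-3
    initial_mean_hs_length: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("activation_ramp_duration", "pre_stretch_hold",
                     "post_stretch_hold"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if not 0.0 <= self.stretch_magnitude < 1.0:
            raise InvalidInputError("stretch_magnitude must be in [0, 1)")
        if self.stretch_magnitude > 0 and self.stretch_velocity <= 0:
            raise InvalidInputError("stretch_velocity must be > 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def final_mean_hs_length(self) -> float:
        return self.initial_mean_hs_length / (1.0 - self.stretch_magnitude)

    @property
    def stretch_duration(self) -> float:
        if self.stretch_magnitude == 0.0:
            return 0.0
        return self.stretch_magnitude / self.stretch_velocity

    @property
    def stretch_start(self) -> float:
        return self.activation_ramp_duration + self.pre_stretch_hold

    @property
    def stretch_end(self) -> float:
        return self.stretch_start + self.stretch_duration

    @property
    def total_duration(self) -> float:
        return self.stretch_end + self.post_stretch_hold

    def length_per_unit(self, t: float, mode: str) -> float:
        return length_trace(t, self, mode)

    @classmethod
    def from_final_length(cls, final_mean_hs_length: float,
                          **kwargs) -> "Protocol":
        """Build a protocol whose stretch *ends* at the given mean length."""
        mag = kwargs.get("stretch_magnitude", 0.08)
        return cls(initial_mean_hs_length=final_mean_hs_length * (1.0 - mag),
                   **kwargs)


def activation_trace(t: float, protocol: Protocol) -> float:
    """Linear activation ramp: min(t / ramp_duration, 1)."""
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    d = protocol.activation_ramp_duration
    return 1.0 if d == 0.0 else min(t / d, 1.0)


def length_trace(t: float, protocol: Protocol, mode: str) -> float:
    """Imposed mean half-sarcomere length (nm) at time ``t``.

    ``stretch``: initial length, constant-velocity ramp, hold at final.
    ``isometric``: final length throughout.
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    Lf = protocol.final_mean_hs_length
    if mode == "isometric":
        return Lf
    if mode != "stretch":
        raise InvalidInputError(f"unknown protocol mode {mode!r}")
    L0 = protocol.initial_mean_hs_length
    t0, t1 = protocol.stretch_start, protocol.stretch_end
    if t <= t0:
        return L0
    if t >= t1:
        return Lf
    return L0 + (Lf - L0) * (t - t0) / (t1 - t0)


@dataclass(frozen=True)
class RfeResult:
    """Residual force enhancement of one trial pair (or trace average)."""

    rfe_percent: float
    t_ss: float
    force_stretch: float
    force_iso: float
    meta: dict = field(default_factory=dict)


@dataclass
class PairResult:
    stretch: SimulationResult
    isometric: SimulationResult
    rfe: RfeResult


def _rfe_from_traces(time: np.ndarray, f_stretch: np.ndarray,
                     f_iso: np.ndarray, t_eval: float, t_ss: float,
                     meta: dict) -> RfeResult:
    i = int(np.argmin(np.abs(time - t_eval)))
    fs, fi = float(f_stretch[i]), float(f_iso[i])
    return RfeResult(rfe_percent=100.0 * (fs - fi) / fi, t_ss=t_ss,
                     force_stretch=fs, force_iso=fi, meta=meta)


def run_protocol_pair(topology: Topology, params: HalfSarcomereParams,
                      protocol: Protocol, het: HeterogeneitySpec,
                      t_ss: float = T_SS_DEFAULT,
                      record_every: float = 0.01) -> PairResult:
    """Run the ramp-and-hold trial and its isometric companion with the
    same multiplier draw, and evaluate RFE at ``t_ss`` after stretch end."""
    if het.n_units != topology.n_series:
        het = replace(het, n_units=topology.n_series)
    zeta, xi = sample_multipliers(het, topology.n_myofibrils)
    seed_meta = {"seed": het.seed, "alpha": het.alpha, "beta": het.beta}
    stretch = run_simulation(topology, params, protocol, "stretch",
                             zeta=zeta, xi=xi, record_every=record_every,
                             seed_meta=seed_meta)
    iso = run_simulation(topology, params, protocol, "isometric",
                         zeta=zeta, xi=xi, record_every=record_every,
                         seed_meta=seed_meta)
    t_eval = protocol.stretch_end + t_ss
    if t_eval > protocol.total_duration + 1e-9:
        raise InvalidInputError(
            "post_stretch_hold too short for the requested t_ss")
    rfe = _rfe_from_traces(stretch.time, stretch.tension, iso.tension,
                           t_eval, t_ss, dict(seed_meta))
    return PairResult(stretch=stretch, isometric=iso, rfe=rfe)


@dataclass
class EnsembleResult:
    """Seed-averaged trial pair.

    ``rfe`` applies the enhancement formula to the *averaged* tension
    traces (the convention used for reported values); ``rfe_per_seed``
    holds the individual-pair statistics for dispersion estimates.
    """

    time: np.ndarray
    mean_stretch: np.ndarray
    mean_iso: np.ndarray
    rfe: RfeResult
    rfe_per_seed: list[RfeResult]

    @property
    def rfe_seed_mean(self) -> float:
        return float(np.mean([r.rfe_percent for r in self.rfe_per_seed]))

    @property
    def rfe_seed_sd(self) -> float:
        return float(np.std([r.rfe_percent for r in self.rfe_per_seed],
                            ddof=1)) if len(self.rfe_per_seed) > 1 else 0.0


def run_ensemble(topology: Topology, params: HalfSarcomereParams,
                 protocol: Protocol, het: HeterogeneitySpec,
                 n_seeds: int, master_seed: int | None = None,
                 t_ss: float = T_SS_DEFAULT,
                 keep_pairs: bool = False) -> EnsembleResult:
    """Average an ensemble of paired trials over multiplier draws."""
    specs = make_ensemble(het, n_seeds, master_seed)
    acc_s = acc_i = None
    per_seed: list[RfeResult] = []
    time = None
    pairs = []
    for spec in specs:
        pair = run_protocol_pair(topology, params, protocol, spec, t_ss=t_ss)
        if acc_s is None:
            time = pair.stretch.time
            acc_s = np.zeros_like(pair.stretch.tension)
            acc_i = np.zeros_like(pair.isometric.tension)
        acc_s += pair.stretch.tension
        acc_i += pair.isometric.tension
        per_seed.append(pair.rfe)
        if keep_pairs:
            pairs.append(pair)
    acc_s /= n_seeds
    acc_i /= n_seeds
    t_eval = protocol.stretch_end + t_ss
    meta = {"n_seeds": n_seeds, "alpha": het.alpha, "beta": het.beta,
            "master_seed": het.seed if master_seed is None else master_seed}
    rfe = _rfe_from_traces(time, acc_s, acc_i, t_eval, t_ss, meta)
    out = EnsembleResult(time=time, mean_stretch=acc_s, mean_iso=acc_i,
                         rfe=rfe, rfe_per_seed=per_seed)
    if keep_pairs:
        out.pairs = pairs  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# steady-state length-tension curve
# ---------------------------------------------------------------------------

def steady_state_length_tension(params: HalfSarcomereParams,
                                length_grid: np.ndarray,
                                drift_tol: float = 1e-4,
                                max_settle: float = 60.0,
                                dt: float = 1.0e-3):
    """Isometric steady-state total tension at each length on the grid.

    Each point holds a single fully activated half-sarcomere at fixed
    length until the tension drift falls below ``drift_tol`` (fraction
    per second), then records total (active + passive) tension.  Returns
    a DataFrame with active/passive components and a limb label.
    """
    import pandas as pd

    grid = np.asarray(length_grid, dtype=float)
    if np.any(grid < 1000.0) or np.any(grid > 1700.0):
        raise InvalidInputError("length grid must lie within [1000, 1700] nm")
    tb = params.rates.tables(params.axis)
    rows = []
    check = max(1, int(round(0.1 / dt)))
    from .halfsarcomere import (XbDistribution, kinetics_step, n_available,
                                set_available)
    for L in grid:
        n = n_available(L, 1.0, params)
        dist = XbDistribution.all_detached(params.axis, n)
        f_prev = None
        converged = False
        t = 0.0
        while t < max_settle:
            for _ in range(check):
                dist = kinetics_step(set_available(dist, n), dt, tb)
            t += check * dt
            f = active_force(dist, params) + passive_force(L, params)
            if f_prev is not None and f > 0:
                drift = abs(f - f_prev) / max(abs(f), 1e-30) / (check * dt)
                if drift < drift_tol:
                    converged = True
                    break
            f_prev = f
        fa = active_force(dist, params)
        fp = passive_force(L, params)
        rows.append({"length": L, "tension": fa + fp, "active": fa,
                     "passive": fp, "converged": converged})
    df = pd.DataFrame(rows)
    geo = params.overlap
    df["limb"] = np.where(df["length"] < geo.plateau_lo, "ascending",
                          np.where(df["length"] <= geo.plateau_hi,
                                   "plateau", "descending"))
    return df
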