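"""Figure-level computational experiments: parameter sweeps, the
multi-myofibril lattice, the two-unit mechanism demonstration and the
post-stretch convergence time.

Sweeps share one convention: every trial pair in a sweep ends at the same
final mean half-sarcomere length (the quantity varied is the stretch
history, not the end point), matching how stretch responses are compared
against a single isometric reference.  Each function returns a tidy
:class:`pandas.DataFrame` plus scalar summaries where meaningful, and is
bit-for-bit reproducible given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .halfsarcomere import HalfSarcomereParams, InvalidInputError
from .heterogeneity import HeterogeneitySpec
from .network import Topology
from .protocols import (EnsembleResult, Protocol, run_ensemble,
                        run_protocol_pair, steady_state_length_tension,
                        T_SS_DEFAULT)

__all__ = ["SweepSpec", "velocity_sweep", "magnitude_sweep", "length_sweep",
           "alpha_sweep", "beta_alpha_grid", "myofibril_lattice_experiment",
           "two_hs_demo", "convergence_time", "DEFAULT_SEEDS_PER_POINT"]

DEFAULT_SEEDS_PER_POINT = 10


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep description.

    ``variable`` is one of velocity | magnitude | final_length | alpha |
    beta | k_im; ``grid`` the values; ``seeds_per_point`` the ensemble
    size at each grid point; ``master_seed`` the reproducibility anchor.
    """

    variable: str
    grid: tuple
    seeds_per_point: int = DEFAULT_SEEDS_PER_POINT
    master_seed: int = 0
    alpha: float = 0.2
    beta: float = 0.0
    topology: Topology = Topology()
    protocol: Protocol = Protocol()

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise InvalidInputError("sweep grid must be non-empty")
        if self.seeds_per_point < 1:
            raise InvalidInputError("seeds_per_point must be >= 1")


def _point(topology, params, protocol, alpha, beta, n_seeds, master,
           t_ss=T_SS_DEFAULT) -> EnsembleResult:
    het = HeterogeneitySpec(alpha=alpha, beta=beta,
                            n_units=topology.n_series)
    return run_ensemble(topology, params, protocol, het, n_seeds,
                        master_seed=master, t_ss=t_ss)


def velocity_sweep(spec: SweepSpec, params: HalfSarcomereParams
                   ) -> pd.DataFrame:
    """Ensemble RFE at fixed 8% magnitude across stretch velocities.

    The returned frame carries a ``max_min_ratio`` attribute; residual
    enhancement is expected to vary little with velocity.
    """
    rows = []
    for k, v in enumerate(spec.grid):
        prot = replace(spec.protocol, stretch_velocity=float(v))
        ens = _point(spec.topology, params, prot, spec.alpha, spec.beta,
                     spec.seeds_per_point, spec.master_seed + k)
        rows.append({"velocity": float(v), "rfe_percent": ens.rfe.rfe_percent,
                     "rfe_seed_mean": ens.rfe_seed_mean,
                     "rfe_seed_sd": ens.rfe_seed_sd})
    df = pd.DataFrame(rows)
    df.attrs["max_min_ratio"] = float(df.rfe_percent.max()
                                      / df.rfe_percent.min()) \
        if (df.rfe_percent > 0).all() else float("nan")
    return df


def magnitude_sweep(spec: SweepSpec, params: HalfSarcomereParams
                    ) -> pd.DataFrame:
    """Ensemble RFE versus stretch magnitude at fixed velocity.

    All magnitudes end at the protocol's standard final length.  The
    frame's attrs carry the least-squares slope/intercept (RFE % per %
    stretch), the through-origin slope and R^2; with fewer than two
    distinct magnitudes the fit is flagged degenerate instead.
    """
    final = spec.protocol.final_mean_hs_length
    rows = []
    for k, m in enumerate(spec.grid):
        prot = Protocol(
            stretch_magnitude=float(m),
            stretch_velocity=spec.protocol.stretch_velocity,
            activation_ramp_duration=spec.protocol.activation_ramp_duration,
            pre_stretch_hold=spec.protocol.pre_stretch_hold,
            post_stretch_hold=spec.protocol.post_stretch_hold,
            dt=spec.protocol.dt,
            initial_mean_hs_length=final * (1.0 - float(m)))
        ens = _point(spec.topology, params, prot, spec.alpha, spec.beta,
                     spec.seeds_per_point, spec.master_seed + k)
        rows.append({"magnitude_percent": 100.0 * float(m),
                     "rfe_percent": ens.rfe.rfe_percent,
                     "rfe_seed_mean": ens.rfe_seed_mean,
                     "rfe_seed_sd": ens.rfe_seed_sd})
    df = pd.DataFrame(rows)
    x = df.magnitude_percent.to_numpy()
    y = df.rfe_percent.to_numpy()
    if len(np.unique(x)) < 2:
        df.attrs["degenerate"] = True
        return df
    df.attrs["degenerate"] = False
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    df.attrs["slope"] = float(coef[0])
    df.attrs["intercept"] = float(coef[1])
    df.attrs["slope_through_origin"] = float((x @ y) / (x @ x))
    resid = y - A @ coef
    tot = ((y - y.mean()) ** 2).sum()
    df.attrs["r_squared"] = float(1.0 - (resid ** 2).sum() / tot) \
        if tot > 0 else float("nan")
    return df


def length_sweep(spec: SweepSpec, params: HalfSarcomereParams
                 ) -> pd.DataFrame:
    """RFE for stretches ending at several final mean lengths, with the
    corresponding isometric tension and limb classification, and whether
    the enhanced tension exceeds the isometric optimum."""
    geo = params.overlap
    rows = []
    iso_opt = None
    for k, L in enumerate(spec.grid):
        prot = Protocol.from_final_length(
            float(L), stretch_magnitude=spec.protocol.stretch_magnitude,
            stretch_velocity=spec.protocol.stretch_velocity,
            dt=spec.protocol.dt,
            post_stretch_hold=spec.protocol.post_stretch_hold)
        ens = _point(spec.topology, params, prot, spec.alpha, spec.beta,
                     spec.seeds_per_point, spec.master_seed + k)
        limb = ("ascending" if L < geo.plateau_lo else
                "plateau" if L <= geo.plateau_hi else "descending")
        rows.append({"final_length": float(L),
                     "rfe_percent": ens.rfe.rfe_percent,
                     "tension_stretch": ens.rfe.force_stretch,
                     "tension_iso": ens.rfe.force_iso,
                     "limb": limb})
    df = pd.DataFrame(rows)
    plateau = df[df.limb == "plateau"]
    if len(plateau):
        iso_opt = float(df.tension_iso.max())
        df.attrs["iso_at_optimum"] = iso_opt
        df.attrs["exceeds_optimum"] = bool(
            (plateau.tension_stretch > iso_opt).any())
    return df


def alpha_sweep(spec: SweepSpec, params: HalfSarcomereParams
                ) -> pd.DataFrame:
    """Ensemble RFE versus the strength-heterogeneity level alpha."""
    rows = []
    for k, a in enumerate(spec.grid):
        ens = _point(spec.topology, params, spec.protocol, float(a),
                     spec.beta, spec.seeds_per_point, spec.master_seed + k)
        rows.append({"alpha": float(a), "rfe_percent": ens.rfe.rfe_percent,
                     "rfe_seed_sd": ens.rfe_seed_sd})
    return pd.DataFrame(rows)


def beta_alpha_grid(params: HalfSarcomereParams,
                    alphas: Sequence[float] = (0.0, 0.1, 0.2),
                    betas: Sequence[float] = (0.0, 0.1, 0.2),
                    seeds_per_point: int = DEFAULT_SEEDS_PER_POINT,
                    master_seed: int = 0,
                    topology: Topology = Topology(),
                    protocol: Protocol = Protocol()) -> pd.DataFrame:
    """RFE over the (beta x alpha) grid of heterogeneity combinations."""
    rows = []
    k = 0
    for b in betas:
        for a in alphas:
            ens = _point(topology, params, protocol, float(a), float(b),
                         seeds_per_point, master_seed + k)
            rows.append({"alpha": float(a), "beta": float(b),
                         "rfe_percent": ens.rfe.rfe_percent})
            k += 1
    return pd.DataFrame(rows)


def myofibril_lattice_experiment(params: HalfSarcomereParams,
                                 n_myofibrils: int = 6,
                                 n_series: int = 50,
                                 k_im: float = 0.1,
                                 alpha: float = 0.2,
                                 stretch_duration: float = 4.0,
                                 seeds: int = 4,
                                 master_seed: int = 0,
                                 dt: float = 1e-3) -> dict:
    """Slow 8% stretch of a z-line-coupled myofibril lattice.

    Returns the ensemble RFE plus the relative variation (SD/mean) of
    whole-sarcomere versus half-sarcomere lengths at the evaluation time,
    computed from the last ensemble member's stretched trial.
    """
    mag = 0.08
    prot = Protocol(stretch_magnitude=mag,
                    stretch_velocity=mag / stretch_duration, dt=dt)
    topo = Topology(n_series=n_series, n_myofibrils=n_myofibrils, k_im=k_im)
    het = HeterogeneitySpec(alpha=alpha, n_units=n_series)
    ens = run_ensemble(topo, params, prot, het, seeds,
                       master_seed=master_seed, keep_pairs=True)
    pair = ens.pairs[-1]
    rt = pair.stretch.record_time
    j = int(np.argmin(np.abs(rt - (prot.stretch_end + T_SS_DEFAULT))))
    hs_len = pair.stretch.unit_lengths[j]              # (M, N)
    sarc_len = hs_len[:, 0::2] + hs_len[:, 1::2]       # adjacent pairs
    rel_sd_hs = float(hs_len.std() / hs_len.mean())
    rel_sd_sarc = float(sarc_len.std() / sarc_len.mean())
    return {"rfe": ens.rfe, "ensemble": ens,
            "rel_sd_half_sarcomere": rel_sd_hs,
            "rel_sd_sarcomere": rel_sd_sarc}


def two_hs_demo(params: HalfSarcomereParams,
                zeta_weak: float = 0.85, zeta_strong: float = 1.15,
                protocol: Protocol | None = None,
                late_time: float = 32.0,
                lt_grid: np.ndarray | None = None) -> dict:
    """Two dissimilar half-sarcomeres in series: the mechanism demo.

    Runs the stretch protocol on a weak/strong pair and reports each
    unit's (length, tension) at 1 s after stretch end and at a late time,
    together with its steady-state length-tension curve, so the transient
    can be seen to lie above the weak unit's curve and below the strong
    unit's.
    """
    from .network import Network

    prot = protocol or Protocol(post_stretch_hold=max(late_time + 1.0, 6.5))
    if prot.stretch_end + late_time > prot.total_duration:
        prot = replace(prot, post_stretch_hold=late_time + 1.0)
    topo = Topology(n_series=2)
    zeta = np.array([[zeta_weak, zeta_strong]])
    net = Network(topo, params, zeta=zeta)
    res = net.run(prot, mode="stretch")
    iso = Network(topo, params, zeta=zeta).run(prot, mode="isometric")

    if lt_grid is None:
        lt_grid = np.linspace(1050.0, 1650.0, 25)
    curves = {}
    for tag, z in (("weak", zeta_weak), ("strong", zeta_strong)):
        pz = replace(params, zeta=z)
        curves[tag] = steady_state_length_tension(pz, lt_grid)

    def snapshot(t):
        j = int(np.argmin(np.abs(res.record_time - t)))
        i = int(np.argmin(np.abs(res.time - t)))
        return {"time": float(res.record_time[j]),
                "length_weak": float(res.unit_lengths[j, 0, 0]),
                "length_strong": float(res.unit_lengths[j, 0, 1]),
                "tension": float(res.tension[i])}

    t1 = prot.stretch_end + 1.0
    out = {"stretch": res, "isometric": iso, "curves": curves,
           "at_1s": snapshot(t1), "late": snapshot(prot.stretch_end
                                                   + late_time)}

    def curve_at(tag, length):
        c = curves[tag]
        return float(np.interp(length, c.length, c.tension))

    s1 = out["at_1s"]
    out["weak_above_curve"] = s1["tension"] > curve_at("weak",
                                                       s1["length_weak"])
    out["strong_below_curve"] = s1["tension"] < curve_at(
        "strong", s1["length_strong"])
    return out


def convergence_time(time: np.ndarray, f_stretch: np.ndarray,
                     f_iso: np.ndarray, stretch_end: float,
                     threshold: float = 0.01) -> float:
    """First time after stretch end at which the relative tension
    difference falls below ``threshold`` and stays below.

    Returns the duration (s) after stretch end, or ``inf`` if the traces
    never converge within the simulated horizon.
    """
    mask = time > stretch_end
    t = time[mask]
    rel = np.abs(f_stretch[mask] - f_iso[mask]) / np.abs(f_iso[mask])
    below = rel < threshold
    if not below.any():
        return float("inf")
    # last crossing from above to below
    above_idx = np.nonzero(~below)[0]
    if len(above_idx) == 0:
        return 0.0
    last_above = above_idx[-1]
    if last_above == len(below) - 1:
        return float("inf")
    return float(t[last_above + 1] - stretch_end)
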