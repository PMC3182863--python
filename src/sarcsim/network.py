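"""Series/parallel networks of half-sarcomeres and their time integration.

A myofibril is a chain of half-sarcomeres sharing one imposed total
length; the computer finds the individual lengths by balancing force at
every connection.  Several myofibrils may run in parallel, optionally
coupled by springs between corresponding z-lines (stiffness ``k_im``),
which penalise z-line misregistration across the fiber.

Within a single time step the force of unit *i* as a function of its
length is exactly

    F_i(l) = A_i + K_i * (l - l_i) + P_i(l)

where ``A_i`` is the current cross-bridge stress, ``K_i = k_cb * n_bound``
the cross-bridge stiffness (a length change shifts every bound head's
strain rigidly, and the conservative shift preserves the first strain
moment exactly), and ``P_i`` the passive curve.  ``F_i`` is strictly
increasing, so the uncoupled balance has a unique solution found by a
nested Newton iteration on the common tension; the coupled lattice is
solved by a damped Newton iteration with a banded Jacobian.

Time stepping uses operator splitting: cross-bridge kinetics at frozen
lengths, then force balance at the new total length with the bound
distributions advected by each unit's length change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.linalg import solve_banded

from .halfsarcomere import (
    HalfSarcomereParams,
    InvalidInputError,
    StrainAxis,
    XbDistribution,
    isometric_steady_state,
    kinetics_step,
    n_available,
    overlap_fraction,
    passive_force,
    passive_stiffness,
    set_available,
    shift_distribution,
)

if TYPE_CHECKING:  # pragma: no cover
    from .protocols import Protocol

__all__ = ["Topology", "NetworkState", "Network", "SimulationResult",
           "SolverError", "run_simulation"]


class SolverError(RuntimeError):
    """Force-balance Newton iteration failed to converge."""


@dataclass(frozen=True)
class Topology:
    """Network shape: ``n_series`` half-sarcomeres per myofibril,
    ``n_myofibrils`` in parallel, z-line coupling stiffness ``k_im``
    (dimensionless; scaled internally by the isometric reference stress
    per nm of misregistration)."""

    n_series: int = 50
    n_myofibrils: int = 1
    k_im: float = 0.0

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_myofibrils < 1:
            raise InvalidInputError("topology counts must be >= 1")
        if self.k_im < 0:
            raise InvalidInputError("k_im must be >= 0")


@dataclass
class NetworkState:
    """Lengths (n_myofibrils, n_series) and batched cross-bridge
    distribution of every half-sarcomere, plus cached forces."""

    lengths: np.ndarray          # (M, N) nm
    dist: XbDistribution         # batch shape (M, N)
    forces: np.ndarray | None = None

    @property
    def total_length(self) -> float:
        return float(self.lengths[0].sum())

    def node_positions(self) -> np.ndarray:
        """Cumulative node positions per myofibril, node 0 at 0 (nm)."""
        M, N = self.lengths.shape
        pos = np.zeros((M, N + 1))
        np.cumsum(self.lengths, axis=1, out=pos[:, 1:])
        return pos


@dataclass
class SimulationResult:
    """Time series produced by :meth:`Network.run`.

    ``tension`` is the fiber stress (mean over myofibrils of the force
    transmitted at the fiber end) at every integration step;
    per-unit lengths and forces are stored on the coarser recording grid.
    """

    time: np.ndarray
    tension: np.ndarray
    activation: np.ndarray
    total_length: np.ndarray
    record_time: np.ndarray
    unit_lengths: np.ndarray      # (T_rec, M, N)
    unit_forces: np.ndarray       # (T_rec, M, N)
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        """Tidy per-unit DataFrame (time, myofibril, unit, length, force)."""
        import pandas as pd
        T, M, N = self.unit_lengths.shape
        t = np.repeat(self.record_time, M * N)
        m = np.tile(np.repeat(np.arange(M), N), T)
        u = np.tile(np.arange(N), T * M)
        return pd.DataFrame({
            "time": t, "myofibril": m, "unit": u,
            "length": self.unit_lengths.reshape(-1),
            "force": self.unit_forces.reshape(-1),
        })

    def trace_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time": self.time, "tension": self.tension,
            "activation": self.activation, "total_length": self.total_length,
        })


class Network:
    """A lattice of half-sarcomeres sharing base parameters, with per-unit
    strength (``zeta``) and passive (``xi``) multipliers."""

    def __init__(self, topology: Topology, params: HalfSarcomereParams,
                 zeta: np.ndarray | None = None,
                 xi: np.ndarray | None = None) -> None:
        M, N = topology.n_myofibrils, topology.n_series
        self.topology = topology
        self.params = params
        self.axis: StrainAxis = params.axis
        self.tables = params.rates.tables(params.axis)
        self.zeta = np.ones((M, N)) if zeta is None else \
            np.broadcast_to(np.asarray(zeta, float), (M, N)).copy()
        self.xi = np.ones((M, N)) if xi is None else \
            np.broadcast_to(np.asarray(xi, float), (M, N)).copy()
        if np.any(self.zeta <= 0) or np.any(self.xi <= 0):
            raise InvalidInputError("zeta and xi must be > 0")
        # reference stress for the dimensionless k_im coupling
        if topology.k_im > 0:
            ss = isometric_steady_state(params, 1200.0, 1.0)
            from .halfsarcomere import active_force
            self._f_ref = float(active_force(ss, params)
                                + passive_force(1200.0, params, xi=1.0))
        else:
            self._f_ref = 0.0
        self.diagnostics = {"solver_iterations": 0, "solver_calls": 0,
                            "max_boundary_occupancy": 0.0,
                            "leaked_mass_frac": 0.0}

    # -- state construction -------------------------------------------------

    def initial_state(self, mean_length: float) -> NetworkState:
        M, N = self.topology.n_myofibrils, self.topology.n_series
        lengths = np.full((M, N), float(mean_length))
        dist = XbDistribution.all_detached(self.axis, 0.0, batch_shape=(M, N))
        st = NetworkState(lengths=lengths, dist=dist)
        st.forces = self._unit_forces(st)
        return st

    # -- force bookkeeping --------------------------------------------------

    def _unit_forces(self, state: NetworkState) -> np.ndarray:
        x = self.axis.centers()
        act = self.params.k_cb * (state.dist.a1 @ x
                                  + state.dist.a2 @ (x + self.params.x_ps))
        return act + passive_force(state.lengths, self.params, xi=self.xi)

    def fiber_tension(self, state: NetworkState) -> float:
        """Stress transmitted at the fiber boundary (mean over myofibrils
        of each myofibril's first half-sarcomere force)."""
        if state.forces is None:
            state.forces = self._unit_forces(state)
        return float(state.forces[:, 0].mean())

    # -- force balance ------------------------------------------------------

    def solve_force_balance(self, state: NetworkState,
                            new_total_length: float) -> NetworkState:
        """Re-balance the network at a new imposed total length.

        Bound distributions are advected by each unit's length change;
        forces are re-cached.  For a single myofibril (or uncoupled
        myofibrils) all forces within a chain are equal afterwards.
        """
        cur = state.total_length
        if not (0.5 * cur <= new_total_length <= 2.0 * cur):
            raise InvalidInputError(
                f"new total length {new_total_length:.1f} outside sanity "
                f"bounds [0.5, 2] x current {cur:.1f}")
        A = self.params.k_cb * (state.dist.a1 @ self.axis.centers()
                                + state.dist.a2 @ (self.axis.centers()
                                                   + self.params.x_ps))
        K = self.params.k_cb * np.asarray(state.dist.total_bound())
        l0 = state.lengths
        if self.topology.k_im == 0.0 or self.topology.n_myofibrils == 1:
            l_new, F = self._solve_chains(A, K, l0, new_total_length)
        else:
            l_new, F = self._solve_lattice(A, K, l0, new_total_length)
        delta = l_new - l0
        # Mass dragged past the axis end during popping excursions is
        # forcibly detached (returned to D); track the cumulative fraction.
        bound_before = float(np.asarray(state.dist.total_bound()).sum())
        half_range = 0.5 * (self.axis.x_max - self.axis.x_min)
        n_sub = max(1, int(np.ceil(np.max(np.abs(delta)) / (0.9 * half_range))))
        dist = state.dist
        for _ in range(n_sub):
            dist = shift_distribution(dist, delta / n_sub, self.axis,
                                      max_leak_frac=5e-2)
        bound_after = float(np.asarray(dist.total_bound()).sum())
        if bound_before > 0:
            self.diagnostics["leaked_mass_frac"] += \
                (bound_before - bound_after) / bound_before
        new = NetworkState(lengths=l_new, dist=dist)
        new.forces = F
        return new

    def _force_of(self, A, K, l0, l):
        return A + K * (l - l0) + passive_force(l, self.params, xi=self.xi)

    def _dforce_of(self, K, l):
        return K + passive_stiffness(l, self.params, xi=self.xi)

    def _invert_lengths(self, A, K, l0, T):
        """Per-unit lengths at which F_i(l) = T (vectorised Newton)."""
        l = l0.copy()
        for _ in range(60):
            r = self._force_of(A, K, l0, l) - T
            dl = r / self._dforce_of(K, l)
            l = l - dl
            if np.max(np.abs(dl)) < 1e-10:
                break
        return l

    def _solve_chains(self, A, K, l0, L_total):
        """Uncoupled myofibrils: Newton on the shared tension per chain."""
        T = self._force_of(A, K, l0, l0).mean(axis=1, keepdims=True)
        it = 0
        for it in range(80):
            l = self._invert_lengths(A, K, l0, T)
            g = l.sum(axis=1, keepdims=True) - L_total
            if np.max(np.abs(g)) < max(1e-12 * L_total, 1e-7):
                break
            dLdT = (1.0 / self._dforce_of(K, l)).sum(axis=1, keepdims=True)
            T = T - g / dLdT
        else:
            raise SolverError("shared-tension Newton did not converge")
        self.diagnostics["solver_calls"] += 1
        self.diagnostics["solver_iterations"] += it + 1
        F = self._force_of(A, K, l0, l)
        return l, F

    def _solve_lattice(self, A, K, l0, L_total):
        """Coupled myofibrils: damped Newton on interior node positions.

        Unknowns are node positions p[m, j] (j = 1..N-1) with both fiber
        ends shared across myofibrils.  Z-line springs act at even node
        indices, all-to-all within a z-disk ring, with stiffness
        k_im * f_ref per nm.
        """
        M, N = l0.shape
        kim = self.topology.k_im * self._f_ref
        p = np.zeros((M, N + 1))
        scale = L_total / l0.sum(axis=1, keepdims=True)
        np.cumsum(l0 * scale, axis=1, out=p[:, 1:])
        interior = np.arange(1, N)
        zmask = (interior % 2 == 0).astype(float)    # z-lines at even nodes

        def residual(p):
            l = np.diff(p, axis=1)
            F = self._force_of(A, K, l0, l)
            r = F[:, 1:] - F[:, :-1]
            if kim > 0:
                pm = p[:, 1:N]
                r = r + kim * zmask * (pm.mean(axis=0, keepdims=True) - pm) * M
            return r, l

        r, l = residual(p)
        norm = np.max(np.abs(r))
        tol = max(1e-6 * np.abs(self._force_of(A, K, l0, l)).mean(), 1e-4)
        n_unknowns = M * (N - 1)
        for it in range(60):
            if norm < tol:
                break
            dF = self._dforce_of(K, l)
            # ordering: u[(j-1)*M + m]; bandwidth M
            ab = np.zeros((2 * M + 1, n_unknowns))
            idx = (np.arange(1, N)[:, None] - 1) * M + np.arange(M)[None, :]
            diag = -(dF[:, 1:] + dF[:, :-1]).T.reshape(-1)
            if kim > 0:
                diag = diag - (kim * (M - 1)) * np.repeat(zmask, M)
            ab[M, :] = diag
            up = dF[:, 1:N - 1].T.reshape(-1) if N > 2 else np.empty(0)
            if N > 2:
                ab[0, M:] = up                      # dR[m,j]/dp[m,j+1]
                ab[2 * M, :-M] = up                 # dR[m,j+1]/dp[m,j]
            if kim > 0 and M > 1:
                # off-diagonal coupling within a z-disk ring
                for off in range(1, M):
                    row_u = M - off
                    row_l = M + off
                    cols = np.arange(n_unknowns - off)
                    jj = np.repeat(zmask, M)
                    same_block = (cols // M) == ((cols + off) // M)
                    val = np.where(same_block, kim * jj[cols], 0.0)
                    ab[row_u, off:] = ab[row_u, off:] + val
                    ab[row_l, :n_unknowns - off] = ab[row_l, :n_unknowns - off] + val
            rhs = -r.T.reshape(-1)
            try:
                du = solve_banded((M, M), ab, rhs)
            except Exception as exc:  # pragma: no cover
                raise SolverError(f"banded solve failed: {exc}") from exc
            step = 1.0
            for _ in range(8):
                p_try = p.copy()
                p_try[:, 1:N] += step * du.reshape(N - 1, M).T
                r_try, l_try = residual(p_try)
                n_try = np.max(np.abs(r_try))
                if n_try < norm or n_try < tol:
                    p, r, l, norm = p_try, r_try, l_try, n_try
                    break
                step *= 0.5
            else:
                raise SolverError(
                    f"lattice Newton stalled at residual {norm:.3e} "
                    f"(tol {tol:.3e}) after {it} iterations")
        else:
            raise SolverError("lattice Newton did not converge")
        self.diagnostics["solver_calls"] += 1
        self.diagnostics["solver_iterations"] += it + 1
        F = self._force_of(A, K, l0, l)
        return l, F

    # -- time stepping ------------------------------------------------------

    def integrate_step(self, state: NetworkState, L_target: float,
                       activation: float, dt: float) -> NetworkState:
        """One operator-split step: refresh available pools, advance the
        kinetics, then re-balance at the target total length."""
        n_av = n_available(state.lengths, activation, self.params,
                           zeta=self.zeta)
        dist = set_available(state.dist, n_av)
        dist = kinetics_step(dist, dt, self.tables)
        state = NetworkState(lengths=state.lengths, dist=dist)
        return self.solve_force_balance(state, L_target)

    def run(self, protocol: "Protocol", mode: str = "stretch",
            record_every: float = 0.01, seed_meta: dict | None = None,
            ) -> SimulationResult:
        """Integrate a full protocol and record tension/length traces.

        Uncoupled chains run through a fused compiled step; the z-line
        coupled lattice uses the compiled kinetics plus the banded Newton
        balance.  Both paths implement the same split scheme as
        :meth:`integrate_step`.
        """
        from ._kernels import chain_step, kinetics_inplace, shift_inplace
        from .protocols import activation_trace, length_trace

        M, N = self.topology.n_myofibrils, self.topology.n_series
        B = self.axis.n_bins
        p = self.params
        tb = self.tables
        dt = protocol.dt
        if dt * tb.max_exit >= 1.0:
            from .halfsarcomere import StepSizeError
            raise StepSizeError(
                f"dt={dt} violates stability guard (dt*max_rate="
                f"{dt * tb.max_exit:.3f} >= 1); reduce dt")
        n_steps = int(round(protocol.total_duration / dt))
        meta_base = {"mode": mode, "topology": self.topology}
        if seed_meta:
            meta_base.update(seed_meta)
        if n_steps == 0:
            meta_base["diagnostics"] = dict(self.diagnostics)
            empty = np.empty(0)
            return SimulationResult(
                time=empty, tension=empty, activation=empty,
                total_length=empty, record_time=empty,
                unit_lengths=np.empty((0, M, N)),
                unit_forces=np.empty((0, M, N)), meta=meta_base)

        L0_unit = protocol.length_per_unit(0.0, mode)
        a1 = np.zeros((M, N, B))
        a2 = np.zeros((M, N, B))
        d = np.zeros((M, N))
        lengths = np.full((M, N), float(L0_unit))
        geo = p.overlap
        rec_stride = max(1, int(round(record_every / dt)))

        time = np.empty(n_steps + 1)
        tension = np.empty(n_steps + 1)
        act_tr = np.empty(n_steps + 1)
        L_tr = np.empty(n_steps + 1)
        rec_t, rec_l, rec_f = [], [], []
        tension_out = np.empty(M)
        bound_integral = 0.0
        leak_integral = 0.0

        f_pass0 = float(np.mean(passive_force(lengths, p, xi=self.xi)))
        time[0], tension[0] = 0.0, f_pass0
        act_tr[0] = activation_trace(0.0, protocol)
        L_tr[0] = L0_unit * N
        rec_t.append(0.0)
        rec_l.append(lengths.copy())
        rec_f.append(np.full((M, N), f_pass0))

        chain = self.topology.k_im == 0.0 or M == 1
        for i in range(1, n_steps + 1):
            t = i * dt
            psi = activation_trace(t, protocol)
            L = length_trace(t, protocol, mode) * N
            if chain:
                bb, lk, edge = chain_step(
                    a1, a2, d, lengths, self.zeta, self.xi, L, psi, dt,
                    tb.x, tb.attach_w, tb.k3, tb.g1x, tb.g2,
                    tb.exit1, tb.exit2, tb.f0, tb.k_minus3, tb.x_ps,
                    p.n0_density, p.k_cb, p.passive_sigma,
                    p.passive_offset, p.passive_lambda,
                    geo.ascending_zero, geo.plateau_lo, geo.plateau_hi,
                    geo.descending_zero, self.axis.bin_width, tension_out)
                tension[i] = tension_out.mean()
                F_units = None
            else:
                n_av = n_available(lengths, psi, p, zeta=self.zeta)
                kinetics_inplace(a1.reshape(M * N, B), a2.reshape(M * N, B),
                                 d.reshape(-1), n_av.reshape(-1), dt,
                                 tb.attach_w, tb.k3, tb.g1x, tb.g2,
                                 tb.exit1, tb.exit2, tb.f0, tb.k_minus3)
                A = p.k_cb * (a1 @ tb.x + a2 @ (tb.x + tb.x_ps))
                K = p.k_cb * (a1.sum(axis=-1) + a2.sum(axis=-1))
                l_new, F_units = self._solve_lattice(A, K, lengths, L)
                deltas = l_new - lengths
                bb, lk = shift_inplace(a1.reshape(M * N, B),
                                       a2.reshape(M * N, B), d.reshape(-1),
                                       deltas.reshape(-1),
                                       self.axis.bin_width)
                edge = float((a1[..., 0].sum() + a1[..., -1].sum()
                              + a2[..., 0].sum() + a2[..., -1].sum())
                             / bb) if bb > 0 else 0.0
                lengths[...] = l_new
                tension[i] = F_units[:, 0].mean()
            bound_integral += bb
            leak_integral += lk
            if edge > self.diagnostics["max_boundary_occupancy"]:
                self.diagnostics["max_boundary_occupancy"] = edge
            time[i] = t
            act_tr[i] = psi
            L_tr[i] = float(lengths[0].sum())
            if i % rec_stride == 0 or i == n_steps:
                rec_t.append(t)
                rec_l.append(lengths.copy())
                rec_f.append(np.full((M, N), tension[i]) if F_units is None
                             else F_units.copy())

        if bound_integral > 0:
            self.diagnostics["leaked_mass_frac"] = leak_integral / \
                (bound_integral / n_steps)
        meta_base["diagnostics"] = dict(self.diagnostics)
        return SimulationResult(
            time=time, tension=tension, activation=act_tr, total_length=L_tr,
            record_time=np.asarray(rec_t), unit_lengths=np.asarray(rec_l),
            unit_forces=np.asarray(rec_f), meta=meta_base)

    def _update_boundary_diag(self, state: NetworkState) -> None:
        bound = np.asarray(state.dist.total_bound())
        tot = bound.sum()
        if tot > 0:
            edge = (state.dist.a1[..., 0] + state.dist.a1[..., -1]
                    + state.dist.a2[..., 0] + state.dist.a2[..., -1]).sum()
            occ = float(edge / tot)
            if occ > self.diagnostics["max_boundary_occupancy"]:
                self.diagnostics["max_boundary_occupancy"] = occ


def run_simulation(topology: Topology, params: HalfSarcomereParams,
                   protocol: "Protocol", mode: str = "stretch",
                   zeta: np.ndarray | None = None,
                   xi: np.ndarray | None = None,
                   record_every: float = 0.01,
                   seed_meta: dict | None = None) -> SimulationResult:
    """Build a :class:`Network` and integrate one protocol."""
    net = Network(topology, params, zeta=zeta, xi=xi)
    return net.run(protocol, mode=mode, record_every=record_every,
                   seed_meta=seed_meta)
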