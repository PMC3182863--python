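"""Sampling of per-unit heterogeneity multipliers and seeded ensembles.

Active strength multipliers ``zeta`` are Gaussian with mean 1 and
standard deviation ``alpha``; passive multipliers ``xi`` are Gaussian
with mean 1 and standard deviation ``beta``.  Draws at or below a small
positive floor are rejected and redrawn, which keeps strengths physical
and is negligible for alpha <= 0.3.  Ensembles derive one child seed per
member from a master seed with a counter-based scheme, so every member
is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .halfsarcomere import InvalidInputError

__all__ = ["HeterogeneitySpec", "sample_multipliers", "make_ensemble",
           "child_seed", "MULTIPLIER_FLOOR"]

MULTIPLIER_FLOOR = 0.05


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Heterogeneity level and sampling context for one network draw."""

    alpha: float = 0.2
    beta: float = 0.0
    seed: int = 0
    n_units: int = 50

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError("alpha and beta must be >= 0")
        if self.n_units < 1:
            raise InvalidInputError("n_units must be >= 1")


def _truncated_normal(rng: np.random.Generator, sd: float,
                      size: int) -> np.ndarray:
    if sd == 0.0:
        return np.ones(size)
    out = rng.normal(1.0, sd, size)
    bad = out <= MULTIPLIER_FLOOR
    while np.any(bad):
        out[bad] = rng.normal(1.0, sd, int(bad.sum()))
        bad = out <= MULTIPLIER_FLOOR
    return out


def sample_multipliers(spec: HeterogeneitySpec,
                       n_myofibrils: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Draw (zeta, xi) arrays of shape (n_myofibrils, n_units).

    Reproducible given ``spec.seed``; zeta draws consume the stream first
    so that the zeta pattern for a seed is independent of beta.
    """
    rng = np.random.default_rng(spec.seed)
    n = n_myofibrils * spec.n_units
    zeta = _truncated_normal(rng, spec.alpha, n)
    xi = _truncated_normal(rng, spec.beta, n)
    shape = (n_myofibrils, spec.n_units)
    return zeta.reshape(shape), xi.reshape(shape)


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed from (master seed, member index)."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_ensemble(base: HeterogeneitySpec, n_seeds: int,
                  master_seed: int | None = None) -> list[HeterogeneitySpec]:
    """Specs for an ensemble of ``n_seeds`` independent multiplier draws.

    If ``master_seed`` is None the base spec's own seed acts as master.
    """
    if n_seeds < 1:
        raise InvalidInputError("n_seeds must be >= 1")
    master = base.seed if master_seed is None else master_seed
    return [replace(base, seed=child_seed(master, k)) for k in range(n_seeds)]
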