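"""Stochastic cellular automaton of a food chain on a fragmented landscape.

Discrete-time, spatially explicit counterpart of the patch-dynamic ODEs,
used to validate them.  Each suitable cell carries a nested chain height
``k``: ``k = 2`` means species 1 and 2 are present, never 2 alone — a
consumer cannot persist locally without its resource.

Per time step three independent event families are sampled from the
start-of-step configuration and then applied together:

1. *Colonization*.  An empty suitable cell gains the basal species with
   probability ``1 - (1 - c1/z)**n1`` (``n1`` occupied von Neumann
   neighbours); a basal-only cell gains a consumer with probability
   ``1 - (1 - c2/S_k)**n2k`` (``n2k`` consumer cells among the ``S_k``
   cells of its habitat cluster); a 1→2 cell gains the top predator with
   probability ``1 - (1 - c3/N)**n3`` (``n3`` predator cells landscape
   wide).  Each form is the independent-trials construction over the
   sources the corresponding dispersal mode can draw on, and linearizes to
   the ODE colonization rates.
2. *Intrinsic extinction*: each species present dies with probability
   ``e_i``.
3. *Top-down extinction*: within each trophic link the prey additionally
   dies with probability ``mu_ji``.

Deaths are drawn only for species present at the start of the step, so a
cell colonized and struck in the same step resolves to the post-extinction
state; afterwards the cascade rule removes every species above a vanished
one (bottom-up collapse is immediate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape, LatticeConfig, generate_landscape
from .epdm import ChainParams

__all__ = [
    "CAState",
    "ReplicateSummary",
    "init_ca",
    "colonization_prob_neighbour",
    "colonization_prob_cluster",
    "colonization_prob_global",
    "step",
    "run",
    "run_replicates",
]


def colonization_prob_neighbour(n1: int | np.ndarray, c1: float,
                                z: int = 4) -> float | np.ndarray:
    """P(empty cell colonized | n1 occupied neighbours) = 1-(1-c1/z)^n1."""
    if c1 < 0 or c1 > z:
        raise ValueError(f"need 0 <= c1 <= z={z} for a valid probability")
    return 1.0 - (1.0 - c1 / z) ** np.asarray(n1)


def colonization_prob_cluster(n2k: int | np.ndarray, Sk: int | np.ndarray,
                              c2: float) -> float | np.ndarray:
    """Within-cluster colonization, 1-(1-c2/Sk)^n2k; needs c2 <= min(Sk)."""
    Sk = np.asarray(Sk)
    if np.any(c2 > Sk):
        raise ValueError(
            f"c2={c2} exceeds a cluster size (min {Sk.min()}); "
            "per-trial probability would leave [0, 1]"
        )
    return 1.0 - (1.0 - c2 / Sk) ** np.asarray(n2k)


def colonization_prob_global(n3: int | np.ndarray, N: int,
                             c3: float) -> float | np.ndarray:
    """Global colonization, 1-(1-c3/N)^n3 ~ c3*rho3 for c3/N small."""
    if c3 < 0 or c3 > N:
        raise ValueError(f"need 0 <= c3 <= N={N}")
    return 1.0 - (1.0 - c3 / N) ** np.asarray(n3)


@dataclass
class CAState:
    landscape: Landscape
    chain_height: np.ndarray  # uint8 L x L, 0..n_levels, 0 on unsuitable
    rng: np.random.Generator = field(repr=False)
    step_index: int = 0

    def occupancies(self) -> np.ndarray:
        """(rho1, rho12, rho23) as fractions of all patches."""
        k = self.chain_height
        n = k.size
        return np.array(
            [(k >= 1).sum() / n, (k >= 2).sum() / n, (k >= 3).sum() / n]
        )


def init_ca(
    landscape: Landscape,
    params: ChainParams,
    init_densities: tuple[float, ...] = (0.1, 0.05, 0.025),
    seed: int | np.random.Generator | None = None,
) -> CAState:
    """Random sparse seeding honouring nesting.

    The basal species lands on each suitable cell with probability
    ``theta1``; each higher level establishes on cells already holding its
    prey with the conditional probability ``theta_k / theta_{k-1}``, so its
    unconditional density is approximately ``theta_k`` and nesting holds by
    construction.
    """
    th = init_densities[: params.n_levels]
    if any(t < 0 or t > 1 for t in th):
        raise ValueError("initial densities must lie in [0, 1]")
    if list(th) != sorted(th, reverse=True) or len(set(th)) != len(th):
        raise ValueError(
            "initial densities must strictly decrease with trophic level"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    suit = landscape.grid
    k = np.zeros(suit.shape, dtype=np.uint8)
    occ = suit & (rng.random(suit.shape) < th[0])
    k[occ] = 1
    prev_theta = th[0]
    for lvl in range(2, params.n_levels + 1):
        cond = th[lvl - 1] / prev_theta
        up = (k == lvl - 1) & (rng.random(suit.shape) < cond)
        k[up] = lvl
        prev_theta = th[lvl - 1]
    return CAState(landscape=landscape, chain_height=k, rng=rng)


def _neighbour_occupied_counts(occ: np.ndarray) -> np.ndarray:
    o = occ.astype(np.uint8)
    return (
        np.roll(o, 1, 0) + np.roll(o, -1, 0) + np.roll(o, 1, 1)
        + np.roll(o, -1, 1)
    )


def step(state: CAState, params: ChainParams,
         synchronous: bool = True) -> CAState:
    """Advance one time step in place (returns the same state object)."""
    if synchronous:
        new_k = _step_once(
            state.chain_height, state.landscape, params, state.rng
        )
    else:
        # sequential variant: colonization applied before deaths are drawn
        k = _apply_colonization(
            state.chain_height, state.landscape, params, state.rng
        )
        new_k = _apply_deaths(k, params, state.rng)
    state.chain_height = new_k
    state.step_index += 1
    return state


def _colonization_events(
    k: np.ndarray, lsc: Landscape, params: ChainParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Boolean arrival masks per level, drawn from configuration ``k``."""
    suit = lsc.grid
    n = k.size
    arrivals: list[np.ndarray] = []

    mode1 = params.dispersal[0]
    targets1 = suit & (k == 0)
    sp1 = k >= 1
    if mode1 == "neighbour":
        n1 = _neighbour_occupied_counts(sp1)
        p1 = colonization_prob_neighbour(n1, params.c[0])
    else:
        p1 = np.full(k.shape,
                     colonization_prob_global(int(sp1.sum()), n, params.c[0]))
    arrivals.append(targets1 & (rng.random(k.shape) < p1))

    if params.n_levels >= 2:
        targets2 = k == 1
        sp2 = k >= 2
        mode2 = params.dispersal[1]
        if mode2 == "cluster":
            labels = lsc.cluster_labels
            n_lab = len(lsc.cluster_sizes)
            n2k = np.bincount(labels[sp2], minlength=n_lab + 1)
            sizes = np.concatenate([[1], lsc.cluster_sizes])  # label 0 unused
            p2_by_cluster = colonization_prob_cluster(
                n2k, sizes, params.c[1]
            )
            p2 = p2_by_cluster[labels]
        elif mode2 == "global":
            p2 = np.full(
                k.shape,
                colonization_prob_global(int(sp2.sum()), n, params.c[1]),
            )
        else:  # neighbour dispersal for level 2
            p2 = colonization_prob_neighbour(
                _neighbour_occupied_counts(sp2), params.c[1]
            )
        arrivals.append(targets2 & (rng.random(k.shape) < p2))

    if params.n_levels >= 3:
        targets3 = k == 2
        sp3 = k >= 3
        mode3 = params.dispersal[2]
        if mode3 == "global":
            p3 = np.full(
                k.shape,
                colonization_prob_global(int(sp3.sum()), n, params.c[2]),
            )
        elif mode3 == "cluster":
            labels = lsc.cluster_labels
            n_lab = len(lsc.cluster_sizes)
            n3k = np.bincount(labels[sp3], minlength=n_lab + 1)
            sizes = np.concatenate([[1], lsc.cluster_sizes])
            p3 = colonization_prob_cluster(n3k, sizes, params.c[2])[labels]
        else:
            p3 = colonization_prob_neighbour(
                _neighbour_occupied_counts(sp3), params.c[2]
            )
        arrivals.append(targets3 & (rng.random(k.shape) < p3))

    return arrivals


def _death_events(
    k: np.ndarray, params: ChainParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Boolean death masks per level (intrinsic + predation), from ``k``."""
    deaths: list[np.ndarray] = []
    mu = params.mu
    for lvl in range(1, params.n_levels + 1):
        present = k >= lvl
        d = present & (rng.random(k.shape) < params.e[lvl - 1])
        if lvl < params.n_levels:  # predation from the level above
            preyed = k >= lvl + 1
            d |= present & preyed & (rng.random(k.shape) < mu[lvl - 1])
        deaths.append(d)
    return deaths


def _step_once(
    k: np.ndarray, lsc: Landscape, params: ChainParams,
    rng: np.random.Generator,
) -> np.ndarray:
    arrivals = _colonization_events(k, lsc, params, rng)
    deaths = _death_events(k, params, rng)
    present = [
        ((k >= lvl) & ~deaths[lvl - 1]) | arrivals[lvl - 1]
        for lvl in range(1, params.n_levels + 1)
    ]
    # cascade: a species persists only on top of its surviving resource
    for lvl in range(1, len(present)):
        present[lvl] &= present[lvl - 1]
    new_k = np.zeros_like(k)
    for lvl, mask in enumerate(present, start=1):
        new_k[mask] = lvl
    return new_k


def _apply_colonization(
    k: np.ndarray, lsc: Landscape, params: ChainParams,
    rng: np.random.Generator,
) -> np.ndarray:
    arrivals = _colonization_events(k, lsc, params, rng)
    new_k = k.copy()
    for lvl, arr in enumerate(arrivals, start=1):
        new_k[arr & (new_k == lvl - 1)] = lvl
    return new_k


def _apply_deaths(
    k: np.ndarray, params: ChainParams, rng: np.random.Generator
) -> np.ndarray:
    deaths = _death_events(k, params, rng)
    present = [
        (k >= lvl) & ~deaths[lvl - 1]
        for lvl in range(1, params.n_levels + 1)
    ]
    for lvl in range(1, len(present)):
        present[lvl] &= present[lvl - 1]
    new_k = np.zeros_like(k)
    for lvl, mask in enumerate(present, start=1):
        new_k[mask] = lvl
    return new_k


def run(
    state: CAState,
    params: ChainParams,
    n_steps: int,
    record_from: int = 0,
    synchronous: bool = True,
) -> np.ndarray:
    """Advance ``n_steps`` steps; return the occupancy series recorded from
    step ``record_from`` on, shape ``(n_recorded, 3)``."""
    series = []
    for t in range(n_steps):
        step(state, params, synchronous=synchronous)
        if t >= record_from:
            series.append(state.occupancies())
    return np.asarray(series)


@dataclass
class ReplicateSummary:
    """Cross-replicate occupancy summary at steady state."""

    mean: np.ndarray  # (3,) per-species mean occupancy (all-patch fractions)
    sd: np.ndarray  # (3,) SD across replicates
    per_replicate: np.ndarray  # (n_reps, 3) window-averaged occupancies
    s: float
    q: float
    L: int
    n_steps: int
    avg_window: int
    n_reps: int
    seed: int | None


def run_replicates(
    landscape_spec: tuple[int, float, float],
    params: ChainParams,
    n_steps: int = 100_000,
    avg_window: int = 10_000,
    n_reps: int = 100,
    seed: int | None = None,
    init_densities: tuple[float, ...] = (0.1, 0.05, 0.025),
    synchronous: bool = True,
    tol_q: float = 0.01,
) -> ReplicateSummary:
    """Replicated CA runs on freshly generated landscapes.

    Each replicate regenerates a landscape with the same (s, q), re-seeds
    the populations, runs ``n_steps`` steps and time-averages the occupancy
    over the final ``avg_window`` steps; the cross-replicate mean and SD
    estimate the steady-state occupancies.  The full-scale reference protocol is
    (L=100, 100000 steps, 10000-step window, 100 replicates); a scaled-down
    profile is the practical default for routine checks.
    """
    if avg_window > n_steps:
        raise ValueError("avg_window cannot exceed n_steps")
    L, s, q = landscape_spec
    root = np.random.SeedSequence(seed)
    per_rep = np.empty((n_reps, 3))
    cfg = LatticeConfig(L)
    for r, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        lsc = generate_landscape(cfg, s, q, rng=rng, tol_q=tol_q)
        state = init_ca(lsc, params, init_densities, seed=rng)
        series = run(state, params, n_steps, record_from=n_steps - avg_window,
                     synchronous=synchronous)
        per_rep[r] = series.mean(axis=0)
    return ReplicateSummary(
        mean=per_rep.mean(axis=0),
        sd=per_rep.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(3),
        per_replicate=per_rep,
        s=s, q=q, L=L, n_steps=n_steps, avg_window=avg_window,
        n_reps=n_reps, seed=seed,
    )
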