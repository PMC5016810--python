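"""Extended patch-dynamic models (EPDM) for food chains on fragmented habitat.

The model tracks occupancies of nested trophic links on the suitable part of
a fragmented landscape, summarised by its availability ``s`` and
connectivity ``q_ss``.  State variables (all fractions of *all* patches):

* ``rho1`` — patches holding the basal species (alone or in a chain),
* ``rho12`` — patches holding the 1→2 link (so ``rho2 = rho12``),
* ``rho23`` — patches holding the full 1→2→3 chain (``rho3 = rho23``),
* ``rho11``, ``rho1u`` — ordered pair densities of (occupied, occupied) and
  (occupied, unsuitable) neighbours, carrying the spatial correlation of
  the neighbour-dispersing basal species.

Dispersal rises with trophic rank: the basal species colonizes empty
suitable neighbours (pair approximation, z = 4), the intermediate consumer
disperses within habitat clusters (its colonization is damped by the patch
connectivity ``q_ss``), and the top predator disperses globally.  Each
trophic link dies at the summed intrinsic rates of its members plus the
top-down predation rates acting inside it; losing the basal species
collapses the whole local chain.

A non-spatial mean-field baseline (all levels global, no pair variables)
provides the randomly-structured-landscape reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .landscape import Z

EXTINCTION_THRESHOLD = 1e-4  # occupancy below this counts as extinct
_FLOOR = 1e-12  # guard for ratios at vanishing occupancy

__all__ = [
    "ChainParams",
    "EPDMState",
    "SteadyStateResult",
    "rhs",
    "rhs_pairs",
    "integrate_to_steady_state",
    "mean_field_baseline",
    "classify_coexistence",
    "initial_state",
    "EXTINCTION_THRESHOLD",
]

_DEFAULT_DISPERSAL = {
    1: ("neighbour",),
    2: ("neighbour", "global"),
    3: ("neighbour", "cluster", "global"),
}


@dataclass(frozen=True)
class ChainParams:
    """Rates of a food chain of 1-3 trophic levels.

    ``c[i]``/``e[i]`` are the colonization and intrinsic extinction rates of
    level ``i+1``; ``mu[i]`` is the top-down extinction rate of level ``i+1``
    due to predation by level ``i+2`` (``mu = (mu21,)`` or ``(mu21, mu32)``).
    ``dispersal`` gives the dispersal mode per level: ``neighbour`` (pair
    approximation), ``cluster`` (global within habitat clusters, colonization
    damped by q_ss) or ``global``.
    """

    n_levels: int
    c: tuple[float, ...]
    e: tuple[float, ...]
    mu: tuple[float, ...] = ()
    dispersal: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_levels not in (1, 2, 3):
            raise ValueError("n_levels must be 1, 2 or 3")
        if not self.dispersal:
            object.__setattr__(
                self, "dispersal", _DEFAULT_DISPERSAL[self.n_levels]
            )
        for name, want in (("c", self.n_levels), ("e", self.n_levels),
                           ("mu", self.n_levels - 1),
                           ("dispersal", self.n_levels)):
            got = getattr(self, name)
            if len(got) != want:
                raise ValueError(f"{name} must have length {want}, got {got}")
        if any(r < 0 for r in self.c + self.e + self.mu):
            raise ValueError("all rates must be non-negative")
        if any(d not in ("neighbour", "cluster", "global")
               for d in self.dispersal):
            raise ValueError(f"unknown dispersal mode in {self.dispersal}")

    @classmethod
    def symmetric(
        cls,
        n_levels: int,
        c: float = 1.0,
        e: float = 0.05,
        mu: float = 0.025,
        dispersal: Sequence[str] | None = None,
    ) -> "ChainParams":
        """Equal rates at every level (the configuration used throughout)."""
        return cls(
            n_levels=n_levels,
            c=(c,) * n_levels,
            e=(e,) * n_levels,
            mu=(mu,) * (n_levels - 1),
            dispersal=tuple(dispersal) if dispersal else (),
        )

    def with_dispersal(self, *modes: str) -> "ChainParams":
        return ChainParams(self.n_levels, self.c, self.e, self.mu,
                           tuple(modes))


@dataclass
class EPDMState:
    """State vector; see module docstring for variable meanings."""

    rho1: float
    rho12: float = 0.0
    rho23: float = 0.0
    rho11: float = 0.0
    rho1u: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.rho1, self.rho12, self.rho23, self.rho11, self.rho1u]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "EPDMState":
        return cls(*map(float, y))

    def conditional_densities(self) -> tuple[float, float]:
        """(q_1/1, q_u/1), read-only view of the pair correlations."""
        r1 = max(self.rho1, _FLOOR)
        return self.rho11 / r1, self.rho1u / r1


@dataclass
class SteadyStateResult:
    occupancies: np.ndarray  # (rho1, rho12, rho23), thresholded
    raw_occupancies: np.ndarray
    coexistence: tuple[int, ...]  # e.g. (1, 2) -> levels 1 and 2 persist
    s: float
    q_ss: float
    t_end: float
    converged: bool
    final_rhs_norm: float
    trajectory: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    @property
    def occupancies_of_suitable(self) -> np.ndarray:
        """Occupancies renormalised to the suitable fraction of the lattice."""
        return self.occupancies / self.s

    @property
    def label(self) -> str:
        return "".join(map(str, self.coexistence)) or "none"


def _guarded_ratio(num: float, den: float, cap: float = 1.0) -> float:
    """num/den capped at ``cap``; the nesting bound makes the cap exact."""
    return min(num / max(den, _FLOOR), cap)


def rhs_pairs(
    rho1: float,
    rho11: float,
    rho1u: float,
    c1: float,
    m1: float,
    s: float,
    q_ss: float,
) -> tuple[float, float]:
    """Pair-density dynamics of the neighbour-dispersing basal species.

    Uses the ordinary pair approximation with the (z-1)/z correction:
    a suitable empty cell is colonized from an occupied neighbour at rate
    ``c1/z`` per neighbour; triple correlations close via
    ``q_{1/0.x} ~ q_1/0 = rho10/rho0``.  ``m1`` is the per-patch mortality
    of the basal species (intrinsic plus mean predation pressure, with
    consumers treated as randomly spread over basal patches).
    """
    rho_su = s * (1.0 - q_ss)  # ordered (suitable, unsuitable) pair density
    rho10 = max(rho1 - rho11 - rho1u, 0.0)
    rho0u = max(rho_su - rho1u, 0.0)
    rho0 = s - rho1
    if rho0 > _FLOOR:
        q10 = min(rho10 / rho0, 1.0)
        colon11 = 2.0 * c1 * rho10 * (1.0 / Z + (Z - 1.0) / Z * q10)
        colon1u = c1 * rho0u * (Z - 1.0) / Z * q10
    else:  # saturated habitat: no empty suitable cells to colonize
        colon11 = colon1u = 0.0
    d11 = colon11 - 2.0 * m1 * rho11
    d1u = colon1u - m1 * rho1u
    return d11, d1u


def rhs(
    y: np.ndarray, params: ChainParams, s: float, q_ss: float
) -> np.ndarray:
    """Time derivative of ``(rho1, rho12, rho23, rho11, rho1u)``."""
    rho1, rho12, rho23 = y[0], y[1], y[2]
    rho11, rho1u = y[3], y[4]
    n = params.n_levels
    c, e = params.c, params.e
    mu21 = params.mu[0] if n >= 2 else 0.0
    mu32 = params.mu[1] if n >= 3 else 0.0

    # basal level
    pred1 = mu21 * rho12
    if params.dispersal[0] == "neighbour":
        r1 = max(rho1, _FLOOR)
        q_s1 = max(1.0 - (rho11 + rho1u) / r1, 0.0)  # = rho10 / rho1
        growth1 = c[0] * rho1 * q_s1
        m1 = e[0] + mu21 * _guarded_ratio(rho12, rho1)
        d11, d1u = rhs_pairs(rho1, rho11, rho1u, c[0], m1, s, q_ss)
    else:  # global basal dispersal: mean-field, pair variables inert
        growth1 = c[0] * rho1 * max(s - rho1, 0.0)
        d11 = d1u = 0.0
    d1 = growth1 - e[0] * rho1 - pred1

    d12 = 0.0
    if n >= 2:
        gate2 = q_ss if params.dispersal[1] == "cluster" else 1.0
        growth2 = c[1] * gate2 * rho12 * max(rho1 - rho12, 0.0)
        d12 = growth2 - (e[0] + e[1] + mu21) * rho12 - mu32 * rho23

    d23 = 0.0
    if n >= 3:
        gate3 = q_ss if params.dispersal[2] == "cluster" else 1.0
        growth3 = c[2] * gate3 * rho23 * max(rho12 - rho23, 0.0)
        d23 = growth3 - (e[0] + e[1] + e[2] + mu21 + mu32) * rho23

    return np.array([d1, d12, d23, d11, d1u])


def initial_state(
    params: ChainParams,
    s: float,
    q_ss: float,
    theta: Sequence[float] = (0.1, 0.05, 0.025),
) -> EPDMState:
    """Sparse random seeding: within-suitable densities ``theta`` per level
    (decreasing with rank), Bernoulli pair correlations for the basal level.
    """
    th = tuple(theta[: params.n_levels])
    if any(t < 0 or t > 1 for t in th) or list(th) != sorted(th, reverse=True):
        raise ValueError(
            "initial densities must lie in [0,1] and decrease with level"
        )
    t1 = th[0]
    return EPDMState(
        rho1=t1 * s,
        rho12=th[1] * s if params.n_levels >= 2 else 0.0,
        rho23=th[2] * s if params.n_levels >= 3 else 0.0,
        rho11=t1 * t1 * q_ss * s,          # theta^2 * rho_ss
        rho1u=t1 * s * (1.0 - q_ss),       # theta * rho_su
    )


def classify_coexistence(
    occupancies: Sequence[float], threshold: float = EXTINCTION_THRESHOLD
) -> tuple[int, ...]:
    """Persisting trophic levels, thresholded and respecting nesting.

    A level counts as present only if every level below it is present
    (bottom-up constraint); non-nested occupancies are rejected.
    """
    occ = np.asarray(occupancies, dtype=float)
    if not np.all(np.isfinite(occ)):
        raise ValueError("occupancies must be finite")
    if np.any(np.diff(occ) > 1e-9):
        raise ValueError(f"occupancies must be nested (decreasing): {occ}")
    out: list[int] = []
    for i, o in enumerate(occ, start=1):
        if o >= threshold:
            out.append(i)
        else:
            break
    return tuple(out)


def integrate_to_steady_state(
    params: ChainParams,
    s: float,
    q_ss: float,
    init: EPDMState | None = None,
    t_max: float = 10_000.0,
    conv_tol: float = 1e-9,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    threshold: float = EXTINCTION_THRESHOLD,
    keep_trajectory: bool = False,
) -> SteadyStateResult:
    """Integrate the chain to its steady state and classify coexistence.

    Adaptive, stiff-capable integration (LSODA) until the derivative norm
    falls below ``conv_tol`` or ``t_max`` is reached; occupancies below
    ``threshold`` are reported as zero and classified extinct.  A state that
    leaves its invariant polytope by more than integrator-scale slack raises
    (that would be a model-definition bug, not something to clip).
    """
    if not (0.0 < s <= 1.0):
        raise ValueError(f"availability s must be in (0, 1], got {s}")
    if not (0.0 <= q_ss <= 1.0):
        raise ValueError(f"connectivity q_ss must be in [0, 1], got {q_ss}")
    if init is None:
        init = initial_state(params, s, q_ss)
    y0 = init.to_array()

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(y, params, s, q_ss)

    def settled(t: float, y: np.ndarray) -> float:
        return float(np.abs(f(t, y)).max()) - conv_tol

    settled.terminal = True  # type: ignore[attr-defined]
    settled.direction = -1  # type: ignore[attr-defined]

    sol = solve_ivp(
        f, (0.0, t_max), y0, method="LSODA", rtol=rtol, atol=atol,
        events=settled, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y_end = sol.y[:, -1]

    slack = 1e-6 + 100 * rtol
    rho1, rho12, rho23 = y_end[:3]
    if (
        rho1 > s + slack
        or rho12 > rho1 + slack
        or rho23 > rho12 + slack
        or min(rho1, rho12, rho23) < -slack
        or y_end[3] > rho1 + slack
        or y_end[4] > min(rho1, s * (1 - q_ss)) + slack
    ):
        raise RuntimeError(
            f"trajectory left the invariant polytope: y={y_end}, s={s}"
        )

    raw = np.clip(y_end[:3], 0.0, None)[: params.n_levels]
    raw = np.minimum.accumulate(np.concatenate([[s], raw]))[1:]  # tidy nesting
    occ = np.where(raw >= threshold, raw, 0.0)
    coex = classify_coexistence(occ, threshold)
    occ_full = np.zeros(3)
    occ_full[: params.n_levels] = occ
    raw_full = np.zeros(3)
    raw_full[: params.n_levels] = raw
    return SteadyStateResult(
        occupancies=occ_full,
        raw_occupancies=raw_full,
        coexistence=coex,
        s=s,
        q_ss=q_ss,
        t_end=float(sol.t[-1]),
        converged=bool(sol.t_events[0].size) ,
        final_rhs_norm=float(np.abs(f(sol.t[-1], y_end)).max()),
        trajectory=(sol.t, sol.y) if keep_trajectory else None,
    )


def _mean_field_equilibrium(params: ChainParams, s: float) -> np.ndarray:
    """Equilibrium of the non-spatial (all-global) chain, by closed form
    where available and a bracketed root-solve for the three-level chain;
    boundary equilibria are used when an interior one is infeasible."""
    c, e = params.c, params.e
    rho1_only = max(s - e[0] / c[0], 0.0)
    if params.n_levels == 1 or rho1_only <= 0.0:
        return np.array([rho1_only, 0.0, 0.0])

    mu21 = params.mu[0]
    d2 = (e[0] + e[1] + mu21) / c[1]  # stationary gap rho1 - rho12

    def bitrophic() -> np.ndarray:
        # c1*rho1^2 - (c1*s - e1 - mu21)*rho1 - mu21*d2 = 0
        b = c[0] * s - e[0] - mu21
        rho1 = (b + np.sqrt(b * b + 4.0 * c[0] * mu21 * d2)) / (2.0 * c[0])
        rho12 = rho1 - d2
        if rho12 <= 0.0:
            return np.array([rho1_only, 0.0, 0.0])
        return np.array([rho1, rho12, 0.0])

    if params.n_levels == 2:
        return bitrophic()

    mu32 = params.mu[1]
    d3 = (e[0] + e[1] + e[2] + mu21 + mu32) / c[2]  # gap rho12 - rho23

    def rho1_of(rho12: float) -> float:
        # stationarity of rho1 given predation load mu21*rho12
        b = c[0] * s - e[0]
        disc = b * b - 4.0 * c[0] * mu21 * rho12
        if disc < 0.0:
            return np.nan
        return (b + np.sqrt(disc)) / (2.0 * c[0])

    def g(rho12: float) -> float:
        rho1 = rho1_of(rho12)
        if not np.isfinite(rho1):
            return -np.inf
        return (
            c[1] * (rho1 - rho12)
            - (e[0] + e[1] + mu21)
            - mu32 * (rho12 - d3) / rho12
        )

    lo, hi = d3 * (1.0 + 1e-12), s
    if hi > lo and g(lo) > 0.0 > g(hi):
        rho12 = brentq(g, lo, hi, xtol=1e-14)
        rho1 = rho1_of(rho12)
        rho23 = rho12 - d3
        if rho23 > 0.0 and rho12 < rho1:
            return np.array([rho1, rho12, rho23])
    out = bitrophic()
    return out


def mean_field_baseline(
    params: ChainParams,
    s: float,
    threshold: float = EXTINCTION_THRESHOLD,
) -> SteadyStateResult:
    """Steady state of the chain with every level dispersing globally and no
    spatial correlations — the randomly-structured patch model used as the
    s = q reference."""
    raw = _mean_field_equilibrium(params, s)[: params.n_levels]
    occ = np.where(raw >= threshold, raw, 0.0)
    coex = classify_coexistence(occ, threshold)
    occ_full, raw_full = np.zeros(3), np.zeros(3)
    occ_full[: params.n_levels] = occ
    raw_full[: params.n_levels] = raw
    return SteadyStateResult(
        occupancies=occ_full,
        raw_occupancies=raw_full,
        coexistence=coex,
        s=s,
        q_ss=s,
        t_end=0.0,
        converged=True,
        final_rhs_norm=0.0,
    )
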