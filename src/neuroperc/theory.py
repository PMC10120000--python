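"""Closed-form percolation/growth curves and the Giant Cluster Self Preference theory.

Reading an attack curve right-to-left turns edge removal into a build-up
process. For an Erdos-Renyi random graph the giant-component fraction has
the classical Lambert-W form

    P(<k>) = 1 + W0(-<k> e^{-<k>}) / <k>,

zero for <k> <= 1 (the percolation critical point).

The Giant Cluster Self Preference (GCSP) model instead grows a network that
is a single cluster at all times: each new edge either lands in one of the
n(n-1)/2 - E open spots inside the existing n-node cluster, or — with
relative propensity 1/alpha per spot across the N - n unplaced nodes —
branches out and recruits a new node. The branching probability is

    p(n -> n+1 | E -> E+1) = (n(N-n)/alpha) / (n(n-1)/2 - E + n(N-n)/alpha),

which drives an exact discrete master equation for p(n|E) from the initial
condition p(n|0) = delta_{n,1}. In the large-N limit (rho = n/N,
kappa = 2E/N fixed) the distribution collapses onto the deterministic
characteristic rho = f(kappa) with

    f'(kappa) = (1 - f) / (2 - (2 - alpha) f),   f(0) = 0,

whose solution is the single-parameter closed form

    P(<k>) = 1 + (1 - 2/alpha)^{-1} W0((2/alpha - 1) e^{2/alpha - 1} e^{-<k>/alpha}).

Unlike the random graph, this curve has no critical point: P > 0 for every
<k> > 0 and every alpha > 0. All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.special import lambertw

__all__ = [
    "GCSPParams",
    "TheoryCurve",
    "MasterEquationState",
    "random_graph_P",
    "gcsp_P",
    "ode_rhs",
    "transition_probability",
    "master_evolve",
    "master_mean_trajectory",
]

#: |alpha - 2| below which the removable singularity is evaluated by its limit
ALPHA_TWO_TOL = 1e-8

#: tolerance on probability-mass conservation in the master equation
MASS_TOL = 1e-12


@dataclass(frozen=True)
class GCSPParams:
    """GCSP model parameters.

    alpha : relative propensity of in-cluster edge placement versus
        branching to a new node (> 0; brain fits give alpha >> 2).
    N : final node count; ``None`` selects the infinite-size closed forms.
    """

    alpha: float
    N: int | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.N is not None and self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")


@dataclass
class TheoryCurve:
    """Closed-form P(<k>) evaluated on a mean-degree grid."""

    mean_degree: np.ndarray
    P: np.ndarray
    model: str  # "random" | "gcsp"
    alpha: float | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kappa\tP\n")
            for k, p in zip(self.mean_degree, self.P):
                fh.write(f"{float(k)!r}\t{float(p)!r}\n")


@dataclass
class MasterEquationState:
    """Distribution p(n|E) over cluster sizes n = 1..N at edge count E."""

    E: int
    p: np.ndarray  # p[i] = p(n = i + 1 | E)

    @property
    def mean_fraction(self) -> float:
        n = np.arange(1, len(self.p) + 1)
        return float(n @ self.p) / len(self.p)


def random_graph_P(mean_degree):
    """Giant-component fraction of an infinite Erdos-Renyi graph.

    Principal-branch Lambert-W evaluation; returns 0 at or below the
    critical point <k> = 1 and coincides with the stable fixed point of
    P = 1 - exp(-<k> P) above it.
    """
    k = np.asarray(mean_degree, dtype=float)
    if np.any(k < 0):
        raise ValueError("mean_degree must be >= 0")
    out = np.zeros_like(k)
    above = k > 1
    ka = k[above]
    w = np.real(lambertw(-ka * np.exp(-ka)))
    out[above] = 1.0 + w / ka
    return out.item() if np.isscalar(mean_degree) else out


def gcsp_P(mean_degree, params: GCSPParams):
    """Closed-form GCSP giant-cluster fraction P(<k>) for one alpha.

    Uses the principal Lambert-W branch; for alpha > 2 the argument
    (2/alpha - 1) e^{2/alpha - 1} e^{-<k>/alpha} lies in (-1/e, 0] where W0
    is real, and for alpha < 2 it is positive. alpha = 2 is the removable
    singularity P = 1 - exp(-<k>/2).
    """
    k = np.asarray(mean_degree, dtype=float)
    if np.any(k < 0):
        raise ValueError("mean_degree must be >= 0")
    alpha = params.alpha
    if abs(alpha - 2.0) < ALPHA_TWO_TOL:
        out = 1.0 - np.exp(-k / 2.0)
        return out.item() if np.isscalar(mean_degree) else out
    c = 2.0 / alpha - 1.0
    arg = c * np.exp(c) * np.exp(-k / alpha)
    if np.any(arg < -np.exp(-1.0) - 1e-12):
        raise AssertionError("Lambert-W argument below -1/e; invalid inputs")
    w = np.real(lambertw(arg))
    out = np.clip(1.0 - w / c, 0.0, 1.0)
    return out.item() if np.isscalar(mean_degree) else out


def gcsp_curve(mean_degree, params: GCSPParams) -> TheoryCurve:
    k = np.atleast_1d(np.asarray(mean_degree, dtype=float))
    return TheoryCurve(mean_degree=k, P=gcsp_P(k, params), model="gcsp", alpha=params.alpha)


def random_curve(mean_degree) -> TheoryCurve:
    k = np.atleast_1d(np.asarray(mean_degree, dtype=float))
    return TheoryCurve(mean_degree=k, P=random_graph_P(k), model="random")


def ode_rhs(f, params: GCSPParams):
    """Characteristic growth ODE right-hand side df/dkappa = (1-f)/(2-(2-alpha)f)."""
    f = np.asarray(f, dtype=float)
    denom = 2.0 - (2.0 - params.alpha) * f
    assert np.all(denom > 0), "ODE denominator non-positive (requires alpha > 0, 0 <= f <= 1)"
    out = (1.0 - f) / denom
    return out.item() if out.ndim == 0 else out


def transition_probability(n: int, E: int, params: GCSPParams) -> float:
    """Probability that edge E+1 recruits a new node (cluster n -> n+1).

    Complement is the in-cluster placement probability. Requires the finite
    final size N; E may not exceed the complete-cluster capacity n(n-1)/2.
    """
    N = params.N
    if N is None:
        raise ValueError("transition_probability requires finite N")
    if not 1 <= n <= N:
        raise ValueError(f"n must be in [1, {N}], got {n}")
    capacity = n * (n - 1) // 2
    if not 0 <= E <= capacity:
        raise ValueError(f"E={E} outside [0, n(n-1)/2={capacity}]")
    if n == N:
        return 0.0
    spots_in = capacity - E
    branch_weight = n * (N - n) / params.alpha
    return branch_weight / (spots_in + branch_weight)


def _branch_probabilities(N: int, alpha: float, E: int) -> np.ndarray:
    """Vectorized Eq.-3 branching probability for n = 1..N at edge count E.

    Infeasible states (cluster capacity < E) always carry zero mass; their
    entries are set to 0 so they stay inert.
    """
    n = np.arange(1, N + 1, dtype=float)
    capacity = n * (n - 1) / 2.0
    spots_in = capacity - E
    branch_weight = n * (N - n) / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(spots_in > 0, branch_weight / (spots_in + branch_weight), 1.0)
    q[spots_in < 0] = 0.0
    q[-1] = 0.0  # n = N cannot branch
    return q


def master_evolve(
    params: GCSPParams, E_max: int, record_every: int = 1
) -> list[MasterEquationState]:
    """Exact forward recursion of the discrete master equation.

    Evolves p(n|E) from the delta at n = 1 up to ``E_max`` edges, recording a
    state every ``record_every`` steps (plus E = 0 and E = E_max).
    Normalization is checked to 1e-12 at every step.
    """
    states = [
        MasterEquationState(E=E, p=p.copy())
        for E, p in _master_iter(params, E_max)
        if E % record_every == 0 or E == E_max
    ]
    return states


def master_mean_trajectory(params: GCSPParams, E_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean cluster fraction E[n]/N versus kappa = 2E/N (O(N) memory)."""
    N = params.N
    n = np.arange(1, N + 1, dtype=float)
    kappa = np.empty(E_max + 1)
    rho = np.empty(E_max + 1)
    for E, p in _master_iter(params, E_max):
        kappa[E] = 2.0 * E / N
        rho[E] = (n @ p) / N
    return kappa, rho


def _master_iter(params: GCSPParams, E_max: int) -> Iterator[tuple[int, np.ndarray]]:
    N = params.N
    if N is None:
        raise ValueError("master equation requires finite N")
    if E_max > N * (N - 1) // 2:
        raise ValueError("E_max exceeds complete-graph capacity")
    p = np.zeros(N)
    p[0] = 1.0
    yield 0, p
    for E in range(E_max):
        q = _branch_probabilities(N, params.alpha, E)
        flow = p * q
        p = p - flow
        p[1:] += flow[:-1]
        total = p.sum()
        if abs(total - 1.0) > MASS_TOL:
            raise FloatingPointError(
                f"probability mass leaked to {total!r} at E={E + 1}"
            )
        yield E + 1, p
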