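"""Benchmark community simulator: environment-coupled generalized
Lotka-Volterra dynamics over a modular scale-free interaction matrix.

The model is dy/dt = y * (b(t) + A y). Growth rates b(t) follow Gaussian
niche responses to one external sinusoidal environmental driver; a second,
"internal" environmental factor is carried as an extra gLV state whose row in
A is zero off-diagonal (microbes do not affect it) while its column couples
it into half the taxa positively and half negatively. Ground-truth
interactions are the nonzero off-diagonal taxon-taxon coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import SampleMatrix

__all__ = [
    "SimulationConfig",
    "NicheParams",
    "InteractionMatrix",
    "CommunityTimeSeries",
    "SimulationError",
    "klemm_eguiluz_topology",
    "build_interaction_matrix",
    "environmental_signal",
    "growth_rate",
    "stick_breaking_abundances",
    "simulate_community",
    "add_poisson_noise",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NicheParams:
    """Gaussian niche response of one organism to the environmental driver."""

    gmax: float
    eopt: float
    sigma: float

    def __post_init__(self) -> None:
        if self.gmax <= 0 or self.sigma <= 0:
            raise ValueError("gmax and sigma must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark generator settings.

    Defaults are the benchmark's study conditions: 50 taxa, interaction
    probability 0.01 with 30% positive coefficients, self-limitation -0.5,
    environmental couplings drawn from +-U(0.2, 0.8), niche gmax and sigma
    from U(0.3, 1), a 12-month sinusoidal driver sampled on t = 0..49.5 at
    resolution 0.5 (100 samples), and an internal factor with gmax 0.8,
    eopt 0.5, sigma 0.5 and initial value 0.001.
    """

    n_taxa: int = 50
    interaction_probability: float = 0.01
    positive_fraction: float = 0.30
    diagonal: float = -0.5
    coupling_low: float = 0.2
    coupling_high: float = 0.8
    gmax_range: tuple[float, float] = (0.3, 1.0)
    sigma_range: tuple[float, float] = (0.3, 1.0)
    period_T: float = 12.0
    t_start: float = 0.0
    t_end: float = 49.5
    dt: float = 0.5
    internal_gmax: float = 0.8
    internal_eopt: float = 0.5
    internal_sigma: float = 0.5
    internal_init: float = 0.001
    clique_size: int = 5
    rewiring_mu: float = 0.1
    gmax_squared: bool = True
    rtol: float = 1e-6
    atol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.interaction_probability < 1:
            raise ValueError("interaction_probability must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)

    @property
    def n_samples(self) -> int:
        return len(self.time_grid)


@dataclass
class InteractionMatrix:
    """Dense coefficient matrix over taxa plus the internal factor.

    ``A[j, i]`` is the effect of organism i on the growth of organism j; the
    last row/column belongs to the internal environmental factor.
    """

    A: np.ndarray
    n_taxa: int

    @property
    def taxon_block(self) -> np.ndarray:
        return self.A[: self.n_taxa, : self.n_taxa]

    def truth_edges(self) -> set[frozenset]:
        """Unordered taxon pairs with a nonzero coefficient in either direction."""
        block = self.taxon_block
        pairs = set()
        idx_i, idx_j = np.nonzero(block)
        for i, j in zip(idx_i, idx_j):
            if i != j:
                pairs.add(frozenset((int(i), int(j))))
        return pairs


@dataclass
class CommunityTimeSeries:
    """Simulated trajectories plus ground truth."""

    abundances: SampleMatrix
    external_env: np.ndarray
    internal_env: np.ndarray
    truth_edges: set
    interaction_matrix: InteractionMatrix
    niches: list[NicheParams]
    times: np.ndarray

    def env_matrix(self) -> SampleMatrix:
        """External + internal factor trajectories as an environment matrix."""
        return SampleMatrix(
            row_ids=["env_external", "env_internal"],
            sample_ids=list(self.abundances.sample_ids),
            values=np.vstack([self.external_env, self.internal_env]),
            role="environment",
        )


def klemm_eguiluz_topology(
    n: int,
    density_target: float,
    clique_size: int = 5,
    rewiring_mu: float = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Modular scale-free adjacency by the Klemm-Eguiluz growth process.

    Starts from a fully connected set of ``clique_size`` active nodes; each
    new node attaches to every active node (each attachment rewired to a
    uniformly random existing node with probability ``rewiring_mu``), joins
    the active set, and one active node is deactivated with probability
    inversely proportional to its degree. Edges are then subsampled (or
    augmented with random non-edges) to hit round(density_target * C(n, 2))
    within one edge.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 2 <= clique_size <= n:
        raise ValueError("need n >= clique_size >= 2")
    if not 0 <= rewiring_mu <= 1:
        raise ValueError("rewiring_mu must lie in [0, 1]")
    target = int(round(density_target * n * (n - 1) / 2))
    if target < 0 or target > n * (n - 1) // 2:
        raise ValueError("unreachable density target")

    adj = np.zeros((n, n), dtype=bool)
    active = list(range(clique_size))
    for i in active:
        for j in active:
            if i != j:
                adj[i, j] = True
    degree = adj.sum(axis=1).astype(float)

    for new in range(clique_size, n):
        for a in list(active):
            partner = a
            if rng.random() < rewiring_mu:
                candidates = [c for c in range(new) if not adj[new, c] and c != new]
                if candidates:
                    partner = int(rng.choice(candidates))
            if not adj[new, partner]:
                adj[new, partner] = adj[partner, new] = True
                degree[new] += 1
                degree[partner] += 1
        active.append(new)
        inv = 1.0 / degree[active]
        drop = int(rng.choice(active, p=inv / inv.sum()))
        active.remove(drop)

    # adjust to the target edge count
    iu = np.triu_indices(n, k=1)
    present = np.flatnonzero(adj[iu])
    absent = np.flatnonzero(~adj[iu])
    if len(present) > target:
        remove = rng.choice(present, size=len(present) - target, replace=False)
        adj[iu[0][remove], iu[1][remove]] = False
        adj[iu[1][remove], iu[0][remove]] = False
    elif len(present) < target:
        add = rng.choice(absent, size=target - len(present), replace=False)
        adj[iu[0][add], iu[1][add]] = True
        adj[iu[1][add], iu[0][add]] = True
    return adj


def build_interaction_matrix(
    adjacency: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> InteractionMatrix:
    """Draw signed coefficients on an adjacency and append the internal factor.

    Every undirected adjacency edge yields two directed coefficients with
    magnitude U(coupling_low, coupling_high); ``positive_fraction`` of the
    off-diagonal nonzero coefficients are positive. Diagonals are set to
    ``cfg.diagonal``. The internal factor's column couples it positively into
    a random half of the taxa and negatively into the rest; its row is zero
    off-diagonal and its diagonal equals ``cfg.diagonal`` (self-limitation,
    keeping the extra state bounded).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = adjacency.shape[0]
    A = np.zeros((n + 1, n + 1))
    iu = np.triu_indices(n, k=1)
    edge_idx = np.flatnonzero(adjacency[iu])
    coeffs = []  # (row, col) positions of directed taxon-taxon coefficients
    for e in edge_idx:
        i, j = int(iu[0][e]), int(iu[1][e])
        coeffs.append((i, j))
        coeffs.append((j, i))
    m = len(coeffs)
    if m:
        magnitudes = rng.uniform(cfg.coupling_low, cfg.coupling_high, size=m)
        n_pos = int(round(cfg.positive_fraction * m))
        signs = np.full(m, -1.0)
        pos_idx = rng.choice(m, size=n_pos, replace=False)
        signs[pos_idx] = 1.0
        for (r, c), mag, s in zip(coeffs, magnitudes, signs):
            A[r, c] = s * mag
    np.fill_diagonal(A, cfg.diagonal)
    # Mutualism damping: a double-positive pair with a_ij*a_ji >= a_ii*a_jj
    # makes the two-species subsystem diverge; rescale such pairs so their
    # product stays strictly below the self-limitation product.
    cap = 0.9 * cfg.diagonal**2
    for e in edge_idx:
        i, j = int(iu[0][e]), int(iu[1][e])
        prod = A[i, j] * A[j, i]
        if A[i, j] > 0 and A[j, i] > 0 and prod >= cap:
            shrink = np.sqrt(cap / prod)
            A[i, j] *= shrink
            A[j, i] *= shrink
    # internal factor column: + for a random half of taxa, - for the other
    half = n // 2
    order = rng.permutation(n)
    A[order[:half], n] = rng.uniform(cfg.coupling_low, cfg.coupling_high, size=half)
    A[order[half:], n] = -rng.uniform(
        cfg.coupling_low, cfg.coupling_high, size=n - half
    )
    A[n, :n] = 0.0
    A[n, n] = cfg.diagonal
    return InteractionMatrix(A=A, n_taxa=n)


def environmental_signal(t, T: float = 12.0):
    """Sinusoidal external driver: round(sin(-2*pi/T * t), 3)."""
    if T <= 0:
        raise ValueError("period T must be positive")
    omega = -2.0 * np.pi / T
    return np.round(np.sin(omega * np.asarray(t, dtype=float)), 3)


def growth_rate(eps, niche: NicheParams, gmax_squared: bool = True):
    """Gaussian niche growth response g = gmax^2 * exp(-(eopt-eps)^2/(2 sigma^2)).

    The squared amplitude follows the reference formulation; set
    ``gmax_squared=False`` for a plain gmax amplitude.
    """
    amp = niche.gmax**2 if gmax_squared else niche.gmax
    eps = np.asarray(eps, dtype=float)
    return amp * np.exp(-0.5 * ((niche.eopt - eps) / niche.sigma) ** 2)


def stick_breaking_abundances(
    n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random broken-stick partition of 1 into n strictly positive parts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    parts = np.empty(n)
    remaining = 1.0
    for i in range(n - 1):
        frac = rng.uniform(0.0, 1.0)
        # keep pieces strictly positive even if the uniform draw hits an end
        frac = min(max(frac, 1e-12), 1 - 1e-12)
        parts[i] = remaining * frac
        remaining -= parts[i]
    parts[n - 1] = remaining
    return parts


def simulate_community(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> CommunityTimeSeries:
    """Run the full benchmark generator for one replicate.

    Draws topology, coefficients, niches and initial abundances, integrates
    the gLV with LSODA on the sample grid, clips tiny negative states to 0,
    and records the ground-truth interaction pairs.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = cfg.n_taxa
    if n == 1:
        adjacency = np.zeros((1, 1), dtype=bool)
    else:
        adjacency = klemm_eguiluz_topology(
            n,
            cfg.interaction_probability,
            min(cfg.clique_size, n),
            cfg.rewiring_mu,
            rng,
        )
    interactions = build_interaction_matrix(adjacency, cfg, rng)

    eps_min, eps_max = -1.0, 1.0  # range of the rounded sinusoid
    niches = [
        NicheParams(
            gmax=rng.uniform(*cfg.gmax_range),
            eopt=rng.uniform(eps_min, eps_max),
            sigma=rng.uniform(*cfg.sigma_range),
        )
        for _ in range(n)
    ]
    internal_niche = NicheParams(
        gmax=cfg.internal_gmax, eopt=cfg.internal_eopt, sigma=cfg.internal_sigma
    )
    all_niches = niches + [internal_niche]
    gmax_amp = np.array(
        [nc.gmax**2 if cfg.gmax_squared else nc.gmax for nc in all_niches]
    )
    eopts = np.array([nc.eopt for nc in all_niches])
    sigmas = np.array([nc.sigma for nc in all_niches])

    y0 = np.concatenate(
        [stick_breaking_abundances(n, rng), [cfg.internal_init]]
    )
    A = interactions.A
    omega = -2.0 * np.pi / cfg.period_T

    def rhs(t, y):
        eps = round(float(np.sin(omega * t)), 3)
        b = gmax_amp * np.exp(-0.5 * ((eopts - eps) / sigmas) ** 2)
        return y * (b + A @ y)

    times = cfg.time_grid
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    state = sol.y
    if np.any(state < -1e-6):
        raise SimulationError("trajectory went substantially negative")
    state = np.clip(state, 0.0, None)

    sample_ids = [f"s{k:03d}" for k in range(len(times))]
    abundances = SampleMatrix(
        row_ids=[f"taxon{j:02d}" for j in range(n)],
        sample_ids=sample_ids,
        values=state[:n],
        role="abundance",
    )
    truth = {
        frozenset((f"taxon{i:02d}", f"taxon{j:02d}"))
        for pair in interactions.truth_edges()
        for i, j in [sorted(pair)]
    }
    return CommunityTimeSeries(
        abundances=abundances,
        external_env=environmental_signal(times, cfg.period_T),
        internal_env=state[n],
        truth_edges=truth,
        interaction_matrix=interactions,
        niches=niches,
        times=times,
    )


def add_poisson_noise(
    abundances: SampleMatrix,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> SampleMatrix:
    """Resample each cell from Poisson(scale * value) / scale.

    scale = 1 draws directly at the abundance value; for count-like output
    use a scale around the intended total count.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if rng is None:
        rng = np.random.default_rng()
    noisy = rng.poisson(scale * abundances.values).astype(float) / scale
    return SampleMatrix(
        row_ids=list(abundances.row_ids),
        sample_ids=list(abundances.sample_ids),
        values=noisy,
        role="abundance",
    )
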