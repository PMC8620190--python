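"""Association-network inference: robust standardization, a zero-delay
local-similarity score, p-values, Bonferroni correction, thresholding.

The scorer is a simplified zero-delay local-similarity statistic: series are
standardized by median/MAD and the score of a pair is the largest absolute
contiguous-window sum of their elementwise products, divided by the series
length. That statistic equals the range of the prefix-sum random walk, whose
null distribution under permutation converges to the range of Brownian
motion; the default p-value uses that asymptotic tail (Feller's series), and
an exact permutation p-value is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_model import AssociationNetwork, Edge, Node, NodeKind, SampleMatrix

__all__ = [
    "AssociationParams",
    "DegenerateSeriesError",
    "robust_z",
    "local_similarity",
    "local_similarity_score",
    "brownian_range_sf",
    "assoc_theoretical_p",
    "assoc_permutation_p",
    "bonferroni",
    "construct_network",
]


class DegenerateSeriesError(ValueError):
    """Series has zero median absolute deviation and cannot be standardized."""


@dataclass(frozen=True)
class AssociationParams:
    """Settings for network construction.

    ``p_method`` chooses between the asymptotic null ("theoretical", the
    default — the only choice whose p-values are fine enough to survive a
    Bonferroni filter at 0.001) and the pure permutation test
    ("permutation") with ``permutations`` iterations.
    """

    permutations: int = 2000
    p_threshold: float = 0.001
    q_threshold: float = 0.001
    seed: int = 0
    p_method: str = "theoretical"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1 or not 0 < self.q_threshold <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.p_method not in ("theoretical", "permutation"):
            raise ValueError(f"unknown p_method {self.p_method!r}")


def robust_z(x: np.ndarray) -> np.ndarray:
    """Standardize by median and (unscaled) median absolute deviation."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateSeriesError("median absolute deviation is zero")
    return (x - med) / mad


def _prefix_sums(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    products = np.asarray(x, dtype=float) * np.asarray(y, dtype=float)
    return np.concatenate([[0.0], np.cumsum(products)])


def local_similarity_score(x: np.ndarray, y: np.ndarray) -> float:
    """The score alone: max |window product sum| / n = walk range / n."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    S = _prefix_sums(x, y)
    return float((S.max() - S.min()) / len(x))


def local_similarity(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, str, int, int]:
    """Zero-delay local similarity: (score, sign, start, duration).

    Maximizes |sum_{t in [i, j]} x_t * y_t| / n over all contiguous windows;
    ties are broken by earliest start, then longest duration.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    S = _prefix_sums(x, y)
    # window [i, j] (inclusive) has sum S[j+1] - S[i]
    diff = S[None, 1:] - S[:-1, None]  # diff[i, j] = sum of window [i, j]
    valid = np.triu(np.ones((n, n), dtype=bool))
    absdiff = np.where(valid, np.abs(diff), -np.inf)
    best = absdiff.max()
    ii, jj = np.nonzero(absdiff == best)
    # earliest start, then longest duration
    order = np.lexsort((-(jj - ii), ii))
    i, j = int(ii[order[0]]), int(jj[order[0]])
    window_sum = S[j + 1] - S[i]
    sign = "+" if window_sum > 0 else "-"
    return float(best / n), sign, i, j - i + 1


def brownian_range_sf(x: float) -> float:
    """P(range of standard Brownian motion on [0,1] >= x).

    Feller's series: 8 * sum_{k>=1} (-1)^(k-1) * k * Phi_c(k x).
    """
    if x <= 0.2:
        return 1.0  # true survival exceeds 1 - 1e-9 here
    kmax = min(max(60, int(np.ceil(12.0 / x))), 5000)
    k = np.arange(1, kmax + 1)
    val = float(np.sum(8.0 * (-1.0) ** (k - 1) * k * norm.sf(k * x)))
    return float(np.clip(val, 0.0, 1.0))


def assoc_theoretical_p(x: np.ndarray, y: np.ndarray,
                        score: float | None = None) -> float:
    """Asymptotic p-value of the local-similarity score.

    Normalizes the walk range by the permutation-null step scale
    sqrt(E[x^2] E[y^2] - (mean x * mean y)^2) (drift neglected) and applies
    the Brownian-range tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if score is None:
        score = local_similarity_score(x, y)
    n = len(x)
    var = float(np.mean(x**2) * np.mean(y**2) - (np.mean(x) * np.mean(y)) ** 2)
    if var <= 0:
        return 1.0
    stat = score * n / (np.sqrt(var) * np.sqrt(n))
    return brownian_range_sf(stat)


def assoc_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    permutations: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Pure permutation p-value: p = (#{score_perm >= score_obs} + 1) / (P + 1)."""
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = local_similarity_score(x, y)
    n = len(x)
    perm_idx = np.empty((permutations, n), dtype=np.intp)
    for i in range(permutations):
        perm_idx[i] = rng.permutation(n)
    products = x[None, :] * y[perm_idx]
    S = np.concatenate(
        [np.zeros((permutations, 1)), np.cumsum(products, axis=1)], axis=1
    )
    scores = (S.max(axis=1) - S.min(axis=1)) / n
    exceed = int(np.count_nonzero(scores >= obs - 1e-12))
    return (exceed + 1) / (permutations + 1)


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-corrected q-values: q_i = min(1, m * p_i)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


def construct_network(
    abund: SampleMatrix,
    env: SampleMatrix | None,
    params: AssociationParams | None = None,
    rng: np.random.Generator | None = None,
) -> AssociationNetwork:
    """Score all taxon-taxon and taxon-factor pairs and keep significant edges.

    Series are median/MAD standardized (degenerate series are dropped with a
    warning); p-values come from ``params.p_method``; Bonferroni q-values are
    computed over all tested pairs; an edge is kept when p <= p_threshold and
    q <= q_threshold. Factor-factor pairs are never tested.
    """
    if params is None:
        params = AssociationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if env is not None and env.sample_ids != abund.sample_ids:
        raise ValueError("abundance and environment matrices have different samples")

    series: dict[str, np.ndarray] = {}
    kinds: dict[str, NodeKind] = {}

    def standardize_rows(matrix: SampleMatrix, kind: NodeKind) -> None:
        for rid in matrix.row_ids:
            try:
                series[rid] = robust_z(matrix.row(rid))
                kinds[rid] = kind
            except DegenerateSeriesError:
                warnings.warn(
                    f"dropping degenerate series {rid!r} (zero MAD)", stacklevel=2
                )

    standardize_rows(abund, NodeKind.TAXON)
    if env is not None:
        standardize_rows(env, NodeKind.ENV)

    taxa = [r for r in abund.row_ids if r in series]
    factors = [r for r in (env.row_ids if env is not None else []) if r in series]
    pairs = [
        (taxa[i], taxa[j]) for i in range(len(taxa)) for j in range(i + 1, len(taxa))
    ] + [(t, f) for t in taxa for f in factors]

    records = []
    for u, v in pairs:
        score, sign, start, duration = local_similarity(series[u], series[v])
        if params.p_method == "theoretical":
            p = assoc_theoretical_p(series[u], series[v], score)
        else:
            p = assoc_permutation_p(
                series[u], series[v], permutations=params.permutations, rng=rng
            )
        records.append((u, v, score, sign, start, duration, p))

    net = AssociationNetwork(n_samples=abund.n_samples)
    if not records:
        return net
    q_values = bonferroni([r[6] for r in records])
    for (u, v, score, sign, start, duration, p), q in zip(records, q_values):
        if p <= params.p_threshold and q <= params.q_threshold:
            net.add_node(Node(u, kinds[u]))
            net.add_node(Node(v, kinds[v]))
            signed_score = score if sign == "+" else -score
            net.add_edge(
                Edge(
                    u=u,
                    v=v,
                    score=signed_score,
                    p_value=float(p),
                    q_value=float(q),
                    start=start,
                    duration=duration,
                )
            )
    return net
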