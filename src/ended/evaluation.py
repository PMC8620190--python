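"""Benchmark bookkeeping: confusion counts, classification rates, the
hypergeometric random-removal model, and the replicate driver.

Convention: the "positive" class is the *false association* (an inferred
edge absent from the ground-truth interaction matrix) and the positive call
is its removal. A true positive is therefore a correctly removed false
association, and a false positive a wrongly removed true interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .core_model import AssociationNetwork
from .edge_methods import ALL_METHODS, EnDEDParams, evaluate_network, removal_set
from .network_construction import AssociationParams, construct_network
from .simulator import SimulationConfig, add_poisson_noise, simulate_community

__all__ = [
    "ConfusionCounts",
    "RateSet",
    "RandomRemovalModel",
    "confusion",
    "rates",
    "hypergeom_pmf",
    "expected_removals",
    "tail_probability",
    "run_benchmark",
    "summarize_benchmark",
    "BENCHMARK_APPROACHES",
]

BENCHMARK_APPROACHES = list(ALL_METHODS) + ["intersection"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        """All false associations in the network."""
        return self.TP + self.FN

    @property
    def N(self) -> int:
        """All true interactions in the network."""
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.P + self.N


@dataclass(frozen=True)
class RateSet:
    """Derived rates; NaN marks an undefined ratio (e.g. PPV with no removals)."""

    TPR: float
    TNR: float
    FPR: float
    PPV: float
    ACC: float


@dataclass(frozen=True)
class RandomRemovalModel:
    """Multivariate hypergeometric model of removing n of N signed edges."""

    N: int
    N_pos: int
    N_neg: int
    n: int

    def __post_init__(self) -> None:
        if self.N_pos + self.N_neg != self.N:
            raise ValueError("N_pos + N_neg must equal N")
        if not 0 <= self.n <= self.N:
            raise ValueError("n must lie in [0, N]")


def confusion(
    removed_edges: set,
    network_edges: set,
    truth_edges: set,
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over a network's microbial edges.

    ``removed_edges`` must be a subset of ``network_edges`` (frozenset
    pairs); false associations are network edges absent from
    ``truth_edges``.
    """
    removed = {frozenset(e) for e in removed_edges}
    network = {frozenset(e) for e in network_edges}
    truth = {frozenset(e) for e in truth_edges}
    stray = removed - network
    if stray:
        raise ValueError(f"removed edges not in the network: {sorted(map(sorted, stray))[:3]}")
    false_assoc = network - truth
    true_inter = network & truth
    return ConfusionCounts(
        TP=len(removed & false_assoc),
        FP=len(removed & true_inter),
        TN=len(true_inter - removed),
        FN=len(false_assoc - removed),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def rates(c: ConfusionCounts) -> RateSet:
    """TPR, TNR, FPR, PPV, ACC; undefined ratios are NaN, never an exception."""
    tnr = _ratio(c.TN, c.N)
    return RateSet(
        TPR=_ratio(c.TP, c.P),
        TNR=tnr,
        FPR=1.0 - tnr if not math.isnan(tnr) else math.nan,
        PPV=_ratio(c.TP, c.TP + c.FP),
        ACC=_ratio(c.TP + c.TN, c.total),
    )


def hypergeom_pmf(model: RandomRemovalModel, k_neg: int, k_pos: int) -> float:
    """P(k_neg, k_pos) = C(N_neg, k_neg) C(N_pos, k_pos) / C(N, n).

    Zero outside the support (including k_neg + k_pos != n). Log-space via
    scipy's hypergeometric logpmf.
    """
    if k_neg + k_pos != model.n:
        return 0.0
    if not (0 <= k_neg <= model.N_neg and 0 <= k_pos <= model.N_pos):
        return 0.0
    return float(np.exp(hypergeom.logpmf(k_neg, model.N, model.N_neg, model.n)))


def expected_removals(
    N: int, N_neg: int, N_pos: int, n: int
) -> tuple[int, int, float, float]:
    """Expected negative/positive removals under random removal of n of N edges.

    Returns (E_neg rounded, E_pos rounded, E_neg exact, E_pos exact).
    """
    if N_neg + N_pos != N:
        raise ValueError("N_neg + N_pos must equal N")
    if not 0 <= n <= N:
        raise ValueError("n must lie in [0, N]")
    e_neg = n * N_neg / N if N else 0.0
    e_pos = n * N_pos / N if N else 0.0
    return int(round(e_neg)), int(round(e_pos)), e_neg, e_pos


def tail_probability(model: RandomRemovalModel, k_neg_obs: int) -> float:
    """P(k_neg >= k_neg_obs) under the model, exact log-space summation."""
    k_max = min(model.n, model.N_neg)
    k_min_support = max(0, model.n - model.N_pos)
    if k_neg_obs > k_max:
        return 0.0
    lo = max(k_neg_obs, k_min_support)
    ks = np.arange(lo, k_max + 1)
    logs = hypergeom.logpmf(ks, model.N, model.N_neg, model.n)
    return float(np.clip(np.exp(logsumexp(logs)), 0.0, 1.0))


def _params_like(base: EnDEDParams, methods: tuple[str, ...], combination: str,
                 rng_seed: int) -> EnDEDParams:
    return EnDEDParams(
        methods=methods,
        combination=combination,
        ol_threshold=base.ol_threshold,
        ii_alpha=base.ii_alpha,
        ii_iterations=base.ii_iterations,
        rng_seed=rng_seed,
        ii_ignore_significance=base.ii_ignore_significance,
        range_denominator=base.range_denominator,
    )


def run_benchmark(
    sim_cfg: SimulationConfig | None = None,
    assoc_params: AssociationParams | None = None,
    ended_params: EnDEDParams | None = None,
    n_datasets: int = 10,
    noise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, infer, filter and score ``n_datasets`` replicates.

    For each replicate every single method and the intersection combination
    are applied (flags are evaluated once per triplet and reused). Returns a
    tidy per-replicate, per-approach table with confusion counts, rates and
    the removed fraction; replicates whose network has no microbial edge are
    recorded with NaN rates. Per-replicate failures are recorded with
    ``error`` set and the run continues.
    """
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    if assoc_params is None:
        assoc_params = AssociationParams()
    if ended_params is None:
        ended_params = EnDEDParams()
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")

    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_datasets)):
        rng = np.random.default_rng(child)
        try:
            community = simulate_community(sim_cfg, rng)
            abund = community.abundances
            if noise:
                abund = add_poisson_noise(abund, rng=rng)
            env = community.env_matrix()
            network = construct_network(abund, env, assoc_params, rng)
            microbial = {e.pair for e in network.microbial_edges()}
            rep_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            # evaluate all four methods once; derive every removal set from
            # the same per-triplet flags
            eval_params = _params_like(
                ended_params, tuple(ALL_METHODS), "intersection", rep_seed
            )
            _, per_edge_flags = evaluate_network(network, abund, env, eval_params)
            approaches: dict[str, set] = {}
            for method in ALL_METHODS:
                approaches[method] = removal_set(
                    per_edge_flags,
                    _params_like(ended_params, (method,), "single", rep_seed),
                )
            approaches["intersection"] = removal_set(per_edge_flags, eval_params)
            for name in BENCHMARK_APPROACHES:
                removed = approaches[name]
                c = confusion(removed, microbial, community.truth_edges)
                r = rates(c)
                rows.append(
                    {
                        "replicate": rep,
                        "approach": name,
                        "n_edges": len(microbial),
                        "n_true": c.N,
                        "n_false": c.P,
                        "n_removed": len(removed),
                        "removed_fraction": (
                            len(removed) / len(microbial) if microbial else math.nan
                        ),
                        "TP": c.TP,
                        "FP": c.FP,
                        "TN": c.TN,
                        "FN": c.FN,
                        "TPR": r.TPR,
                        "TNR": r.TNR,
                        "FPR": r.FPR,
                        "PPV": r.PPV,
                        "ACC": r.ACC,
                        "error": "",
                    }
                )
        except Exception as exc:  # keep the sweep alive, record the failure
            rows.append(
                {
                    "replicate": rep,
                    "approach": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Per-approach medians and standard deviations of the benchmark table."""
    ok = table[table["approach"] != "failed"]
    metrics = ["removed_fraction", "TPR", "TNR", "FPR", "PPV", "ACC"]
    out = []
    for name, grp in ok.groupby("approach", sort=False):
        row: dict = {"approach": name, "n_replicates": len(grp)}
        for m in metrics:
            row[f"{m}_median"] = float(grp[m].median())
            row[f"{m}_std"] = float(grp[m].std())
        out.append(row)
    summary = pd.DataFrame(out)
    order = {name: i for i, name in enumerate(BENCHMARK_APPROACHES)}
    return summary.sort_values(
        "approach", key=lambda s: s.map(order)
    ).reset_index(drop=True)
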