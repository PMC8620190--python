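"""The four indirect-edge classifiers and their combination.

Each classifier judges, within one environmental triplet {v, w, f}, whether
the microbial edge v-w looks environmentally driven:

* sign pattern (SP): the product of the three association signs is positive;
* overlap (OL): the v-w association window overlaps the two taxon-factor
  windows by more than a threshold percentage (default 60);
* interaction information (II): II = CMI - MI is negative and its
  permutation p-value passes alpha;
* data processing inequality (DPI): MI(v;w) <= min(MI(v;f), MI(w;f)).

The intersection combination removes an edge only when all selected methods
flag it within the same triplet (any one such triplet suffices); edges in no
triplet are always kept, and taxon-factor edges are never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    AssociationNetwork,
    Edge,
    EnvironmentalTriplet,
    SampleMatrix,
    find_environmental_triplets,
)
from .info_theory import (
    conditional_mutual_information,
    equal_width_discretize,
    ii_significance,
    mutual_information,
)

__all__ = [
    "EnDEDParams",
    "MethodFlags",
    "EdgeVerdict",
    "sign_pattern",
    "overlap_percent",
    "dpi_flag",
    "evaluate_triplet",
    "evaluate_network",
    "removal_set",
    "apply_ended",
]

ALL_METHODS = ("SP", "OL", "II", "DPI")


@dataclass(frozen=True)
class EnDEDParams:
    """Run parameters for the edge classifiers.

    Defaults follow the reference analysis: all four methods combined by
    intersection, overlap threshold 60%, II significance alpha 0.05 with
    1000 permutations.
    """

    methods: tuple[str, ...] = ALL_METHODS
    combination: str = "intersection"
    ol_threshold: float = 60.0
    ii_alpha: float = 0.05
    ii_iterations: int = 1000
    rng_seed: int = 0
    ii_ignore_significance: bool = False
    agree_across_triplets: bool = False
    range_denominator: bool = False

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method must be selected")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.combination not in ("intersection", "union", "single"):
            raise ValueError(f"unknown combination {self.combination!r}")
        if self.combination == "single" and len(self.methods) != 1:
            raise ValueError("combination 'single' requires exactly one method")
        if not 0 < self.ol_threshold <= 100:
            raise ValueError("ol_threshold must lie in (0, 100]")
        if not 0 < self.ii_alpha < 1:
            raise ValueError("ii_alpha must lie in (0, 1)")
        if self.ii_iterations < 1:
            raise ValueError("ii_iterations must be >= 1")


@dataclass
class MethodFlags:
    """Per-triplet method outputs; a None flag means the method was not run."""

    sp: bool | None = None
    ol: bool | None = None
    ii: bool | None = None
    dpi: bool | None = None
    overlap_O: float | None = None
    ii_value: float | None = None
    ii_p: float | None = None
    mi_vw: float | None = None
    mi_vf: float | None = None
    mi_wf: float | None = None

    def flag(self, method: str) -> bool | None:
        return {"SP": self.sp, "OL": self.ol, "II": self.ii, "DPI": self.dpi}[method]


@dataclass
class EdgeVerdict:
    """Final per-edge bookkeeping after all triplets are evaluated."""

    n_triplets: int = 0
    flagged_counts: dict = field(default_factory=lambda: {m: 0 for m in ALL_METHODS})
    removed: bool = False


def sign_pattern(s_vw: str, s_vf: str, s_wf: str) -> bool:
    """True iff the product of the three association signs is positive."""
    for s in (s_vw, s_vf, s_wf):
        if s not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {s!r}")
    n_minus = sum(s == "-" for s in (s_vw, s_vf, s_wf))
    return n_minus % 2 == 0


def overlap_percent(edge_vw: Edge, edge_vf: Edge, edge_wf: Edge) -> float:
    """Percent overlap of the three association windows, relative to v-w.

    O = 100 * (min(e_vw, e_vf, e_wf) - max(b_vw, b_vf, b_wf)) / (e_vw - b_vw),
    unclipped: disjoint windows give a negative value.
    """
    if edge_vw.duration == 0:
        raise ValueError("zero-length v-w association window")
    lo = max(edge_vw.start, edge_vf.start, edge_wf.start)
    hi = min(edge_vw.end, edge_vf.end, edge_wf.end)
    return 100.0 * (hi - lo) / (edge_vw.end - edge_vw.start)


def dpi_flag(mi_vw: float, mi_vf: float, mi_wf: float) -> bool:
    """True iff the taxon-taxon MI is the smallest of the three (ties flag)."""
    for name, val in (("mi_vw", mi_vw), ("mi_vf", mi_vf), ("mi_wf", mi_wf)):
        if val < 0:
            raise ValueError(f"{name} is negative ({val})")
    return mi_vw <= min(mi_vf, mi_wf)


def evaluate_triplet(
    t: EnvironmentalTriplet,
    abund: SampleMatrix,
    env: SampleMatrix,
    params: EnDEDParams,
    rng: np.random.Generator,
) -> MethodFlags:
    """Run the selected classifiers on one triplet.

    II and DPI need the raw vectors; missing abundance/environment rows raise
    a KeyError naming the id. Methods not selected stay None.
    """
    flags = MethodFlags()
    if "SP" in params.methods:
        flags.sp = sign_pattern(t.edge_vw.sign, t.edge_vf.sign, t.edge_wf.sign)
    if "OL" in params.methods:
        flags.overlap_O = overlap_percent(t.edge_vw, t.edge_vf, t.edge_wf)
        flags.ol = flags.overlap_O > params.ol_threshold
    needs_vectors = "II" in params.methods or "DPI" in params.methods
    if needs_vectors:
        v = abund.row(t.v)
        w = abund.row(t.w)
        f = env.row(t.f)
        vd = equal_width_discretize(v, params.range_denominator)
        wd = equal_width_discretize(w, params.range_denominator)
        fd = equal_width_discretize(f, params.range_denominator)
        flags.mi_vw = mutual_information(vd, wd)
        if "II" in params.methods:
            cmi = conditional_mutual_information(vd, wd, fd)
            flags.ii_value = cmi - flags.mi_vw
            if params.ii_ignore_significance:
                flags.ii = flags.ii_value < 0
            else:
                flags.ii_p = ii_significance(
                    v, w, f,
                    iterations=params.ii_iterations,
                    rng=rng,
                    range_denominator=params.range_denominator,
                )
                flags.ii = flags.ii_value < 0 and flags.ii_p <= params.ii_alpha
        if "DPI" in params.methods:
            flags.mi_vf = mutual_information(vd, fd)
            flags.mi_wf = mutual_information(wd, fd)
            flags.dpi = dpi_flag(flags.mi_vw, flags.mi_vf, flags.mi_wf)
    return flags


def evaluate_network(
    network: AssociationNetwork,
    abund: SampleMatrix | None,
    env: SampleMatrix | None,
    params: EnDEDParams,
) -> tuple[dict, dict]:
    """Evaluate every triplet once; returns (base verdicts, per-edge flags).

    The base verdicts carry triplet counts and per-method flagged counts for
    every edge (``removed`` left False); ``per_edge_flags`` maps each
    microbial edge pair to the list of its triplets' :class:`MethodFlags`.
    """
    rng = np.random.default_rng(params.rng_seed)
    verdicts: dict = {e.pair: EdgeVerdict() for e in network.edges()}
    per_edge_flags: dict = {}
    for t in find_environmental_triplets(network):
        for pair in (t.edge_vw.pair, t.edge_vf.pair, t.edge_wf.pair):
            verdicts[pair].n_triplets += 1
        flags = evaluate_triplet(t, abund, env, params, rng)
        per_edge_flags.setdefault(t.edge_vw.pair, []).append(flags)
        verdict = verdicts[t.edge_vw.pair]
        for m in params.methods:
            if flags.flag(m):
                verdict.flagged_counts[m] += 1
    return verdicts, per_edge_flags


def removal_set(per_edge_flags: dict, params: EnDEDParams) -> set:
    """Derive the removed edge set from precomputed per-triplet flags.

    All of ``params.methods`` must have been evaluated when the flags were
    produced; an edge in zero triplets is never removed.
    """
    removed = set()
    for pair, flag_list in per_edge_flags.items():
        for m in params.methods:
            if any(fl.flag(m) is None for fl in flag_list):
                raise ValueError(f"method {m} was not evaluated for edge {set(pair)}")
        if params.agree_across_triplets and params.combination == "intersection":
            hit = all(any(fl.flag(m) for fl in flag_list) for m in params.methods)
        elif params.combination == "intersection":
            hit = any(all(fl.flag(m) for m in params.methods) for fl in flag_list)
        elif params.combination == "union":
            hit = any(fl.flag(m) for fl in flag_list for m in params.methods)
        else:  # single
            (method,) = params.methods
            hit = any(fl.flag(method) for fl in flag_list)
        if hit:
            removed.add(pair)
    return removed


def apply_ended(
    network: AssociationNetwork,
    abund: SampleMatrix | None,
    env: SampleMatrix | None,
    params: EnDEDParams,
) -> tuple[dict, set]:
    """Annotate and filter a network; returns (verdicts, removed pairs).

    ``verdicts`` maps each edge's frozenset pair to an :class:`EdgeVerdict`.
    For intersection, a triplet flags the edge iff every selected method
    flags it in that triplet, and one flagging triplet removes the edge.
    For union, any method flagging any triplet removes it. For single, the
    one selected method must flag at least one triplet. With
    ``agree_across_triplets``, each method instead only needs to flag the
    edge in *some* (possibly different) triplet. Edges in zero triplets are
    always kept; taxon-factor edges are never removed.
    """
    verdicts, per_edge_flags = evaluate_network(network, abund, env, params)
    removed_pairs = removal_set(per_edge_flags, params)
    for pair in removed_pairs:
        verdicts[pair].removed = True
    return verdicts, removed_pairs
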