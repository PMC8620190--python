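"""Network and matrix data model, file I/O, triplet enumeration, Jaccard index.

An association network is an undirected graph whose nodes are microbial taxa
or environmental factors and whose edges are signed, timed statistical
associations (co-presence / mutual exclusion), *not* ecological interactions.
The unit all downstream detection methods operate on is the *environmental
triplet*: two taxa and one factor with all three pairwise edges present.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeKind",
    "Node",
    "Edge",
    "AssociationNetwork",
    "EnvironmentalTriplet",
    "SampleMatrix",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_edge_table",
    "read_node_table",
    "write_annotated_edge_table",
    "write_edge_table",
    "find_environmental_triplets",
    "jaccard_index",
]

EDGE_COLUMNS = ["node1", "node2", "score", "p", "q", "start", "duration"]
ANNOTATION_COLUMNS = [
    "n_triplets",
    "sp_flags",
    "ol_flags",
    "ii_flags",
    "dpi_flags",
    "removed",
]


class NetworkFormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class NetworkValidationError(ValueError):
    """Input data violates a network invariant (self-loop, zero score, ...)."""


class NodeKind(str, Enum):
    TAXON = "taxon"
    ENV = "env"


@dataclass(frozen=True)
class Node:
    id: str
    kind: NodeKind

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be non-empty")


@dataclass(frozen=True)
class Edge:
    """A signed, timed association between two nodes.

    ``start``/``duration`` delimit the association window as a 0-based
    half-open sample-index interval [start, start + duration).
    """

    u: str
    v: str
    score: float
    p_value: float
    q_value: float
    start: int
    duration: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise NetworkValidationError(f"self-loop on node {self.u!r}")
        if self.score == 0:
            raise NetworkValidationError(
                f"edge {self.u!r}-{self.v!r} has score 0; signed score required"
            )
        if self.duration < 1:
            raise NetworkValidationError(
                f"edge {self.u!r}-{self.v!r} has duration {self.duration} < 1"
            )
        if self.start < 0:
            raise NetworkValidationError(
                f"edge {self.u!r}-{self.v!r} has negative start {self.start}"
            )
        for name in ("p_value", "q_value"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise NetworkValidationError(
                    f"edge {self.u!r}-{self.v!r}: {name}={val} outside [0,1]"
                )

    @property
    def sign(self) -> str:
        return "+" if self.score > 0 else "-"

    @property
    def end(self) -> int:
        return self.start + self.duration

    @property
    def pair(self) -> frozenset:
        return frozenset((self.u, self.v))


class AssociationNetwork:
    """Undirected association network over taxon and factor nodes.

    Thin wrapper around a :class:`networkx.Graph`; node kind lives in the
    ``kind`` node attribute and each edge stores its :class:`Edge` record in
    the ``record`` edge attribute.
    """

    def __init__(self, n_samples: int | None = None) -> None:
        self.graph = nx.Graph()
        self.n_samples = n_samples

    # -- construction -------------------------------------------------
    def add_node(self, node: Node) -> None:
        if node.id in self.graph and self.graph.nodes[node.id]["kind"] != node.kind:
            raise NetworkValidationError(
                f"node {node.id!r} declared with conflicting kinds"
            )
        self.graph.add_node(node.id, kind=node.kind)

    def add_edge(self, edge: Edge) -> None:
        for endpoint in (edge.u, edge.v):
            if endpoint not in self.graph:
                raise NetworkValidationError(
                    f"edge endpoint {endpoint!r} is not a declared node"
                )
        if self.graph.has_edge(edge.u, edge.v):
            raise NetworkValidationError(
                f"duplicate edge for pair {{{edge.u!r}, {edge.v!r}}}"
            )
        if self.n_samples is not None and edge.end > self.n_samples:
            raise NetworkValidationError(
                f"edge {edge.u!r}-{edge.v!r} window [{edge.start}, {edge.end}) "
                f"exceeds {self.n_samples} samples"
            )
        self.graph.add_edge(edge.u, edge.v, record=edge)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_kind(self, node_id: str) -> NodeKind:
        return self.graph.nodes[node_id]["kind"]

    def nodes(self, kind: NodeKind | None = None) -> list[str]:
        if kind is None:
            return sorted(self.graph.nodes)
        return sorted(n for n, k in self.graph.nodes(data="kind") if k == kind)

    def edges(self) -> list[Edge]:
        return sorted(
            (data["record"] for _, _, data in self.graph.edges(data=True)),
            key=lambda e: tuple(sorted((e.u, e.v))),
        )

    def get_edge(self, u: str, v: str) -> Edge:
        try:
            return self.graph.edges[u, v]["record"]
        except KeyError:
            raise KeyError(f"no edge for pair {{{u!r}, {v!r}}}") from None

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def microbial_edges(self) -> list[Edge]:
        """Edges whose two endpoints are both taxa."""
        return [
            e
            for e in self.edges()
            if self.node_kind(e.u) == NodeKind.TAXON
            and self.node_kind(e.v) == NodeKind.TAXON
        ]


@dataclass(frozen=True)
class EnvironmentalTriplet:
    """Two taxa ``v``, ``w`` and one factor ``f`` with all three edges present."""

    v: str
    w: str
    f: str
    edge_vw: Edge
    edge_vf: Edge
    edge_wf: Edge


@dataclass
class SampleMatrix:
    """A (rows x samples) real matrix with ordered row and sample ids.

    ``role`` distinguishes abundance matrices (values >= 0) from
    environmental-factor matrices (unconstrained values).
    """

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    role: str = "abundance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise NetworkValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise NetworkValidationError("duplicate row ids in sample matrix")
        if self.role == "abundance" and np.any(self.values < 0):
            raise NetworkValidationError("abundance matrix has negative entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, row_id: str) -> np.ndarray:
        try:
            idx = self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"no row {row_id!r} in {self.role} matrix") from None
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.sample_ids)

    @classmethod
    def from_tsv(cls, source, role: str = "abundance") -> "SampleMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0, comment="#")
        return cls(
            row_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            role=role,
        )

    def to_tsv(self, sink, header_lines: Sequence[str] = ()) -> None:
        _write_with_header(sink, self.to_frame(), header_lines, index=True,
                           index_label="id")


def _write_with_header(sink, df: pd.DataFrame, header_lines: Sequence[str],
                       index: bool = False, index_label: str | None = None) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index, index_label=index_label)
    text = buf.getvalue()
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def read_node_table(source) -> dict[str, NodeKind]:
    """Read a two-column ``id<TAB>kind`` table with kind in {taxon, env}."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    for col in ("id", "kind"):
        if col not in df.columns:
            raise NetworkFormatError(f"node table is missing required column {col!r}")
    kinds: dict[str, NodeKind] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.kind not in ("taxon", "env"):
            raise NetworkFormatError(
                f"node table line {row_no}: kind {row.kind!r} not in {{taxon, env}}"
            )
        kinds[str(row.id)] = NodeKind(row.kind)
    return kinds


def read_edge_table(
    source,
    node_kinds: Mapping[str, NodeKind] | None = None,
    env_prefix: str | None = None,
    n_samples: int | None = None,
) -> AssociationNetwork:
    """Load an association network from a TSV edge table.

    Node kinds are declared either through ``node_kinds`` (a mapping such as
    the one produced by :func:`read_node_table`) or through ``env_prefix``
    (ids starting with the prefix are factors, the rest taxa). Exactly one of
    the two must be supplied unless the table is empty.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"node1": str, "node2": str})
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise NetworkFormatError(f"edge table is missing required column {col!r}")

    net = AssociationNetwork(n_samples=n_samples)

    def kind_of(node_id: str) -> NodeKind:
        if node_kinds is not None:
            if node_id not in node_kinds:
                raise NetworkFormatError(
                    f"node {node_id!r} appears in the edge table but not in the "
                    "node table"
                )
            return node_kinds[node_id]
        if env_prefix is not None:
            return NodeKind.ENV if node_id.startswith(env_prefix) else NodeKind.TAXON
        raise NetworkFormatError(
            "node kinds undeclared: supply node_kinds or env_prefix"
        )

    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            edge = Edge(
                u=str(row.node1),
                v=str(row.node2),
                score=float(row.score),
                p_value=float(row.p),
                q_value=float(row.q),
                start=int(row.start),
                duration=int(row.duration),
            )
            net.add_node(Node(edge.u, kind_of(edge.u)))
            net.add_node(Node(edge.v, kind_of(edge.v)))
            net.add_edge(edge)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"edge table line {row_no}: {exc}") from None
    return net


def _edge_frame(edges: Iterable[Edge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node1": e.u,
                "node2": e.v,
                "score": e.score,
                "p": e.p_value,
                "q": e.q_value,
                "start": e.start,
                "duration": e.duration,
            }
            for e in edges
        ],
        columns=EDGE_COLUMNS,
    )


def write_edge_table(network: AssociationNetwork, sink,
                     header_lines: Sequence[str] = ()) -> None:
    """Write the plain seven-column edge table."""
    _write_with_header(sink, _edge_frame(network.edges()), header_lines)


def write_annotated_edge_table(
    network: AssociationNetwork,
    verdicts: Mapping[frozenset, "EdgeVerdict"],
    sink,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the edge table plus per-edge verdict columns.

    Column order is the seven input columns followed by ``n_triplets``,
    ``sp_flags``, ``ol_flags``, ``ii_flags``, ``dpi_flags``, ``removed``.
    Every edge must have a verdict (an edge that sits in no triplet carries an
    all-zero verdict).
    """
    edges = network.edges()
    rows = _edge_frame(edges)
    annotations = []
    for e in edges:
        verdict = verdicts.get(e.pair)
        if verdict is None:
            raise NetworkValidationError(
                f"no verdict for edge {e.u!r}-{e.v!r}"
            )
        annotations.append(
            {
                "n_triplets": verdict.n_triplets,
                "sp_flags": verdict.flagged_counts.get("SP", 0),
                "ol_flags": verdict.flagged_counts.get("OL", 0),
                "ii_flags": verdict.flagged_counts.get("II", 0),
                "dpi_flags": verdict.flagged_counts.get("DPI", 0),
                "removed": verdict.removed,
            }
        )
    out = pd.concat(
        [rows, pd.DataFrame(annotations, columns=ANNOTATION_COLUMNS)], axis=1
    )
    _write_with_header(sink, out, header_lines)


def find_environmental_triplets(
    network: AssociationNetwork,
) -> list[EnvironmentalTriplet]:
    """Enumerate all environmental triplets, sorted by (v, w, f) ids.

    One triplet per (unordered taxon pair, factor); ``v < w`` lexically.
    """
    triplets: list[EnvironmentalTriplet] = []
    for f in network.nodes(kind=NodeKind.ENV):
        taxon_neighbours = sorted(
            n
            for n in network.graph.neighbors(f)
            if network.node_kind(n) == NodeKind.TAXON
        )
        for v, w in itertools.combinations(taxon_neighbours, 2):
            if network.has_edge(v, w):
                triplets.append(
                    EnvironmentalTriplet(
                        v=v,
                        w=w,
                        f=f,
                        edge_vw=network.get_edge(v, w),
                        edge_vf=network.get_edge(v, f),
                        edge_wf=network.get_edge(w, f),
                    )
                )
    triplets.sort(key=lambda t: (t.v, t.w, t.f))
    return triplets


def jaccard_index(x: np.ndarray, y: np.ndarray, threshold: float = 0.0) -> float:
    """Co-presence Jaccard index of two abundance rows.

    Presence means value > ``threshold``. Defined as |both present| /
    |at least one present|; two all-absent rows give 0.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    px = x > threshold
    py = y > threshold
    union = np.count_nonzero(px | py)
    if union == 0:
        return 0.0
    return np.count_nonzero(px & py) / union
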