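"""STRING-style protein-protein interaction networks and local target environments.

The interaction graph is undirected; each edge carries an integer confidence
score in [150, 999] and a weight equal to the reciprocal of that confidence,
so high-confidence interactions are "short". The local environment of a
target protein is its N nearest neighbors under weighted shortest-path
(Dijkstra) distance, annotated with differential-expression values and ranked
by distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CONFIDENCE_MIN = 150
CONFIDENCE_MAX = 999

#: Distance recorded for padding entries when fewer than N nodes are reachable.
UNREACHABLE = math.inf


class NetworkError(ValueError):
    """Malformed or out-of-contract network input."""


def edge_weight(confidence: int) -> float:
    """Reciprocal-confidence edge weight.

    Parameters
    ----------
    confidence : int
        STRING combined score in [150, 999].

    Returns
    -------
    float
        1 / confidence; strictly decreasing in confidence.
    """
    if not (CONFIDENCE_MIN <= confidence <= CONFIDENCE_MAX):
        raise NetworkError(
            f"confidence {confidence} outside [{CONFIDENCE_MIN}, {CONFIDENCE_MAX}]"
        )
    return 1.0 / confidence


@dataclass
class PPINetwork:
    """Undirected weighted PPI graph backed by a :class:`networkx.Graph`.

    Edge attributes: ``confidence`` (int) and ``weight`` (1/confidence).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self):
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, u: str, v: str, confidence: int) -> None:
        if u == v:
            raise NetworkError(f"self-loop on node {u!r}")
        w = edge_weight(int(confidence))
        self.graph.add_edge(u, v, confidence=int(confidence), weight=w)

    def confidence(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["confidence"]

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise NetworkError(f"self-loop on node {u!r}")
            c = d["confidence"]
            if not (CONFIDENCE_MIN <= c <= CONFIDENCE_MAX):
                raise NetworkError(f"edge {u}-{v} confidence {c} out of range")
            if abs(d["weight"] - 1.0 / c) > 1e-12:
                raise NetworkError(f"edge {u}-{v} weight is not 1/confidence")


def load_network(source, min_confidence: int = CONFIDENCE_MIN) -> PPINetwork:
    """Load a tab-separated edge table (protein1, protein2, combined_score).

    A header row is auto-detected. Rows below ``min_confidence`` are dropped,
    duplicate pairs are collapsed keeping the maximum confidence, and
    self-loops are discarded; counts are reported through logging.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    rows: list[tuple[str, str, int]] = []
    n_dropped = n_self = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # tolerate space-separated STRING dumps
            parts = line.split()
        if len(parts) < 3:
            raise NetworkError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        a, b, raw = parts[0], parts[1], parts[2]
        try:
            conf = int(raw)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise NetworkError(f"line {lineno}: non-integer confidence {raw!r}") from None
        if a == b:
            n_self += 1
            continue
        if conf < min_confidence:
            n_dropped += 1
            continue
        if not (CONFIDENCE_MIN <= conf <= CONFIDENCE_MAX):
            raise NetworkError(
                f"line {lineno}: confidence {conf} outside "
                f"[{CONFIDENCE_MIN}, {CONFIDENCE_MAX}]"
            )
        rows.append((a, b, conf))

    net = PPINetwork()
    n_collapsed = 0
    for a, b, conf in rows:
        if net.graph.has_edge(a, b):
            n_collapsed += 1
            if conf > net.graph.edges[a, b]["confidence"]:
                net.add_edge(a, b, conf)
        else:
            net.add_edge(a, b, conf)
    if not rows:
        logger.warning("loaded an empty network from %s", source)
    logger.info(
        "network loaded: %d nodes, %d edges (%d below cutoff, %d self-loops, "
        "%d duplicates collapsed)",
        len(net.nodes), net.n_edges, n_dropped, n_self, n_collapsed,
    )
    return net


@dataclass
class ExpressionProfile:
    """One perturbation signature: moderated Z-scores per protein."""

    signature_id: str
    cell_line: str
    concentration: float  # µM
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")


def load_expression(source) -> list[ExpressionProfile]:
    """Read signature_id / cell_line / concentration_uM / protein / modz TSV."""
    df = pd.read_csv(source, sep="\t")
    required = {"signature_id", "cell_line", "concentration_uM", "protein", "modz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    profiles = []
    for (sig, cell, conc), grp in df.groupby(
        ["signature_id", "cell_line", "concentration_uM"], sort=True
    ):
        profiles.append(
            ExpressionProfile(
                signature_id=str(sig),
                cell_line=str(cell),
                concentration=float(conc),
                values=dict(zip(grp["protein"].astype(str), grp["modz"].astype(float))),
            )
        )
    return profiles


@dataclass
class NeighborRecord:
    node: str | None
    rank: int
    distance: float
    expression: float
    present: bool = True
    expression_measured: bool = True


@dataclass
class LocalEnvironment:
    """Target protein plus its N distance-ranked neighbors.

    ``neighbors`` always has exactly N entries; when fewer nodes are
    reachable the tail is padding (``present=False``, infinite distance).
    ``induced_edges`` are the weighted edges among {target} ∪ real neighbors.
    """

    target: str
    n: int
    neighbors: list[NeighborRecord]
    induced_edges: list[tuple[str, str, float]]
    target_expression: float = 0.0

    @property
    def real_neighbors(self) -> list[NeighborRecord]:
        return [r for r in self.neighbors if r.present]

    def environment_id(self) -> str:
        return f"{self.target}|N{self.n}"


def shortest_path_distance(network: PPINetwork, source: str, target: str) -> float:
    """Minimal total reciprocal-confidence weight between two proteins.

    Returns 0 for ``source == target`` and :data:`UNREACHABLE` (+inf) when no
    path exists.
    """
    g = network.graph
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node!r} not in network")
    if source == target:
        return 0.0
    try:
        return nx.dijkstra_path_length(g, source, target, weight="weight")
    except nx.NetworkXNoPath:
        return UNREACHABLE


def extract_local_environment(
    network: PPINetwork,
    target: str,
    n: int,
    profile: ExpressionProfile | None = None,
    strict: bool = False,
) -> LocalEnvironment:
    """Select the N nearest reachable neighbors of ``target`` by Dijkstra distance.

    Ties are broken by (distance, node identifier) so the environment does not
    depend on hash order. Neighbors missing from ``profile`` get expression 0
    with ``expression_measured=False``. With ``strict=True`` a target with
    fewer than N reachable nodes is rejected instead of padded.
    """
    g = network.graph
    if target not in g:
        raise KeyError(f"target {target!r} not in network")
    if n < 1:
        raise ValueError("environment size N must be >= 1")

    dist = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    dist.pop(target, None)
    ordered = sorted(dist.items(), key=lambda kv: (kv[1], kv[0]))[:n]
    if strict and len(ordered) < n:
        raise NetworkError(
            f"target {target!r} has only {len(ordered)} reachable nodes (< {n})"
        )

    values = profile.values if profile is not None else {}
    neighbors: list[NeighborRecord] = []
    for rank, (node, d) in enumerate(ordered, start=1):
        measured = node in values
        neighbors.append(
            NeighborRecord(
                node=node,
                rank=rank,
                distance=float(d),
                expression=float(values.get(node, 0.0)),
                present=True,
                expression_measured=measured,
            )
        )
    for rank in range(len(ordered) + 1, n + 1):
        neighbors.append(
            NeighborRecord(
                node=None, rank=rank, distance=UNREACHABLE,
                expression=0.0, present=False, expression_measured=False,
            )
        )

    selected = {target, *(r.node for r in neighbors if r.present)}
    induced = [
        (u, v, d["weight"])
        for u, v, d in g.edges(selected, data=True)
        if u in selected and v in selected
    ]
    induced = sorted({(min(u, v), max(u, v), w) for u, v, w in induced})
    return LocalEnvironment(
        target=target,
        n=n,
        neighbors=neighbors,
        induced_edges=induced,
        target_expression=float(values.get(target, 0.0)),
    )
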