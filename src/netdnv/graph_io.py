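"""Gene networks: reading scored edge lists, subnetwork construction, weights.

A gene network is an undirected graph over gene identifiers.  Each gene i
carries a degree ``d_i`` (number of distinct neighbors) and an MRF weight
``w_i``: the square root of the degree in network mode, or 0 everywhere in
no-network mode (which makes the coupled prior collapse to independent
genes).  Edge lists follow the STRING convention of an integer confidence
score in [0, 1000] per pair; 400 is the usual "medium confidence" cutoff and
950 is near the top of the scale.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneNetwork",
    "ParseError",
    "read_edge_list",
    "read_gene_list",
    "build_seed_subnetwork",
    "restrict_to_genes",
    "write_edge_list",
    "write_degree_summary",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected gene network in CSR form over lexicographically sorted nodes.

    Attributes
    ----------
    nodes : tuple of str
        Gene identifiers, sorted lexicographically.  All index-based arrays
        (degrees, weights, CSR adjacency) follow this order.
    indptr, indices : ndarray of int64
        CSR adjacency; neighbors of node ``i`` are
        ``indices[indptr[i]:indptr[i+1]]``.
    degrees : ndarray of int64
    weights : ndarray of float64
        ``sqrt(d_i)`` in network mode, all zeros in no-network mode.
    edge_scores : dict
        Confidence score per undirected edge, keyed by the (min, max) gene-id
        pair; empty if scores were not supplied.
    no_network : bool
        When True, all weights are zero regardless of the edge structure.
    """

    nodes: tuple
    indptr: np.ndarray
    indices: np.ndarray
    degrees: np.ndarray
    weights: np.ndarray
    edge_scores: dict = field(default_factory=dict)
    no_network: bool = False

    # -- construction ------------------------------------------------------
    @staticmethod
    def from_edges(
        nodes: Iterable[str],
        edges: Iterable[tuple],
        scores: dict | None = None,
        no_network: bool = False,
    ) -> "GeneNetwork":
        """Build a network from a node set and undirected edge pairs.

        Self-loops are dropped and reciprocal/duplicate pairs collapse to a
        single undirected edge.  ``scores`` maps (a, b) pairs (any order) to
        integer confidence scores.
        """
        node_list = sorted(set(nodes))
        index = {g: i for i, g in enumerate(node_list)}
        adj: list[set] = [set() for _ in node_list]
        edge_scores: dict = {}
        for e in edges:
            a, b = e[0], e[1]
            if a == b:
                continue
            ia, ib = index[a], index[b]
            adj[ia].add(ib)
            adj[ib].add(ia)
            key = (a, b) if a < b else (b, a)
            if scores is not None and (a, b) in scores:
                edge_scores[key] = scores[(a, b)]
            elif scores is not None and (b, a) in scores:
                edge_scores[key] = scores[(b, a)]
            elif len(e) > 2:
                edge_scores[key] = e[2]
        indptr = np.zeros(len(node_list) + 1, dtype=np.int64)
        chunks = []
        for i, nb in enumerate(adj):
            arr = np.array(sorted(nb), dtype=np.int64)
            chunks.append(arr)
            indptr[i + 1] = indptr[i] + arr.size
        indices = (
            np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
        )
        degrees = np.diff(indptr)
        weights = (
            np.zeros(len(node_list)) if no_network else np.sqrt(degrees.astype(float))
        )
        return GeneNetwork(
            nodes=tuple(node_list),
            indptr=indptr,
            indices=indices,
            degrees=degrees,
            weights=weights,
            edge_scores=edge_scores,
            no_network=no_network,
        )

    # -- queries -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    def __contains__(self, gene: str) -> bool:
        return gene in self.node_index

    @property
    def node_index(self) -> dict:
        idx = getattr(self, "_node_index_cache", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.nodes)}
            object.__setattr__(self, "_node_index_cache", idx)
        return idx

    def neighbors(self, gene: str) -> list:
        i = self.node_index[gene]
        return [self.nodes[k] for k in self.indices[self.indptr[i] : self.indptr[i + 1]]]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (u, v) with u < v, one entry per undirected edge."""
        cached = getattr(self, "_edge_arrays_cache", None)
        if cached is None:
            us, vs = [], []
            for i in range(self.n_nodes):
                for k in self.indices[self.indptr[i] : self.indptr[i + 1]]:
                    if i < k:
                        us.append(i)
                        vs.append(k)
            cached = (np.array(us, dtype=np.int64), np.array(vs, dtype=np.int64))
            object.__setattr__(self, "_edge_arrays_cache", cached)
        return cached

    def edges(self):
        """Yield undirected edges as (gene_a, gene_b) with gene_a < gene_b."""
        u, v = self.edge_arrays()
        for a, b in zip(u, v):
            yield self.nodes[a], self.nodes[b]

    def score(self, a: str, b: str):
        key = (a, b) if a < b else (b, a)
        return self.edge_scores.get(key)

    def with_zero_weights(self) -> "GeneNetwork":
        """Copy of the network with all MRF weights set to zero (no-network mode)."""
        return GeneNetwork(
            nodes=self.nodes,
            indptr=self.indptr,
            indices=self.indices,
            degrees=self.degrees,
            weights=np.zeros(self.n_nodes),
            edge_scores=self.edge_scores,
            no_network=True,
        )


def read_gene_list(path) -> list:
    """Read a gene list (one identifier per line, '#' comments ignored)."""
    genes = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def read_edge_list(path, score_threshold: int = 400, strict: bool = False) -> GeneNetwork:
    """Read a scored TSV edge list and filter by confidence score.

    The file has >= 3 tab-separated columns (gene_a, gene_b, score).  A
    header row is auto-detected by a non-numeric third field.  Edges are
    retained when ``score >= score_threshold`` (``>`` when ``strict``);
    self-loops are dropped and duplicate or reciprocal pairs collapse to one
    undirected edge (keeping the maximum score seen for the pair).
    """
    edges: dict = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"expected >= 3 columns (gene_a, gene_b, score), got {len(parts)}",
                    lineno,
                )
            a, b, score_str = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if lineno == 1:
                try:
                    int(score_str)
                except ValueError:
                    continue  # header row
            try:
                score = int(score_str)
            except ValueError:
                raise ParseError(f"non-integer score {score_str!r}", lineno) from None
            if not (0 <= score <= 1000):
                raise ParseError(f"score {score} outside [0, 1000]", lineno)
            if a == b:
                continue
            keep = score > score_threshold if strict else score >= score_threshold
            if not keep:
                continue
            key = (a, b) if a < b else (b, a)
            if key not in edges or score > edges[key]:
                edges[key] = score
    if not edges:
        warnings.warn(
            f"no edges retained from {path} at score threshold {score_threshold}",
            stacklevel=2,
        )
        return GeneNetwork.from_edges([], [])
    nodes = set()
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
    return GeneNetwork.from_edges(nodes, list(edges.keys()), scores=edges)


def build_seed_subnetwork(
    full: GeneNetwork,
    seeds: Sequence[str],
    dnv_genes: Sequence[str],
    neighbor_score_threshold: int = 950,
    only_high_confidence_edges: bool = False,
) -> GeneNetwork:
    """Extract the seed-anchored subnetwork used for analysis.

    Starting from a base network (typically read at the medium-confidence
    threshold), take the seed genes plus their direct neighbors connected by
    an edge scoring strictly above ``neighbor_score_threshold``, then keep
    only genes present in ``dnv_genes`` (the genes with count data).  By
    default all base-network edges among the retained genes are kept;
    ``only_high_confidence_edges`` restricts the induced subgraph to edges
    above the neighbor threshold as well.
    """
    if not seeds:
        raise ValueError("seed gene list is empty")
    seeds_in_net = [s for s in seeds if s in full]
    if not seeds_in_net:
        raise ValueError("no seed gene is present in the network")
    dnv_set = set(dnv_genes)
    dropped = [s for s in seeds_in_net if s not in dnv_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} seed gene(s) absent from the DNV gene list were dropped",
            stacklevel=2,
        )
    expanded = set(seeds_in_net)
    for s in seeds_in_net:
        for nb in full.neighbors(s):
            sc = full.score(s, nb)
            if sc is not None and sc > neighbor_score_threshold:
                expanded.add(nb)
    retained = expanded & dnv_set
    kept_edges = []
    scores = {}
    for a, b in full.edges():
        if a in retained and b in retained:
            sc = full.score(a, b)
            if only_high_confidence_edges and not (
                sc is not None and sc > neighbor_score_threshold
            ):
                continue
            kept_edges.append((a, b))
            if sc is not None:
                scores[(a, b)] = sc
    return GeneNetwork.from_edges(retained, kept_edges, scores=scores)


def restrict_to_genes(net: GeneNetwork, genes: Sequence[str]) -> GeneNetwork:
    """Induced subgraph on ``genes``; genes absent from the network become
    isolated nodes (degree 0, weight 0)."""
    gene_set = set(genes)
    kept_edges = []
    scores = {}
    for a, b in net.edges():
        if a in gene_set and b in gene_set:
            kept_edges.append((a, b))
            sc = net.score(a, b)
            if sc is not None:
                scores[(a, b)] = sc
    return GeneNetwork.from_edges(
        gene_set, kept_edges, scores=scores, no_network=net.no_network
    )


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write the network as a TSV edge list (gene_a, gene_b, score)."""
    with open(path, "wt") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b in net.edges():
            sc = net.score(a, b)
            fh.write(f"{a}\t{b}\t{sc if sc is not None else 1000}\n")


def write_degree_summary(net: GeneNetwork, path) -> None:
    """Write a per-gene degree/weight summary TSV."""
    with open(path, "wt") as fh:
        fh.write("gene\tdegree\tweight\n")
        for g, d, w in zip(net.nodes, net.degrees, net.weights):
            fh.write(f"{g}\t{int(d)}\t{w:.10g}\n")
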