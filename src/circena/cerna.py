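"""ceRNA (circRNA–miRNA–mRNA) network construction.

Three selection rules, applied to expression matrices over a common sample
set: (1) sponge pairs — Spearman rank correlation strictly below −0.7
between a miRNA and a circRNA or mRNA; (2) partner pairs — Pearson
correlation strictly above 0.9 between a circRNA and an mRNA; (3) a
hypergeometric upper-tail test on the shared sponge-miRNA sets of each
partner pair, retained at p < 0.05.  Retained triads are assembled into a
typed network exported as SIF / GraphML / attribute tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

SCC_THRESHOLD = -0.7
PCC_THRESHOLD = 0.9
SPONGE_ALPHA = 0.05


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class PairScore:
    a_id: str
    a_type: str
    b_id: str
    b_type: str
    kind: str  # "SCC" or "PCC"
    value: float
    n: int


def filter_features(
    matrix: ExpressionMatrix, max_zero_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop features whose zero fraction exceeds the threshold (mostly-zero
    profiles give tie-degenerate ranks)."""
    zf = (matrix.data == 0).mean(axis=1)
    keep = zf[zf <= max_zero_fraction].index
    dropped = len(matrix.data) - len(keep)
    if dropped:
        logger.info("filter_features: dropped %d mostly-zero features", dropped)
    return ExpressionMatrix(matrix.data.loc[keep], matrix.groups, matrix.units)


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross Pearson correlation of two (features × samples)
    arrays; rows with zero variance come out as NaN."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (a @ b.T) / np.outer(sa, sb)
    return c


def _check_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> int:
    if a.samples != b.samples:
        raise InputError("matrices must share an identical sample ordering")
    n = len(a.samples)
    if n < 3:
        raise InputError("need at least 3 samples for correlation")
    return n


def spearman_pairs(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    threshold: float = SCC_THRESHOLD,
    a_type: str = "circRNA",
    b_type: str = "miRNA",
) -> list[PairScore]:
    """All cross pairs with Spearman correlation strictly below ``threshold``.

    Ranks use the average-rank convention for ties; constant features are
    skipped (undefined coefficient) with a log entry.
    """
    n = _check_samples(a, b)
    ra = np.apply_along_axis(stats.rankdata, 1, a.data.to_numpy(dtype=float))
    rb = np.apply_along_axis(stats.rankdata, 1, b.data.to_numpy(dtype=float))
    corr = _cross_correlation(ra, rb)
    return _collect_pairs(corr, a.features, b.features, "SCC",
                          lambda v: v < threshold, a_type, b_type, n)


def pearson_pairs(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    threshold: float = PCC_THRESHOLD,
    a_type: str = "circRNA",
    b_type: str = "mRNA",
) -> list[PairScore]:
    """All cross pairs with Pearson correlation strictly above ``threshold``."""
    n = _check_samples(a, b)
    corr = _cross_correlation(
        a.data.to_numpy(dtype=float), b.data.to_numpy(dtype=float)
    )
    return _collect_pairs(corr, a.features, b.features, "PCC",
                          lambda v: v > threshold, a_type, b_type, n)


def _collect_pairs(corr, a_ids, b_ids, kind, accept, a_type, b_type, n):
    nan_rows = np.isnan(corr).all(axis=1).sum()
    if nan_rows:
        logger.info("%s: %d constant features skipped", kind, int(nan_rows))
    pairs = []
    ii, jj = np.nonzero(~np.isnan(corr))
    for i, j in zip(ii, jj):
        v = float(corr[i, j])
        if accept(v):
            pairs.append(
                PairScore(a_id=a_ids[i], a_type=a_type, b_id=b_ids[j],
                          b_type=b_type, kind=kind, value=v, n=n)
            )
    return pairs


# ------------------------------------------------------------ sponge test


@dataclass
class CeRNATriad:
    circ_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    k: int  # |shared|
    K: int  # circRNA sponge-miRNA count
    n: int  # mRNA miRNA count
    N: int  # miRNA universe size
    p: float
    retained: bool


def sponge_test(
    circ_mirnas: set[str],
    mrna_mirnas: set[str],
    universe: set[str],
    circ_id: str = "",
    mrna_id: str = "",
    alpha: float = SPONGE_ALPHA,
) -> CeRNATriad:
    """Hypergeometric upper-tail test on the shared sponge-miRNA set:
    p = P[X ≥ k], X ~ Hypergeom(N=|universe|, K=|circ set|, n=|mRNA set|)."""
    if not universe:
        raise InputError("empty miRNA universe")
    if not circ_mirnas <= universe or not mrna_mirnas <= universe:
        raise InputError("miRNA sets must be subsets of the universe")
    shared = frozenset(circ_mirnas & mrna_mirnas)
    k, K, n, N = len(shared), len(circ_mirnas), len(mrna_mirnas), len(universe)
    p = float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))
    return CeRNATriad(
        circ_id=circ_id, mrna_id=mrna_id, shared_mirnas=shared,
        k=k, K=K, n=n, N=N, p=p, retained=p < alpha,
    )


def build_triads(
    circ_mir_pairs: list[PairScore],
    mrna_mir_pairs: list[PairScore],
    circ_mrna_pairs: list[PairScore],
    universe: set[str],
    alpha: float = SPONGE_ALPHA,
) -> list[CeRNATriad]:
    """Run the sponge test for every correlated circRNA–mRNA partner pair.

    A pair's miRNA sets are the miRNAs negatively correlated with each
    member; retained triads have a shared set whose overlap is significant
    at ``alpha``.
    """
    circ_sets: dict[str, set[str]] = {}
    for p in circ_mir_pairs:
        circ_sets.setdefault(p.a_id, set()).add(p.b_id)
    mrna_sets: dict[str, set[str]] = {}
    for p in mrna_mir_pairs:
        mrna_sets.setdefault(p.a_id, set()).add(p.b_id)
    triads = []
    for pair in circ_mrna_pairs:
        cset = circ_sets.get(pair.a_id, set())
        mset = mrna_sets.get(pair.b_id, set())
        if not cset or not mset:
            continue
        triads.append(
            sponge_test(cset, mset, universe, circ_id=pair.a_id,
                        mrna_id=pair.b_id, alpha=alpha)
        )
    return triads


# ---------------------------------------------------------------- network


@dataclass
class CeRNANetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)

    def composition(self) -> dict[str, int]:
        nodes = {"circRNA": 0, "miRNA": 0, "mRNA": 0}
        for _n, d in self.graph.nodes(data=True):
            nodes[d["node_type"]] += 1
        edges = {"circRNA-miRNA": 0, "miRNA-mRNA": 0, "circRNA-mRNA": 0}
        for _u, _v, d in self.graph.edges(data=True):
            edges[d["edge_type"]] += 1
        return {
            "n_circRNA": nodes["circRNA"],
            "n_miRNA": nodes["miRNA"],
            "n_mRNA": nodes["mRNA"],
            "n_circ_mir_edges": edges["circRNA-miRNA"],
            "n_mir_mrna_edges": edges["miRNA-mRNA"],
            "n_circ_mrna_edges": edges["circRNA-mRNA"],
        }


def assemble_network(
    scc_pairs: list[PairScore],
    pcc_pairs: list[PairScore],
    triads: list[CeRNATriad],
) -> CeRNANetwork:
    """Build the typed graph from retained triads.

    Every retained triad contributes its circRNA–miRNA and miRNA–mRNA edges
    (one per shared miRNA) plus one circRNA–mRNA edge; nodes and edges are
    deduplicated.  Edge statistics are looked up from the pair lists; a
    triad id with no backing pair is a consistency error.
    """
    scc_lookup = {(p.a_id, p.b_id): p.value for p in scc_pairs}
    scc_lookup.update({(p.b_id, p.a_id): p.value for p in scc_pairs})
    pcc_lookup = {(p.a_id, p.b_id): p.value for p in pcc_pairs}
    pcc_lookup.update({(p.b_id, p.a_id): p.value for p in pcc_pairs})

    net = CeRNANetwork()
    g = net.graph
    for t in triads:
        if not t.retained:
            continue
        if (t.circ_id, t.mrna_id) not in pcc_lookup:
            raise InputError(
                f"triad ({t.circ_id}, {t.mrna_id}) has no backing PCC pair"
            )
        g.add_node(t.circ_id, node_type="circRNA")
        g.add_node(t.mrna_id, node_type="mRNA")
        g.add_edge(t.circ_id, t.mrna_id, edge_type="circRNA-mRNA",
                   statistic="PCC", value=pcc_lookup[(t.circ_id, t.mrna_id)],
                   p=t.p)
        for mir in sorted(t.shared_mirnas):
            g.add_node(mir, node_type="miRNA")
            g.add_edge(t.circ_id, mir, edge_type="circRNA-miRNA",
                       statistic="SCC",
                       value=scc_lookup.get((t.circ_id, mir), float("nan")))
            g.add_edge(mir, t.mrna_id, edge_type="miRNA-mRNA",
                       statistic="SCC",
                       value=scc_lookup.get((t.mrna_id, mir), float("nan")))
    return net


# ---------------------------------------------------------------- exports

_SIF_INTERACTION = {
    "circRNA-miRNA": "sponges",
    "miRNA-mRNA": "targets",
    "circRNA-mRNA": "ceRNA",
}


def write_sif(net: CeRNANetwork, path: str | Path) -> None:
    """Cytoscape SIF: source <tab> interaction <tab> target, sorted."""
    types = nx.get_node_attributes(net.graph, "node_type")
    lines = []
    for u, v, d in net.graph.edges(data=True):
        etype = d["edge_type"]
        # canonical orientation: the edge-type's first node type goes first
        if types[u] != etype.split("-")[0]:
            u, v = v, u
        lines.append(f"{u}\t{_SIF_INTERACTION[etype]}\t{v}")
    with open(path, "w") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                u, interaction, v = line.rstrip("\n").split("\t")
                edges.append((u, interaction, v))
    return edges


def write_graphml(net: CeRNANetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_node_attributes(net: CeRNANetwork, path: str | Path) -> None:
    rows = [
        {"id": n, "node_type": d["node_type"]}
        for n, d in sorted(net.graph.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["id", "node_type"]).to_csv(path, sep="\t",
                                                           index=False)


def write_edge_attributes(net: CeRNANetwork, path: str | Path) -> None:
    rows = []
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append(
            {"source": a, "target": b, "edge_type": d["edge_type"],
             "statistic": d["statistic"], "value": d["value"]}
        )
    rows.sort(key=lambda r: (r["source"], r["target"], r["edge_type"]))
    pd.DataFrame(rows, columns=["source", "target", "edge_type", "statistic",
                                "value"]).to_csv(path, sep="\t", index=False)


def network_pipeline(
    circ: ExpressionMatrix,
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    scc_threshold: float = SCC_THRESHOLD,
    pcc_threshold: float = PCC_THRESHOLD,
    alpha: float = SPONGE_ALPHA,
    max_zero_fraction: float = 0.5,
) -> tuple[CeRNANetwork, list[CeRNATriad], dict]:
    """End-to-end network construction from three expression matrices.

    The miRNA universe for the sponge test is the full filtered miRNA
    matrix (the maximal defensible universe when no annotation narrows it).
    """
    circ = filter_features(circ, max_zero_fraction)
    mirna = filter_features(mirna, max_zero_fraction)
    mrna = filter_features(mrna, max_zero_fraction)
    circ_mir = spearman_pairs(circ, mirna, scc_threshold, "circRNA", "miRNA")
    mrna_mir = spearman_pairs(mrna, mirna, scc_threshold, "mRNA", "miRNA")
    circ_mrna = pearson_pairs(circ, mrna, pcc_threshold, "circRNA", "mRNA")
    universe = set(mirna.features)
    triads = build_triads(circ_mir, mrna_mir, circ_mrna, universe, alpha)
    net = assemble_network(circ_mir + mrna_mir, circ_mrna, triads)
    return net, triads, net.composition()
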