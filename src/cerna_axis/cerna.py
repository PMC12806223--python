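"""Disease-specific ceRNA network construction and axis enumeration.

Starting from the reference network and the DE sets, the disease network
keeps only edges whose endpoints are both differentially expressed, then
applies the sponge-hypothesis filters: a miRNA--ceRNA edge whose two
endpoints move in the same direction is inconsistent with miRNA-mediated
repression and is removed (direction filter); optionally, edges must also
show negative expression correlation across samples (correlation filter,
off by default because correlation estimates are unstable in small
cohorts); finally, miRNAs left with partners in only one ceRNA class
cannot anchor a lncRNA--miRNA--mRNA axis and are pruned to a fixed point.
Surviving (lncRNA, miRNA, mRNA) triples with co-directional lncRNA and
mRNA are the candidate regulatory axes, ranked by a configurable
evidence-combination heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DESets, ExpressionMatrix
from .refnet import ReferenceNetwork

__all__ = [
    "NodeDE",
    "DiseaseNetwork",
    "CeRNAAxis",
    "subset_network",
    "direction_filter",
    "correlation_filter",
    "prune_mirnas",
    "enumerate_axes",
    "score_axes",
]


@dataclass(frozen=True)
class NodeDE:
    """DE annotation carried by every disease-network node."""

    node_class: str
    direction: str  # "up" or "down"
    log2fc: float
    p: float


@dataclass
class DiseaseNetwork:
    """Reference-network edges restricted to DE nodes, with annotations.

    Edge stores mirror :class:`~cerna_axis.refnet.ReferenceNetwork`
    (``(ceRNA, miRNA)`` keys mapping to source sets); ``nodes`` carries the
    per-node DE annotation and ``edge_corr`` optional per-edge correlation
    results ``(method, rho, rho_p)``.
    """

    lnc_mi: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    mi_m: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    nodes: dict[str, NodeDE] = field(default_factory=dict)
    edge_corr: dict[tuple[str, str], tuple[str, float, float]] = field(
        default_factory=dict
    )

    def copy(self) -> "DiseaseNetwork":
        return DiseaseNetwork(
            lnc_mi={e: set(s) for e, s in self.lnc_mi.items()},
            mi_m={e: set(s) for e, s in self.mi_m.items()},
            nodes=dict(self.nodes),
            edge_corr=dict(self.edge_corr),
        )

    @property
    def n_edges(self) -> int:
        return len(self.lnc_mi) + len(self.mi_m)

    def mirnas(self) -> set[str]:
        return {m for _, m in self.lnc_mi} | {m for m, _ in self.mi_m}

    def counts(self) -> dict[str, int]:
        classes = [nd.node_class for nd in self.nodes.values()]
        return {
            "n_lnc_mi_edges": len(self.lnc_mi),
            "n_mi_m_edges": len(self.mi_m),
            "n_lncRNA": classes.count("lncRNA"),
            "n_miRNA": classes.count("miRNA"),
            "n_mRNA": classes.count("mRNA"),
        }

    def _drop_orphans(self) -> None:
        used = {n for e in self.lnc_mi for n in e} | {n for e in self.mi_m for n in e}
        self.nodes = {n: nd for n, nd in self.nodes.items() if n in used}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), srcs in sorted(self.lnc_mi.items()):
            rows.append(("lnc_mi", a, b, len(srcs)))
        for (b, a), srcs in sorted(self.mi_m.items()):
            rows.append(("mi_m", a, b, len(srcs)))
        return pd.DataFrame(
            rows, columns=["edge_class", "cerna", "mirna", "support_count"]
        )

    def to_networkx(self):
        """Export as a networkx graph (for GraphML etc.)."""
        import networkx as nx

        g = nx.Graph()
        for n, nd in self.nodes.items():
            g.add_node(
                n,
                node_class=nd.node_class,
                direction=nd.direction,
                log2fc=nd.log2fc,
            )
        for (a, b), srcs in self.lnc_mi.items():
            g.add_edge(a, b, edge_class="lnc_mi", support=len(srcs))
        for (m, g2), srcs in self.mi_m.items():
            g.add_edge(m, g2, edge_class="mi_m", support=len(srcs))
        return g


def subset_network(ref: ReferenceNetwork, de_sets: DESets) -> DiseaseNetwork:
    """Keep exactly the reference edges whose both endpoints are DE.

    Nodes are annotated with class, direction, log2fc and p from the DE
    sets. An empty overlap is legitimate (a warning, not an error).
    """
    net = DiseaseNetwork()
    de = de_sets.direction
    for (lnc, mi), srcs in ref.lnc_mi.items():
        if lnc in de and mi in de:
            net.lnc_mi[(lnc, mi)] = set(srcs)
    for (mi, m), srcs in ref.mi_m.items():
        if mi in de and m in de:
            net.mi_m[(mi, m)] = set(srcs)
    for n in sorted(
        {x for e in net.lnc_mi for x in e} | {x for e in net.mi_m for x in e}
    ):
        net.nodes[n] = NodeDE(
            node_class=ref.node_class[n],
            direction=de_sets.direction[n],
            log2fc=de_sets.log2fc[n],
            p=de_sets.p[n],
        )
    if not net.lnc_mi and not net.mi_m:
        warnings.warn("DE sets and reference network do not overlap", stacklevel=2)
    return net


def direction_filter(net: DiseaseNetwork) -> DiseaseNetwork:
    """Remove direction-concordant miRNA--ceRNA edges.

    Under the sponge model the miRNA represses its targets, so in cases a
    miRNA and its ceRNA partner are expected to move in opposite
    directions; edges whose endpoints are both up or both down are
    removed. Applies to both lncRNA--miRNA and miRNA--mRNA edges.
    """
    out = net.copy()
    for n, nd in out.nodes.items():
        if nd.direction not in ("up", "down"):
            raise ValueError(f"node {n!r} lacks a DE direction")
    out.lnc_mi = {
        (lnc, mi): s
        for (lnc, mi), s in out.lnc_mi.items()
        if out.nodes[lnc].direction != out.nodes[mi].direction
    }
    out.mi_m = {
        (mi, m): s
        for (mi, m), s in out.mi_m.items()
        if out.nodes[mi].direction != out.nodes[m].direction
    }
    out._drop_orphans()
    return out


def _edge_rho(
    x: np.ndarray, y: np.ndarray, method: str
) -> tuple[float, float]:
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def correlation_filter(
    net: DiseaseNetwork,
    expr: ExpressionMatrix,
    method: str = "spearman",
    min_abs_rho: float = 0.3,
    corr_p: float = 0.05,
) -> DiseaseNetwork:
    """Optional stage: require negative miRNA--ceRNA expression correlation.

    A miRNA--ceRNA edge survives only if across *all* samples (cases plus
    controls) rho < 0 with ``|rho| >= min_abs_rho`` and ``rho_p < corr_p``.
    Edges with a constant expression vector (rho undefined) are dropped
    with a warning. The rho of every tested edge is recorded in
    ``edge_corr``. The complementary positive lncRNA--mRNA check is
    offered at axis enumeration, not here (lncRNA--mRNA pairs are not
    edges of this network).
    """
    if expr.counts.shape[1] < 4:
        raise ValueError("correlation filter needs >= 4 samples")
    out = net.copy()
    values = expr.counts

    def _keep(cerna: str, mirna: str, edge: tuple[str, str]) -> bool:
        for node in (cerna, mirna):
            if node not in values.index:
                raise ValueError(f"node {node!r} absent from expression matrix")
        x = values.loc[cerna].to_numpy(dtype=float)
        y = values.loc[mirna].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn(
                f"constant expression for edge {edge}; rho undefined, edge dropped",
                stacklevel=3,
            )
            return False
        rho, p = _edge_rho(x, y, method)
        out.edge_corr[edge] = (method, rho, p)
        return rho < 0 and abs(rho) >= min_abs_rho and p < corr_p

    out.lnc_mi = {
        (lnc, mi): s for (lnc, mi), s in out.lnc_mi.items() if _keep(lnc, mi, (lnc, mi))
    }
    out.mi_m = {
        (mi, m): s for (mi, m), s in out.mi_m.items() if _keep(m, mi, (mi, m))
    }
    out._drop_orphans()
    return out


def prune_mirnas(net: DiseaseNetwork) -> DiseaseNetwork:
    """Drop miRNAs lacking a partner in either ceRNA class, to a fixed point.

    A miRNA that interacts only with mRNAs or only with lncRNAs cannot sit
    at the center of an axis; it and its edges are removed. Removal can
    orphan ceRNA nodes, so the rule is iterated until stable and
    degree-zero nodes are dropped.
    """
    out = net.copy()
    while True:
        deg_lnc: dict[str, int] = {}
        deg_m: dict[str, int] = {}
        for _, mi in out.lnc_mi:
            deg_lnc[mi] = deg_lnc.get(mi, 0) + 1
        for mi, _ in out.mi_m:
            deg_m[mi] = deg_m.get(mi, 0) + 1
        bad = {
            mi
            for mi in set(deg_lnc) | set(deg_m)
            if deg_lnc.get(mi, 0) == 0 or deg_m.get(mi, 0) == 0
        }
        if not bad:
            break
        out.lnc_mi = {e: s for e, s in out.lnc_mi.items() if e[1] not in bad}
        out.mi_m = {e: s for e, s in out.mi_m.items() if e[0] not in bad}
    out._drop_orphans()
    return out


@dataclass
class CeRNAAxis:
    """An ordered lncRNA--miRNA--mRNA triple with its evidence fields."""

    lncrna: str
    mirna: str
    mrna: str
    lnc_support: int = 1
    m_support: int = 1
    lnc_log2fc: float = 0.0
    mi_log2fc: float = 0.0
    m_log2fc: float = 0.0
    lnc_mi_rho: float | None = None
    mi_m_rho: float | None = None
    n_risk_snps_lnc: int | None = None
    n_risk_snps_m: int | None = None
    score: float = 0.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


def enumerate_axes(
    net: DiseaseNetwork,
    expr: ExpressionMatrix | None = None,
    require_pos_corr: bool = False,
    method: str = "spearman",
    min_abs_rho: float = 0.3,
    corr_p: float = 0.05,
) -> list[CeRNAAxis]:
    """Emit every axis (lnc, mi, m) with both edges present and
    ``direction(lnc) == direction(mRNA)``, in lexicographic order.

    The axis count equals, over miRNAs, the product of lncRNA-degree and
    mRNA-degree restricted to direction-consistent pairs. With
    ``require_pos_corr=True`` (and an expression matrix) the optional
    lncRNA--mRNA positive-correlation check (rho > 0, same thresholds as
    the correlation filter) is applied per triple.
    """
    axes: list[CeRNAAxis] = []
    lnc_by_mi: dict[str, list[str]] = {}
    m_by_mi: dict[str, list[str]] = {}
    for lnc, mi in net.lnc_mi:
        lnc_by_mi.setdefault(mi, []).append(lnc)
    for mi, m in net.mi_m:
        m_by_mi.setdefault(mi, []).append(m)

    for mi in sorted(set(lnc_by_mi) & set(m_by_mi)):
        for lnc in sorted(lnc_by_mi[mi]):
            for m in sorted(m_by_mi[mi]):
                if net.nodes[lnc].direction != net.nodes[m].direction:
                    continue
                if require_pos_corr:
                    if expr is None:
                        raise ValueError(
                            "require_pos_corr needs an expression matrix"
                        )
                    x = expr.counts.loc[lnc].to_numpy(dtype=float)
                    y = expr.counts.loc[m].to_numpy(dtype=float)
                    if np.all(x == x[0]) or np.all(y == y[0]):
                        continue
                    rho, p = _edge_rho(x, y, method)
                    if not (rho > 0 and rho >= min_abs_rho and p < corr_p):
                        continue
                corr_lm = net.edge_corr.get((lnc, mi))
                corr_mm = net.edge_corr.get((mi, m))
                axes.append(
                    CeRNAAxis(
                        lncrna=lnc,
                        mirna=mi,
                        mrna=m,
                        lnc_support=len(net.lnc_mi[(lnc, mi)]),
                        m_support=len(net.mi_m[(mi, m)]),
                        lnc_log2fc=net.nodes[lnc].log2fc,
                        mi_log2fc=net.nodes[mi].log2fc,
                        m_log2fc=net.nodes[m].log2fc,
                        lnc_mi_rho=corr_lm[1] if corr_lm else None,
                        mi_m_rho=corr_mm[1] if corr_mm else None,
                    )
                )
    axes.sort(key=lambda a: a.key)
    return axes


def score_axes(
    axes: list[CeRNAAxis],
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    cap: float = 10.0,
) -> list[CeRNAAxis]:
    """Rank axes by a documented evidence-combination heuristic.

    score = w1 * mean(|log2fc| of the three members, each capped at
    ``cap``) + w2 * (lnc_support + m_support) + w3 * (n_risk_snps_lnc +
    n_risk_snps_m) + w4 * mean(|rho|) over whichever edge correlations
    were computed. Missing SNP counts and correlations contribute zero.
    This arithmetic is defined by this package (the underlying study
    selects axes by narrative criteria, not a formula); it is monotone in
    every evidence term. Ties break lexicographically on (lnc, mi, m).
    """
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    w1, w2, w3, w4 = weights
    scored = []
    for ax in axes:
        fc_term = np.mean(
            [
                min(abs(ax.lnc_log2fc), cap),
                min(abs(ax.mi_log2fc), cap),
                min(abs(ax.m_log2fc), cap),
            ]
        )
        support_term = ax.lnc_support + ax.m_support
        snp_term = (ax.n_risk_snps_lnc or 0) + (ax.n_risk_snps_m or 0)
        rhos = [abs(r) for r in (ax.lnc_mi_rho, ax.mi_m_rho) if r is not None]
        rho_term = float(np.mean(rhos)) if rhos else 0.0
        score = w1 * fc_term + w2 * support_term + w3 * snp_term + w4 * rho_term
        scored.append(replace(ax, score=float(score)))
    scored.sort(key=lambda a: (-a.score, a.key))
    return scored


def axes_to_frame(axes: list[CeRNAAxis]) -> pd.DataFrame:
    """Ranked axis table as written to ``axes_ranked.tsv``."""
    return pd.DataFrame(
        {
            "lncRNA": [a.lncrna for a in axes],
            "miRNA": [a.mirna for a in axes],
            "mRNA": [a.mrna for a in axes],
            "lnc_log2fc": [a.lnc_log2fc for a in axes],
            "mi_log2fc": [a.mi_log2fc for a in axes],
            "m_log2fc": [a.m_log2fc for a in axes],
            "lnc_support": [a.lnc_support for a in axes],
            "m_support": [a.m_support for a in axes],
            "lnc_mi_rho": [a.lnc_mi_rho for a in axes],
            "mi_m_rho": [a.mi_m_rho for a in axes],
            "n_risk_snps_lnc": [a.n_risk_snps_lnc for a in axes],
            "n_risk_snps_m": [a.n_risk_snps_m for a in axes],
            "score": [a.score for a in axes],
        }
    )
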