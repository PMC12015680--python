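"""lncRNA-mRNA co-expression screening, cis/trans labeling, network export.

The target map follows the two-filter definition: a pair is retained when
the Pearson correlation of expression across samples satisfies |r| > 0.6 and
p <= 0.01 (both configurable), and is labeled cis when the two genes are
additionally co-located within the genomic window, trans otherwise. The
correlation p-value is the two-sided Student-t transform
t = r * sqrt(df / (1 - r^2)).

Correlations are computed by default across all samples pooled over groups;
``scope="within_group"`` instead centers each gene within its groups first
(removing mean group differences) and reduces the t degrees of freedom
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import FpkmMatrix

PAIR_COLUMNS = ["lncrna_id", "gene_id", "r", "p_value", "sign", "relation"]


def _t_pvalue(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r, dtype=float)
    interior = np.abs(r) < 1.0
    t = np.abs(r[interior]) * np.sqrt(df / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(t, df)
    p[~interior] = 0.0  # |r| = 1
    return p


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-based p-value.

    Requires n >= 3 and both vectors non-constant; |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    p = float(_t_pvalue(np.array([r]), n - 2)[0])
    return r, p


def coexpressed_pairs(
    lnc_fpkm: FpkmMatrix,
    mrna_fpkm: FpkmMatrix,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    scope: str = "pooled",
    log_transform: bool = True,
) -> pd.DataFrame:
    """All lncRNA x mRNA pairs with |r| > r_threshold and p <= p_threshold.

    Correlations are computed on log2(FPKM+1) across the shared sample
    columns. Constant genes are skipped (their correlations are undefined).
    The returned table has the relation column unset ("").
    """
    if lnc_fpkm.samples != mrna_fpkm.samples:
        raise ValueError("lncRNA and mRNA matrices must share identically ordered samples")
    n = len(lnc_fpkm.samples)
    if n < 3:
        raise ValueError("need at least 3 shared samples")

    def prepare(fm: FpkmMatrix) -> tuple[np.ndarray, list[str]]:
        x = fm.fpkm.to_numpy(dtype=float)
        if log_transform:
            x = np.log2(x + 1.0)
        if scope == "within_group":
            for grp in fm.design.unique():
                cols = np.array([fm.design[s] == grp for s in fm.samples])
                x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True)
        elif scope == "pooled":
            x = x - x.mean(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        norms = np.sqrt((x**2).sum(axis=1))
        ok = norms > 0
        x = x[ok] / norms[ok][:, None]
        return x, [g for g, keep in zip(fm.genes, ok) if keep]

    xl, lnc_ids = prepare(lnc_fpkm)
    xm, mrna_ids = prepare(mrna_fpkm)
    df_resid = n - 2 if scope == "pooled" else n - 2 - (lnc_fpkm.design.nunique() - 1)
    if df_resid < 1:
        raise ValueError("too few samples for within-group correlation")

    rows = []
    if len(lnc_ids) and len(mrna_ids):
        rmat = xl @ xm.T
        hits = np.argwhere(np.abs(rmat) > r_threshold)
        if hits.size:
            rvals = rmat[hits[:, 0], hits[:, 1]]
            pvals = _t_pvalue(rvals, df_resid)
            keep = pvals <= p_threshold
            for (i, j), r, p in zip(hits[keep], rvals[keep], pvals[keep]):
                rows.append(
                    (lnc_ids[i], mrna_ids[j], float(r), float(p),
                     "positive" if r > 0 else "negative", "")
                )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return out.sort_values(["lncrna_id", "gene_id"], ignore_index=True)


def label_cis_trans(pairs: pd.DataFrame, colocated: set[tuple[str, str]]) -> pd.DataFrame:
    """relation = cis iff (lncrna_id, gene_id) is in the co-location set."""
    out = pairs.copy()
    out["relation"] = [
        "cis" if (l, g) in colocated else "trans"
        for l, g in zip(out["lncrna_id"], out["gene_id"])
    ]
    return out


@dataclass(frozen=True)
class NetworkSummary:
    """Pair/node counts of the target map, stratified by correlation sign."""

    all_pairs: int
    all_lncrna: int
    all_gene: int
    positive_pairs: int
    positive_lncrna: int
    positive_gene: int
    negative_pairs: int
    negative_lncrna: int
    negative_gene: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("all_pairs", self.all_pairs),
            ("all_lncRNA", self.all_lncrna),
            ("all_gene", self.all_gene),
            ("Positive_correlation_pairs", self.positive_pairs),
            ("Positive_correlation_lncRNA", self.positive_lncrna),
            ("Positive_correlation_gene", self.positive_gene),
            ("negative_correlation_pairs", self.negative_pairs),
            ("negative_correlation_lncRNA", self.negative_lncrna),
            ("negative_correlation_gene", self.negative_gene),
        ]
        return pd.DataFrame(rows, columns=["type", "number"])


def network_summary(pairs: pd.DataFrame) -> NetworkSummary:
    pos = pairs[pairs["sign"] == "positive"]
    neg = pairs[pairs["sign"] == "negative"]
    return NetworkSummary(
        all_pairs=len(pairs),
        all_lncrna=pairs["lncrna_id"].nunique(),
        all_gene=pairs["gene_id"].nunique(),
        positive_pairs=len(pos),
        positive_lncrna=pos["lncrna_id"].nunique(),
        positive_gene=pos["gene_id"].nunique(),
        negative_pairs=len(neg),
        negative_lncrna=neg["lncrna_id"].nunique(),
        negative_gene=neg["gene_id"].nunique(),
    )


def build_network(
    pairs: pd.DataFrame,
    de_direction: dict[str, dict[str, str]] | None = None,
) -> nx.Graph:
    """Undirected lncRNA-gene graph with sorted, deterministic ordering.

    Node attributes: role (lncRNA/gene) and, if ``de_direction`` maps
    contrast -> gene -> direction, one attribute per contrast. Edge
    attributes: r, sign, relation.
    """
    g = nx.Graph()
    lnc_nodes = sorted(set(pairs["lncrna_id"]))
    gene_nodes = sorted(set(pairs["gene_id"]))
    for node in lnc_nodes:
        g.add_node(node, role="lncRNA")
    for node in gene_nodes:
        g.add_node(node, role="gene")
    if de_direction:
        for contrast in sorted(de_direction):
            for node in g.nodes:
                g.nodes[node][f"direction_{contrast}"] = de_direction[contrast].get(node, "none")
    ordered = pairs.sort_values(["lncrna_id", "gene_id"])
    for row in ordered.itertuples(index=False):
        g.add_edge(row.lncrna_id, row.gene_id,
                   r=float(row.r), sign=row.sign, relation=row.relation)
    return g


def export_network(
    pairs: pd.DataFrame,
    graphml_path,
    sif_path,
    de_direction: dict[str, dict[str, str]] | None = None,
) -> nx.Graph:
    """Write the pair graph as GraphML and SIF; byte-identical on re-export."""
    g = build_network(pairs, de_direction)
    nx.write_graphml(g, graphml_path)
    ordered = pairs.sort_values(["lncrna_id", "gene_id"])
    with open(sif_path, "w") as fh:
        for row in ordered.itertuples(index=False):
            fh.write(f"{row.lncrna_id}\t{row.relation}\t{row.gene_id}\n")
    return g
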