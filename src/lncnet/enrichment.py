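"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

Gene sets come from GMT text; the test is the upper tail P(X >= k) for
X ~ Hypergeometric(N, K, n), i.e. over-representation only, with BH applied
across all reported terms.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy import stats

ENRICHMENT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr", "genes"]


class GmtParseError(ValueError):
    pass


def parse_gmt(text: str) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT lines (term_id TAB description TAB gene...) -> {term_id: (name, genes)}.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is a parse error naming the line number.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(f"line {lineno}: expected >= 3 tab-separated fields")
        term_id, name, *genes = fields
        members = frozenset(g for g in genes if g)
        if members:
            terms[term_id] = (name, members)
    return terms


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min over j >= i of (m * p_(j) / j), clipped at 1, where p_(j)
    is the j-th smallest p-value of m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def hypergeom_enrich(
    query: set[str],
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    universe: set[str],
    drop_empty: bool = False,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of the query against each gene set.

    Terms are intersected with the universe before testing; the query must
    be a subset of the universe. Terms with no query overlap are reported
    with p = 1 unless ``drop_empty``. BH FDR is computed across all reported
    terms; the result is sorted by (p_value, term_id).
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:10]}")
    n_universe = len(universe)
    n_query = len(query)

    rows = []
    for term_id in sorted(gene_sets):
        name, members = gene_sets[term_id]
        in_universe = members & universe
        big_k = len(in_universe)
        if big_k < min_term_size:
            continue
        hit = sorted(query & in_universe)
        k = len(hit)
        if k == 0 and drop_empty:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query)) if k > 0 else 1.0
        rows.append((term_id, name, k, big_k, n_query, n_universe, min(1.0, p), np.nan, ",".join(hit)))

    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term_id"], ignore_index=True)
    return out
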