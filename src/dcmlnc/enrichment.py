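"""Hypergeometric term enrichment with kappa-score term grouping.

Terms come from user-supplied two-column (term_id, gene_id) maps —
GO/KEGG-style annotations at whatever version the user trusts.  Each term
is tested by the exact hypergeometric upper tail P(X >= k) for drawing k
term genes in a DE set of size n from a universe of N genes of which K
carry the term, with BH correction across tested terms.  Significant
terms are then grouped by single-linkage connected components of the
term-term Cohen's kappa graph (edges where kappa exceeds the threshold),
each group represented by its most significant member.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class TermGroup:
    group_id: int
    members: tuple
    representative: str


def hypergeom_enrich(
    de_genes,
    universe,
    terms: dict,
    term_names: dict | None = None,
) -> pd.DataFrame:
    """Enrichment table for every term hitting the DE set at least once.

    ``terms`` maps term_id -> iterable of gene ids; term gene sets are
    intersected with the universe before testing.  Columns: term_id,
    term_name, k, K, n, N, p, q; sorted by p then term_id.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe or not de:
        raise ValueError("universe and de_genes must be nonempty")
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    N, n = len(universe), len(de)
    rows = []
    for term_id in sorted(terms):
        genes = set(terms[term_id]) & universe
        k = len(genes & de)
        if k == 0:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, p))
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q"])
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "p"])
    out["n"] = n
    out["N"] = N
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["term_name"] = out["term_id"].map(term_names or {}).fillna(out["term_id"])
    out = out[["term_id", "term_name", "k", "K", "n", "N", "p", "q"]]
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


def kappa_score(term_a, term_b, universe) -> float:
    """Cohen's kappa of the two terms' gene-membership indicators.

    Degenerate case pe = 1 (both sets empty or both equal to the whole
    universe): kappa is 1 for identical sets, else 0.
    """
    universe = set(universe)
    a = set(term_a) & universe
    b = set(term_b) & universe
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    po = (both + neither) / n
    p_yes = (len(a) / n) * (len(b) / n)
    p_no = ((n - len(a)) / n) * ((n - len(b)) / n)
    pe = p_yes + p_no
    if pe == 1.0:
        return 1.0 if a == b else 0.0
    return (po - pe) / (1 - pe)


def group_terms(
    results: pd.DataFrame,
    terms: dict,
    universe,
    q_cut: float = 0.05,
    kappa_threshold: float = 0.03,
) -> list:
    """Single-linkage kappa grouping of significant terms.

    Builds a graph over terms with q <= q_cut, connecting pairs whose
    kappa exceeds ``kappa_threshold``; groups are connected components,
    represented by the member with smallest p (ties by term_id).  Group
    ids are assigned in order of the representatives' significance.
    """
    sig = results[results["q"] <= q_cut]
    if sig.empty:
        return []
    ids = list(sig["term_id"])
    pmap = dict(zip(sig["term_id"], sig["p"]))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, ta in enumerate(ids):
        for tb in ids[i + 1 :]:
            if kappa_score(terms[ta], terms[tb], universe) > kappa_threshold:
                g.add_edge(ta, tb)
    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda t: (pmap[t], t))
        groups.append((rep, members))
    groups.sort(key=lambda rm: (pmap[rm[0]], rm[0]))
    return [TermGroup(i, members, rep) for i, (rep, members) in enumerate(groups)]


def read_term_map(path) -> dict:
    """Two-column TSV (term_id <TAB> gene_id) -> {term_id: set of genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], comment="#")
    if df.columns.size != 2 or df.empty:
        raise ValueError("term map must be a nonempty two-column TSV")
    if (df["term_id"] == "term_id").any():  # tolerate a header line
        df = df[df["term_id"] != "term_id"]
    return {t: set(sub["gene_id"]) for t, sub in df.groupby("term_id")}


def write_term_map(terms: pd.DataFrame, path) -> None:
    terms.to_csv(path, sep="\t", index=False, header=False)
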