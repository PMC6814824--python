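"""Bipartite lncRNA-mRNA co-expression network and hub discovery.

Every DE lncRNA x DE mRNA pair is scored by the sample Pearson
correlation over the chosen sample scope (default: the eight samples of
the relevant age, both genotypes); pairs with |r| above ``r_threshold``
(default 0.995) and two-sided p below ``p_threshold`` (default 0.05)
become signed edges.  Hub lncRNAs are the top-degree nodes, ties broken
by summed |r| then id — the field's "maximum connections with mRNAs"
criterion made deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

EDGE_COLUMNS = ["lnc_id", "mrna_id", "r", "p", "sign"]


@dataclass
class HubReport:
    """Degree ranking of lncRNA nodes and the selected top-k hubs."""

    ranking: pd.DataFrame  # lnc_id, degree, sum_abs_r
    hubs: list
    k: int
    short: bool  # fewer lncRNA nodes than requested


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p via the t transform t = r sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(t, df=n - 2))


def pearson_with_p(x, y):
    """Sample Pearson r and two-sided p; None for a zero-variance vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must share length n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, pearson_p_from_r(r, x.size)


def _select_samples(metadata: pd.DataFrame, sample_scope: str, age) -> list:
    if sample_scope == "all_samples":
        return list(metadata.index)
    if sample_scope == "age_specific":
        if age is None:
            raise ValueError("age_specific scope requires an age")
        return list(metadata.index[metadata["age"] == age])
    raise ValueError(f"unknown sample_scope {sample_scope!r}")


def build_network(
    norm,
    de_lnc,
    de_mrna,
    metadata: pd.DataFrame | None = None,
    sample_scope: str = "age_specific",
    age=None,
    r_threshold: float = 0.995,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """All lncRNA x mRNA pairs with |r| > r_threshold and p < p_threshold.

    Returns an edge table ``lnc_id, mrna_id, r, p, sign`` ordered by
    (lnc_id, mrna_id).  Zero-variance probes yield no edges.  An empty
    result is a valid (empty) network.  With no metadata the correlation
    runs over every sample column; otherwise ``sample_scope`` picks either
    the age-matched groups (default) or all samples.
    """
    lnc_ids = sorted(set(de_lnc) & set(norm.values.index))
    mrna_ids = sorted(set(de_mrna) & set(norm.values.index))
    if not set(de_lnc) or not set(de_mrna):
        raise ValueError("both DE sets must be nonempty")
    if not lnc_ids or not mrna_ids:
        raise ValueError("DE sets are absent from the matrix")
    if metadata is None:
        cols = list(norm.values.columns)
    else:
        cols = _select_samples(metadata, sample_scope, age)
    n = len(cols)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    xl = norm.values.loc[lnc_ids, cols].to_numpy()
    xm = norm.values.loc[mrna_ids, cols].to_numpy()

    def _standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = np.zeros_like(x)
        z[ok] = (x[ok] - mu[ok]) / sd[ok]
        return z, ok

    zl, okl = _standardize(xl)
    zm, okm = _standardize(xm)
    r = zl @ zm.T / n
    r = np.clip(r, -1.0, 1.0)
    r[~okl, :] = 0.0
    r[:, ~okm] = 0.0

    hit = np.abs(r) > r_threshold
    rows = []
    for i, j in zip(*np.nonzero(hit)):
        rij = float(r[i, j])
        p = pearson_p_from_r(rij, n)
        if p < p_threshold:
            rows.append((lnc_ids[i], mrna_ids[j], rij, p, "positive" if rij > 0 else "negative"))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["lnc_id", "mrna_id"], kind="stable").reset_index(drop=True)


def rank_hubs(edges: pd.DataFrame, k: int = 5) -> HubReport:
    """Rank lncRNA nodes by degree desc, summed |r| desc, id asc; take top k."""
    if edges.empty:
        ranking = pd.DataFrame(columns=["lnc_id", "degree", "sum_abs_r"])
        return HubReport(ranking, [], k, short=k > 0)
    grp = edges.groupby("lnc_id", sort=False)
    ranking = pd.DataFrame(
        {
            "lnc_id": list(grp.groups),
            "degree": grp.size().to_numpy(),
            "sum_abs_r": grp["r"].apply(lambda s: float(np.abs(s).sum())).to_numpy(),
        }
    ).sort_values(
        ["degree", "sum_abs_r", "lnc_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    hubs = list(ranking["lnc_id"].head(k))
    return HubReport(ranking, hubs, k, short=len(hubs) < k)


def extract_subnetwork(
    edges: pd.DataFrame,
    hubs: HubReport,
    directions: dict | None = None,
) -> nx.Graph:
    """Induced bipartite subgraph on the selected hubs and their partners.

    ``directions`` maps probe id -> up/down from the DE stage and is
    attached as a node attribute when given.
    """
    g = nx.Graph()
    sub = edges[edges["lnc_id"].isin(hubs.hubs)]
    for _, e in sub.iterrows():
        g.add_node(e.lnc_id, kind="lncRNA")
        g.add_node(e.mrna_id, kind="mRNA")
        g.add_edge(e.lnc_id, e.mrna_id, r=float(e.r), p=float(e.p), sign=e.sign)
    for h in hubs.hubs:
        if h not in g:
            g.add_node(h, kind="lncRNA")
    if directions:
        for node in g.nodes:
            if node in directions:
                g.nodes[node]["direction"] = directions[node]
    for node, deg in g.degree:
        g.nodes[node]["degree"] = deg
    return g


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path) -> None:
    """Simple interaction format: `lnc pos|neg mrna` per line."""
    with open(path, "w") as fh:
        for _, e in edges.iterrows():
            rel = "pos" if e.sign == "positive" else "neg"
            fh.write(f"{e.lnc_id}\t{rel}\t{e.mrna_id}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
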