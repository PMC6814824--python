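"""Per-contrast differential expression with volcano-style filtering.

A probe is called deregulated in a genotype contrast at one age when its
linear fold change between group means of log2 intensity is at least
``fc_threshold`` (default 2) and the two-group test p-value is below
``p_threshold`` (default 0.05).  Welch's t is the default test; Student's
t and the exact Mann-Whitney rank-sum (exact null at the 4-vs-4 design
sizes) are available.  Benjamini-Hochberg q-values are always reported
and can optionally gate the calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

TEST_METHODS = ("welch_t", "student_t", "mann_whitney")


@dataclass
class DEGSets:
    """Up/down probe-id sets for one contrast."""

    up: set
    down: set

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a probe cannot be both up and down in one contrast")

    @property
    def all(self) -> set:
        return self.up | self.down

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DEGSets":
        return cls(
            up=set(table.loc[table["direction"] == "up", "probe_id"]),
            down=set(table.loc[table["direction"] == "down", "probe_id"]),
        )


def test_two_groups(values_a, values_b, method: str = "welch_t") -> float:
    """Two-sided p-value comparing two expression vectors.

    Zero variance in both groups with equal means yields p = 1 (no
    evidence of difference by convention).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if method not in TEST_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "mann_whitney":
        mw_method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method).pvalue)
    p = stats.ttest_ind(a, b, equal_var=(method == "student_t")).pvalue
    return float(p) if np.isfinite(p) else 1.0


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(metadata: pd.DataFrame, genotype: str, age) -> list:
    mask = (metadata["genotype"] == genotype) & (metadata["age"] == age)
    return list(metadata.index[mask])


def differential_expression(
    norm,
    metadata: pd.DataFrame,
    contrast: tuple,
    method: str = "welch_t",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    q_threshold: float | None = None,
) -> pd.DataFrame:
    """One record per probe for the contrast (genotype_a, genotype_b, age).

    log2fc = mean_b - mean_a of log2 normalized intensities; fc_linear =
    2^|log2fc|.  ``significant`` requires fc_linear >= fc_threshold and
    p < p_threshold (and q <= q_threshold when given); direction is up
    (b over a) or down for significant probes, else none.  Sorted by p
    then probe_id.
    """
    genotype_a, genotype_b, age = contrast
    cols_a = _group_columns(metadata, genotype_a, age)
    cols_b = _group_columns(metadata, genotype_b, age)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"contrast {contrast} has a group with < 2 samples")
    values = norm.values
    xa = values[cols_a].to_numpy()
    xb = values[cols_b].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log2fc = mean_b - mean_a

    with warnings.catch_warnings():
        # quantile normalization maps equal ranks to equal values, so some
        # rows are near-constant; scipy warns about the resulting precision
        # loss and returns nan, which is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "welch_t":
            p = stats.ttest_ind(xa, xb, axis=1, equal_var=False).pvalue
        elif method == "student_t":
            p = stats.ttest_ind(xa, xb, axis=1, equal_var=True).pvalue
        elif method == "mann_whitney":
            mw_method = "exact" if max(xa.shape[1], xb.shape[1]) <= 8 else "asymptotic"
            p = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided", method=mw_method).pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    # degenerate rows (zero variance in both groups): p = 1 when means equal
    p = np.asarray(p, dtype=float)
    degen = ~np.isfinite(p)
    p[degen & (log2fc == 0)] = 1.0
    p[degen & (log2fc != 0)] = 0.0

    q = bh_adjust(p)
    fc_linear = np.exp2(np.abs(log2fc))
    significant = (fc_linear >= fc_threshold) & (p < p_threshold)
    if q_threshold is not None:
        significant &= q <= q_threshold
    direction = np.where(significant & (log2fc > 0), "up", np.where(significant & (log2fc < 0), "down", "none"))

    table = pd.DataFrame(
        {
            "probe_id": values.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "fc_linear": fc_linear,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
        }
    )
    return table.sort_values(["p", "probe_id"], kind="stable").reset_index(drop=True)


def overlap_sets(contrast_a: DEGSets, contrast_b: DEGSets) -> dict:
    """Overlap report between the DE sets of two contrasts.

    ``multiplicity_total`` counts the union with multiplicity (|A| + |B|),
    the convention used when adding per-age deregulated-transcript counts
    into a combined total.
    """
    a, b = contrast_a.all, contrast_b.all
    return {
        "size_a": len(a),
        "size_b": len(b),
        "intersection": len(a & b),
        "a_only": len(a - b),
        "b_only": len(b - a),
        "union": len(a | b),
        "multiplicity_total": len(a) + len(b),
    }


def hierarchical_order(
    norm,
    subset,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[list, np.ndarray]:
    """Agglomerative clustering of probes for heatmap row ordering.

    Rows are pre-sorted by probe_id so the leaf order is invariant to the
    input row permutation.  Under the correlation metric, zero-variance
    probes get distance 1 to everything.  Returns (leaf probe ids, scipy
    linkage matrix).
    """
    ids = sorted(subset)
    if len(ids) < 2:
        raise ValueError("need at least 2 probes to cluster")
    x = norm.values.loc[ids].to_numpy()
    if metric == "euclidean":
        d = pdist(x, metric="euclidean")
    elif metric == "correlation":
        sd = x.std(axis=1)
        ok = sd > 0
        r = np.zeros((len(ids), len(ids)))
        if ok.sum() >= 2:
            r_ok = np.corrcoef(x[ok])
            r[np.ix_(ok, ok)] = r_ok
        np.fill_diagonal(r, 1.0)
        d = squareform(1.0 - r, checks=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(z)
    return [ids[i] for i in leaves], z
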