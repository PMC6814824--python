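"""Detection-flag filtering and quantile normalization.

Single-channel arrays report a Present/Marginal/Absent detection call per
probe per sample; probes reliably detected in at least ``min_detected``
samples are retained.  Intensities are put on log2 scale (pseudocount 1)
and quantile-normalized with the classic rank/mean algorithm: replace the
k-th order statistic of every column by the mean k-th order statistic
across columns, ties within a column receiving the mean of the reference
values over the tied ranks.  Both pipeline orders (normalize-then-filter,
the default, and filter-then-normalize) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import ExpressionStudy

PSEUDOCOUNT = 1.0
DETECTED_FLAGS = frozenset({"P", "M"})


@dataclass
class NormalizedMatrix:
    """Probe-by-sample matrix of log2 quantile-normalized intensities."""

    values: pd.DataFrame

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def subset(self, probe_ids) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values.loc[list(probe_ids)])


def filter_by_flags(study: ExpressionStudy, min_detected: int = 4) -> ExpressionStudy:
    """Keep probes flagged Present or Marginal in >= min_detected samples."""
    n_samples = len(study.sample_ids)
    if min_detected > n_samples:
        raise ValueError(f"min_detected={min_detected} exceeds the {n_samples} samples")
    detected = study.flags.isin(DETECTED_FLAGS).sum(axis=1)
    keep = study.flags.index[detected >= min_detected]
    return study.subset_probes(keep)


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Rank/mean quantile normalization of a probes x samples array.

    Reference distribution = mean of the per-column order statistics;
    within-column ties are assigned the mean reference value over the
    tied ranks so that ties stay ties.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty matrix")
    n, m = values.shape
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # average reference values over tied ranks
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                mapped[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return out


def quantile_normalize(study: ExpressionStudy, pseudocount: float = PSEUDOCOUNT) -> NormalizedMatrix:
    """log2(intensity + pseudocount), then rank/mean quantile normalization."""
    if len(study.sample_ids) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    log2 = np.log2(study.intensities.to_numpy() + pseudocount)
    normed = quantile_normalize_values(log2)
    return NormalizedMatrix(
        pd.DataFrame(normed, index=study.intensities.index, columns=study.intensities.columns)
    )


def run_preprocessing(
    study: ExpressionStudy,
    min_detected: int = 4,
    order: str = "normalize_first",
) -> tuple[NormalizedMatrix, ExpressionStudy]:
    """Run the flag filter and quantile normalization in the chosen order.

    ``normalize_first`` (default) normalizes the full matrix and then drops
    undetected probes; ``filter_first`` normalizes only the retained
    probes.  Returns the normalized matrix restricted to retained probes
    and the filtered study.
    """
    if order not in ("normalize_first", "filter_first"):
        raise ValueError(f"unknown order {order!r}")
    if order == "normalize_first":
        norm = quantile_normalize(study)
        filtered = filter_by_flags(study, min_detected)
        return norm.subset(filtered.probe_ids), filtered
    filtered = filter_by_flags(study, min_detected)
    return quantile_normalize(filtered), filtered
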