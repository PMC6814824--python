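"""Relative quantification by the ddCt method and array concordance.

Each target gene's Ct is normalized within-sample to a reference gene
(the small nuclear RNA Rnu-6 in the cardiac lncRNA setting):
dCt = Ct_target - Ct_ref; dCt is then referenced to the calibrator
group's mean dCt, and RQ = 2^-ddCt under the classic assumption of
amplification efficiency 2.  The calibrator group's geometric-mean RQ is
1 by construction.  Concordance checks whether the qPCR direction
(log2 of the non-calibrator group's mean RQ) matches the array fold
change direction gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CtTable:
    """Long-format Ct measurements with reference gene and calibrator group.

    ``data`` columns: sample_id, group, gene_id, ct.  Every (sample, gene)
    pair must be unique, Ct finite and positive, and the reference gene
    measured in every sample.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_group: str

    def __post_init__(self) -> None:
        d = self.data
        required = {"sample_id", "group", "gene_id", "ct"}
        if not required <= set(d.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        if d.duplicated(["sample_id", "gene_id"]).any():
            raise ValueError("duplicate (sample, gene) Ct measurements")
        ct = d["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        samples = set(d["sample_id"])
        ref_samples = set(d.loc[d["gene_id"] == self.reference_gene, "sample_id"])
        missing = samples - ref_samples
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene} missing in samples: {sorted(missing)}"
            )
        if self.calibrator_group not in set(d["group"]):
            raise ValueError(f"calibrator group {self.calibrator_group!r} is empty")


def delta_delta_ct(table: CtTable, target: str) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample RQ for one target plus geometric group-mean RQ.

    Returns (per-sample frame with columns sample_id, group, delta_ct,
    delta_delta_ct, rq; group series of geometric-mean RQ).  The
    calibrator group's mean RQ is exactly 1.
    """
    d = table.data
    tgt = d[d["gene_id"] == target].set_index("sample_id")
    ref = d[d["gene_id"] == table.reference_gene].set_index("sample_id")
    missing = set(d["sample_id"]) - set(tgt.index)
    if missing:
        raise ValueError(f"target {target} not measured in samples: {sorted(missing)}")
    dct = tgt["ct"] - ref.loc[tgt.index, "ct"]
    cal_mask = tgt["group"] == table.calibrator_group
    ddct = dct - dct[cal_mask].mean()
    rq = np.exp2(-ddct)
    per_sample = pd.DataFrame(
        {
            "sample_id": tgt.index,
            "group": tgt["group"].to_numpy(),
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "rq": rq.to_numpy(),
        }
    ).reset_index(drop=True)
    group_rq = per_sample.groupby("group")["rq"].apply(
        lambda s: float(np.exp2(np.log2(s).mean()))
    )
    return per_sample, group_rq


def concordance(
    array_fc: pd.DataFrame,
    qpcr_rq: dict,
    genes,
    test_group: str,
) -> tuple[float, pd.DataFrame, list]:
    """Fraction of genes whose qPCR and array directions agree.

    ``array_fc`` is a differential_expression table; ``qpcr_rq`` maps
    gene -> group RQ series from :func:`delta_delta_ct`; the comparison
    is sign(log2fc) vs sign(log2 RQ[test_group]).  Genes missing from
    either input are excluded and returned in the third element.
    """
    fc = array_fc.set_index("probe_id")["log2fc"]
    rows, excluded = [], []
    for g in sorted(genes):
        if g not in fc.index or g not in qpcr_rq or test_group not in qpcr_rq[g].index:
            excluded.append(g)
            continue
        a = float(fc[g])
        q = float(np.log2(qpcr_rq[g][test_group]))
        rows.append((g, a, q, bool(np.sign(a) == np.sign(q))))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "array_log2fc", "qpcr_log2rq", "match"])
    frac = float(per_gene["match"].mean()) if len(per_gene) else float("nan")
    return frac, per_gene, excluded


def read_ct_table(path, reference_gene: str, calibrator_group: str) -> CtTable:
    data = pd.read_csv(path, sep="\t")
    return CtTable(data, reference_gene, calibrator_group)
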