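"""Positional classification of lncRNAs relative to protein-coding genes.

Long noncoding RNAs are conventionally binned by their genomic relationship
to the nearest protein-coding gene: *sense-overlapping* (exonic overlap on
the same strand), *antisense* (exonic overlap on the opposite strand),
*intronic* (wholly contained in an intron), *bidirectional* (divergently
transcribed from a promoter within a short window of a coding gene's TSS)
and *intergenic* (none of the above).  This module implements that
taxonomy as a total function with a fixed precedence order, plus
per-chromosome and per-class tabulations of differentially expressed
lncRNA sets.

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED (0-based half-open) conventions are converted at the format
boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

LNC_CLASSES = (
    "intergenic",
    "bidirectional",
    "intronic",
    "antisense",
    "sense_overlapping",
)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclass
class GeneAnnotation:
    """Genomic intervals for coding genes and lncRNAs.

    ``genes`` has one row per gene (columns ``gene_id, chrom, start, end,
    strand, biotype`` with biotype in {"coding", "lncRNA"}); ``exons`` has
    one row per exon of a coding gene.  lncRNAs are modelled as
    single-exon transcripts spanning their gene interval.  Coordinates are
    0-based half-open.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.exons = self.exons.reset_index(drop=True)
        missing = set(GENE_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"genes frame missing columns: {sorted(missing)}")
        if (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene intervals must satisfy start < end")

    @property
    def coding(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "coding"]

    @property
    def lncrna(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "lncRNA"]

    def chrom_of(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["chrom"]))


@dataclass(frozen=True)
class LncClass:
    """Positional class assignment for one lncRNA."""

    lnc_id: str
    lnc_class: str
    partner_gene: str | None

    def __post_init__(self) -> None:
        if self.lnc_class not in LNC_CLASSES:
            raise ValueError(f"unknown class {self.lnc_class!r}")
        if (self.partner_gene is None) != (self.lnc_class == "intergenic"):
            raise ValueError("partner_gene present iff class != intergenic")


@dataclass
class ChromDistribution:
    """Per-chromosome up/down counts of a DE set, with percentages."""

    table: pd.DataFrame  # chrom, up, down, total, percent
    modal_chrom: str | None
    n_excluded: int

    @property
    def total(self) -> int:
        return int(self.table["total"].sum())


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _overlaps(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return (starts < end) & (start < ends)


def _interval_distance(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Gap between [start, end) and each [starts_i, ends_i); 0 if they touch/overlap."""
    left = starts - end  # positive when gene right of lnc
    right = start - ends  # positive when gene left of lnc
    return np.maximum(np.maximum(left, right), 0)


def _pick_partner(cand: pd.DataFrame, dist: np.ndarray) -> str:
    """Nearest candidate gene; ties broken by smaller gene_id."""
    order = sorted(range(len(cand)), key=lambda i: (dist[i], cand["gene_id"].iat[i]))
    return cand["gene_id"].iat[order[0]]


def classify_lncrna(
    lnc: pd.Series,
    coding: GeneAnnotation,
    bidirectional_window: int = 1000,
) -> LncClass:
    """Assign a positional class to one lncRNA interval.

    Precedence: exonic overlap same strand -> sense_overlapping; exonic
    overlap opposite strand -> antisense; wholly inside one intron (either
    strand) -> intronic; no gene overlap but divergently oriented TSS
    within ``bidirectional_window`` bp of a coding TSS -> bidirectional;
    otherwise intergenic.  The partner gene is the nearest qualifying
    coding gene, ties resolved by the lexicographically smaller gene id.
    """
    lnc_id = lnc["gene_id"]
    chrom, start, end, strand = lnc["chrom"], int(lnc["start"]), int(lnc["end"]), lnc["strand"]
    genes = coding.coding
    genes_c = genes[genes["chrom"] == chrom]
    if genes_c.empty:
        warnings.warn(
            f"lncRNA {lnc_id}: chromosome {chrom} absent from coding annotation; "
            "classified intergenic",
            stacklevel=2,
        )
        return LncClass(lnc_id, "intergenic", None)

    exons_c = coding.exons[coding.exons["chrom"] == chrom]
    ex_starts = exons_c["start"].to_numpy()
    ex_ends = exons_c["end"].to_numpy()
    ex_hit = _overlaps(start, end, ex_starts, ex_ends)

    # 1-2: exonic overlap, split by strand
    if ex_hit.any():
        hit = exons_c[ex_hit]
        same = hit[hit["strand"] == strand]
        pool = same if not same.empty else hit
        dist = np.zeros(len(pool))
        partner = _pick_partner(pool, dist)
        cls = "sense_overlapping" if not same.empty else "antisense"
        return LncClass(lnc_id, cls, partner)

    # 3: wholly inside an intron of a coding gene (either strand)
    g_starts = genes_c["start"].to_numpy()
    g_ends = genes_c["end"].to_numpy()
    inside = (g_starts <= start) & (end <= g_ends)
    if inside.any():
        # no exon overlap (checked above) and within the gene body ==> intronic;
        # gene-level containment plus exon disjointness implies containment in
        # one intron for well-formed annotations (exons flank every intron)
        hosts = genes_c[inside]
        dist = np.zeros(len(hosts))
        return LncClass(lnc_id, "intronic", _pick_partner(hosts, dist))

    g_hit = _overlaps(start, end, g_starts, g_ends)
    if not g_hit.any():
        # 4: divergent promoter pairing
        opp = genes_c[genes_c["strand"] != strand]
        if not opp.empty and strand in ("+", "-"):
            lnc_tss = start if strand == "+" else end - 1
            g_tss = np.where(opp["strand"] == "+", opp["start"], opp["end"] - 1)
            tss_dist = np.abs(g_tss - lnc_tss)
            # divergent: the pair transcribes away from each other
            divergent = np.where(
                opp["strand"] == "+",
                lnc_tss <= g_tss,  # lnc is '-' and sits upstream-left of the gene
                lnc_tss >= g_tss,  # lnc is '+' and sits upstream-right
            )
            ok = (tss_dist <= bidirectional_window) & divergent
            if ok.any():
                cand = opp[ok]
                return LncClass(lnc_id, "bidirectional", _pick_partner(cand, tss_dist[ok]))
        return LncClass(lnc_id, "intergenic", None)

    # partial gene-body overlap without exon overlap: closest to the
    # intron-overlap situation; treat as intronic with the overlapped gene
    hosts = genes_c[g_hit]
    return LncClass(lnc_id, "intronic", _pick_partner(hosts, np.zeros(len(hosts))))


def classify_all(annotation: GeneAnnotation, bidirectional_window: int = 1000) -> pd.DataFrame:
    """Classify every lncRNA in the annotation.

    Returns a frame with columns ``lnc_id, class, partner_gene`` in
    lncRNA-id order.
    """
    rows = [
        classify_lncrna(lnc, annotation, bidirectional_window)
        for _, lnc in annotation.lncrna.iterrows()
    ]
    return pd.DataFrame(
        {
            "lnc_id": [r.lnc_id for r in rows],
            "class": [r.lnc_class for r in rows],
            "partner_gene": [r.partner_gene for r in rows],
        }
    ).sort_values("lnc_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tabulations
# ---------------------------------------------------------------------------

def chromosome_distribution(deg, annotation: GeneAnnotation) -> ChromDistribution:
    """Per-chromosome up/down counts of a DE set.

    ``deg`` is a DEGSets-like object with ``up`` and ``down`` id sets.
    Probes without a chromosome assignment are excluded with a warning and
    counted in ``n_excluded``.  ``percent`` is each chromosome's share of
    the full DE set.
    """
    chrom_of = annotation.chrom_of()
    counts: dict[str, list[int]] = {}
    excluded = 0
    for direction, ids in (("up", deg.up), ("down", deg.down)):
        for pid in ids:
            chrom = chrom_of.get(pid)
            if chrom is None:
                excluded += 1
                continue
            row = counts.setdefault(chrom, [0, 0])
            row[0 if direction == "up" else 1] += 1
    if excluded:
        warnings.warn(f"{excluded} DE probes lack a chromosome assignment; excluded")
    if not counts:
        table = pd.DataFrame(columns=["chrom", "up", "down", "total", "percent"])
        return ChromDistribution(table, None, excluded)
    table = pd.DataFrame(
        [(c, u, d, u + d) for c, (u, d) in counts.items()],
        columns=["chrom", "up", "down", "total"],
    ).sort_values("chrom", kind="stable").reset_index(drop=True)
    grand = len(deg.up) + len(deg.down)
    table["percent"] = 100.0 * table["total"] / grand
    modal = table.sort_values(["total", "chrom"], ascending=[False, True])["chrom"].iat[0]
    return ChromDistribution(table, modal, excluded)


def class_composition(classes: pd.DataFrame, deg) -> pd.DataFrame:
    """Fraction of a DE lncRNA set per positional class.

    ``classes`` is the classify_all frame; ``deg`` supplies the DE ids
    (union of up and down).  Returns ``class, count, percent`` over all
    five classes (zero rows included) with percentages summing to 100 for
    a nonempty DE set.
    """
    de_ids = set(deg.up) | set(deg.down)
    sub = classes[classes["lnc_id"].isin(de_ids)]
    counts = sub["class"].value_counts()
    total = int(counts.sum())
    rows = []
    for cls in LNC_CLASSES:
        k = int(counts.get(cls, 0))
        rows.append((cls, k, 100.0 * k / total if total else 0.0))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


# ---------------------------------------------------------------------------
# annotation I/O (GTF 1-based inclusive, BED 0-based half-open)
# ---------------------------------------------------------------------------

def write_gtf(annotation: GeneAnnotation, path) -> None:
    lines = []
    for _, g in annotation.genes.iterrows():
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(
            f"{g.chrom}\tdcmlnc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
    for _, e in annotation.exons.iterrows():
        attrs = f'gene_id "{e.gene_id}"; gene_biotype "coding";'
        lines.append(
            f"{e.chrom}\tdcmlnc\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gtf(path) -> GeneAnnotation:
    df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    genes = df[df["Feature"] == "gene"]
    exons = df[df["Feature"] == "exon"]
    genes = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["Chromosome"].astype(str).to_numpy(),
            "start": genes["Start"].astype(int).to_numpy(),
            "end": genes["End"].astype(int).to_numpy(),
            "strand": genes["Strand"].astype(str).to_numpy(),
            "biotype": genes["gene_biotype"].to_numpy(),
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": exons["gene_id"].to_numpy(),
            "chrom": exons["Chromosome"].astype(str).to_numpy(),
            "start": exons["Start"].astype(int).to_numpy(),
            "end": exons["End"].astype(int).to_numpy(),
            "strand": exons["Strand"].astype(str).to_numpy(),
        },
        columns=EXON_COLUMNS,
    )
    return GeneAnnotation(genes, exons)


def write_bed(annotation: GeneAnnotation, path) -> None:
    """BED6 of gene intervals; biotype carried in the score-adjacent name field."""
    with open(path, "w") as fh:
        for _, g in annotation.genes.iterrows():
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}|{g.biotype}\t0\t{g.strand}\n")


def read_bed(path) -> pd.DataFrame:
    """Gene-level frame from the BED6 written by :func:`write_bed`."""
    df = pr.read_bed(str(path)).df
    name = df["Name"].str.split("|", expand=True)
    return pd.DataFrame(
        {
            "gene_id": name[0].to_numpy(),
            "chrom": df["Chromosome"].astype(str).to_numpy(),
            "start": df["Start"].astype(int).to_numpy(),
            "end": df["End"].astype(int).to_numpy(),
            "strand": df["Strand"].astype(str).to_numpy(),
            "biotype": name[1].to_numpy(),
        }
    )
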