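"""Synthetic microarray study generator with planted ground truth.

Emulates a two-genotype (control vs db/db) by two-age (6 wk, 20 wk)
single-channel expression study with four replicates per group — sixteen
arrays carrying both lncRNA and mRNA probes.  The generator plants three
kinds of structure the downstream pipeline must recover:

* differential expression: a fraction of probes per age contrast get a
  genotype log2 offset drawn as ``log2(U(fc_range))``, so every planted
  effect clears a two-fold change by construction;
* co-expression hubs: each hub lncRNA and its module of mRNAs load on a
  shared per-sample latent factor whose loading is scaled so the
  population pairwise correlation equals ``hub_r_target``;
* positional lncRNA classes: each lncRNA is placed on the genome so its
  class (intergenic, bidirectional, intronic, antisense,
  sense-overlapping) is unambiguous under the classifier's precedence
  rules.

Everything is a pure function of (config, seed); the returned
:class:`PlantedTruth` is the oracle for the recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_class import EXON_COLUMNS, GENE_COLUMNS, LNC_CLASSES, GeneAnnotation

DEFAULT_GROUPS = (("control", 6), ("dbdb", 6), ("control", 20), ("dbdb", 20))

# locus geometry (bp): coding genes are 3 exons of EXON_LEN separated by two
# introns of INTRON_LEN, laid out on a fixed grid of SLOT_LEN so that hosted
# lncRNAs never collide with a neighbouring gene
EXON_LEN = 1000
INTRON_LEN = 3000
GENE_LEN = 3 * EXON_LEN + 2 * INTRON_LEN
SLOT_MARGIN = 4000
SLOT_LEN = SLOT_MARGIN + GENE_LEN + 3000  # 16 kb


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design the pipeline targets: 16 samples in four
    (genotype, age) groups, a scaled-down array of 2,000 lncRNA and 1,500
    mRNA probes, planted fold changes of at least 2.5, log2 noise SD 0.25,
    and five hub lncRNAs each driving a disjoint module of 25 mRNAs at a
    population correlation of 0.999.
    """

    seed: int = 0
    n_chromosomes: int = 10
    chrom_length: int = 5_000_000
    n_coding: int = 1500
    n_lnc_per_class: int = 400
    n_samples_per_group: int = 4
    groups: tuple = DEFAULT_GROUPS
    frac_de: float = 0.05
    fc_range: tuple = (2.5, 8.0)
    sigma_noise: float = 0.25
    sigma_module: float = 0.05
    n_hubs: int = 5
    module_size: int = 25
    hub_r_target: float = 0.999
    flag_absent_quantile: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    disjoint_modules: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.frac_de < 1):
            raise ValueError("frac_de must be in [0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if self.sigma_module <= 0:
            raise ValueError("sigma_module must be positive")
        if self.fc_range[0] < 2:
            raise ValueError("fc_range lower bound must be >= 2 (planted effects must exceed the two-fold threshold)")
        if self.fc_range[1] < self.fc_range[0]:
            raise ValueError("fc_range must be nondecreasing")
        if not (0 < self.hub_r_target < 1):
            raise ValueError("hub_r_target must be in (0, 1)")
        if not (0 < self.flag_absent_quantile < 0.5):
            raise ValueError("flag_absent_quantile must be in (0, 0.5)")
        if self.n_lnc_per_class > self.n_coding:
            raise ValueError("n_lnc_per_class may not exceed n_coding (each hosted lncRNA needs a host gene)")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.groups)

    @property
    def ages(self) -> list:
        seen = []
        for _, age in self.groups:
            if age not in seen:
                seen.append(age)
        return seen


@dataclass
class ExpressionStudy:
    """Probe-by-sample raw intensities with detection flags and metadata.

    ``intensities`` and ``flags`` share index (probe ids) and columns
    (sample ids); flags take values P/M/A (Present/Marginal/Absent).
    ``metadata`` is indexed by sample id with columns genotype, age,
    replicate; ``probe_kind`` maps probe id to "lncRNA" or "mRNA".
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    metadata: pd.DataFrame
    probe_kind: pd.Series

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        if not self.intensities.index.equals(self.flags.index) or not self.intensities.columns.equals(self.flags.columns):
            raise ValueError("intensities and flags must be aligned")
        if not self.intensities.columns.equals(self.metadata.index):
            raise ValueError("metadata must cover exactly the sample columns")

    @property
    def probe_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.columns)

    def subset_probes(self, probe_ids) -> "ExpressionStudy":
        return ExpressionStudy(
            self.intensities.loc[probe_ids],
            self.flags.loc[probe_ids],
            self.metadata,
            self.probe_kind.loc[probe_ids],
        )


@dataclass
class PlantedTruth:
    """Generator ground truth used as the oracle in recovery tests."""

    de_sets: dict  # age -> {probe_id: "up"|"down"}
    hub_ids: list
    hub_modules: dict  # hub lnc id -> list of module mRNA ids
    lnc_class: dict  # lnc id -> positional class
    chrom_of: dict  # probe id -> chromosome
    de_fc: dict = field(default_factory=dict)  # age -> {probe_id: linear fold change}


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _coding_gene(gene_id: str, chrom: str, slot_start: int, strand: str):
    g0 = slot_start + SLOT_MARGIN
    gene = (gene_id, chrom, g0, g0 + GENE_LEN, strand, "coding")
    exons = [
        (gene_id, chrom, g0 + i * (EXON_LEN + INTRON_LEN), g0 + i * (EXON_LEN + INTRON_LEN) + EXON_LEN, strand)
        for i in range(3)
    ]
    return gene, exons


def _hosted_lnc(lnc_id, cls, host_gene, host_exons, rng):
    """Interval + strand realising ``cls`` relative to the host coding gene."""
    _, chrom, g_start, g_end, g_strand, _ = host_gene
    flip = {"+": "-", "-": "+"}
    if cls == "sense_overlapping":
        e2 = host_exons[1]
        return (lnc_id, chrom, e2[2] - 500, e2[2] + 500, g_strand, "lncRNA")
    if cls == "antisense":
        e3 = host_exons[2]
        return (lnc_id, chrom, e3[2] - 400, e3[2] + 400, flip[g_strand], "lncRNA")
    if cls == "intronic":
        intron2_start = host_exons[1][3]
        strand = rng.choice(["+", "-"])
        return (lnc_id, chrom, intron2_start + 500, intron2_start + 1500, strand, "lncRNA")
    if cls == "bidirectional":
        if g_strand == "+":
            return (lnc_id, chrom, g_start - 700, g_start - 200, "-", "lncRNA")
        return (lnc_id, chrom, g_end + 200, g_end + 700, "+", "lncRNA")
    raise ValueError(cls)


def generate_annotation(config: SimulationConfig) -> tuple[GeneAnnotation, dict]:
    """Lay out coding genes and class-labelled lncRNAs on a slot grid.

    Returns the annotation and the true class map (fed into
    :class:`PlantedTruth` by :func:`simulate_expression`).  Raises a
    sizing error naming the chromosome if the grid does not fit.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    slots_per_chrom = config.chrom_length // SLOT_LEN
    n_intergenic = config.n_lnc_per_class
    n_slots_needed = config.n_coding + n_intergenic
    if n_slots_needed > slots_per_chrom * config.n_chromosomes:
        short = chroms[-1]
        raise ValueError(
            f"chromosome {short} too short: need {n_slots_needed} loci of {SLOT_LEN} bp "
            f"but only {slots_per_chrom} fit per {config.chrom_length} bp chromosome"
        )

    # interleave coding and intergenic-lncRNA slots deterministically
    slot_kinds = ["coding"] * config.n_coding + ["intergenic"] * n_intergenic
    rng.shuffle(slot_kinds)

    genes, exons = [], []
    lnc_class: dict[str, str] = {}
    coding_records = []  # (gene tuple, exon tuples) for host assignment
    n_lnc = 0
    ci = 0
    for k, kind in enumerate(slot_kinds):
        chrom = chroms[k // slots_per_chrom]
        slot_start = (k % slots_per_chrom) * SLOT_LEN
        if kind == "coding":
            strand = rng.choice(["+", "-"])
            gene, gexons = _coding_gene(f"MRNA_{ci:06d}", chrom, slot_start, strand)
            ci += 1
            genes.append(gene)
            exons.extend(gexons)
            coding_records.append((gene, gexons))
        else:
            mid = slot_start + SLOT_LEN // 2
            strand = rng.choice(["+", "-"])
            lnc_id = f"LNC_{n_lnc:06d}"
            n_lnc += 1
            genes.append((lnc_id, chrom, mid - 400, mid + 400, strand, "lncRNA"))
            lnc_class[lnc_id] = "intergenic"

    hosted = [c for c in LNC_CLASSES if c != "intergenic"]
    host_order = rng.permutation(len(coding_records))
    for cls in hosted:
        for i in range(config.n_lnc_per_class):
            host_gene, host_exons = coding_records[host_order[i]]
            lnc_id = f"LNC_{n_lnc:06d}"
            n_lnc += 1
            genes.append(_hosted_lnc(lnc_id, cls, host_gene, host_exons, rng))
            lnc_class[lnc_id] = cls

    genes_df = pd.DataFrame(genes, columns=GENE_COLUMNS)
    exons_df = pd.DataFrame(exons, columns=EXON_COLUMNS)
    return GeneAnnotation(genes_df, exons_df), lnc_class


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for genotype, age in config.groups:
        for rep in range(1, config.n_samples_per_group + 1):
            rows.append((f"{genotype}_{age}wk_r{rep}", genotype, age, rep))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "age", "replicate"]).set_index("sample_id")


def simulate_expression(
    annotation: GeneAnnotation,
    config: SimulationConfig,
    lnc_class: dict | None = None,
) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate raw intensities + flags and record the planted truth.

    Model (log2 scale): baseline_p + genotype offset (planted DE probes,
    db/db group at the designated age) + hub latent contribution +
    N(0, sigma_noise).  The latent loading is
    ``sigma_noise * sqrt(r/(1-r))`` so module pairs attain population
    correlation ``r = hub_r_target``.  Flags: per sample, intensities
    below the ``flag_absent_quantile`` quantile are Absent, below twice
    that quantile Marginal, else Present.
    """
    if annotation.genes.empty:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng([config.seed, 1])
    meta = _sample_frame(config)
    probe_ids = list(annotation.genes["gene_id"])
    kinds = annotation.genes.set_index("gene_id")["biotype"].map(
        {"coding": "mRNA", "lncRNA": "lncRNA"}
    )
    mrna_ids = [p for p in probe_ids if kinds[p] == "mRNA"]
    lnc_ids = [p for p in probe_ids if kinds[p] == "lncRNA"]
    n_probes, n_samples = len(probe_ids), len(meta)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}

    if config.n_hubs * config.module_size > len(mrna_ids) and config.n_hubs > 0:
        raise ValueError(
            f"module_size {config.module_size} x n_hubs {config.n_hubs} exceeds "
            f"{len(mrna_ids)} available mRNA probes"
        )

    log2x = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)[:, None] * np.ones(
        (1, n_samples)
    )

    # --- planted differential expression, per age contrast -----------------
    ages = config.ages
    de_sets: dict = {age: {} for age in ages}
    de_fc: dict = {age: {} for age in ages}
    dbdb_cols = {
        age: np.array([(meta["genotype"].iloc[j] == "dbdb") & (meta["age"].iloc[j] == age) for j in range(n_samples)])
        for age in ages
    }
    n_de = int(round(config.frac_de * n_probes))
    offsets = np.zeros((n_probes, n_samples))
    for age in ages:
        chosen = rng.choice(n_probes, size=n_de, replace=False)
        directions = rng.choice([1, -1], size=n_de)
        fcs = rng.uniform(config.fc_range[0], config.fc_range[1], size=n_de)
        for idx, sgn, fc in zip(chosen, directions, fcs):
            pid = probe_ids[idx]
            de_sets[age][pid] = "up" if sgn > 0 else "down"
            de_fc[age][pid] = float(fc)
            offsets[idx, dbdb_cols[age]] += sgn * np.log2(fc)

    # --- hub lncRNAs and their mRNA modules --------------------------------
    hub_ids: list = []
    hub_modules: dict = {}
    if config.n_hubs > 0:
        hub_idx = rng.choice(len(lnc_ids), size=config.n_hubs, replace=False)
        hub_ids = [lnc_ids[i] for i in hub_idx]
        mrna_pool = rng.permutation(len(mrna_ids))
        beta = config.sigma_module * np.sqrt(config.hub_r_target / (1 - config.hub_r_target))
        # hub transcripts are modelled as moderately-to-highly expressed so
        # their latent swings stay inside the array's dynamic range (away
        # from the detection floor where the log transform compresses)
        cursor = 0
        for h, hub in enumerate(hub_ids):
            if config.disjoint_modules:
                members = [mrna_ids[j] for j in mrna_pool[cursor : cursor + config.module_size]]
                cursor += config.module_size
            else:
                members = [mrna_ids[j] for j in rng.choice(len(mrna_ids), size=config.module_size, replace=False)]
            hub_modules[hub] = sorted(members)
            z = rng.normal(size=n_samples)
            # standardize the latent within each age block so the realized
            # within-age module correlation matches hub_r_target instead of
            # fluctuating with the small-sample variance of z
            for age in ages:
                blk = meta["age"].to_numpy() == age
                z[blk] = (z[blk] - z[blk].mean()) / z[blk].std()
            sgn_mod = rng.choice([1, -1])
            # one fold change per module: the hub and its members move as a
            # co-regulated block, so the genotype offset is shared signal
            # rather than per-probe decorrelating structure
            fc = rng.uniform(config.fc_range[0], config.fc_range[1])
            for pid in [hub] + hub_modules[hub]:
                i = probe_pos[pid]
                log2x[i] = rng.normal(config.baseline_mean + 1.0, 0.5) + beta * z
                for age in ages:
                    de_sets[age][pid] = "up" if sgn_mod > 0 else "down"
                    de_fc[age][pid] = float(fc)
                    offsets[i, dbdb_cols[age]] = sgn_mod * np.log2(fc)

    # hub-module probes are tightly co-regulated: their residual noise is
    # sigma_module (the latent loading is scaled against it), all other
    # probes get the array-level sigma_noise
    sigma_row = np.full(n_probes, config.sigma_noise)
    for hub, members in hub_modules.items():
        for pid in [hub] + members:
            sigma_row[probe_pos[pid]] = config.sigma_module
    log2x = log2x + offsets + sigma_row[:, None] * rng.normal(size=(n_probes, n_samples))
    intensities = pd.DataFrame(
        np.exp2(log2x), index=pd.Index(probe_ids, name="probe_id"), columns=meta.index
    )

    # --- detection flags ----------------------------------------------------
    flags = np.full((n_probes, n_samples), "P", dtype="<U1")
    q = config.flag_absent_quantile
    vals = intensities.to_numpy()
    t_abs = np.quantile(vals, q, axis=0)
    t_marg = np.quantile(vals, min(2 * q, 1.0), axis=0)
    flags[vals < t_marg[None, :]] = "M"
    flags[vals < t_abs[None, :]] = "A"
    flags = pd.DataFrame(flags, index=intensities.index, columns=intensities.columns)

    study = ExpressionStudy(intensities, flags, meta, kinds.loc[probe_ids])
    truth = PlantedTruth(
        de_sets=de_sets,
        hub_ids=hub_ids,
        hub_modules=hub_modules,
        lnc_class=dict(lnc_class or {}),
        chrom_of=annotation.chrom_of(),
        de_fc=de_fc,
    )
    return study, truth


def simulate_study(config: SimulationConfig) -> tuple[ExpressionStudy, PlantedTruth, GeneAnnotation]:
    """Convenience: annotation + expression in one call."""
    annotation, lnc_class = generate_annotation(config)
    study, truth = simulate_expression(annotation, config, lnc_class)
    return study, truth, annotation


# ---------------------------------------------------------------------------
# synthetic qPCR and term maps (validation-arm inputs)
# ---------------------------------------------------------------------------

def simulate_qpcr(
    study: ExpressionStudy,
    genes,
    seed: int,
    sigma_ct: float = 0.05,
    reference_gene: str = "Rnu6",
    ct_offset: float = 32.0,
):
    """Generate a triplicate-free Ct table consistent with the array signal.

    Ct is inversely proportional to log2 template abundance, so
    ``Ct = ct_offset - log2(intensity) + noise`` for each target and a
    constant-abundance reference gene, mirroring a qPCR run on the same
    RNA the arrays measured.  Group labels are "{genotype}_{age}wk".
    """
    rng = np.random.default_rng([seed, 2])
    rows = []
    meta = study.metadata
    for s in study.sample_ids:
        group = f"{meta.loc[s, 'genotype']}_{meta.loc[s, 'age']}wk"
        rows.append((s, group, reference_gene, 18.0 + rng.normal(0, sigma_ct)))
        for g in genes:
            ct = ct_offset - np.log2(study.intensities.loc[g, s]) + rng.normal(0, sigma_ct)
            rows.append((s, group, g, float(ct)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "ct"])


def synthetic_term_map(
    truth: PlantedTruth,
    universe,
    seed: int,
    n_random_terms: int = 30,
    random_term_size: int = 40,
) -> pd.DataFrame:
    """Two-column (term_id, gene_id) map: hub modules as coherent terms plus
    random background terms drawn from the universe."""
    rng = np.random.default_rng([seed, 3])
    universe = sorted(universe)
    rows = []
    for h, hub in enumerate(sorted(truth.hub_modules)):
        for g in truth.hub_modules[hub]:
            rows.append((f"TERM_MODULE_{h:02d}", g))
    for t in range(n_random_terms):
        size = min(random_term_size, len(universe))
        for g in rng.choice(universe, size=size, replace=False):
            rows.append((f"TERM_RAND_{t:03d}", g))
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

_FILES = (
    "expression.tsv",
    "flags.tsv",
    "samples.tsv",
    "annotation.gtf",
    "annotation.bed",
    "truth.json",
)


def write_fixture(
    study: ExpressionStudy,
    truth: PlantedTruth,
    annotation: GeneAnnotation,
    outdir,
    overwrite: bool = False,
) -> list:
    """Write the study to plain-text files; refuse to clobber without overwrite."""
    from . import genomic_class as gc

    os.makedirs(outdir, exist_ok=True)
    paths = [os.path.join(outdir, f) for f in _FILES]
    if not overwrite:
        existing = [p for p in paths if os.path.exists(p)]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}; pass overwrite=True")
    study.intensities.to_csv(paths[0], sep="\t", index_label="probe_id")
    study.flags.to_csv(paths[1], sep="\t", index_label="probe_id")
    study.metadata.to_csv(paths[2], sep="\t", index_label="sample_id")
    gc.write_gtf(annotation, paths[3])
    gc.write_bed(annotation, paths[4])
    with open(paths[5], "w") as fh:
        json.dump(
            {
                "de_sets": {str(a): m for a, m in truth.de_sets.items()},
                "hub_ids": truth.hub_ids,
                "hub_modules": truth.hub_modules,
                "lnc_class": truth.lnc_class,
                "chrom_of": truth.chrom_of,
                "de_fc": {str(a): m for a, m in truth.de_fc.items()},
            },
            fh,
            indent=1,
        )
    return paths


def read_fixture(outdir) -> tuple[ExpressionStudy, PlantedTruth, GeneAnnotation]:
    from . import genomic_class as gc

    paths = {f: os.path.join(outdir, f) for f in _FILES}
    intensities = pd.read_csv(paths["expression.tsv"], sep="\t", index_col="probe_id")
    flags = pd.read_csv(paths["flags.tsv"], sep="\t", index_col="probe_id")
    meta = pd.read_csv(paths["samples.tsv"], sep="\t", index_col="sample_id")
    annotation = gc.read_gtf(paths["annotation.gtf"])
    with open(paths["truth.json"]) as fh:
        raw = json.load(fh)
    truth = PlantedTruth(
        de_sets={int(a): m for a, m in raw["de_sets"].items()},
        hub_ids=raw["hub_ids"],
        hub_modules=raw["hub_modules"],
        lnc_class=raw["lnc_class"],
        chrom_of=raw["chrom_of"],
        de_fc={int(a): m for a, m in raw.get("de_fc", {}).items()},
    )
    kinds = annotation.genes.set_index("gene_id")["biotype"].map(
        {"coding": "mRNA", "lncRNA": "lncRNA"}
    ).loc[intensities.index]
    study = ExpressionStudy(intensities, flags, meta, kinds)
    return study, truth, annotation
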