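# dcmlnc

Genome-wide lncRNA/mRNA expression profiling for early diabetic
cardiomyopathy, reimplemented as a reusable, tested pipeline.

Type 2 diabetic *db/db* mice develop cardiac hypertrophy early (6 weeks)
and diastolic dysfunction later (20 weeks).  Microarray studies of this
model profile tens of thousands of long noncoding RNA (lncRNA) and mRNA
probes across a 16-sample design — 2 genotypes (C57BL/6J control vs
*db/db*) × 2 ages × 4 replicates — and ask which transcripts are
deregulated, where the deregulated lncRNAs sit in the genome, and which
lncRNAs sit at the center of the lncRNA–mRNA co-expression network.
`dcmlnc` implements that analysis chain end to end, plus a synthetic-data
generator that emulates the study design with planted ground truth, so
every stage is testable without any array deposit.

## The analysis

1. **Preprocess** — probes detected (`Present`/`Marginal` flag) in ≥ 4 of
   16 samples are retained; intensities are log2-transformed and
   quantile-normalized (rank/mean: the k-th order statistic of every
   sample is replaced by the mean k-th order statistic across samples).
2. **Differential expression** — per age-matched genotype contrast, a
   probe is deregulated when its linear fold change
   `FC = 2^|mean_b − mean_a|` satisfies FC ≥ 2 **and** the two-group test
   p < 0.05 (Welch's t by default; Student's t and the exact Mann–Whitney
   rank-sum for n ≤ 8 per group are available).  Benjamini–Hochberg
   q-values are reported alongside and can optionally gate the calls.
3. **Genomic classification** — each lncRNA gets one positional class
   relative to protein-coding genes, by precedence: sense-overlapping
   (exonic overlap, same strand) → antisense (exonic overlap, opposite
   strand) → intronic (wholly inside an intron) → bidirectional
   (divergent TSSs within 1 kb on opposite strands) → intergenic.
   Per-chromosome up/down counts and per-class compositions are
   tabulated.
4. **Co-expression network** — every DE-lncRNA × DE-mRNA pair is scored
   by Pearson correlation over the 8 samples of one age; pairs with
   |r| > 0.995 and p < 0.05 become signed edges of a bipartite network.
   Hub lncRNAs are the top-degree nodes ("maximum connections with
   mRNAs"), exported as GraphML/SIF with an induced hub subnetwork.
5. **Enrichment** — user-supplied term→gene maps (GO/KEGG style) are
   tested by the exact hypergeometric upper tail with BH correction;
   significant terms are grouped by connected components of the
   term–term Cohen's-kappa graph (kappa > 0.03).
6. **qPCR concordance** — ΔΔCt relative quantification
   (`RQ = 2^−ΔΔCt`, normalized to a reference gene such as Rnu-6 and a
   calibrator group) and the fraction of genes whose qPCR direction
   matches the array fold change.

## Worked example

```python
import dcmlnc

cfg = dcmlnc.SimulationConfig(seed=1)           # 16 samples, 3,500 probes
study, truth, annotation = dcmlnc.simulate_study(cfg)
norm, filtered = dcmlnc.run_preprocessing(study)

de = dcmlnc.differential_expression(norm, filtered.metadata, ("control", "dbdb", 20))
sig = de[de["significant"]]

kinds = filtered.probe_kind
edges = dcmlnc.build_network(
    norm,
    set(truth.de_sets[20]) & set(kinds.index[kinds == "lncRNA"]),
    set(truth.de_sets[20]) & set(kinds.index[kinds == "mRNA"]),
    metadata=filtered.metadata, age=20,
)
hubs = dcmlnc.rank_hubs(edges, k=5)
print(hubs.ranking.head(5).to_string(index=False))
```

prints

```
    lnc_id  degree  sum_abs_r
LNC_000697      25  24.987010
LNC_001334      25  24.974985
LNC_001909      25  24.959308
LNC_001006      23  22.955652
LNC_000957      23  22.953373
```

The five top-degree lncRNAs are exactly the five planted hubs: each hub
drives a module of 25 mRNAs, and 23–25 of each module's edges survive the
|r| > 0.995 filter at this noise level.  The same run calls 103 lncRNAs
and 109 mRNAs deregulated at 20 weeks out of 3,399 detected probes
(5% of probes carry planted effects per contrast, plus the hub modules).

The full chain — simulation through report — runs from the shell:

```bash
dcmlnc run-all --seed 1 --out results/
dcmlnc simulate --seed 1 --out fixture/
dcmlnc de --fixture fixture/ --age 20 --out de20.tsv
```

`run-all` writes every stage artifact (TSV/GTF/BED/JSON/GraphML), a
Markdown report, and a `manifest.json` with parameter values and content
hashes; rerunning with the same seed reproduces the hashes byte for byte.

## Layout

- `src/dcmlnc/synthetic_data.py` — study generator + planted truth
- `src/dcmlnc/preprocess.py` — flag filter, quantile normalization
- `src/dcmlnc/diffexpr.py` — two-group tests, BH, volcano calls, clustering
- `src/dcmlnc/genomic_class.py` — lncRNA positional classes, GTF/BED I/O
- `src/dcmlnc/coexpression.py` — correlation network, hub ranking, exports
- `src/dcmlnc/enrichment.py` — hypergeometric tests, kappa grouping
- `src/dcmlnc/qpcr.py` — ΔΔCt, concordance
- `src/dcmlnc/cli.py` — config, orchestration, report, `dcmlnc` CLI
- `docs/methods.md` — model assumptions, parameter rationale, limitations
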