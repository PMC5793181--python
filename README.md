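# srnascape

Small non-coding RNA (sRNA) landscape analysis for short-read sequencing of
tumor cell-line panels — built for the kind of study that profiles
triple-negative breast cancer (TNBC) lines across their four
transcriptional subtypes (BL1, BL2, M, LAR) and asks which sRNA species
distinguish them and how miRNAs co-vary with mRNAs.

The pipeline takes single-end small RNA-seq reads (~50 nt FASTQ), a
reference genome (FASTA) and sRNA annotations (GFF3), and produces:

- **Preprocessing** — 3' adapter trimming, a strict ≥ 16 nt length filter,
  and collapsing to unique tags with copy numbers (the unit of
  quantification).
- **Alignment** — full-length genome mapping with at most one substitution,
  aware of 1–3 non-templated 3' additions (NTA): the best hit tier
  minimizes mismatches over the aligned portion first, then the trimmed
  NTA length.
- **Annotation & quantification** — assignment to seven sRNA categories
  (miRNA, tRNA, snoRNA, snRNA, yRNA, 7SK, 7SL) with a fixed priority
  order; isomiR calling for reads whose 5' end sits +1/+2 nt downstream of
  the annotated miRNA start (isomiRs are quantified as their own species);
  detection curves at thresholds 1/5/10/15/20 and median expression
  profiles.
- **tRNA analysis** — anticodon-family abundance fractions and positional
  coverage with the 5'-half enrichment statistic
  (fraction of depth at positions < L/2).
- **Differential expression** — per feature, a rank aggregation of the
  Wilcoxon rank-sum p, Welch t p and |log2 fold change| on log2(CPM+1),
  with BH FDR; all six pairwise subtype comparisons and the four
  one-vs-rest comparisons, plus subtype-exclusive feature sets (significant
  in exactly one "S vs others" test).
- **Correlation networks** — all-pairs Spearman rho between miRNA and mRNA
  matrices, the positive/negative direction-bias profile by |rho| bin,
  tumor-suppressor/oncogene per-gene miRNA counts, subtype-aware
  miRNA–target tables, and deterministic edge/node-table export.
- **Synthetic data** — a first-class generator producing genomes,
  annotations, ground-truthed reads (adapters, errors, isomiR offsets,
  NTAs, 5'-biased tRNA fragments) and copula-calibrated paired
  sRNA/mRNA matrices (latent Pearson r = 2·sin(π·ρs/6) for a Spearman
  target ρs), so every stage is testable against known truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run a self-contained synthetic study (26 samples over the four subtypes,
20,000 reads each here; the default is 200,000):

```python
from srnascape import RunConfig, run_pipeline
from srnascape.simulate import SimulationConfig

sim = SimulationConfig(seed=7, reads_per_sample=20_000)
cfg = RunConfig(outdir="example_run", seed=7, sim=sim)
report = run_pipeline(cfg)
print("stages:", ", ".join(s["stage"] + ":" + s["status"] for s in report.stages))
print("conservation:", report.conservation)
print("tRNA 5'-half fraction:", round(report.summary["trna_five_prime_half_fraction"], 3))
print("exclusive sRNAs per subtype:", report.summary["exclusive_counts"])
```

prints

```
stages: simulate:ok, preprocess:ok, quantify:ok, trna:ok, differential:ok, correlate:ok
conservation: {'preprocess_funnel': True, 'quantify_totals': True}
tRNA 5'-half fraction: 0.912
exclusive sRNAs per subtype: {'BL1': 1, 'BL2': 3, 'M': 9, 'LAR': 23}
```

Reading the output: both conservation checks are exact identities (the
read funnel `n_raw = n_usable + n_too_short` and
`Σ category counts + unannotated = mapped copies`), so no read was silently
lost or double-counted. The tRNA 5'-half fraction of 0.91 reflects the
generator's 85% 5'-half fragment bias — sequenced tRNA fragments
overwhelmingly cover the first half of the parent tRNA. The exclusive-set
sizes recover the simulated design's ordering (LAR the most
subtype-specific features, BL2 the fewest); sizes differ from the spiked
counts because spiked miRNAs also spawn differential isomiR features and
because strong spikes shift library composition (see
`docs/methods.md`).

The run directory contains per-species count matrices
(`counts/*.tsv`), detection curves, anticodon fraction and coverage
tables, per-comparison DE tables with pairwise and exclusivity summaries,
correlation records with the direction-bias profile, network edge/node
tables, the ground truth (`truth/`), and `run_report.json` with a sha256
manifest — two runs with the same seed are byte-identical.

The same stages are available from the shell:

```bash
srnascape all --outdir example_run --seed 7
srnascape simulate --outdir sim --seed 7
srnascape preprocess --fastq-dir sim/reads --metadata sim/metadata.tsv \
    --adapter TGGAATTCTCGGGTGCCAAGG --outdir pp
srnascape quantify --genome sim/genome.fa --gff sim/annotations.gff3 \
    --tags-dir pp/tags --metadata sim/metadata.tsv --outdir quant
srnascape de --counts-dir quant/counts --metadata sim/metadata.tsv --outdir de
```

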