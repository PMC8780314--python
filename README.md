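# armflip

Small-RNA analysis toolkit for detecting **miRNA arm switching** and
screening **miRNA:lncRNA interactions**, with a built-in synthetic data
generator so every stage is verifiable against planted ground truth.

## What it does

- **Read processing** — 3' adapter trimming (exact prefix match, min
  overlap 5) and QC filtering (mean Phred >= 20, length 16–30 nt).
- **Arm quantification** — ungapped alignment of reads against hairpin
  precursors; a read is assigned to the 5p or 3p arm when its alignment
  covers >= 50% of the read length within the annotated arm interval.
- **Arm-selection statistic** — `omega = 5p / (5p + 3p)` per hairpin per
  sample; dominance is 5p when omega > 0.7, 3p when omega < 0.3 (strict
  inequalities), and only samples where either arm exceeds 50 reads are
  classified. An **arm switch** between two conditions is called when every
  replicate of one condition shows one dominance and every replicate of the
  other shows the opposite.
- **Differential expression** — CPM normalization, a conditional binomial
  exact test on pooled counts (the dispersion→0 limit of the
  negative-binomial exact test; a documented stand-in, not an edgeR clone),
  Benjamini–Hochberg FDR, and the screening thresholds CPM >= 50 in at
  least one sample, |log2FC| >= 1, FDR <= 0.05.
- **Interaction screen** — a penalty-based complementarity scanner
  (Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap 2, seed positions 2–8
  weighted x2, zero seed mismatches by default, total penalty <= 4) combined
  with antagonistic DE: a miRNA:lncRNA pair is called when a duplex site
  exists and the two features move in opposite directions in the same
  contrast.
- **Synthetic data** — hairpins, arm-derived FASTQ reads (negative-binomial
  counts, planted dominance shifts), lncRNAs with planted complementary
  sites, count matrices with planted antagonistic fold changes, and a
  ground-truth manifest (`truth.json`).

## CLI

```sh
# full synthetic pipeline: simulate -> trim -> quantify -> switch -> de -> interact
armflip run --config run.yaml --out-dir results/

# individual stages
armflip simulate --seed 7 --out-dir sim/
armflip trim --fastq in.fastq --adapter UCGUAUGCCGUCUUCUGCUUG --out out.fastq --report qc.tsv
armflip quantify --fastq s1.fastq --fastq s2.fastq --hairpins hp.fa --arms arms.gff3 --out armcounts.tsv
armflip switch --counts armcounts.tsv --samples samples.tsv --min-count 50 --low 0.3 --high 0.7 --out switches.tsv
armflip de --counts counts.tsv --samples samples.tsv --contrast "C08,root,4 vs C08,root,24" --out de.tsv
armflip interact --mirna-fa mirna.fa --lncrna-fa lnc.fa --mirna-de de_mirna.tsv --lncrna-de de_lncrna.tsv --out interactions.tsv
```

Config files are YAML with sections `sim`, `filter`, `switch`, `de`,
`duplex`, `contrast`; CLI flags override config values. Example:

```yaml
sim:
  n_hairpins: 50
  n_switch_loci: 5
  accessions: [C08, W05]
  tissues: [root, leaf]
  time_points_h: [0, 1, 2, 4, 24, 48]
  seed: 1
switch:
  min_count: 50
  low_cut: 0.3
  high_cut: 0.7
```

## Conventions

- Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
  inclusive.
- Sequences are normalized to uppercase RNA (T -> U) on input.
- Negative binomial distributions are parameterized by (mean m,
  dispersion a) with variance m + a·m²; a = 0 degenerates to Poisson.
- Library sizes are total retained reads per sample, not count-matrix
  column sums.
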