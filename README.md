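# allelescan

Base-pair-resolution analysis of how genetic variation reshapes
transcription-factor (TF) binding and chromatin accessibility.

Two phenotypically matched cell lines (e.g. two erythroid lines) differ
at millions of homozygous substitutions.  Where one line is homozygous
for a variant and the other is homozygous reference — a *discriminatory
SNP* (discSNP) — the two genomes form a natural mutagenesis experiment:
the same trans environment reading two sequences that differ by one
base.  `allelescan` implements the full analysis stack around this idea
for researchers in regulatory genomics:

- **Zygosity calling** from ChIP-seq input pileups: per-site calls from
  read depth and variant read fraction, block-level rescue of ambiguous
  calls, pairing of two lines into discSNPs, and precision/recall
  evaluation against a truth set.
- **Motif-disruption scoring**: a 40-bp window centred on each discSNP
  is scanned with position weight matrices (PWMs) on both strands; at
  the best SNP-containing placement the two alleles are scored, giving
  `Score_max = max(S_A, S_B)` and `DiffScore = |S_A − S_B|` (log2-odds,
  bits).  A disruption is called when `Score_max ≥ 7.5` and
  `DiffScore ≥ 2.5`; the thresholds themselves can be re-derived by
  random-walk optimization against allele-resolved signal loss.
- **Impact statistics**: percent residual binding
  `100 · I_disrupted / I_intact` on input-subtracted, library-size
  normalized intensities, grouped by motif, motif position, variant
  base, distance bin or peak class; one-sample Wilcoxon tests against
  100%, bootstrap CIs of group medians (1,000 resamples), and maxT
  label-permutation q-values (1,000 permutations) for multiple testing.
- **CRISPR deletion scanning**: amplicon reads from ChIP input and IP
  libraries are globally aligned (affine gaps, open 10 / extend 0.5) to
  the wild-type sequence, kept when wild type or carrying a single
  deletion at >80% identity, tallied, and normalized so the wild-type
  allele's IP/Input enrichment ratio is exactly 1; sliding 2-bp windows
  localize the effect of 1–2-bp deletions.
- **Contextual binding prediction**: logistic regression on the anchor
  motif score plus the best score of each contextual motif within
  100 bp, with composition-matched negatives, column-shuffled-PWM
  controls, 10× cross-validation, and DeLong's paired AUC test.
- **Synthetic data**: a generator producing genomes, pileups,
  allele-resolved overdispersed ChIP counts and deletion libraries with
  machine-readable ground truth, so every stage is testable without
  external data.

## Worked example

Plant known per-position effects, run the pipeline, and recover them:

```python
import numpy as np
import allelescan as a

anchor = a.PWM.from_consensus("GATA1", "AGATAA", tf_name="GATA1", family="GATA")
truth = a.simulate_genome_pair(
    length=2_100_000, n_peaks=1000, n_snps=600, pwms=[anchor], seed=7,
    effect_by_offset={1: 1.0, 2: 0.7, 4: 0.3},  # motif position -> residual binding
    frac_in_motif=1.0,
)

# variant calling from pileups
sites_a, sites_b = a.simulate_pileups(truth, mean_depth=30, error_rate=0.003, seed=8)
disc_snps = a.find_disc_snps(a.call_sites(sites_a), a.call_sites(sites_b))

# motif-disruption scoring at each discSNP
seq_a = {truth.reference.contig_name: truth.line_a_seq.sequence}
seq_b = {truth.reference.contig_name: truth.line_b_seq.sequence}
events = []
for snp in disc_snps:
    events.extend(a.analyze_disc_snp(snp, seq_a, seq_b, [anchor]))
called = [e for e in a.call_disruptions(events) if e.is_called_disruption]

# allele-resolved signal -> percent residual binding -> grouped statistics
counts = a.simulate_chip_counts(truth, a.NoiseModel(dispersion=0.2), seed=9)
int_a = a.normalize_chip(counts["ip_A"], counts["input_A"], 1e6, 1e6)
int_b = a.normalize_chip(counts["ip_B"], counts["input_B"], 1e6, 1e6)
idx = [next(i for i, p in enumerate(truth.peaks)
            if p.contains_pos(e.disc_snp.pos - 1)) for e in called]
residuals, kept = a.percent_residual(called, int_a[idx], int_b[idx])
groups = np.array([e.position_in_motif for e in called])[kept]

stats = a.group_impact(residuals, groups, n_boot=1000, seed=10)
q = a.permutation_adjust(residuals, groups, n_perm=1000, seed=10)
print(stats.merge(q[["group", "q"]], on="group").round(4).to_string(index=False))
```

Output:

```
 group   n   median   ci_lo    ci_hi  wilcoxon_p     q
     1 200  95.9148 83.5034 105.9563      0.1871 1.000
     2 195  64.3770 60.2207  73.9090      0.0000 1.000
     4 200  28.6667 24.4280  33.2103      0.0000 0.001
     6   5 197.1119 44.4175 408.1744      0.3125 1.000
```

All 600 planted discSNPs were recovered and called as motif disruptions.
The group medians recover the planted effects: position 1 (effect 1.0,
i.e. no binding change) sits at ~96% residual binding with a CI spanning
100; positions 2 and 4 (planted 70% and 30%) are estimated at 64% and
29% with CIs covering the truth.  The maxT `q` column is deliberately
conservative: because position 4's massive effect enters every permuted
null, only the strongest group stays significant after correction — the
behaviour to expect when most tested groups carry real signal.  The
small position-6 group collects a handful of events whose best
SNP-containing placement was a secondary motif match; its wide CI and
q = 1 show the minimum-group-size and correction machinery doing their
job.

## Command line

A thin CLI wraps the main pipeline stages:

```bash
allelescan simulate --preset full --seed 3 --out-dir demo/
allelescan call-variants demo/pileup_line_A.tsv --out demo/calls_A.tsv
allelescan disc-snps demo/calls_A.tsv demo/calls_B.tsv --out demo/discsnps.tsv
allelescan scan-motifs demo/line_A.fa demo/line_B.fa demo/discsnps.tsv motifs.meme --out demo/events.tsv
allelescan deletion-scan demo/amplicon_ref.fa --input-reads demo/amplicon_input.fa \
    --ip-reads demo/amplicon_ip.fa --motif-start 88 --motif-end 94 --out demo/alleles.tsv
```

`motif-enrich`, `impact`, `classify-peaks`, `eval-variants` and
`predict-binding` cover the remaining stages; quantile normalization,
aggregate profiles, threshold optimization and the binding-vs-expression
correlation curves are available through the library API.

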