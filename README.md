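# mengen

Somatic-genomics cohort analyses for high-grade meningioma — the downstream
statistics a tumor-evolution study runs once variants, copy-number segments
and rearrangement junctions are on disk. For analysts working with
MAF-like mutation tables, SEG files and BEDPE junctions who need the
bespoke cohort statistics of meningioma genomics as reusable, tested code
rather than one-off scripts.

## What it computes

- **Mutation burden & spectrum** — per-sample nonsynonymous counts, allelic
  fractions, the 6-class pyrimidine-reference substitution spectrum,
  hypermutator flagging, and two-sided t / Wilcoxon rank-sum group
  comparisons.
- **Copy-number disruption** — percent genome disrupted
  (100 × altered autosomal length / covered autosomal length at
  |log2| ≥ 0.2), arm-level gain/loss calls (≥ 80% of covered arm length),
  chromosome-22-loss detection, and cohort arm incidence with angiomatous
  samples excluded.
- **Driver association & power** — NF2 / chr22-loss / canonical-driver
  flags, Fisher exact co-occurrence with BH correction, and the binomial
  detection-power model: the per-patient mutation rate p at which
  P(X ≥ k | n, p) reaches a target power, solved by bisection.
- **Heterogeneity & phylogeny** — ubiquitous/shared/private partitions,
  Jaccard pairwise overlap with per-patient averages, cumulative discovery
  curves, detection-power-filtered neighbor-joining trees of serial
  resections with a germline outgroup, and linear-vs-branched topology
  classification.
- **Rearrangements** — breakend-proximity clustering into events (≥ 4
  linked junctions = complex), composition by SV class, and repair-mechanism
  calls (insertion ≥ 10 bp → MMBIR; homology ≥ 3 bp → MMEJ; else NHEJ).
- **Neoantigens** — peptide enumeration (8–11-mers and 15-mers), median
  composite affinity across predictors, neoepitope ratio, best-epitope
  selection, 500 nM binder calls, a closed-form cancer-cell-fraction
  clonality estimate, and a bottom-quartile expression filter.
- **Synthetic cohorts** — a seeded generator producing all of the above
  inputs from known clone trees, with truth tables for recovery testing.

## Worked example

The detection-power question — *how rare a driver gene could this cohort
have seen?* — for a 115-patient cohort requiring at least 15 mutated
patients:

```
$ mengen power --n 115 --k 15 --targets 0.95,0.5
  n  k  target_power  detectable_rate  detectable_rate_pct
115 15          0.95         0.183753                   19
115 15          0.50         0.127178                   13
```

Read: a gene mutated in 19% of patients would be detected (≥ 15 mutated
patients observed) with 95% probability; at a 13% rate the odds drop to a
coin flip. The whole-percent figure is the smallest rate whose power meets
the target; `detectable_rate` is the exact bisection root.

An end-to-end synthetic run:

```
$ mengen --seed 7 simulate --out cohort/
simulated 20 patients, 40 samples -> cohort/
$ mengen run-all --in cohort/ --out report/
```

`report/summary.tsv` collects the figure-level statistics, e.g. (seed 7):

```
metric                         group  value
mean_nonsyn_burden             II     18.43
chr22_loss_incidence           all    0.60
mean_pairwise_shared_fraction  all    0.67
complex_junction_fraction      all    0.44
end_joining_fraction           all    0.90
neoantigenic_fraction          all    0.69
```

Per-stage outputs (burden, arm calls, co-occurrence, partitions, discovery
curves, newick trees with topology calls, cluster-annotated junctions,
mechanism profile, neoantigen and CCF tables) land beside it, each headed
by the package version and a configuration hash. `cohort/truth_*.tsv`
holds the generator's ground truth for comparison.

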