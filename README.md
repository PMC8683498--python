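# clonedyn

Clonal-evolution tracking and drug-response scoring for multi-region tumor
sequencing, built around the kind of question that arises when an
EGFR-mutant lung adenocarcinoma acquires a BRAF-driven resistance mechanism
under EGFR-inhibitor therapy: which genetically distinct subclones exist in
each metastasis, how are they related, and how do candidate drug
combinations score against them in vitro?

It is aimed at translational cancer-genomics analysts who have somatic
mutation calls with read counts, copy-number segments, and purity estimates
per biopsy (variant calling and purity/ploidy estimation are upstream and
out of scope), plus the usual cohort tables and viability plates.

## What it computes

**Cancer cell fractions.** A variant at allele fraction `VAF` in a biopsy
with purity ρ and local total copy number `CN_t` is carried by

    CCF = VAF · (ρ·CN_t + (1−ρ)·2) / (ρ·m)

of the cancer cells, with integer multiplicity `m` estimated by a
nearest-integer rule and variance propagated from binomial read sampling.

**Subclone deconvolution.** Mutations cluster in CCF space; clusters are
found by weighted kernel-density mode seeking (mean shift) with a
binomial-noise bandwidth, then classified as clonal in all samples,
shared-subclonal, or private to one biopsy.

**Clone trees and composition.** Clusters are ordered into a rooted lineage
tree under two constraints — a descendant cannot exceed its ancestor's CCF
in any sample, and sibling CCFs cannot sum past their parent (the
pigeonhole sum rule). Per biopsy, each clone's exclusive cell fraction is
its CCF minus its children's. Inter-lesion distance is the mean absolute
per-mutation CCF difference, with an all-zero "normal" baseline.

**Cohort statistics.** Kaplan–Meier estimation (product-limit, via
lifelines) with the median as the first event time where S(t) ≤ 0.5;
co-occurrence percentages; PET metabolic response (SUVmax reduction ≥ 30%,
inclusive); caliper tumor volume `V = 0.5·length·width²`; normalized
growth-rate slopes.

**Pharmacology.** Relative AUC resistance scores (trapezoid area of
viability over log10 dose, normalized to a non-responder, in %);
4-parameter log-logistic dose-response fits; ZIP (zero-interaction-potency)
synergy surfaces in 2-D and stacked 3-D, summarized as the mean of the nine
highest deltas.

**Synthetic data.** A ground-truth generator inverts the CCF model: given a
clone tree with per-sample CCFs, it emits read counts (Poisson depth,
binomial alt reads), plus Bliss-structured dose-response plates and a
packaged six-patient survival table, so the whole pipeline is testable
without access to patient sequencing.

## Worked example

The packaged `p04_like` scenario encodes a three-biopsy case (one
peritoneal and two longitudinal liver samples) whose peritoneal lesion
contains two subclones at 60%/40%:

```python
import clonedyn as cd

sc = cd.build_scenario("p04_like")                 # 5 clones, 3 biopsies
calls = cd.simulate_all_biopsies(sc, seed=7)       # 150x depth, purity 0.7
matrix = cd.ccf_matrix(
    calls,
    {s.sample_id: s.purity for s in sc.samples},
    {s.sample_id: s.cn_profile for s in sc.samples},
)
print(cd.ClonalStructureModel(matrix).fit().summary())
```

```
Clonal structure fit
  mutations: 750  samples: 3  clusters: 5
  tree: ((C3)C2,(C0)C4)C1;

cluster  n_mutations     classification  subclonal parent  forced_root  ccf_peritoneal  ccf_liver1  ccf_liver2
     C0          151 private:peritoneal       True     C4        False           0.398       0.000       0.000
     C1          150         clonal_all      False               False           1.000       0.997       0.988
     C2          150   shared_subclonal       True     C1        False           0.000       0.997       0.993
     C3          150     private:liver2      False     C2        False           0.000       0.000       1.000
     C4          149 private:peritoneal      False     C1        False           0.999       0.000       0.000

Per-biopsy composition (exclusive cell fractions):
  peritoneal: C0: 39.8%, C1: 0.1%, C4: 60.2%
  liver1: C1: 0.0%, C2: 99.7%
  liver2: C1: 0.0%, C2: 0.0%, C3: 100.0%

Inter-lesion distances (mean |dCCF|):
            peritoneal  liver1  liver2  normal
peritoneal       0.000   0.474   0.666   0.463
liver1           0.474   0.000   0.217   0.382
liver2           0.666   0.217   0.000   0.572
normal           0.463   0.382   0.572   0.000
```

Reading it: cluster C1 is the founding clone (clonal in all three
biopsies); the peritoneal lesion carries a private clone (C4, 60.2% of
cells) that spawned a nested subclone (C0, 39.8%); the liver lesion derives
independently from the founder via C2, and its rebiopsy adds C3. The two
liver biopsies are far closer to each other (0.217) than either is to the
peritoneal lesion — branched, not linear, evolution.

There is also a CLI over the same pipeline:

```sh
clonedyn simulate --scenario p04_like --seed 7 --outdir sim/
clonedyn clonal --mutations sim/mutations.tsv --segments sim/segments.tsv \
                --purities sim/purity.tsv --outdir out/
clonedyn survival --survival sim/survival.tsv --outdir out/
```

File dialects (mutation TSV, SEG-like TSV, purity TSV, survival TSV, plate
CSV, scenario YAML, VCF with AD/DP) each have a commented example under
`docs/examples/`. The model and its numerical choices are documented in
`docs/methods.md`.

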