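# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Cancer cell fraction model

For a somatic variant with `alt`/`total` reads in a biopsy of purity ρ,
local total copy number `CN_t` (from the covering SEG segment; diploid
default when uncovered) and multiplicity `m`:

    VAF_expected = m·ρ·CCF / (ρ·CN_t + (1−ρ)·2)
    CCF_raw      = VAF · (ρ·CN_t + (1−ρ)·2) / (ρ·m)

Assumptions: normal cells are diploid at every site (sex chromosomes are
excluded by default rather than special-cased), purity and CN are known
inputs, and a mutation is either absent from a cell or present at `m`
copies. Multiplicity is estimated as `round(VAF·(ρ·CN_t+(1−ρ)·2)/ρ)`
(half-up), clamped to `[1, CN_t]` — the standard nearest-integer rule;
no subclonal copy-number model is attempted. The reported CCF is clamped
at 1 but the raw value is kept: the clamp is a reporting convention, and
downstream density estimation uses the raw value (see below). Variance is
first-order propagation of the binomial VAF variance,
`(∂CCF/∂VAF)²·VAF(1−VAF)/total`.

Matrix semantics: the mutation universe is the union over biopsies. A
mutation uncalled in a biopsy is CCF 0 only when its site is covered at
`min_depth ≥ 20` reads with no alternate support; below that it is missing
(NaN), never imputed. Rows missing everywhere are dropped with a logged
count.

## Subclone deconvolution

Mutations from one clone share a per-sample CCF; read sampling smears each
observation approximately Gaussian at depth ~150×. The deconvolution is a
weighted kernel-density mode search (mean shift, diagonal Gaussian kernel):

* bandwidth per sample = median binomial SD of the *informative* CCF
  observations (exact-zero VAFs carry no noise scale and are excluded from
  the median), floored at 0.05;
* weights = regularized inverse variances, `1/(var + mean var)`, so
  zero-variance observations stay bounded;
* every mutation climbs to its density mode; modes, and then clusters by
  their (clipped) centers, are merged when within `merge_tol = 0.10` in
  every sample; clusters below `min_cluster_size = 5` dissolve into their
  nearest neighbor.

Clustering runs on the **raw** (unclamped) CCFs. At 150× depth a truly
clonal cluster clamped at 1 would average ≈ 0.96 — the mean of a
half-truncated distribution — and that bias propagates directly into
composition estimates; the raw-scale mean is unbiased, and final centers
are clipped to [0, 1] afterwards.

Classification, with `clonal_threshold = 0.85` and
`absent_threshold = 0.10` (both configurable; no thresholds are dictated by
the data, these are conventional working values):

* `clonal_all` — center ≥ 0.85 in every sample;
* `private:<sample>` — present (> 0.10) in exactly one sample; a
  `subclonal` flag is kept when that center is below 0.85, so a
  single-biopsy subclone is still reported as private to that biopsy;
* `shared_subclonal` — everything else.

The mode-seeking design was validated against an independent EM
binomial-mixture oracle with BIC model selection (test suite): on 1-D
instances with up to three components separated by ≥ 0.25 and ≥ 50 members,
cluster counts agree and centers match within 0.05.

## Clone-tree reconstruction

Two constraints order clusters into a lineage: containment (a descendant's
CCF cannot exceed its ancestor's in any sample) and the pigeonhole sum rule
(sibling CCFs cannot sum past their parent). The builder explores
attachments depth-first in descending total-CCF order, preferring the
deepest feasible parent with deterministic id tie-breaks, and backtracks
when a choice strands a later cluster — so a fully feasible tree is found
whenever one exists (bounded exploration, 2·10⁵ states; far beyond any
realistic cluster count). The tolerance on both constraints is 0.10
absolute, sized to absorb binomial noise at ~150× depth. A cluster with no
feasible parent under any completion attaches to the root with a warning
flag instead of aborting: degraded FFPE data violate the rules routinely,
and a visible flagged node is more useful than a failed run. Flagged nodes
are excluded from composition (they receive no cell mass) and from the
sum-rule validator.

Identifiability caveat: CCFs alone often admit several feasible trees
(moving a clone from its parent to a grandparent preserves containment and
may preserve the sum rule). The test suite certifies, by brute-force
enumeration, that the packaged worked example is uniquely determined; on
random trees the builder's output is always feasible and equals the truth
whenever enumeration certifies uniqueness.

Per-biopsy composition assigns node v the fraction
`ccf_s(v) − Σ_children ccf_s(child)`, floored at 0; nodes below the absent
threshold are omitted. Inter-lesion distance is the mean absolute
per-mutation CCF difference — chosen for its metric properties (it is the
L1 distance scaled by mutation count) and because it gives the synthetic
all-zero "normal" sample a natural place as the origin. It is one
reasonable choice among several, not a canonical formula.

## Survival and cohort statistics

Kaplan–Meier estimation delegates to lifelines' product-limit
implementation (events before censorings at tied times). Conventions fixed
here: the median is the smallest observed event time with S(t) ≤ 0.5 and
is "undefined" (a typed outcome) when the curve never reaches 0.5; one
month is 365.25/12 days. Greenwood/log-log confidence intervals are
computed and reported but not validated against any external reference —
they depend on exact per-patient calendar dates that a day-count table does
not determine. Co-occurrence rates are `100·k/n` rounded half-up to one
decimal. The PET metabolic-response boundary (SUVmax reduction ≥ 30%) is
inclusive. Tumor volume `V = 0.5·length·width²` auto-corrects swapped
dimensions with a warning. Growth rate is the OLS slope of
day-1-normalized counts against day index.

## Dose-response and synergy

Viability is normalized to the mean DMSO control; inhibition is
`1 − viability`, clipped to [0, 1]. Relative AUC divides the trapezoid area
of viability over log10 dose by the area of a constant-1 non-responder over
the same dose range (×100) — the only normalization under which a
completely resistant line scores exactly 100%. Zero doses have no log
coordinate and are excluded from the axis.

Monotherapy curves are 4-parameter log-logistic,
`y = lower + (upper−lower)/(1+(EC50/x)^slope)`, fitted by bounded least
squares over a deterministic multi-start grid (slopes {0.5, 1, 2, 4} ×
three log-EC50 starts; EC50 bounded to the dose range ×[10⁻², 10²];
asymptotes in [0, 1]; EC50 parameterized in log space). A constant response
short-circuits to a flagged fixed-effect fallback; a response that
*decreases* with dose is treated as viability passed by mistake and flipped
with a warning.

ZIP synergy: the independence expectation at dose pair (a, b) is
`y_A(a) + y_B(b) − y_A(a)·y_B(b)` from the fitted monotherapy curves. Each
combination row (fixed b) is refitted along a with the lower asymptote
fixed at `y_B(b)` and the upper asymptote free in `[y_B(b), 1]` — the
potency-shift idea — and symmetrically for columns; the delta surface is
the mean of the two directional refits minus the expectation, defined on
the 5×5 nonzero-dose grid. The plate summary is the mean of the nine
highest deltas (a contiguous most-synergistic 3×3 window is available as
an option). Note the top-9 statistic is positively biased under a noisy
null by construction (it selects extremes); at noise SD 0.02 the bias is
≈ +0.015, which the test suite bounds via the across-seed mean.

3-D stacks (a third drug at one fixed dose per plate, all normalized to the
global DMSO control): the layer's double-DMSO well reads the third drug's
own inhibition y_C, the A/B monotherapy rows are deflated by
`(y − y_C)/(1 − y_C)` before fitting, the expectation becomes
`1 − (1−y_A)(1−y_B)(1−y_C)`, and the refit floors fold y_C in the same
way. With an inert third drug every layer reduces exactly to the 2-D score.

## Synthetic data: what it does and does not show

The generator emulates multi-region WES at the study's stated working
point — 150 mutations per clone, purity 0.7, mean depth 150×, diploid CN —
with Poisson depth and binomial alt counts, and mutations absent from a
biopsy emitted at zero alt reads (so the covered-absent/missing distinction
is exercised). Dose-response plates use 6×6 grids with five 4-fold
dilutions from 300 nM and 100 nM tops (the assay's starting doses; the
dilution factor itself is a generator choice), log-logistic monotherapies
with Emax 1 by default, Bliss-independent combinations plus an optional
injected interaction, and Gaussian well noise. The mutation count per clone
is an artifact choice (none is dictated by any cohort); 150 per clone gives
cluster standard errors ≈ 0.01, comfortably inside every tolerance used.

Not modeled: sequencing error, strand bias, germline contamination, FFPE
artifacts, subclonal copy number, inter-assay plate drift. Passing tests
therefore demonstrate correctness of the estimators under their own noise
model, not robustness to real-data artifacts — the force-rooted-cluster
fallback and the missing-data contracts are the hooks where real data will
exercise paths the synthetic benchmarks do not.

## Determinism and problem sizes

All randomness flows through explicit integer seeds (per-biopsy substreams
are spawned from a root seed sequence). Fixed seed + config reproduces
byte-identical output bundles, and every output table carries the config
hash in a header comment. Test and benchmark sizes — 750-mutation
scenarios, 20-seed synergy panels, 50-seed topology-recovery panels — were
chosen so the full suite exercises every claim at standard-error levels an
order of magnitude below the asserted tolerances.
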