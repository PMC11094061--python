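# Methods

## The two-segment coverage model

A gene with one proximal (pPAS) and one distal (dPAS) cleavage site
expresses a mixture of a short and a long 3′UTR isoform. Both isoforms
cover the UTR 5′ of the proximal site; only the long isoform covers the
region between pPAS and dPAS. Expected per-base read depth in transcript
orientation is therefore a two-segment step function

    depth(x) = w_L + w_S · 1[x < b],

with `w_L, w_S ≥ 0` the isoform abundances (RPM units after
normalization) and `b` the proximal cleavage position. The percentage
of distal polyA-site usage is `PDUI = 100 · w_L / (w_L + w_S)`.

**Fitting.** For each candidate breakpoint the non-negative
least-squares solution is closed form: `w_L` is the downstream segment
mean and `w_S` the upstream−downstream mean difference; if that
difference is negative, `w_S` clamps to 0 and the remaining free
parameter refits to the overall mean (the flat model). Residuals for
all candidate breakpoints are computed at once from prefix sums, and
the breakpoint minimizing the total residual across *all* samples of a
gene is selected — a single shared proximal site per gene, matching the
one-event model, and borrowing strength across conditions and
replicates. Abundances and PDUI are then reported per sample at the
chosen breakpoint.

**Numerical choices.**

- Search range `[search_min, L − search_min]` with `search_min` =
  100 nt: forbids degenerate edge breakpoints on which the two-segment
  model is unidentifiable.
- Ties in the residual resolve to the most distal breakpoint. This is
  deterministic and, because a more distal breakpoint implies a longer
  "both isoforms" segment, biases against calling spurious shortening.
- `min_mean_depth` = 1 (RPM-scale units): genes where no sample reaches
  this mean coverage are flagged `low_coverage` and not fitted.
- `min_fit_gain` = 0.05: if the best two-segment fit does not reduce
  the flat-fit residual by at least 5%, the gene is flagged
  `no_breakpoint` (values are still reported — a uniformly covered gene
  legitimately has PDUI 100).
- All-zero samples yield `w_L + w_S = 0` and an undefined (NaN) PDUI
  rather than an arbitrary number.

## Event testing and calling

For a stimulated-vs-reference comparison, `dPDUI` is the difference of
group mean PDUIs. The default significance test is Fisher's exact test
on the 2×2 table of pooled, rounded `Σw_L` / `Σw_S` per group. With
three replicates per group a replicate-level test has almost no power
and poorly behaved p-values; the pooled exact test is well defined at
any replicate count and is conservative in the presence of
between-replicate PDUI variability (verified on no-effect simulations:
the realized false-positive rate is far below nominal). A Welch t-test
on per-replicate PDUI is exposed as `test_method="welch"` so the choice
is auditable. With fewer than two samples in a group, p = 1 is reported
alongside the dPDUI.

Benjamini–Hochberg adjustment is applied within each comparison batch.
Calls: shortened (dPDUI ≤ −20, adjusted p < 0.05), lengthened
(dPDUI ≥ +20, adjusted p < 0.05), non-changing (|dPDUI| < 3 and raw
p > 0.05), otherwise indeterminate. The non-changing rule deliberately
uses the raw p-value: it is an acceptance band for "confidently
unchanged", not a discovery threshold.

## Classification

- **Basal bins** at 33/66: `long` strictly above 66 (genes
  predominantly expressing the long 3′UTR at baseline), `short`
  strictly below 33, `mid` otherwise. Only the >66 cut is used as a
  headline statement; 33 symmetrically completes the tertiles.
- **Temporal classes** are strict: `48h_only` requires a significant
  late call *and* a non-changing early call (an indeterminate early
  call goes to `other`), and symmetrically for `8h_only`. Every gene
  gets exactly one label.
- **Costimulation enhancement**: ratio = |dPDUI(CD3/CD28)| /
  max(|dPDUI(CD3)|, 1), over events significant under costimulation;
  ratio > 2 flags enhancement. The 1-point floor prevents near-zero
  CD3 effects from exploding the ratio. Sign-discordant pairs
  (shortening under one stimulus, lengthening under the other) are
  flagged and excluded from interpretation rather than silently folded
  into an absolute ratio.
- **Correlation** between conditions uses Pearson r plus OLS slope,
  on the union of events significant in either condition by default
  (`correlation_set="intersection"` restricts to both).

## Motif analysis

Windows are extracted in transcript orientation around the fitted
proximal breakpoint and the annotated distal site, with DNA `T`
transliterated to `U` (defaults: 200 nt upstream, 120 nt downstream —
the downstream flank covers a (−100, +100) offset span plus the 10-nt
sliding window). PAS strength is the presence of the core hexamer
AAUAAA or the CFI element UGUA within 100 nt strictly upstream of the
cleavage position.

Positional maps report, for each offset o (0 = cleavage position,
advancing 1 nt at a time), the fraction of events whose 10-nt window
[o, o+10) contains at least one exact occurrence of the target hexamer
(AAUAUA, the RBM3 binding motif, by default). Occurrences equal to the
core PAS hexamer are excluded — a no-op for the literal AAUAUA target
but meaningful if users supply degenerate motifs. An event counts once
per offset regardless of multiple matches; matching is exact substring
matching (the motifs of interest are literal hexamers, so no
position-weight matrix is involved). Smoothing is a centered running
mean of 5 offsets with shrinking edge windows, which preserves the
span instead of truncating it. A requested span wider than the
available windows is evaluated on the intersection and flagged.

## Enrichment

Overlap of a query gene set with an annotation set is tested with the
exact hypergeometric upper tail (including the observed count),
identical to a one-sided Fisher test; fold enrichment is
`(overlap/query) / (set/background)` and the standard filter is
p < 0.05 with fold > 2. The recommended background is the set of genes
with a clean (`qc_flag = ok`) PDUI fit — the genes assessable for APA —
because a whole-genome background would inflate enrichment of any
expression-linked set. BH adjustment runs across annotation sets within
each query.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded for every gene:

- **Design**: five conditions (naive reference, CD3 and CD3/CD28 at
  8 h and 48 h) with three replicates — structurally isomorphic to a
  three-donor stimulation time course. Any condition list works; labels
  containing "48" act as the late time point, "8" as the early one, and
  "CD28" as costimulated.
- **Regimes**: `frac_shortened` = 0.6 of genes shorten upon stimulation
  and `frac_lengthened` = 0.1 lengthen (activation-induced APA is
  dominated by shortening), the rest are unchanged. To-be-shortened
  genes draw basal PDUI from Uniform(66, 100) — genes that shorten
  start out predominantly long — lengthened genes from Uniform(0, 34),
  unchanged genes from Uniform(10, 90). Effect sizes draw from
  Uniform(25, 55) so planted changes clearly exceed the 20-point
  calling threshold; `frac_early` = 0.4 of changing genes change
  already at 8 h, the rest only at 48 h.
- **Costimulation**: `frac_cd28_enhanced` = 0.3 of changing genes get a
  2.5-fold larger dPDUI under CD3/CD28. For those genes the CD3 effect
  is drawn so the amplified effect still fits inside [0, 100]; without
  this constraint boundary truncation would silently destroy the
  planted ratio.
- **Coverage**: expected depth follows the two-segment model at
  `mean_depth` = 30 reads/base; replicate-level PDUI adds
  truncated-normal jitter (`replicate_pdui_sd` = 5 points — a free
  choice, as donor-to-donor PDUI variability is not well characterized;
  parameter-recovery checks use 3). Count noise is Poisson by default,
  negative-binomial on request, or disabled for exact checks. Simulated
  depths are written on the reads-per-million scale directly, so the
  emitted manifest lists 1e6 mapped reads per sample and RPM
  normalization is the identity for synthetic data.
- **Sequence**: uniform A/C/G/T background per gene (UTR + 120-nt
  flank), written on the genomic strand (minus-strand genes
  reverse-complemented, and their coverage reversed, so strand handling
  is exercised for real). AAUAAA is planted within 100 nt upstream of
  each cleavage site with probability `pas_fidelity_p` (0.4) at the
  proximal and `pas_fidelity_d` (0.9) at the distal site — proximal
  sites are typically weaker; otherwise a scrambled permutation is
  planted, with its flanking context scrubbed so no accidental
  consensus arises at the site. For `frac_rbm3` = 0.8 of
  early-shortening genes an AAUAUA is planted entirely within ±25 nt of
  the distal site (the proposed mechanism: RBM3 binding over the distal
  PAS suppresses its use early after activation).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artifacts (fragment-length
bias, mappability, internal priming), more than two isoforms per gene,
intronic PAS, non-uniform background sequence composition,
donor-paired correlation structure across conditions, and
expression–APA coupling. Recovery results on synthetic data are
best-case statements about the estimator, not about any particular
RNA-seq dataset; headline event counts from real T-cell data are not
reproducible at this scale and are not targeted.

## Problem sizes used in the checks

Acceptance-style checks run at desk scale, chosen to keep the whole
suite in the order of a minute while leaving binomial error bands
tight enough to be meaningful: definitional limits on a single
noiseless 1 kb gene; breakpoint-oracle equivalence on 50 genes;
parameter recovery on 200 genes × 15 samples (PDUI RMSE < 5 points,
median breakpoint error ≤ 20 nt); costimulation-enhancement recovery
on 500 genes; PAS-fidelity recovery on 500 genes; motif-map planted
signal on 100 genes per group; type-I control on 1000 genes.

## Known limitations

- The breakpoint is shared across all samples of a gene; a genuine
  condition-specific proximal-site switch (different pPAS positions,
  not different usage) would be averaged over.
- Fisher's test on pooled abundances treats replicate variability as
  sampling noise; it is conservative rather than calibrated, so raw
  p-values should not be interpreted as exact tail probabilities.
- The two-segment model fits only one internal breakpoint; genes with
  several tandem PAS report a compromise site.
- bedGraph parsing assumes non-overlapping intervals per sample track
  (later intervals overwrite earlier ones at shared positions).
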