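# apashift

Alternative-polyadenylation (APA) analysis of 3′UTR coverage: de-novo
proximal polyadenylation-site estimation and PDUI quantification, APA
event calling with temporal and costimulation-dependent classification,
polyadenylation-signal and RBM3-motif positional analysis, and gene-set
overlap enrichment — plus a synthetic-data generator with known ground
truth, so the whole pipeline is testable without any downloads.

It is aimed at transcriptomics analysts studying 3′UTR shortening and
lengthening in stimulus-response settings (the built-in study design
mirrors T-cell activation: a naive reference plus CD3 or CD3/CD28
stimulation at 8 h and 48 h, three donors each).

## The model

Per-base coverage of a two-isoform 3′UTR is modelled as a two-segment
function of transcript position *x*:

```
depth(x) ≈ w_L + w_S · 1[x < b]
```

where `w_L` ≥ 0 is the abundance of the long (distal) isoform, `w_S` ≥ 0
the abundance of the short (proximal) isoform and `b` the breakpoint —
the de-novo proximal cleavage site. For fixed `b` the non-negative
least-squares solution is closed form (segment means, clamped at zero);
`b` is chosen to minimize the residual sum of squares jointly over all
samples of a gene. Per sample,

```
PDUI = 100 · w_L / (w_L + w_S)
```

is the percentage of distal polyA-site usage: 100 when every transcript
reaches the distal site (uniform coverage), 0 when every transcript stops
at the proximal site (a step to zero at `b`).

For a pairwise comparison, `dPDUI = mean PDUI(stim) − mean PDUI(ref)`;
events are called **shortened** (dPDUI ≤ −20, BH-adjusted p < 0.05),
**lengthened** (dPDUI ≥ +20, adjusted p < 0.05), **non-changing**
(|dPDUI| < 3, raw p > 0.05) or **indeterminate**. Significance comes
from Fisher's exact test on pooled long/short abundances (a Welch
t-test on per-replicate PDUI is available as an alternative).
Downstream classification covers basal PDUI tertiles (long > 66),
temporal classes (8 h-only / 48 h-only / both), costimulation
enhancement (|dPDUI| ratio > 2 with a 1-point floor), motif maps
(10-nt sliding window, 5-offset running mean) and hypergeometric
overlap enrichment (p < 0.05, fold > 2).

## Worked example

Run the full synthetic pipeline (simulate → quantify → call → classify
→ motifs → enrich) on 40 genes:

```python
from apashift.config import RunConfig, SimConfig
from apashift.pipeline import run_pipeline

cfg = RunConfig(sim=SimConfig(n_genes=40, seed=5), outdir="demo", seed=5)
run_pipeline(cfg)
```

`demo/summary.tsv` then contains (excerpt):

```
                   metric     value
      n_shortened_CD3_48h 23.000000
     n_lengthened_CD3_48h  4.000000
       n_shortened_CD3_8h  9.000000
    temporal_CD3_48h_only 12.000000
        temporal_CD3_both 10.000000
   cd28_enhanced_frac_48h  0.333333
            pearson_r_48h  0.838648
     regression_slope_48h  1.123782
```

Reading: of 40 genes, 23 are called significantly shortened and 4
lengthened at 48 h of CD3 stimulation (the generator plants 60%
shortened / 10% lengthened); 12 genes shorten only at 48 h while 10
change at both time points; a third of significant events show a
more-than-2-fold larger dPDUI under CD3/CD28 costimulation (30% is
planted); and dPDUIs under the two stimuli correlate with a regression
slope near 1. `demo/enrichment.tsv` shows the genes shortened at 8 h
strongly enriched for the planted RBM3-motif set
(fold = 3.9, p = 1.5e-05), while the 48 h set is not — the planted
motif marks early-shortening genes only.

The same stages are available from the shell:

```sh
apashift simulate --outdir demo/sim --seed 5 --n-genes 40
apashift quantify --bed demo/sim/utr.bed --manifest demo/sim/manifest.tsv --out fits.tsv
apashift call --fits fits.tsv --ref naive --stim CD3_48h --out events.tsv
apashift run --config run.yaml
```

## Layout

```
src/apashift/
  simulate.py    synthetic two-isoform datasets with planted truth
  coverage.py    BED/bedGraph I/O, RPM normalization, replicate averaging
  quant.py       two-segment breakpoint fit, PDUI, event testing/calling
  events.py      direction/basal/temporal/CD28 classification, correlation
  motifs.py      PAS windows, signal presence, positional motif maps
  enrichment.py  hypergeometric overlap tests with BH adjustment
  pipeline.py    stage orchestration with manifest + checksums
  cli.py         `apashift` command-line entry points
docs/methods.md  model, assumptions, parameter choices, limitations
```
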