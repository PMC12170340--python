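# polkinetics

Kinetics of promoter-proximal RNA polymerase II from stranded,
base-resolution nascent-transcription signals.

RNA Pol II pauses 30–100 bp downstream of the transcription start site
before either releasing into productive elongation or terminating
prematurely. Whether, and how much, promoter-proximal *termination* is used
to regulate genes is invisible to any single assay: occupancy profiling
shows how much polymerase sits in the pause region, but not how fast it
turns over or where it goes. `polkinetics` implements the multiomics kinetic
framework that resolves this by combining three signal types per gene:

| assay | signal | quantity |
|---|---|---|
| TT-seq | coverage of newly synthesized RNA | productive initiation frequency `I` |
| mNET-seq | nascent-RNA 3′-end counts (Pol II position) | pause site, pause-window occupancy `PWcov` |
| ChIP-nexus | Pol II occupancy during an initiation block (triptolide) | clearance rate `k` of paused Pol II |

From these it estimates, per gene and time point (all in arbitrary units,
a.u.):

- **productive initiation frequency** `I_g = cov_g / L_g`, TT-seq coverage
  over non-first exons (or TSS+300 → pA for single-exon genes) divided by
  their length;
- **apparent pause duration** `d_g = PWcov_g / I_g`, the mNET-seq signal in
  a 200 bp window around the pause site relative to `I` — an *apparent*
  duration because frequent termination inflates it above the
  single-molecule pause time;
- **promoter-proximal half-life** from the exponential fit
  `p(t) = p0 · e^(−kt)` to spike-in-normalized ChIP-nexus coverage at the
  pause site ±20 bp after initiation inhibition, `t½ = ln2 / k`;
- **total turnover rate** `r = −ln2 · p0 / t½` (so `|r| = p0·k`), the rate
  at which Pol II leaves the pause region by release *plus* termination;
- **termination fraction** `1 − I/|r|` and its complement, the productive
  elongation fraction `I/|r|`.

Cohort-level analyses build on the per-gene kinetics: temporal
classification of synthesis trajectories (downregulated / bending /
peaking / upregulated), bootstrapped consensus k-means subclustering of the
upregulated genes on their `(I, d)` trajectories, quantile summaries,
scaled TSS→pA metagene profiles with 95% CIs, and two-sided
Kolmogorov–Smirnov group contrasts.

A first-class synthetic-data module (`polkinetics.synth`) generates every
input the pipeline consumes — annotation, isoform TPMs, stranded bedGraph
signal tracks, spike-in totals — from known ground-truth kinetics, so each
estimator is validated by parameter recovery rather than by fixture
snapshots.

## Worked example

`examples/01_simulate_and_recover.py` simulates 60 genes without noise,
runs the full pipeline, and compares estimates to the generating truth:

```
genes with a major isoform: 57
genes with stable pause sites: 55

gene        class     I_0h (est/true)   t1/2 0h min (est/true)  termination 0h (est/true)
G00001    stable     0.613/0.613        9.16/9.16            0.485/0.485
G00002     pre-B     0.789/0.789        5.28/5.28            0.235/0.235
G00003   peaking     0.543/0.543        5.06/5.06            0.401/0.401

max relative error, productive initiation I: 2.04e-16
max relative error, Pol II half-life t1/2:   3.45e-16
```

Machine-precision agreement on noise-free input means the estimators
exactly invert the generator's forward model — normalization, pause
calling, windowing and curve fitting are mutually consistent. The other
examples show pause-site calling (`02`), a single-gene decay fit with its
turnover and termination numbers (`03`), and the cohort classification
with group contrasts (`04`). On Poisson-noise cohorts the signatures of the
two regulatory strategies appear exactly as designed: downregulated genes
lose `I` and gain termination at unchanged `t½`, while upregulated genes
split into a turnover-driven and a termination-release cluster.

There is also a thin CLI mirroring the library stages
(`simulate → annotate → quantify → pause → decay → cohort → report`):

```sh
polkinetics all --config examples/pipeline.yaml --out run/
```

Every stage writes TSVs plus a JSON manifest (hashed inputs, parameters),
and reruns are byte-identical for a fixed seed.

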