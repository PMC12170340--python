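# Methods

## The kinetic model

Each gene's promoter-proximal region is treated as a single compartment fed
by transcription initiation at total rate `r` (polymerases entering per
unit time) and drained by two routes: release into productive elongation,
at rate `I`, and premature termination, at rate `r − I`. At steady state
the compartment holds

    p0 = r · t½ / ln2

polymerases, where `t½` is the half-life of promoter-proximal Pol II. When
initiation is blocked (triptolide inhibits TFIIH/XPB within minutes), the
occupancy decays as `p(t) = p0 · e^(−kt)` with `k = ln2/t½`, regardless of
which exit route dominates — the fit therefore measures the *total*
turnover rate

    r = −ln2 · p0 / t½    (reported as |r| = p0 · k).

TT-seq measures newly made RNA in gene bodies and yields the productive
initiation frequency `I = cov/L` — only polymerases that actually left the
pause region contribute. The ratio `I/|r|` is then the productive
elongation fraction and

    termination fraction = 1 − I/|r|.

The apparent pause duration `d = PWcov/I` (promoter-proximal mNET-seq
signal over `I`) overestimates the single-molecule pause time by the
factor `1/(1 − f)` when a fraction `f` of polymerases terminates: in the
model, `d ∝ p0/I = t½ / (ln2 · (1 − f))`. That inflation is the readout
that makes `d` informative about termination-driven regulation even
without the inhibition time course.

Assumptions: one well-mixed promoter-proximal compartment per gene with
first-order exit; steady state at the moment of inhibition; DMSO controls
represent that steady state and enter the fit at `t = 0`; initiation stops
instantly at triptolide addition; no Pol II degradation on the time scale
of the treatment (minutes).

### Units and calibration

`I` (TT-seq scale) and `|r|` (ChIP-nexus scale) are each known only up to
an assay proportionality constant, so on real data `1 − I/|r|` is a
*relative* termination measure: differences and ranks across genes and
conditions are meaningful, absolute values are not. The synthetic
generator's *unit* calibration sets every constant to 1, making the
fraction numerically equal to the generating `f` — this is what the exact
round-trip tests exploit. When assay depths differ by a factor `c`, the
estimate becomes `1 − c·(1−f)`: a strictly monotone transform of `f`, so
rank correlations and two-sample KS statistics are unaffected.

## Estimators and thresholds

All coordinates are 0-based half-open; `tss`/`pa` are boundary coordinates
of the transcription unit (span start/end on `+`, reversed on `−`), and
"downstream" follows transcription direction.

| step | rule | default |
|---|---|---|
| major isoform | share of per-time-point mean TPM strictly > threshold at ≥1 time point, and no competing isoform qualifying at any time point | 0.70 |
| excluded chromosomes | genes dropped | chrM |
| read retention | signal masked outside major isoform ± flank | 500 bp |
| expressed genes | reads per kilobase at ≥1 time point | ≥ 10 |
| antisense ratio | Σ antisense / Σ sense at positions without antisense annotation and sense coverage ≥ threshold | 100 |
| antisense correction | 2×2 mixing inversion `obs_s = true_s + c·true_a`, `obs_a = true_a + c·true_s`; negatives clamped to 0 (logged) | — |
| size factors | median-of-ratios over genes positive in all samples, renormalized to geometric mean 1 | — |
| pause search | window downstream of TSS | 250 bp |
| pause call | window max ≥ fold × median of nonzero values (inclusive); ties → 5′-most | fold = 5 |
| pause stability | sample s.d. of detected offsets across time points; single detection counts as stable | ≤ 75 bp |
| consensus offset | call at the time point with the largest peak (ties → earliest) | — |
| pause window (d) | consensus ± halfwidth, clipped at the TSS only | 100 bp |
| half-life window | consensus ± halfwidth, inclusive (41 bases), both strands | 20 bp |
| decay eligibility | excluded if any condition mean is 0, or if final-inhibition-time coverage ≥ control mean | — |
| DE gate | external calls (\|FC\| > 1.5, padj < 0.05) or fold-change-only fallback | 1.5 / 0.05 |
| subclustering | bootstrapped consensus k-means on z-scored log2 `(I_t, d_t)` | k = 2, B = 100 |
| metagene | TSS→pA interval-mean pooling; CI = mean ± 1.96·sd/√n | 100 bins |

Numerical choices worth noting:

- The decay fit minimizes untransformed squared residuals after a
  log-linear initialization; pure log-space fitting over-weights small late
  counts under Poisson noise. `k` is bounded at 0; `k̂ < 1e−10` is flagged
  `degenerate_flat` with `t½ = +∞` and `r = 0`. On values lying exactly on
  an exponential the initialization is already exact and the refinement
  preserves it to ≲1e−9 relative for `t½ ∈ [1, 60]` min.
- `p0` used in the turnover formula is the fitted intercept, for
  consistency with the fitted model, not the raw control mean.
- Median of nonzero window values uses the midpoint convention for even
  counts.
- Antisense correction is linear, so applying it per base or to window
  sums is equivalent except for the clamp at zero; the implementation
  corrects the replicate-normalized windows and counts and clamps last.
- Quantile bins are rank-based with stable tie order; an all-equal vector
  collapses to bin 1 with a warning.
- A ratio fitting mode (`R(t) = TRP(t)/DMSO`, `R(0) ≡ 1`) is available as
  an alternative to absolute coverages with DMSO at `t = 0`; on noiseless
  data both give identical half-lives.

Open design points resolved here (the source analyses leave them
unspecified): the pause-anchoring time point (we use the maximal-peak time
point), the bending/peaking disambiguation (interior extremum with the
larger relative excursion from the terminal baseline; exact ties are
unclassified), the stability s.d. computed over detected time points only,
and the feature scaling for clustering (log2 then per-feature z-score, so
the dynamic range of `I` cannot dominate `d`).

## The synthetic-data generator

`polkinetics.synth` emulates the statistical structure the estimators
assume, with per-gene ground truth `(r_t, f_t, t½_t)` over the time course
`{0, 12, 24, 72, 96 h}` and derived `I_t = r_t(1−f_t)`,
`p0_t = r_t·t½_t/ln2` (identities held to 1e−12 and checked):

- **Temporal classes** shape the trajectories: `pre-B` (downregulated:
  `f` rises ~0.2 → ~0.8 at constant `r` and `t½` — termination-driven
  shutdown whose median `I` fold change comes out near 0.25), `bending`
  and `peaking` (interior extremum of `r`), `iMac-I` (release-driven
  upregulation: `r` up ~4×, low flat `f`), `iMac-II` (termination-driven
  upregulation: `r` up ~3×, `f` falls ~0.65 → ~0.3, `t½` falls ~40%), and
  a constant `stable` majority (55% of genes by default; the
  differentially expressed classes follow the ratio 938:316:487:193:223).
  A majority of unchanged genes is also what makes median-of-ratios size
  factors well-posed across a time course.
- **Gene-level variation**: `r0` log-normal (σ = 0.35), `t½` log-normal
  around 7.5 min clipped to [3, 25] — cohort medians land near 7.5 min —
  and class-specific `f` draws spanning ~0.1–0.85 so termination ranks are
  identifiable.
- **TT-seq**: expected sense coverage `depth · I_t` at every exonic base.
- **mNET-seq**: a symmetric triangular peak of half-width `w` (default
  2 bp; the peak's true spatial spread is a free parameter, not an
  inferred quantity) carrying mass `p0_t` at the pause site, over a
  uniform gene-body density `body_density · I_t` per base (default 0.005 —
  Pol II transits the body much faster than it dwells at the pause).
  Genes flagged undetectable get their peak scaled so the window maximum
  sits below the 5× rule.
- **ChIP-nexus**: peak-shaped signal with expectation
  `p0_t · e^(−ln2·τ/t½)` for triptolide at inhibition time τ (defaults 6
  and 30 min) and `p0_t` for DMSO, two replicates each, at the first and
  last profiled time points; spike-in totals encode the true per-sample
  scale factors. No antisense leak is applied to ChIP-nexus: the antisense
  bias being corrected is a reverse-transcription artifact of the
  RNA-based assays, and ChIP is DNA-based.
- **Noise**: none (exact expectations) or per-base Poisson, with optional
  gamma-Poisson overdispersion; a mirrored antisense leak (default ratio
  0.1) is added to both RNA assays. *Arbitrary* calibration multiplies
  each assay by a hidden constant and varies per-sample depths to exercise
  "up to a proportionality constant" behaviour.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level artifacts (mappability, PCR
duplicates, fragment-length and GC bias), overlapping or bidirectional
transcription units, enhancer RNAs, the upstream PIC-site signal shift
after triptolide (available only as a cosmetic constant), multimodal or
drifting pause positions, cell-to-cell heterogeneity, and deviations from
first-order clearance. Recovery results certify the *estimators given the
model*, not the model given biology.

## Problem sizes

Defaults are sized for interactive runs and CI: the noiseless round-trip
uses 200 genes (machine-precision recovery, seconds), the Poisson cohort
500 genes at depths chosen so expected ChIP-nexus window counts are ≥ 200
(the regime where the exponential fit is well-conditioned; ~1 min), and
clustering checks use 80 trajectories. All sizes scale linearly and are
plain function arguments.

## Known limitations

- The termination fraction is relative outside calibrated simulation; raw
  values can leave [0, 1] when assay constants differ (a clamp mode
  exists, off by default).
- With only two inhibition times plus controls, the exponential fit has
  little redundancy; genes with `t½` far outside the sampled range (≪ 6 or
  ≫ 30 min) are poorly constrained and surface as outliers or
  `degenerate_flat`.
- The fold-change-only DE fallback has no error control; supply external
  DE calls (any count-model tool) for inference-grade gating.
- The bending/peaking rule and the consensus-clustering variant are
  reasonable standard choices, not uniquely determined by the source
  analyses; alternatives could shift borderline genes between classes.
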