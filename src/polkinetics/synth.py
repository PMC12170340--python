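"""Synthetic cohorts with known promoter-proximal Pol II kinetics.

The generator emits every input the estimation pipeline consumes —
annotation, isoform TPMs, TT-seq coverage, mNET-seq 3'-end counts, a
ChIP-nexus initiation-inhibition time course and spike-in totals — from a
ground-truth kinetic parameterization, so each estimator is testable by
parameter recovery.

Ground-truth model (per gene, per time point ``t``):

* ``r_t``    — total initiation rate (events/min): polymerases entering the
  promoter-proximal region per unit time,
* ``f_t``    — termination fraction in [0, 1]: share of those polymerases
  that terminate prematurely instead of entering productive elongation,
* ``t½_t``   — promoter-proximal Pol II half-life (min) under an
  initiation block,
* derived ``I_t = r_t * (1 - f_t)`` — productive initiation frequency,
* derived ``p0_t = r_t * t½_t / ln2`` — steady-state promoter-proximal
  occupancy (so that the turnover rate ``ln2 * p0 / t½`` equals ``r``).

Temporal classes shape the trajectories of ``r`` and ``f`` over the
transdifferentiation time course: downregulated genes (``pre-B``) keep ``r``
constant while ``f`` rises; one class of upregulated genes (``iMac-I``)
raises ``r`` at constant ``f``; the other (``iMac-II``) raises ``r`` while
``f`` and ``t½`` fall; ``bending``/``peaking`` genes carry an interior
extremum of ``r``; ``stable`` genes change nothing.

In *unit* calibration every assay's proportionality constant is 1, so the
pipeline's arbitrary-unit estimates coincide numerically with the truth;
*arbitrary* calibration multiplies each assay by a hidden constant to
exercise "up to a proportionality constant" behaviour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .errors import InvalidConfigError
from .signal import StrandedBaseSignal

LN2 = float(np.log(2.0))

TEMPORAL_CLASSES = ("stable", "pre-B", "bending", "peaking", "iMac-I", "iMac-II")

#: differentially expressed classes in the cohort ratio 938:316:487:193:223,
#: scaled into the non-stable share of the cohort
_DE_RATIO = {"pre-B": 938, "bending": 316, "peaking": 487, "iMac-I": 193, "iMac-II": 223}


def default_class_proportions(stable_fraction: float = 0.55) -> dict[str, float]:
    de_total = sum(_DE_RATIO.values())
    props = {
        cls: (1.0 - stable_fraction) * n / de_total for cls, n in _DE_RATIO.items()
    }
    props["stable"] = stable_fraction
    return props


@dataclass
class SimConfig:
    """Study design and noise model of a synthetic cohort.

    Depth scalars multiply each assay's expected signal; ``body_density``
    (occupancy per bp per unit I) sets the mNET-seq gene-body level relative
    to the promoter-proximal peak.  ``seed`` fixes all randomness end-to-end.
    """

    n_genes: int = 200
    seed: int = 0
    time_points_h: tuple[int, ...] = (0, 12, 24, 72, 96)
    nexus_time_points_h: tuple[int, ...] = (0, 96)
    inhibition_times_min: tuple[float, ...] = (0.0, 6.0, 30.0)
    n_replicates: int = 2
    noise: str = "none"  # none | poisson
    nb_dispersion: float = 0.0  # gamma-Poisson overdispersion, 0 = pure Poisson
    calibration: str = "unit"  # unit | arbitrary
    tt_depth: float = 1.0
    mnet_depth: float = 1.0
    nexus_depth: float = 1.0
    body_density: float = 0.005
    peak_halfwidth: int = 2
    antisense_ratio: float = 0.1
    pic_level: float = 0.0
    spike_base_total: float = 1e5
    class_proportions: dict[str, float] | None = None
    undetectable_fraction: float = 0.05
    conflict_fraction: float = 0.05
    single_exon_fraction: float = 0.1
    single_isoform_fraction: float = 0.3

    def __post_init__(self):
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        for name in ("tt_depth", "mnet_depth", "nexus_depth"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if 0.0 not in self.inhibition_times_min:
            raise InvalidConfigError("inhibition_times_min must include 0")
        if self.noise not in ("none", "poisson"):
            raise InvalidConfigError(f"unknown noise model {self.noise!r}")
        if self.calibration not in ("unit", "arbitrary"):
            raise InvalidConfigError(f"unknown calibration {self.calibration!r}")
        if not 0 <= self.antisense_ratio < 0.5:
            raise InvalidConfigError("antisense_ratio must be in [0, 0.5)")
        if self.class_proportions is None:
            self.class_proportions = default_class_proportions()
        unknown = set(self.class_proportions) - set(TEMPORAL_CLASSES)
        if unknown:
            raise InvalidConfigError(f"unknown temporal classes {unknown}")

    @property
    def triptolide_times(self) -> tuple[float, ...]:
        return tuple(t for t in self.inhibition_times_min if t > 0)


class SimTruth:
    """Ground-truth table of a simulated cohort.

    ``df`` has one row per gene with geometry, flags and per-time-point
    kinetic parameters in columns ``r_{t}``, ``f_{t}``, ``thalf_{t}``,
    ``I_{t}``, ``p0_{t}`` (t in hours).
    """

    def __init__(self, df: pd.DataFrame, config: SimConfig):
        self.df = df.set_index("gene_id", drop=False)
        self.config = config

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    def exons(self, gene_id: str) -> tuple[tuple[int, int], ...]:
        return tuple(
            tuple(int(x) for x in part.split("-"))
            for part in self.df.loc[gene_id, "exons"].split(",")
        )

    def param(self, name: str, t: int) -> pd.Series:
        return self.df[f"{name}_{t}"]

    def validate(self) -> None:
        """Check the self-consistency identities of the model."""
        for t in self.config.time_points_h:
            r, f = self.param("r", t), self.param("f", t)
            thalf, I, p0 = self.param("thalf", t), self.param("I", t), self.param("p0", t)
            assert ((f >= 0) & (f <= 1)).all()
            assert (thalf > 0).all()
            np.testing.assert_allclose(I, r * (1 - f), rtol=1e-12)
            np.testing.assert_allclose(p0 * LN2 / thalf, r, rtol=1e-12)


# --------------------------------------------------------------------------
# truth
# --------------------------------------------------------------------------

def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), *stream])


def _class_counts(config: SimConfig) -> list[str]:
    """Deterministic class assignment honoring the configured proportions."""
    props = config.class_proportions
    classes = [c for c in TEMPORAL_CLASSES if props.get(c, 0) > 0]
    weights = np.array([props[c] for c in classes], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * config.n_genes).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = config.n_genes - counts.sum()
    frac = weights * config.n_genes - counts
    for i in np.argsort(-frac)[:rem]:
        counts[i] += 1
    labels = [c for c, n in zip(classes, counts) for _ in range(n)]
    return labels


# trajectory shapes over the 5 canonical time points (scaled by t/96 otherwise)
_R_SHAPES = {
    "stable": (1.0, 1.0, 1.0, 1.0, 1.0),
    "pre-B": (1.0, 1.0, 1.0, 1.0, 1.0),
    "bending": (1.0, 0.65, 0.45, 0.8, 1.05),
    "peaking": (1.0, 2.1, 2.5, 1.5, 1.2),
    "iMac-I": (1.0, 1.5, 2.2, 3.2, 4.2),
    "iMac-II": (1.0, 1.3, 1.8, 2.4, 3.0),
}


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-gene geometry and kinetic trajectories. Deterministic by seed."""
    rng = _rng(config, 1)
    n = config.n_genes
    times = np.asarray(config.time_points_h, dtype=float)
    tfrac = times / times.max() if times.max() > 0 else times
    labels = _class_counts(config)
    rng.shuffle(labels)

    records = []
    cursor = 1000  # leading margin on the synthetic chromosome
    for i in range(n):
        gid = f"G{i:05d}"
        cls = labels[i]
        strand = "+" if rng.random() < 0.5 else "-"
        single = rng.random() < config.single_exon_fraction

        # ---- geometry (genomic-ascending exon coordinates)
        if single:
            glen = int(rng.integers(1800, 5000))
            exon_lens, intron_lens = [glen], []
        else:
            n_exons = int(rng.integers(2, 4))
            exon_lens = [int(rng.integers(320, 600))] + [
                int(rng.integers(800, 2500)) for _ in range(n_exons - 1)
            ]
            intron_lens = [int(rng.integers(200, 800)) for _ in range(n_exons - 1)]
        tx_lens = exon_lens if strand == "+" else exon_lens[::-1]
        in_lens = intron_lens if strand == "+" else intron_lens[::-1]
        exons = []
        pos = cursor
        for j, el in enumerate(tx_lens):
            exons.append((pos, pos + el))
            pos += el
            if j < len(in_lens):
                pos += in_lens[j]
        span_start, span_end = exons[0][0], exons[-1][1]
        cursor = span_end + int(rng.integers(1500, 3000))
        tss = span_start if strand == "+" else span_end
        pa = span_end if strand == "+" else span_start

        # ---- kinetics
        r0 = float(np.exp(rng.normal(np.log(1.0), 0.35)))
        thalf0 = float(np.clip(np.exp(rng.normal(np.log(7.5), 0.25)), 3.0, 25.0))
        shape = np.interp(tfrac, (0, 12 / 96, 24 / 96, 72 / 96, 1.0), _R_SHAPES[cls])
        # stable genes are constant by definition; DE classes get mild
        # per-time-point variation around their class shape
        jitter = 0.0 if cls == "stable" else rng.normal(0.0, 0.03, size=len(times))
        r_t = r0 * shape * np.exp(jitter)
        if cls == "pre-B":
            f_start = rng.uniform(0.12, 0.30)
            f_end = min(f_start + rng.uniform(0.50, 0.65), 0.92)
            f_t = f_start + (f_end - f_start) * tfrac
            thalf_t = np.full(len(times), thalf0)
        elif cls == "iMac-II":
            f_start = rng.uniform(0.50, 0.85)
            f_end = max(f_start - rng.uniform(0.30, 0.45), 0.05)
            f_t = f_start + (f_end - f_start) * tfrac
            thalf_t = thalf0 * (1.0 + (0.6 - 1.0) * tfrac)
        elif cls == "iMac-I":
            # release-driven upregulation: little termination, unchanged
            f_t = np.full(len(times), rng.uniform(0.10, 0.35))
            thalf_t = np.full(len(times), thalf0)
        else:
            f_t = np.full(len(times), rng.uniform(0.10, 0.70))
            thalf_t = np.full(len(times), thalf0)
        f_t = np.clip(f_t, 0.02, 0.95)

        rec = {
            "gene_id": gid,
            "chrom": "chrS",
            "strand": strand,
            "span_start": span_start,
            "span_end": span_end,
            "tss": tss,
            "pa": pa,
            "exons": ",".join(f"{s}-{e}" for s, e in exons),
            "single_exon": single,
            "pause_offset": int(rng.integers(25, 180)),
            "temporal_class": cls,
            "detectable": bool(rng.random() >= config.undetectable_fraction),
            "conflict": bool(rng.random() < config.conflict_fraction),
            "antisense_ratio": config.antisense_ratio,
        }
        for t, r, f, th in zip(config.time_points_h, r_t, f_t, thalf_t):
            rec[f"r_{t}"] = r
            rec[f"f_{t}"] = f
            rec[f"thalf_{t}"] = th
            rec[f"I_{t}"] = r * (1.0 - f)
            rec[f"p0_{t}"] = r * th / LN2
        records.append(rec)

    return SimTruth(pd.DataFrame.from_records(records), config)


# --------------------------------------------------------------------------
# annotation & isoform TPMs
# --------------------------------------------------------------------------

def _minor_structure(exons: tuple[tuple[int, int], ...], strand: str, shrink: int):
    """A minor isoform: the major structure with a truncated 3' end."""
    exons = list(exons)
    if strand == "+":
        s, e = exons[-1]
        exons[-1] = (s, max(s + 50, e - shrink))
    else:
        s, e = exons[0]
        exons[0] = (min(e - 50, s + shrink), e)
    return tuple(exons)


def simulate_annotation(
    truth: SimTruth,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Isoform structures and a TPM table exercising the 70% dominance rule.

    Non-conflicted genes get one dominant isoform (share 0.85 at every time
    point, or a single isoform); genes flagged ``conflict`` get two isoforms
    that each dominate at different time points, so the selector must drop
    exactly those genes.
    """
    config = truth.config
    rng = _rng(config, 2)
    times = config.time_points_h
    transcripts: list[TranscriptModel] = []
    rows = []
    for gid in truth.gene_ids:
        row = truth.df.loc[gid]
        exons = truth.exons(gid)
        base_tpm = np.array([50.0 * row[f"I_{t}"] + 5.0 for t in times])
        major = TranscriptModel(f"{gid}.t1", gid, row["chrom"], row["strand"], exons)
        transcripts.append(major)
        if row["conflict"]:
            minor = TranscriptModel(
                f"{gid}.t2", gid, row["chrom"], row["strand"],
                _minor_structure(exons, row["strand"], 200),
            )
            transcripts.append(minor)
            half = (len(times) + 1) // 2
            share1 = np.where(np.arange(len(times)) < half, 0.85, 0.15)
            rows.append([major.transcript_id, gid, *(base_tpm * share1)])
            rows.append([minor.transcript_id, gid, *(base_tpm * (1 - share1))])
        elif rng.random() < config.single_isoform_fraction:
            rows.append([major.transcript_id, gid, *base_tpm])
        else:
            n_minor = int(rng.integers(1, 3))
            shares = rng.dirichlet(np.ones(n_minor)) * 0.15
            rows.append([major.transcript_id, gid, *(base_tpm * 0.85)])
            for j, sh in enumerate(shares):
                minor = TranscriptModel(
                    f"{gid}.t{j + 2}", gid, row["chrom"], row["strand"],
                    _minor_structure(exons, row["strand"], 200 + 100 * j),
                )
                transcripts.append(minor)
                rows.append([minor.transcript_id, gid, *(base_tpm * sh)])
    tpm = pd.DataFrame(rows, columns=["transcript_id", "gene_id", *[f"{t}h" for t in times]])
    return transcripts, tpm


# --------------------------------------------------------------------------
# signal forward models
# --------------------------------------------------------------------------

def _sample_counts(rng: np.random.Generator, lam: np.ndarray, config: SimConfig):
    if config.noise == "none":
        return lam
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, np.maximum(lam, 0) / shape)
    return rng.poisson(np.maximum(lam, 0)).astype(np.float64)


def _triangular_kernel(halfwidth: int) -> np.ndarray:
    """Symmetric triangular weights over ±halfwidth bp, summing to 1."""
    w = np.arange(-halfwidth, halfwidth + 1)
    k = (halfwidth + 1 - np.abs(w)).astype(np.float64)
    return k / k.sum()


def _hidden_scale(config: SimConfig, assay: str) -> float:
    if config.calibration == "unit":
        return 1.0
    rng = _rng(config, 99, hash(assay) % 1000)
    return float(np.exp(rng.normal(0.0, 0.5)))


def _add_gene_signal(
    sig: StrandedBaseSignal,
    chrom: str,
    strand: str,
    start: int,
    lam: np.ndarray,
    antisense_ratio: float,
    rng: np.random.Generator,
    config: SimConfig,
) -> None:
    """Emit sense signal with expectation ``lam`` plus antisense leak."""
    sig.add_array(chrom, strand, start, _sample_counts(rng, lam, config))
    if antisense_ratio > 0:
        anti = _sample_counts(rng, antisense_ratio * lam, config)
        sig.add_array(chrom, "-" if strand == "+" else "+", start, anti)


def simulate_ttseq(truth: SimTruth, config: SimConfig | None = None):
    """TT-seq coverage per (time point, replicate): expected sense coverage
    ``tt_depth * I_t`` at every exonic base, antisense leak mirrored at ratio
    ``antisense_ratio``."""
    config = config or truth.config
    scale = config.tt_depth * _hidden_scale(config, "tt")
    out = {}
    for ti, t in enumerate(config.time_points_h):
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config, 10, ti, rep)
            sig = StrandedBaseSignal({"assay": "ttseq", "time_h": t, "replicate": rep})
            for gid in truth.gene_ids:
                row = truth.df.loc[gid]
                lam_value = scale * row[f"I_{t}"]
                for s, e in truth.exons(gid):
                    lam = np.full(e - s, lam_value)
                    _add_gene_signal(
                        sig, row["chrom"], row["strand"], s, lam,
                        config.antisense_ratio, rng, config,
                    )
            out[(t, rep)] = sig
    return out


def _mnet_gene_lambda(row, exons, t: int, config: SimConfig, scale: float) -> np.ndarray:
    """Expected mNET-seq 3'-end profile over the gene span (genomic order)."""
    span_start, span_end = exons[0][0], exons[-1][1]
    lam = np.full(span_end - span_start, scale * config.body_density * row[f"I_{t}"])
    kernel = _triangular_kernel(config.peak_halfwidth)
    body = scale * config.body_density * row[f"I_{t}"]
    if row["detectable"]:
        peak_total = scale * row[f"p0_{t}"]
    else:
        # scaled so the peak maximum sits below the 5x median-of-nonzero rule
        peak_total = 2.0 * body / kernel.max()
    w = config.peak_halfwidth
    tss = row["tss"]
    if row["strand"] == "+":
        center = tss + row["pause_offset"]
        lo = center - w - span_start
    else:
        center = tss - row["pause_offset"] - 1
        lo = center - w - span_start
        kernel = kernel[::-1]
    lam[lo : lo + 2 * w + 1] += peak_total * kernel
    return lam


def simulate_mnetseq(truth: SimTruth, config: SimConfig | None = None):
    """mNET-seq 3'-end counts per (time point, replicate): a promoter-proximal
    peak with mass ``p0_t`` spread over pause_offset ± halfwidth plus uniform
    gene-body signal ``body_density * I_t`` per base."""
    config = config or truth.config
    scale = config.mnet_depth * _hidden_scale(config, "mnet")
    out = {}
    for ti, t in enumerate(config.time_points_h):
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config, 20, ti, rep)
            sig = StrandedBaseSignal({"assay": "mnet", "time_h": t, "replicate": rep})
            for gid in truth.gene_ids:
                row = truth.df.loc[gid]
                exons = truth.exons(gid)
                lam = _mnet_gene_lambda(row, exons, t, config, scale)
                _add_gene_signal(
                    sig, row["chrom"], row["strand"], exons[0][0], lam,
                    config.antisense_ratio, rng, config,
                )
            out[(t, rep)] = sig
    return out


def nexus_sample_id(t: int, condition: str, tau: float, rep: int) -> str:
    return f"{t}h_{condition}{tau:g}_r{rep}"


def simulate_chipnexus_timecourse(truth: SimTruth, config: SimConfig | None = None):
    """ChIP-nexus signals for the initiation-inhibition time course.

    For each profiled time point, DMSO controls and triptolide treatments at
    each inhibition time tau, in replicates.  The expected windowed signal at
    the pause site is ``p0_t * exp(-k * tau)`` (k = ln2 / t½) for triptolide
    and ``p0_t`` for DMSO.  ChIP is DNA-based, so no reverse-transcription
    antisense leak is applied.  Returns (signals, spike_totals, true_factors).
    """
    config = config or truth.config
    scale = config.nexus_depth * _hidden_scale(config, "nexus")
    kernel = _triangular_kernel(config.peak_halfwidth)
    w = config.peak_halfwidth
    signals = {}
    spike = {}
    true_factors = {}
    sample_keys = [
        (t, cond, tau, rep)
        for t in config.nexus_time_points_h
        for cond in ("DMSO", "TRP")
        for tau in config.triptolide_times
        for rep in range(1, config.n_replicates + 1)
    ]
    # per-sample depth multipliers (hidden; 1 in unit calibration)
    if config.calibration == "arbitrary":
        m_rng = _rng(config, 98)
        mult = {k: float(np.exp(m_rng.normal(0.0, 0.15))) for k in sample_keys}
    else:
        mult = {k: 1.0 for k in sample_keys}
    ref_key = sample_keys[0]
    for si, key in enumerate(sample_keys):
        t, cond, tau, rep = key
        rng = _rng(config, 30, si)
        sig = StrandedBaseSignal(
            {"assay": "nexus", "time_h": t, "condition": cond,
             "inhibition_min": tau, "replicate": rep}
        )
        for gid in truth.gene_ids:
            row = truth.df.loc[gid]
            decay = 1.0
            if cond == "TRP":
                decay = float(np.exp(-LN2 / row[f"thalf_{t}"] * tau))
            total = scale * mult[key] * row[f"p0_{t}"] * decay
            lam = total * (kernel if row["strand"] == "+" else kernel[::-1])
            if row["strand"] == "+":
                start = row["tss"] + row["pause_offset"] - w
            else:
                start = row["tss"] - row["pause_offset"] - 1 - w
            if config.pic_level > 0:
                pic = config.pic_level * scale * mult[key]
                pic_start = row["tss"] - 60 if row["strand"] == "+" else row["tss"] + 55
                sig.add_array(row["chrom"], row["strand"], pic_start,
                              _sample_counts(rng, np.full(5, pic), config))
            sig.add_array(row["chrom"], row["strand"], start,
                          _sample_counts(rng, lam, config))
        sid = nexus_sample_id(*key)
        signals[key] = sig
        tot = config.spike_base_total * mult[key]
        if config.noise == "poisson":
            tot = float(_rng(config, 31, si).poisson(tot))
        spike[sid] = tot
        true_factors[sid] = mult[ref_key] / mult[key]
    return signals, pd.Series(spike, name="spike_total"), pd.Series(true_factors)


# --------------------------------------------------------------------------
# cohort bundle
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """All assays of one simulated study, keyed the way the pipeline expects."""

    config: SimConfig
    truth: SimTruth
    transcripts: list[TranscriptModel]
    tpm: pd.DataFrame
    ttseq: dict
    mnet: dict
    nexus: dict
    spike_totals: pd.Series
    true_spike_factors: pd.Series


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run every generator stage with a shared seed."""
    truth = simulate_truth(config)
    transcripts, tpm = simulate_annotation(truth)
    ttseq = simulate_ttseq(truth, config)
    mnet = simulate_mnetseq(truth, config)
    nexus, spike, factors = simulate_chipnexus_timecourse(truth, config)
    return SyntheticCohort(config, truth, transcripts, tpm, ttseq, mnet, nexus,
                           spike, factors)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Serialize a cohort to plain-text artifacts (bedGraph/BED12/TSV)."""
    from .annotation import write_bed12

    outdir = Path(outdir)
    for sub in ("ttseq", "mnet", "nexus"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    cohort.truth.df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.tpm.to_csv(outdir / "isoform_tpm.tsv", sep="\t", index=False)
    cohort.spike_totals.rename_axis("sample_id").reset_index().to_csv(
        outdir / "spikeins.tsv", sep="\t", index=False
    )
    write_bed12(cohort.transcripts, outdir / "isoforms.bed")
    for (t, rep), sig in cohort.ttseq.items():
        base = outdir / "ttseq" / f"tt_{t}h_r{rep}"
        sig.write_bedgraph_pair(f"{base}.plus.bedgraph", f"{base}.minus.bedgraph")
    for (t, rep), sig in cohort.mnet.items():
        base = outdir / "mnet" / f"mnet_{t}h_r{rep}"
        sig.write_bedgraph_pair(f"{base}.plus.bedgraph", f"{base}.minus.bedgraph")
    for key, sig in cohort.nexus.items():
        base = outdir / "nexus" / f"nexus_{nexus_sample_id(*key)}"
        sig.write_bedgraph_pair(f"{base}.plus.bedgraph", f"{base}.minus.bedgraph")
    with open(outdir / "config.json", "w") as fh:
        import json

        fh.write(json.dumps(dataclasses.asdict(cohort.config), indent=2, default=str))
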