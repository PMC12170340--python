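"""End-to-end orchestration: signals in, kinetic parameters and groups out.

The stages mirror the analysis workflow: select major isoforms, quantify
TT-seq into productive initiation frequencies, call and filter pause sites
from mNET-seq and compute apparent pause durations, fit ChIP-nexus clearance
kinetics into half-lives / turnover rates / termination fractions, then
classify and subcluster the cohort.  Each stage is usable on its own; this
module wires them together for in-memory runs (tests, acceptance) and for
the file-based CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_ops
from . import decay as decay_ops
from . import pause as pause_ops
from .annotation import GeneModel, select_major_isoforms
from .errors import InputError
from .signal import (
    StrandedBaseSignal,
    correct_antisense,
    estimate_antisense_ratio,
    filter_expressed,
    mask_signal,
    size_factors,
    spikein_factors,
)
from .synth import SyntheticCohort


@dataclass
class AnalysisParams:
    """Thresholds and modes of the analysis; defaults follow the study design.

    dominance_threshold   major isoform share (strictly greater than)
    pause_search_bp       promoter-proximal search window downstream of TSS
    pause_fold            peak must be >= fold x median of nonzero window values
    max_position_sd       pause-position stability filter (bp, sample s.d.)
    pause_halfwidth       d-window: peak ± halfwidth (200 bp total)
    nexus_halfwidth       half-life window: peak ± halfwidth, inclusive
    min_rpk               expressed-gene filter (reads per kb at >= 1 time point)
    antisense_min_coverage  sense coverage needed at positions used for the
                            antisense-ratio estimate (lower for shallow data)
    """

    dominance_threshold: float = 0.70
    exclude_chroms: tuple[str, ...] = ("chrM",)
    retention_flank: int = 500
    pause_search_bp: int = 250
    pause_fold: float = 5.0
    max_position_sd: float = 75.0
    pause_halfwidth: int = 100
    nexus_halfwidth: int = 20
    min_rpk: float = 10.0
    antisense_min_coverage: float = 100.0
    fc_threshold: float = 1.5
    padj_threshold: float = 0.05
    kmeans_k: int = 2
    kmeans_boot: int = 100
    n_quantiles: int = 4
    metagene_bins: int = 100
    clamp_fractions: bool = False
    ratio_mode: bool = False
    apply_retention_mask: bool = True
    seed: int = 0


@dataclass
class PipelineResults:
    models: dict[str, GeneModel]
    tt_counts: pd.DataFrame | None = None
    tt_size_factors: pd.Series | None = None
    tt_antisense: dict = field(default_factory=dict)
    cov_table: pd.DataFrame | None = None
    i_table: pd.DataFrame | None = None
    mnet_size_factors: pd.Series | None = None
    mnet_antisense: dict = field(default_factory=dict)
    kinetic: pd.DataFrame | None = None
    sites: dict = field(default_factory=dict)
    reasons: pd.Series | None = None
    spike_factors: pd.Series | None = None
    decay: dict = field(default_factory=dict)
    groups: pd.DataFrame | None = None
    params: AnalysisParams | None = None

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot the kinetic table to genes x time points for one quantity."""
        return self.kinetic.pivot(index="gene_id", columns="time_h", values=column)


# --------------------------------------------------------------------------
# stage: annotate
# --------------------------------------------------------------------------

def annotate_stage(tpm, structures, params: AnalysisParams) -> dict[str, GeneModel]:
    struct_map = {t.transcript_id: t for t in structures} if not isinstance(
        structures, dict
    ) else structures
    return select_major_isoforms(
        tpm,
        struct_map,
        dominance_threshold=params.dominance_threshold,
        exclude_chroms=params.exclude_chroms,
    )


# --------------------------------------------------------------------------
# stage: quantify (TT-seq -> I)
# --------------------------------------------------------------------------

def _antisense_regions(models: dict[str, GeneModel]):
    return [(m.chrom, m.strand, *sorted(m.span)) for m in models.values()]


def _corrected_gene_counts(
    signal: StrandedBaseSignal,
    models: dict[str, GeneModel],
    intervals: dict[str, tuple],
    c: float,
) -> pd.Series:
    sense, anti = {}, {}
    for gid, model in models.items():
        s = a = 0.0
        for lo, hi in intervals[gid]:
            s += signal.count(model.chrom, model.strand, lo, hi)
            a += signal.count(model.chrom, "-" if model.strand == "+" else "+", lo, hi)
        sense[gid], anti[gid] = s, a
    sense = pd.Series(sense)
    corrected, _ = correct_antisense(sense.to_numpy(), pd.Series(anti).to_numpy(), c)
    return pd.Series(corrected, index=sense.index)


def quantify_stage(
    models: dict[str, GeneModel],
    ttseq: dict,
    params: AnalysisParams,
) -> dict:
    """TT-seq counts over quantification intervals -> normalized I table."""
    time_points = sorted({t for t, _ in ttseq})
    usable = {g: m for g, m in models.items() if m.usable_for_initiation}
    regions = _antisense_regions(usable)
    intervals = {g: m.i_intervals() for g, m in usable.items()}
    retention = [m.retention_window(params.retention_flank) for m in models.values()]

    counts = {}
    ratios = {}
    for key, sig in ttseq.items():
        if params.apply_retention_mask:
            sig = mask_signal(sig, retention)
        c = estimate_antisense_ratio(sig, regions, params.antisense_min_coverage)
        ratios[key] = c
        counts[key] = _corrected_gene_counts(sig, usable, intervals, c)
    counts = pd.DataFrame(counts)

    lengths = pd.Series({g: m.nonfirst_exon_length for g, m in usable.items()})
    tp_means = pd.DataFrame(
        {t: counts[[k for k in counts.columns if k[0] == t]].mean(axis=1)
         for t in time_points}
    )
    expressed = filter_expressed(tp_means, lengths, params.min_rpk)

    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    cov_table = pd.DataFrame(
        {t: norm[[k for k in norm.columns if k[0] == t]].mean(axis=1)
         for t in time_points}
    ).loc[expressed]
    i_table = cov_table.div(lengths.loc[expressed], axis=0)
    return {
        "counts": counts,
        "size_factors": sf,
        "antisense": ratios,
        "cov_table": cov_table,
        "i_table": i_table,
    }


# --------------------------------------------------------------------------
# stage: pause (mNET-seq -> pause sites, d)
# --------------------------------------------------------------------------

def pause_stage(
    models: dict[str, GeneModel],
    mnet: dict,
    i_table: pd.DataFrame,
    params: AnalysisParams,
) -> dict:
    time_points = sorted({t for t, _ in mnet})
    regions = _antisense_regions(models)
    spans = {g: (sorted(m.span),) for g, m in models.items()}
    retention = [m.retention_window(params.retention_flank) for m in models.values()]

    masked = {}
    ratios = {}
    counts = {}
    for key, sig in mnet.items():
        if params.apply_retention_mask:
            sig = mask_signal(sig, retention)
        masked[key] = sig
        c = estimate_antisense_ratio(sig, regions, params.antisense_min_coverage)
        ratios[key] = c
        counts[key] = _corrected_gene_counts(sig, models, spans, c)
    counts = pd.DataFrame(counts)
    sf = size_factors(counts)

    win_len = params.pause_search_bp + params.pause_halfwidth
    windows: dict[str, dict] = {}
    candidates = [g for g in models if g in i_table.index]
    for gid in candidates:
        model = models[gid]
        per_tp = {}
        for t in time_points:
            reps = [k for k in masked if k[0] == t]
            acc = np.zeros(win_len)
            for k in reps:
                sense = pause_ops.oriented_window(masked[k], model, 0, win_len, True)
                anti = pause_ops.oriented_window(masked[k], model, 0, win_len, False)
                corr_s, _ = correct_antisense(sense, anti, ratios[k])
                acc += corr_s / sf[k]
            per_tp[t] = acc / len(reps)
        windows[gid] = per_tp

    kinetic, sites, reasons = pause_ops.build_kinetic_table(
        {g: models[g] for g in candidates},
        i_table,
        windows,
        fold=params.pause_fold,
        max_sd=params.max_position_sd,
        pause_halfwidth=params.pause_halfwidth,
    )
    return {
        "kinetic": kinetic,
        "sites": sites,
        "reasons": reasons,
        "size_factors": sf,
        "antisense": ratios,
    }


# --------------------------------------------------------------------------
# stage: decay (ChIP-nexus -> t½, r, termination)
# --------------------------------------------------------------------------

def decay_stage(
    models: dict[str, GeneModel],
    sites: dict,
    nexus: dict,
    spike_totals: pd.Series,
    i_table: pd.DataFrame,
    params: AnalysisParams,
) -> dict:
    from .synth import nexus_sample_id

    factors = spikein_factors(spike_totals)
    nexus_tps = sorted({key[0] for key in nexus})
    fits = {}
    stable_genes = [
        g for g, s in sites.items()
        if s.stable and g in i_table.index and (i_table.loc[g] > 0).all()
    ]
    for t in nexus_tps:
        rows = []
        for key, sig in nexus.items():
            if key[0] != t:
                continue
            _, cond, tau, rep = key
            factor = factors[nexus_sample_id(*key)]
            for gid in stable_genes:
                value = decay_ops.extract_peak_window(
                    sig, models[gid], sites[gid].consensus_offset,
                    params.nexus_halfwidth,
                ) * factor
                rows.append(
                    {"gene_id": gid, "condition": cond, "tau_min": tau,
                     "replicate": rep, "value": value}
                )
        windowed = pd.DataFrame(rows)
        if windowed.empty:
            continue
        fit = decay_ops.fit_decay_table(
            windowed,
            i_table[t] if t in i_table.columns else i_table.iloc[:, 0],
            clamp=params.clamp_fractions,
            ratio_mode=params.ratio_mode,
        )
        fit["time_h"] = t
        fits[t] = fit
    return {"decay": fits, "spike_factors": factors}


# --------------------------------------------------------------------------
# stage: cohort grouping
# --------------------------------------------------------------------------

def group_stage(
    cov_table: pd.DataFrame,
    kinetic: pd.DataFrame,
    params: AnalysisParams,
    external_de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    time_points = tuple(cov_table.columns)
    de = cohort_ops.de_gate(
        cov_table, params.fc_threshold, params.padj_threshold, external_de
    )
    classes = {
        gid: cohort_ops.classify_temporal(cov_table.loc[gid].to_numpy(), time_points)
        for gid in de
    }
    groups = pd.DataFrame(
        {"gene_id": cov_table.index,
         "de": cov_table.index.isin(de)}
    ).set_index("gene_id", drop=False)
    groups["temporal_class"] = groups["gene_id"].map(classes).fillna("none")
    groups["subcluster"] = "none"
    groups["stability"] = np.nan

    imac = [g for g, c in classes.items() if c == "iMac"]
    if kinetic is not None and len(imac) >= max(params.kmeans_k * 2, 4):
        i_wide = kinetic.pivot(index="gene_id", columns="time_h", values="I")
        d_wide = kinetic.pivot(index="gene_id", columns="time_h", values="d")
        idx = [g for g in imac if g in i_wide.index]
        feats = pd.concat(
            [i_wide.loc[idx].add_prefix("I_"), d_wide.loc[idx].add_prefix("d_")],
            axis=1,
        ).dropna()
        feats = feats[(feats > 0).all(axis=1)]
        if len(feats) >= params.kmeans_k * 2:
            last = max(t for t in d_wide.columns)
            labels, stability, _ = cohort_ops.bootstrap_kmeans(
                feats,
                k=params.kmeans_k,
                n_boot=params.kmeans_boot,
                seed=params.seed,
                final_d_columns=[f"d_{last}"],
            )
            names = labels.map(lambda c: f"iMac {'I' * int(c)}" if c <= 2 else f"iMac {c}")
            groups.loc[names.index, "subcluster"] = names
            groups.loc[stability.index, "stability"] = stability
    return groups


# --------------------------------------------------------------------------
# full run on a synthetic cohort
# --------------------------------------------------------------------------

def run_cohort_pipeline(
    cohort: SyntheticCohort, params: AnalysisParams | None = None
) -> PipelineResults:
    """Execute every stage on an in-memory synthetic cohort."""
    params = params or AnalysisParams()
    models = annotate_stage(cohort.tpm, cohort.transcripts, params)
    res = PipelineResults(models=models, params=params)

    q = quantify_stage(models, cohort.ttseq, params)
    res.tt_counts = q["counts"]
    res.tt_size_factors = q["size_factors"]
    res.tt_antisense = q["antisense"]
    res.cov_table = q["cov_table"]
    res.i_table = q["i_table"]

    p = pause_stage(models, cohort.mnet, res.i_table, params)
    res.kinetic = p["kinetic"]
    res.sites = p["sites"]
    res.reasons = p["reasons"]
    res.mnet_size_factors = p["size_factors"]

    d = decay_stage(models, res.sites, cohort.nexus, cohort.spike_totals,
                    res.i_table, params)
    res.decay = d["decay"]
    res.spike_factors = d["spike_factors"]

    res.groups = group_stage(res.cov_table, res.kinetic, params)
    return res


def summarize_groups(res: PipelineResults) -> pd.DataFrame:
    """Group-level contrasts between the first and last profiled time points.

    For each temporal class (and iMac subcluster) and each kinetic quantity
    (I, d, half-life, |r|, termination fraction): medians at both time
    points, the median per-gene fold change, and the two-sided KS test.
    """
    if not res.decay:
        raise InputError("run the decay stage before summarizing")
    t0, t1 = min(res.decay), max(res.decay)
    i_wide, d_wide = res.wide("I"), res.wide("d")
    rows = []
    group_sets = {}
    for cls in ("pre-B", "bending", "peaking", "iMac"):
        group_sets[cls] = set(res.groups.index[res.groups["temporal_class"] == cls])
    for sub in sorted(set(res.groups["subcluster"]) - {"none"}):
        group_sets[sub] = set(res.groups.index[res.groups["subcluster"] == sub])

    quantities = {
        "I": (i_wide, min(i_wide.columns), max(i_wide.columns)),
        "d": (d_wide, min(d_wide.columns), max(d_wide.columns)),
    }
    for name, col in (("half_life", "half_life_min"), ("turnover", "r_abs"),
                      ("termination", "termination_fraction")):
        ok0 = res.decay[t0][res.decay[t0]["status"] == "ok"]
        ok1 = res.decay[t1][res.decay[t1]["status"] == "ok"]
        wide = pd.DataFrame({t0: ok0[col], t1: ok1[col]}).dropna()
        quantities[name] = (wide, t0, t1)

    for gname, genes in group_sets.items():
        for qname, (wide, c0, c1) in quantities.items():
            idx = wide.index.intersection(genes)
            sub = wide.loc[idx, [c0, c1]].replace([np.inf, -np.inf], np.nan).dropna()
            if len(sub) < 3:
                continue
            a, b = sub[c0].to_numpy(), sub[c1].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.where(a != 0, b / a, np.nan)
            stat, p = cohort_ops.ks_compare(a, b)
            rows.append(
                {"group": gname, "quantity": qname, "n": len(sub),
                 "median_t0": float(np.median(a)), "median_t1": float(np.median(b)),
                 "median_fc": float(np.nanmedian(fc)), "ks_D": stat, "ks_p": p}
            )
    return pd.DataFrame(rows)
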