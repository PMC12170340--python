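"""Productive initiation frequency, pause-site detection and pause duration.

The estimators operate on normalized, antisense-corrected signals:

* productive initiation frequency ``I_g = cov_g / L_g`` — TT-seq coverage
  over the quantification intervals (non-first exons; TSS+300 to pA for
  single-exon genes) divided by their length, in arbitrary units;
* pause sites — the position of a clear mNET-seq 3'-end maximum within
  250 bp downstream of the TSS (max >= 5x the median of nonzero values in
  the window), kept only if positionally stable across the time course
  (s.d. <= 75 bp);
* apparent pause duration ``d_g = PWcov_g / I_g`` — mNET-seq signal in a
  200 bp window around the pause site divided by I.  ``d`` overestimates the
  single-molecule pause time when a large fraction of promoter-proximal
  polymerases terminates rather than elongates, which is precisely what
  makes it informative about termination-driven regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .errors import InputError

PAUSE_SEARCH_BP = 250
PAUSE_FOLD = 5.0
MAX_POSITION_SD = 75.0
PAUSE_WINDOW_HALFWIDTH = 100


def productive_initiation(cov: float, length: float) -> float:
    """I = cov / L (a.u.); requires a positive quantification length."""
    if length <= 0:
        raise InputError("quantification length must be positive")
    if cov < 0:
        raise InputError("coverage must be non-negative")
    return cov / length


def detect_pause_site(window: np.ndarray, fold: float = PAUSE_FOLD) -> int | None:
    """Call the promoter-proximal peak in a strand-oriented signal window.

    Returns the offset (bp downstream of the TSS) of the window maximum iff
    the maximum is at least ``fold`` times the median of the window's nonzero
    values (inclusive comparison), else ``None``.  Ties take the smallest
    offset (5'-most).
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0 or not np.any(window > 0):
        return None
    m = float(window.max())
    med = float(np.median(window[window > 0]))
    if m >= fold * med:
        return int(np.argmax(window))
    return None


@dataclass
class PauseSite:
    """Per-gene pause-site call across the time course."""

    gene_id: str
    offsets: dict  # time point -> offset (detected time points only)
    peak_values: dict  # time point -> peak height at the detected offset
    consensus_offset: int | None
    position_sd: float
    detected_any: bool
    stable: bool


def stable_pause_sites(
    gene_id: str,
    offsets: dict,
    peak_values: dict,
    max_sd: float = MAX_POSITION_SD,
) -> PauseSite:
    """Positional-stability filter over per-time-point pause calls.

    The s.d. is the sample standard deviation (n-1 denominator) over detected
    time points only; a single detection counts as perfectly stable (sd 0).
    The consensus offset is the call at the time point with the largest peak,
    earliest time point on ties.
    """
    detected = sorted(offsets)
    if not detected:
        return PauseSite(gene_id, {}, {}, None, float("nan"), False, False)
    vals = np.array([offsets[t] for t in detected], dtype=float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    stable = sd <= max_sd
    best_t = max(detected, key=lambda t: (peak_values.get(t, 0.0), -detected.index(t)))
    # ties -> earliest time point
    best_val = peak_values.get(best_t, 0.0)
    for t in detected:
        if peak_values.get(t, 0.0) == best_val:
            best_t = t
            break
    return PauseSite(
        gene_id=gene_id,
        offsets=dict(offsets),
        peak_values=dict(peak_values),
        consensus_offset=int(offsets[best_t]),
        position_sd=sd,
        detected_any=True,
        stable=stable,
    )


def pause_window_coverage(
    window_signal: np.ndarray,
    consensus_offset: int,
    halfwidth: int = PAUSE_WINDOW_HALFWIDTH,
) -> float:
    """Sum of signal over [peak - halfwidth, peak + halfwidth) in
    transcription direction, clipped at the TSS (offset 0) but not downstream.

    ``window_signal`` must be strand-oriented with offset 0 at the TSS and
    long enough to cover ``consensus_offset + halfwidth``.
    """
    lo = max(0, consensus_offset - halfwidth)
    hi = consensus_offset + halfwidth
    return float(np.sum(window_signal[lo:hi]))


def apparent_pause_duration(pwcov: float, initiation: float) -> float:
    """d = PWcov / I (a.u.); genes with I = 0 at any time point are excluded
    upstream."""
    if initiation <= 0:
        raise InputError("apparent pause duration requires I > 0")
    return pwcov / initiation


# --------------------------------------------------------------------------
# cohort driver
# --------------------------------------------------------------------------

def oriented_window(signal, model: GeneModel, offset_start: int, offset_end: int,
                    strand_sense: bool = True) -> np.ndarray:
    """Dense strand-oriented signal for TSS offsets [offset_start, offset_end)."""
    g0, g1 = model.downstream_interval(offset_start, offset_end)
    strand = model.strand if strand_sense else ("-" if model.strand == "+" else "+")
    dense = signal.dense(model.chrom, strand, g0, g1)
    return dense if model.strand == "+" else dense[::-1]


def build_kinetic_table(
    models: dict[str, GeneModel],
    i_table: pd.DataFrame,
    mnet_windows: dict[str, dict],
    fold: float = PAUSE_FOLD,
    max_sd: float = MAX_POSITION_SD,
    pause_halfwidth: int = PAUSE_WINDOW_HALFWIDTH,
) -> tuple[pd.DataFrame, dict[str, PauseSite], pd.Series]:
    """Combine per-gene I estimates and mNET-seq windows into the kinetic table.

    Parameters
    ----------
    i_table:
        genes x time points table of I estimates (a.u.).
    mnet_windows:
        gene -> {time point -> strand-oriented normalized mNET-seq signal
        covering offsets [0, PAUSE_SEARCH_BP + pause_halfwidth)}.

    Returns
    -------
    kinetic:
        long-format table gene x time point with I, PWcov, d.
    sites:
        per-gene :class:`PauseSite`.
    reasons:
        exclusion reason per excluded gene.
    """
    time_points = list(i_table.columns)
    records = []
    sites: dict[str, PauseSite] = {}
    reasons: dict[str, str] = {}
    for gid, model in models.items():
        if gid not in i_table.index:
            reasons[gid] = "not_expressed"
            continue
        if not model.usable_for_initiation:
            reasons[gid] = "no_quantification_length"
            continue
        windows = mnet_windows.get(gid)
        if windows is None:
            reasons[gid] = "no_mnet_signal"
            continue
        offsets, peaks = {}, {}
        for t in time_points:
            off = detect_pause_site(windows[t][:PAUSE_SEARCH_BP], fold=fold)
            if off is not None:
                offsets[t] = off
                peaks[t] = float(windows[t][off])
        site = stable_pause_sites(gid, offsets, peaks, max_sd=max_sd)
        sites[gid] = site
        if not site.detected_any:
            reasons[gid] = "no_pause_site"
            continue
        if not site.stable:
            reasons[gid] = "unstable_pause_site"
            continue
        ivals = i_table.loc[gid]
        if (ivals <= 0).any():
            reasons[gid] = "zero_initiation"
            continue
        for t in time_points:
            pw = pause_window_coverage(windows[t], site.consensus_offset,
                                       halfwidth=pause_halfwidth)
            records.append(
                {
                    "gene_id": gid,
                    "time_h": t,
                    "I": float(ivals[t]),
                    "PWcov": pw,
                    "d": apparent_pause_duration(pw, float(ivals[t])),
                    "pause_offset": site.consensus_offset,
                }
            )
    kinetic = pd.DataFrame.from_records(
        records, columns=["gene_id", "time_h", "I", "PWcov", "d", "pause_offset"]
    )
    return kinetic, sites, pd.Series(reasons, dtype=object, name="reason")
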