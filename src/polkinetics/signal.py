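"""Stranded base-resolution genomic signals and their normalization.

The central container is :class:`StrandedBaseSignal`, a run-length encoded,
per-chromosome, per-strand non-negative signal, as produced by coverage or
3'-end counting of nascent-transcription assays (TT-seq, mNET-seq,
ChIP-nexus).  The module also provides the normalization steps every
downstream estimator relies on:

* antisense-bias estimation and correction (spurious reverse-transcription
  reads appearing on the opposite strand),
* median-of-ratios size factors across samples,
* spike-in scale factors,
* the expressed-gene filter (reads per kilobase at any time point).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


def _other_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


class StrandedBaseSignal:
    """Non-negative base-resolution signal per chromosome and strand.

    Values are stored run-length encoded as sorted, non-overlapping
    ``(start, end, value)`` runs with half-open 0-based coordinates.
    Zero is implicit outside stored runs.

    Parameters
    ----------
    metadata:
        Free-form sample annotation (assay, time point, condition, replicate).
    """

    def __init__(self, metadata: Mapping | None = None):
        # compacted state: (chrom, strand) -> (starts, ends, values), sorted,
        # non-overlapping; appends go to _pending and are merged lazily so
        # building a signal gene by gene stays linear
        self._compacted: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._pending: dict[tuple[str, str], list] = {}
        self.metadata = dict(metadata or {})

    def _compact(self, key) -> None:
        chunks = self._pending.pop(key, None)
        if not chunks:
            return
        if key in self._compacted:
            chunks.append(self._compacted[key])
        starts = np.concatenate([c[0] for c in chunks])
        ends = np.concatenate([c[1] for c in chunks])
        values = np.concatenate([c[2] for c in chunks])
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise InputError(f"overlapping intervals on {key[0]}{key[1]}")
        self._compacted[key] = (starts, ends, values)

    @property
    def _runs(self) -> dict:
        for key in list(self._pending):
            self._compact(key)
        return self._compacted

    # ------------------------------------------------------------------ build

    def add_intervals(
        self,
        chrom: str,
        strand: str,
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float],
    ) -> None:
        """Add non-overlapping intervals; merged with existing runs by summation is
        NOT supported — intervals must not overlap anything already stored."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if np.any(values < 0):
            raise InputError("signal values must be non-negative")
        if np.any(ends <= starts):
            raise InputError("intervals must have end > start")
        keep = values != 0
        starts, ends, values = starts[keep], ends[keep], values[keep]
        if starts.size == 0:
            return
        self._pending.setdefault((chrom, strand), []).append((starts, ends, values))

    def add_array(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        """Place a dense per-base array at ``start`` (run-length compressed)."""
        values = np.asarray(values, dtype=np.float64)
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        run_starts = np.concatenate([[0], change])
        run_ends = np.concatenate([change, [values.size]])
        self.add_intervals(
            chrom, strand, run_starts + start, run_ends + start, values[run_starts]
        )

    # ------------------------------------------------------------------ query

    @property
    def chroms(self) -> set[str]:
        return {c for c, _ in self._runs}

    def runs(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            (chrom, strand),
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def count(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total signal over the half-open interval ``[start, end)``."""
        if end <= start:
            return 0.0
        starts, ends, values = self.runs(chrom, strand)
        if starts.size == 0:
            return 0.0
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        s = np.maximum(starts[i0:i1], start)
        e = np.minimum(ends[i0:i1], end)
        return float(np.sum(values[i0:i1] * (e - s)))

    def dense(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)`` as a dense array."""
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self.runs(chrom, strand)
        if starts.size == 0:
            return out
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[i0:i1], ends[i0:i1], values[i0:i1]):
            out[max(s, start) - start : min(e, end) - start] = v
        return out

    def total_mass(self) -> float:
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self._runs.values())
        )

    # ------------------------------------------------------------------- I/O

    @classmethod
    def read_bedgraph_pair(
        cls, plus_path, minus_path, metadata: Mapping | None = None
    ) -> "StrandedBaseSignal":
        """Read one bedGraph file per strand into a signal.

        Files must be 4-column, 0-based half-open, with non-negative values and
        no overlapping intervals; violations raise :class:`ParseError` with the
        offending line number.
        """
        sig = cls(metadata)
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            per_chrom: dict[str, list[tuple[int, int, float]]] = {}
            with open(path) as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith(("track", "#", "browser")):
                        continue
                    parts = line.split()
                    if len(parts) != 4:
                        raise ParseError("expected 4 columns", str(path), lineno)
                    chrom = parts[0]
                    try:
                        start, end = int(parts[1]), int(parts[2])
                        value = float(parts[3])
                    except ValueError as exc:
                        raise ParseError(f"malformed line: {exc}", str(path), lineno)
                    if value < 0:
                        raise ParseError("negative value", str(path), lineno)
                    if end <= start:
                        raise ParseError("end must exceed start", str(path), lineno)
                    per_chrom.setdefault(chrom, []).append((start, end, value))
            for chrom, ivs in per_chrom.items():
                ivs.sort()
                arr = np.asarray(ivs, dtype=np.float64)
                if np.any(arr[1:, 0] < arr[:-1, 1]):
                    bad = int(np.flatnonzero(arr[1:, 0] < arr[:-1, 1])[0])
                    raise ParseError(
                        f"overlapping intervals on {chrom} near position "
                        f"{int(arr[bad, 1])}",
                        str(path),
                    )
                sig.add_intervals(chrom, strand, arr[:, 0].astype(np.int64),
                                  arr[:, 1].astype(np.int64), arr[:, 2])
        return sig

    def write_bedgraph_pair(self, plus_path, minus_path) -> None:
        """Write one bedGraph per strand; values use shortest round-trip repr so
        a write/read cycle reproduces the signal exactly."""
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            with open(path, "w") as fh:
                for chrom in sorted(self.chroms):
                    starts, ends, values = self.runs(chrom, strand)
                    for s, e, v in zip(starts, ends, values):
                        fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{float(v)!r}\n")


def mask_signal(
    signal: StrandedBaseSignal, regions: Iterable[tuple[str, int, int]]
) -> StrandedBaseSignal:
    """Zero the signal outside the given genomic regions (both strands).

    Stands in for the read-pair retention filter (major isoform ± flank):
    since inputs are position-level signals rather than alignments, retaining
    read pairs inside the window is equivalent to masking signal outside it.
    """
    out = StrandedBaseSignal(signal.metadata)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    # merge overlapping/adjacent regions so masked runs are emitted once
    for chrom, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        by_chrom[chrom] = [tuple(x) for x in merged]
    for (chrom, strand), (starts, ends, values) in signal._runs.items():
        keep_s, keep_e, keep_v = [], [], []
        for rs, re_ in by_chrom.get(chrom, []):
            i0 = int(np.searchsorted(ends, rs, side="right"))
            i1 = int(np.searchsorted(starts, re_, side="left"))
            if i1 <= i0:
                continue
            s = np.maximum(starts[i0:i1], rs)
            e = np.minimum(ends[i0:i1], re_)
            keep_s.append(s)
            keep_e.append(e)
            keep_v.append(values[i0:i1])
        if keep_s:
            out.add_intervals(
                chrom, strand,
                np.concatenate(keep_s), np.concatenate(keep_e), np.concatenate(keep_v),
            )
    return out


def count_region(
    signal: StrandedBaseSignal,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    unknown_chrom: str = "warn",
) -> float:
    """Sum of base values over a half-open interval on one strand.

    Unknown chromosomes yield 0 with a warning by default
    (``unknown_chrom="error"`` raises instead).
    """
    if chrom not in signal.chroms:
        if unknown_chrom == "error":
            raise InputError(f"unknown chromosome {chrom!r}")
        log.warning("count_region: unknown chromosome %r, returning 0", chrom)
        return 0.0
    return signal.count(chrom, strand, start, end)


# --------------------------------------------------------------------------
# antisense bias
# --------------------------------------------------------------------------

def estimate_antisense_ratio(
    signal: StrandedBaseSignal,
    regions: Sequence[tuple[str, str, int, int]],
    min_coverage: float = 100.0,
) -> float:
    """Estimate the antisense leak ratio ``c`` of a sample.

    ``regions`` are (chrom, sense_strand, start, end) intervals whose opposite
    strand carries no annotated transcription, so any antisense signal there is
    spurious.  Over positions with sense coverage >= ``min_coverage``::

        c = sum(antisense) / sum(sense)

    Raises
    ------
    InputError
        If no position qualifies; lower ``min_coverage``.
    """
    sense_sum = 0.0
    anti_sum = 0.0
    n_pos = 0
    for chrom, strand, start, end in regions:
        sense = signal.dense(chrom, strand, start, end)
        anti = signal.dense(chrom, _other_strand(strand), start, end)
        mask = sense >= min_coverage
        n_pos += int(mask.sum())
        sense_sum += float(sense[mask].sum())
        anti_sum += float(anti[mask].sum())
    if n_pos == 0 or sense_sum == 0:
        raise InputError(
            f"no positions with sense coverage >= {min_coverage}; "
            "lower min_coverage"
        )
    return anti_sum / sense_sum


def correct_antisense(
    sense_count, antisense_count, c: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Invert the strand-mixing model to recover true strand counts.

    Observed counts are modelled as ``obs_s = true_s + c*true_a`` and
    ``obs_a = true_a + c*true_s`` (each strand receives a fraction ``c`` of
    the other strand's true signal).  The 2x2 inversion is exact for
    ``0 <= c < 1``; corrected values are clamped at zero with a warning, since
    counting noise can push the inversion slightly negative.
    """
    if not 0 <= c < 1:
        raise InputError(f"antisense ratio must be in [0, 1), got {c}")
    if c == 0:
        return sense_count, antisense_count
    s = np.asarray(sense_count, dtype=np.float64)
    a = np.asarray(antisense_count, dtype=np.float64)
    denom = 1.0 - c * c
    true_s = (s - c * a) / denom
    true_a = (a - c * s) / denom
    scale = max(float(np.max(s, initial=0.0)), float(np.max(a, initial=0.0)), 1.0)
    if min(float(np.min(true_s)), float(np.min(true_a))) < -1e-9 * scale:
        # routine under counting noise, so logged below warning level
        log.debug("antisense correction produced negative counts; clamping to 0")
    true_s = np.clip(true_s, 0.0, None)
    true_a = np.clip(true_a, 0.0, None)
    if np.isscalar(sense_count) and np.isscalar(antisense_count):
        return float(true_s), float(true_a)
    return true_s, true_a


# --------------------------------------------------------------------------
# sample scaling
# --------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    For genes positive in every sample, each sample's factor is the median of
    ``count / geometric-mean-across-samples``.  Factors are renormalized to
    geometric mean 1, fixing the arbitrary overall scale the method leaves
    open; divide counts by the factor to normalize.
    """
    if (counts.values < 0).any():
        raise InputError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise InputError("no gene has positive counts in every sample")
    sub = counts.loc[positive].to_numpy(dtype=np.float64)
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geomean
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def spikein_factors(spike_totals: pd.Series, reference: str | None = None) -> pd.Series:
    """Per-sample scale factors from exogenous spike-in totals.

    ``factor_j = total_ref / total_j`` with the first sample as reference by
    default; multiply raw signal by the factor to normalize.
    """
    totals = pd.Series(spike_totals, dtype=float)
    if (totals <= 0).any():
        raise InputError("spike-in totals must be positive")
    ref = totals.index[0] if reference is None else reference
    return (totals[ref] / totals).rename("spikein_factor")


def filter_expressed(
    counts: pd.DataFrame, gene_lengths: pd.Series, min_rpk: float = 10.0
) -> pd.Index:
    """Expressed genes: >= ``min_rpk`` reads per kilobase at >= 1 time point.

    ``counts`` columns are per-time-point values (replicates already
    averaged); lengths in bp.
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    rpk = counts.div(lengths / 1000.0, axis=0)
    return counts.index[(rpk >= min_rpk).any(axis=1)]
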