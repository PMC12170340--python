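"""Gene models from isoform quantifications.

One *major* transcribed isoform is selected per gene — the isoform carrying
more than 70% of the gene's expression at one or more time points, provided
no competing isoform does so at any time point.  All downstream windows
(pause search, quantification intervals, read-retention flanks) are defined
on the major isoform.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open.  ``tss`` and ``pa`` are *boundary*
coordinates of the transcription unit: on ``+`` the TSS is the span start and
the pA site the span end; on ``-`` the TSS is the span end and the pA site
the span start.  "Downstream" means increasing coordinate on ``+`` and
decreasing on ``-``; an offset ``o`` downstream of the TSS therefore covers
``[tss + o, tss + o + 1)`` on ``+`` and ``[tss - o - 1, tss - o)`` on ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationMismatchError, InputError

#: single-exon genes are quantified from this many bp downstream of the TSS
SINGLE_EXON_TSS_OFFSET = 300


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one isoform (exons genomic-sorted, half-open)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if any(e <= s for s, e in exons):
            raise InputError(f"{self.transcript_id}: empty exon")
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            raise InputError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """One gene represented by its major isoform.

    ``exons`` are genomic-sorted half-open intervals; ``nonfirst_exon_length``
    is the quantification length L (non-first exons for multi-exon genes, the
    region from 300 bp past the TSS to the pA site for single-exon genes).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    single_exon: bool = field(init=False)
    nonfirst_exon_length: int = field(init=False)

    def __post_init__(self):
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        self.single_exon = len(self.exons) == 1
        self.nonfirst_exon_length = sum(e - s for s, e in self.i_intervals())

    # boundary coordinates (see module docstring)
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]

    @property
    def pa(self) -> int:
        return self.span[1] if self.strand == "+" else self.span[0]

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def usable_for_initiation(self) -> bool:
        return self.nonfirst_exon_length > 0

    # ------------------------------------------------------------- windows

    def first_exon(self) -> tuple[int, int]:
        """The 5'-most exon in transcription direction."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def i_intervals(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals over which initiation frequency is quantified."""
        if len(self.exons) > 1:
            first = self.exons[0] if self.strand == "+" else self.exons[-1]
            return tuple(e for e in self.exons if e != first)
        s, e = self.exons[0]
        if e - s <= SINGLE_EXON_TSS_OFFSET:
            return ()
        if self.strand == "+":
            return ((s + SINGLE_EXON_TSS_OFFSET, e),)
        return ((s, e - SINGLE_EXON_TSS_OFFSET),)

    def pause_window(self, size: int = 250) -> tuple[int, int]:
        """Genomic interval of the promoter-proximal search window
        [TSS, TSS + size) in transcription direction."""
        if self.strand == "+":
            return self.tss, self.tss + size
        return self.tss - size, self.tss

    def retention_window(self, flank: int = 500) -> tuple[str, int, int]:
        """Read-retention window: the major isoform span ± ``flank`` bp."""
        s, e = self.span
        return self.chrom, max(0, s - flank), e + flank

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of the base ``offset`` bp downstream of the TSS."""
        return self.tss + offset if self.strand == "+" else self.tss - offset - 1

    def downstream_interval(self, offset_start: int, offset_end: int) -> tuple[int, int]:
        """Genomic half-open interval for TSS offsets [offset_start, offset_end)."""
        if self.strand == "+":
            return self.tss + offset_start, self.tss + offset_end
        return self.tss - offset_end, self.tss - offset_start


def gene_region_windows(model: GeneModel, flank: int = 500, pause_size: int = 250) -> dict:
    """All assay regions of one gene as strand-resolved genomic intervals."""
    return {
        "retention": model.retention_window(flank),
        "pause": model.pause_window(pause_size),
        "i_intervals": model.i_intervals(),
        "usable_for_initiation": model.usable_for_initiation,
    }


# --------------------------------------------------------------------------
# major isoform selection
# --------------------------------------------------------------------------

def select_major_isoforms(
    tpm_table: pd.DataFrame,
    structures: Mapping[str, TranscriptModel],
    dominance_threshold: float = 0.70,
    exclude_chroms: Iterable[str] = ("chrM",),
    sample_groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, GeneModel]:
    """Select one major isoform per gene and build its :class:`GeneModel`.

    An isoform is major iff its share of the gene's per-time-point mean TPM
    strictly exceeds ``dominance_threshold`` at >= 1 time point, and no other
    isoform of the gene does so at any time point.  Genes on excluded
    chromosomes, and genes without a qualifying isoform (including those with
    conflicting dominance across time points), are dropped.

    Parameters
    ----------
    tpm_table:
        Columns ``transcript_id``, ``gene_id``, then one TPM column per
        sample.  TPM must be non-negative.
    structures:
        transcript_id -> :class:`TranscriptModel`.
    sample_groups:
        Optional time-point label -> list of replicate column names; replicate
        columns are averaged per time point first.  By default every sample
        column is its own time point.
    """
    value_cols = [c for c in tpm_table.columns if c not in ("transcript_id", "gene_id")]
    if not value_cols:
        raise InputError("tpm_table has no sample columns")
    if (tpm_table[value_cols].values < 0).any():
        raise InputError("negative TPM values")

    if sample_groups is None:
        means = tpm_table[value_cols].copy()
    else:
        means = pd.DataFrame(
            {tp: tpm_table[list(cols)].mean(axis=1) for tp, cols in sample_groups.items()}
        )
    means.index = tpm_table.index

    exclude = set(exclude_chroms)
    models: dict[str, GeneModel] = {}
    for gene_id, grp in tpm_table.groupby("gene_id", sort=False):
        sub = means.loc[grp.index].to_numpy(dtype=float)
        totals = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(totals > 0, sub / totals, 0.0)
        dominant = (shares > dominance_threshold).any(axis=1)
        if dominant.sum() != 1:
            continue  # none, or conflicting dominance between isoforms
        tx_id = grp["transcript_id"].iloc[int(np.flatnonzero(dominant)[0])]
        if tx_id not in structures:
            raise AnnotationMismatchError(
                f"no transcript structure for selected isoform {tx_id!r}"
            )
        tx = structures[tx_id]
        if tx.chrom in exclude:
            continue
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript_id=tx_id,
            chrom=tx.chrom,
            strand=tx.strand,
            exons=tx.exons,
        )
    return models


# --------------------------------------------------------------------------
# BED12 I/O (plain-text structure interchange)
# --------------------------------------------------------------------------

def write_bed12(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            s, e = tx.span
            sizes = ",".join(str(ee - ss) for ss, ee in tx.exons)
            starts = ",".join(str(ss - s) for ss, ee in tx.exons)
            fh.write(
                f"{tx.chrom}\t{s}\t{e}\t{tx.transcript_id}|{tx.gene_id}\t0\t"
                f"{tx.strand}\t{s}\t{e}\t0\t{len(tx.exons)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path) -> dict[str, TranscriptModel]:
    out: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise InputError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            tx_id, _, gene_id = name.partition("|")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            out[tx_id] = TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id or tx_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
    return out
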