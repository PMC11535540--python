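"""Gene- and window-level scoring of binned genomic signal tracks.

The central quantity is the weighted mean of a binned log2-ratio signal
over a genomic interval, with bin values weighted by their overlap with the
interval.  From it derive:

* the genic nuclear-lamina association score — the mean DamID log2 ratio
  over the gene body extended by a 10 kb flank on each side; genes with a
  strictly positive score are called LAD genes, all others iLAD;
* promoter ChIP scores over a +/-500 bp window around the TSS;
* per-gene signal deltas between two conditions;
* gain/loss classification of the most proximal peak around a TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenomeLayout, SignalTrack

__all__ = [
    "GeneNLScore",
    "weighted_mean_signal",
    "genic_nl_score",
    "annotate_genes",
    "promoter_score",
    "active_promoter_filter",
    "gene_signal_delta",
    "proximal_peak_change",
]


@dataclass(frozen=True)
class GeneNLScore:
    """Genic NL-association score; LAD call is strictly score > 0."""

    gene_id: str
    score: float  # mean log2 ratio over gene +/- flank; NaN if no data

    @property
    def is_lad(self) -> bool:
        return bool(self.score > 0)  # NaN compares False: missing genes are not LAD

    @property
    def missing(self) -> bool:
        return math.isnan(self.score)


def weighted_mean_signal(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Overlap-weighted mean of track values over [start, end).

    Returns NaN when no bin overlaps the interval (missing data).
    """
    if not start < end:
        raise ValueError(f"empty interval {chrom}:{start}-{end}")
    starts, ends, values = track.arrays(chrom)
    if len(starts) == 0:
        return math.nan
    lo = int(np.searchsorted(ends, start, side="right"))
    hi = int(np.searchsorted(starts, end, side="left"))
    if lo >= hi:
        return math.nan
    ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
    ov = np.clip(ov, 0, None).astype(float)
    w = ov.sum()
    if w == 0:
        return math.nan
    return float(np.dot(values[lo:hi], ov) / w)


def _clipped_window(
    chrom: str, start: int, end: int, layout: GenomeLayout | None
) -> tuple[int, int]:
    start = max(0, start)
    if layout is not None:
        end = min(end, layout.chrom_lengths.get(chrom, end))
    return start, end


def genic_nl_score(
    track: SignalTrack,
    model: GeneModel,
    flank: int = 10_000,
    layout: GenomeLayout | None = None,
) -> GeneNLScore:
    """NL-association score over the gene body +/- ``flank``, clipped at chromosome ends."""
    start, end = _clipped_window(
        model.chrom, model.region_start - flank, model.region_end + flank, layout
    )
    score = weighted_mean_signal(track, model.chrom, start, end)
    return GeneNLScore(model.gene_id, score)


def annotate_genes(
    track: SignalTrack,
    models: Sequence[GeneModel],
    flank: int = 10_000,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Genic NL scores and LAD calls for a set of genes.

    Genes with no overlapping bins get a NaN score and ``is_lad = False``;
    downstream LAD/iLAD contrasts should drop them (see ``missing`` column).
    """
    rows = []
    for m in models:
        s = genic_nl_score(track, m, flank=flank, layout=layout)
        rows.append((s.gene_id, s.score, s.is_lad, s.missing))
    return pd.DataFrame(rows, columns=["gene_id", "score", "is_lad", "missing"])


def promoter_score(
    track: SignalTrack,
    chrom: str,
    tss: int,
    strand: str = "+",
    halfwidth: int = 500,
    layout: GenomeLayout | None = None,
) -> float:
    """Weighted mean signal over [tss - halfwidth, tss + halfwidth), clipped.

    The strand only locates the TSS upstream/downstream sense; the window
    itself is symmetric, so the score does not depend on it.
    """
    del strand  # symmetric window
    start, end = _clipped_window(chrom, tss - halfwidth, tss + halfwidth, layout)
    if start >= end:
        return math.nan
    return weighted_mean_signal(track, chrom, start, end)


def active_promoter_filter(
    table: pd.DataFrame, activity_col: str = "activity", threshold: float = 0.3
) -> pd.DataFrame:
    """Keep rows with activity strictly above the threshold (TPM > 0.3 rule)."""
    return table[table[activity_col] > threshold].copy()


def gene_signal_delta(
    track_a: SignalTrack,
    track_b: SignalTrack,
    model: GeneModel,
    flank: int = 0,
    layout: GenomeLayout | None = None,
) -> float:
    """Genic score on track_b minus track_a (e.g. heterochromatin change after knockout)."""
    sa = genic_nl_score(track_a, model, flank=flank, layout=layout).score
    sb = genic_nl_score(track_b, model, flank=flank, layout=layout).score
    return sb - sa


def _proximal_midpoint(peaks: pd.DataFrame, chrom: str, tss: int, max_dist: int) -> float | None:
    sel = peaks[peaks["chrom"] == chrom]
    if sel.empty:
        return None
    mid = ((sel["start"] + sel["end"]) // 2).to_numpy()
    dist = np.abs(mid - tss)
    i = int(np.argmin(dist))
    if dist[i] > max_dist:
        return None
    return float(mid[i])


def proximal_peak_change(
    peaks_wt: pd.DataFrame,
    peaks_ko: pd.DataFrame,
    chrom: str,
    tss: int,
    max_dist: int = 100_000,
    match_tol: int = 1_000,
) -> str:
    """Classify the most proximal peak around a TSS as gained, lost or stable.

    The nearest peak (by midpoint) within ``max_dist`` of the TSS is found in
    each condition.  A peak is *matched* if the other condition has a peak
    midpoint within ``match_tol`` of it.  Status: ``gain`` if the proximal
    knockout peak is unmatched in wild type; ``loss`` if the proximal wild-type
    peak is unmatched in knockout; ``stable`` if the proximal peaks match;
    ``none`` if neither condition has a peak within ``max_dist``.  Both
    default distances are interpretive choices, exposed as parameters.
    """
    wt = _proximal_midpoint(peaks_wt, chrom, tss, max_dist)
    ko = _proximal_midpoint(peaks_ko, chrom, tss, max_dist)
    if wt is None and ko is None:
        return "none"

    def matched(mid: float, other: pd.DataFrame) -> bool:
        sel = other[other["chrom"] == chrom]
        if sel.empty:
            return False
        om = ((sel["start"] + sel["end"]) // 2).to_numpy()
        return bool(np.min(np.abs(om - mid)) <= match_tol)

    if ko is not None and not matched(ko, peaks_wt):
        return "gain"
    if wt is not None and not matched(wt, peaks_ko):
        return "loss"
    return "stable"
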