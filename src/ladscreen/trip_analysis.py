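"""Barcoded-reporter (TRIP) expression analysis.

Thousands of reporters integrated in parallel carry unique barcodes; each
barcode is sequenced in genomic DNA (abundance of the integration in the
cell pool) and in cDNA (its expression).  Expression per barcode and sample
is the cDNA share normalized by the gDNA share; barcodes must exceed a
gDNA count of 100 in every sample to be analyzed.  Per-barcode log2 fold
changes between a perturbation and its control are contrasted between LAD
and iLAD integration sites with a rank-sum test, and replicate concordance
is summarized with Spearman rank correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import SignalTrack
from .lad_annotation import weighted_mean_signal

__all__ = [
    "TripContrast",
    "annotate_barcodes",
    "filter_barcodes",
    "normalize_expression",
    "expression_matrix",
    "barcode_lfc",
    "lad_contrast",
    "replicate_correlation",
    "flag_low_depth_samples",
    "gdna_columns",
    "cdna_columns",
]


def gdna_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("gDNA:")]


def cdna_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("cDNA:")]


def sample_names(table: pd.DataFrame) -> list[str]:
    names = [c.split(":", 1)[1] for c in gdna_columns(table)]
    cdna = {c.split(":", 1)[1] for c in cdna_columns(table)}
    if set(names) != cdna:
        raise ValueError("gDNA and cDNA sample columns do not match")
    return names


def annotate_barcodes(
    table: pd.DataFrame, track: SignalTrack, flank: int = 10_000
) -> pd.DataFrame:
    """Attach an NL score and LAD call to each barcode's integration site.

    The score is the weighted mean DamID signal over position +/- ``flank``
    (genic-style point score); ``is_lad`` is strictly score > 0.
    """
    out = table.copy()
    scores = [
        weighted_mean_signal(track, str(r.chrom), max(0, int(r.pos) - flank), int(r.pos) + flank)
        for r in table.itertuples(index=False)
    ]
    out["nl_score"] = scores
    out["is_lad"] = [bool(s > 0) for s in scores]
    return out


def filter_barcodes(table: pd.DataFrame, min_gdna: int = 100) -> pd.DataFrame:
    """Keep barcodes whose gDNA count is strictly above ``min_gdna`` in every sample."""
    gcols = gdna_columns(table)
    if not gcols:
        raise ValueError("no gDNA: columns in table")
    keep = (table[gcols] > min_gdna).all(axis=1)
    return table[keep].copy()


def normalize_expression(
    table: pd.DataFrame, sample: str, mode: str = "share"
) -> pd.Series:
    """Per-barcode expression in one sample, normalized by gDNA.

    ``share`` mode (default): (cDNA_i / sum_j cDNA_j) / (gDNA_i / sum_j gDNA_j),
    sums over barcodes within the sample — invariant to global rescaling of
    either library.  ``ratio`` mode: the raw cDNA_i / gDNA_i ratio.
    """
    g = table[f"gDNA:{sample}"].astype(float)
    c = table[f"cDNA:{sample}"].astype(float)
    if mode == "share":
        gs, cs = g.sum(), c.sum()
        if gs == 0 or cs == 0:
            raise ValueError(f"sample {sample!r} has zero total counts")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (c / cs) / (g / gs)
    elif mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = c / g
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out.name = sample
    return out


def expression_matrix(
    table: pd.DataFrame, samples: Sequence[str] | None = None, mode: str = "share"
) -> pd.DataFrame:
    """Barcodes x samples matrix of gDNA-normalized expression values."""
    if samples is None:
        samples = sample_names(table)
    mat = pd.DataFrame({s: normalize_expression(table, s, mode=mode) for s in samples})
    mat.index = pd.Index(table["barcode"], name="barcode")
    return mat


def barcode_lfc(
    table: pd.DataFrame,
    condition_samples: Sequence[str],
    control_samples: Sequence[str],
    mode: str = "share",
) -> pd.DataFrame:
    """Per-barcode log2 fold change of mean normalized expression.

    Barcodes with zero mean control expression cannot yield a finite fold
    change; they are returned flagged (``excluded = True``) with NaN log2FC.
    """
    expr = expression_matrix(table, list(condition_samples) + list(control_samples), mode=mode)
    cond = expr[list(condition_samples)].mean(axis=1)
    ctrl = expr[list(control_samples)].mean(axis=1)
    excluded = ctrl == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(cond / ctrl)
    lfc[excluded] = np.nan
    return pd.DataFrame({"log2fc": lfc, "excluded": excluded})


@dataclass
class TripContrast:
    """LAD-vs-iLAD contrast of per-barcode expression fold changes."""

    n_lad: int
    n_ilad: int
    median_lad: float
    median_ilad: float
    mean_lad: float
    mean_ilad: float
    ranksum_p: float

    @property
    def mean_difference(self) -> float:
        return self.mean_lad - self.mean_ilad


def lad_contrast(lfc: pd.Series | np.ndarray, is_lad: pd.Series | np.ndarray) -> TripContrast:
    """Rank-sum test of LAD vs iLAD barcode log2 fold changes."""
    lfc = np.asarray(lfc, dtype=float)
    is_lad = np.asarray(is_lad, dtype=bool)
    ok = np.isfinite(lfc)
    lad = lfc[ok & is_lad]
    ilad = lfc[ok & ~is_lad]
    if len(lad) == 0 or len(ilad) == 0:
        raise ValueError("both LAD and iLAD groups must be non-empty")
    p = float(stats.mannwhitneyu(lad, ilad, alternative="two-sided").pvalue)
    return TripContrast(
        n_lad=len(lad),
        n_ilad=len(ilad),
        median_lad=float(np.median(lad)),
        median_ilad=float(np.median(ilad)),
        mean_lad=float(lad.mean()),
        mean_ilad=float(ilad.mean()),
        ranksum_p=p,
    )


def replicate_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between sample columns."""
    samples = list(expr.columns)
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        rho = stats.spearmanr(expr[a], expr[b]).statistic
        out.loc[a, b] = out.loc[b, a] = float(rho)
    return out


def flag_low_depth_samples(table: pd.DataFrame, min_total_cdna: int) -> list[str]:
    """Samples whose total cDNA count falls below a floor (candidate discards).

    Low-depth replicates are flagged for the analyst, never dropped silently.
    """
    flagged = []
    for s in sample_names(table):
        if table[f"cDNA:{s}"].sum() < min_total_cdna:
            flagged.append(s)
    return flagged
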