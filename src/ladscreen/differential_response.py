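"""LAD-vs-iLAD differential-response analysis of expression perturbations.

Given a per-gene differential-expression table (log2 fold change, adjusted
p-value, control expression in TPM) and LAD/iLAD labels, this module

* drops completely inactive genes (control TPM < 0.3),
* classifies genes as up / down / not-significant at an adjusted-p cutoff,
* builds an expression-matched iLAD control set by walking the TPM-sorted
  gene list in blocks of 20 and sampling, per block, as many iLAD genes as
  there are LAD genes,
* contrasts response proportions between strata with Fisher's exact test,
  and log2FC distributions with a rank-sum (location) and a Levene-type
  (spread) test.

A deliberately simple DE caller on raw count matrices is included so the
whole analysis can run on synthetic counts: per-gene log2(count+1) means
compared by Welch's t-test with BH correction.  It is a desk-scale caller,
not a negative-binomial GLM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_stats import bh_adjust, fisher_two_sided

__all__ = [
    "MatchedSet",
    "ResponseSummary",
    "simple_de_caller",
    "activity_filter",
    "classify_de",
    "expression_match",
    "proportion_tests",
    "shift_and_variance_tests",
]


def simple_de_caller(
    counts: pd.DataFrame,
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression from a genes x samples count matrix.

    log2FC is the difference of mean log2(count + pseudocount) between
    treatment and control; p comes from Welch's unequal-variance t-test on
    the same transformed values, adjusted by Benjamini-Hochberg.  tpm_ctrl
    is the control-mean count share scaled to one million (genes are treated
    as equal-length, so this is a TPM-like activity measure).
    """
    for s in list(control_samples) + list(treatment_samples):
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} not in count matrix")
    if len(control_samples) < 2 or len(treatment_samples) < 2:
        raise ValueError("need >= 2 replicates per group")
    ctrl = counts[list(control_samples)].to_numpy(dtype=float)
    treat = counts[list(treatment_samples)].to_numpy(dtype=float)
    log_c = np.log2(ctrl + pseudocount)
    log_t = np.log2(treat + pseudocount)
    lfc = log_t.mean(axis=1) - log_c.mean(axis=1)
    with warnings.catch_warnings():
        # silent genes have (near-)zero variance in both groups; their NaN p
        # is mapped to 1 below, so scipy's precision-loss warning is noise
        warnings.simplefilter("ignore", RuntimeWarning)
        _t, p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    share = ctrl / np.maximum(ctrl.sum(axis=0, keepdims=True), 1.0)
    tpm_ctrl = share.mean(axis=1) * 1e6
    return pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2fc": lfc,
            "padj": bh_adjust(p),
            "tpm_ctrl": tpm_ctrl,
        }
    ).reset_index(drop=True)


def activity_filter(de: pd.DataFrame, tpm_min: float = 0.3) -> pd.DataFrame:
    """Drop completely inactive genes: keep exactly tpm_ctrl >= tpm_min.

    The exclusion rule is "TPM < 0.3", so a gene sitting exactly on the
    threshold is kept.
    """
    return de[de["tpm_ctrl"] >= tpm_min].copy()


def classify_de(de: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-gene response label: up / down / ns.

    ``up`` iff padj < alpha and log2fc > 0; ``down`` iff padj < alpha and
    log2fc < 0.  Missing padj or exactly zero log2fc is ``ns``.
    """
    padj = de["padj"]
    sig = padj.notna() & (padj < alpha)
    label = pd.Series("ns", index=de.index)
    label[sig & (de["log2fc"] > 0)] = "up"
    label[sig & (de["log2fc"] < 0)] = "down"
    return label


@dataclass
class MatchedSet:
    """Expression-matched iLAD control genes with per-block bookkeeping."""

    selected: list[str]
    blocks: pd.DataFrame  # block, n_genes, n_lad, n_ilad, n_selected, shortfall

    @property
    def total_shortfall(self) -> int:
        return int(self.blocks["shortfall"].sum())


def expression_match(
    de: pd.DataFrame,
    lad_labels: Mapping[str, bool],
    block: int = 20,
    seed: int | np.random.Generator = 0,
    descending: bool = True,
) -> MatchedSet:
    """Sample iLAD genes that match the LAD gene expression distribution.

    Genes are sorted by ``tpm_ctrl`` (descending by default; ties broken by
    gene_id for determinism) and walked in consecutive blocks of ``block``
    genes (the last block may be short).  In each block, with k LAD genes
    present, min(k, #iLAD in block) iLAD genes are drawn uniformly without
    replacement; blocks where LAD genes outnumber iLAD genes record the
    shortfall.  The union over blocks is the matched control set.
    """
    missing = [g for g in de["gene_id"] if g not in lad_labels]
    if missing:
        raise ValueError(f"no LAD label for {len(missing)} genes (first: {missing[0]!r})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = de.sort_values(
        ["tpm_ctrl", "gene_id"], ascending=[not descending, True], kind="mergesort"
    ).reset_index(drop=True)
    selected: list[str] = []
    rows = []
    for bi, lo in enumerate(range(0, len(ordered), block)):
        chunk = ordered.iloc[lo : lo + block]
        is_lad = chunk["gene_id"].map(lad_labels).astype(bool)
        lad_n = int(is_lad.sum())
        ilad_genes = chunk.loc[~is_lad, "gene_id"].tolist()
        take = min(lad_n, len(ilad_genes))
        if take > 0:
            picked = rng.choice(len(ilad_genes), size=take, replace=False)
            selected.extend(ilad_genes[i] for i in sorted(picked))
        rows.append((bi, len(chunk), lad_n, len(ilad_genes), take, lad_n - take))
    blocks = pd.DataFrame(
        rows, columns=["block", "n_genes", "n_lad", "n_ilad", "n_selected", "shortfall"]
    )
    return MatchedSet(selected, blocks)


@dataclass
class ResponseSummary:
    """Two-stratum response contrast: proportions, Fisher, shift and spread tests."""

    strata: pd.DataFrame  # stratum, n, n_up, n_down, frac_up, frac_down
    fisher_up_p: float
    fisher_down_p: float
    ranksum_p: float
    levene_p: float


def proportion_tests(
    de: pd.DataFrame,
    labels: pd.Series,
    strata: pd.Series,
    levene_center: str = "mean",
) -> ResponseSummary:
    """Contrast up/down response frequencies and log2FC distributions.

    ``labels`` holds up/down/ns per gene, ``strata`` exactly two stratum
    names (e.g. LAD and iLAD, or LAD and matched-iLAD), both aligned to
    ``de``.  Up- and down-proportions are contrasted separately with the
    two-sided Fisher's exact test; log2FC location with a rank-sum test and
    spread with a Levene-type test.
    """
    names = sorted(strata.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two strata, got {names}")
    rows = []
    tables = {}
    for name in names:
        sel = strata == name
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"empty stratum {name!r}")
        n_up = int((labels[sel] == "up").sum())
        n_down = int((labels[sel] == "down").sum())
        rows.append((name, n, n_up, n_down, n_up / n, n_down / n))
        tables[name] = (n, n_up, n_down)
    (n0, up0, dn0), (n1, up1, dn1) = tables[names[0]], tables[names[1]]
    fisher_up = fisher_two_sided(up0, n0 - up0, up1, n1 - up1)
    fisher_down = fisher_two_sided(dn0, n0 - dn0, dn1, n1 - dn1)
    lfc0 = de.loc[(strata == names[0]).to_numpy(), "log2fc"].to_numpy()
    lfc1 = de.loc[(strata == names[1]).to_numpy(), "log2fc"].to_numpy()
    ranksum_p, levene_p = shift_and_variance_tests(lfc0, lfc1, levene_center=levene_center)
    return ResponseSummary(
        pd.DataFrame(rows, columns=["stratum", "n", "n_up", "n_down", "frac_up", "frac_down"]),
        fisher_up,
        fisher_down,
        ranksum_p,
        levene_p,
    )


def shift_and_variance_tests(
    x: np.ndarray, y: np.ndarray, levene_center: str = "mean"
) -> tuple[float, float]:
    """Rank-sum p (location) and Levene-type p (spread) for two samples.

    The rank-sum test uses the exact null distribution when the combined
    sample is small (n <= 25, no ties), otherwise the tie-corrected normal
    approximation.  ``levene_center`` is "mean" for the classic Levene test
    or "median" for the Brown-Forsythe variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    exact_ok = len(combined) <= 25 and len(np.unique(combined)) == len(combined)
    method = "exact" if exact_ok else "asymptotic"
    ranksum = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    if levene_center not in ("mean", "median"):
        raise ValueError("levene_center must be 'mean' or 'median'")
    if len(x) < 2 or len(y) < 2:
        levene_p = math.nan
    else:
        levene_p = float(stats.levene(x, y, center=levene_center).pvalue)
    return float(ranksum.pvalue), levene_p
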