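"""Study-condition benchmark trials on synthetic data.

Each function runs one seeded end-to-end trial of a pipeline stage under
the package's reference study conditions (screen depth of ~100 sense
insertions per gene per pool, two-level DamID tracks at sigma = 0.5,
LAD-depressed expression with planted response fractions, TRIP pools with
a planted knockdown effect) and returns the summary quantities a method
evaluation needs: hit counts under the null, sensitivity/FDR with planted
effects, LAD-call rates, matching quality, response-contrast p-values and
TRIP effect estimates.  The trials are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import differential_response as deresp
from . import lad_annotation, screen_stats, trip_analysis
from .formats_io import GeneModel
from .synthetic_data import (
    DESimConfig,
    control_expression_levels,
    LadSimConfig,
    ScreenSimConfig,
    TripSimConfig,
    rng_for,
    simulate_damid_track,
    simulate_de_counts,
    simulate_screen,
    simulate_trip,
    synthetic_gene_models,
    synthetic_lads,
)

__all__ = [
    "planted_theta",
    "screen_trial",
    "ScreenRecovery",
    "screen_null_hits",
    "screen_recovery",
    "lad_call_trial",
    "matching_trial",
    "de_response_trial",
    "trip_trial",
]


def planted_theta(
    models: Sequence[GeneModel], n_repressors: int, n_activators: int,
    theta_rep: float = 4.0, theta_act: float = 0.25,
) -> dict[str, float]:
    """Plant effects on the first genes of the catalogue (deterministic)."""
    ids = [m.gene_id for m in models]
    theta = {g: theta_rep for g in ids[:n_repressors]}
    theta.update({g: theta_act for g in ids[n_repressors : n_repressors + n_activators]})
    return theta


def screen_trial(
    seed: int,
    n_genes: int = 2_000,
    n_repressors: int = 0,
    n_activators: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and score one screen; returns (scores, truth)."""
    layout, models = synthetic_gene_models(n_genes=n_genes, seed=rng_for(seed, "genome"))
    cfg = ScreenSimConfig(theta=planted_theta(models, n_repressors, n_activators), seed=seed)
    high, low, truth = simulate_screen(cfg, models, layout)
    regions = screen_stats.build_counting_regions(models)
    scores = screen_stats.score_screen(high, low, regions)
    return scores, truth


def screen_null_hits(seed: int, n_genes: int = 2_000, alpha: float = 0.05) -> int:
    """Number of fcpv < alpha genes in an all-neutral screen."""
    scores, _ = screen_trial(seed, n_genes=n_genes)
    return int((scores["fcpv"] < alpha).sum())


@dataclass
class ScreenRecovery:
    """Hit-recovery bookkeeping for one planted-effect screen."""

    n_planted: int
    n_hits: int
    n_true_positives: int
    n_false_positives: int
    n_direction_errors: int  # true positives whose log2 MI sign contradicts log2 theta

    @property
    def sensitivity(self) -> float:
        return self.n_true_positives / self.n_planted

    @property
    def fdr(self) -> float:
        return self.n_false_positives / self.n_hits if self.n_hits else 0.0


def screen_recovery(
    seed: int,
    n_neutral: int = 1_900,
    n_repressors: int = 50,
    n_activators: int = 50,
    alpha: float = 0.05,
) -> ScreenRecovery:
    """Recovery of planted repressors (theta=4) and activators (theta=0.25)."""
    n_genes = n_neutral + n_repressors + n_activators
    scores, truth = screen_trial(
        seed, n_genes=n_genes, n_repressors=n_repressors, n_activators=n_activators
    )
    theta = dict(zip(truth["gene_id"], truth["theta"]))
    hits = scores[scores["fcpv"] < alpha]
    planted = {g for g, th in theta.items() if th != 1.0}
    tp = hits[hits["gene_id"].isin(planted)]
    direction_errors = int(
        (np.sign(tp["log2_mi"]) != np.sign(np.log2([theta[g] for g in tp["gene_id"]]))).sum()
    )
    return ScreenRecovery(
        n_planted=len(planted),
        n_hits=len(hits),
        n_true_positives=len(tp),
        n_false_positives=len(hits) - len(tp),
        n_direction_errors=direction_errors,
    )


def lad_call_trial(
    seed: int,
    n_genes: int = 100,
    sigma: float = 0.5,
    bin_size: int = 2_000,
    margin: int = 20_000,
    flank: int = 10_000,
) -> tuple[int, int]:
    """(n called LAD, n eligible) for genes lying >= margin inside planted LADs."""
    layout, models = synthetic_gene_models(
        n_genes=n_genes, intergene_gap_mean=50_000.0, seed=rng_for(seed, "genome")
    )
    # broad planted LADs so a useful share of the fixture's genes sits well
    # inside one (the call-rate denominator)
    lads = synthetic_lads(
        layout, lad_fraction=0.5, mean_lad_length=2e6, seed=rng_for(seed, "lads")
    )
    track, lads = simulate_damid_track(
        LadSimConfig(lads=lads, bin_size=bin_size, sigma=sigma, seed=seed), layout
    )
    called = eligible = 0
    for m in models:
        deep = any(
            s + margin <= m.region_start and m.region_end <= e - margin
            for s, e in lads.get(m.chrom, [])
        )
        if not deep:
            continue
        eligible += 1
        if lad_annotation.genic_nl_score(track, m, flank=flank, layout=layout).is_lad:
            called += 1
    return called, eligible


def matching_trial(
    seed: int,
    n_genes: int = 5_000,
    lad_fraction: float = 0.3,
    block: int = 20,
    tpm_min: float = 0.3,
) -> tuple[float, float]:
    """Expression-matching quality: (rank-sum p, median log10 TPM difference).

    Control TPM is drawn from the LAD-depressed log-normal model of the DE
    generator (no counts needed); after blockwise matching, LAD and matched
    iLAD TPM distributions are compared.
    """
    cfg = DESimConfig(seed=seed)
    rng = rng_for(seed, "de")
    is_lad = rng.random(n_genes) < lad_fraction
    level = control_expression_levels(cfg, is_lad, rng)
    tpm = level / level.sum() * 1e6
    width = len(str(n_genes - 1))
    de = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(n_genes)],
            "log2fc": 0.0,
            "padj": 1.0,
            "tpm_ctrl": tpm,
        }
    )
    labels = dict(zip(de["gene_id"], is_lad))
    de = deresp.activity_filter(de, tpm_min=tpm_min).reset_index(drop=True)
    matched = deresp.expression_match(de, labels, block=block, seed=rng)
    lad_tpm = de.loc[de["gene_id"].map(labels).astype(bool), "tpm_ctrl"].to_numpy()
    ctl_tpm = de.loc[de["gene_id"].isin(set(matched.selected)), "tpm_ctrl"].to_numpy()
    p, _ = deresp.shift_and_variance_tests(np.log10(lad_tpm), np.log10(ctl_tpm))
    diff = float(np.median(np.log10(lad_tpm)) - np.median(np.log10(ctl_tpm)))
    return p, diff


def de_response_trial(
    seed: int,
    n_genes: int = 4_000,
    lad_fraction: float = 0.3,
) -> dict[str, float]:
    """End-to-end differential response under planted LAD-biased upregulation.

    A third of genes sit in LADs (the synthetic gene layout is uniform, and
    LADs canonically hold about a third of the genome).  Returns the LAD
    and matched-iLAD up-proportions and the Fisher p of their contrast.
    """
    from .cli import run_de_response  # local import: cli pulls in click

    rng = rng_for(seed, "de")
    width = len(str(n_genes - 1))
    labels = {
        f"g{i:0{width}d}": bool(v) for i, v in enumerate(rng.random(n_genes) < lad_fraction)
    }
    cfg = DESimConfig(seed=seed)
    counts, _truth = simulate_de_counts(cfg, labels, rng=rng)
    de = deresp.simple_de_caller(
        counts,
        [c for c in counts.columns if c.startswith("ctrl_")],
        [c for c in counts.columns if c.startswith("treat_")],
    )
    lad_table = pd.DataFrame(
        {
            "gene_id": list(labels),
            "score": [1.0 if v else -1.0 for v in labels.values()],
            "is_lad": list(labels.values()),
            "missing": False,
        }
    )
    summary, _matched = run_de_response(de, lad_table, seed=seed)
    by = summary.set_index("stratum")
    return {
        "frac_up_lad": float(by.loc["LAD", "frac_up"]),
        "frac_up_matched_ilad": float(by.loc["matched-iLAD", "frac_up"]),
        "fisher_up_p": float(by["fisher_up_p"].iloc[0]),
    }


def trip_trial(
    seed: int,
    n_barcodes: int = 600,
    lad_fraction: float = 0.5,
    delta: float = 0.5,
    sigma: float = 0.5,
) -> tuple[float, float]:
    """(rank-sum p, LAD-minus-iLAD mean log2FC) for a planted TRIP knockdown.

    LADs cover about half the genome so the pool splits near 300/300.
    LAD labels come from the generator truth (the contrast measures effect
    recovery, not track annotation).
    """
    layout, _models = synthetic_gene_models(n_genes=500, seed=rng_for(seed, "genome"))
    lads = synthetic_lads(layout, lad_fraction=lad_fraction, seed=rng_for(seed, "lads"))
    cfg = TripSimConfig(n_barcodes=n_barcodes, delta=delta, expr_sigma=sigma, seed=seed)
    table, truth = simulate_trip(cfg, lads, layout)
    keep = trip_analysis.filter_barcodes(table, min_gdna=100)
    truth = truth.set_index("barcode").loc[keep["barcode"]]
    n_rep = cfg.n_replicates
    lfc = trip_analysis.barcode_lfc(
        keep,
        [f"kd_r{r + 1}" for r in range(n_rep)],
        [f"ctrl_r{r + 1}" for r in range(n_rep)],
    )
    contrast = trip_analysis.lad_contrast(lfc["log2fc"], truth["is_lad"].to_numpy())
    return contrast.ranksum_p, contrast.mean_difference
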