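"""Synthetic inputs with planted ground truth for every pipeline stage.

Nothing downstream of read mapping requires real sequencing data: this
module emulates

* a synthetic genome of non-overlapping genes on a few chromosomes,
* HIGH/LOW sorted insertion pools from a gene-trap screen, where each
  gene's planted effect theta_g is the odds that one of its disruptive
  (genic sense) insertions ends up in the HIGH pool (theta = 1 neutral,
  theta > 1 repressor, theta < 1 activator),
* binned DamID-style log2-ratio tracks with planted LAD intervals,
* negative-binomial RNA-seq count matrices with LAD-dependent response
  fractions and a realistic (log-normal, LAD-depressed) expression
  distribution,
* TRIP barcode gDNA/cDNA count tables with a planted knockdown effect on
  LAD integrations.

All generators are deterministic given their config seed.  A single root
seed is split into fixed per-generator substreams (:func:`rng_for`), so a
full pipeline run is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenomeLayout, SignalTrack
from .screen_stats import InsertionPool, pool_from_arrays

__all__ = [
    "rng_for",
    "ScreenSimConfig",
    "LadSimConfig",
    "DESimConfig",
    "TripSimConfig",
    "synthetic_gene_models",
    "synthetic_lads",
    "control_expression_levels",
    "simulate_screen",
    "simulate_damid_track",
    "simulate_de_counts",
    "simulate_trip",
    "lads_to_frame",
]

_STREAMS = {"genome": 0, "screen": 1, "damid": 2, "de": 3, "trip": 4, "lads": 5}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator substream of one root seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r} (choose from {sorted(_STREAMS)})")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def synthetic_gene_models(
    n_genes: int = 2_000,
    gene_length_median: float = 20_000.0,
    gene_length_sigma: float = 0.5,
    intergene_gap_mean: float = 20_000.0,
    n_chroms: int = 4,
    seed: int | np.random.Generator = 0,
) -> tuple[GenomeLayout, list[GeneModel]]:
    """Non-overlapping genes laid out sequentially on a few chromosomes.

    Gene lengths are log-normal (median ~20 kb, a human-like scale but with
    a moderate spread) and intergenic gaps exponential.  Strands alternate
    at random.  The chromosome lengths are whatever the layout requires.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lengths = np.maximum(
        600, rng.lognormal(np.log(gene_length_median), gene_length_sigma, n_genes)
    ).astype(np.int64)
    gaps = np.maximum(500, rng.exponential(intergene_gap_mean, n_genes)).astype(np.int64)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    per_chrom = int(np.ceil(n_genes / n_chroms))
    models: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    width = len(str(n_genes - 1))
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 0
        for gi in range(ci * per_chrom, min((ci + 1) * per_chrom, n_genes)):
            cursor += int(gaps[gi])
            start = cursor
            end = start + int(lengths[gi])
            models.append(
                GeneModel(
                    gene_id=f"g{gi:0{width}d}",
                    chrom=chrom,
                    strand=str(strands[gi]),
                    region_start=start,
                    region_end=end,
                    orf_length=max(300, int(lengths[gi]) // 2),
                )
            )
            cursor = end
        if cursor > 0:
            chrom_lengths[chrom] = cursor + int(intergene_gap_mean)
    return GenomeLayout(chrom_lengths), models


# ---------------------------------------------------------------------------
# Gene-trap screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Conditions of the synthetic gene-trap screen.

    ``theta`` maps gene_id -> planted effect (odds that a disruptive
    insertion of the gene lands in HIGH rather than LOW); unlisted genes are
    neutral (theta = 1).  ``expected_insertions_per_pool`` of ``None``
    resolves to an expectation of ~100 genic sense insertions per gene per
    pool, the depth of the screens this package emulates.
    """

    expected_insertions_per_pool: int | None = None
    mean_sense_per_gene: float = 100.0
    intergenic_fraction: float = 0.4
    antisense_fraction: float = 0.5
    duplicate_rate: float = 0.05
    theta: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intergenic_fraction", "antisense_fraction", "duplicate_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for g, th in self.theta.items():
            if not th > 0:
                raise ValueError(f"theta must be > 0 (gene {g}: {th})")

    def resolved_expectation(self, n_genes: int) -> float:
        if self.expected_insertions_per_pool is not None:
            return float(self.expected_insertions_per_pool)
        genic_sense_frac = (1 - self.intergenic_fraction) * (1 - self.antisense_fraction)
        return n_genes * self.mean_sense_per_gene / genic_sense_frac


def _intergenic_space(
    layout: GenomeLayout, models: Sequence[GeneModel]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Complement of gene spans: chroms, interval starts and cumulative lengths."""
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    for m in models:
        spans.setdefault(m.chrom, []).append((m.region_start, m.region_end))
    chroms: list[str] = []
    starts: list[int] = []
    lengths: list[int] = []
    for chrom in layout.chrom_names:
        cur = 0
        for s, e in sorted(spans.get(chrom, [])):
            if s > cur:
                chroms.append(chrom)
                starts.append(cur)
                lengths.append(s - cur)
            cur = max(cur, e)
        clen = layout.chrom_lengths[chrom]
        if cur < clen:
            chroms.append(chrom)
            starts.append(cur)
            lengths.append(clen - cur)
    return chroms, np.array(starts, dtype=np.int64), np.cumsum(lengths, dtype=np.int64)


def simulate_screen(
    cfg: ScreenSimConfig,
    models: Sequence[GeneModel],
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> tuple[InsertionPool, InsertionPool, pd.DataFrame]:
    """HIGH and LOW insertion pools with planted per-gene effects.

    Genic sense insertions are allocated to genes with probability
    proportional to counting-region length, placed uniformly within the
    region, and sent to HIGH with probability theta_g / (1 + theta_g).
    Antisense and intergenic insertions split 50/50 between the pools.
    Duplicate sites are injected at the configured rate (each pool's totals
    are realized, not balanced).  Returns (HIGH, LOW, truth) where truth
    lists gene_id, theta and the planted class.
    """
    if not models:
        raise ValueError("need at least one gene model")
    rng = rng if rng is not None else rng_for(cfg.seed, "screen")
    n_genes = len(models)
    expected = cfg.resolved_expectation(n_genes)
    n_total = int(rng.poisson(2 * expected))

    p_inter = cfg.intergenic_fraction
    p_anti = (1 - p_inter) * cfg.antisense_fraction
    p_sense = 1 - p_inter - p_anti
    n_inter, n_anti, n_sense = rng.multinomial(n_total, [p_inter, p_anti, p_sense])

    glen = np.array([m.length for m in models], dtype=float)
    gp = glen / glen.sum()
    gstart = np.array([m.region_start for m in models], dtype=np.int64)
    gchrom = np.array([m.chrom for m in models], dtype="U32")
    gstrand = np.array([m.strand for m in models], dtype="U1")
    anti = np.where(gstrand == "+", "-", "+")
    theta = np.array([float(cfg.theta.get(m.gene_id, 1.0)) for m in models])

    chrom_parts, pos_parts, orient_parts, pool_parts = [], [], [], []

    # genic sense: disruptive, pool chosen by the planted odds
    gi = rng.choice(n_genes, size=n_sense, p=gp)
    offs = np.floor(rng.random(n_sense) * glen[gi]).astype(np.int64)
    chrom_parts.append(gchrom[gi])
    pos_parts.append(gstart[gi] + offs)
    orient_parts.append(gstrand[gi])
    pool_parts.append(rng.random(n_sense) < theta[gi] / (1 + theta[gi]))

    # genic antisense: non-disruptive, 50/50
    gi = rng.choice(n_genes, size=n_anti, p=gp)
    offs = np.floor(rng.random(n_anti) * glen[gi]).astype(np.int64)
    chrom_parts.append(gchrom[gi])
    pos_parts.append(gstart[gi] + offs)
    orient_parts.append(anti[gi])
    pool_parts.append(rng.random(n_anti) < 0.5)

    # intergenic: uniform over the gene-free genome, 50/50
    ic, istart, icum = _intergenic_space(layout, models)
    if len(istart) > 0 and n_inter > 0:
        offs = rng.integers(0, icum[-1], size=n_inter)
        seg = np.searchsorted(icum, offs, side="right")
        prev = np.where(seg > 0, icum[seg - 1], 0)
        chrom_parts.append(np.array([ic[s] for s in seg], dtype="U32"))
        pos_parts.append(istart[seg] + (offs - prev))
        orient_parts.append(rng.choice(np.array(["+", "-"]), size=n_inter))
        pool_parts.append(rng.random(n_inter) < 0.5)

    chrom = np.concatenate(chrom_parts)
    pos = np.concatenate(pos_parts)
    orient = np.concatenate(orient_parts)
    in_high = np.concatenate(pool_parts)

    pools = {}
    for label, mask in (("HIGH", in_high), ("LOW", ~in_high)):
        c, p, o = chrom[mask], pos[mask], orient[mask]
        n = len(p)
        if n > 1 and cfg.duplicate_rate > 0:
            n_dup = rng.binomial(n, cfg.duplicate_rate)
            if n_dup > 0:
                tgt = rng.choice(n, size=n_dup, replace=False)
                src = rng.integers(0, n, size=n_dup)
                c[tgt], p[tgt], o[tgt] = c[src], p[src], o[src]
        pools[label] = pool_from_arrays(label, c, p, o)

    klass = np.where(theta > 1, "repressor", np.where(theta < 1, "activator", "neutral"))
    truth = pd.DataFrame(
        {"gene_id": [m.gene_id for m in models], "theta": theta, "class": klass}
    )
    return pools["HIGH"], pools["LOW"], truth


# ---------------------------------------------------------------------------
# DamID-style tracks
# ---------------------------------------------------------------------------

@dataclass
class LadSimConfig:
    """Planted LAD intervals plus the two-level Gaussian track model."""

    lads: Mapping[str, Sequence[tuple[int, int]]]
    bin_size: int = 2_000
    mu_in: float = 1.0
    mu_out: float = -1.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def synthetic_lads(
    layout: GenomeLayout,
    lad_fraction: float = 0.3,
    mean_lad_length: float = 1_000_000.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, list[tuple[int, int]]]:
    """Alternating iLAD/LAD segments with exponential lengths.

    About a third of the genome sits in megabase-scale LADs, mirroring the
    canonical genome-wide picture.
    """
    if not 0 < lad_fraction < 1:
        raise ValueError("lad_fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_gap = mean_lad_length * (1 - lad_fraction) / lad_fraction
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, clen in layout.chrom_lengths.items():
        cur = 0
        ivs = []
        while True:
            cur += int(rng.exponential(mean_gap)) + 1
            start = cur
            cur += int(rng.exponential(mean_lad_length)) + 1
            if cur >= clen:
                if start < clen - 1:
                    ivs.append((start, clen))
                break
            ivs.append((start, cur))
        out[chrom] = ivs
    return out


def simulate_damid_track(
    cfg: LadSimConfig,
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> tuple[SignalTrack, dict[str, list[tuple[int, int]]]]:
    """Binned log2-ratio track: Normal(mu_in, sigma) for bins whose midpoint
    lies inside a planted LAD, Normal(mu_out, sigma) elsewhere."""
    rng = rng if rng is not None else rng_for(cfg.seed, "damid")
    lads = {c: sorted((int(s), int(e)) for s, e in cfg.lads.get(c, [])) for c in layout.chrom_names}
    for chrom, ivs in lads.items():
        clen = layout.chrom_lengths[chrom]
        for s, e in ivs:
            if not (0 <= s < e <= clen):
                raise ValueError(f"LAD {chrom}:{s}-{e} outside chromosome (length {clen})")
    bins = []
    for chrom in layout.chrom_names:
        clen = layout.chrom_lengths[chrom]
        starts = np.arange(0, clen, cfg.bin_size, dtype=np.int64)
        ends = np.minimum(starts + cfg.bin_size, clen)
        mids = (starts + ends) // 2
        inside = np.zeros(len(starts), dtype=bool)
        ivs = lads.get(chrom, [])
        if ivs:
            ls = np.array([s for s, _ in ivs])
            le = np.array([e for _, e in ivs])
            idx = np.searchsorted(ls, mids, side="right") - 1
            ok = idx >= 0
            inside[ok] = mids[ok] < le[idx[ok]]
        mu = np.where(inside, cfg.mu_in, cfg.mu_out)
        values = mu + (rng.normal(0.0, cfg.sigma, len(mu)) if cfg.sigma > 0 else 0.0)
        bins.extend(
            (chrom, int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)
        )
    return SignalTrack(bins), lads


def lads_to_frame(lads: Mapping[str, Sequence[tuple[int, int]]]) -> pd.DataFrame:
    rows = [(c, s, e) for c, ivs in lads.items() for s, e in ivs]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def position_in_lads(
    lads: Mapping[str, Sequence[tuple[int, int]]], chrom: str, pos: int
) -> bool:
    for s, e in lads.get(chrom, []):
        if s <= pos < e:
            return True
    return False


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class DESimConfig:
    """Conditions of the synthetic expression-perturbation experiment.

    Control expression is log-normal per stratum, with LAD genes a
    two-component mixture: a silent majority (``lad_silent_fraction``,
    drawn far below the TPM-0.3 activity floor — the completely inactive
    genes the analysis discards) and an "escaper" minority whose expression
    resembles lowly expressed iLAD genes.  This reproduces the defining
    expression structure of LADs: most genes off, expressed LAD genes a
    small minority of the expressed catalogue and still several-fold below
    the iLAD median.  Responsive fractions are per (LAD, iLAD) stratum;
    responsive genes scale their treatment mean by 2**lfc with
    lfc ~ Normal(lfc_mean, lfc_sd) (negated
    for down-responders).  Counts are negative binomial via gamma-Poisson
    mixing at the configured dispersion and sequencing depth.
    """

    n_replicates: int = 6
    frac_up_lad: float = 0.25
    frac_down_lad: float = 0.10
    frac_up_ilad: float = 0.10
    frac_down_ilad: float = 0.10
    lfc_mean: float = 1.0
    lfc_sd: float = 0.25
    tpm_logmean_lad: float = 0.5  # expressed "escaper" LAD genes
    tpm_logmean_ilad: float = 2.0
    tpm_logmean_silent: float = -8.0
    lad_silent_fraction: float = 0.75
    tpm_logsd: float = 2.0
    dispersion: float = 0.05
    depth: float = 2e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.frac_up_lad + self.frac_down_lad > 1 or self.frac_up_ilad + self.frac_down_ilad > 1:
            raise ValueError("responsive fractions must sum to <= 1 per stratum")
        if self.dispersion < 0 or self.depth <= 0:
            raise ValueError("dispersion must be >= 0 and depth > 0")
        if not 0 <= self.lad_silent_fraction <= 1:
            raise ValueError("lad_silent_fraction must be in [0, 1]")


def control_expression_levels(
    cfg: DESimConfig, is_lad: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene control expression levels (arbitrary units; TPM after scaling)."""
    is_lad = np.asarray(is_lad, dtype=bool)
    silent = is_lad & (rng.random(len(is_lad)) < cfg.lad_silent_fraction)
    logmu = np.where(
        silent,
        cfg.tpm_logmean_silent,
        np.where(is_lad, cfg.tpm_logmean_lad, cfg.tpm_logmean_ilad),
    )
    return rng.lognormal(mean=logmu, sigma=cfg.tpm_logsd)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_de_counts(
    cfg: DESimConfig,
    lad_labels: Mapping[str, bool],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted LAD-dependent responses.

    Returns (counts, truth): counts is genes x samples (ctrl_1..n,
    treat_1..n); truth lists gene_id, is_lad, planted label (up/down/ns),
    planted lfc, and the true control TPM.
    """
    rng = rng if rng is not None else rng_for(cfg.seed, "de")
    genes = list(lad_labels)
    if not genes:
        raise ValueError("lad_labels is empty")
    is_lad = np.array([bool(lad_labels[g]) for g in genes])
    n = len(genes)

    level = control_expression_levels(cfg, is_lad, rng)
    tpm = level / level.sum() * 1e6

    u = rng.random(n)
    frac_up = np.where(is_lad, cfg.frac_up_lad, cfg.frac_up_ilad)
    frac_down = np.where(is_lad, cfg.frac_down_lad, cfg.frac_down_ilad)
    label = np.where(u < frac_up, "up", np.where(u < frac_up + frac_down, "down", "ns"))
    magnitude = rng.normal(cfg.lfc_mean, cfg.lfc_sd, n)
    lfc = np.where(label == "up", magnitude, np.where(label == "down", -magnitude, 0.0))

    mean_ctrl = cfg.depth * tpm / 1e6
    mean_treat = mean_ctrl * np.power(2.0, lfc)
    data = {}
    for r in range(cfg.n_replicates):
        data[f"ctrl_{r + 1}"] = _nb_counts(rng, mean_ctrl, cfg.dispersion)
    for r in range(cfg.n_replicates):
        data[f"treat_{r + 1}"] = _nb_counts(rng, mean_treat, cfg.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame(
        {"gene_id": genes, "is_lad": is_lad, "label": label, "lfc": lfc, "tpm": tpm}
    )
    return counts, truth


# ---------------------------------------------------------------------------
# TRIP barcodes
# ---------------------------------------------------------------------------

@dataclass
class TripSimConfig:
    """Conditions of the synthetic TRIP knockdown experiment.

    Barcodes integrate uniformly over the genome.  Per-barcode abundance is
    log-normal (driving gDNA counts); log2 expression is a barcode baseline
    minus a LAD penalty, plus the knockdown effect ``delta`` for LAD
    barcodes in knockdown samples, plus per-sample Gaussian noise of scale
    ``expr_sigma``.  A configured fraction of barcodes gets gDNA counts
    forced to <= 100 in every sample to exercise the depth filter.
    """

    n_barcodes: int = 600
    n_replicates: int = 3
    gdna_logmu: float = float(np.log(1_000.0))
    gdna_logsigma: float = 0.3
    cdna_mean_per_barcode: float = 500.0
    base_log2_expr: float = 3.0
    lad_penalty: float = 3.0
    expr_sigma: float = 0.5
    delta: float = 0.5
    low_gdna_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_barcodes < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 barcodes and >= 1 replicate")
        if not 0 <= self.low_gdna_fraction < 1:
            raise ValueError("low_gdna_fraction must be in [0, 1)")
        if self.expr_sigma < 0:
            raise ValueError("expr_sigma must be >= 0")


def simulate_trip(
    cfg: TripSimConfig,
    lads: Mapping[str, Sequence[tuple[int, int]]],
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode count table (gDNA:/cDNA: columns per sample) plus truth.

    Samples are ctrl_r1..n and kd_r1..n.  Truth records each barcode's
    position, LAD membership, planted log2 effect and low-gDNA flag.
    """
    rng = rng if rng is not None else rng_for(cfg.seed, "trip")
    n = cfg.n_barcodes
    clens = np.array(list(layout.chrom_lengths.values()), dtype=np.int64)
    cnames = list(layout.chrom_lengths)
    cum = np.cumsum(clens)
    offs = rng.integers(0, cum[-1], size=n)
    ci = np.searchsorted(cum, offs, side="right")
    prev = np.where(ci > 0, cum[ci - 1], 0)
    pos = (offs - prev).astype(np.int64)
    chrom = np.array([cnames[i] for i in ci], dtype="U32")
    in_lad = np.array([position_in_lads(lads, c, p) for c, p in zip(chrom, pos)])

    abundance = rng.lognormal(cfg.gdna_logmu, cfg.gdna_logsigma, n)
    n_low = int(np.floor(n * cfg.low_gdna_fraction))
    low_idx = rng.choice(n, size=n_low, replace=False) if n_low else np.array([], dtype=int)
    low_mask = np.zeros(n, dtype=bool)
    low_mask[low_idx] = True

    base = cfg.base_log2_expr - cfg.lad_penalty * in_lad

    samples = [f"ctrl_r{r + 1}" for r in range(cfg.n_replicates)] + [
        f"kd_r{r + 1}" for r in range(cfg.n_replicates)
    ]
    data: dict[str, np.ndarray] = {}
    for s in samples:
        is_kd = s.startswith("kd")
        gdna = rng.poisson(abundance)
        if n_low:
            gdna[low_mask] = rng.integers(5, 101, size=n_low)
        x = base + (cfg.delta * in_lad if is_kd else 0.0)
        x = x + rng.normal(0.0, cfg.expr_sigma, n)
        weight = abundance * np.power(2.0, x)
        cdna_mean = cfg.cdna_mean_per_barcode * n * weight / weight.sum()
        data[f"gDNA:{s}"] = gdna
        data[f"cDNA:{s}"] = rng.poisson(cdna_mean)

    width = len(str(n - 1))
    barcodes = [f"bc{i:0{width}d}" for i in range(n)]
    table = pd.DataFrame({"barcode": barcodes, "chrom": chrom, "pos": pos, **data})
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "chrom": chrom,
            "pos": pos,
            "is_lad": in_lad,
            "delta": np.where(in_lad, cfg.delta, 0.0),
            "low_gdna": low_mask,
        }
    )
    return table, truth
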