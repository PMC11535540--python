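"""Mutational-index statistics for FACS-sorted gene-trap insertion pools.

A haploid insertional screen sorts mutagenized cells into a HIGH and a LOW
reporter-expression pool and maps gene-trap integrations in each.  For a
gene g with ``a`` unique sense insertions in HIGH and ``b`` in LOW, out of
pool totals ``T_H`` and ``T_L``, the mutational index is the odds ratio

    MI(g) = [a / (T_H - a)] / [b / (T_L - b)]

MI > 1 means disrupting g preferentially raised reporter expression, i.e. g
is a putative repressor of the reporter; MI < 1 flags a putative activator.
Significance per gene comes from a two-sided Fisher's exact test on the
2x2 table [[a, T_H - a], [b, T_L - b]] with Benjamini-Hochberg correction
across all testable genes (``fcpv``).

Only *sense* insertions count as disruptive, and only within a gene's
counting region (TSS through stop codon of its longest-ORF transcript),
after removing base pairs claimed by more than one gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .formats_io import GeneModel, Insertion

__all__ = [
    "InsertionPool",
    "CountingRegions",
    "dedupe_pool",
    "merge_pools",
    "build_counting_regions",
    "count_sense_insertions",
    "mutational_index",
    "fisher_two_sided",
    "bh_adjust",
    "score_screen",
    "screen_overlap",
    "set_enrichment",
    "EnrichmentResult",
]

_CHROM_DTYPE = "U32"


@dataclass(frozen=True)
class InsertionPool:
    """Deduplicated insertions of one sorted population, as sorted arrays."""

    label: str
    chrom: np.ndarray
    pos: np.ndarray
    orientation: np.ndarray

    @property
    def size(self) -> int:
        return len(self.pos)

    def as_insertions(self) -> list[Insertion]:
        return [
            Insertion(str(c), int(p), str(o), self.label)
            for c, p, o in zip(self.chrom, self.pos, self.orientation)
        ]


def _to_arrays(insertions: Iterable[Insertion]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    items = list(insertions)
    chrom = np.array([i.chrom for i in items], dtype=_CHROM_DTYPE)
    pos = np.array([i.pos for i in items], dtype=np.int64)
    orient = np.array([i.orientation for i in items], dtype="U1")
    return chrom, pos, orient


def _unique_pool(label: str, chrom: np.ndarray, pos: np.ndarray, orient: np.ndarray) -> InsertionPool:
    if len(pos) == 0:
        return InsertionPool(label, chrom, pos.astype(np.int64), orient)
    pos = pos.astype(np.int64)
    if np.any(pos >= (1 << 42)):
        raise ValueError("position exceeds supported coordinate range (2^42)")
    # hash-based chromosome codes + packed integer keys: much faster than a
    # lexicographic sort of string records at screen scale (~10^6 sites)
    codes, names = pd.factorize(chrom)
    rank = np.empty(len(names), dtype=np.int64)
    rank[np.argsort(np.asarray(names).astype(str))] = np.arange(len(names))
    key = (rank[codes] << 43) | (pos << 1) | (orient == "-")
    # unique values come back sorted, so their first-occurrence indices are
    # already in canonical (chrom, pos, orientation) order
    idx = np.unique(key, return_index=True)[1]
    return InsertionPool(
        label,
        np.asarray(chrom[idx], dtype=_CHROM_DTYPE),
        pos[idx],
        np.asarray(orient[idx], dtype="U1"),
    )


def dedupe_pool(insertions: Iterable[Insertion], label: str | None = None) -> InsertionPool:
    """Collapse insertions to unique (chrom, pos, orientation) triples.

    The result is order-independent (triples are kept sorted).  All input
    insertions must carry the same pool label unless ``label`` overrides it.
    """
    items = list(insertions)
    labels = {i.pool_label for i in items}
    if label is None:
        if len(labels) > 1:
            raise ValueError(f"insertions from multiple pools: {sorted(labels)}")
        label = next(iter(labels)) if labels else ""
    chrom, pos, orient = _to_arrays(items)
    return _unique_pool(label, chrom, pos, orient)


def pool_from_arrays(
    label: str, chrom: np.ndarray, pos: np.ndarray, orientation: np.ndarray
) -> InsertionPool:
    """Build a deduplicated pool directly from parallel arrays (fast path)."""
    return _unique_pool(
        label,
        np.asarray(chrom, dtype=_CHROM_DTYPE),
        np.asarray(pos, dtype=np.int64),
        np.asarray(orientation, dtype="U1"),
    )


def merge_pools(pool1: InsertionPool, pool2: InsertionPool, label: str | None = None) -> InsertionPool:
    """Union of two pools at the insertion level, deduplicated.

    Mirrors merging the raw libraries of two sorted bins of the same kind
    (e.g. HIGH1 with HIGH2) before any counting.
    """
    if label is None:
        label = pool1.label if pool1.label == pool2.label else f"{pool1.label}+{pool2.label}"
    return _unique_pool(
        label,
        np.concatenate([pool1.chrom, pool2.chrom]),
        np.concatenate([pool1.pos, pool2.pos]),
        np.concatenate([pool1.orientation, pool2.orientation]),
    )


# ---------------------------------------------------------------------------
# Counting regions
# ---------------------------------------------------------------------------

def _subtract(interval: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """interval minus a sorted list of disjoint blocks."""
    out = []
    cur = interval[0]
    for bs, be in blocks:
        if be <= interval[0] or bs >= interval[1]:
            continue
        if bs > cur:
            out.append((cur, min(bs, interval[1])))
        cur = max(cur, be)
        if cur >= interval[1]:
            break
    if cur < interval[1]:
        out.append((cur, interval[1]))
    return out


@dataclass
class CountingRegions:
    """Per-gene disjoint intervals usable for unambiguous insertion assignment.

    ``by_gene`` maps gene_id to its intervals (model region minus every bp
    covered by two or more gene models, any strand).  Flattened per-chromosome
    arrays support fast position lookup, and per-strand merged unions of the
    *raw* model regions support the ``all-sense`` totals mode.
    """

    gene_ids: list[str]
    strands: dict[str, str]
    by_gene: dict[str, list[tuple[str, int, int]]]
    _lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False)
    _model_union: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(repr=False)

    def intervals(self, gene_id: str) -> list[tuple[str, int, int]]:
        return self.by_gene[gene_id]


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def build_counting_regions(models: Sequence[GeneModel]) -> CountingRegions:
    """Remove multi-gene overlap from each gene's model region.

    A base pair covered by >= 2 gene-model regions (regardless of strand)
    cannot be attributed to a single gene and is excluded from every gene.
    Genes left with no unique sequence get an empty interval list and a
    warning downstream (they can never accrue counts).
    """
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in models")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        per_chrom.setdefault(m.chrom, []).append((m.region_start, m.region_end))

    # segments covered by >=2 models, per chromosome
    multi: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        events: list[tuple[int, int]] = []
        for s, e in ivs:
            events.append((s, 1))
            events.append((e, -1))
        events.sort()
        cov = 0
        segs = []
        prev = None
        for pos, delta in events:
            if prev is not None and cov >= 2 and pos > prev:
                segs.append((prev, pos))
            cov += delta
            prev = pos
        multi[chrom] = _merge_intervals(segs)

    by_gene: dict[str, list[tuple[str, int, int]]] = {}
    strands: dict[str, str] = {}
    flat: dict[str, list[tuple[int, int, int]]] = {}
    for gi, m in enumerate(models):
        strands[m.gene_id] = m.strand
        kept = _subtract((m.region_start, m.region_end), multi.get(m.chrom, []))
        by_gene[m.gene_id] = [(m.chrom, s, e) for s, e in kept]
        for s, e in kept:
            flat.setdefault(m.chrom, []).append((s, e, gi))

    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in flat.items():
        rows.sort()
        lookup[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=np.int64),
        )

    union: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    per_cs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in models:
        per_cs.setdefault((m.chrom, m.strand), []).append((m.region_start, m.region_end))
    for key, ivs in per_cs.items():
        merged = _merge_intervals(ivs)
        union[key] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )

    return CountingRegions(ids, strands, by_gene, lookup, union)


def _positions_in(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall in the sorted disjoint intervals."""
    if len(starts) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(pos), dtype=bool)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def count_sense_insertions(
    pool: InsertionPool, regions: CountingRegions
) -> tuple[pd.Series, int]:
    """Unique sense insertions per gene plus the assigned total.

    An insertion counts for gene g iff its position falls in g's counting
    region *and* its orientation matches g's strand.  The returned total T
    is the sum of per-gene counts (conservation holds by construction).
    """
    counts = np.zeros(len(regions.gene_ids), dtype=np.int64)
    strand_arr = np.array([regions.strands[g] for g in regions.gene_ids], dtype="U1")
    for chrom in np.unique(pool.chrom):
        sel = pool.chrom == chrom
        pos = pool.pos[sel]
        orient = pool.orientation[sel]
        starts, ends, gene_idx = regions._lookup.get(
            str(chrom), (np.array([], dtype=np.int64),) * 3
        )
        if len(starts) == 0:
            continue
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(pos), dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        gi = gene_idx[idx[inside]]
        sense = orient[inside] == strand_arr[gi]
        counts += np.bincount(gi[sense], minlength=len(counts))
    series = pd.Series(counts, index=pd.Index(regions.gene_ids, name="gene_id"))
    return series, int(counts.sum())


def count_all_sense(pool: InsertionPool, regions: CountingRegions) -> int:
    """Unique pool insertions that are sense to >= 1 raw gene-model span.

    This is the ``all-sense`` totals mode: ambiguous-overlap base pairs are
    *not* excluded, so an insertion inside two genes still contributes to the
    pool total (though it is assigned to no gene).
    """
    total = 0
    for chrom in np.unique(pool.chrom):
        sel = pool.chrom == chrom
        pos = pool.pos[sel]
        orient = pool.orientation[sel]
        for strand in ("+", "-"):
            su = regions._model_union.get((str(chrom), strand))
            if su is None:
                continue
            mask = _positions_in(su[0], su[1], pos[orient == strand])
            total += int(mask.sum())
    return total


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mutational_index(a: int, t_high: int, b: int, t_low: int) -> float:
    """Odds-ratio mutational index [a/(T_H-a)] / [b/(T_L-b)].

    Degenerate cases: returns ``inf`` when b == 0 < a, ``0.0`` when
    a == 0 < b, and ``nan`` when a == b == 0 or when a pool total is
    exhausted by the gene itself (a == T_H or b == T_L, division by zero).
    """
    if not (0 <= a <= t_high and 0 <= b <= t_low):
        raise ValueError(f"counts exceed totals: a={a}, T_H={t_high}, b={b}, T_L={t_low}")
    if a == 0 and b == 0:
        return math.nan
    if (a == t_high and a > 0) or (b == t_low and b > 0):
        return math.nan  # degenerate pool: zero denominator inside an odds
    if b == 0:
        return math.inf
    if a == 0:
        return 0.0
    return (a / (t_high - a)) / (b / (t_low - b))


@lru_cache(maxsize=200_000)
def _support_numerators(n1: int, n2: int, m: int) -> tuple[int, tuple[int, ...], int]:
    """Hypergeometric numerators C(n1,x)*C(n2,m-x) over the support, exact.

    Built by the integer recurrence
        N(x+1) = N(x) * (n1-x) // (x+1) * (m-x) // (n2-m+x+1)
    (each division is exact), which is much cheaper than fresh binomials
    when the margins are large and the support is short.
    """
    lo = max(0, m - n2)
    hi = min(n1, m)
    cur = math.comb(n1, lo) * math.comb(n2, m - lo)
    nums = [cur]
    for x in range(lo, hi):
        cur = cur * (n1 - x) // (x + 1) * (m - x) // (n2 - m + x + 1)
        nums.append(cur)
    return lo, tuple(nums), math.comb(n1 + n2, m)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Uses the method of small p-values on the exact integer hypergeometric
    distribution (margins fixed): sum the probabilities of every table whose
    probability is <= that of the observed table.  Comparisons are exact
    integer comparisons, so ties are handled without floating-point slack.
    Any zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or b + d == 0:
        return 1.0
    lo, nums, total = _support_numerators(n1, n2, m)
    obs = nums[a - lo]
    acc = 0
    for x in nums:
        if x <= obs:
            acc += x
    return min(1.0, acc / total)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Screen scoring
# ---------------------------------------------------------------------------

def score_screen(
    high: InsertionPool,
    low: InsertionPool,
    regions: CountingRegions,
    alpha: float = 0.05,
    total_mode: str = "assigned",
) -> pd.DataFrame:
    """Per-gene mutational indices, Fisher p, BH-adjusted fcpv and hit class.

    Only genes with at least one sense insertion in either pool (a + b > 0)
    are tested; they alone form the BH family.  ``total_mode`` chooses the
    pool totals: ``assigned`` (default) counts only insertions assigned to a
    unique counting region, ``all-sense`` counts every unique insertion that
    is sense to at least one raw gene-model span.

    Hit classes at ``fcpv < alpha``: ``repressor`` if MI > 1, ``activator``
    if MI < 1, else ``ns``.
    """
    if high.size == 0 or low.size == 0:
        raise ValueError("empty insertion pool")
    if total_mode not in ("assigned", "all-sense"):
        raise ValueError(f"unknown total_mode {total_mode!r}")

    counts_h, assigned_h = count_sense_insertions(high, regions)
    counts_l, assigned_l = count_sense_insertions(low, regions)
    if total_mode == "assigned":
        t_high, t_low = assigned_h, assigned_l
    else:
        t_high = count_all_sense(high, regions)
        t_low = count_all_sense(low, regions)

    df = pd.DataFrame({"a": counts_h, "b": counts_l})
    df = df[(df["a"] + df["b"]) > 0].copy()
    df["T_H"] = t_high
    df["T_L"] = t_low
    df["mi"] = [
        mutational_index(a, t_high, b, t_low) for a, b in zip(df["a"], df["b"])
    ]
    with np.errstate(divide="ignore"):
        df["log2_mi"] = np.log2(df["mi"].to_numpy())
    df["p"] = [
        fisher_two_sided(a, t_high - a, b, t_low - b) for a, b in zip(df["a"], df["b"])
    ]
    df["fcpv"] = bh_adjust(df["p"].to_numpy())
    sig = df["fcpv"] < alpha
    df["hit_class"] = "ns"
    df.loc[sig & (df["mi"] > 1), "hit_class"] = "repressor"
    df.loc[sig & (df["mi"] < 1), "hit_class"] = "activator"
    return df.reset_index()


def screen_overlap(hits_a: pd.DataFrame, hits_b: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Shared fraction of the union of two screens' hits, overall and per class.

    Inputs are :func:`score_screen` tables.  The overall overlap uses all
    genes with ``fcpv < alpha``; per-class overlaps restrict both screens to
    the same hit class.
    """
    def hit_sets(df: pd.DataFrame) -> dict[str, set[str]]:
        sig = df[df["fcpv"] < alpha]
        return {
            "all": set(sig["gene_id"]),
            "repressor": set(sig.loc[sig["hit_class"] == "repressor", "gene_id"]),
            "activator": set(sig.loc[sig["hit_class"] == "activator", "gene_id"]),
        }

    sa, sb = hit_sets(hits_a), hit_sets(hits_b)
    out = {}
    for key in ("all", "repressor", "activator"):
        union = sa[key] | sb[key]
        inter = sa[key] & sb[key]
        out[key] = {
            "n_a": len(sa[key]),
            "n_b": len(sb[key]),
            "n_shared": len(inter),
            "shared_fraction": len(inter) / len(union) if union else math.nan,
        }
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher enrichment of a gene category among screen hits."""

    fold: float
    odds_ratio: float
    p: float
    n_hits_in_set: int
    n_hits: int
    n_background_in_set: int
    n_background: int


def set_enrichment(
    hits: set[str], background: set[str], gene_set: frozenset[str] | set[str]
) -> EnrichmentResult:
    """2x2 Fisher enrichment (hit/not x in-set/not) over a background universe."""
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    members = set(gene_set) & background
    k = len(hits & members)
    n_hits = len(hits)
    big_k = len(members)
    big_n = len(background)
    a, b = k, n_hits - k
    c, d = big_k - k, (big_n - n_hits) - (big_k - k)
    p = fisher_two_sided(a, b, c, d)
    fold = (
        (k / n_hits) / (big_k / big_n)
        if n_hits > 0 and big_k > 0
        else math.nan
    )
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    return EnrichmentResult(fold, odds, p, k, n_hits, big_k, big_n)
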