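"""Core genomic data types and readers/writers for the pipeline's file formats.

Every interval in this package is 0-based half-open, the native convention
of BED and bedGraph.  1-based coordinates (e.g. genome-browser style
integration sites) must be converted on input; :func:`from_one_based` is
provided for that.

Supported formats
-----------------
* BED6 for insertion sites and peak sets
* bedGraph (4 columns) for binned log2-ratio signal tracks
* tab-separated tables with a header for gene models, transcripts,
  differential-expression results and TRIP barcode counts
* GMT for gene-category sets
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomeLayout",
    "Transcript",
    "GeneModel",
    "Insertion",
    "SignalTrack",
    "GeneSet",
    "from_one_based",
    "read_insertions",
    "write_insertions",
    "build_gene_models",
    "read_transcripts",
    "write_transcripts",
    "read_gene_models",
    "write_gene_models",
    "read_track",
    "write_track",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_barcode_table",
    "write_barcode_table",
    "read_peaks",
    "write_peaks",
]

STRANDS = ("+", "-")

DE_COLUMNS = ["gene_id", "log2fc", "padj", "tpm_ctrl"]


class ParseError(ValueError):
    """A malformed record in an input file (message names the line)."""


def from_one_based(pos: int) -> int:
    """Convert a 1-based genomic position to the internal 0-based convention."""
    return pos - 1


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp) of a (synthetic) genome."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome layout needs at least one chromosome")
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom in self.chrom_lengths and 0 <= pos < self.chrom_lengths[chrom]


@dataclass(frozen=True)
class Transcript:
    """A transcript with its CDS, in genomic (0-based half-open) coordinates."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.transcript_id}: tx_start must be < tx_end")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: CDS must have both or neither bound")
        if self.cds_start is not None:
            if not self.cds_start < self.cds_end:
                raise ValueError(f"{self.transcript_id}: cds_start must be < cds_end")
            if self.cds_start < self.tx_start or self.cds_end > self.tx_end:
                raise ValueError(f"{self.transcript_id}: CDS not contained in transcript")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def orf_length(self) -> int:
        if not self.has_cds:
            return 0
        return self.cds_end - self.cds_start

    @property
    def tx_length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class GeneModel:
    """Per-gene disruptive counting region: TSS through stop codon.

    On the + strand the region runs from the transcript start to the CDS end;
    on the - strand from the CDS start to the transcript end.  The stop codon
    itself lies inside the region.
    """

    gene_id: str
    chrom: str
    strand: str
    region_start: int
    region_end: int
    orf_length: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.region_start < self.region_end:
            raise ValueError(f"{self.gene_id}: empty or inverted counting region")

    @property
    def length(self) -> int:
        return self.region_end - self.region_start


@dataclass(frozen=True)
class Insertion:
    """One gene-trap integration site (0-based position, cassette orientation)."""

    chrom: str
    pos: int
    orientation: str
    pool_label: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in STRANDS:
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")


class SignalTrack:
    """Binned genomic signal (log2 ratio), non-overlapping bins per chromosome.

    Bins are stored per chromosome as sorted numpy arrays so window queries
    (weighted means over intervals) are O(log n).
    """

    def __init__(self, bins: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in bins:
            if not start < end:
                raise ValueError(f"empty bin {chrom}:{start}-{end}")
            if not math.isfinite(value):
                raise ValueError(f"non-finite value in bin {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping bins on {chrom} near {starts[i + 1]} (bins must be disjoint)"
                )
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        if chrom not in self._data:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.float64)
        return self._data[chrom]

    def bins(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return list(self.bins()) == list(other.bins())

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._data.values())


@dataclass(frozen=True)
class GeneSet:
    """A named gene category (e.g. one GMT line)."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


# ---------------------------------------------------------------------------
# BED6 insertions
# ---------------------------------------------------------------------------

def read_insertions(path: str | Path, pool_label: str = "") -> list[Insertion]:
    """Read insertion sites from a BED6 file (position = BED start)."""
    out: list[Insertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, _end, _name, _score, strand = parts[:6]
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            try:
                pos = int(start)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad start coordinate {start!r}") from exc
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative start coordinate")
            out.append(Insertion(chrom, pos, strand, pool_label))
    return out


def write_insertions(path: str | Path, insertions: Iterable[Insertion]) -> None:
    with open(path, "w") as fh:
        for i, ins in enumerate(insertions):
            name = f"i{i}"
            fh.write(f"{ins.chrom}\t{ins.pos}\t{ins.pos + 1}\t{name}\t0\t{ins.orientation}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def build_gene_models(transcripts: Sequence[Transcript]) -> list[GeneModel]:
    """One counting region per gene, from its longest-ORF transcript.

    Ties on ORF length fall back to the longer transcript span, then the
    lexicographically smallest transcript_id.  Genes without any CDS-bearing
    transcript are omitted with a warning.
    """
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    models: list[GeneModel] = []
    for gene_id, txs in by_gene.items():
        coding = [t for t in txs if t.has_cds]
        if not coding:
            warnings.warn(f"gene {gene_id}: no CDS-bearing transcript; omitted", stacklevel=2)
            continue
        best = min(coding, key=lambda t: (-t.orf_length, -t.tx_length, t.transcript_id))
        if best.strand == "+":
            start, end = best.tx_start, best.cds_end
        else:
            start, end = best.cds_start, best.tx_end
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=best.chrom,
                strand=best.strand,
                region_start=start,
                region_end=end,
                orf_length=best.orf_length,
            )
        )
    return models


_TRANSCRIPT_COLUMNS = [
    "transcript_id", "gene_id", "chrom", "strand",
    "tx_start", "tx_end", "cds_start", "cds_end",
]


def read_transcripts(path: str | Path) -> list[Transcript]:
    """Read a GTF-lite transcript table (TSV with header; empty CDS = non-coding)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = set(_TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cds_start = None if pd.isna(row.cds_start) else int(row.cds_start)
        cds_end = None if pd.isna(row.cds_end) else int(row.cds_end)
        out.append(
            Transcript(
                transcript_id=str(row.transcript_id),
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return out


def write_transcripts(path: str | Path, transcripts: Iterable[Transcript]) -> None:
    rows = [
        (t.transcript_id, t.gene_id, t.chrom, t.strand, t.tx_start, t.tx_end,
         t.cds_start, t.cds_end)
        for t in transcripts
    ]
    pd.DataFrame(rows, columns=_TRANSCRIPT_COLUMNS).to_csv(path, sep="\t", index=False)


_MODEL_COLUMNS = ["gene_id", "chrom", "strand", "region_start", "region_end", "orf_length"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = set(_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom), strand=str(r.strand),
            region_start=int(r.region_start), region_end=int(r.region_end),
            orf_length=int(r.orf_length),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    rows = [
        (m.gene_id, m.chrom, m.strand, m.region_start, m.region_end, m.orf_length)
        for m in models
    ]
    pd.DataFrame(rows, columns=_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def read_track(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (errors on overlapping bins)."""
    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                bins.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph row") from exc
    return SignalTrack(bins)


def write_track(path: str | Path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.bins():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table (gene_id, log2fc, padj, tpm_ctrl).

    Missing padj (``NA``/empty) becomes NaN; such genes are never called
    significant downstream.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df[DE_COLUMNS + [c for c in df.columns if c not in DE_COLUMNS]].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    if (df["tpm_ctrl"] < 0).any():
        raise ParseError(f"{path}: negative tpm_ctrl")
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ParseError(f"{path}: padj outside [0, 1]")
    return df


def write_de_table(path: str | Path, de: pd.DataFrame) -> None:
    de.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs id, description, members")
            sets.append(GeneSet(parts[0], parts[1], frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.description}\t{members}\n")


# ---------------------------------------------------------------------------
# TRIP barcode tables
# ---------------------------------------------------------------------------

def read_barcode_table(path: str | Path) -> pd.DataFrame:
    """Read a TRIP barcode count table.

    Expected columns: ``barcode``, ``chrom``, ``pos`` plus per-sample count
    columns named ``gDNA:<sample>`` and ``cDNA:<sample>``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    for col in ("barcode", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    count_cols = [c for c in df.columns if c.startswith(("gDNA:", "cDNA:"))]
    if not count_cols:
        raise ParseError(f"{path}: no gDNA:/cDNA: count columns")
    if (df[count_cols] < 0).any().any():
        raise ParseError(f"{path}: negative counts")
    df["barcode"] = df["barcode"].astype(str)
    return df


def write_barcode_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peak sets (BED3+)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a peak set from BED (first three columns used)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED row") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_peaks(path: str | Path, peaks: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for r in peaks.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
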