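"""Coordinate conventions, interval algebra, and file I/O.

Every coordinate in this package is 0-based, half-open (BED-native).
Formats with other conventions are converted at the I/O boundary.
Chromosome names are matched by exact string equality; there is no
"chr" aliasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate universe.

    The insertion order of chromosomes is preserved and defines iteration
    and sort order for everything downstream (bins, merged intervals, ...).
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = list(chromosomes)
        names = [c[0] for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in chroms:
            if not name:
                raise ValueError("empty chromosome name")
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has length {length} < 1")
        self._lengths: dict[str, int] = {n: int(l) for n, l in chroms}

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length_of(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def sort_key(self, chrom: str) -> int:
        """Rank of a chromosome in layout order (for deterministic sorting)."""
        return self.names.index(chrom)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(zip(df["chrom"].astype(str), df["length"].astype(int)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self:
                fh.write(f"{name}\t{length}\n")


@dataclass
class Interval:
    """Half-open genomic interval with optional name, score and summit.

    ``summit`` is an offset from ``start`` (narrowPeak column-10 style) and
    must fall inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit_position(self) -> int:
        """Absolute summit coordinate; midpoint fallback for BED3 input."""
        if self.summit is not None:
            return self.start + self.summit
        return self.midpoint

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class PeakSet:
    """A labelled collection of intervals (one ChIP-seq peak collection)."""

    def __init__(self, intervals: Iterable[Interval], label: str = ""):
        self.intervals: list[Interval] = list(intervals)
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def validate_against(self, layout: GenomeLayout) -> None:
        for i, iv in enumerate(self.intervals):
            if iv.chrom not in layout:
                raise ValueError(f"interval {i}: unknown chromosome {iv.chrom!r}")
            if iv.end > layout.length_of(iv.chrom):
                raise ValueError(
                    f"interval {i}: end {iv.end} exceeds {iv.chrom} length "
                    f"{layout.length_of(iv.chrom)}"
                )

    def sorted_copy(self, layout: GenomeLayout | None = None) -> "PeakSet":
        if layout is not None:
            key = lambda iv: (layout.sort_key(iv.chrom), iv.start, iv.end)
        else:
            key = lambda iv: (iv.chrom, iv.start, iv.end)
        return PeakSet(sorted(self.intervals, key=key), self.label)

    def deduplicated(self) -> "PeakSet":
        """Remove exact coordinate duplicates; duplicates are retained on read."""
        seen: set[tuple[str, int, int]] = set()
        out = []
        for iv in self.intervals:
            k = (iv.chrom, iv.start, iv.end)
            if k not in seen:
                seen.add(k)
                out.append(iv)
        return PeakSet(out, self.label)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware transcript with a derived TSS.

    TSS is ``tx_start`` on the + strand and ``tx_end - 1`` on the − strand
    (the last covered base of the half-open span).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"{self.gene_id}: invalid transcript span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def promoter(self, halfwidth: int = 2500) -> tuple[int, int]:
        """Symmetric promoter window TSS ± halfwidth, clipped at zero."""
        return max(0, self.tss - halfwidth), self.tss + halfwidth

    def span_with_upstream(self, upstream: int = 2500) -> tuple[int, int]:
        """Strand-aware span from ``upstream`` bp before the TSS to the 3' end."""
        if self.strand == "+":
            return max(0, self.tx_start - upstream), self.tx_end
        return self.tx_start, self.tx_end + upstream


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    label: str = "",
    summit_column: int | None = None,
) -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet, coordinates preserved exactly.

    ``summit_column`` declares a 0-based column index holding a summit offset
    (narrowPeak keeps it in column 10, i.e. index 9).  Malformed lines raise
    ``ValueError`` naming the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            if layout is not None:
                if chrom not in layout:
                    raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
                if end > layout.length_of(chrom):
                    raise ValueError(f"line {lineno}: end beyond chromosome length")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            summit = None
            if summit_column is not None:
                if len(fields) <= summit_column:
                    raise ValueError(f"line {lineno}: missing summit column")
                summit = int(fields[summit_column])
            try:
                intervals.append(Interval(chrom, start, end, name, score, summit))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return PeakSet(intervals, label)


def write_bed(peaks: PeakSet, path: str | Path, strand: Mapping[int, str] | None = None) -> None:
    """Write BED3/BED6; columns extend only as far as data is present."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            has_strand = strand is not None and i in strand
            if iv.name is not None or iv.score is not None or has_strand:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or has_strand:
                cols.append(_format_score(iv.score) if iv.score is not None else ".")
            if has_strand:
                cols.append(strand[i])
            fh.write("\t".join(cols) + "\n")


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV with header gene_id/chrom/strand/tx_start/tx_end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tx_start", "tx_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tx_start), int(r.tx_end))
        for r in df.itertuples()
    ]


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read bedGraph (0-based half-open) into a chrom/start/end/value frame."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    validate_bedgraph(df, layout)
    return df

def validate_bedgraph(df: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
    if (df["start"] >= df["end"]).any():
        raise ValueError("bedGraph contains empty or inverted intervals")
    if layout is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in layout:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in layout")
            if int(sub["end"].max()) > layout.length_of(chrom):
                raise ValueError(
                    f"bedGraph interval crosses end of chromosome {chrom}"
                )


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def intersect_sets(
    a: PeakSet, b: PeakSet, min_overlap: int = 1
) -> list[tuple[int, int, int]]:
    """All (index in a, index in b, overlap bp) pairs sharing >= min_overlap bases.

    Sorted-sweep join per chromosome; output ordered by a-index then b-index.
    The default 1-bp threshold reflects that no stricter overlap rule is
    assumed for peak-set comparison; reciprocal-fraction filtering can be
    emulated by post-filtering on the returned overlap sizes.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    pairs: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        cands = by_chrom.get(iv.chrom)
        if not cands:
            continue
        for bs, be, j in cands:
            if bs >= iv.end:
                break
            ov = min(iv.end, be) - max(iv.start, bs)
            if ov >= min_overlap:
                pairs.append((i, j, ov))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs


@dataclass
class MergedRegion:
    """One maximal interval of the union, with its contributing peaks."""

    interval: Interval
    sources: dict[str, list[int]] = field(default_factory=dict)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.sources)


def merge_with_sources(
    sets: Sequence[PeakSet], layout: GenomeLayout | None = None
) -> list[MergedRegion]:
    """Merge the union of several peak sets into maximal non-overlapping regions.

    Overlapping and book-ended intervals coalesce (bedtools-merge semantics).
    Each region records, per input label, the indices of contributing peaks.
    """
    labels = [ps.label or str(k) for k, ps in enumerate(sets)]
    if len(set(labels)) != len(labels):
        raise ValueError("peak sets must carry distinct labels for merging")
    entries: list[tuple[str, int, int, str, int]] = []
    for label, ps in zip(labels, sets):
        for idx, iv in enumerate(ps):
            entries.append((iv.chrom, iv.start, iv.end, label, idx))
    if layout is not None:
        entries.sort(key=lambda e: (layout.sort_key(e[0]), e[1], e[2]))
    else:
        entries.sort(key=lambda e: (e[0], e[1], e[2]))

    regions: list[MergedRegion] = []
    cur = None  # [chrom, start, end, sources]
    for chrom, start, end, label, idx in entries:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].setdefault(label, []).append(idx)
        else:
            if cur is not None:
                regions.append(
                    MergedRegion(Interval(cur[0], cur[1], cur[2]), cur[3])
                )
            cur = [chrom, start, end, {label: [idx]}]
    if cur is not None:
        regions.append(MergedRegion(Interval(cur[0], cur[1], cur[2]), cur[3]))
    return regions


def merge_union(
    sets: Sequence[PeakSet], layout: GenomeLayout | None = None, label: str = "union"
) -> PeakSet:
    """Union of input peak sets as maximal non-overlapping intervals.

    Output interval names carry the comma-joined labels of contributing sets.
    """
    regions = merge_with_sources(sets, layout)
    order = [ps.label or str(k) for k, ps in enumerate(sets)]
    out = []
    for reg in regions:
        name = ",".join(l for l in order if l in reg.sources)
        out.append(replace(reg.interval, name=name))
    return PeakSet(out, label)


def subtract_intervals(
    base: Sequence[tuple[int, int]], minus: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of two interval lists on one chromosome (half-open)."""
    merged_minus = merge_plain(minus)
    out: list[tuple[int, int]] = []
    for s, e in merge_plain(base):
        cur = s
        for ms, me in merged_minus:
            if me <= cur:
                continue
            if ms >= e:
                break
            if ms > cur:
                out.append((cur, min(ms, e)))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def merge_plain(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Coalesce (start, end) pairs on a single chromosome."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def overlaps_any(start: int, end: int, sorted_intervals: Sequence[tuple[int, int]]) -> bool:
    """Whether [start, end) shares >=1 bp with any of a sorted merged list."""
    import bisect

    i = bisect.bisect_right([s for s, _ in sorted_intervals], start)
    for s, e in sorted_intervals[max(0, i - 1):]:
        if s >= end:
            return False
        if e > start:
            return True
    return False
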