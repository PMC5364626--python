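"""Domain types and I/O for genomic intervals, gene models and signal tracks.

All internal coordinates are 0-based half-open ``[start, end)``.  BED is the
native interval format; GTF-style annotation (1-based inclusive) is converted
on read.  The TSS of a minus-strand gene is ``end - 1`` — the last covered
base — so that every anchor is a real genomic position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

GENE_CLASSES = ("protein_coding", "snRNA", "snoRNA", "lincRNA", "miRNA")

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class BoundsError(ValueError):
    """An interval that does not fit its chromosome."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp); the coordinate frame of a dataset."""

    lengths: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.lengths)) != len(list(self.lengths)):
            raise ValueError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(path, lineno, "expected name<TAB>length")
                try:
                    lengths[parts[0]] = int(parts[1])
                except ValueError:
                    raise ParseError(path, lineno, f"bad length {parts[1]!r}") from None
        return cls(lengths)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a chromosome; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise BoundsError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout[self.chrom]:
            raise BoundsError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {layout[self.chrom]}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene record with exon structure and a class label."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    gene_class: str

    def __post_init__(self):
        if self.interval.strand == ".":
            raise ValueError(f"gene {self.gene_id}: strand is mandatory")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown class {self.gene_class!r}"
            )
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end


def tss_tes(gene: GeneModel) -> tuple[int, int]:
    """Strand-aware (TSS, TES) anchors of a gene.

    Plus strand: TSS = start, TES = end - 1.  Minus strand: TSS = end - 1,
    TES = start.  Both anchors are covered positions.
    """
    iv = gene.interval
    if iv.strand == "+":
        return iv.start, iv.end - 1
    if iv.strand == "-":
        return iv.end - 1, iv.start
    raise ValueError(f"gene {gene.gene_id} is unstranded")


@dataclass(frozen=True)
class Peak:
    """Scored interval with a summit offset relative to its start."""

    interval: GenomicInterval
    summit: int  # offset within interval
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length "
                f"{len(self.interval)}"
            )
        if self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def summit_pos(self) -> int:
        return self.interval.start + self.summit


def _default_summit(start: int, end: int) -> int:
    return (start + end) // 2 - start


class PeakSet:
    """Ordered collection of peaks, sorted by (chromosome, start, end).

    Ties at identical coordinates are broken by score descending, then input
    order.  Duplicate (chromosome, start, end) triples are rejected.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = ""):
        peaks = list(peaks)
        order = sorted(
            range(len(peaks)),
            key=lambda i: (
                peaks[i].interval.chrom,
                peaks[i].interval.start,
                peaks[i].interval.end,
                -peaks[i].score,
                i,
            ),
        )
        self.peaks: tuple[Peak, ...] = tuple(peaks[i] for i in order)
        self.label = label
        seen: set[tuple[str, int, int]] = set()
        for p in self.peaks:
            key = (p.interval.chrom, p.interval.start, p.interval.end)
            if key in seen:
                raise ValueError(f"duplicate interval {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.peaks == other.peaks
            and self.label == other.label
        )

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(p.interval.chrom for p in self.peaks))

    def by_chromosome(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 3) arrays of (start, end, summit_pos)."""
        out: dict[str, list[list[int]]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(
                [p.interval.start, p.interval.end, p.summit_pos]
            )
        return {c: np.asarray(rows, dtype=np.int64) for c, rows in out.items()}

    def summit_positions(self) -> dict[str, np.ndarray]:
        return {
            c: arr[:, 2] for c, arr in self.by_chromosome().items()
        }

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class SignalTrack:
    """Fixed-step binned numeric coverage, one vector per chromosome."""

    bin_width: int
    values: dict[str, np.ndarray]

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on chromosome {c}")

    def validate(self, layout: GenomeLayout) -> None:
        for c, v in self.values.items():
            expect = math.ceil(layout[c] / self.bin_width)
            if len(v) != expect:
                raise ValueError(
                    f"{c}: expected {expect} bins for length {layout[c]} at "
                    f"bin width {self.bin_width}, got {len(v)}"
                )

    def concat(self, chrom_order: Sequence[str] | None = None) -> np.ndarray:
        order = chrom_order if chrom_order is not None else list(self.values)
        return np.concatenate([self.values[c] for c in order])

    @classmethod
    def from_layout(cls, layout: GenomeLayout, bin_width: int) -> "SignalTrack":
        return cls(
            bin_width,
            {
                c: np.zeros(math.ceil(length / bin_width))
                for c, length in layout.lengths.items()
            },
        )


# ---------------------------------------------------------------------------
# Interval I/O


def read_intervals(path, layout: GenomeLayout, label: str = "") -> PeakSet:
    """Read BED3/BED6(+optional 7th summit-offset column) into a PeakSet.

    Missing summit defaults to the interval midpoint; missing score to 0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start >= end or start < 0:
                raise ParseError(path, lineno, f"bad interval [{start}, {end})")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            score = 0.0
            if len(parts) >= 5 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {parts[4]!r}") from None
            summit = _default_summit(start, end)
            if len(parts) >= 7 and parts[6] not in (".", ""):
                try:
                    summit = int(parts[6])
                except ValueError:
                    raise ParseError(path, lineno, f"bad summit {parts[6]!r}") from None
            iv = GenomicInterval(chrom, start, end, strand)
            iv.validate(layout)
            peaks.append(Peak(iv, summit, score))
    return PeakSet(peaks, label=label)


def write_intervals(peaks: PeakSet, path, with_summit: bool = True) -> None:
    """Write a PeakSet as BED6(+summit offset column)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), f"peak_{i}",
                    repr(float(p.score)), iv.strand]
            if with_summit:
                cols.append(str(p.summit))
            fh.write("\t".join(cols) + "\n")


def _parse_attributes(field9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_genes(path, layout: GenomeLayout) -> tuple[list[GeneModel], list[str]]:
    """Read GTF-style annotation (1-based inclusive) into GeneModel records.

    Gene class is taken from the ``gene_class`` attribute.  Returns the gene
    list plus a list of rejection reasons (genes without strand or with an
    unknown class are skipped, never silently coerced).
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    rejects: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(path, lineno, "fewer than 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attr_field = parts[:9]
            try:
                start0, end = int(start1) - 1, int(end1)  # to 0-based half-open
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            attrs = _parse_attributes(attr_field)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            if feature == "gene":
                if strand not in ("+", "-"):
                    rejects.append(f"{gid}: gene without strand")
                    continue
                gclass = attrs.get("gene_class", "")
                if gclass not in GENE_CLASSES:
                    rejects.append(f"{gid}: unknown class {gclass!r}")
                    continue
                iv = GenomicInterval(chrom, start0, end, strand)
                iv.validate(layout)
                gene_rows[gid] = {"interval": iv, "class": gclass}
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append(
                    GenomicInterval(chrom, start0, end, strand if strand in "+-" else ".")
                )
    genes = []
    for gid, row in gene_rows.items():
        exons = tuple(sorted(exon_rows.get(gid, []), key=lambda e: e.start))
        if not exons:
            exons = (row["interval"],)
        genes.append(GeneModel(gid, row["interval"], exons, row["class"]))
    return genes, rejects


def write_genes(genes: Iterable[GeneModel], path, source: str = "regulomekit") -> None:
    """Write gene models as GTF-style annotation (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_class "{g.gene_class}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


def read_bedgraph(path, layout: GenomeLayout, bin_width: int) -> SignalTrack:
    """Read a fixed-step bedGraph (every line spans exactly one bin)."""
    track = SignalTrack.from_layout(layout, bin_width)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, "fewer than 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in layout:
                raise BoundsError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start % bin_width != 0:
                raise ParseError(path, lineno, f"start {start} not on bin grid {bin_width}")
            track.values[chrom][start // bin_width] = value
    return track


def write_bedgraph(track: SignalTrack, layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            length = layout[chrom]
            for i, v in enumerate(vec):
                start = i * track.bin_width
                end = min(start + track.bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Interval queries


class _ChromIndex:
    """Sorted merged intervals on one chromosome for O(log n) stab queries."""

    __slots__ = ("starts", "ends")

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        self.starts = np.asarray(merged_s, dtype=np.int64)
        self.ends = np.asarray(merged_e, dtype=np.int64)

    def any_overlap(self, q_starts: np.ndarray, q_ends: np.ndarray) -> np.ndarray:
        """Vectorised: does each half-open query hit any stored interval?"""
        if len(self.starts) == 0:
            return np.zeros(len(q_starts), dtype=bool)
        # overlap iff some interval has start < q_end and end > q_start
        left = np.searchsorted(self.ends, q_starts, side="right")
        right = np.searchsorted(self.starts, q_ends, side="left")
        return left < right


def build_index(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> dict[str, _ChromIndex]:
    """Per-chromosome query index over intervals expanded by ``gap`` bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((max(0, iv.start - gap), iv.end + gap))
    return {
        c: _ChromIndex(
            np.asarray([p[0] for p in pairs], dtype=np.int64),
            np.asarray([p[1] for p in pairs], dtype=np.int64),
        )
        for c, pairs in by_chrom.items()
    }


def overlaps_any(
    query: PeakSet,
    subject: Iterable[GenomicInterval],
    gap: int = 0,
    layout: GenomeLayout | None = None,
) -> np.ndarray:
    """Per-query boolean: ≥1 bp overlap with any subject after gap expansion.

    Half-open semantics; a query on a chromosome with no subject intervals is
    False.  When a layout is given both inputs are validated against it.
    """
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    subject = list(subject)
    if layout is not None:
        for iv in subject:
            iv.validate(layout)
        for p in query:
            p.interval.validate(layout)
    index = build_index(subject, gap=gap)
    out = np.zeros(len(query), dtype=bool)
    for i, p in enumerate(query):
        idx = index.get(p.interval.chrom)
        if idx is None:
            continue
        out[i] = bool(
            idx.any_overlap(
                np.asarray([p.interval.start]), np.asarray([p.interval.end])
            )[0]
        )
    return out
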