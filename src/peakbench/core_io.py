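"""Genomic interval algebra and file I/O.

Coordinates are 0-based, half-open (BED convention) everywhere. Abutting
intervals ``[x, y)`` / ``[y, z)`` have gap 0 and therefore count as
overlapping whenever a ``maxgap >= 0`` rule is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "Peak",
    "ReadSet",
    "GeneModel",
    "CoverageTrack",
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_fragments",
    "write_fragments",
    "read_genes",
    "write_genes",
    "read_bedgraph",
    "write_bedgraph",
    "gap",
    "coverage_from_fragments",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ChromSizes:
    """Ordered chromosome-name -> length map.

    Iteration order is file/insertion order so downstream window ids are
    deterministic.
    """

    def __init__(self, items: Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"non-positive length for {name!r}: {length}")
            self._sizes[name] = length

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChromSizes):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"ChromSizes({dict(self._sizes)!r})"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, chrom_sizes: ChromSizes) -> None:
        if self.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > chrom_sizes[self.chrom]:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {chrom_sizes[self.chrom]}"
            )


@dataclass(frozen=True)
class Peak:
    """A called peak; narrowPeak-style optional fields use the -1 sentinel.

    ``p`` and ``q`` are -log10-transformed; ``q`` carries the caller FDR.
    ``summit`` is an offset in bp from ``interval.start``.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    p: float = -1.0
    q: float = -1.0
    summit: int = -1

    def __post_init__(self):
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        for label, v in (("p", self.p), ("q", self.q)):
            if v != -1 and v < 0:
                raise ValueError(f"{label} must be -1 or >= 0, got {v}")
        if self.summit != -1 and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit {self.summit} outside peak of length {len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def anchor(self) -> int:
        """Absolute summit position if present, else interval midpoint."""
        if self.summit >= 0:
            return self.start + self.summit
        return (self.start + self.end) // 2


@dataclass
class ReadSet:
    """Sequenced fragments as plain intervals; strand is irrelevant here."""

    fragments: list[GenomicInterval]

    @property
    def total(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class GeneModel:
    interval: GenomicInterval
    strand: str
    id: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """Transcription start coordinate (0-based base position)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class CoverageTrack:
    """Per-chromosome non-negative step function tiling [0, chrom_length).

    Stored as ``edges`` (k+1 breakpoints, first 0, last = chrom length) and
    ``values`` (k step values). A step representation keeps megabase
    synthetic genomes and real chromosomes on one code path.
    """

    def __init__(self, chrom_sizes: ChromSizes, normalization: str = "raw"):
        if normalization not in ("raw", "rpm"):
            raise ValueError(f"normalization must be raw or rpm, got {normalization!r}")
        self.chrom_sizes = chrom_sizes
        self.normalization = normalization
        self._edges: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, length in chrom_sizes.items():
            self._edges[chrom] = np.array([0, length], dtype=np.int64)
            self._values[chrom] = np.zeros(1, dtype=np.float64)
        self._cum: dict[str, np.ndarray] | None = None

    def set_steps(self, chrom: str, edges: np.ndarray, values: np.ndarray) -> None:
        edges = np.asarray(edges, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        length = self.chrom_sizes[chrom]
        if edges[0] != 0 or edges[-1] != length or len(edges) != len(values) + 1:
            raise ValueError(f"steps do not tile {chrom}:[0,{length})")
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"step edges not strictly increasing on {chrom}")
        if np.any(values < 0):
            raise ValueError("negative coverage value")
        self._edges[chrom] = edges
        self._values[chrom] = values
        self._cum = None

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._edges[chrom], self._values[chrom]

    def _cumulative(self) -> dict[str, np.ndarray]:
        if self._cum is None:
            self._cum = {}
            for chrom in self.chrom_sizes:
                e, v = self._edges[chrom], self._values[chrom]
                c = np.zeros(len(e), dtype=np.float64)
                np.cumsum(np.diff(e) * v, out=c[1:])
                self._cum[chrom] = c
        return self._cum

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, x) for each x in ``positions``.

        Positions are clipped to the chromosome; evaluation is exact for
        the step function.
        """
        e = self._edges[chrom]
        v = self._values[chrom]
        c = self._cumulative()[chrom]
        x = np.clip(np.asarray(positions, dtype=np.float64), 0, e[-1])
        idx = np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(v) - 1)
        return c[idx] + (x - e[idx]) * v[idx]

    def mean(self, chrom: str, start: float, end: float) -> float:
        if end <= start:
            raise ValueError("empty query interval")
        lo, hi = self.integral(chrom, np.array([start, end]))
        return float((hi - lo) / (end - start))

    def bin_means(self, chrom: str, boundaries: np.ndarray) -> np.ndarray:
        """Mean per-base value over consecutive bins given their boundaries."""
        ints = self.integral(chrom, np.asarray(boundaries, dtype=np.float64))
        widths = np.diff(np.asarray(boundaries, dtype=np.float64))
        return np.diff(ints) / widths

    def total_signal(self) -> float:
        return float(
            sum(
                np.sum(np.diff(self._edges[c]) * self._values[c])
                for c in self.chrom_sizes
            )
        )

    def values_dense(self, chrom: str) -> np.ndarray:
        """Per-base expansion; only for small chromosomes (tests)."""
        e, v = self._edges[chrom], self._values[chrom]
        return np.repeat(v, np.diff(e))


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> ChromSizes:
    items: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
        if length < 1:
            raise ParseError(f"{path}:{lineno}: non-positive length {length}")
        seen.add(name)
        items.append((name, length))
    return ChromSizes(items)


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


_DIALECT_COLS = {"bed6": (3, 6), "narrowPeak": (10, 10), "broadPeak": (9, 9)}


def read_peaks(path, dialect: str = "narrowPeak",
               chrom_sizes: ChromSizes | None = None) -> list[Peak]:
    """Read peaks in bed6 / ENCODE narrowPeak / ENCODE broadPeak format.

    Missing p/q/summit fields are set to the -1 sentinel. Coordinates are
    validated against ``chrom_sizes`` when one is given.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lo, hi = _DIALECT_COLS[dialect]
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if not (lo <= len(parts) <= hi):
            raise ParseError(
                f"{path}:{lineno}: {dialect} expects {lo}"
                + (f"-{hi}" if hi != lo else "")
                + f" columns, got {len(parts)}"
            )
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad coordinates") from None
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = parts[3] if len(parts) > 3 else "."
        score = float(parts[4]) if len(parts) > 4 else 0.0
        strand = parts[5] if len(parts) > 5 else "."
        signal, p, q, summit = 0.0, -1.0, -1.0, -1
        if dialect in ("narrowPeak", "broadPeak"):
            signal, p, q = float(parts[6]), float(parts[7]), float(parts[8])
            if dialect == "narrowPeak":
                summit = int(parts[9])
        try:
            peak = Peak(GenomicInterval(chrom, start, end), name, score,
                        strand, signal, p, q, summit)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if chrom_sizes is not None:
            peak.interval.validate(chrom_sizes)
        peaks.append(peak)
    return peaks


def _fmt(x: float) -> str:
    return format(x, "g")


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            cols = [pk.chrom, str(pk.start), str(pk.end), pk.name,
                    _fmt(pk.score), pk.strand]
            if dialect in ("narrowPeak", "broadPeak"):
                cols += [_fmt(pk.signal), _fmt(pk.p), _fmt(pk.q)]
            if dialect == "narrowPeak":
                cols.append(str(pk.summit))
            fh.write("\t".join(cols) + "\n")


def read_fragments(path, chrom_sizes: ChromSizes | None = None) -> ReadSet:
    """Read BED6/tagAlign fragment intervals; only the first 3 columns count."""
    frags: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
        try:
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if chrom_sizes is not None:
            iv.validate(chrom_sizes)
        frags.append(iv)
    return ReadSet(frags)


def write_fragments(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for iv in reads.fragments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes(path) -> list[GeneModel]:
    """Read gene models from BED6 (name column = gene id)."""
    genes: list[GeneModel] = []
    ids: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: gene BED needs 6 columns")
        try:
            gene = GeneModel(GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                             parts[5], parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if gene.id in ids:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene.id!r}")
        ids.add(gene.id)
        genes.append(gene)
    return genes


def write_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.interval.start}\t{g.interval.end}"
                     f"\t{g.id}\t0\t{g.strand}\n")


def read_bedgraph(path, chrom_sizes: ChromSizes) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack (gaps filled with 0).

    Records must be sorted and non-overlapping per chromosome.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: bedGraph expects 4 columns")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in chrom_sizes:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        if end > chrom_sizes[chrom]:
            raise ParseError(f"{path}:{lineno}: coordinate {end} beyond "
                             f"chromosome length {chrom_sizes[chrom]}")
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative coverage {value}")
        recs = per_chrom[chrom]
        if recs and start < recs[-1][1]:
            raise ParseError(f"{path}:{lineno}: overlapping or unsorted records")
        recs.append((start, end, value))

    track = CoverageTrack(chrom_sizes, normalization="raw")
    for chrom, length in chrom_sizes.items():
        edges = [0]
        values = []
        for start, end, value in per_chrom[chrom]:
            if start > edges[-1]:
                values.append(0.0)
                edges.append(start)
            values.append(value)
            edges.append(end)
        if edges[-1] < length:
            values.append(0.0)
            edges.append(length)
        track.set_steps(chrom, np.array(edges), np.array(values))
    return track


def write_bedgraph(track: CoverageTrack, path, omit_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            edges, values = track.steps(chrom)
            for i, v in enumerate(values):
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{edges[i]}\t{edges[i + 1]}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance between two intervals: 0 when they intersect or abut,
    inf on different chromosomes, else nearest-end distance."""
    if a.chrom != b.chrom:
        return math.inf
    d = max(a.start, b.start) - min(a.end, b.end)
    return float(max(d, 0))


def coverage_from_fragments(reads: ReadSet, chrom_sizes: ChromSizes,
                            normalize: str = "raw",
                            midpoints: bool = False) -> CoverageTrack:
    """Per-base fragment (or fragment-midpoint) coverage as a step function.

    ``rpm`` scales by 1e6 / total fragment count. ``midpoints=True`` counts
    only the single midpoint base of each fragment, for callers that match
    5'-end style tracks.
    """
    if normalize not in ("raw", "rpm"):
        raise ValueError(f"normalize must be raw or rpm, got {normalize!r}")
    if normalize == "rpm" and reads.total == 0:
        raise ValueError("rpm normalization requested on an empty ReadSet")
    scale = 1.0 if normalize == "raw" else 1e6 / reads.total

    starts: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    ends: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for iv in reads.fragments:
        iv.validate(chrom_sizes)
        if midpoints:
            mid = (iv.start + iv.end) // 2
            starts[iv.chrom].append(mid)
            ends[iv.chrom].append(mid + 1)
        else:
            starts[iv.chrom].append(iv.start)
            ends[iv.chrom].append(iv.end)

    track = CoverageTrack(chrom_sizes, normalization=normalize)
    for chrom, length in chrom_sizes.items():
        if not starts[chrom]:
            continue
        # sweep over +1/-1 events at fragment boundaries
        bounds = np.concatenate([
            np.zeros(1, dtype=np.int64),
            np.asarray(starts[chrom], dtype=np.int64),
            np.asarray(ends[chrom], dtype=np.int64),
            np.full(1, length, dtype=np.int64),
        ])
        edges = np.unique(bounds)
        delta = np.zeros(len(edges), dtype=np.float64)
        s_idx = np.searchsorted(edges, np.asarray(starts[chrom], dtype=np.int64))
        e_idx = np.searchsorted(edges, np.asarray(ends[chrom], dtype=np.int64))
        np.add.at(delta, s_idx, 1.0)
        np.add.at(delta, e_idx, -1.0)
        values = np.cumsum(delta)[:-1] * scale
        track.set_steps(chrom, edges, values)
    return track
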