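"""Binned correlation, metagene profiles, log2 fold-change and peak-centered
profile matrices over coverage tracks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ChromSizes, CoverageTrack, GeneModel, Peak

__all__ = [
    "BinnedTrack",
    "ProfileMatrix",
    "ProfileSummary",
    "bin_track",
    "pearson_bins",
    "metagene",
    "log2fc_profile",
    "peak_centered",
]


@dataclass
class BinnedTrack:
    bin_size: int
    chrom_sizes: ChromSizes
    values: dict[str, np.ndarray]  # per chromosome, mean coverage per bin

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.chrom_sizes])


@dataclass
class ProfileMatrix:
    """regions x bins matrix of mean per-base signal.

    ``column_kind`` records bin provenance (flank5 / body / flank3 or a
    centered offset). Rows whose bins would leave the chromosome are
    flagged, kept in the matrix (NaN), and excluded from summaries.
    """

    values: np.ndarray
    row_labels: list[str]
    column_kind: list[str]
    flagged: np.ndarray = field(default=None)  # bool per row

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = np.zeros(self.values.shape[0], dtype=bool)

    def valid_rows(self) -> np.ndarray:
        return self.values[~self.flagged]


@dataclass
class ProfileSummary:
    mean: np.ndarray
    sem: np.ndarray  # sd / sqrt(n), ddof=1 (0 when n < 2)
    n: int


def summarize(matrix: ProfileMatrix) -> ProfileSummary:
    rows = matrix.valid_rows()
    n = rows.shape[0]
    if n == 0:
        raise ValueError("no unflagged rows to summarize")
    mean = rows.mean(axis=0)
    sem = rows.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ProfileSummary(mean, sem, n)


def bin_track(cov: CoverageTrack, bin_size: int,
              chrom_sizes: ChromSizes | None = None) -> BinnedTrack:
    """Mean per-base coverage in consecutive fixed bins (last bin partial,
    averaged over its true length)."""
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    chrom_sizes = chrom_sizes or cov.chrom_sizes
    values: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        boundaries = np.arange(0, length, bin_size, dtype=np.float64)
        boundaries = np.append(boundaries, length)
        values[chrom] = cov.bin_means(chrom, boundaries)
    return BinnedTrack(bin_size, chrom_sizes, values)


def pearson_bins(a: BinnedTrack, b: BinnedTrack,
                 drop_joint_zero_bins: bool = False) -> float:
    """Pearson correlation over all bins (zero bins included by default)."""
    if a.bin_size != b.bin_size:
        raise ValueError("bin size mismatch")
    if list(a.chrom_sizes.items()) != list(b.chrom_sizes.items()):
        raise ValueError("chromosome mismatch")
    x, y = a.flat(), b.flat()
    if drop_joint_zero_bins:
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("need at least 2 bins")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one track; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _gene_boundaries(gene: GeneModel, flank: int, body_bins: int,
                     flank_bin: int) -> tuple[np.ndarray, bool]:
    """Bin boundaries 5'->3' in genomic coordinates; returns (boundaries,
    reverse) where reverse means the row must be flipped after extraction."""
    n_flank = flank // flank_bin
    start, end = gene.interval.start, gene.interval.end
    up = np.linspace(start - flank, start, n_flank + 1)
    body = np.linspace(start, end, body_bins + 1)
    down = np.linspace(end, end + flank, n_flank + 1)
    boundaries = np.concatenate([up, body[1:], down[1:]])
    return boundaries, gene.strand == "-"


def metagene(cov: CoverageTrack, genes: list[GeneModel], flank: int = 1000,
             body_bins: int = 100,
             flank_bin: int = 20) -> tuple[ProfileMatrix, ProfileSummary]:
    """Scaled gene-body profile with fixed-width flanks.

    Each gene contributes flank/flank_bin fixed bins upstream of the TSS,
    ``body_bins`` equal bins across [TSS, TES), and the downstream flank;
    minus-strand rows are reversed so column 0 is always 5'. Genes shorter
    than ``body_bins`` bp, or whose flanks leave the chromosome, are flagged
    and excluded from the summary.
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    ncol = 2 * n_flank + body_bins
    values = np.full((len(genes), ncol), np.nan)
    flagged = np.zeros(len(genes), dtype=bool)
    labels = []
    for i, gene in enumerate(genes):
        labels.append(gene.id)
        chrom_len = cov.chrom_sizes[gene.chrom]
        if len(gene.interval) < body_bins:
            flagged[i] = True
            continue
        boundaries, reverse = _gene_boundaries(gene, flank, body_bins, flank_bin)
        if boundaries[0] < 0 or boundaries[-1] > chrom_len:
            flagged[i] = True
            continue
        row = cov.bin_means(gene.chrom, boundaries)
        if reverse:
            row = row[::-1]
        values[i] = row
    if flagged.all():
        raise ValueError("no genes retained (all too short or out of bounds)")
    kinds = (["flank5"] * n_flank + ["body"] * body_bins + ["flank3"] * n_flank)
    matrix = ProfileMatrix(values, labels, kinds, flagged)
    return matrix, summarize(matrix)


def log2fc_profile(signal: ProfileMatrix, control: ProfileMatrix,
                   pseudocount: float = 0.1
                   ) -> tuple[ProfileMatrix, ProfileSummary]:
    """Per-cell log2((s + psi) / (c + psi)); inputs should be RPM-scaled."""
    if signal.values.shape != control.values.shape:
        raise ValueError(
            f"shape mismatch: {signal.values.shape} vs {control.values.shape}"
        )
    if signal.row_labels != control.row_labels:
        raise ValueError("region mismatch between signal and control matrices")
    vals = np.log2((signal.values + pseudocount) / (control.values + pseudocount))
    flagged = signal.flagged | control.flagged
    matrix = ProfileMatrix(vals, list(signal.row_labels),
                           list(signal.column_kind), flagged)
    return matrix, summarize(matrix)


def peak_centered(cov: CoverageTrack, peaks: list[Peak], half_width: int = 1000,
                  bin: int = 10,
                  sort_by: CoverageTrack | None = None) -> ProfileMatrix:
    """Profile matrix centered on peak summits (or midpoints).

    Rows are sorted by decreasing mean of ``sort_by`` over the row span
    (coordinate tie-break); without a sort track the input order is kept.
    Peaks whose window leaves the chromosome are flagged.
    """
    if half_width < bin:
        raise ValueError("half_width must be >= bin")
    if (2 * half_width) % bin != 0:
        raise ValueError("2*half_width must be a multiple of bin")
    ncol = 2 * half_width // bin
    values = np.full((len(peaks), ncol), np.nan)
    flagged = np.zeros(len(peaks), dtype=bool)
    labels = []
    sort_keys: list[tuple[float, str, int]] = []
    for i, pk in enumerate(peaks):
        labels.append(pk.name if pk.name != "." else f"peak_{i + 1}")
        anchor = pk.anchor()
        lo, hi = anchor - half_width, anchor + half_width
        chrom_len = cov.chrom_sizes[pk.chrom]
        if lo < 0 or hi > chrom_len:
            flagged[i] = True
            sort_keys.append((math.inf, pk.chrom, pk.start))
            continue
        boundaries = np.linspace(lo, hi, ncol + 1)
        values[i] = cov.bin_means(pk.chrom, boundaries)
        if sort_by is not None:
            key = -sort_by.mean(pk.chrom, lo, hi)
        else:
            key = 0.0
        sort_keys.append((key, pk.chrom, pk.start))
    offsets = np.arange(-half_width, half_width, bin)
    kinds = [f"{o:+d}" for o in offsets]
    if sort_by is not None:
        order = sorted(range(len(peaks)), key=lambda i: sort_keys[i])
        values = values[order]
        labels = [labels[i] for i in order]
        flagged = flagged[order]
    return ProfileMatrix(values, labels, kinds, flagged)


def write_matrix_tsv(matrix: ProfileMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tflagged\t" + "\t".join(matrix.column_kind) + "\n")
        for i, lab in enumerate(matrix.row_labels):
            row = "\t".join("nan" if np.isnan(v) else f"{v:.10g}"
                            for v in matrix.values[i])
            fh.write(f"{lab}\t{int(matrix.flagged[i])}\t{row}\n")


def write_summary_tsv(summary: ProfileSummary, column_kind: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n\t{summary.n}\n")
        fh.write("column\tkind\tmean\tsem\n")
        for j, kind in enumerate(column_kind):
            fh.write(f"{j}\t{kind}\t{summary.mean[j]:.10g}\t{summary.sem[j]:.10g}\n")
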