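"""Peak-set comparison: maxgap overlaps, replicate consensus, FDR-quantile
recovery, saturation of recall, matched random regions, read coverage over
peak classes, and a simplified nearest-gene annotator.

Two intervals are partners when their gap (0 for intersecting or abutting
half-open intervals) is at most ``maxgap``. Merged entities are connected
components of the partner graph built over both input sets with the same
gap rule, mirroring how upstream Venn-style overlap counters merge peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import ChromSizes, GeneModel, GenomicInterval, Peak, ReadSet

__all__ = [
    "OverlapReport",
    "QuantileRecovery",
    "SaturationCurve",
    "PeakAnnotation",
    "find_overlaps",
    "merge_replicates",
    "fdr_quantile_recovery",
    "saturation_recall",
    "partition_unique_common",
    "random_matched_regions",
    "region_read_coverage",
    "annotate_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    maxgap: int
    nA: int
    nB: int
    nA_hit: int
    nB_hit: int
    components_both: int
    components_onlyA: int
    components_onlyB: int

    @property
    def pctA(self) -> float:
        return self.nA_hit / self.nA if self.nA else 0.0

    @property
    def pctB(self) -> float:
        return self.nB_hit / self.nB if self.nB else 0.0

    @property
    def pct_venn(self) -> float:
        total = self.components_both + self.components_onlyA + self.components_onlyB
        return self.components_both / total if total else 0.0


@dataclass
class QuantileRecovery:
    """Recovery per FDR quantile; quantile 1 holds the lowest-FDR peaks."""

    n_quantiles: int
    counts: list[int]
    recovered: list[int]

    @property
    def fractions(self) -> list[float]:
        return [r / c if c else 0.0 for r, c in zip(self.recovered, self.counts)]


@dataclass
class SaturationCurve:
    depths: list[str]
    fractions: list[float]


@dataclass
class PeakAnnotation:
    categories: list[str]          # Promoter | GeneBody | DistalIntergenic
    nearest_gene: list[str]
    distance_to_tss: list[int]     # signed, positive = downstream of TSS


# ---------------------------------------------------------------------------
# partner queries


class _SortedIntervals:
    """Per-chromosome interval index for maxgap partner queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in tmp.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def has_partner(self, iv: GenomicInterval, maxgap: int) -> bool:
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, _, ends_cummax = entry
        # partner iff start <= iv.end + maxgap and end >= iv.start - maxgap
        hi = int(np.searchsorted(starts, iv.end + maxgap, side="right"))
        if hi == 0:
            return False
        return bool(ends_cummax[hi - 1] >= iv.start - maxgap)


def _partner_flags(queries: list[GenomicInterval],
                   targets: list[GenomicInterval], maxgap: int) -> np.ndarray:
    idx = _SortedIntervals(targets)
    return np.array([idx.has_partner(iv, maxgap) for iv in queries], dtype=bool)


def _components(intervals: list[tuple[GenomicInterval, int]],
                maxgap: int) -> list[list[int]]:
    """Connected components (single-linkage at gap <= maxgap) of tagged
    intervals; returns lists of indices into the input list."""
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i][0].chrom, intervals[i][0].start,
                                  intervals[i][0].end))
    comps: list[list[int]] = []
    cur: list[int] = []
    cur_chrom, cur_end = None, -1
    for i in order:
        iv = intervals[i][0]
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= maxgap:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                comps.append(cur)
            cur = [i]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cur:
        comps.append(cur)
    return comps


def find_overlaps(A: list[Peak], B: list[Peak], maxgap: int) -> OverlapReport:
    """Maxgap overlap accounting between two peak sets.

    Reports per-set hit counts/fractions and Venn-style merged-component
    counts; all three percentage conventions are exposed because published
    single-number overlaps do not pin down the denominator.
    """
    if maxgap < 0:
        raise ValueError(f"maxgap must be >= 0, got {maxgap}")
    a_ivs = [pk.interval for pk in A]
    b_ivs = [pk.interval for pk in B]
    a_hit = _partner_flags(a_ivs, b_ivs, maxgap)
    b_hit = _partner_flags(b_ivs, a_ivs, maxgap)

    tagged = [(iv, 0) for iv in a_ivs] + [(iv, 1) for iv in b_ivs]
    both = only_a = only_b = 0
    for comp in _components(tagged, maxgap):
        sets = {tagged[i][1] for i in comp}
        if sets == {0, 1}:
            both += 1
        elif sets == {0}:
            only_a += 1
        else:
            only_b += 1
    return OverlapReport(maxgap, len(A), len(B), int(a_hit.sum()),
                         int(b_hit.sum()), both, only_a, only_b)


def _neglog10_cutoff(fdr_cutoff: float) -> float:
    return -math.log10(fdr_cutoff)


def _filter_fdr(peaks: list[Peak], fdr_cutoff: float | None) -> list[Peak]:
    if fdr_cutoff is None:
        return list(peaks)
    if peaks and all(pk.q == -1 for pk in peaks):
        raise ValueError("FDR cutoff requested but peaks carry no q values")
    thr = _neglog10_cutoff(fdr_cutoff)
    return [pk for pk in peaks if pk.q != -1 and pk.q >= thr]


def merge_replicates(rep1: list[Peak], rep2: list[Peak],
                     fdr_cutoff: float | None = None,
                     maxgap: int = 0) -> list[Peak]:
    """Consensus peaks present (at the cutoff) in both replicates.

    Cross-replicate connected components at the gap rule are collapsed to
    their coordinate span; consensus p/q is the best (max -log10) among
    members. Components supported by a single replicate are dropped.
    """
    r1 = _filter_fdr(rep1, fdr_cutoff)
    r2 = _filter_fdr(rep2, fdr_cutoff)
    tagged = [(pk.interval, 0) for pk in r1] + [(pk.interval, 1) for pk in r2]
    all_peaks = r1 + r2
    out: list[Peak] = []
    for comp in _components(tagged, maxgap):
        sets = {tagged[i][1] for i in comp}
        if sets != {0, 1}:
            continue
        members = [all_peaks[i] for i in comp]
        start = min(pk.start for pk in members)
        end = max(pk.end for pk in members)
        best_p = max(pk.p for pk in members)
        best_q = max(pk.q for pk in members)
        best_sig = max(pk.signal for pk in members)
        out.append(Peak(GenomicInterval(members[0].chrom, start, end),
                        name=f"consensus_{len(out) + 1}", score=0.0, strand=".",
                        signal=best_sig, p=best_p, q=best_q, summit=-1))
    out.sort(key=lambda pk: (pk.chrom, pk.start, pk.end))
    for i, pk in enumerate(out):
        object.__setattr__(pk, "name", f"consensus_{i + 1}")
    return out


def fdr_quantile_recovery(candidates: list[Peak], reference: list[Peak],
                          maxgap: int, n_quantiles: int = 10) -> QuantileRecovery:
    """Split candidates into near-equal blocks by increasing FDR and measure
    the fraction of each block rediscovered in the reference at ``maxgap``.

    Remainder peaks go to the earliest (lowest-FDR) blocks; the sort is
    stable with coordinate tie-breaking so membership is reproducible.
    """
    if n_quantiles < 1:
        raise ValueError(f"n_quantiles must be >= 1, got {n_quantiles}")
    if not reference:
        raise ValueError("empty reference peak set")
    if any(pk.q == -1 for pk in candidates):
        raise ValueError("all candidates must carry q values")
    # increasing FDR = decreasing -log10 q
    ordered = sorted(candidates,
                     key=lambda pk: (-pk.q, pk.chrom, pk.start, pk.end))
    hit = _partner_flags([pk.interval for pk in ordered],
                         [pk.interval for pk in reference], maxgap)
    n = len(ordered)
    base, rem = divmod(n, n_quantiles)
    counts, recovered = [], []
    pos = 0
    for qi in range(n_quantiles):
        size = base + (1 if qi < rem else 0)
        counts.append(size)
        recovered.append(int(hit[pos:pos + size].sum()))
        pos += size
    return QuantileRecovery(n_quantiles, counts, recovered)


def saturation_recall(full: list[Peak], per_depth: dict[str, list[Peak]],
                      maxgap: int) -> SaturationCurve:
    """Fraction of full-depth peaks re-found in each subsampled peak set."""
    if not full:
        raise ValueError("empty full-depth peak set")
    full_ivs = [pk.interval for pk in full]
    depths, fractions = [], []
    for depth, peaks in per_depth.items():
        if depth in depths:
            raise ValueError(f"duplicate depth label {depth!r}")
        hit = _partner_flags(full_ivs, [pk.interval for pk in peaks], maxgap)
        depths.append(depth)
        fractions.append(float(hit.mean()))
    return SaturationCurve(depths, fractions)


def partition_unique_common(A: list[Peak], B: list[Peak],
                            maxgap: int) -> dict[str, list[Peak]]:
    if maxgap < 0:
        raise ValueError(f"maxgap must be >= 0, got {maxgap}")
    a_hit = _partner_flags([pk.interval for pk in A],
                           [pk.interval for pk in B], maxgap)
    b_hit = _partner_flags([pk.interval for pk in B],
                           [pk.interval for pk in A], maxgap)
    return {
        "A_only": [pk for pk, h in zip(A, a_hit) if not h],
        "B_only": [pk for pk, h in zip(B, b_hit) if not h],
        "A_common": [pk for pk, h in zip(A, a_hit) if h],
        "B_common": [pk for pk, h in zip(B, b_hit) if h],
    }


def random_matched_regions(template: list[Peak], chrom_sizes: ChromSizes,
                           exclusions: list[GenomicInterval] | None = None,
                           seed: int = 0,
                           max_tries: int = 1000) -> list[GenomicInterval]:
    """One uniformly placed region per template peak, matched for chromosome
    and length, rejection-sampled away from ``exclusions`` (gap-0 rule)."""
    rng = np.random.default_rng(seed)
    excl_idx = _SortedIntervals(list(exclusions or []))
    out: list[GenomicInterval] = []
    for pk in template:
        length = len(pk.interval)
        chrom_len = chrom_sizes[pk.chrom]
        if length >= chrom_len:
            raise ValueError(
                f"template {pk.chrom}:{pk.start}-{pk.end} is not shorter than "
                f"its chromosome ({chrom_len} bp)"
            )
        region = None
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - length + 1))
            candidate = GenomicInterval(pk.chrom, start, start + length)
            if not excl_idx.has_partner(candidate, 0):
                region = candidate
                break
        if region is None:
            logger.warning(
                "random region for %s:%d-%d still overlaps exclusions after "
                "%d tries; accepting the last draw",
                pk.chrom, pk.start, pk.end, max_tries,
            )
            region = candidate
        out.append(region)
    return out


def region_read_coverage(reads: ReadSet,
                         regions: list[GenomicInterval]) -> np.ndarray:
    """Count of fragments overlapping (>= 1 bp) each region."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in reads.fragments:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        starts[chrom] = np.sort(np.array([p[0] for p in pairs], dtype=np.int64))
        ends[chrom] = np.sort(np.array([p[1] for p in pairs], dtype=np.int64))
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        if region.chrom not in starts:
            continue
        n_start_before_end = np.searchsorted(starts[region.chrom], region.end,
                                             side="left")
        n_end_before_start = np.searchsorted(ends[region.chrom], region.start,
                                             side="right")
        counts[i] = n_start_before_end - n_end_before_start
    return counts


def coverage_summary(counts: np.ndarray) -> dict[str, float]:
    """Boxplot-style summary of per-region fragment counts."""
    if len(counts) == 0:
        return {"n": 0, "median": 0.0, "q1": 0.0, "q3": 0.0, "mean": 0.0}
    return {
        "n": int(len(counts)),
        "median": float(np.median(counts)),
        "q1": float(np.percentile(counts, 25)),
        "q3": float(np.percentile(counts, 75)),
        "mean": float(np.mean(counts)),
    }


def annotate_peaks(peaks: list[Peak], genes: list[GeneModel],
                   promoter_up: int = 1000,
                   promoter_down: int = 1000) -> PeakAnnotation:
    """Three-way peak categorisation anchored at the summit (or midpoint).

    Promoter: anchor within [TSS - up, TSS + down) measured along the gene's
    orientation. GeneBody: anchor inside a gene interval. Otherwise
    DistalIntergenic. Nearest gene minimises |anchor - TSS| with ties going
    to the smaller gene id.
    """
    if not genes:
        raise ValueError("empty gene set")
    categories, nearest, distances = [], [], []
    for pk in peaks:
        anchor = pk.anchor()
        in_promoter = False
        in_body = False
        best: tuple[int, str] | None = None
        best_signed = 0
        for g in genes:
            if g.chrom != pk.chrom:
                continue
            # signed distance along the gene: positive = downstream of TSS
            signed = anchor - g.tss if g.strand == "+" else g.tss - anchor
            if -promoter_up <= signed < promoter_down:
                in_promoter = True
            if g.interval.start <= anchor < g.interval.end:
                in_body = True
            key = (abs(signed), g.id)
            if best is None or key < best:
                best = key
                best_signed = signed
                best_id = g.id
        if best is None:
            # no gene on this chromosome: fall back to genome-wide nearest
            for g in genes:
                signed = anchor - g.tss if g.strand == "+" else g.tss - anchor
                key = (abs(signed), g.id)
                if best is None or key < best:
                    best = key
                    best_signed = signed
                    best_id = g.id
        if in_promoter:
            categories.append("Promoter")
        elif in_body:
            categories.append("GeneBody")
        else:
            categories.append("DistalIntergenic")
        nearest.append(best_id)
        distances.append(int(best_signed))
    return PeakAnnotation(categories, nearest, distances)
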