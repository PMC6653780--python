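import math

import numpy as np
import pytest

from peakbench.core_io import ChromSizes, GenomicInterval, Peak
from peakbench.window_eval import ScoredWindows, WindowSet


@pytest.fixture
def small_sizes():
    return ChromSizes([("chr1", 20_000), ("chr2", 10_000)])


@pytest.fixture
def one_chrom():
    return ChromSizes([("chr1", 10_000)])


def make_peak(chrom, start, end, name=".", p=-1.0, q=-1.0, summit=-1,
              signal=0.0, strand="."):
    return Peak(GenomicInterval(chrom, start, end), name=name, strand=strand,
                signal=signal, p=p, q=q, summit=summit)


def random_intervals(rng, n, chrom_sizes, max_len=500):
    out = []
    chroms = list(chrom_sizes)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_window_set(rng, chrom_sizes, window_size, density=0.2):
    from peakbench.window_eval import tile_genome

    ids = set()
    for w in tile_genome(chrom_sizes, window_size):
        if rng.random() < density:
            ids.add((w.chrom, w.start // window_size))
    return WindowSet(window_size, chrom_sizes, ids)


# ---------------------------------------------------------------------------
# independent oracles (brute force; never share code with the implementation)


def auc_pairwise_oracle(reference: WindowSet, scored: ScoredWindows,
                        universe_ids) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie); unscored windows share one
    sentinel worst score."""
    sentinel = -math.inf
    pos = [scored.scores.get(w, sentinel) for w in universe_ids
           if w in reference.ids]
    neg = [scored.scores.get(w, sentinel) for w in universe_ids
           if w not in reference.ids]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def overlap_oracle(A, B, maxgap=0):
    """O(n^2) partner flags: interval gap (half-open, abut=0) <= maxgap."""

    def pair_gap(a, b):
        if a.chrom != b.chrom:
            return math.inf
        return max(0, max(a.start, b.start) - min(a.end, b.end))

    a_hit = [any(pair_gap(a, b) <= maxgap for b in B) for a in A]
    b_hit = [any(pair_gap(a, b) <= maxgap for a in A) for b in B]
    return a_hit, b_hit


def region_coverage_oracle(fragments, regions):
    counts = []
    for r in regions:
        c = 0
        for f in fragments:
            if f.chrom == r.chrom and f.start < r.end and f.end > r.start:
                c += 1
        counts.append(c)
    return counts


def jaccard_oracle(ids_a, ids_b):
    inter = sum(1 for w in ids_a if w in ids_b)
    union = len(set(list(ids_a) + list(ids_b)))
    return 1.0 if union == 0 else inter / union
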