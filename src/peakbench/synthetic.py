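"""Synthetic ChIP-seq-like data with known truth.

Generates a small multi-chromosome genome, non-overlapping genes,
point-source (sharp, promoter-like) or broad-domain enrichment regions with
per-region enrichment factors, replicate-noised fragment sets at chosen
depths, and a surrogate Poisson window caller that emits peaks with -log10
p/q values correlated with true enrichment. Every operation is a pure
function of (config, seed) — reruns are byte-identical.

The caller is a test surrogate, not a reimplementation of any published
peak caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .core_io import ChromSizes, GeneModel, GenomicInterval, Peak, ReadSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_genome_and_genes",
    "simulate_truth",
    "simulate_fragments",
    "subsample_fragments",
    "benjamini_hochberg",
    "call_peaks_poisson",
]

_LN10 = math.log(10.0)


@dataclass
class SimConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 600_000, "chrS2": 400_000})
    n_genes: int = 60
    gene_length_mu: float = 7.6      # lognormal log-mean of gene length (bp)
    gene_length_sigma: float = 0.4
    gene_length_min: int = 200
    mark_type: str = "point"         # point | broad
    gene_fraction_marked: float = 0.5
    point_halfwidth: int = 500
    n_domains: int = 12
    domain_length_range: tuple[int, int] = (5_000, 20_000)
    enrichment_mu: float = 2.3       # lognormal log-mean of enrichment factor e
    enrichment_sigma: float = 0.4
    replicate_noise: float = 0.1     # lognormal sd on log e, per replicate
    n_fragments: int = 50_000
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    fragment_length_min: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.mark_type not in ("point", "broad"):
            raise ValueError(f"mark_type must be point or broad, got {self.mark_type!r}")
        if not (0.0 <= self.gene_fraction_marked <= 1.0):
            raise ValueError("gene_fraction_marked must be in [0, 1]")
        for name in ("n_genes", "n_domains", "n_fragments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_sizes.items())


@dataclass
class SyntheticTruth:
    mark_type: str
    regions: list[tuple[GenomicInterval, float]]  # (interval, enrichment e >= 1)

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.regions]


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def _place_nonoverlapping(rng: np.random.Generator, chrom_sizes: ChromSizes,
                          lengths: list[int], pad: int,
                          max_tries: int = 200) -> list[GenomicInterval]:
    """Uniform rejection placement of intervals that stay >= 2*pad apart."""
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomicInterval] = []
    for length in lengths:
        ok = False
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = chrom_sizes[chrom] - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + length
            if all(start - pad >= e or end + pad <= s
                   for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all intervals without overlap; "
                "reduce n_genes/n_domains or enlarge the genome"
            )
    return out


def simulate_genome_and_genes(cfg: SimConfig) -> tuple[ChromSizes, list[GeneModel]]:
    """Non-overlapping genes placed uniformly; strands Bernoulli(1/2).

    Genes are kept at least 2*point_halfwidth apart so promoter-centred
    truth regions can never collide.
    """
    sizes = cfg.sizes()
    rng = _rng(cfg, 1)
    lengths = [max(cfg.gene_length_min,
                   int(round(rng.lognormal(cfg.gene_length_mu,
                                           cfg.gene_length_sigma))))
               for _ in range(cfg.n_genes)]
    if sum(lengths) >= sizes.total_length():
        raise ValueError("total gene length demand exceeds genome size")
    # inter-gene distance > 2*halfwidth keeps TSS-centred truth regions disjoint
    intervals = _place_nonoverlapping(rng, sizes, lengths,
                                      pad=2 * cfg.point_halfwidth + 1)
    genes = []
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i].chrom, intervals[i].start))
    for rank, i in enumerate(order):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(intervals[i], strand, f"gene_{rank + 1:04d}"))
    return sizes, genes


def simulate_truth(cfg: SimConfig, genes: list[GeneModel]) -> SyntheticTruth:
    """Plant enrichment regions with lognormal enrichment factors (e >= 1).

    point mode: TSS +/- point_halfwidth of a random gene subset
    (probability = gene_fraction_marked). broad mode: n_domains intervals
    with uniform lengths from domain_length_range, placed non-overlapping.
    """
    sizes = cfg.sizes()
    rng = _rng(cfg, 2)
    if cfg.mark_type == "point":
        if not genes and cfg.gene_fraction_marked > 0:
            raise ValueError("point mode requires genes")
        regions: list[GenomicInterval] = []
        for g in genes:
            if rng.random() < cfg.gene_fraction_marked:
                lo = max(0, g.tss - cfg.point_halfwidth)
                hi = min(sizes[g.chrom], g.tss + cfg.point_halfwidth)
                regions.append(GenomicInterval(g.chrom, lo, hi))
    else:
        lo, hi = cfg.domain_length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_domains)]
        try:
            regions = _place_nonoverlapping(rng, sizes, lengths, pad=1)
        except RuntimeError as exc:
            raise RuntimeError(f"broad domains could not be placed: {exc}") from exc
    e = np.maximum(rng.lognormal(cfg.enrichment_mu, cfg.enrichment_sigma,
                                 size=len(regions)), 1.0)
    return SyntheticTruth(cfg.mark_type, list(zip(regions, map(float, e))))


def simulate_fragments(truth: SyntheticTruth, cfg: SimConfig,
                       replicate_index: int = 1) -> ReadSet:
    """Sample fragments from background + enriched regions.

    Per replicate, each region's enrichment is jittered multiplicatively by
    lognormal(0, replicate_noise). A fragment picks its source with weight
    genome_length for background and length_i * (e'_i - 1) for region i, so
    e = 1 means exactly no enrichment; the midpoint is uniform in the source
    and the length is Normal(mean, sd) clipped below at fragment_length_min.
    """
    if cfg.n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    sizes = cfg.sizes()
    rng = _rng(cfg, 3, replicate_index)
    chroms = list(sizes)
    chrom_lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    chrom_offsets = np.concatenate([[0], np.cumsum(chrom_lengths)])
    genome_length = int(chrom_offsets[-1])

    e_prime = np.array(
        [e * rng.lognormal(0.0, cfg.replicate_noise) for _, e in truth.regions])
    region_len = np.array([len(iv) for iv, _ in truth.regions], dtype=np.float64)
    weights = np.concatenate([[float(genome_length)],
                              region_len * np.maximum(e_prime - 1.0, 0.0)])
    probs = weights / weights.sum()

    sources = rng.choice(len(weights), size=cfg.n_fragments, p=probs)
    u = rng.random(cfg.n_fragments)
    lengths = np.maximum(
        np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd,
                           size=cfg.n_fragments)),
        cfg.fragment_length_min,
    ).astype(np.int64)

    fragments: list[GenomicInterval] = []
    for src, frac, flen in zip(sources, u, lengths):
        if src == 0:
            pos = int(frac * genome_length)
            ci = int(np.searchsorted(chrom_offsets, pos, side="right") - 1)
            chrom = chroms[ci]
            mid = pos - int(chrom_offsets[ci])
        else:
            iv = truth.regions[src - 1][0]
            chrom = iv.chrom
            mid = iv.start + int(frac * len(iv))
        half = int(flen) // 2
        start = max(0, mid - half)
        end = min(int(sizes[chrom]), mid - half + int(flen))
        if end <= start:
            start, end = max(0, end - 1), max(1, end)
        fragments.append(GenomicInterval(chrom, start, end))
    return ReadSet(fragments)


def subsample_fragments(reads: ReadSet, fraction: float, seed: int) -> ReadSet:
    """Keep each fragment independently with probability ``fraction``."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep = rng.random(reads.total) < fraction
    return ReadSet([iv for iv, k in zip(reads.fragments, keep) if k])


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_peaks_poisson(reads: ReadSet, chrom_sizes: ChromSizes,
                       window: int = 200, q_cutoff: float | None = 0.05,
                       merge_gap: int | None = None,
                       p_floor: float = 0.1) -> list[Peak]:
    """Poisson-window surrogate peak caller.

    Fragment midpoints are counted per tiled window; each window gets an
    upper-tail Poisson p-value against the uniform background rate and a BH
    q-value computed over all windows. Windows passing the q cutoff (or,
    when the cutoff is None, every window nominally above background at
    p <= p_floor — the unrestricted mode used for score sweeps) are merged
    when within ``merge_gap`` (default: one window), and each peak carries
    the best member -log10 p/q, the max-count window center as summit, and
    the max fold enrichment as signal.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if reads.total < 1:
        raise ValueError("empty ReadSet")
    if merge_gap is None:
        merge_gap = window
    genome_length = chrom_sizes.total_length()

    chroms = list(chrom_sizes)
    counts: dict[str, np.ndarray] = {}
    for chrom in chroms:
        counts[chrom] = np.zeros(math.ceil(chrom_sizes[chrom] / window),
                                 dtype=np.int64)
    for iv in reads.fragments:
        mid = (iv.start + iv.end) // 2
        counts[iv.chrom][min(mid // window, len(counts[iv.chrom]) - 1)] += 1

    all_counts = np.concatenate([counts[c] for c in chroms])
    widths = np.concatenate([
        np.minimum(
            np.full(len(counts[c]), window, dtype=np.int64),
            chrom_sizes[c] - np.arange(len(counts[c]), dtype=np.int64) * window,
        )
        for c in chroms
    ])
    lam = reads.total * widths / genome_length
    logp = stats.poisson.logsf(all_counts - 1, lam)  # log P(X >= k)
    pvals = np.exp(logp)
    qvals = benjamini_hochberg(pvals)
    # logsf underflows to -inf for counts far above background; cap -log10
    cap = 10_000.0
    neglog_p = np.minimum(-logp / _LN10, cap)
    with np.errstate(divide="ignore"):
        neglog_q = np.minimum(-np.log10(qvals), cap)

    if q_cutoff is None:
        significant = (all_counts >= 1) & (pvals <= p_floor)
    else:
        significant = qvals <= q_cutoff

    # map flat window index back to (chrom, local index, interval)
    offsets = np.concatenate([[0], np.cumsum([len(counts[c]) for c in chroms])])
    peaks: list[Peak] = []
    sig_idx = np.nonzero(significant)[0]
    if len(sig_idx) == 0:
        return peaks

    def win_interval(flat: int) -> GenomicInterval:
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        chrom = chroms[ci]
        k = flat - int(offsets[ci])
        return GenomicInterval(chrom, k * window,
                               min((k + 1) * window, chrom_sizes[chrom]))

    cluster: list[int] = []

    def flush(cluster: list[int]) -> None:
        ivs = [win_interval(i) for i in cluster]
        start = ivs[0].start
        end = ivs[-1].end
        chrom = ivs[0].chrom
        member_counts = all_counts[cluster]
        best = cluster[int(np.argmax(member_counts))]
        best_iv = win_interval(best)
        summit = (best_iv.start + best_iv.end) // 2 - start
        fold = float(np.max(member_counts / np.maximum(lam[cluster], 1e-300)))
        peaks.append(Peak(
            GenomicInterval(chrom, start, end),
            name=f"peak_{len(peaks) + 1}",
            score=float(min(1000, round(10 * np.max(neglog_p[cluster])))),
            strand=".",
            signal=fold,
            p=float(np.max(neglog_p[cluster])),
            q=float(np.max(neglog_q[cluster])),
            summit=summit,
        ))

    prev_iv = None
    for flat in sig_idx:
        iv = win_interval(int(flat))
        if cluster and prev_iv is not None and iv.chrom == prev_iv.chrom \
                and iv.start - prev_iv.end <= merge_gap:
            cluster.append(int(flat))
        else:
            if cluster:
                flush(cluster)
            cluster = [int(flat)]
        prev_iv = iv
    if cluster:
        flush(cluster)
    peaks.sort(key=lambda pk: (pk.chrom, pk.start, pk.end))
    return peaks
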