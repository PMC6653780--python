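"""Window-mapped ROC / precision-recall evaluation of peak sets.

Peaks are mapped onto fixed non-overlapping genomic windows; a reference
window set defines the positives and a scored candidate set is swept over
significance thresholds. All unscored windows enter the curve in a single
final tie-completion segment, so an area is always computable — but it is
flagged invalid when the scored part of the sweep recalls less than a
configurable floor (default 75%) of the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ChromSizes, GenomicInterval, Peak

__all__ = [
    "WindowSet",
    "ScoredWindows",
    "EvaluationCurve",
    "tile_genome",
    "peaks_to_windows",
    "score_windows",
    "roc_prc",
    "auc_trapezoid",
    "DEFAULT_VALIDITY_FLOOR",
]

DEFAULT_VALIDITY_FLOOR = 0.75

WindowId = tuple[str, int]


@dataclass
class WindowSet:
    """Identity of fixed windows hit by at least one peak."""

    window_size: int
    chrom_sizes: ChromSizes
    ids: set[WindowId]

    def __len__(self) -> int:
        return len(self.ids)

    def _check_compatible(self, other: "WindowSet | ScoredWindows") -> None:
        if self.window_size != other.window_size:
            raise ValueError(
                f"window size mismatch: {self.window_size} vs {other.window_size}"
            )


@dataclass
class ScoredWindows:
    """Per-window best peak significance (-log10 p) for threshold sweeps."""

    window_size: int
    chrom_sizes: ChromSizes
    scores: dict[WindowId, float]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EvaluationCurve:
    thresholds: np.ndarray          # descending distinct scores (real sweep)
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    auc_roc: float
    auc_pr: float
    scored_recall_max: float
    auc_valid: bool
    n_pos: int
    n_neg: int
    validity_floor: float = DEFAULT_VALIDITY_FLOOR

    def roc_points(self) -> np.ndarray:
        """(fpr, tpr) pairs including the (0,0) origin and the (1,1) tie end."""
        x = np.concatenate([[0.0], self.fpr])
        y = np.concatenate([[0.0], self.tpr])
        return np.column_stack([x, y])


def tile_genome(chrom_sizes: ChromSizes, window_size: int) -> list[GenomicInterval]:
    """Consecutive windows [k*w, (k+1)*w) per chromosome, final one clipped."""
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        for k in range(math.ceil(length / window_size)):
            out.append(GenomicInterval(chrom, k * window_size,
                                       min((k + 1) * window_size, length)))
    return out


def n_windows(chrom_sizes: ChromSizes, window_size: int) -> int:
    return sum(math.ceil(length / window_size) for _, length in chrom_sizes.items())


def _overlapping_window_ids(peak: Peak, window_size: int,
                            chrom_sizes: ChromSizes) -> list[WindowId]:
    peak.interval.validate(chrom_sizes)
    first = peak.start // window_size
    last = (peak.end - 1) // window_size
    return [(peak.chrom, k) for k in range(first, last + 1)]


def peaks_to_windows(peaks: list[Peak], window_size: int, chrom_sizes: ChromSizes,
                     fdr_cutoff: float | None = None) -> WindowSet:
    """Windows touched (>=1 bp) by peaks, optionally filtered at an FDR cutoff.

    ``fdr_cutoff`` is a plain FDR (e.g. 0.05); peaks are retained when their
    -log10 q is at least -log10(cutoff).
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    retained = peaks
    if fdr_cutoff is not None:
        if peaks and all(pk.q == -1 for pk in peaks):
            raise ValueError("fdr_cutoff given but no peak carries a q value")
        min_q = -math.log10(fdr_cutoff)
        retained = [pk for pk in peaks if pk.q != -1 and pk.q >= min_q]
    ids: set[WindowId] = set()
    for pk in retained:
        ids.update(_overlapping_window_ids(pk, window_size, chrom_sizes))
    return WindowSet(window_size, chrom_sizes, ids)


def score_windows(peaks: list[Peak], window_size: int,
                  chrom_sizes: ChromSizes, use: str = "p") -> ScoredWindows:
    """Window score = max -log10 significance over overlapping peaks.

    ``use`` selects the p or q column (the sweep statistic).
    """
    if use not in ("p", "q"):
        raise ValueError(f"use must be 'p' or 'q', got {use!r}")
    scores: dict[WindowId, float] = {}
    for pk in peaks:
        s = pk.p if use == "p" else pk.q
        if s == -1:
            raise ValueError(f"peak {pk.name} at {pk.chrom}:{pk.start}-{pk.end} "
                             f"has no {use} value")
        for wid in _overlapping_window_ids(pk, window_size, chrom_sizes):
            if scores.get(wid, -math.inf) < s:
                scores[wid] = s
    return ScoredWindows(window_size, chrom_sizes, scores)


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoid area under (x, y) points ordered by non-decreasing x."""
    pts = np.asarray(points, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    dx = np.diff(x)
    if np.any(dx < 0):
        raise ValueError("x must be non-decreasing")
    return float(np.sum(dx * (y[1:] + y[:-1]) / 2.0))


def roc_prc(reference: WindowSet, scored: ScoredWindows,
            validity_floor: float = DEFAULT_VALIDITY_FLOOR) -> EvaluationCurve:
    """Threshold sweep of scored windows against a reference window set.

    The negatives universe is every tiled window not in the reference. Each
    distinct score is one threshold (ties enter together); all unscored
    windows then enter at once, producing the terminal (1, 1) point as one
    straight segment. auc_pr prepends (recall 0, strictest precision).
    """
    reference._check_compatible(scored)
    n_universe = n_windows(reference.chrom_sizes, reference.window_size)
    n_pos = len(reference.ids)
    n_neg = n_universe - n_pos
    if n_pos < 1:
        raise ValueError("empty reference window set")
    if n_neg < 1:
        raise ValueError("reference covers the whole universe; no negatives")

    for wid in scored.scores:
        chrom, k = wid
        if chrom not in reference.chrom_sizes or not (
            0 <= k * scored.window_size < reference.chrom_sizes[chrom]
        ):
            raise ValueError(f"scored window {wid} outside the genome")

    labels = np.fromiter((wid in reference.ids for wid in scored.scores),
                         dtype=bool, count=len(scored.scores))
    values = np.fromiter(scored.scores.values(), dtype=np.float64,
                         count=len(scored.scores))
    order = np.argsort(-values, kind="stable")
    values = values[order]
    labels = labels[order]

    # one curve point per distinct score
    if len(values):
        distinct_ends = np.nonzero(np.diff(values))[0]
        last_idx = np.concatenate([distinct_ends, [len(values) - 1]])
        tp_cum = np.cumsum(labels)
        fp_cum = np.cumsum(~labels)
        thresholds = values[last_idx]
        tp = tp_cum[last_idx].astype(np.int64)
        fp = fp_cum[last_idx].astype(np.int64)
    else:
        thresholds = np.empty(0)
        tp = np.empty(0, dtype=np.int64)
        fp = np.empty(0, dtype=np.int64)

    scored_recall_max = float(tp[-1] / n_pos) if len(tp) else 0.0

    # tie-completion: every remaining window predicted positive
    tp_full = np.concatenate([tp, [n_pos]])
    fp_full = np.concatenate([fp, [n_neg]])
    fn_full = n_pos - tp_full
    tn_full = n_neg - fp_full
    tpr = tp_full / n_pos
    fpr = fp_full / n_neg
    with np.errstate(invalid="ignore"):
        precision = np.where(tp_full + fp_full > 0,
                             tp_full / np.maximum(tp_full + fp_full, 1), 1.0)

    auc_roc = auc_trapezoid(np.column_stack([
        np.concatenate([[0.0], fpr]),
        np.concatenate([[0.0], tpr]),
    ]))
    # PRC: linear interpolation, strictest-threshold precision extended to 0
    auc_pr = auc_trapezoid(np.column_stack([
        np.concatenate([[0.0], tpr]),
        np.concatenate([[precision[0]], precision]),
    ]))

    return EvaluationCurve(
        thresholds=thresholds,
        tp=tp_full, fp=fp_full, fn=fn_full, tn=tn_full,
        tpr=tpr, fpr=fpr, precision=precision,
        auc_roc=auc_roc, auc_pr=auc_pr,
        scored_recall_max=scored_recall_max,
        auc_valid=scored_recall_max >= validity_floor,
        n_pos=n_pos, n_neg=n_neg,
        validity_floor=validity_floor,
    )


def write_curve_tsv(curve: EvaluationCurve, path) -> None:
    """Curve table with summary header lines (lines starting with '#')."""
    with open(path, "w") as fh:
        fh.write(f"# auc_roc\t{curve.auc_roc:.10g}\n")
        fh.write(f"# auc_pr\t{curve.auc_pr:.10g}\n")
        fh.write(f"# scored_recall_max\t{curve.scored_recall_max:.10g}\n")
        fh.write(f"# auc_valid\t{str(curve.auc_valid).lower()}\n")
        fh.write("threshold\ttp\tfp\tfn\ttn\ttpr\tfpr\tprecision\n")
        thr = [format(t, "g") for t in curve.thresholds] + ["tie-completion"]
        for i in range(len(curve.tp)):
            fh.write(
                f"{thr[i]}\t{curve.tp[i]}\t{curve.fp[i]}\t{curve.fn[i]}\t"
                f"{curve.tn[i]}\t{curve.tpr[i]:.10g}\t{curve.fpr[i]:.10g}\t"
                f"{curve.precision[i]:.10g}\n"
            )
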