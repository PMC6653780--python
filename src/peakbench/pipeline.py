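"""Configuration-driven benchmark orchestration.

Reads a YAML/JSON config naming labeled peak/coverage datasets with roles,
runs the full battery (window ROC/PRC, Jaccard clusterogram, maxgap
overlaps, FDR-quantile recovery, optional profiles) and writes one report
directory with a manifest of inputs, seed and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .core_io import read_chrom_sizes, read_peaks
from .peak_compare import fdr_quantile_recovery, find_overlaps, merge_replicates
from .set_similarity import (cluster, similarity_matrix, write_dendrogram_tsv,
                             write_similarity_tsv)
from .window_eval import peaks_to_windows, roc_prc, score_windows, write_curve_tsv

logger = logging.getLogger(__name__)

_ANALYSIS_DEFAULTS = {
    "window_size": 5000,
    "ref_fdr": 0.05,
    "maxgap": 100,
    "n_quantiles": 10,
    "bin_size": 2000,
    "flank": 1000,
    "body_bins": 100,
    "flank_bin": 20,
    "validity_floor": 0.75,
    "sweep_on": "p",
    "seed": 0,
}

_DATASET_KEYS = {"label", "peaks", "dialect", "fragments", "coverage", "role"}
_ROLES = {"candidate", "reference-replicate", "control"}


class ConfigError(ValueError):
    pass


@dataclass
class Dataset:
    label: str
    peaks: str
    dialect: str = "narrowPeak"
    fragments: str | None = None
    coverage: str | None = None
    role: str = "candidate"


@dataclass
class BenchmarkConfig:
    genome: str
    datasets: list[Dataset]
    analysis: dict = field(default_factory=dict)

    @property
    def candidates(self) -> list[Dataset]:
        return [d for d in self.datasets if d.role == "candidate"]

    @property
    def reference_replicates(self) -> list[Dataset]:
        return [d for d in self.datasets if d.role == "reference-replicate"]


def validate_config(path) -> BenchmarkConfig:
    """Load, default-fill and validate a benchmark config."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - {"genome", "datasets", "analysis"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "genome" not in raw:
        raise ConfigError("missing required key: genome")
    if "datasets" not in raw or not raw["datasets"]:
        raise ConfigError("missing or empty: datasets")

    analysis = dict(_ANALYSIS_DEFAULTS)
    for key, value in (raw.get("analysis") or {}).items():
        if key not in _ANALYSIS_DEFAULTS:
            raise ConfigError(f"unknown analysis key: {key!r}")
        analysis[key] = value
    for key, value in analysis.items():
        if key not in (raw.get("analysis") or {}):
            logger.info("analysis.%s defaulted to %r", key, value)

    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    datasets: list[Dataset] = []
    labels: set[str] = set()
    for i, entry in enumerate(raw["datasets"]):
        if not isinstance(entry, dict):
            raise ConfigError(f"dataset #{i + 1} must be a mapping")
        unknown = set(entry) - _DATASET_KEYS
        if unknown:
            raise ConfigError(f"dataset #{i + 1}: unknown key(s) {sorted(unknown)}")
        for req in ("label", "peaks"):
            if req not in entry:
                raise ConfigError(f"dataset #{i + 1}: missing {req!r}")
        if entry["label"] in labels:
            raise ConfigError(f"duplicate dataset label {entry['label']!r}")
        labels.add(entry["label"])
        ds = Dataset(
            label=entry["label"],
            peaks=resolve(entry["peaks"]),
            dialect=entry.get("dialect", "narrowPeak"),
            fragments=resolve(entry["fragments"]) if entry.get("fragments") else None,
            coverage=resolve(entry["coverage"]) if entry.get("coverage") else None,
            role=entry.get("role", "candidate"),
        )
        if ds.role not in _ROLES:
            raise ConfigError(f"dataset {ds.label!r}: unknown role {ds.role!r}")
        datasets.append(ds)

    cfg = BenchmarkConfig(genome=resolve(raw["genome"]), datasets=datasets,
                          analysis=analysis)
    if not cfg.reference_replicates:
        raise ConfigError("need at least one reference-replicate dataset")
    if not cfg.candidates:
        raise ConfigError("need at least one candidate dataset")
    for p in [cfg.genome] + [d.peaks for d in datasets]:
        if not os.path.exists(p):
            raise ConfigError(f"referenced path does not exist: {p}")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_benchmark(cfg: BenchmarkConfig, out_dir) -> None:
    """Execute every stage and write TSV reports + a manifest.

    The report directory is the only side effect; inputs are never mutated.
    Any stage error aborts with the stage name and dataset label.
    """
    os.makedirs(out_dir, exist_ok=True)
    a = cfg.analysis
    sizes = read_chrom_sizes(cfg.genome)

    peak_sets = {}
    for ds in cfg.datasets:
        try:
            peak_sets[ds.label] = read_peaks(ds.peaks, ds.dialect, sizes)
        except Exception as exc:
            raise RuntimeError(f"stage=load dataset={ds.label}: {exc}") from exc

    # reference = consensus of replicates at ref_fdr (single replicate: its
    # peaks at ref_fdr)
    refs = cfg.reference_replicates
    try:
        if len(refs) >= 2:
            ref_peaks = merge_replicates(peak_sets[refs[0].label],
                                         peak_sets[refs[1].label],
                                         fdr_cutoff=a["ref_fdr"],
                                         maxgap=a["maxgap"])
        else:
            from .peak_compare import _filter_fdr
            ref_peaks = _filter_fdr(peak_sets[refs[0].label], a["ref_fdr"])
    except Exception as exc:
        raise RuntimeError(f"stage=reference: {exc}") from exc
    ref_windows = peaks_to_windows(ref_peaks, a["window_size"], sizes)
    logger.info("reference: %d peaks -> %d windows at %d%% FDR",
                len(ref_peaks), len(ref_windows), round(100 * a["ref_fdr"]))

    # ROC / PRC per candidate (window-mapped score sweep)
    for ds in cfg.candidates:
        try:
            scored = score_windows(peak_sets[ds.label], a["window_size"], sizes,
                                   use=a["sweep_on"])
            curve = roc_prc(ref_windows, scored,
                            validity_floor=a["validity_floor"])
        except Exception as exc:
            raise RuntimeError(f"stage=roc dataset={ds.label}: {exc}") from exc
        write_curve_tsv(curve, os.path.join(out_dir, f"curve_{ds.label}.tsv"))
        logger.info("ROC vs replicated reference for %s: auc_roc=%.4f "
                    "auc_valid=%s", ds.label, curve.auc_roc, curve.auc_valid)

    # Jaccard clusterogram over every dataset at ref_fdr
    labels = [ds.label for ds in cfg.datasets]
    try:
        wsets = [peaks_to_windows(peak_sets[lab], a["window_size"], sizes,
                                  fdr_cutoff=a["ref_fdr"]) for lab in labels]
        S = similarity_matrix(wsets, labels)
        tree = cluster(S)
    except Exception as exc:
        raise RuntimeError(f"stage=cluster: {exc}") from exc
    write_similarity_tsv(S, os.path.join(out_dir, "jaccard_matrix.tsv"))
    write_dendrogram_tsv(tree, os.path.join(out_dir, "dendrogram.tsv"))

    # maxgap overlap + quantile recovery per candidate vs reference
    with open(os.path.join(out_dir, "overlaps.tsv"), "w") as ofh, \
            open(os.path.join(out_dir, "quantile_recovery.tsv"), "w") as qfh:
        ofh.write("candidate\tmaxgap\tnA\tnB\tnA_hit\tnB_hit\tcomponents_both\t"
                  "components_onlyA\tcomponents_onlyB\tpctA\tpctB\tpct_venn\n")
        qfh.write("candidate\tquantile\tcount\trecovered\tfraction\n")
        for ds in cfg.candidates:
            cand = peak_sets[ds.label]
            try:
                rep = find_overlaps(cand, ref_peaks, a["maxgap"])
                ofh.write(
                    f"{ds.label}\t{rep.maxgap}\t{rep.nA}\t{rep.nB}\t{rep.nA_hit}"
                    f"\t{rep.nB_hit}\t{rep.components_both}\t{rep.components_onlyA}"
                    f"\t{rep.components_onlyB}\t{rep.pctA:.10g}\t{rep.pctB:.10g}"
                    f"\t{rep.pct_venn:.10g}\n")
                if any(pk.q != -1 for pk in cand) and ref_peaks:
                    qr = fdr_quantile_recovery(
                        [pk for pk in cand if pk.q != -1], ref_peaks,
                        a["maxgap"], a["n_quantiles"])
                    for qi, (c, r, f) in enumerate(
                            zip(qr.counts, qr.recovered, qr.fractions), start=1):
                        qfh.write(f"{ds.label}\t{qi}\t{c}\t{r}\t{f:.10g}\n")
            except Exception as exc:
                raise RuntimeError(
                    f"stage=overlap dataset={ds.label}: {exc}") from exc

    manifest = {
        "peakbench_version": __version__,
        "seed": a["seed"],
        "analysis": a,
        "inputs": {
            "genome": {"path": cfg.genome, "sha256": _sha256(cfg.genome)},
            "datasets": [
                {"label": ds.label, "role": ds.role, "peaks": ds.peaks,
                 "sha256": _sha256(ds.peaks)}
                for ds in cfg.datasets
            ],
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("benchmark complete: %s", out_dir)
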