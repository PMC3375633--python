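"""End-to-end orchestration: maps -> pairs -> boosting -> reports.

``run_pipeline`` executes the whole analysis for one ontology namespace
and writes every artifact (descriptors, sample chunks, split ids, model,
metrics, cumulated weights, voxel significance, curve, manifest) as plain
TSV/JSON into a run directory.  Runs are deterministic: rerunning with the
same manifest reproduces the model byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

from pathlib import Path

import numpy as np

from . import boost, maps, ontology, pairs, report
from .layout import pair_layout_of
from .mask import enumerate_neighbor_pairs, load_mask

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run (one ontology namespace)."""

    matrix_path: str
    mask_path: str
    obo_path: str
    annotation_path: str
    mfep_path: str | None = None
    namespace: str = "biological_process"
    feature_set: str = "full"  # full | stats | base
    mode: str = "classify"  # classify | regress
    threshold: float = 0.3
    rho: float | None = None
    n_bins: int = 20
    n_rounds: int = 1000
    split_fraction: float = 0.5
    stats_domain: str = "voxels"
    wavelet_name: str = "haar"
    level: int = 3
    filter_lo: float = -1.0
    filter_hi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in ("base", "stats", "full"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.mode not in ("classify", "regress"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _feature_columns(layout, feature_set: str) -> np.ndarray:
    """Column indices of the requested feature subset.

    ``base`` keeps wavelet + voxel slots (110 under the reference layout),
    ``stats`` adds R/P/dE (113), ``full`` keeps all slots (455).
    """
    if feature_set == "full":
        return np.arange(layout.total)
    stop = layout.slice("stats").stop if feature_set == "stats" else layout.slice("voxels").stop
    return np.arange(stop)


def load_mfep_members(path) -> set[str]:
    """Read a gene -> profile membership TSV; returns the member gene ids."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            members.add(line.split("\t")[0])
    return members


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis and write artifacts; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mask = load_mask(config.mask_path)
    neighbor = enumerate_neighbor_pairs(mask)
    expr = maps.read_expression_matrix(config.matrix_path, mask)
    logger.info("stage load: %d genes, %d voxels", len(expr), mask.n_voxels)
    expr = maps.filter_noisy_genes(expr, config.filter_lo, config.filter_hi)
    logger.info("stage filter: %d genes kept", len(expr))

    graph, annot = ontology.build_graph(
        config.obo_path, config.annotation_path, config.namespace
    )
    keep = {m.gene_id for m in expr} & annot.keys()
    if config.mfep_path:
        keep &= load_mfep_members(config.mfep_path)
    genes = [(m, annot[m.gene_id]) for m in expr if m.gene_id in keep]
    logger.info("stage annotate: %d genes with %s annotations", len(genes), config.namespace)

    descriptors = [
        maps.map_descriptor(m, mask, neighbor, config.level, config.wavelet_name)
        for m, _ in genes
    ]
    maps.write_descriptors(descriptors, outdir / "descriptors.tsv", outdir / "layout.json")

    stream = pairs.build_dataset(
        genes,
        mask,
        graph,
        level=config.level,
        wavelet_name=config.wavelet_name,
        stats_domain=config.stats_domain,
        class_threshold=config.threshold,
    )
    layout = pair_layout_of(descriptors[0].layout)
    if config.rho is not None:
        stream = pairs.restrict_by_correlation(stream, layout, config.rho)
    X, y, ids = pairs.samples_to_arrays(stream)
    logger.info("stage pairs: %d samples, %d features", X.shape[0], X.shape[1])
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tlabel\n")
        for (a, b), label in zip(ids, y):
            fh.write(f"{a}\t{b}\t{label:.10g}\n")

    cols = _feature_columns(layout, config.feature_set)
    split = pairs.train_test_split(X.shape[0], config.split_fraction, config.seed)
    np.savetxt(outdir / "train_ids.txt", split.train, fmt="%d")
    np.savetxt(outdir / "test_ids.txt", split.test, fmt="%d")
    Xtr, Xte = X[split.train][:, cols], X[split.test][:, cols]
    ytr, yte = y[split.train], y[split.test]

    metrics: dict[str, float] = {"n_train": len(ytr), "n_test": len(yte)}
    if config.mode == "classify":
        ctr = np.array([ontology.binarize_label(v, config.threshold) for v in ytr])
        cte = np.array([ontology.binarize_label(v, config.threshold) for v in yte])
        clf = boost.adaboost_train(Xtr, ctr, config.n_bins, config.n_rounds)
        metrics["train_error"] = boost.classification_error(clf, Xtr, ctr)
        metrics["test_error"] = boost.classification_error(clf, Xte, cte)
        weights = boost.cumulated_feature_weights(clf)
        boost.save_model(clf, outdir / "model.json")
    else:
        reg = boost.regression_train(Xtr, ytr, config.n_bins, config.n_rounds, config.threshold)
        metrics["train_rmse"] = reg.train_rmse_
        metrics["test_rmse"] = boost.rmse(reg.predict(Xte), yte)
        weights = (
            boost.cumulated_feature_weights(reg.classifier_)
            if reg.constant_ is None
            else np.zeros(len(cols))
        )
        if reg.constant_ is None:
            boost.save_model(reg.classifier_, outdir / "model.json")

    full_weights = np.zeros(layout.total)
    full_weights[cols] = weights
    sig = report.voxel_significance(full_weights, layout, mask, neighbor)
    report.write_voxel_significance(sig, outdir / "voxel_significance.tsv")
    with open(outdir / "weights.tsv", "w") as fh:
        fh.write("feature_index\tweight\n")
        for i, w in enumerate(full_weights):
            fh.write(f"{i}\t{w:.10g}\n")

    r_index = layout.offset("stats")
    curve = pairs.binned_similarity_curve(X[:, r_index], y)
    report.write_curve(curve, outdir / "curve.tsv")

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)
        fh.write("\n")
    manifest = {"config": asdict(config), "n_genes": len(genes), "metrics": metrics}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
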