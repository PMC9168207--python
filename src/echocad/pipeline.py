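"""End-to-end experiment orchestration.

run_pipeline executes preprocess -> transform(s) -> LSDA -> rank ->
cross-validation for every (method, classifier) pair and writes a
classifiers x methods accuracy table, per-method accuracy-vs-k curves
(when incremental selection is enabled) and a JSON run manifest with all
seeds and the full configuration, so every reported number is recomputable
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import CvReport, cross_validate, incremental_selection, rank_features
from .config import PipelineConfig
from .lsda import LSDA
from .phantom import PhantomConfig, generate_dataset
from .preprocess import preprocess_frame
from .transforms import get_extractor

log = logging.getLogger("echocad")


def _load_inputs(cfg: PipelineConfig):
    """Return (list of RawFrame, labels) from the configured source."""
    if cfg.source == "synthetic":
        records = generate_dataset(
            PhantomConfig(seed=cfg.seed),
            n_normal=cfg.synthetic.n_normal,
            n_htn=cfg.synthetic.n_htn,
            seed=cfg.seed,
        )
        return [r.image for r in records], np.array([r.label for r in records])
    manifest = Path(cfg.input_dir) / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing {manifest}")
    table = pd.read_csv(manifest)
    frames = [
        io.load_frame(Path(cfg.input_dir) / row.filename, label=row.label)
        for row in table.itertuples()
    ]
    return frames, table["label"].to_numpy()


def preprocess_all(frames, cfg: PipelineConfig) -> np.ndarray:
    t0 = time.perf_counter()
    images = np.stack(
        [
            preprocess_frame(
                f, clip_limit=cfg.preprocess.clip_limit, tiles=cfg.preprocess.tiles
            ).pixels
            for f in frames
        ]
    )
    log.info("preprocessed %d frames in %.1fs", len(frames), time.perf_counter() - t0)
    return images


def featurize(images: np.ndarray, method: str) -> np.ndarray:
    t0 = time.perf_counter()
    X = get_extractor(method).transform(images)
    log.info("featurized %s -> %s in %.1fs", method, X.shape, time.perf_counter() - t0)
    return X


def evaluate_method(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig
) -> dict[str, CvReport]:
    """Cross-validate every configured classifier on one feature matrix."""
    lsda_kwargs = dict(
        n_components=cfg.lsda.n_components,
        n_neighbors=cfg.lsda.n_neighbors,
        alpha=cfg.lsda.alpha,
        ridge=cfg.lsda.ridge,
    )
    if cfg.mode == "leakage_free":
        X_eval, reducer = X, (lambda: LSDA(**lsda_kwargs))
    else:  # paper_mode: reduce once on the full dataset, then plain CV
        model = LSDA(**lsda_kwargs).fit(X, y)
        reduced = model.transform(X)
        ranking = rank_features(reduced, y)
        X_eval, reducer = reduced[:, ranking.order], None

    out = {}
    for clf in cfg.classifiers:
        out[clf] = cross_validate(
            X_eval, y, clf, n_folds=cfg.n_folds, seed=cfg.seed, reducer=reducer
        )
        log.info("%s: accuracy %.2f%%", clf, out[clf].accuracy)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, dict[str, CvReport]]:
    """Execute the full experiment; writes artifacts under cfg.output_dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, y = _load_inputs(cfg)
    images = preprocess_all(frames, cfg)

    results: dict[str, dict[str, CvReport]] = {}
    curves: dict[str, list[float]] = {}
    for method in cfg.methods:
        X = featurize(images, method)
        results[method] = evaluate_method(X, y, cfg)
        if cfg.max_features:
            model = LSDA(
                n_components=cfg.lsda.n_components,
                n_neighbors=cfg.lsda.n_neighbors,
                alpha=cfg.lsda.alpha,
                ridge=cfg.lsda.ridge,
            ).fit(X, y)
            reduced = model.transform(X)
            ranking = rank_features(reduced, y)
            _, reports = incremental_selection(
                reduced[:, ranking.order],
                y,
                "DT",
                max_features=cfg.max_features,
                n_folds=cfg.n_folds,
                seed=cfg.seed,
            )
            curves[method] = [r.accuracy for r in reports]

    table = pd.DataFrame(
        {m: {c: results[m][c].accuracy for c in cfg.classifiers} for m in cfg.methods}
    )
    table.index.name = "Classifier"
    table.to_csv(outdir / "accuracy_table.csv")
    if curves:
        pd.DataFrame(curves).rename_axis("k_minus_1").to_csv(
            outdir / "accuracy_vs_k.csv"
        )

    config_json = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_samples": int(len(y)),
        "results": {
            m: {c: vars(r).copy() for c, r in res.items()} for m, res in results.items()
        },
    }
    io.write_manifest(manifest, outdir / "run_manifest.json")
    return results
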