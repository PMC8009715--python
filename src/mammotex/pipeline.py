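"""End-to-end pipeline: features -> oversample -> select -> train -> evaluate.

Mirrors the four-stage methodology: per-image 88-feature extraction, ADASYN
balancing of the full feature table, ReliefF top-n feature selection, and a
Levenberg-Marquardt-trained feedforward network evaluated on the held-out
test split with the per-class and pooled confusion-matrix metric tables.

Note the evaluation protocol deliberately matches the methodology it
reimplements: oversampling happens *before* the stratified split, so
synthetic neighbors of training rows can land in the test split.  The
methods note discusses why this inflates scores relative to a
split-first protocol.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import adasyn as ad
from . import evaluation as ev
from . import network as nn
from . import relieff as rf
from .io import PipelineConfig, read_image, stage_seed, write_feature_table
from .synthetic import make_texture_dataset
from .textures import GrayImage, extract_features

logger = logging.getLogger("mammotex")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def extract_table(
    images: list[GrayImage] | list[np.ndarray],
    labels: np.ndarray,
    config: PipelineConfig,
    sources: list[str] | None = None,
) -> ad.LabeledDataset:
    """88-feature table for a list of images."""
    rows = []
    names = None
    for img in images:
        if not isinstance(img, GrayImage):
            img = GrayImage.from_array(img)
        fv = extract_features(img, config.features)
        rows.append(fv.values)
        names = fv.names
    logger.info("extracted %d feature rows of width %d", len(rows), len(names or ()))
    return ad.LabeledDataset(np.array(rows), np.asarray(labels), names)


def _load_images(config: PipelineConfig):
    if config.image_dir is None:
        manifest = make_texture_dataset(
            size=config.image_size, seed=stage_seed(config.seed, "fixtures")
        )
        images = [GrayImage.from_array(im) for im in manifest.images]
        return images, manifest.labels, manifest.paths
    mpath = Path(config.image_dir) / "manifest.csv"
    df = pd.read_csv(mpath)
    images = [read_image(p) for p in df["path"]]
    return images, df["label"].to_numpy(), df["path"].tolist()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report.

    The report carries per-stage row counts, the selected feature names,
    the per-class metric table and the pooled summary; identical config and
    seed give an identical report.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    try:
        images, labels, sources = _load_images(config)
    except Exception as exc:
        raise PipelineError("load", exc) from exc
    report["stages"]["load"] = {"n_images": len(images)}

    try:
        table = extract_table(images, labels, config)
    except Exception as exc:
        raise PipelineError("extract", exc) from exc
    report["stages"]["extract"] = {
        "n_rows": table.n_samples,
        "n_features": table.n_features,
    }
    if out is not None:
        write_feature_table(table, out / "features.csv", sources)

    if config.oversample_enabled:
        try:
            acfg = dataclasses.replace(
                config.adasyn, seed=stage_seed(config.seed, "adasyn")
            )
            balanced = ad.oversample(table, acfg)
        except Exception as exc:
            raise PipelineError("oversample", exc) from exc
    else:
        balanced = table
    report["stages"]["oversample"] = {
        "enabled": config.oversample_enabled,
        "n_rows": balanced.n_samples,
        "class_counts": {str(k): v for k, v in balanced.class_counts.items()},
    }
    if out is not None and config.oversample_enabled:
        write_feature_table(balanced, out / "balanced.csv")

    try:
        weights = rf.relieff_weights(balanced.X, balanced.y, config.relieff)
        top = rf.select_top(weights, config.relieff.n_select)
    except Exception as exc:
        raise PipelineError("select", exc) from exc
    names = balanced.feature_names or tuple(
        f"f{i}" for i in range(balanced.n_features)
    )
    selected_names = [names[i] for i in top]
    report["stages"]["select"] = {
        "n_selected": len(top),
        "selected": selected_names,
    }
    if out is not None:
        pd.DataFrame(
            {"feature": [names[i] for i in weights.ranking],
             "weight": weights.W[weights.ranking]}
        ).to_csv(out / "weights.csv", index=False)

    selected = ad.LabeledDataset(
        balanced.X[:, top], balanced.y, tuple(selected_names), balanced.synthetic
    )
    try:
        spec = nn.NetworkSpec(
            n_inputs=len(top),
            hidden=config.hidden,
            n_outputs=len(np.unique(selected.y)),
            seed=stage_seed(config.seed, "init"),
            layer1_linear=config.layer1_linear,
        )
        tcfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
        net = nn.train(nn.init(spec), selected, tcfg)
    except Exception as exc:
        raise PipelineError("train", exc) from exc
    report["stages"]["train"] = {
        "epochs": len(net.history),
        "final_sse": net.history[-1]["sse"] if net.history else None,
        "split_sizes": {k: int(len(v)) for k, v in net.split_indices.items()},
    }
    if out is not None:
        np.savez(
            out / "model.npz",
            **{f"W{l}": w for l, w in enumerate(net.weights)},
            **{f"b{l}": b for l, b in enumerate(net.biases)},
        )

    try:
        test_idx = net.split_indices["test"]
        y_pred = nn.predict(net, selected.X[test_idx])
        cm = ev.confusion(
            selected.y[test_idx], y_pred, labels=np.unique(selected.y)
        )
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc
    per_class = ev.per_class_report(cm)
    report["per_class"] = per_class.to_dict(orient="records")
    report["pooled"] = ev.pooled_report(cm)
    report["confusion"] = cm.counts.tolist()
    report["class_labels"] = [int(l) for l in cm.class_labels]
    if out is not None:
        per_class.to_csv(out / "per_class.csv", index=False)
        pd.DataFrame(
            cm.counts, index=cm.class_labels, columns=cm.class_labels
        ).to_csv(out / "confusion.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
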