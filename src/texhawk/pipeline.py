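"""End-to-end orchestration: preprocess -> extract -> fuse -> select -> train -> report.

The run configuration bundles every stage's settings under one global seed;
identical (config, dataset) runs are byte-for-byte reproducible.  Feature
standardization, feature selection and classifier training see only the
training split; the held-out split is touched once, for the final report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deep import FusionScaler, RandomConvBackend, extract_deep_features, fuse_features
from .evaluate import ClassificationReport, classification_metrics, confusion_counts
from .glcm import GLCMConfig, extract_texture_vector, quantize_image
from .hho import HHOParams
from .lstm import ClassifierConfig, LSTMClassifier, predict, train_classifier
from .preprocess import PreprocessConfig, preprocess_image, split_dataset
from .selection import EvaluatorConfig, FeatureMask, SelectionCostWeights, hho_select_features
from .table import FeatureTable

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "extract_fused_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All stage settings plus the global seed; serializable round-trip."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    backend_dim: int = 20
    glcm_levels: int = 32  # quantization applied before co-occurrence counting
    hho: HHOParams = field(default_factory=HHOParams)
    weights: SelectionCostWeights = field(default_factory=SelectionCostWeights)
    evaluator: EvaluatorConfig = field(default_factory=EvaluatorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, blob: dict) -> "RunConfig":
        def build(tp, value):
            if value is None:
                return tp()
            kw = dict(value)
            for k, v in list(kw.items()):
                if isinstance(v, list):
                    kw[k] = tuple(v)
            return tp(**kw)

        return cls(
            preprocess=build(PreprocessConfig, blob.get("preprocess")),
            glcm=build(GLCMConfig, blob.get("glcm")),
            backend_dim=blob.get("backend_dim", 20),
            glcm_levels=blob.get("glcm_levels", 32),
            hho=build(HHOParams, blob.get("hho")),
            weights=build(SelectionCostWeights, blob.get("weights")),
            evaluator=build(EvaluatorConfig, blob.get("evaluator")),
            classifier=build(ClassifierConfig, blob.get("classifier")),
            seed=blob.get("seed", 0),
        )

    def fingerprint(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: ClassificationReport
    mask: FeatureMask
    feature_names: list[str]
    model: LSTMClassifier
    history_rows: list[dict]
    manifest: dict

    def report_json(self) -> str:
        blob = {"report": self.report.to_dict(), "manifest": self.manifest}
        return json.dumps(blob, sort_keys=True, indent=2)


def extract_fused_table(dataset, config: RunConfig) -> FeatureTable:
    """Preprocess every image and build the fused deep+texture feature table."""
    backend = RandomConvBackend(output_dim=config.backend_dim, seed=config.seed)
    rows, labels, names = [], [], None
    for image, label in dataset:
        img = preprocess_image(np.asarray(image, dtype=np.float64), config.preprocess)
        deep_vec = extract_deep_features(img, backend)
        q = quantize_image(np.rint(img).astype(np.int64) - int(min(0, np.rint(img).min())), config.glcm_levels)
        glcm_cfg = dataclasses.replace(config.glcm, levels=config.glcm_levels)
        tex_vec, tex_names = extract_texture_vector(q, glcm_cfg)
        fused = fuse_features(deep_vec, tex_vec, texture_names=tex_names)
        if names is None:
            names = list(fused.names)
        rows.append(fused.values)
        labels.append(int(label))
    return FeatureTable(X=pd.DataFrame(np.asarray(rows), columns=names), y=np.asarray(labels))


def run_pipeline(dataset, config: RunConfig | None = None, output_dir: str | Path | None = None) -> PipelineResult:
    """Run the full hybrid pipeline on ``(image, label)`` pairs.

    Stages: preprocessing (smooth, resize), texture + deep feature extraction,
    fusion, stratified 70/30 split, training-split standardization, hawk-based
    wrapper feature selection on the training split, LSTM training on the
    selected columns, and held-out evaluation.  Artifacts (report, selected
    mask, convergence history, manifest) are written when ``output_dir`` is
    given.
    """
    config = config or RunConfig()

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        stage("features")
        table = extract_fused_table(dataset, config)
        stage("split")
        idx_pairs = list(zip(range(table.n_samples), table.y.tolist()))
        train_idx_pairs, test_idx_pairs = split_dataset(
            idx_pairs, config.preprocess.train_fraction, seed=config.seed, stratified=True
        )
        tr = np.asarray(sorted(i for i, _ in train_idx_pairs))
        te = np.asarray(sorted(i for i, _ in test_idx_pairs))

        stage("standardize")
        scaler = FusionScaler().fit(table.values()[tr])
        Xz = scaler.transform(table.values())
        ztable = FeatureTable(X=pd.DataFrame(Xz, columns=table.feature_names), y=table.y)
        train_table = FeatureTable(X=ztable.X.iloc[tr].reset_index(drop=True), y=ztable.y[tr])
        test_table = FeatureTable(X=ztable.X.iloc[te].reset_index(drop=True), y=ztable.y[te])

        stage("select")
        hho = dataclasses.replace(config.hho, seed=config.seed)
        evaluator = dataclasses.replace(config.evaluator, seed=config.seed)
        mask, history = hho_select_features(train_table, hho, config.weights, evaluator)

        stage("train")
        clf_cfg = dataclasses.replace(config.classifier, seed=config.seed)
        model = train_classifier(train_table.subset(mask.as_array()), clf_cfg)

        stage("evaluate")
        y_pred, _ = predict(model, test_table.subset(mask.as_array()).values())
        report = classification_metrics(confusion_counts(test_table.y, y_pred))
    except Exception as exc:  # tag the failing stage for the caller
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "n_samples": table.n_samples,
        "n_train": int(tr.size),
        "n_test": int(te.size),
        "n_features_total": table.n_features,
        "n_features_selected": mask.m,
        "selected_features": mask.selected_names(table.feature_names),
    }
    result = PipelineResult(
        report=report,
        mask=mask,
        feature_names=table.feature_names,
        model=model,
        history_rows=history.to_rows(),
        manifest=manifest,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(result.report_json())
        pd.DataFrame(
            {"feature": table.feature_names, "selected": list(mask.bits)}
        ).to_csv(out / "selected_mask.csv", index=False)
        pd.DataFrame(result.history_rows).to_csv(out / "hho_history.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
        result.model.save(out / "lstm_model.json")
    return result
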