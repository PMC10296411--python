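"""End-to-end pipeline: segment -> extract -> fuse -> select -> classify.

The feature extractors see the *segmented* image — the original gray values
inside the predicted tumor mask, zero elsewhere — so the descriptor carries
the tumor's location, shape and intensity.  HOG and residual-embedding
features are concatenated (deep first), scored by per-feature entropy over
the training batch, and the top ``select_n`` are kept; the same selected
index set is applied to every later sample.  A BiLSTM classifies the
selected vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .classify import BiLSTM, BiLSTMSpec, EvalReport, TrainConfig, evaluate, train
from .features import (
    FeatureSource,
    FeatureVector,
    HOGConfig,
    ResidualBackbone,
    ResidualBackboneSpec,
    hog_features,
)
from .fusion import FusedVector, FusionConfig, concat_features, entropy_scores, select_features
from .phantoms import PhantomSample
from .segmentation import SegmentationResult, segment

__all__ = ["PipelineConfig", "PipelineModel", "extract_fused", "build_feature_matrix", "fit_pipeline", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    n_seg_classes: int = 5  # one class per phantom intensity population
    hog: HOGConfig = field(default_factory=HOGConfig)
    backbone: ResidualBackboneSpec = field(default_factory=ResidualBackboneSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    hidden_units: int = 100
    seq_len: int = 100
    seed: int = 0


@dataclass
class PipelineModel:
    config: PipelineConfig
    selected_indices: np.ndarray
    classifier: BiLSTM

    def save(self, path: str) -> None:
        arrays = {f"param_{i}": p for i, p in enumerate(self.classifier.params())}
        arrays["selected_indices"] = self.selected_indices
        meta = {
            "spec": self.classifier.spec.__dict__,
            "n_seg_classes": self.config.n_seg_classes,
            "seed": self.config.seed,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "PipelineModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        spec = BiLSTMSpec(**meta["spec"])
        clf = BiLSTM(spec)
        for i, p in enumerate(clf.params()):
            p[...] = data[f"param_{i}"]
        config = PipelineConfig(n_seg_classes=meta["n_seg_classes"], seed=meta["seed"])
        return cls(config=config, selected_indices=data["selected_indices"], classifier=clf)


def extract_fused(
    image: np.ndarray,
    mask: np.ndarray,
    config: PipelineConfig,
    backbone: ResidualBackbone,
) -> FusedVector:
    """Fused (deep + HOG) features of the mask-segmented image."""
    segmented = np.asarray(image, dtype=float) * np.asarray(mask).astype(bool)
    f_hog = hog_features(segmented, config.hog)
    f_deep = FeatureVector(values=backbone.embed(segmented), source=FeatureSource.DEEP)
    return concat_features(f_deep, f_hog)


def build_feature_matrix(
    samples: list[PhantomSample],
    config: PipelineConfig,
    backbone: ResidualBackbone | None = None,
    seed_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[SegmentationResult]]:
    """Segment each phantom and stack fused feature vectors.

    Per-sample MFO seeds derive from the pipeline seed so the whole matrix
    is reproducible.  Returns (X, y, segmentation results).
    """
    if backbone is None:
        backbone = ResidualBackbone(config.backbone)
    rows, labels, segs = [], [], []
    for i, sample in enumerate(samples):
        seg = segment(
            sample.image,
            n_classes=config.n_seg_classes,
            seed=(config.seed * 100_003 + seed_offset + i) % (2**31),
        )
        fused = extract_fused(sample.image, seg.tumor_mask, config, backbone)
        rows.append(fused.values)
        labels.append(sample.label)
        segs.append(seg)
    return np.asarray(rows), np.asarray(labels, dtype=int), segs


def fit_pipeline(
    train_samples: list[PhantomSample], config: PipelineConfig | None = None
) -> tuple[PipelineModel, np.ndarray]:
    """Train the full pipeline on labeled phantoms.

    Returns the fitted model and the per-epoch loss trace.
    """
    if config is None:
        config = PipelineConfig()
    backbone = ResidualBackbone(config.backbone)
    X_full, y, _ = build_feature_matrix(train_samples, config, backbone)
    scores = entropy_scores(X_full, config.fusion)
    template = select_features(FusedVector(values=X_full[0]), scores, config.fusion)
    keep = template.selected_indices
    X = X_full[:, keep]
    spec = BiLSTMSpec(
        input_dim=X.shape[1],
        seq_len=config.seq_len,
        hidden_units=config.hidden_units,
        seed=config.seed,
    )
    clf = BiLSTM(spec)
    clf, trace = train(clf, X, y, config.train)
    return PipelineModel(config=config, selected_indices=keep, classifier=clf), trace


def _apply(model: PipelineModel, samples: list[PhantomSample], backbone, seed_offset=1_000_000):
    X_full, y, segs = build_feature_matrix(samples, model.config, backbone, seed_offset=seed_offset)
    return X_full[:, model.selected_indices], y, segs


def run_pipeline(
    train_samples: list[PhantomSample],
    test_samples: list[PhantomSample],
    config: PipelineConfig | None = None,
) -> tuple[PipelineModel, EvalReport]:
    """Fit on the training phantoms and evaluate on the held-out ones."""
    if config is None:
        config = PipelineConfig()
    model, _ = fit_pipeline(train_samples, config)
    backbone = ResidualBackbone(config.backbone)
    X_test, y_test, _ = _apply(model, test_samples, backbone)
    return model, evaluate(model.classifier, X_test, y_test)
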