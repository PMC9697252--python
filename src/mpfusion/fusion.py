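"""Hierarchical deep-fusion core: slice -> perspective -> volume (-> multi-feature).

The classifier is a stacked ensemble trained modularly, one level at a time:

1. three slice modules ``MS_1..MS_3`` (one small CNN per perspective) classify
   individual 56x56 slices;
2. the per-slice nodule scores of each perspective are re-arranged into an
   ``n_slices``-vector and a perspective module ``MP_i`` (one-hidden-layer
   feedforward net) predicts a per-perspective score;
3. the three perspective scores form a 3-vector and the volume module ``MV``
   produces the final decision for the volume of interest.

Each level is trained on the frozen outputs of the level below — no joint
backpropagation.  With a feature-image filter attached, the same scheme runs
on filtered slices (single-feature fusion); several such trained models can
be fused by one more level that stacks their volume scores (multi-feature
fusion).

The public surface follows the Model/Results convention: construct a model
from labelled VOIs, ``fit(seed)`` it, and use the returned results object for
prediction, evaluation and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .dcnn import DcnnConfig, build_dcnn, label_to_index
from .filters import FilterSpec, filter_stack
from .nn import Network, TrainConfig, build_mlp, train_network
from .voi import PERSPECTIVES, VolumeOfInterest, select_slices

PERSPECTIVE_ORDER = tuple(sorted(PERSPECTIVES))  # ("V1", "V2", "V3")


@dataclass
class FusionConfig:
    n_slices: int = 6
    dcnn: DcnnConfig = field(default_factory=DcnnConfig)
    fusion_hidden: int = 8
    fusion_training: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-2, batch_size=32, epochs=150, val_frac=0.15, patience=15))


# ---------------------------------------------------------------------------
# score re-arrangement


def assemble_perspective_features(scores) -> np.ndarray:
    """Slice-ordered vector of nodule-class scores for one VOI/perspective."""
    vec = np.asarray(getattr(scores, "scores", scores), float)
    if vec.ndim != 1 or len(vec) == 0 or not np.all(np.isfinite(vec)):
        raise ValueError("incomplete slice scores")
    return vec


def assemble_volume_features(p_scores) -> np.ndarray:
    """Fixed-order (V1, V2, V3) 3-vector of perspective scores."""
    vec = np.asarray(p_scores, float)
    if vec.shape != (3,):
        raise ValueError("exactly one score per perspective is required")
    return vec


def _child_seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(int(seed)).generate_state(n) % (2**31 - 1)]


def _train_fusion_mlp(features, y, hidden, training, seed):
    features = np.asarray(features, np.float32)
    if len(features) != len(y):
        raise ValueError("feature/label length mismatch")
    net = build_mlp(features.shape[1], hidden, 2, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]).generate_state(1)[0])
    log = train_network(net, features, np.asarray(y, np.int64), training, rng)
    return net, log


def train_perspective_module(features, labels, config: FusionConfig | None = None,
                             seed=0):
    """Train MP_i on slice-score vectors produced by a frozen MS_i."""
    cfg = config or FusionConfig()
    return _train_fusion_mlp(features, labels, cfg.fusion_hidden,
                             cfg.fusion_training, seed)


def train_volume_module(features, labels, config: FusionConfig | None = None,
                        seed=0):
    """Train MV on (V1, V2, V3) perspective-score vectors from frozen MPs."""
    cfg = config or FusionConfig()
    return _train_fusion_mlp(features, labels, cfg.fusion_hidden,
                             cfg.fusion_training, seed)


# ---------------------------------------------------------------------------
# model / results


class HierarchicalFusion:
    """Multi-perspective hierarchical fusion model over labelled VOIs.

    Parameters
    ----------
    train_vois : sequence of VolumeOfInterest
        The training objects; labels are taken from each VOI.
    feature_spec : FilterSpec, optional
        When given, every slice is replaced by its feature image before
        slice-level training (single-feature fusion).
    config : FusionConfig
    """

    def __init__(self, train_vois, feature_spec: FilterSpec | None = None,
                 config: FusionConfig | None = None):
        if len(train_vois) == 0:
            raise ValueError("empty training set")
        self.train_vois = list(train_vois)
        self.feature_spec = feature_spec
        self.config = config or FusionConfig()

    # slice tensors: dict perspective -> (N, n_slices, 56, 56)
    def _slice_tensors(self, vois):
        cfg = self.config
        out = {}
        for p in PERSPECTIVE_ORDER:
            stacks = []
            for voi in vois:
                stack = select_slices(voi, p, cfg.n_slices)
                if self.feature_spec is not None:
                    stack = filter_stack(stack, self.feature_spec)
                stacks.append(np.stack([np.asarray(s, np.float32)
                                        for s in stack.slices]))
            out[p] = np.stack(stacks)
        return out

    def fit(self, seed=0) -> "HierarchicalFusionResults":
        """Run the modular protocol: train MS_1..3, freeze, train MP_1..3,
        freeze, train MV.  Returns the fitted results object."""
        cfg = self.config
        y = np.array([label_to_index(v.label) for v in self.train_vois], np.int64)
        seeds = _child_seeds(seed, 7)
        tensors = self._slice_tensors(self.train_vois)

        slice_modules, slice_logs = {}, {}
        for i, p in enumerate(PERSPECTIVE_ORDER):
            X = tensors[p].reshape(-1, 1, cfg.dcnn.input_size, cfg.dcnn.input_size)
            y_slices = np.repeat(y, cfg.n_slices)
            net = build_dcnn(cfg.dcnn, seed=seeds[i])
            rng = np.random.default_rng(
                np.random.SeedSequence([seeds[i], 1]).generate_state(1)[0])
            try:
                slice_logs[p] = train_network(net, X, y_slices, cfg.dcnn.training, rng)
            except Exception as exc:  # pragma: no cover - stage attribution
                raise RuntimeError(f"slice-module training failed for {p}") from exc
            slice_modules[p] = net

        # frozen MS outputs -> perspective features
        perspective_modules, perspective_logs = {}, {}
        p_scores = {}
        for i, p in enumerate(PERSPECTIVE_ORDER):
            N = len(self.train_vois)
            probs = slice_modules[p].predict_proba(
                tensors[p].reshape(-1, 1, cfg.dcnn.input_size, cfg.dcnn.input_size))
            features = probs[:, 1].reshape(N, cfg.n_slices)
            try:
                mp, perspective_logs[p] = train_perspective_module(
                    features, y, cfg, seed=seeds[3 + i])
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(f"perspective-module training failed for {p}") from exc
            perspective_modules[p] = mp
            p_scores[p] = mp.predict_proba(features.astype(np.float32))[:, 1]

        volume_features = np.stack([p_scores[p] for p in PERSPECTIVE_ORDER], axis=1)
        try:
            volume_module, volume_log = train_volume_module(
                volume_features, y, cfg, seed=seeds[6])
        except Exception as exc:  # pragma: no cover
            raise RuntimeError("volume-module training failed") from exc

        return HierarchicalFusionResults(
            model=self, slice_modules=slice_modules,
            perspective_modules=perspective_modules, volume_module=volume_module,
            logs={"slice": slice_logs, "perspective": perspective_logs,
                  "volume": volume_log},
            seed=int(seed))


@dataclass
class HierarchicalFusionResults:
    """Fitted hierarchical fusion model: frozen modules plus diagnostics."""

    model: HierarchicalFusion
    slice_modules: dict
    perspective_modules: dict
    volume_module: Network
    logs: dict
    seed: int

    @property
    def feature_spec(self):
        return self.model.feature_spec

    @property
    def config(self):
        return self.model.config

    def params_digests(self) -> dict:
        """Per-module SHA-256 parameter digests (modular-isolation checks)."""
        d = {f"MS_{p}": self.slice_modules[p].params_digest()
             for p in PERSPECTIVE_ORDER}
        d.update({f"MP_{p}": self.perspective_modules[p].params_digest()
                  for p in PERSPECTIVE_ORDER})
        d["MV"] = self.volume_module.params_digest()
        return d

    def predict_levels(self, vois) -> dict:
        """All intermediate scores for a set of VOIs.

        Returns arrays ``slice_scores`` (N, 3, n_slices), ``perspective_scores``
        (N, 3), ``volume_scores`` (N,), predicted ``labels`` (N,), plus the
        true label indices when available.
        """
        vois = list(vois)
        cfg = self.config
        tensors = self.model._slice_tensors(vois)
        N = len(vois)
        slice_scores = np.zeros((N, 3, cfg.n_slices))
        p_scores = np.zeros((N, 3))
        for i, p in enumerate(PERSPECTIVE_ORDER):
            probs = self.slice_modules[p].predict_proba(
                tensors[p].reshape(-1, 1, cfg.dcnn.input_size, cfg.dcnn.input_size))
            feats = probs[:, 1].reshape(N, cfg.n_slices)
            slice_scores[:, i, :] = feats
            p_scores[:, i] = self.perspective_modules[p].predict_proba(
                feats.astype(np.float32))[:, 1]
        v_probs = self.volume_module.predict_proba(p_scores.astype(np.float32))
        return {
            "slice_scores": slice_scores,
            "perspective_scores": p_scores,
            "volume_scores": v_probs[:, 1],
            "labels": v_probs.argmax(axis=1),
            "true_labels": np.array([label_to_index(v.label) for v in vois]),
            "scan_ids": [v.consensus.source_scan for v in vois],
        }

    def predict(self, vois):
        return self.predict_levels(vois)["labels"]

    def evaluate(self, test_vois) -> "evaluation.EvaluationReport":
        return evaluation.level_report(self, test_vois)

    def summary(self, test_vois=None) -> str:
        lines = ["Hierarchical multi-perspective fusion", "=" * 44]
        lines.append(f"feature image : {self.feature_spec.family if self.feature_spec else 'raw slices'}")
        lines.append(f"training VOIs : {len(self.model.train_vois)}")
        lines.append(f"slices/persp. : {self.config.n_slices}")
        lines.append(f"seed          : {self.seed}")
        for p in PERSPECTIVE_ORDER:
            log = self.logs["slice"][p]
            lines.append(f"MS_{p}: {len(log)} epochs, final train loss "
                         f"{log['train_loss'].iloc[-1]:.4f}")
        if test_vois is not None:
            report = self.evaluate(test_vois)
            lines.append("")
            lines.append(report.table.to_string(index=False,
                                                float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def predict_hierarchy(results: HierarchicalFusionResults, voi: VolumeOfInterest):
    """Per-level scores for a single VOI (slice x3 stacks, perspective x3,
    volume score and final label)."""
    levels = results.predict_levels([voi])
    return {
        "slice_scores": {p: levels["slice_scores"][0, i]
                         for i, p in enumerate(PERSPECTIVE_ORDER)},
        "perspective_scores": {p: float(levels["perspective_scores"][0, i])
                               for i, p in enumerate(PERSPECTIVE_ORDER)},
        "volume_score": float(levels["volume_scores"][0]),
        "label": int(levels["labels"][0]),
    }


def train_mpf(train_vois, config: FusionConfig | None = None, seed=0,
              feature_spec: FilterSpec | None = None) -> HierarchicalFusionResults:
    """Convenience wrapper: build and fit a hierarchical fusion model (raw
    slices, or single-feature fusion when ``feature_spec`` is given)."""
    return HierarchicalFusion(train_vois, feature_spec=feature_spec,
                              config=config).fit(seed=seed)


# ---------------------------------------------------------------------------
# multi-feature fusion (top level over several fitted models)


class MultiFeatureFusion:
    """One more fusion level stacking the volume scores of several fitted
    hierarchical models (typically the four feature-image models plus the
    raw-slice model)."""

    def __init__(self, members, train_vois, config: FusionConfig | None = None):
        if len(members) < 2:
            raise ValueError("need at least two member models")
        ids = {tuple(id(v) for v in m.model.train_vois) for m in members}
        if len(ids) != 1:
            raise ValueError("member models were trained on mismatched splits")
        self.members = list(members)
        self.train_vois = list(train_vois)
        self.config = config or FusionConfig()

    def member_scores(self, vois) -> np.ndarray:
        return np.stack([m.predict_levels(vois)["volume_scores"]
                         for m in self.members], axis=1)

    def fit(self, seed=0) -> "MultiFeatureFusionResults":
        y = np.array([label_to_index(v.label) for v in self.train_vois], np.int64)
        features = self.member_scores(self.train_vois)
        top, log = _train_fusion_mlp(features, y, self.config.fusion_hidden,
                                     self.config.fusion_training,
                                     _child_seeds(seed, 1)[0])
        return MultiFeatureFusionResults(model=self, top_module=top, log=log,
                                         seed=int(seed))


@dataclass
class MultiFeatureFusionResults:
    model: MultiFeatureFusion
    top_module: Network
    log: pd.DataFrame
    seed: int

    def predict_scores(self, vois) -> np.ndarray:
        features = self.model.member_scores(vois).astype(np.float32)
        return self.top_module.predict_proba(features)[:, 1]

    def predict(self, vois) -> np.ndarray:
        return (self.predict_scores(vois) >= 0.5).astype(int)

    def evaluate(self, test_vois) -> pd.DataFrame:
        y = np.array([label_to_index(v.label) for v in test_vois])
        scores = self.predict_scores(test_vois)
        counts = evaluation.confusion_counts(y, (scores >= 0.5).astype(int))
        m = evaluation.metrics(counts)
        m["auc"] = evaluation.roc_auc(y, scores)[1]
        return pd.DataFrame([{"level": "mfmpf", "perspective": "all", **m}])


def train_mfmpf(members, train_vois, config: FusionConfig | None = None,
                seed=0) -> MultiFeatureFusionResults:
    return MultiFeatureFusion(members, train_vois, config=config).fit(seed=seed)
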