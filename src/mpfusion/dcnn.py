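"""Slice-level classifier MS: a small CNN over single 56x56 slices.

Architecture: four blocks of [3x3 same-padding convolution, ReLU, 2x2 max
pool] with 8 / 16 / 32 / 64 filters (doubling per block), a 32-unit fully
connected ReLU layer, and a 2-class softmax head trained with cross-entropy.
The spatial trace for a 56x56 input is 56 -> 28 -> 14 -> 7 -> 3.  One such
module is trained per perspective on that perspective's slices; every slice
inherits the label of its parent volume of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Conv2D, Dense, Flatten, MaxPool2, Network, ReLU, TrainConfig,
                 train_network)
from .phantoms import NODULE

LABEL_INDEX = {NODULE: 1}  # nodule is the positive class; everything else -> 0


def label_to_index(label) -> int:
    return LABEL_INDEX.get(label, 0)


@dataclass
class DcnnConfig:
    input_size: int = 56
    conv_filters: tuple[int, ...] = (8, 16, 32, 64)
    kernel_size: int = 3
    fc_units: int = 32
    n_classes: int = 2
    training: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, batch_size=32, epochs=10, val_frac=0.1, patience=3))

    def validate(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        for prev, cur in zip(self.conv_filters, self.conv_filters[1:]):
            if cur != 2 * prev:
                raise ValueError("conv_filters must double per layer")
        size = self.input_size
        for _ in self.conv_filters:
            size //= 2
        if size < 1:
            raise ValueError("input too small for the pooling cascade")
        return self


@dataclass
class SliceScores:
    """Per-slice class probabilities and the scalar nodule-class score."""

    probabilities: np.ndarray  # (n_slices, n_classes), rows sum to 1
    scores: np.ndarray         # (n_slices,) nodule-class probability


def build_dcnn(config: DcnnConfig | None = None, seed=0) -> Network:
    """Seeded untrained slice CNN per the configured architecture."""
    cfg = (config or DcnnConfig()).validate()
    rng = np.random.default_rng(seed)
    layers = []
    in_ch, size = 1, cfg.input_size
    for n_filters in cfg.conv_filters:
        layers += [Conv2D(in_ch, n_filters, rng, kernel=cfg.kernel_size),
                   ReLU(), MaxPool2()]
        in_ch, size = n_filters, size // 2
    layers += [Flatten(), Dense(in_ch * size * size, cfg.fc_units, rng), ReLU(),
               Dense(cfg.fc_units, cfg.n_classes, rng)]
    return Network(layers)


def stacks_to_arrays(labeled_stacks):
    """Flatten ``[(PerspectiveStack, label), ...]`` into (X, y) slice arrays;
    each slice inherits its VOI's label."""
    images, labels = [], []
    for stack, label in labeled_stacks:
        for s in stack.slices:
            images.append(np.asarray(s, np.float32))
            labels.append(label_to_index(label))
    X = np.stack(images)[:, None, :, :]
    return X, np.asarray(labels, np.int64)


def train_slice_module(labeled_stacks, config: DcnnConfig | None = None, seed=0):
    """Train one slice module MS on the stacks of a single perspective.

    Returns ``(model, log)`` where ``log`` is the per-epoch training record.
    """
    cfg = (config or DcnnConfig()).validate()
    X, y = (labeled_stacks if isinstance(labeled_stacks, tuple)
            else stacks_to_arrays(labeled_stacks))
    if len(X) == 0:
        raise ValueError("empty training set")
    net = build_dcnn(cfg, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]).generate_state(1)[0])
    log = train_network(net, X, y, cfg.training, rng)
    return net, log


def predict_slice_scores(model: Network, stack) -> SliceScores:
    """Class probabilities for every slice of one perspective stack."""
    X = np.stack([np.asarray(s, np.float32) for s in stack.slices])[:, None]
    probs = model.predict_proba(X)
    return SliceScores(probabilities=probs, scores=probs[:, 1])
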