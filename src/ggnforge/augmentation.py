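"""Data-augmentation experiment: does adding GAN-synthesised GGNs help?

A small residual-network classifier learns to recognise ground-glass
nodules (GGNs) against solid nodules.  The dataset is split once into ten
ordered, stratified training subsets plus an independent held-out test set.
For each requested fraction f of the real training data, two arms run on
identical subsets: the real-only arm trains the classifier on the first
f% of subsets; the synthetic arm first trains the inpainting GAN on the
same subsets' GGN slices, generates one synthetic GGN per real GGN (from
the real backgrounds with the nodule region blanked), adds them to the
training set, and trains the same classifier.  Both arms are scored on the
held-out test set with per-class precision and recall.

The classifier consumes the fixed-size nodule patch (the same ROI crop the
GAN's region discriminator judges), which keeps the experiment tractable
on one CPU while preserving the class signal -- subsolid versus solid
texture lives inside the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gan import GANConfig, crop_roi
from .preprocess import blank_roi, roi_box_for
from .training import TrainState, generate_synthetic, train_gan
from .types import CTSlice, NoduleAnnotation

__all__ = [
    "ClassifierCase", "ClassifierConfig", "AugmentationRun",
    "split_subsets", "train_classifier", "evaluate_classifier",
    "augmentation_experiment", "SplitError",
]


class SplitError(ValueError):
    """A subset or the test set ended up without both classes."""


@dataclass
class ClassifierCase:
    """One labelled slice: normalized image + its nodule annotation."""

    image: CTSlice
    annotation: NoduleAnnotation
    case_id: str

    @property
    def is_ggn(self) -> bool:
        return self.annotation.is_ggn


@dataclass
class ClassifierConfig:
    patch_size: int = 16
    base_channels: int = 8
    n_blocks: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 16
    steps: int = 150
    seed: int = 0


@dataclass
class AugmentationRun:
    fraction: int
    arm: str                      # "real-only" | "real-plus-synthetic"
    precision: dict[str, float]   # per class: "ggn", "solid"
    recall: dict[str, float]
    n_train_real: int
    n_train_synth: int
    seed: int

    def __post_init__(self) -> None:
        if self.arm == "real-only" and self.n_train_synth != 0:
            raise ValueError("real-only arm cannot contain synthetic cases")
        for d in (self.precision, self.recall):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("precision/recall must lie in [0, 1]")


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_subsets(
    dataset: list[ClassifierCase],
    n_subsets: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[list[ClassifierCase]], list[ClassifierCase]]:
    """Stratified, disjoint, seed-reproducible subsets + held-out test set.

    Cases are dealt class-by-class round-robin so every subset's GGN share
    is within one case of the global share; cumulative unions of the
    ordered subsets give nested training fractions.
    """
    rng = np.random.default_rng(seed)
    pos = [c for c in dataset if c.is_ggn]
    neg = [c for c in dataset if not c.is_ggn]
    for group in (pos, neg):
        rng.shuffle(group)  # type: ignore[arg-type]
    n_test_pos = int(round(len(pos) * test_fraction))
    n_test_neg = int(round(len(neg) * test_fraction))
    test = pos[:n_test_pos] + neg[:n_test_neg]
    train_pos, train_neg = pos[n_test_pos:], neg[n_test_neg:]

    subsets: list[list[ClassifierCase]] = [[] for _ in range(n_subsets)]
    for i, case in enumerate(train_pos):
        subsets[i % n_subsets].append(case)
    for i, case in enumerate(train_neg):
        # reverse deal keeps subset sizes within one case of each other
        subsets[n_subsets - 1 - (i % n_subsets)].append(case)

    if not test or any(not s for s in subsets):
        raise SplitError("dataset too small for the requested split")
    if len({c.is_ggn for c in test}) < 2:
        raise SplitError("test set lacks one class")
    return subsets, test


# --------------------------------------------------------------------------
# Classifier
# --------------------------------------------------------------------------

class _ClfBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.act = nn.LeakyReLU(0.2)
        self.conv2 = nn.Conv2d(channels, channels, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.act(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return self.act(x + y)


class PatchClassifier(nn.Module):
    """Basic residual network with a two-logit head and cross-entropy loss."""

    def __init__(self, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.config = config
        self.head = nn.Conv2d(1, c, rng=rng)
        self.act = nn.LeakyReLU(0.2)
        self.blocks = [_ClfBlock(c, rng) for _ in range(config.n_blocks)]
        self.down = nn.Conv2d(c, 2 * c, stride=2, rng=rng)
        self.down_bn = nn.BatchNorm2d(2 * c)
        self.fc = nn.Dense(2 * c, 2, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.act(self.head(x))
        for block in self.blocks:
            y = block(y)
        y = self.act(self.down_bn(self.down(y)))
        return self.fc(y.mean(axis=(2, 3)))  # logits (N, 2)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        self.eval()
        try:
            logits = self(nn.Tensor(patches.astype(np.float32)[:, None])).data
        finally:
            self.train()
        return logits.argmax(axis=1)


def _softmax_ce(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    shift = nn.Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    log_norm = (z.exp().sum(axis=1, keepdims=True)).log()
    log_probs = z - log_norm
    picked = log_probs[np.arange(len(labels)), labels]
    return -(picked.mean())


def _patch(case: ClassifierCase, patch_size: int) -> np.ndarray:
    box = roi_box_for(case.annotation.centroid, patch_size, case.image.shape)
    return crop_roi(case.image.pixels, box)


def train_classifier(
    train_set: list[ClassifierCase],
    config: ClassifierConfig | None = None,
) -> PatchClassifier:
    """Fit the residual patch classifier (label 1 = GGN, 0 = solid)."""
    if config is None:
        config = ClassifierConfig()
    labels = np.array([1 if c.is_ggn else 0 for c in train_set])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    patches = np.stack([_patch(c, config.patch_size) for c in train_set])

    rng = np.random.default_rng(config.seed)
    clf = PatchClassifier(config)
    opt = nn.Adam(clf.parameters(), lr=config.learning_rate)
    n = len(train_set)
    for _step in range(config.steps):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        x = nn.Tensor(patches[idx].astype(np.float32)[:, None])
        loss = _softmax_ce(clf(x), labels[idx])
        clf.zero_grad()
        loss.backward()
        opt.step()
        opt.zero_grad()
    return clf


def evaluate_classifier(
    clf: PatchClassifier, test_set: list[ClassifierCase]
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-class precision and recall on the held-out test set."""
    if not test_set:
        raise ValueError("empty test set")
    patches = np.stack([_patch(c, clf.config.patch_size) for c in test_set])
    y_true = np.array([1 if c.is_ggn else 0 for c in test_set])
    y_pred = clf.predict(patches)
    precision, recall = {}, {}
    for cls, name in [(1, "ggn"), (0, "solid")]:
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        precision[name] = tp / (tp + fp) if tp + fp else 0.0
        recall[name] = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


# --------------------------------------------------------------------------
# The sweep
# --------------------------------------------------------------------------

def _synthesise_ggns(
    ggn_cases: list[ClassifierCase],
    gan_config: GANConfig,
) -> tuple[TrainState, list[ClassifierCase]]:
    """Train the GAN on the given GGN slices and synthesise one replacement
    nodule per case from its blanked background."""
    pairs = [blank_roi(c.image, c.annotation, gan_config.roi_size)
             for c in ggn_cases]
    state = train_gan(pairs, gan_config)
    synth = []
    for case, pair in zip(ggn_cases, pairs):
        out = generate_synthetic(state, pair.input_image, pair.roi_box)
        synth.append(ClassifierCase(
            image=out,
            annotation=case.annotation,
            case_id=case.case_id + "-synth",
        ))
    return state, synth


def augmentation_experiment(
    real_dataset: list[ClassifierCase],
    fractions: list[int],
    gan_config: GANConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    seed: int = 0,
    n_subsets: int = 10,
    test_fraction: float = 0.2,
) -> list[AugmentationRun]:
    """Run both arms at every requested fraction of the real training data."""
    if classifier_config is None:
        classifier_config = ClassifierConfig(seed=seed)
    subsets, test = split_subsets(real_dataset, n_subsets=n_subsets,
                                  test_fraction=test_fraction, seed=seed)
    runs: list[AugmentationRun] = []
    for fraction in fractions:
        n_use = max(1, int(round(fraction / 100 * n_subsets)))
        train_cases = [c for s in subsets[:n_use] for c in s]
        try:
            # ---- arm A: real only ---------------------------------------
            clf = train_classifier(train_cases, classifier_config)
            prec, rec = evaluate_classifier(clf, test)
            runs.append(AugmentationRun(
                fraction=fraction, arm="real-only", precision=prec, recall=rec,
                n_train_real=len(train_cases), n_train_synth=0, seed=seed,
            ))
            # ---- arm B: real + synthetic GGNs ---------------------------
            ggn_cases = [c for c in train_cases if c.is_ggn]
            if gan_config is not None and ggn_cases:
                size = train_cases[0].image.shape[0]
                _state, synth = _synthesise_ggns(ggn_cases, gan_config)
            else:
                synth = []
            clf_b = train_classifier(train_cases + synth, classifier_config)
            prec_b, rec_b = evaluate_classifier(clf_b, test)
            runs.append(AugmentationRun(
                fraction=fraction, arm="real-plus-synthetic",
                precision=prec_b, recall=rec_b,
                n_train_real=len(train_cases), n_train_synth=len(synth),
                seed=seed,
            ))
        except (ValueError, RuntimeError) as err:
            raise type(err)(f"fraction {fraction}: {err}") from err
    return runs


def runs_to_rows(runs: list[AugmentationRun]) -> list[dict]:
    """Flatten runs for a results CSV:
    (fraction, arm, class, precision, recall, n_train_real, n_train_synth, seed)."""
    rows = []
    for run in runs:
        for cls in ("ggn", "solid"):
            rows.append({
                "fraction": run.fraction, "arm": run.arm, "class": cls,
                "precision": run.precision[cls], "recall": run.recall[cls],
                "n_train_real": run.n_train_real,
                "n_train_synth": run.n_train_synth, "seed": run.seed,
            })
    return rows
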