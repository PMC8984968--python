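"""Feature fusion, segmentation, velocity labels and dataset splits.

The spectral sequence (rows = n - 39) and the temporal sequence (rows =
n - l + 1 = n - 29 at defaults) are right-aligned by dropping the temporal
sequence's leading surplus rows (the first 10 redundant time steps at
defaults) and concatenated column-wise, spectral first, giving the fused
feature matrix of shape ``(n - 39, 2m)``.  Segmenting it into consecutive
non-overlapping blocks of T = 30 rows yields the decoder's samples; each
sample's velocity label is the mean ground-truth velocity over the raw
samples its block covers, zeroed on the non-class axis (up/down trials have
zero horizontal label, left/right trials zero vertical label).

Splits are made at trial granularity (no trial's segments straddle TRAIN
and TEST) and class-balanced; TESTUD/TESTLR are the class-filtered views of
TEST used to measure suppression of the non-imaginary velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spectral import SpectralSpec, spectral_feature_sequence
from .temporal import WaveletSpec, temporal_feature_sequence
from .trial import CLASS_AXIS_SIGN, CLASSES, EEGTrial, EegCursorError, FeatureSequence

__all__ = [
    "FusedDataset",
    "Standardizer",
    "align_and_concat",
    "segment",
    "make_labels",
    "build_dataset",
    "split_dataset",
]


def align_and_concat(xs: FeatureSequence, xt: FeatureSequence) -> FeatureSequence:
    """Right-align the temporal sequence to the spectral one and concatenate.

    The temporal extractor's shorter window makes its sequence start earlier;
    its leading ``rows(xt) - rows(xs)`` rows describe raw samples the
    spectral windows never complete on, so they are dropped.  Columns come
    out spectral-first.
    """
    surplus = xt.n_steps - xs.n_steps
    if surplus < 0:
        raise EegCursorError(
            f"temporal sequence ({xt.n_steps} rows) shorter than spectral "
            f"({xs.n_steps} rows); cannot right-align")
    fused = np.hstack([xs.values, xt.values[surplus:]])
    return FeatureSequence(values=fused, start_offset=xs.start_offset,
                           step_samples=xs.step_samples, kind="fused")


def segment(fused: FeatureSequence, seq_len: int = 30) -> list[np.ndarray]:
    """Cut the fused sequence into consecutive blocks of ``seq_len`` rows.

    Blocks are non-overlapping and taken from the start; trailing remainder
    rows are discarded.  Fewer rows than ``seq_len`` yields an empty list
    with a warning.
    """
    rows = fused.n_steps
    if rows < seq_len:
        warnings.warn(f"only {rows} feature rows; no full {seq_len}-row segment",
                      RuntimeWarning)
        return []
    n_blocks = rows // seq_len
    return [fused.values[b * seq_len:(b + 1) * seq_len] for b in range(n_blocks)]


def make_labels(trial: EEGTrial, blocks: Sequence[np.ndarray],
                start_offset: int = 39, seq_len: int | None = None) -> np.ndarray:
    """Velocity labels, one ``(horizontal, vertical)`` pair per block.

    Each block's label is the mean ground-truth velocity over the raw-sample
    span its feature rows summarize, then zeroed on the non-class axis.
    """
    if trial.true_velocity is None:
        raise EegCursorError("trial carries no ground-truth velocity")
    labels = np.zeros((len(blocks), 2))
    axis, _ = CLASS_AXIS_SIGN[trial.class_label]
    for b, block in enumerate(blocks):
        t = seq_len if seq_len is not None else len(block)
        first_row = b * t
        last_row = first_row + t - 1
        span = trial.true_velocity[first_row:last_row + start_offset + 1]
        labels[b] = span.mean(axis=0)
    labels[:, 1 - axis] = 0.0
    return labels


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on the training split.

    Band powers and wavelet outputs differ by orders of magnitude; the
    decoder sees z-scored features.  Zero-variance features pass through
    unscaled.
    """

    mean: Optional[np.ndarray] = None
    std: Optional[np.ndarray] = None

    def fit(self, features: np.ndarray) -> "Standardizer":
        flat = features.reshape(-1, features.shape[-1])
        self.mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise EegCursorError("standardizer has not been fitted")
        return (features - self.mean) / self.std


@dataclass
class FusedDataset:
    """Segmented samples and labels: the decoder's dataset D = {(x_i, y_i)}.

    ``features`` has shape ``(N, T, E)`` with E = 2m (spectral columns then
    temporal columns); ``labels`` is ``(N, 2)``.
    """

    features: np.ndarray
    labels: np.ndarray
    class_labels: np.ndarray
    trial_ids: np.ndarray
    segment_index: np.ndarray
    split_tag: str = "none"

    def __post_init__(self) -> None:
        if len({len(self.features), len(self.labels), len(self.class_labels),
                len(self.trial_ids), len(self.segment_index)}) != 1:
            raise EegCursorError("dataset arrays must have equal first dimension")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def seq_len(self) -> int:
        return self.features.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    def view(self, classes: Sequence[str], split_tag: str) -> "FusedDataset":
        mask = np.isin(self.class_labels, list(classes))
        return FusedDataset(self.features[mask], self.labels[mask],
                            self.class_labels[mask], self.trial_ids[mask],
                            self.segment_index[mask], split_tag)

    def subset_by_trials(self, trial_ids: Sequence[str], split_tag: str) -> "FusedDataset":
        mask = np.isin(self.trial_ids, list(trial_ids))
        return FusedDataset(self.features[mask], self.labels[mask],
                            self.class_labels[mask], self.trial_ids[mask],
                            self.segment_index[mask], split_tag)


def build_dataset(trials: Sequence[EEGTrial],
                  spectral_spec: SpectralSpec = SpectralSpec(),
                  wavelet_spec: WaveletSpec = WaveletSpec(),
                  seq_len: int = 30) -> FusedDataset:
    """Run feature extraction, fusion, segmentation and labelling on trials."""
    feats, labels, classes, ids, seg_idx = [], [], [], [], []
    for trial in trials:
        xs = spectral_feature_sequence(trial, spectral_spec)
        xt = temporal_feature_sequence(trial, wavelet_spec)
        fused = align_and_concat(xs, xt)
        blocks = segment(fused, seq_len)
        if not blocks:
            continue
        y = make_labels(trial, blocks, start_offset=fused.start_offset,
                        seq_len=seq_len)
        for b, block in enumerate(blocks):
            feats.append(block)
            labels.append(y[b])
            classes.append(trial.class_label)
            ids.append(trial.trial_id)
            seg_idx.append(b)
    if not feats:
        raise EegCursorError("no trial produced a full segment")
    return FusedDataset(np.asarray(feats), np.asarray(labels),
                        np.asarray(classes), np.asarray(ids),
                        np.asarray(seg_idx))


def split_dataset(dataset: FusedDataset, ratio: float = 0.7, seed: int = 0,
                  ) -> tuple[FusedDataset, FusedDataset, FusedDataset, FusedDataset]:
    """Class-balanced trial-level split into (TRAIN, TEST, TESTUD, TESTLR).

    Within each class the trials are shuffled deterministically by ``seed``
    and ``round(ratio * n_class)`` of them go to TRAIN; TESTUD/TESTLR are
    the up/down and left/right views of TEST.
    """
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in CLASSES:
        mask = dataset.class_labels == cls
        ids = np.unique(dataset.trial_ids[mask])
        if len(ids) == 0:
            raise EegCursorError(f"class {cls!r} has no trials; cannot split")
        perm = rng.permutation(len(ids))
        n_train = int(round(ratio * len(ids)))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    train = dataset.subset_by_trials(train_ids, "TRAIN")
    test = dataset.subset_by_trials(test_ids, "TEST")
    testud = test.view(["U", "D"], "TESTUD")
    testlr = test.view(["L", "R"], "TESTLR")
    return train, test, testud, testlr
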