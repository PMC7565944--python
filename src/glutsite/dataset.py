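"""Labeled dataset assembly: redundancy reduction, splitting, oversampling.

The benchmark workflow is fixed: annotate proteins, cut lysine windows,
reduce redundancy among *negative* windows (positives are never discarded —
they are the scarce class), split into train and independent test sets, and
only then balance the training partition by scalar-multiplication
oversampling of the positive rows.  Augmented rows therefore never reach a
test partition.

Redundancy reduction is a greedy single-linkage identity filter standing in
for CD-HIT clustering at a 40% identity cutoff: windows are visited in input
order and a window is dropped when its ungapped identity with any already
retained window exceeds the threshold.

Oversampling multiplies each positive feature vector element-wise by each
scalar in turn (defaults 1.0001 and 1.0005), appending near-copies that sit
within 0.05% of the originals.  With two scalars the positive count triples
(e.g. 723 originals become 2169 rows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from glutsite.features import FEATURE_NAMES
from glutsite.windows import PeptideWindow

logger = logging.getLogger(__name__)

#: The default oversampling scalars.
DEFAULT_SCALARS = (1.0001, 1.0005)

#: The default negative-set identity cutoff.
DEFAULT_IDENTITY_THRESHOLD = 0.40


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with binary labels and per-row provenance."""

    features: np.ndarray  # n x d
    labels: np.ndarray  # n, {0, 1}; 1 = glutarylated
    provenance: tuple[str, ...]  # n sample identifiers ("protein|center")
    augmented: np.ndarray = field(default=None)  # n booleans

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        augmented = (
            np.zeros(len(labels), dtype=bool)
            if self.augmented is None
            else np.asarray(self.augmented, dtype=bool)
        )
        if features.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {features.shape}")
        n = features.shape[0]
        if not (len(labels) == len(self.provenance) == len(augmented) == n):
            raise ValueError(
                f"inconsistent row counts: {n} feature rows, {len(labels)} labels, "
                f"{len(self.provenance)} provenance ids, {len(augmented)} flags"
            )
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        object.__setattr__(self, "augmented", augmented)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self) - self.labels.sum())

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            provenance=tuple(self.provenance[i] for i in idx),
            augmented=self.augmented[idx],
        )


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped identity: matching positions / window length (X-X matches)."""
    if len(a) != len(b):
        raise ValueError(f"window lengths differ: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reduce_redundancy(
    windows: Sequence[PeptideWindow],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[PeptideWindow]:
    """Greedy identity filter over negative windows; positives pass through.

    Visits windows in input order and drops a negative window whose identity
    with any retained negative exceeds ``identity_threshold``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    retained: list[PeptideWindow] = []
    kept_negatives: list[str] = []
    n_dropped = 0
    for w in windows:
        if w.label == 1:
            retained.append(w)
            continue
        if any(pairwise_identity(w.sequence, seq) > identity_threshold
               for seq in kept_negatives):
            n_dropped += 1
            continue
        retained.append(w)
        kept_negatives.append(w.sequence)
    if n_dropped:
        logger.info(
            "redundancy filter dropped %d of %d negative windows at %.0f%% identity",
            n_dropped, n_dropped + len(kept_negatives), 100 * identity_threshold,
        )
    return retained


def oversample_positives(
    data: LabeledDataset, scalars: Sequence[float] = DEFAULT_SCALARS
) -> LabeledDataset:
    """Append one scaled near-copy of every positive row per scalar.

    Each copy is the positive feature vector multiplied element-wise by the
    scalar, flagged augmented; negatives are untouched.  The positive count
    becomes ``(1 + len(scalars))`` times the original.
    """
    scalars = tuple(scalars)
    if not scalars:
        warnings.warn("empty scalar list: oversampling is a no-op", stacklevel=2)
        return data
    pos_idx = np.flatnonzero(data.labels == 1)
    if pos_idx.size == 0:
        raise ValueError("dataset contains no positive rows to oversample")
    blocks = [data.features]
    labels = [data.labels]
    prov = list(data.provenance)
    flags = [data.augmented]
    for s in scalars:
        blocks.append(data.features[pos_idx] * s)
        labels.append(np.ones(pos_idx.size, dtype=int))
        prov.extend(f"{data.provenance[i]}*{s}" for i in pos_idx)
        flags.append(np.ones(pos_idx.size, dtype=bool))
    return LabeledDataset(
        features=np.vstack(blocks),
        labels=np.concatenate(labels),
        provenance=tuple(prov),
        augmented=np.concatenate(flags),
    )


def split_train_test(
    data: LabeledDataset,
    test_fraction: float = 0.10,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random disjoint train/test partition with |test| = round(fraction * n).

    Stratified by label by default so small datasets keep both classes in
    the test set.  Must be applied *before* oversampling; augmented rows are
    rejected.
    """
    n = len(data)
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test fraction must be in (0, 1), got {test_fraction}")
    if data.augmented.any():
        raise ValueError("split must precede oversampling: augmented rows present")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    if stratify:
        test_idx: list[int] = []
        # largest-remainder allocation of n_test across classes
        classes = [np.flatnonzero(data.labels == c) for c in (0, 1)]
        quotas = [len(idx) * test_fraction for idx in classes]
        counts = [int(q) for q in quotas]
        remainders = np.argsort([c - q for c, q in zip(counts, quotas)])
        for c in remainders:
            if sum(counts) >= n_test:
                break
            counts[c] += 1
        for idx, c in zip(classes, counts):
            if len(idx):
                test_idx.extend(rng.permutation(idx)[:c].tolist())
        test_set = set(test_idx)
    else:
        test_set = set(rng.permutation(n)[:n_test].tolist())
    train_idx = np.array([i for i in range(n) if i not in test_set], dtype=int)
    test_idx_arr = np.array(sorted(test_set), dtype=int)
    return data.subset(train_idx), data.subset(test_idx_arr)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def dataset_to_frame(data: LabeledDataset) -> pd.DataFrame:
    pid, center = [], []
    for sid in data.provenance:
        base = sid.split("*")[0]
        p, _, c = base.rpartition("|")
        pid.append(p)
        center.append(int(c) if c.isdigit() else -1)
    names = FEATURE_NAMES if data.features.shape[1] == len(FEATURE_NAMES) else [
        f"f{j + 1:03d}" for j in range(data.features.shape[1])
    ]
    df = pd.DataFrame(data.features, columns=names)
    df.insert(0, "augmented", data.augmented)
    df.insert(0, "label", data.labels)
    df.insert(0, "center", center)
    df.insert(0, "protein_id", pid)
    df.insert(0, "sample_id", list(data.provenance))
    return df


def write_dataset_csv(data: LabeledDataset, path: str | Path) -> None:
    dataset_to_frame(data).to_csv(path, index=False, float_format="%.12g")


def read_dataset_csv(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path)
    feature_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return LabeledDataset(
        features=df[feature_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        provenance=tuple(df["sample_id"].astype(str)),
        augmented=df["augmented"].to_numpy(dtype=bool) if "augmented" in df else None,
    )
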