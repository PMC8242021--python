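"""Privacy-aware dataset handling: manifests, splits, samplers, counting.

The unit of privacy is the image record (the package reports image-level
guarantees; subject-level grouping is honoured at *split* time when subject
ids are present, so no subject ever spans two splits, but subject-level
accounting is out of scope).  Two minibatch samplers are provided:

* uniform — a seeded shuffle partitioned into ceil(n/B) batches, every
  index exactly once per epoch (what shuffled data loaders do);
* Poisson — each of T batches contains every index independently with
  probability q, the sampling scheme the Poisson GDP/RDP accountants
  analyse.  Empty batches are emitted (they become noise-only steps) and
  every emitted batch counts one accounting step.

Occurrence counting implements the conservative rule that every
presentation of a record — augmented or not — counts against the budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .noise import GaussianNoiseSource

__all__ = [
    "DataError",
    "DatasetManifest",
    "split_counts",
    "assign_splits",
    "class_weights",
    "uniform_batches",
    "poisson_batches",
    "count_occurrences",
]

MANIFEST_COLUMNS = ("path", "label", "mask_path", "subject_id", "split")


class DataError(ValueError):
    pass


@dataclass
class DatasetManifest:
    """File paths, labels (and masks), split membership.

    Backed by a DataFrame with columns ``path, label[, mask_path]
    [, subject_id], split``; the CSV on disk uses the same schema.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"path", "split"} - set(self.records.columns)
        if missing:
            raise DataError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.records["split"].unique()) - {"train", "val", "test"}
        if bad:
            raise DataError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict:
        if "label" not in self.records.columns:
            return {}
        return self.records["label"].value_counts().to_dict()

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            self.records[self.records["split"] == split].reset_index(drop=True)
        )

    def validate_paths(self) -> None:
        for col in ("path", "mask_path"):
            if col not in self.records.columns:
                continue
            for p in self.records[col].dropna():
                if not Path(p).exists():
                    raise DataError(f"manifest references missing file: {p}")

    @classmethod
    def read_csv(cls, path: str | Path, check_paths: bool = True
                 ) -> "DatasetManifest":
        m = cls(pd.read_csv(path))
        if check_paths:
            m.validate_paths()
        return m

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in MANIFEST_COLUMNS if c in self.records.columns]
        self.records[cols].to_csv(path, index=False)


def split_counts(n: int, train_fraction: float) -> tuple[int, int]:
    """Train/validation sizes: half-up rounding on the training share.

    5163 records at 0.85 give (4389, 774).
    """
    if not 0 < train_fraction < 1:
        raise DataError(f"train fraction must lie in (0, 1), got {train_fraction}")
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_val = n - n_train
    if n_train == 0 or n_val <= 0:
        raise DataError(
            f"degenerate split: n={n}, fraction={train_fraction} "
            f"gives ({n_train}, {n_val})"
        )
    return n_train, n_val


def assign_splits(
    manifest: DatasetManifest, train_fraction: float, seed: int
) -> DatasetManifest:
    """Randomly assign train/val membership, subject-disjoint when possible.

    Without subject ids, a seeded permutation of records is cut at the
    half-up training count.  With subject ids, whole subjects are assigned
    greedily in a seeded random order until the training share is reached,
    so no subject spans the two splits.
    """
    df = manifest.records.copy()
    pool = df[df["split"] != "test"]
    n = len(pool)
    n_train, _ = split_counts(n, train_fraction)
    rng = np.random.default_rng(seed)
    if "subject_id" in df.columns and df.loc[pool.index, "subject_id"].notna().all():
        subjects = pool["subject_id"].unique()
        rng.shuffle(subjects)
        taken = 0
        train_subjects = set()
        sizes = pool.groupby("subject_id").size()
        for s in subjects:
            if taken >= n_train:
                break
            train_subjects.add(s)
            taken += int(sizes[s])
        is_train = pool["subject_id"].isin(train_subjects)
    else:
        perm = rng.permutation(n)
        is_train = pd.Series(False, index=pool.index)
        is_train.iloc[perm[:n_train]] = True
    df.loc[pool.index, "split"] = np.where(is_train, "train", "val")
    return DatasetManifest(df)


def class_weights(class_counts: dict) -> dict:
    """Loss weight per class: one minus the class's share of the dataset.

    Up-weights minority classes under imbalance; for k classes the weights
    always sum to k - 1.
    """
    if len(class_counts) < 2:
        raise DataError("class weighting needs at least two classes")
    if any(c <= 0 for c in class_counts.values()):
        raise DataError("class counts must be positive")
    total = sum(class_counts.values())
    return {label: 1.0 - count / total for label, count in class_counts.items()}


def uniform_batches(
    n: int, batch_size: int, seed: int
) -> list[np.ndarray]:
    """One epoch of shuffled minibatches: ceil(n/B) batches, each index once."""
    if not 1 <= batch_size <= n:
        raise DataError(f"need 1 <= B <= n, got B={batch_size}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i:i + batch_size] for i in range(0, n, batch_size)]


def poisson_batches(
    n: int,
    sample_rate: float,
    steps: int,
    noise_source: GaussianNoiseSource | None = None,
    seed: int | None = None,
) -> Iterator[np.ndarray]:
    """T Poisson-subsampled batches: each index in with probability q.

    Batch sizes are Binomial(n, q); empty batches are yielded too, since
    the accountant charges every emitted batch as one step.  Inclusion
    decisions come from the given noise source (secure by default in
    training) or, for tests, a seeded generator.
    """
    if not 0 < sample_rate <= 1:
        raise DataError(f"sample rate must lie in (0, 1], got {sample_rate}")
    if steps < 0:
        raise DataError(f"steps must be >= 0, got {steps}")
    if noise_source is None:
        noise_source = (GaussianNoiseSource(secure=True) if seed is None
                        else GaussianNoiseSource(secure=False, seed=seed))
    for _ in range(steps):
        u = noise_source.uniform(n)
        yield np.flatnonzero(u < sample_rate)


def count_occurrences(
    training_log: Sequence[tuple[int, Sequence[int]]], n: int
) -> tuple[np.ndarray, int]:
    """Per-record presentation counts from a (step, indices) log.

    Augmented presentations count identically to raw ones (the log does
    not distinguish them — by design).  Returns (counts, total_steps);
    ``total_steps`` is what must be reported to the accountant.  Step
    numbers must be contiguous from 0: a gap means unlogged mechanism
    applications, which would under-count privacy.
    """
    counts = np.zeros(n, dtype=np.int64)
    steps_seen = [s for s, _ in training_log]
    if steps_seen != list(range(len(steps_seen))):
        raise DataError(
            "training log steps are not contiguous from 0; refusing to "
            "count occurrences against an incomplete log"
        )
    for _, indices in training_log:
        for i in indices:
            counts[i] += 1
    return counts, len(steps_seen)
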