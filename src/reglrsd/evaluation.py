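"""Subsampling protocol: marker-set stability and centroid classification.

The protocol repeatedly splits the labeled table into train/test parts,
runs a marker detector on each training part, and summarizes (i) how
stable the selected marker sets are across subsamples — pairwise Kuncheva
indices and their mean ``C_avg`` — and (ii) how well a nearest-centroid
classifier built on the selected markers separates the two phenotypes.

The Kuncheva index corrects raw set overlap for chance agreement:
``KI(A, B) = (|A ∩ B| - s^2/p) / (s - s^2/p)`` for two size-``s`` subsets
of ``p`` features, so random selections score around 0 and identical sets
score 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ProtocolError
from .scoring import MarkerRanking
from .table import AbundanceTable

__all__ = [
    "ProtocolConfig",
    "StabilityReport",
    "ClassificationReport",
    "CentroidModel",
    "subsample_split",
    "kuncheva_index",
    "pairwise_kuncheva",
    "average_consistency",
    "fit_ncc",
    "predict_ncc",
    "classification_metrics",
    "run_protocol",
]

Detector = Callable[[AbundanceTable], MarkerRanking]


@dataclass
class ProtocolConfig:
    """Settings of the repeated-subsampling evaluation.

    ``K`` subsamples each keep a fraction ``r`` of the samples for
    training (``ceil(r * n)`` columns, stratified by class by default);
    ``m`` markers are selected per subsample.  ``positive_label`` names the
    class counted as positive for sensitivity/specificity and is required
    whenever classification is run.
    """

    m: int
    K: int = 500
    r: float = 0.8
    seed: int = 0
    stratified: bool = True
    classifier_norms: tuple[str, ...] = ("l1", "l2")
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"train fraction r must lie in (0, 1), got {self.r}")
        if self.K < 2:
            raise ValueError(f"K must be at least 2, got {self.K}")
        if self.m < 1:
            raise ValueError(f"m must be positive, got {self.m}")
        bad = set(self.classifier_norms) - {"l1", "l2"}
        if bad:
            raise ValueError(f"unknown classifier norms: {sorted(bad)}")


@dataclass
class StabilityReport:
    """Pairwise Kuncheva indices, their mean, and rank stability data."""

    ki_values: np.ndarray
    c_avg: float
    rank_matrix: np.ndarray        # K x m, NaN when a reference marker is unselected
    reference_markers: list[str]
    selection_frequency: pd.Series


@dataclass
class ClassificationReport:
    """Per-iteration confusion counts and averaged metrics per norm."""

    per_iteration: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class CentroidModel:
    """Two class centroids over the selected marker features."""

    classes: list[str]
    centroids: np.ndarray  # shape (2, n_features)
    norm: str

    def __post_init__(self) -> None:
        if len(self.classes) != 2 or self.centroids.shape[0] != 2:
            raise ValueError("exactly two class centroids required")
        if self.norm not in ("l1", "l2"):
            raise ValueError(f"norm must be 'l1' or 'l2', got {self.norm!r}")


def subsample_split(
    table: AbundanceTable,
    r: float,
    rng_seed: int | np.random.Generator,
    stratified: bool = True,
) -> tuple[AbundanceTable, AbundanceTable]:
    """Split samples into train (``ceil(r * n)`` columns) and test parts.

    Stratified splits draw ``ceil(r * n_c)`` per class and trim any excess
    from the larger class so the train size is exactly ``ceil(r * n)``.
    Raises :class:`ProtocolError` if either part loses a class entirely.
    """
    if table.labels is None:
        raise ProtocolError("subsampling requires a labeled table")
    if not 0 < r < 1:
        raise ValueError(f"train fraction r must lie in (0, 1), got {r}")
    rng = np.random.default_rng(rng_seed)
    n = table.n
    n_train = math.ceil(r * n)
    labels = table.label_vector()
    classes = table.class_labels
    if stratified:
        chosen: dict[str, np.ndarray] = {}
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            take = math.ceil(r * idx.size)
            chosen[cls] = rng.choice(idx, size=take, replace=False)
        excess = sum(len(v) for v in chosen.values()) - n_train
        if excess > 0:
            sizes = {cls: np.sum(labels == cls) for cls in classes}
            larger = max(classes, key=lambda c: sizes[c])
            keep = rng.choice(
                len(chosen[larger]), size=len(chosen[larger]) - excess, replace=False
            )
            chosen[larger] = chosen[larger][keep]
        train_idx = np.sort(np.concatenate(list(chosen.values())))
    else:
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    for cls in classes:
        if not np.any(labels[train_idx] == cls):
            raise ProtocolError(f"class {cls!r} has no training samples")
        if not np.any(labels[test_idx] == cls):
            raise ProtocolError(f"class {cls!r} has no test samples")
    return table.subset_samples(train_idx), table.subset_samples(test_idx)


def kuncheva_index(set_a: Iterable, set_b: Iterable, p: int) -> float:
    """Chance-corrected overlap of two equal-size feature sets out of ``p``."""
    a, b = set(set_a), set(set_b)
    if len(a) != len(b):
        raise ValueError(f"marker sets differ in size: {len(a)} vs {len(b)}")
    s = len(a)
    if s == 0 or s >= p:
        raise ValueError(
            f"set size must satisfy 0 < s < p, got s={s}, p={p} (denominator zero)"
        )
    correction = s * s / p
    return (len(a & b) - correction) / (s - correction)


def pairwise_kuncheva(sets: Sequence[Iterable], p: int) -> np.ndarray:
    """All K(K-1)/2 pairwise Kuncheva indices, in (i, j>i) order."""
    sets = [set(s) for s in sets]
    K = len(sets)
    if K < 2:
        raise ValueError("need at least two marker sets")
    out = np.empty(K * (K - 1) // 2)
    pos = 0
    for i in range(K):
        for j in range(i + 1, K):
            out[pos] = kuncheva_index(sets[i], sets[j], p)
            pos += 1
    return out


def average_consistency(sets: Sequence[Iterable], p: int) -> float:
    """Mean Kuncheva index over all pairs of marker sets (``C_avg``)."""
    return float(pairwise_kuncheva(sets, p).mean())


def fit_ncc(train: AbundanceTable, norm: str = "l2") -> CentroidModel:
    """Mean sample vector per class, over the table's (marker) rows."""
    if train.labels is None:
        raise ProtocolError("NCC training requires labels")
    labels = train.label_vector()
    classes = train.class_labels
    cents = []
    for cls in classes:
        cols = np.flatnonzero(labels == cls)
        if cols.size == 0:
            raise ProtocolError(f"class {cls!r} is empty in the training table")
        cents.append(train.values[:, cols].mean(axis=1))
    return CentroidModel(classes=list(classes), centroids=np.stack(cents), norm=norm)


def predict_ncc(model: CentroidModel, z: np.ndarray) -> str:
    """Class of the nearest centroid; ties go to the first class in order."""
    z = np.asarray(z, dtype=float)
    if z.shape != model.centroids[0].shape:
        raise ValueError(
            f"sample has {z.shape} features, centroids have "
            f"{model.centroids[0].shape}"
        )
    diff = model.centroids - z
    if model.norm == "l1":
        dists = np.abs(diff).sum(axis=1)
    else:
        dists = np.sqrt((diff * diff).sum(axis=1))
    return model.classes[int(np.argmin(dists))]


def classification_metrics(
    tp: int, tn: int, fp: int, fn: int
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios become NaN."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn < 1:
        raise ValueError("confusion counts must be non-negative and sum to >= 1")
    accuracy = (tp + tn) / (tp + fn + tn + fp)
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    specificity = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return accuracy, sensitivity, specificity


def _iteration_rng(seed: int, k: int) -> np.random.Generator:
    # independent, reproducible stream per iteration
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def run_protocol(
    table: AbundanceTable,
    detector: Detector,
    config: ProtocolConfig,
) -> tuple[StabilityReport, ClassificationReport]:
    """Run the full K-fold subsampling evaluation of a marker detector.

    Each iteration ``k`` draws its own RNG stream from ``config.seed`` so
    runs are reproducible.  The rank matrix records, per iteration, the
    rank (1-based) that each top-``m`` marker of the *full-data* ranking
    attains within the iteration's top-``m`` list, NaN when unselected.
    Detector failures are tolerated up to 1% of ``K``; beyond that the
    protocol aborts.
    """
    if table.labels is None:
        raise ProtocolError("the evaluation protocol requires a labeled table")
    if config.m > table.p:
        raise ValueError(f"m={config.m} exceeds the {table.p} available OTUs")
    if config.classifier_norms and config.positive_label is None:
        raise ProtocolError("positive_label must be set to run classification")
    if config.positive_label is not None and config.positive_label not in table.class_labels:
        raise ProtocolError(
            f"positive label {config.positive_label!r} not among classes "
            f"{table.class_labels}"
        )

    reference = detector(table)
    ref_top = reference.top_ids(config.m)

    sets: list[set[str]] = []
    rank_rows: list[np.ndarray] = []
    counts: dict[str, int] = {o: 0 for o in table.otu_ids}
    rows: list[dict] = []
    failures = 0
    max_failures = config.K * 0.01
    for k in range(config.K):
        rng = _iteration_rng(config.seed, k)
        train, test = subsample_split(table, config.r, rng, config.stratified)
        try:
            ranking = detector(train)
        except Exception:  # noqa: BLE001 -- per-iteration failure is recorded
            failures += 1
            if failures > max_failures:
                raise ProtocolError(
                    f"detector failed on {failures} of {k + 1} subsamples "
                    f"(more than 1% of K={config.K})"
                )
            continue
        top = ranking.top_ids(config.m)
        sets.append(set(top))
        position = {otu: i + 1 for i, otu in enumerate(top)}
        rank_rows.append(
            np.array([position.get(o, np.nan) for o in ref_top], dtype=float)
        )
        for o in top:
            counts[o] += 1

        for norm in config.classifier_norms:
            sub_train = _restrict_rows(train, top)
            sub_test = _restrict_rows(test, top)
            model = fit_ncc(sub_train, norm)
            tp = tn = fp = fn = 0
            test_labels = sub_test.label_vector()
            for j in range(sub_test.n):
                pred = predict_ncc(model, sub_test.values[:, j])
                truth = test_labels[j]
                if truth == config.positive_label:
                    if pred == truth:
                        tp += 1
                    else:
                        fn += 1
                else:
                    if pred == truth:
                        tn += 1
                    else:
                        fp += 1
            acc, sens, spec = classification_metrics(tp, tn, fp, fn)
            rows.append(
                dict(
                    iteration=k, norm=norm, tp=tp, tn=tn, fp=fp, fn=fn,
                    accuracy=acc, sensitivity=sens, specificity=spec,
                )
            )

    n_ok = len(sets)
    if n_ok < 2:
        raise ProtocolError("fewer than two successful subsamples")
    ki = pairwise_kuncheva(sets, table.p)
    freq = pd.Series(
        {o: counts[o] / n_ok for o in table.otu_ids}, name="selection_frequency"
    )
    stability = StabilityReport(
        ki_values=ki,
        c_avg=float(ki.mean()),
        rank_matrix=np.vstack(rank_rows) if rank_rows else np.empty((0, config.m)),
        reference_markers=ref_top,
        selection_frequency=freq,
    )
    per_it = pd.DataFrame(
        rows,
        columns=[
            "iteration", "norm", "tp", "tn", "fp", "fn",
            "accuracy", "sensitivity", "specificity",
        ],
    )
    if len(per_it):
        summary = (
            per_it.groupby("norm")[["accuracy", "sensitivity", "specificity"]]
            .mean()
        )
    else:
        summary = pd.DataFrame(
            columns=["accuracy", "sensitivity", "specificity"]
        )
    return stability, ClassificationReport(per_iteration=per_it, summary=summary)


def _restrict_rows(table: AbundanceTable, otu_ids: list[str]) -> AbundanceTable:
    index = {o: i for i, o in enumerate(table.otu_ids)}
    rows = [index[o] for o in otu_ids]
    return AbundanceTable(
        table.values[rows],
        list(otu_ids),
        list(table.sample_ids),
        None if table.labels is None else dict(table.labels),
    )
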