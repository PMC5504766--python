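"""Synthetic abundance matrices with planted low-rank + sparse structure.

The generator emulates the statistical structure the decomposition model
assumes: a smooth low-rank background ``L0`` (non-differential taxa whose
profiles vary little across samples), a sparse component ``S0`` whose
nonzero rows are whole-OTU shifts confined to one phenotype's samples
(enrichment or depletion), and dense i.i.d. Gaussian noise.  The observed
table is ``clip(L0 + S0 + noise, 0)`` — abundances are non-negative while
the additive model is unconstrained — with ground truth exported so that
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .table import AbundanceTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "recovery_metrics"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults describe a typical small two-phenotype 16S study scaled for
    benchmarking: 200 OTUs, 20 samples per class, a smooth rank-2
    background with typical entries near 1, 10 differential OTUs whose
    abundance shifts by about 40% of a typical background value (mean
    |shift| 0.5, fold change around 1.4) in one class's samples, and
    measurement noise of 0.05 sd (a tenth of the effect).  Columns can
    optionally be normalized to sum to one to mimic relative-abundance
    input.
    """

    p: int = 200
    n: int = 40
    n_per_class: tuple[int, int] = (20, 20)
    rank: int = 2
    marker_rows: int = 10
    effect_size: float = 0.5
    noise_sd: float = 0.05
    smoothness_span: int = 20
    seed: int = 0
    normalize_columns: bool = False
    class_names: tuple[str, str] = ("control", "case")

    def __post_init__(self) -> None:
        if sum(self.n_per_class) != self.n:
            raise ValueError(
                f"n_per_class {self.n_per_class} must sum to n={self.n}"
            )
        if min(self.n_per_class) < 1:
            raise ValueError("both classes need at least one sample")
        if not 1 <= self.rank <= min(self.p, self.n):
            raise ValueError(
                f"rank must lie in [1, min(p, n)] = [1, {min(self.p, self.n)}], "
                f"got {self.rank}"
            )
        if not 0 <= self.marker_rows <= self.p:
            raise ValueError(f"marker_rows must lie in [0, p], got {self.marker_rows}")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if self.smoothness_span < 1:
            raise ValueError("smoothness_span must be a positive integer")


@dataclass
class SyntheticDataset:
    """Generated table plus the planted ground truth."""

    table: AbundanceTable
    true_L: np.ndarray
    true_S: np.ndarray
    true_markers: set[int]
    marker_signs: dict[int, int]


def _moving_average(x: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average; windows slide inward at the edges so every
    window keeps full width (span = n therefore yields a constant vector)."""
    n = x.size
    span = min(span, n)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    half = span // 2
    for t in range(n):
        lo = min(max(0, t - half), n - span)
        out[t] = (cum[lo + span] - cum[lo]) / span
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    p, n, rank = spec.p, spec.n, spec.rank

    # Low-rank smooth background: positive mixing weights bounded away from
    # zero times row-smoothed positive basis profiles.  Keeping every entry
    # well above effect_size means a planted depletion never clips to zero:
    # a taxon can only lose abundance it actually has.
    A = rng.uniform(0.2, 1.0, size=(p, rank))
    B = np.abs(rng.normal(1.0, 0.3, size=(rank, n)))
    B = np.vstack([_moving_average(row, spec.smoothness_span) for row in B])
    L0 = A @ B

    # Sparse planted markers: whole-row shifts confined to one class's
    # columns, with per-sample magnitudes drawn around effect_size (mean
    # |shift| = effect_size).  Subject-to-subject variability is what makes
    # the pattern sparse-like rather than a rank-1 block the background
    # could absorb.
    S0 = np.zeros((p, n))
    markers = rng.choice(p, size=spec.marker_rows, replace=False)
    n0 = spec.n_per_class[0]
    class_cols = [np.arange(n0), np.arange(n0, n)]
    signs: dict[int, int] = {}
    for row in markers:
        sign = int(rng.choice([-1, 1]))
        cls = int(rng.integers(0, 2))
        cols = class_cols[cls]
        magnitudes = spec.effect_size * rng.uniform(0.5, 1.5, size=cols.size)
        S0[row, cols] = sign * magnitudes
        signs[int(row)] = sign

    noise = rng.normal(0.0, spec.noise_sd, size=(p, n)) if spec.noise_sd > 0 else 0.0
    values = np.clip(L0 + S0 + noise, 0.0, None)

    labels = {}
    sample_ids = []
    for j in range(n):
        sid = f"S{j:03d}"
        sample_ids.append(sid)
        labels[sid] = spec.class_names[0] if j < n0 else spec.class_names[1]
    table = AbundanceTable(
        values=values,
        otu_ids=[f"OTU{i:04d}" for i in range(p)],
        sample_ids=sample_ids,
        labels=labels,
    )
    if spec.normalize_columns:
        table = table.renormalized()
    return SyntheticDataset(
        table=table,
        true_L=L0,
        true_S=S0,
        true_markers={int(i) for i in markers},
        marker_signs=signs,
    )


def recovery_metrics(
    selected: Iterable, truth: Iterable
) -> tuple[float, float]:
    """(precision, recall) of a selected marker set against the truth.

    Precision is NaN (not an error) when nothing was selected.
    """
    sel, tru = set(selected), set(truth)
    if not tru:
        raise ValueError("truth set must be non-empty")
    hits = len(sel & tru)
    precision = hits / len(sel) if sel else float("nan")
    recall = hits / len(tru)
    return precision, recall
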