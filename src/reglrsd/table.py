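"""Labeled OTU-by-sample abundance matrices.

The central container is :class:`AbundanceTable`: a non-negative matrix
``values`` of shape ``(p, n)`` whose rows are OTUs (or any taxa) and whose
columns are samples, together with unique row/column identifiers and an
optional two-class phenotype labeling of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """A p x n relative-abundance matrix with identifiers and optional labels.

    Parameters
    ----------
    values
        Non-negative, finite matrix; rows are OTUs, columns are samples.
    otu_ids
        ``p`` unique row identifiers.
    sample_ids
        ``n`` unique column identifiers.
    labels
        Optional mapping ``sample_id -> class label``.  When present it must
        cover every sample and use exactly two distinct labels, each with at
        least one sample.
    """

    values: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataError("abundance values must form a 2-D matrix")
        p, n = self.values.shape
        if p < 1 or n < 2:
            raise DataError(
                f"matrix must have at least 1 OTU and 2 samples, got {p}x{n}"
            )
        if len(self.otu_ids) != p:
            raise DataError(f"{len(self.otu_ids)} OTU ids for {p} rows")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.otu_ids)) != p:
            raise DataError("OTU identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample identifiers are not unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite abundance at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise DataError(
                f"negative abundance {self.values[i, j]!r} at OTU "
                f"{self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.labels is not None:
            self.labels = {str(k): str(v) for k, v in self.labels.items()}
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise DataError(f"samples without a label: {missing}")
            classes = self.class_labels
            if len(classes) != 2:
                raise DataError(
                    f"exactly two class labels required, got {sorted(set(self.labels[s] for s in self.sample_ids))}"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> list[str]:
        """Distinct labels in order of first appearance along ``sample_ids``."""
        if self.labels is None:
            return []
        seen: list[str] = []
        for s in self.sample_ids:
            lab = self.labels[s]
            if lab not in seen:
                seen.append(lab)
        return seen

    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise DataError("table carries no sample labels")
        return np.array([self.labels[s] for s in self.sample_ids])

    # -- conversions -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, labels: dict[str, str] | None = None
    ) -> "AbundanceTable":
        """Build a table from a DataFrame indexed by OTU id, columns = samples."""
        return cls(
            values=frame.to_numpy(dtype=float),
            otu_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            labels=labels,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    # -- transformations -------------------------------------------------
    def subset_samples(self, indices: np.ndarray | list[int]) -> "AbundanceTable":
        """Return a new table with the given sample columns, labels carried over."""
        idx = np.asarray(indices, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in ids}
        return AbundanceTable(self.values[:, idx], list(self.otu_ids), ids, labels)

    def class_block_order(self) -> np.ndarray:
        """Column permutation placing same-class samples contiguously.

        Classes appear in order of first appearance; within a class the
        original sample order is preserved.
        """
        if self.labels is None:
            return np.arange(self.n)
        order: list[int] = []
        for cls in self.class_labels:
            order.extend(
                j for j, s in enumerate(self.sample_ids) if self.labels[s] == cls
            )
        return np.asarray(order, dtype=int)

    def renormalized(self) -> "AbundanceTable":
        """Return a copy with each sample column scaled to sum to one.

        All-zero columns are left untouched rather than divided by zero.
        """
        sums = self.values.sum(axis=0)
        scale = np.where(sums > 0, sums, 1.0)
        return AbundanceTable(
            self.values / scale, list(self.otu_ids), list(self.sample_ids),
            None if self.labels is None else dict(self.labels),
        )
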