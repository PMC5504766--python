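"""Ranking OTUs by the magnitude of their sparse-component rows.

The score of OTU ``i`` is the l1 norm of row ``i`` of the sparse matrix
``S``: the strength of its differential behaviour, regardless of whether
the taxon is enriched or depleted.  The sign of the row mean is kept as
reporting metadata (which phenotype the marker is enriched in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarkerRanking", "score_markers", "rank_markers", "select_top_m"]


@dataclass
class MarkerRanking:
    """Scores aligned to ``otu_ids``, with the induced descending order."""

    otu_ids: list[str]
    scores: np.ndarray
    order: np.ndarray            # permutation sorting scores descending
    enrichment_sign: np.ndarray  # sign of each row mean of S: -1, 0 or +1

    def top_ids(self, m: int) -> list[str]:
        return [self.otu_ids[i] for i in self.order[:m]]


def score_markers(S: np.ndarray) -> np.ndarray:
    """Per-OTU score: sum of absolute values along each row of ``S``."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("S must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(S)):
        raise ValueError("S must be finite")
    return np.abs(S).sum(axis=1)


def rank_markers(S: np.ndarray, otu_ids: list[str] | None = None) -> MarkerRanking:
    """Build the full ranking from a sparse component.

    Ties in score are broken by ascending original row index (stable sort
    on the negated scores), so the ranking is deterministic.
    """
    scores = score_markers(S)
    p = scores.size
    if otu_ids is None:
        otu_ids = [str(i) for i in range(p)]
    if len(otu_ids) != p:
        raise ValueError(f"{len(otu_ids)} ids for {p} rows")
    order = np.argsort(-scores, kind="stable")
    row_means = np.asarray(S, dtype=float).mean(axis=1)
    return MarkerRanking(
        otu_ids=list(otu_ids),
        scores=scores,
        order=order,
        enrichment_sign=np.sign(row_means).astype(int),
    )


def select_top_m(ranking: MarkerRanking, m: int) -> list[str]:
    """The ``m`` highest-scoring OTU identifiers, in rank order."""
    p = len(ranking.otu_ids)
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    return ranking.top_ids(m)
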