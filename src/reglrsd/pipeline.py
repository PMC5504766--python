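"""End-to-end detection: decompose, score, select.

Thin glue over :mod:`reglrsd.decomposition` and :mod:`reglrsd.scoring`,
plus the detector factory the evaluation protocol consumes.
"""

from __future__ import annotations

from typing import Callable

from .decomposition import Decomposition, RegLRSDConfig, decompose
from .scoring import MarkerRanking, rank_markers
from .table import AbundanceTable

__all__ = ["detect_markers", "reglrsd_detector"]


def detect_markers(
    table: AbundanceTable, config: RegLRSDConfig | None = None
) -> tuple[Decomposition, MarkerRanking]:
    """Decompose a table and rank its OTUs by sparse-row magnitude."""
    result = decompose(table, config)
    ranking = rank_markers(result.S, table.otu_ids)
    return result, ranking


def reglrsd_detector(
    config: RegLRSDConfig | None = None,
) -> Callable[[AbundanceTable], MarkerRanking]:
    """A detector (table -> ranking) suitable for the evaluation protocol."""

    def detector(table: AbundanceTable) -> MarkerRanking:
        return detect_markers(table, config)[1]

    return detector
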