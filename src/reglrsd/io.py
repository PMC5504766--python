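"""Readers and writers for tables, labels, configs and reports.

All delimited-text formats are plain TSV (CSV by flag): abundance tables
have the OTU identifier in the first column and sample identifiers in the
header row; label files are two columns (sample_id, label); configs are
flat ``key = value`` text.  Writers produce files the paired readers parse
back losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ClassificationReport, StabilityReport
from .exceptions import DataError
from .scoring import MarkerRanking
from .table import AbundanceTable

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_labels",
    "write_labels",
    "read_config_file",
    "write_markers",
    "write_manifest",
    "write_stability_report",
    "write_classification_report",
    "write_ground_truth",
]

_SEPS = {"tsv": "\t", "csv": ","}


def read_abundance_table(
    path: str | Path,
    format: str = "tsv",
    labels: dict[str, str] | None = None,
) -> AbundanceTable:
    """Parse a delimited OTU table (first column = OTU id, header = samples).

    Negative, missing or non-numeric cells are rejected with their
    coordinates; BIOM input is supported when the ``biom`` package is
    importable.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "biom":
        return _read_biom(path, labels)
    if format not in _SEPS:
        raise DataError(f"unknown format {format!r}; expected tsv, csv or biom")
    try:
        frame = pd.read_csv(
            path, sep=_SEPS[format], index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate OTU identifiers in {path}: {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample identifiers in {path}: {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric or missing cell at OTU {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r} in {path}"
        )
    neg = numeric < 0
    if neg.any().any():
        i, j = np.argwhere(neg.to_numpy())[0]
        raise DataError(
            f"negative abundance {numeric.iat[i, j]} at OTU {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r} in {path}"
        )
    return AbundanceTable.from_dataframe(numeric, labels=labels)


def _read_biom(path: Path, labels: dict[str, str] | None) -> AbundanceTable:
    try:
        import biom  # type: ignore
    except ImportError as exc:
        raise DataError(
            "BIOM input requires the optional 'biom-format' package"
        ) from exc
    bt = biom.load_table(str(path))
    frame = bt.to_dataframe(dense=True)
    return AbundanceTable.from_dataframe(frame, labels=labels)


def write_abundance_table(
    table: AbundanceTable, path: str | Path, format: str = "tsv"
) -> None:
    if format not in _SEPS:
        raise DataError(f"unknown format {format!r}; expected tsv or csv")
    frame = table.to_dataframe()
    frame.index.name = "otu_id"
    frame.to_csv(path, sep=_SEPS[format], float_format="%.17g")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column (sample_id, label) TSV, with or without a header row."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] != 2:
        raise DataError(
            f"label file {path} must have exactly two columns, got {frame.shape[1]}"
        )
    if list(frame.iloc[0].str.lower()) == ["sample_id", "label"]:
        frame = frame.iloc[1:]
    if frame[0].duplicated().any():
        dupes = frame[0][frame[0].duplicated()].tolist()
        raise DataError(f"duplicate sample identifiers in {path}: {dupes}")
    labels = dict(zip(frame[0], frame[1]))
    if len(set(labels.values())) != 2:
        raise DataError(
            f"label file {path} must define exactly two classes, "
            f"got {sorted(set(labels.values()))}"
        )
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def read_config_file(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` text; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_markers(ranking: MarkerRanking, path: str | Path, m: int | None = None) -> None:
    """Ranked marker list: rank, otu_id, score, enrichment_sign."""
    limit = len(ranking.otu_ids) if m is None else m
    with open(path, "w") as fh:
        fh.write("rank\totu_id\tscore\tenrichment_sign\n")
        for rank, row in enumerate(ranking.order[:limit], start=1):
            fh.write(
                f"{rank}\t{ranking.otu_ids[row]}\t{ranking.scores[row]:.17g}\t"
                f"{ranking.enrichment_sign[row]}\n"
            )


def write_manifest(manifest: dict, path: str | Path) -> None:
    """All resolved parameters and diagnostics of a run, as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_stability_report(report: StabilityReport, directory: str | Path) -> None:
    """KI values, rank matrix (long form) and selection frequencies as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "ki_values.tsv", "w") as fh:
        fh.write("# pairwise Kuncheva indices over subsample marker sets; "
                 f"c_avg={report.c_avg:.17g}\n")
        fh.write("ki\n")
        for v in report.ki_values:
            fh.write(f"{v:.17g}\n")
    with open(directory / "rank_matrix.tsv", "w") as fh:
        fh.write("# rank of each full-data top-m marker within each subsample's "
                 "top-m list; NA = not selected that iteration\n")
        fh.write("iteration\totu_id\trank\n")
        for k, row in enumerate(report.rank_matrix):
            for otu, r in zip(report.reference_markers, row):
                txt = "NA" if np.isnan(r) else str(int(r))
                fh.write(f"{k}\t{otu}\t{txt}\n")
    freq = report.selection_frequency.rename_axis("otu_id").reset_index()
    with open(directory / "selection_frequency.tsv", "w") as fh:
        fh.write("# fraction of subsamples in which each OTU entered the top-m set\n")
        freq.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def write_classification_report(
    report: ClassificationReport, directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "classification_iterations.tsv", "w") as fh:
        fh.write("# per-subsample confusion counts and metrics; norm l1 = NCC-1, "
                 "l2 = NCC-2\n")
        report.per_iteration.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    with open(directory / "classification_summary.tsv", "w") as fh:
        fh.write("# metrics averaged over subsamples, per classifier norm\n")
        report.summary.to_csv(fh, sep="\t", float_format="%.17g")


def write_ground_truth(
    markers: set[int], signs: dict[int, int], p: int, path: str | Path
) -> None:
    """Planted-marker truth table: row_index, is_marker, sign."""
    with open(path, "w") as fh:
        fh.write("row_index\tis_marker\tsign\n")
        for i in range(p):
            fh.write(f"{i}\t{int(i in markers)}\t{signs.get(i, 0)}\n")
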