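"""Readers and writers for the plain-text interchange formats.

Genus/gene count tables travel as TSV (feature rows, sample columns,
integer cells) with a metadata sidecar TSV (sample, arm, timepoint,
subject).  Gene sets are GMT; annotation registries are TSV.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError
from .normdiff import AbundanceTable


def read_abundance(counts_path, metadata_path) -> AbundanceTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    try:
        counts = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        raise DataError(f"{counts_path}: counts must be integers") from exc
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample")
    return AbundanceTable(counts=counts, metadata=metadata)


def write_abundance(table: AbundanceTable, counts_path, metadata_path) -> None:
    out = table.counts.copy()
    out.index.name = "feature"
    out.to_csv(counts_path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def write_registry(registry: pd.DataFrame, path) -> None:
    required = {"genus", "label"}
    if not required.issubset(registry.columns):
        raise DataError(f"registry frame must have columns {sorted(required)}")
    registry.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str).set_index("sample")["group"]
    absent = [s for s in mat.columns if s not in groups.index]
    if absent:
        raise DataError(f"expression samples without a group: {absent}")
    return mat, groups.loc[list(mat.columns)]
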