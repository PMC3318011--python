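"""Readers and writers for the plain-text interchange formats.

Probe matrices, annotations and sample metadata travel as TSV; virtual arrays
as TSV plus a JSON metadata sidecar (see :meth:`VirtualArray.to_tsv`); event
tables and FISH counts as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .integration import ProbeAnnotation, ProbeMatrix
from .phenotype import CHANNELS, FishCell

__all__ = [
    "read_probe_matrix",
    "read_annotation",
    "read_metadata",
    "read_events",
    "write_events",
    "read_fish_counts",
    "write_fish_counts",
]


def read_probe_matrix(path: str | Path, platform_id: str | None = None) -> ProbeMatrix:
    """Read a probe × sample TSV (first column ``probe_id``).

    ``platform_id`` defaults to the file stem (minus a ``.probes`` suffix).
    """
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="probe_id", float_precision="round_trip")
    if platform_id is None:
        platform_id = path.stem.removesuffix(".probes")
    return ProbeMatrix(platform_id=platform_id, values=values)


def read_annotation(path: str | Path, platform_id: str | None = None) -> ProbeAnnotation:
    """Read a two-column TSV (probe_id, gene_symbol); repeated probes accumulate genes."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if platform_id is None:
        platform_id = path.stem.removesuffix(".annotation")
    pairs = list(zip(table["probe_id"], table["gene_symbol"]))
    return ProbeAnnotation.from_pairs(platform_id, pairs)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV indexed by ``sample_id``."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table CSV with the fixed channel schema."""
    table = pd.read_csv(path)
    missing = set(CHANNELS) - set(table.columns)
    if missing:
        raise ValueError(f"event table lacks channel column(s): {sorted(missing)}")
    return table


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_fish_counts(path: str | Path) -> list[FishCell]:
    """Read FISH counts CSV (cell_id, probe_id, count) into per-cell count tuples."""
    table = pd.read_csv(path)
    cells = []
    for _, group in table.groupby("cell_id", sort=True):
        group = group.sort_values("probe_id")
        cells.append(FishCell(counts=tuple(int(c) for c in group["count"])))
    return cells


def write_fish_counts(cells: Sequence[FishCell], path: str | Path) -> None:
    rows = [
        {"cell_id": f"cell{ci:05d}", "probe_id": f"probe{pi+1}", "count": c}
        for ci, cell in enumerate(cells)
        for pi, c in enumerate(cell.counts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
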