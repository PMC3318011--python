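"""Cross-platform integration: probe annotation, gene collapsing, and virtual-array assembly.

A "virtual array" is a single gene × sample expression matrix compiled from
several microarray platforms restricted to the set of genes measured by all of
them.  Building one proceeds in three steps implemented here:

1. :func:`collapse_probes_to_genes` — reduce each platform's probe-level matrix
   to one row per annotated gene symbol (median across probes by default).
2. :func:`intersect_genes` — determine the gene set common to all platforms.
3. :func:`assemble_virtual_array` — column-concatenate the per-platform
   gene-level matrices, restricted to the common genes, attaching per-sample
   metadata (platform, batch, cell type).

All intensities are handled on the log2 scale throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMatrix",
    "ProbeAnnotation",
    "VirtualArray",
    "collapse_probes_to_genes",
    "intersect_genes",
    "assemble_virtual_array",
]

#: metadata columns a VirtualArray carries for every sample
METADATA_COLUMNS = ("platform", "batch", "cell_type")


@dataclass
class ProbeMatrix:
    """One platform's probe-level log2 intensities.

    Parameters
    ----------
    platform_id:
        Label of the measuring platform.
    values:
        probe × sample DataFrame of log2 intensities.  Missing measurements
        are represented as NaN; everything else must be finite.
    """

    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id {dup!r} on platform {self.platform_id!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r} on platform {self.platform_id!r}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~(np.isfinite(arr) | np.isnan(arr))
        if bad.any():
            raise ValueError(f"non-finite intensity on platform {self.platform_id!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Mapping from probe identifiers to gene symbols for one platform.

    ``mapping`` takes each probe to the set of gene symbols it interrogates.
    Probes mapping to no gene (empty set) are permitted and are dropped at
    collapse time; probes mapping to several genes contribute to each.
    """

    platform_id: str
    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.mapping = {p: frozenset(g) for p, g in self.mapping.items()}

    @classmethod
    def from_pairs(cls, platform_id: str, pairs: Iterable[tuple[str, str]]) -> "ProbeAnnotation":
        """Build from (probe_id, gene_symbol) rows; repeated probes accumulate genes."""
        mapping: dict[str, set[str]] = {}
        for probe, gene in pairs:
            mapping.setdefault(probe, set())
            if gene:
                mapping[probe].add(gene)
        return cls(platform_id, {p: frozenset(g) for p, g in mapping.items()})

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.mapping.values():
            out |= genes
        return out


@dataclass
class VirtualArray:
    """Gene × sample matrix over the cross-platform gene intersection.

    ``values`` holds log2 intensities (genes as rows, samples as columns,
    no missing values); ``metadata`` is indexed by sample_id and carries at
    least ``platform``, ``batch`` and ``cell_type`` columns, in the same
    order as the value columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"metadata missing for samples: {missing}")
        # keep metadata aligned with column order
        self.metadata = self.metadata.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ValueError("VirtualArray values must not contain missing entries")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "VirtualArray":
        """Return a copy carrying ``values`` and the same metadata."""
        return VirtualArray(values=values, metadata=self.metadata.copy())

    def subset_genes(self, genes: Sequence[str]) -> "VirtualArray":
        return VirtualArray(values=self.values.loc[list(genes)], metadata=self.metadata.copy())

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, values_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write values as TSV and metadata as a JSON sidecar.

        The sidecar defaults to ``<values_path>.meta.json``.
        """
        values_path = Path(values_path)
        # %.17g round-trips IEEE doubles exactly
        self.values.to_csv(values_path, sep="\t", index_label="gene", float_format="%.17g")
        meta_path = Path(metadata_path) if metadata_path else values_path.with_suffix(
            values_path.suffix + ".meta.json"
        )
        payload = {
            "samples": {
                s: {k: _jsonable(v) for k, v in row.items()}
                for s, row in self.metadata.to_dict(orient="index").items()
            }
        }
        meta_path.write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_tsv(cls, values_path: str | Path, metadata_path: str | Path | None = None) -> "VirtualArray":
        values_path = Path(values_path)
        values = pd.read_csv(values_path, sep="\t", index_col="gene",
                             float_precision="round_trip")
        meta_path = Path(metadata_path) if metadata_path else values_path.with_suffix(
            values_path.suffix + ".meta.json"
        )
        payload = json.loads(meta_path.read_text())
        metadata = pd.DataFrame.from_dict(payload["samples"], orient="index")
        metadata = metadata.loc[values.columns]
        return cls(values=values, metadata=metadata)


def _jsonable(v):
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


# --------------------------------------------------------------------------
# step: collapse probes to genes


def collapse_probes_to_genes(
    m: ProbeMatrix,
    a: ProbeAnnotation,
    stat: str = "median",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene symbol.

    Each gene's row is the per-sample ``stat`` (median by default, mean as the
    alternative) over all probes annotated to it.  Probes with an empty
    annotation are dropped.  Probes annotated to several genes contribute to
    every one of them (logged).  A gene for which every probe is missing in
    some sample cannot be represented without imputation and is excluded from
    this platform's output (logged with the reason).

    Raises
    ------
    ValueError
        If annotation and matrix platforms differ, ``stat`` is unknown, or no
        probe of the matrix carries an annotation.
    """
    if a.platform_id != m.platform_id:
        raise ValueError(
            f"annotation platform {a.platform_id!r} does not match matrix platform {m.platform_id!r}"
        )
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown collapse statistic {stat!r}")

    gene_to_probes: dict[str, list[str]] = {}
    n_annotated = 0
    for probe, genes in a.mapping.items():
        if probe not in m.values.index:
            logger.warning(
                "platform %s: annotation references probe %r absent from the matrix; ignored",
                m.platform_id, probe,
            )
            continue
        if not genes:
            continue
        n_annotated += 1
        if len(genes) > 1:
            logger.info(
                "platform %s: probe %r maps to %d genes (%s); contributing to all",
                m.platform_id, probe, len(genes), ",".join(sorted(genes)),
            )
        for g in genes:
            gene_to_probes.setdefault(g, []).append(probe)

    if n_annotated == 0:
        raise ValueError(f"platform {m.platform_id!r}: no annotated probe present in the matrix")

    agg = np.nanmedian if stat == "median" else np.nanmean
    rows: dict[str, np.ndarray] = {}
    for gene in sorted(gene_to_probes):
        block = m.values.loc[gene_to_probes[gene]].to_numpy(dtype=float)
        all_missing = np.isnan(block).all(axis=0)
        if all_missing.any():
            bad = [m.sample_ids[i] for i in np.flatnonzero(all_missing)]
            logger.warning(
                "platform %s: gene %r has only missing probes in sample(s) %s; "
                "gene excluded from this platform",
                m.platform_id, gene, ",".join(bad),
            )
            continue
        rows[gene] = agg(block, axis=0)

    out = pd.DataFrame.from_dict(rows, orient="index", columns=m.values.columns)
    out.index.name = "gene"
    return out


# --------------------------------------------------------------------------
# step: match genes common to all platforms


def intersect_genes(gene_sets: Sequence[Iterable[str]]) -> list[str]:
    """Sorted intersection of ≥2 gene sets, logging per-platform losses.

    Raises ``ValueError`` naming the pair of sets with the smallest pairwise
    overlap when the overall intersection is empty.
    """
    sets = [set(s) for s in gene_sets]
    if len(sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    common = set.intersection(*sets)
    if not common:
        worst = min(
            ((i, j) for i in range(len(sets)) for j in range(i + 1, len(sets))),
            key=lambda ij: len(sets[ij[0]] & sets[ij[1]]),
        )
        raise ValueError(
            "empty gene intersection across platforms; smallest pairwise overlap is between "
            f"set {worst[0]} and set {worst[1]} ({len(sets[worst[0]] & sets[worst[1]])} genes)"
        )
    for i, s in enumerate(sets):
        lost = len(s) - len(common)
        logger.info("gene intersection: set %d loses %d of %d genes", i, lost, len(s))
    return sorted(common)


# --------------------------------------------------------------------------
# step: assemble the virtual array


def assemble_virtual_array(
    collapsed: Sequence[pd.DataFrame],
    metadata: pd.DataFrame,
) -> VirtualArray:
    """Column-concatenate per-platform gene-level matrices into a VirtualArray.

    All input matrices must already be restricted to the common gene list in
    identical order (no silent reindexing happens here); sample ids must be
    globally unique and each must have a metadata record.  Columns of the
    result follow the metadata row order.
    """
    if not collapsed:
        raise ValueError("no matrices to assemble")
    ref_genes = list(collapsed[0].index)
    for k, mat in enumerate(collapsed[1:], start=1):
        if list(mat.index) != ref_genes:
            raise ValueError(
                f"gene order mismatch between matrix 0 and matrix {k}; "
                "restrict all matrices to the common gene list first"
            )
    merged = pd.concat(list(collapsed), axis=1)
    if merged.columns.has_duplicates:
        dup = merged.columns[merged.columns.duplicated()][0]
        raise ValueError(f"duplicate sample_id across platforms: {dup!r}")
    missing_meta = [s for s in merged.columns if s not in metadata.index]
    if missing_meta:
        raise ValueError(f"metadata missing for samples: {missing_meta}")
    ordered = [s for s in metadata.index if s in set(merged.columns)]
    merged = merged[ordered]
    return VirtualArray(values=merged, metadata=metadata.loc[ordered].copy())


def build_virtual_array(
    matrices: Sequence[ProbeMatrix],
    annotations: Sequence[ProbeAnnotation],
    metadata: pd.DataFrame,
    stat: str = "median",
) -> VirtualArray:
    """Full integration: collapse each platform, intersect genes, assemble.

    Convenience wrapper running the three steps in order; annotations are
    matched to matrices by platform_id.
    """
    by_platform = {a.platform_id: a for a in annotations}
    collapsed = []
    for m in matrices:
        if m.platform_id not in by_platform:
            raise ValueError(f"no annotation provided for platform {m.platform_id!r}")
        collapsed.append(collapse_probes_to_genes(m, by_platform[m.platform_id], stat=stat))
    if len(collapsed) == 1:
        common = sorted(collapsed[0].index)
    else:
        common = intersect_genes([c.index for c in collapsed])
    restricted = [c.loc[common] for c in collapsed]
    return assemble_virtual_array(restricted, metadata)
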