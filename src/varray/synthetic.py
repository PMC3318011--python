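"""Synthetic multi-platform expression studies, flow-cytometry events, and FISH counts.

The generators produce data with known ground truth for every stage of the
pipeline:

* :func:`generate_multiplatform_study` — probe-level expression matrices from
  several platforms measuring overlapping gene sets, with distinct cell-type
  expression programs, additive/multiplicative per-batch effects, per-platform
  probe multiplicity and affine platform transforms, and shared reference
  samples in every batch (stand-ins for MAQC internal controls).
* :func:`generate_marker_panel_study` — a gene × sample matrix realising a
  surface-marker panel with a chosen +/− pattern plus background genes, to
  exercise the transcript-positivity caller.
* :func:`generate_flow_events` — flow-cytometry event tables with hidden true
  population labels and Gaussian channel models.
* :func:`generate_fish_counts` — interphase-FISH signal counts with a known
  aberrant-cell fraction.

All expression intensities are generated on the log2 scale; a sample's
gene-level value is ``program base + batch gamma + batch delta × N(0, noise_sd)``
and each probe of that gene adds the platform's affine transform plus
independent ``N(0, probe_sd)`` jitter.  Identical seeds reproduce outputs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import json
import numpy as np
import pandas as pd

from .integration import ProbeAnnotation, ProbeMatrix, VirtualArray

__all__ = [
    "ExpressionProgram",
    "PlatformSpec",
    "BatchEffectTruth",
    "SyntheticStudy",
    "generate_multiplatform_study",
    "generate_marker_panel_study",
    "generate_flow_events",
    "generate_fish_counts",
    "make_programs",
    "default_study",
    "SURFACE_MARKER_PANEL",
    "DEFAULT_POPULATION_FRACTIONS",
    "DEFAULT_CHANNEL_MODELS",
    "DEFAULT_GATES",
]


# --------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionProgram:
    """A cell type's expression program.

    ``base_level`` maps every gene of the universe to its expected log2
    intensity in this cell type; ``marker_genes`` names the genes elevated in
    the program (they must appear in ``base_level``).
    """

    name: str
    base_level: dict[str, float]
    marker_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.marker_genes = frozenset(self.marker_genes)
        missing = self.marker_genes - set(self.base_level)
        if missing:
            raise ValueError(f"program {self.name!r}: marker genes missing from base_level: {sorted(missing)}")
        vals = np.fromiter(self.base_level.values(), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"program {self.name!r}: non-finite base levels")


@dataclass
class PlatformSpec:
    """A microarray platform: which genes it measures and how.

    ``probes_per_gene`` is a positive integer applied to all genes or a
    per-gene mapping; ``scale``/``offset`` define the platform's affine
    transform of the (log2) gene value.
    """

    platform_id: str
    measured_genes: frozenset[str]
    probes_per_gene: Union[int, Mapping[str, int]] = 1
    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        self.measured_genes = frozenset(self.measured_genes)
        if not self.measured_genes:
            raise ValueError(f"platform {self.platform_id!r} measures no genes")
        for g in sorted(self.measured_genes):
            if self.n_probes(g) < 1:
                raise ValueError(f"platform {self.platform_id!r}: gene {g!r} needs >=1 probe")

    def n_probes(self, gene: str) -> int:
        if isinstance(self.probes_per_gene, int):
            return self.probes_per_gene
        return int(self.probes_per_gene.get(gene, 1))


def _per_gene(value: Union[float, Mapping[str, float]], genes: Sequence[str], default: float) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([float(value.get(g, default)) for g in genes])
    return np.full(len(genes), float(value))


@dataclass
class BatchEffectTruth:
    """True per-batch location/scale effects of the generative model.

    ``gamma`` is the additive per-gene shift, ``delta`` the multiplicative
    factor on the noise SD (so the per-gene noise variance is
    ``(delta·noise_sd)²``); both accept a scalar or a per-gene mapping.
    ``delta`` must be strictly positive.
    """

    batch_id: str
    gamma: Union[float, Mapping[str, float]] = 0.0
    delta: Union[float, Mapping[str, float]] = 1.0

    def gamma_for(self, genes: Sequence[str]) -> np.ndarray:
        return _per_gene(self.gamma, genes, 0.0)

    def delta_for(self, genes: Sequence[str]) -> np.ndarray:
        d = _per_gene(self.delta, genes, 1.0)
        if np.any(d <= 0):
            raise ValueError(f"batch {self.batch_id!r}: delta must be > 0 for all genes")
        return d


@dataclass
class SyntheticStudy:
    """A generated multi-platform study plus its complete ground truth.

    ``truth`` records the cell type and batch of every sample, the true batch
    effects, the expression programs, and the noise-free / noisy gene-level
    values, so every downstream estimate can be checked against what was
    generated.
    """

    probe_matrices: list[ProbeMatrix]
    annotations: list[ProbeAnnotation]
    metadata: pd.DataFrame
    truth: dict
    seed: int

    def write(self, out_dir: str | Path) -> None:
        """Write probe matrices, annotations, metadata (TSV) and truth (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in self.probe_matrices:
            m.values.to_csv(out / f"{m.platform_id}.probes.tsv", sep="\t", index_label="probe_id")
        for a in self.annotations:
            rows = [(p, g) for p, genes in sorted(a.mapping.items()) for g in sorted(genes)]
            pd.DataFrame(rows, columns=["probe_id", "gene_symbol"]).to_csv(
                out / f"{a.platform_id}.annotation.tsv", sep="\t", index=False
            )
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
        truth = {
            "seed": self.seed,
            "cell_type": self.truth["cell_type"],
            "batch": self.truth["batch"],
            "batch_effects": {
                b: {"gamma": g, "delta": d}
                for b, (g, d) in self.truth["batch_effects_serializable"].items()
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


# --------------------------------------------------------------------------
# multi-platform expression study


def generate_multiplatform_study(
    programs: Sequence[ExpressionProgram],
    platforms: Sequence[PlatformSpec],
    batch_truths: Sequence[BatchEffectTruth],
    n_per_group: int = 5,
    noise_sd: float = 0.5,
    probe_sd: float = 0.25,
    n_reference_per_batch: int = 2,
    reference_program: Optional[ExpressionProgram] = None,
    batch_platform: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate probe-level matrices for several platforms, batches and cell types.

    Each batch is measured on one platform (round-robin assignment unless
    ``batch_platform`` is given) and contains ``n_per_group`` samples of every
    program plus ``n_reference_per_batch`` replicates of one fixed reference
    program shared by all batches (MAQC-style internal controls; defaults to
    the per-gene mean of the supplied programs).

    Gene-level value: ``base + gamma_batch + delta_batch · N(0, noise_sd)``;
    probe-level value: ``scale · gene_value + offset + N(0, probe_sd)``.
    """
    if noise_sd < 0 or probe_sd < 0:
        raise ValueError("noise_sd and probe_sd must be >= 0")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not programs or not platforms or not batch_truths:
        raise ValueError("need at least one program, platform and batch")

    universe = sorted(programs[0].base_level)
    for p in programs[1:]:
        if sorted(p.base_level) != universe:
            raise ValueError(f"program {p.name!r} does not share the gene universe of {programs[0].name!r}")
    for pl in platforms:
        extra = pl.measured_genes - set(universe)
        if extra:
            raise ValueError(f"platform {pl.platform_id!r} measures genes outside the universe: {sorted(extra)[:5]}")
    for i in range(len(platforms)):
        for j in range(i + 1, len(platforms)):
            if not (platforms[i].measured_genes & platforms[j].measured_genes):
                raise ValueError(
                    "platforms share no genes: "
                    f"{platforms[i].platform_id!r} and {platforms[j].platform_id!r}"
                )

    if reference_program is None:
        mean_levels = {
            g: float(np.mean([p.base_level[g] for p in programs])) for g in universe
        }
        reference_program = ExpressionProgram(name="reference", base_level=mean_levels)
    all_programs = list(programs) + [reference_program]

    batch_ids = [b.batch_id for b in batch_truths]
    if len(set(batch_ids)) != len(batch_ids):
        raise ValueError("duplicate batch ids")
    if batch_platform is None:
        batch_platform = {
            b.batch_id: platforms[i % len(platforms)].platform_id
            for i, b in enumerate(batch_truths)
        }
    platform_by_id = {p.platform_id: p for p in platforms}

    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(universe)}

    # draw gene-level values sample by sample in a fixed order
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    gene_values: dict[str, np.ndarray] = {}
    for bt in batch_truths:
        gamma = bt.gamma_for(universe)
        delta = bt.delta_for(universe)
        plat = batch_platform[bt.batch_id]
        for prog in all_programs:
            n = n_reference_per_batch if prog is reference_program else n_per_group
            base = np.array([prog.base_level[g] for g in universe])
            for k in range(n):
                sid = f"{bt.batch_id}_{prog.name}_{k:02d}"
                noise = rng.normal(0.0, noise_sd, size=len(universe)) if noise_sd > 0 else np.zeros(len(universe))
                gene_values[sid] = base + gamma + delta * noise
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "platform": plat, "batch": bt.batch_id, "cell_type": prog.name}
                )

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    probe_matrices: list[ProbeMatrix] = []
    annotations: list[ProbeAnnotation] = []
    for pl in platforms:
        cols = [s for s in sample_ids if metadata.loc[s, "platform"] == pl.platform_id]
        if not cols:
            continue
        genes = sorted(pl.measured_genes)
        probe_ids: list[str] = []
        mapping: dict[str, frozenset[str]] = {}
        for g in genes:
            for j in range(pl.n_probes(g)):
                pid = f"{g}__p{j+1}"
                probe_ids.append(pid)
                mapping[pid] = frozenset([g])
        rows = np.empty((len(probe_ids), len(cols)))
        for cj, s in enumerate(cols):
            gv = gene_values[s]
            r = 0
            for g in genes:
                val = pl.scale * gv[gene_index[g]] + pl.offset
                k = pl.n_probes(g)
                jitter = rng.normal(0.0, probe_sd, size=k) if probe_sd > 0 else np.zeros(k)
                rows[r : r + k, cj] = val + jitter
                r += k
        probe_matrices.append(
            ProbeMatrix(platform_id=pl.platform_id, values=pd.DataFrame(rows, index=probe_ids, columns=cols))
        )
        annotations.append(ProbeAnnotation(platform_id=pl.platform_id, mapping=mapping))

    truth = {
        "cell_type": {s: metadata.loc[s, "cell_type"] for s in sample_ids},
        "batch": {s: metadata.loc[s, "batch"] for s in sample_ids},
        "batch_truths": list(batch_truths),
        "batch_effects_serializable": {
            bt.batch_id: (
                dict(zip(universe, bt.gamma_for(universe).tolist())),
                dict(zip(universe, bt.delta_for(universe).tolist())),
            )
            for bt in batch_truths
        },
        "programs": all_programs,
        "reference_program": reference_program.name,
        "gene_values": pd.DataFrame(
            {s: gene_values[s] for s in sample_ids}, index=universe
        ),
        "noise_sd": noise_sd,
        "probe_sd": probe_sd,
    }
    return SyntheticStudy(
        probe_matrices=probe_matrices,
        annotations=annotations,
        metadata=metadata,
        truth=truth,
        seed=seed,
    )


# --------------------------------------------------------------------------
# marker-panel study

#: 22-marker surface panel with its transcript-level +/− pattern
#: (CD184 is the CXCR4 gene symbol; CD56 carries the PSA-NCAM epitope)
SURFACE_MARKER_PANEL: dict[str, str] = {
    "MSCA-1": "−", "SSEA-3": "−", "SSEA-4": "−", "Tra-1-81": "−", "CD15": "−",
    "CD31": "+", "CD34": "−", "CD38": "−", "CD48": "−", "CD56": "−",
    "CD84": "+", "CD90": "−", "CD105": "−", "CD133": "−", "CD140a": "−",
    "CD144": "−", "CD184": "+", "CD243": "−", "CD244": "−", "CD271": "−",
    "CD324": "−", "CD338": "−",
}


def generate_marker_panel_study(
    marker_table: Union[Mapping[str, str], Sequence[tuple[str, str]]],
    n_background_genes: int = 500,
    pos_level: float = 10.0,
    neg_level: float = 6.0,
    level_sd: float = 0.25,
    baseline_sd: float = 1.0,
    n_samples: int = 6,
    seed: int = 0,
) -> VirtualArray:
    """Gene × sample matrix realising a +/− marker panel over a background.

    Genes marked ``+`` sit at ``pos_level``, genes marked ``−`` at
    ``neg_level`` (log2 units); each of the ``n_background_genes`` background
    genes gets its own baseline drawn around ``neg_level`` with SD
    ``baseline_sd``, emulating the several-log2-unit gene-to-gene spread of a
    real transcriptome that defines the array-wide outlier fence.  Per-sample
    replicate noise is Gaussian with SD ``level_sd``.  Used to exercise the
    positivity caller.
    """
    if not isinstance(marker_table, Mapping):
        pairs = list(marker_table)
        names = [g for g, _ in pairs]
        if len(set(names)) != len(names):
            dup = sorted({g for g in names if names.count(g) > 1})
            raise ValueError(f"duplicate gene symbols in marker table: {dup}")
        marker_table = dict(pairs)
    if not marker_table:
        raise ValueError("marker table is empty")
    bad = {g: c for g, c in marker_table.items() if c not in ("+", "-", "−")}
    if bad:
        raise ValueError(f"marker calls must be '+' or '−', got {bad}")
    if pos_level <= neg_level:
        raise ValueError("pos_level must exceed neg_level")
    if n_background_genes < 0:
        raise ValueError("n_background_genes must be >= 0")

    rng = np.random.default_rng(seed)
    genes: list[str] = []
    levels: list[float] = []
    for g, call in marker_table.items():
        genes.append(g)
        levels.append(pos_level if call == "+" else neg_level)
    i = 0
    while len(genes) < len(marker_table) + n_background_genes:
        name = f"BG{i:04d}"
        i += 1
        if name in marker_table:
            continue
        genes.append(name)
        levels.append(neg_level + rng.normal(0.0, baseline_sd))

    values = rng.normal(np.array(levels)[:, None], level_sd, size=(len(genes), n_samples))
    sample_ids = [f"S{k+1:02d}" for k in range(n_samples)]
    metadata = pd.DataFrame(
        {
            "platform": "synthetic",
            "batch": "b1",
            "cell_type": "vsel",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return VirtualArray(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        metadata=metadata,
    )


# --------------------------------------------------------------------------
# flow-cytometry events

from .phenotype import CHANNELS, Gate  # noqa: E402  (shared channel schema)

#: population mix of a lineage-depleted cord-blood preparation: a CD34+CD45dim
#: progenitor population (~33%), CD34− VSEL-like events (~22%), a rare CD34+
#: VSEL-like subset (~0.76%), and remaining mature lymphocytes
DEFAULT_POPULATION_FRACTIONS: dict[str, float] = {
    "cd34_cd45dim": 0.33,
    "vsel": 0.22,
    "vsel_cd34pos": 0.0076,
    "other": 1.0 - 0.33 - 0.22 - 0.0076,
}

#: Gaussian (mean, sd) channel models per population, arbitrary linear units.
#: VSEL-like events carry twice the Hoechst 33342 signal of the progenitors,
#: are CD45−Lin−CXCR4+, and have lower side scatter.
DEFAULT_CHANNEL_MODELS: dict[str, dict[str, tuple[float, float]]] = {
    "cd34_cd45dim": {
        "PI": (20, 10), "Hoechst-A": (200, 20), "Hoechst-W": (100, 10),
        "SSC-A": (150, 20), "CD45": (200, 20), "Lin": (50, 10),
        "CXCR4": (80, 15), "CD34": (300, 30),
    },
    "vsel": {
        "PI": (20, 10), "Hoechst-A": (400, 40), "Hoechst-W": (100, 10),
        "SSC-A": (100, 15), "CD45": (40, 10), "Lin": (40, 10),
        "CXCR4": (300, 30), "CD34": (40, 10),
    },
    "vsel_cd34pos": {
        "PI": (20, 10), "Hoechst-A": (400, 40), "Hoechst-W": (100, 10),
        "SSC-A": (100, 15), "CD45": (40, 10), "Lin": (40, 10),
        "CXCR4": (300, 30), "CD34": (300, 30),
    },
    "other": {
        "PI": (20, 10), "Hoechst-A": (200, 20), "Hoechst-W": (100, 10),
        "SSC-A": (150, 20), "CD45": (400, 40), "Lin": (300, 30),
        "CXCR4": (80, 15), "CD34": (40, 10),
    },
}

#: sequential gating hierarchy: live nucleated singlets, then population gates
DEFAULT_GATES: dict[str, list[Gate]] = {
    "denominator": [  # living (PI−) nucleated singlet non-granulocyte events
        Gate("PI", "below", 100),
        Gate("Hoechst-A", "above", 100),
        Gate("Hoechst-W", "below", 150),
        Gate("SSC-A", "below", 300),
    ],
    "cd34_cd45dim": [
        Gate("CD45", "above", 100), Gate("CD45", "below", 300),
        Gate("Lin", "below", 100), Gate("CD34", "above", 200),
    ],
    "vsel": [
        Gate("CD45", "below", 100), Gate("Lin", "below", 100),
        Gate("CXCR4", "above", 200), Gate("CD34", "below", 200),
    ],
    "vsel_cd34pos": [
        Gate("CD45", "below", 100), Gate("Lin", "below", 100),
        Gate("CXCR4", "above", 200), Gate("CD34", "above", 200),
    ],
}


def generate_flow_events(
    population_fractions: Mapping[str, float],
    channel_models: Mapping[str, Mapping[str, tuple[float, float]]],
    n_events: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table with hidden true population labels.

    Each event gets a label drawn from ``population_fractions`` and Gaussian
    channel values from that population's model.  Fractions must lie in
    [0, 1] and sum to 1 (±1e-9).
    """
    labels = sorted(population_fractions)
    fracs = np.array([population_fractions[l] for l in labels], dtype=float)
    if np.any((fracs < 0) | (fracs > 1)):
        raise ValueError("population fractions must lie in [0, 1]")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {fracs.sum()!r}, not 1")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    for l in labels:
        missing = set(CHANNELS) - set(channel_models.get(l, {}))
        if missing:
            raise ValueError(f"population {l!r} lacks channel model(s) for {sorted(missing)}")

    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(labels), size=n_events, p=fracs)
    data = {ch: np.empty(n_events) for ch in CHANNELS}
    for li, l in enumerate(labels):
        idx = np.flatnonzero(drawn == li)
        for ch in CHANNELS:
            mean, sd = channel_models[l][ch]
            data[ch][idx] = rng.normal(mean, sd, size=len(idx))
    table = pd.DataFrame(data)
    table["true_label"] = [labels[i] for i in drawn]
    return table


# --------------------------------------------------------------------------
# FISH counts

from .phenotype import FishCell  # noqa: E402

#: signal counts observed in aberrant nuclei (anything but the disomic 2)
ABERRANT_COUNTS = (0, 1, 3, 4)


def generate_fish_counts(
    n_cells: int,
    aberrant_fraction: float,
    n_probes: int = 2,
    seed: int = 0,
) -> list[FishCell]:
    """FISH count sets with a known aberrant fraction.

    Normal cells show exactly two signals for every probe; aberrant cells have
    at least one probe whose count is drawn from {0, 1, 3, 4} (each remaining
    probe is aberrant with probability ½), so all counts lie in 0–4.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0.0 <= aberrant_fraction <= 1.0:
        raise ValueError("aberrant_fraction must lie in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    cells: list[FishCell] = []
    for _ in range(n_cells):
        if rng.random() < aberrant_fraction:
            counts = np.full(n_probes, 2, dtype=int)
            n_aberrant = 1 + rng.binomial(n_probes - 1, 0.5)
            which = rng.choice(n_probes, size=n_aberrant, replace=False)
            counts[which] = rng.choice(ABERRANT_COUNTS, size=n_aberrant)
            cells.append(FishCell(counts=tuple(int(c) for c in counts)))
        else:
            cells.append(FishCell(counts=(2,) * n_probes))
    return cells


# --------------------------------------------------------------------------
# canonical study conditions


def make_programs(
    names: Sequence[str],
    n_genes: int = 300,
    markers_per_program: int = 30,
    base_mean: float = 7.0,
    base_sd: float = 1.0,
    marker_boost: float = 3.0,
    seed: int = 0,
) -> list[ExpressionProgram]:
    """Build cell-type programs over a shared gene universe.

    A common baseline of per-gene log2 levels ~ N(base_mean, base_sd) is drawn
    once; each program elevates its own disjoint block of
    ``markers_per_program`` genes by ``marker_boost`` log2 units.
    """
    if markers_per_program * len(names) > n_genes:
        raise ValueError("gene universe too small for the requested marker blocks")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    baseline = rng.normal(base_mean, base_sd, size=n_genes)
    programs = []
    for pi, name in enumerate(names):
        markers = genes[pi * markers_per_program : (pi + 1) * markers_per_program]
        levels = dict(zip(genes, baseline.tolist()))
        for m in markers:
            levels[m] += marker_boost
        programs.append(
            ExpressionProgram(name=name, base_level=levels, marker_genes=frozenset(markers))
        )
    return programs


def default_study(seed: int = 0, n_per_group: int = 5) -> SyntheticStudy:
    """The canonical desk-scale study: 3 programs × 2 platforms × 2 batches.

    300-gene universe; platform A measures every gene with 2 probes, platform
    B measures 280 of them with 1 probe; batch b2 carries a strong per-gene
    additive shift (~N(2, 2) log2 units — the gene-to-gene spread survives
    quantile normalization) and 1.5× noise scale, so uncorrected data group
    by batch while corrected data group by cell type.  Two reference
    replicates per batch act as cross-platform internal controls.
    """
    master = np.random.default_rng(seed)
    s_prog, s_gamma, s_study = (int(x) for x in master.integers(0, 2**31 - 1, size=3))
    programs = make_programs(
        ["pluripotent", "hematopoietic", "vsel_like"], n_genes=300, seed=s_prog
    )
    genes = sorted(programs[0].base_level)
    gamma_rng = np.random.default_rng(s_gamma)
    gamma_b2 = dict(zip(genes, gamma_rng.normal(2.0, 2.0, size=len(genes)).tolist()))
    platforms = [
        PlatformSpec("platformA", frozenset(genes), probes_per_gene=2),
        PlatformSpec("platformB", frozenset(genes[:280]), probes_per_gene=1,
                     scale=1.0, offset=0.5),
    ]
    batches = [
        BatchEffectTruth("b1", gamma=0.0, delta=1.0),
        BatchEffectTruth("b2", gamma=gamma_b2, delta=1.5),
    ]
    return generate_multiplatform_study(
        programs, platforms, batches,
        n_per_group=n_per_group, noise_sd=0.5, probe_sd=0.25, seed=s_study,
    )
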