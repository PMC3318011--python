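"""Cytometry and cytogenetics scoring.

Event-level flow-cytometry analysis (sequential threshold gating, population
frequencies), density-gradient recovery arithmetic, fluorescence-ratio and
cell-size comparisons, and interphase-FISH ploidy classification.

Event tables are pandas DataFrames with a fixed channel schema
(:data:`CHANNELS`) plus an optional ``true_label`` column carried by
synthetic data.  Gate thresholds are configuration values — gates are set
manually on cytometry plots in practice, so nothing is learned here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .downstream import interpolated_quartiles

__all__ = [
    "CHANNELS",
    "Gate",
    "GateSpec",
    "FishCell",
    "gate_events",
    "population_frequency",
    "ficoll_recovery",
    "fluorescence_ratio",
    "five_number_summary",
    "compare_sizes",
    "classify_fish",
]

#: fixed channel schema for event tables
CHANNELS = ("PI", "Hoechst-A", "Hoechst-W", "SSC-A", "CD45", "Lin", "CXCR4", "CD34")


@dataclass(frozen=True)
class Gate:
    """One threshold gate: keep events with channel value strictly above/below."""

    channel: str
    side: str  # "above" | "below"
    threshold: float

    def __post_init__(self):
        if self.side not in ("above", "below"):
            raise ValueError(f"gate side must be 'above' or 'below', got {self.side!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")

    def mask(self, t: pd.DataFrame) -> np.ndarray:
        if self.channel not in t.columns:
            raise ValueError(f"unknown channel {self.channel!r}; known: {list(t.columns)}")
        col = t[self.channel].to_numpy(dtype=float)
        return col > self.threshold if self.side == "above" else col < self.threshold


#: a gating sequence is just an ordered list of Gates applied conjunctively
GateSpec = Sequence[Gate]


def gate_events(t: pd.DataFrame, gates: GateSpec) -> tuple[pd.DataFrame, list[dict]]:
    """Apply threshold gates in order; return survivors and a retention report.

    The report lists, per gate, the number of events remaining after it.
    Conjunctive threshold gates commute, so the surviving set does not depend
    on gate order (only the intermediate counts do).
    """
    kept = np.ones(len(t), dtype=bool)
    report = [{"gate": "input", "remaining": int(len(t))}]
    for g in gates:
        kept &= g.mask(t)
        report.append(
            {"gate": f"{g.channel} {g.side} {g.threshold:g}", "remaining": int(kept.sum())}
        )
    return t.loc[kept], report


def population_frequency(
    t: pd.DataFrame,
    gates_by_population: Mapping[str, GateSpec],
    denominator: GateSpec,
) -> dict[str, float]:
    """Fraction of denominator-gated events falling in each population gate.

    Population gates are applied on top of the denominator gate, so disjoint
    exhaustive populations have fractions summing to 1.
    """
    denom, _ = gate_events(t, denominator)
    if len(denom) == 0:
        raise ValueError("denominator gate retains no events")
    out: dict[str, float] = {}
    for label, gates in gates_by_population.items():
        sub, _ = gate_events(denom, gates)
        out[label] = len(sub) / len(denom)
    return out


def ficoll_recovery(interphase_count: int, pellet_count: int) -> dict[str, float]:
    """Recovery fractions for a density-gradient separation.

    For a population conventionally recovered from the interphase, cells that
    sediment into the pellet are lost to the standard protocol, so
    ``loss_fraction`` equals the pellet fraction of all recovered cells.
    Fractions sum to one exactly; losses to the gradient itself are not
    modelled.
    """
    if interphase_count < 0 or pellet_count < 0:
        raise ValueError("counts must be non-negative")
    total = interphase_count + pellet_count
    if total == 0:
        raise ValueError("at least one compartment must contain cells")
    interphase_fraction = interphase_count / total
    return {
        "interphase_fraction": interphase_fraction,
        "pellet_fraction": 1.0 - interphase_fraction,
        "loss_fraction": 1.0 - interphase_fraction,
    }


def fluorescence_ratio(t1: pd.DataFrame, t2: pd.DataFrame, channel: str) -> float:
    """Ratio of per-population medians of one channel (t1 over t2)."""
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both event tables must be non-empty")
    for t in (t1, t2):
        if channel not in t.columns:
            raise ValueError(f"unknown channel {channel!r}")
    denom = float(np.median(t2[channel].to_numpy(dtype=float)))
    if denom == 0:
        raise ValueError(f"median of {channel!r} in the reference population is zero")
    return float(np.median(t1[channel].to_numpy(dtype=float))) / denom


def five_number_summary(values: Sequence[float]) -> dict[str, float]:
    """Skeletal box-plot summary: median, Q1, Q3, min, max (interpolated quartiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("empty sample")
    q1, q3 = interpolated_quartiles(arr)
    return {
        "median": float(np.median(arr)),
        "q1": q1,
        "q3": q3,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def compare_sizes(
    diameters_a: Sequence[float], diameters_b: Sequence[float]
) -> dict:
    """Compare two cell-diameter samples (µm).

    Returns skeletal box-plot summaries per group and two-sided p-values from
    both Student's t-test and the Mann-Whitney test.
    """
    a = np.asarray(list(diameters_a), dtype=float)
    b = np.asarray(list(diameters_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two measurements")
    t_p = float(scipy.stats.ttest_ind(a, b).pvalue)
    u_p = float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "summary_a": five_number_summary(a),
        "summary_b": five_number_summary(b),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "t_test_p": t_p,
        "mann_whitney_p": u_p,
    }


# --------------------------------------------------------------------------
# interphase FISH


@dataclass(frozen=True)
class FishCell:
    """Per-cell FISH signal counts, one non-negative integer per probe.

    A cell is euploid at the interrogated loci ("normal") iff every probe
    shows exactly two signals.
    """

    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) < 1:
            raise ValueError("a FISH cell needs at least one probe count")
        if any((c < 0 or int(c) != c) for c in self.counts):
            raise ValueError(f"counts must be non-negative integers, got {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def classification(self) -> str:
        return "normal" if all(c == 2 for c in self.counts) else "aberrant"


def classify_fish(cells: Sequence[FishCell]) -> dict:
    """Score a set of FISH-probed cells.

    Returns the aberrant fraction (any probe count ≠ 2) and, per probe, the
    histogram of signal counts.
    """
    if len(cells) == 0:
        raise ValueError("no cells to classify")
    n_probes = len(cells[0].counts)
    if any(len(c.counts) != n_probes for c in cells):
        raise ValueError("all cells must have the same number of probes")
    aberrant = sum(1 for c in cells if c.classification == "aberrant")
    hist: list[dict[int, int]] = []
    for p in range(n_probes):
        counts: dict[int, int] = {}
        for c in cells:
            counts[c.counts[p]] = counts.get(c.counts[p], 0) + 1
        hist.append(dict(sorted(counts.items())))
    return {
        "n_cells": len(cells),
        "aberrant_fraction": aberrant / len(cells),
        "per_probe_histogram": hist,
    }
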