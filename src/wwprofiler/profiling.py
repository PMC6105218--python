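"""Sample-level summaries: matrix effects, stage-wise removal, mass/RT
distributions, and persistence-based pollution-marker selection.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screen import DetectionMatrix

__all__ = ["MatrixEffectResult", "RemovalSummary", "MassClassHistogram",
           "matrix_effect", "matrix_effect_table", "removal_rates",
           "mass_rt_profile", "select_markers", "MASS_CLASS_EDGES"]

#: Half-open mass-class bins, Da: low [100, 500), medium [500, 1000), high [1000, inf)
MASS_CLASS_EDGES = (100.0, 500.0, 1000.0)
MASS_CLASS_LABELS = ("low_100_500", "medium_500_1000", "high_above_1000")


def matrix_effect(a_matrix: float, a_solvent: float) -> float:
    """Matrix effect ME% = (A_matrix / A_solvent - 1) * 100.

    ``a_matrix`` must already be background-subtracted (the analyte signal
    natively present in the extract removed).  Negative values are ion
    suppression, positive values enhancement.
    """
    if a_solvent <= 0:
        raise ValueError("A_solvent must be positive")
    return (a_matrix / a_solvent - 1.0) * 100.0


@dataclass
class MatrixEffectResult:
    compound: str
    a_matrix: float          # mean over replicates
    a_solvent: float         # mean over replicates
    me_pct: float            # ME% of the replicate means
    me_sd_pct: float         # SD of per-replicate ME%
    n_replicates: int


def matrix_effect_table(pairs: Iterable[tuple[str, float, float]]) -> pd.DataFrame:
    """Aggregate replicate (compound, A_matrix, A_solvent) pairs.

    Replicate areas are averaged before applying the ME formula; the SD of
    the per-replicate ME% values is reported alongside.
    """
    df = pd.DataFrame(pairs, columns=["compound", "a_matrix", "a_solvent"])
    if df.empty:
        return pd.DataFrame(columns=["compound", "a_matrix", "a_solvent",
                                     "me_pct", "me_sd_pct", "n_replicates"])
    rows = []
    for name, grp in df.groupby("compound", sort=True):
        per_rep = [matrix_effect(m, s) for m, s in zip(grp.a_matrix, grp.a_solvent)]
        rows.append(MatrixEffectResult(
            compound=name, a_matrix=float(grp.a_matrix.mean()),
            a_solvent=float(grp.a_solvent.mean()),
            me_pct=matrix_effect(grp.a_matrix.mean(), grp.a_solvent.mean()),
            me_sd_pct=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
            n_replicates=len(per_rep)))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class RemovalSummary:
    """Feature counts per treatment stage and removal percentages.

    ``removal_vs_previous[i]`` is the removal from stage i-1 to stage i
    (first entry None); ``removal_vs_first[i]`` is cumulative removal
    relative to the first stage.  An entry is None when its reference count
    is zero (undefined).
    """

    polarity: str | None
    stages: tuple[str, ...]
    counts: tuple[int, ...]
    removal_vs_previous: tuple[float | None, ...]
    removal_vs_first: tuple[float | None, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": self.stages, "count": self.counts,
            "removal_vs_previous_pct": self.removal_vs_previous,
            "removal_vs_first_pct": self.removal_vs_first,
            "polarity": self.polarity})


def removal_rates(counts: Sequence[int],
                  stages: Sequence[str] | None = None,
                  polarity: str | None = None) -> RemovalSummary:
    """Removal percentages from per-stage feature counts.

    removal% = 100 * (1 - count_after / count_before), exact arithmetic.
    """
    counts = [int(c) for c in counts]
    if len(counts) < 2:
        raise ValueError("need at least two stages")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    stages = tuple(stages) if stages is not None else tuple(
        f"stage_{i}" for i in range(len(counts)))
    if len(stages) != len(counts):
        raise ValueError("stages and counts length mismatch")

    def _rm(before: int, after: int) -> float | None:
        if before == 0:
            return None
        return 100.0 * (1.0 - after / before)

    prev = (None,) + tuple(_rm(a, b) for a, b in zip(counts, counts[1:]))
    first = (None,) + tuple(_rm(counts[0], c) for c in counts[1:])
    return RemovalSummary(polarity=polarity, stages=stages,
                          counts=tuple(counts), removal_vs_previous=prev,
                          removal_vs_first=first)


@dataclass
class MassClassHistogram:
    """Counts in the three fixed molecular-weight classes (half-open bins)."""

    low: int        # [100, 500) Da
    medium: int     # [500, 1000) Da
    high: int       # [1000, inf) Da

    @property
    def total(self) -> int:
        return self.low + self.medium + self.high

    def as_dict(self) -> dict[str, int]:
        return dict(zip(MASS_CLASS_LABELS, (self.low, self.medium, self.high)))


def mass_rt_profile(masses: Sequence[float], rts: Sequence[float],
                    mass_edges: np.ndarray | None = None,
                    rt_edges: np.ndarray | None = None
                    ) -> tuple[pd.DataFrame, MassClassHistogram]:
    """2-D mass x RT histogram plus the fixed mass-class counts.

    Default grid: 100 Da x 2 min bins over 100-1700 Da / 0-26 min.  Masses
    below 100 Da fall outside every mass class.
    """
    masses = np.asarray(list(masses), dtype=float)
    rts = np.asarray(list(rts), dtype=float)
    if masses.shape != rts.shape:
        raise ValueError("masses and rts must have equal length")
    if mass_edges is None:
        mass_edges = np.arange(100.0, 1800.0, 100.0)
    if rt_edges is None:
        rt_edges = np.arange(0.0, 28.0, 2.0)
    if masses.size:
        hist, _, _ = np.histogram2d(masses, rts, bins=[mass_edges, rt_edges])
    else:
        hist = np.zeros((len(mass_edges) - 1, len(rt_edges) - 1))
    grid = pd.DataFrame(
        hist.astype(int),
        index=[f"[{a:g},{b:g})" for a, b in zip(mass_edges, mass_edges[1:])],
        columns=[f"[{a:g},{b:g})" for a, b in zip(rt_edges, rt_edges[1:])])
    grid.index.name = "mass_da"
    grid.columns.name = "rt_min"
    lo, mid, hi = MASS_CLASS_EDGES
    classes = MassClassHistogram(
        low=int(np.sum((masses >= lo) & (masses < mid))),
        medium=int(np.sum((masses >= mid) & (masses < hi))),
        high=int(np.sum(masses >= hi)))
    return grid, classes


def select_markers(matrix: DetectionMatrix,
                   effluent_stage: str = "effluent") -> list[str]:
    """Effluent-persistent pollution markers: compounds detected in the
    final (effluent) stage under at least one extraction protocol."""
    stage_df = matrix.stage_columns(effluent_stage)
    if stage_df.shape[1] == 0:
        raise ValueError(f"no columns for stage {effluent_stage!r}")
    return sorted(stage_df.index[stage_df.any(axis=1)])
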