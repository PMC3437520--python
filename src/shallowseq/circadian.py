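"""Entropy of transcript subsets across a circadian time course.

Genes reshuffle their expression rank over a circadian cycle, so the
information captured by a top-N subset must be assessed per time point,
with the ranking recomputed at every CT (circadian time) hour.  Two
grouping schemes are supported: an externally supplied co-expression
module assignment, and CT phase groups — genes binned by the CT hour of
their peak expression (24 groups at 1 h width, 96 at 0.25 h).  Beyond
the entropy trajectory itself, the module provides a one-way ANOVA for
the time effect on entropy, and the reconstruction of each CT group's
mean-expression oscillation from subsets, scored by Pearson correlation
against the full-transcriptome trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import (
    EntropyResult,
    GroupAssignment,
    ValidationError,
    rank_genes,
    subset_entropy,
    top_subset,
)

__all__ = [
    "TimeCourseMatrix",
    "PhaseAssignment",
    "EntropyTrajectory",
    "GroupTrajectory",
    "ct_group_assign",
    "timepoint_entropy",
    "entropy_trajectory",
    "time_effect_anova",
    "group_trajectory",
    "oscillation_fidelity",
]


@dataclass(frozen=True)
class TimeCourseMatrix:
    """Genes x samples expression with CT-hour time labels per column.

    ``data`` columns are samples; ``times[j]`` is the CT hour of column
    j and ``replicates[j]`` its replicate index (all zeros when the
    design is unreplicated).  Values must be finite and non-negative.
    """

    data: pd.DataFrame
    times: tuple[float, ...]
    replicates: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.times):
            raise ValidationError("one time label required per column")
        if self.replicates is not None and len(self.replicates) != len(self.times):
            raise ValidationError("one replicate index required per column")
        if len(set(self.times)) < 2:
            raise ValidationError("need at least 2 distinct time points")
        if list(self.times) != sorted(self.times):
            raise ValidationError("time labels must be non-decreasing")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValidationError("expression values must be finite and >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def unique_times(self) -> list[float]:
        return sorted(set(self.times))

    def column_profile(self, time: float) -> dict[str, float]:
        """Per-gene expression at one time point, replicates averaged."""
        cols = [j for j, t in enumerate(self.times) if t == time]
        if not cols:
            raise ValidationError(f"no column at CT {time}")
        return dict(self.data.iloc[:, cols].mean(axis=1))

    def replicate_profiles(self, time: float) -> list[dict[str, float]]:
        cols = [j for j, t in enumerate(self.times) if t == time]
        return [dict(self.data.iloc[:, [j]].iloc[:, 0]) for j in cols]


@dataclass(frozen=True)
class PhaseAssignment:
    """Gene -> peak phase in CT hours, values in [0, 24)."""

    phases: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, p in self.phases.items():
            if not (0.0 <= p < 24.0) or not math.isfinite(p):
                raise ValidationError(f"phase for {g!r} must be in [0, 24), got {p}")


@dataclass(frozen=True)
class EntropyTrajectory:
    """Entropy and fraction-of-full per (CT time, subset size) cell."""

    table: pd.DataFrame  # columns: time, subset_size, entropy_bits, fraction_of_full

    def cell(self, time: float, size: int) -> tuple[float, float]:
        row = self.table[
            (self.table["time"] == time) & (self.table["subset_size"] == size)
        ]
        if row.empty:
            raise KeyError((time, size))
        return float(row["entropy_bits"].iloc[0]), float(row["fraction_of_full"].iloc[0])


@dataclass(frozen=True)
class GroupTrajectory:
    """Mean expression of subset-and-group intersections over time.

    ``values[(group, size)]`` is an array over ``times``; NaN marks time
    points where the top-``size`` subset contains no member of the group.
    """

    times: tuple[float, ...]
    sizes: tuple[int, ...]
    groups: tuple[str, ...]
    values: Mapping[tuple[str, int], np.ndarray]

    def series(self, group: str, size: int) -> np.ndarray:
        return self.values[(group, size)]


def ct_group_assign(
    phases: PhaseAssignment | Mapping[str, float], bin_width_hours: float = 1.0
) -> GroupAssignment:
    """Bin peak phases into CT groups of the given width.

    The width must divide 24 h; labels are the integers 0..24/width - 1
    (as strings), with phases wrapped modulo 24.  A 1 h width yields 24
    possible groups, 0.25 h yields 96.
    """
    if not isinstance(phases, PhaseAssignment):
        phases = PhaseAssignment(phases)
    if bin_width_hours <= 0:
        raise ValidationError("bin width must be positive")
    n_bins = 24.0 / bin_width_hours
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError(f"bin width {bin_width_hours} h does not divide 24 h")
    membership = {
        g: str(int((p % 24.0) // bin_width_hours)) for g, p in phases.phases.items()
    }
    return GroupAssignment(membership)


def timepoint_entropy(
    matrix: TimeCourseMatrix,
    assignment: GroupAssignment,
    n: int,
    *,
    include_unassigned: bool = False,
) -> list[tuple[float, EntropyResult]]:
    """Subset entropy at each time point, ranking recomputed per column.

    Replicate columns are averaged before ranking.  Failures are
    reported with the offending CT label.
    """
    out = []
    for t in matrix.unique_times:
        profile = matrix.column_profile(t)
        try:
            res = subset_entropy(
                profile, assignment, n, include_unassigned=include_unassigned
            )
        except ValidationError as e:
            raise ValidationError(f"CT {t}: {e}") from e
        out.append((t, res))
    return out


def entropy_trajectory(
    matrix: TimeCourseMatrix,
    assignment: GroupAssignment,
    sizes: Sequence[int],
    *,
    include_unassigned: bool = False,
) -> EntropyTrajectory:
    """Grid of per-time-point entropies with per-time-point fractions.

    The fraction denominator is each time point's own full-set entropy
    (constant over time for a fixed assignment, since the membership
    distribution does not depend on the ranking at full size).
    """
    n_total = len(matrix.genes)
    grid = sorted({min(int(s), n_total) for s in sizes} | {n_total})
    rows = []
    for t in matrix.unique_times:
        profile = matrix.column_profile(t)
        full = subset_entropy(
            profile, assignment, n_total, include_unassigned=include_unassigned
        ).entropy_bits
        for s in grid:
            h = subset_entropy(
                profile, assignment, s, include_unassigned=include_unassigned
            ).entropy_bits
            rows.append(
                {
                    "time": t,
                    "subset_size": s,
                    "entropy_bits": h,
                    "fraction_of_full": h / full if full > 0 else 1.0,
                }
            )
    return EntropyTrajectory(table=pd.DataFrame(rows))


def time_effect_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from its sums-of-squares definition.

    ``groups`` holds the replicate entropies of each time point.  The F
    statistic is the ratio of between- to within-group mean squares; the
    p value is the upper tail of the F distribution on (k-1, N-k)
    degrees of freedom.  All-identical data gives F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups (time points)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValidationError(
                f"group {i} has {a.size} replicate(s); >= 2 required for "
                "within-group variance"
            )
    grand = np.concatenate(arrays).mean()
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    msb = ss_between / df_b
    msw = ss_within / df_w
    if msw == 0.0:
        if msb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def group_trajectory(
    matrix: TimeCourseMatrix,
    ct_groups: GroupAssignment,
    sizes: Sequence[int],
) -> GroupTrajectory:
    """Mean expression of each CT group's members inside per-time top subsets.

    For each time point the top subset is recomputed from that column's
    ranking, then each group's mean is taken over subset members only.
    At full size this reproduces the plain per-group means.
    """
    n_total = len(matrix.genes)
    grid = tuple(sorted({min(int(s), n_total) for s in sizes} | {n_total}))
    times = tuple(matrix.unique_times)
    groups = tuple(sorted(ct_groups.groups(), key=lambda g: (len(g), g)))
    members: dict[str, list[str]] = {g: [] for g in groups}
    for gene, lab in ct_groups.membership.items():
        members[lab].append(gene)
    values: dict[tuple[str, int], np.ndarray] = {
        (g, s): np.full(len(times), np.nan) for g in groups for s in grid
    }
    for ti, t in enumerate(times):
        profile = matrix.column_profile(t)
        ranked = rank_genes(profile)
        for s in grid:
            subset = top_subset(ranked, s)
            for g in groups:
                inside = [profile[m] for m in members[g] if m in subset]
                if inside:
                    values[(g, s)][ti] = float(np.mean(inside))
    return GroupTrajectory(times=times, sizes=grid, groups=groups, values=values)


def oscillation_fidelity(
    sub: GroupTrajectory,
    full: GroupTrajectory,
    *,
    sub_size: int | None = None,
    full_size: int | None = None,
) -> dict[str, float | None]:
    """Per-group Pearson correlation between subset and full trajectories.

    Defaults compare the smallest size of ``sub`` against the largest of
    ``full``.  Correlations use the time points where both series are
    defined; groups with a constant series (zero variance) are returned
    as None rather than 0, and fewer than 3 shared points is an error.
    """
    if sub.times != full.times:
        raise ValidationError("trajectories must share the same time grid")
    if sub_size is None:
        sub_size = min(sub.sizes)
    if full_size is None:
        full_size = max(full.sizes)
    out: dict[str, float | None] = {}
    for g in sorted(set(sub.groups) & set(full.groups), key=lambda g: (len(g), g)):
        a = sub.series(g, sub_size)
        b = full.series(g, full_size)
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < 3:
            raise ValidationError(
                f"group {g!r}: only {int(mask.sum())} shared time points (< 3)"
            )
        av, bv = a[mask], b[mask]
        if np.ptp(av) == 0 or np.ptp(bv) == 0:
            out[g] = None
            continue
        out[g] = float(np.corrcoef(av, bv)[0, 1])
    return out
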