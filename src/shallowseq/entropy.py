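"""Shannon entropy of group membership among top-expressed transcript subsets.

The central quantity throughout this package is the Shannon entropy

    H(X) = -sum_i p_i * log2(p_i)

of a discrete distribution over group labels (co-expression modules,
genome bins, circadian phase groups), where ``p_i`` is the fraction of
items (transcripts or eQTLs) falling in group *i*.  Entropy is reported
in bits.  The machinery here ranks genes by expression, takes the top-N
subset, tabulates its group membership and computes H, both for a single
subset size and along a curve of sizes normalised by the full-set
entropy ("fraction of maximal information").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GroupedCounts",
    "ExpressionProfile",
    "GroupAssignment",
    "EntropyResult",
    "EntropyCurve",
    "DEFAULT_SIZE_GRID",
    "shannon_entropy",
    "rank_genes",
    "top_subset",
    "subset_entropy",
    "entropy_curve",
]

#: Subset-size grid used for all headline analyses; the full gene set is
#: always appended as the final size.
DEFAULT_SIZE_GRID: tuple[int, ...] = (100, 500, 1000, 2500, 5000, 10000)

UNASSIGNED_LABEL = "_unassigned"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GroupedCounts:
    """Counts of items per group label.

    Parameters
    ----------
    counts
        Mapping from opaque group label to a non-negative integer count.
        Zero-count groups are allowed and contribute nothing to the
        entropy (0*log2(0) == 0 by convention).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for label, c in self.counts.items():
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise ValidationError(
                    f"count for group {label!r} must be an integer, got {c!r}"
                )
            if c < 0:
                raise ValidationError(f"negative count for group {label!r}: {c}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def nonempty(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.counts.items() if v > 0}


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene expression levels for one condition (arbitrary platform units)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite expression for gene {gene!r}: {v}")
            if v < 0:
                raise ValidationError(f"negative expression for gene {gene!r}: {v}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GroupAssignment:
    """Gene -> single group label; genes absent from the mapping are unassigned."""

    membership: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.membership) > 0 and len(set(self.membership.values())) == 0:
            raise ValidationError("group label set must be nonempty")

    def groups(self) -> set[str]:
        return set(self.membership.values())

    def __len__(self) -> int:
        return len(self.membership)


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of one grouped-count distribution."""

    entropy_bits: float
    n_groups_nonempty: int
    n_items: int

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValidationError("n_items must be positive")
        cap = math.log2(self.n_groups_nonempty)
        if not (-1e-9 <= self.entropy_bits <= cap + 1e-9):
            raise ValidationError(
                f"entropy {self.entropy_bits} outside [0, log2({self.n_groups_nonempty})]"
            )


@dataclass(frozen=True)
class EntropyCurve:
    """Entropy (bits) and fraction of full-set entropy vs subset size."""

    points: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        sizes = [p[0] for p in self.points]
        if sizes != sorted(set(sizes)):
            raise ValidationError("subset sizes must be strictly increasing")

    @property
    def sizes(self) -> list[int]:
        return [p[0] for p in self.points]

    def as_records(self) -> list[dict]:
        return [
            {"subset_size": s, "entropy_bits": h, "fraction_of_full": f}
            for s, h, f in self.points
        ]


def shannon_entropy(counts: GroupedCounts | Mapping[str, int]) -> EntropyResult:
    """Shannon entropy H(X) = -sum p_i log2 p_i of grouped counts, in bits.

    Empty groups contribute nothing; an all-zero or empty distribution is
    undefined and raises :class:`ValidationError`.
    """
    if not isinstance(counts, GroupedCounts):
        counts = GroupedCounts(counts)
    nz = np.array(list(counts.nonempty().values()), dtype=float)
    if nz.size == 0:
        raise ValidationError("entropy undefined: all counts are zero or empty")
    total = nz.sum()
    p = nz / total
    h = float(-(p * np.log2(p)).sum())
    # clip the tiny negative round-off a one-group distribution can produce
    h = max(h, 0.0)
    return EntropyResult(
        entropy_bits=h, n_groups_nonempty=int(nz.size), n_items=int(total)
    )


def rank_genes(profile: ExpressionProfile | Mapping[str, float]) -> list[str]:
    """Rank genes by descending expression.

    Ties are broken by ascending lexicographic gene identifier so the
    ordering is reproducible regardless of input mapping order.
    """
    if not isinstance(profile, ExpressionProfile):
        profile = ExpressionProfile(profile)
    if len(profile) == 0:
        raise ValidationError("cannot rank an empty expression profile")
    return sorted(profile.values, key=lambda g: (-profile.values[g], g))


def top_subset(ranked: Sequence[str], n: int) -> set[str]:
    """First min(n, total) genes of a ranking, as a set."""
    if n < 1:
        raise ValidationError(f"subset size must be >= 1, got {n}")
    return set(ranked[: min(n, len(ranked))])


def _membership_counts(
    genes: Iterable[str],
    assignment: GroupAssignment,
    include_unassigned: bool,
) -> tuple[GroupedCounts, int]:
    counts: dict[str, int] = {}
    n_unassigned = 0
    for g in genes:
        label = assignment.membership.get(g)
        if label is None:
            n_unassigned += 1
            if include_unassigned:
                counts[UNASSIGNED_LABEL] = counts.get(UNASSIGNED_LABEL, 0) + 1
        else:
            counts[label] = counts.get(label, 0) + 1
    return GroupedCounts(counts), n_unassigned


def subset_entropy(
    profile: ExpressionProfile | Mapping[str, float],
    assignment: GroupAssignment,
    n: int,
    *,
    include_unassigned: bool = False,
) -> EntropyResult:
    """Entropy of group membership among the top-n expressed genes.

    Genes with no group assignment are excluded from both numerator and
    denominator by default; with ``include_unassigned=True`` they are
    pooled into a reserved ``"_unassigned"`` group instead.
    """
    ranked = rank_genes(profile)
    subset = top_subset(ranked, n)
    counts, n_unassigned = _membership_counts(subset, assignment, include_unassigned)
    if counts.total == 0:
        raise ValidationError(
            f"no assigned genes among top-{n} subset "
            f"({n_unassigned} unassigned of {len(subset)})"
        )
    return shannon_entropy(counts)


def entropy_curve(
    profile: ExpressionProfile | Mapping[str, float],
    assignment: GroupAssignment,
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
    *,
    include_unassigned: bool = False,
) -> EntropyCurve:
    """Entropy and fraction-of-full at each subset size.

    Sizes are deduplicated, sorted and clipped to the gene total; the
    full gene set is appended if absent.  The fraction denominator is the
    entropy of the complete gene set under the same grouping, so the
    final point always has fraction 1.0 exactly.
    """
    if not isinstance(profile, ExpressionProfile):
        profile = ExpressionProfile(profile)
    if len(sizes) == 0:
        raise ValidationError("sizes must be nonempty")
    total = len(profile)
    grid = sorted({min(int(s), total) for s in sizes} | {total})
    points = []
    full_h: float | None = None
    for s in grid:
        try:
            res = subset_entropy(
                profile, assignment, s, include_unassigned=include_unassigned
            )
        except ValidationError as e:
            raise ValidationError(f"subset size {s}: {e}") from e
        points.append((s, res.entropy_bits))
        if s == total:
            full_h = res.entropy_bits
    assert full_h is not None
    curve = tuple(
        (s, h, h / full_h if full_h > 0 else 1.0) for s, h in points[:-1]
    ) + ((total, full_h, 1.0),)
    return EntropyCurve(points=curve)
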