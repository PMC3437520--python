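"""Sequencing-depth saturation for shallow RNA-seq design.

Reads are modelled as i.i.d. multinomial draws over transcripts with
fixed relative abundances (no length or GC bias).  The per-gene read
count at depth R is then Binomial(R, p_g), so the expected number of
genes reaching a coverage threshold c is

    E[genes >= c] = sum_g P(Binomial(R, p_g) >= c),

an analytic curve the multinomial simulation must match within
Monte-Carlo error.  A bisection on that expectation gives the minimal
read depth for a target gene count, and dividing a lane's read budget by
the per-sample depth gives the multiplexing capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import ValidationError

__all__ = [
    "AbundanceProfile",
    "SaturationCurve",
    "sample_reads",
    "genes_at_coverage",
    "expected_genes_at_coverage",
    "reads_needed",
    "multiplex_capacity",
    "saturation_curve",
]


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-gene relative abundances, normalised to sum to 1."""

    genes: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.genes),):
            raise ValidationError("one probability required per gene")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValidationError("abundances must be finite and >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("abundances must sum to 1 (use from_raw to normalise)")

    @classmethod
    def from_raw(cls, values: Mapping[str, float]) -> "AbundanceProfile":
        genes = tuple(values)
        raw = np.array([values[g] for g in genes], dtype=float)
        if np.any(raw < 0) or not np.all(np.isfinite(raw)):
            raise ValidationError("abundances must be finite and >= 0")
        total = raw.sum()
        if total <= 0:
            raise ValidationError("cannot normalise an all-zero abundance profile")
        return cls(genes=genes, probabilities=raw / total)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SaturationCurve:
    """Genes reaching >=1 and >=10 reads vs total read depth.

    ``table`` columns: reads, mean_genes_ge_1, sd_genes_ge_1,
    mean_genes_ge_10, sd_genes_ge_10, expected_genes_ge_1,
    expected_genes_ge_10.
    """

    table: pd.DataFrame
    n_replicates: int
    seed: int


def sample_reads(
    abundance: AbundanceProfile, reads: int, seed: int | np.random.Generator
) -> np.ndarray:
    """One multinomial draw of per-gene read counts summing to ``reads``."""
    if reads < 1:
        raise ValidationError(f"reads must be >= 1, got {reads}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(reads, abundance.probabilities)


def genes_at_coverage(counts: np.ndarray | Mapping[str, int], threshold: int) -> int:
    """Number of genes with read count >= threshold."""
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    if isinstance(counts, Mapping):
        counts = np.array(list(counts.values()))
    return int(np.count_nonzero(np.asarray(counts) >= threshold))


def expected_genes_at_coverage(
    abundance: AbundanceProfile, reads: int, threshold: int
) -> float:
    """Analytic expectation sum_g P(Binomial(reads, p_g) >= threshold).

    Uses the binomial survival function, which is numerically stable
    across the small-p, large-R regimes shallow sequencing lives in.
    """
    if reads < 1:
        raise ValidationError(f"reads must be >= 1, got {reads}")
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    p = abundance.probabilities
    return float(stats.binom.sf(threshold - 1, reads, p).sum())


def variance_genes_at_coverage(
    abundance: AbundanceProfile, reads: int, threshold: int
) -> float:
    """Analytic variance bound for the genes-at-coverage count.

    Sum of Bernoulli variances of the per-gene tail probabilities; the
    multinomial's negative covariances make this a (slightly
    conservative) upper bound on the true variance.
    """
    tail = stats.binom.sf(threshold - 1, reads, abundance.probabilities)
    return float((tail * (1.0 - tail)).sum())


def reads_needed(
    abundance: AbundanceProfile, target_genes: int, threshold: int
) -> int:
    """Minimal read depth whose expected gene count reaches the target.

    Monotone bisection on ``expected_genes_at_coverage`` with an
    expanding upper bracket.  The target must not exceed the number of
    genes with positive abundance.
    """
    if target_genes < 1:
        raise ValidationError("target_genes must be >= 1")
    achievable = int(np.count_nonzero(abundance.probabilities > 0))
    if target_genes > achievable:
        raise ValidationError(
            f"target of {target_genes} genes exceeds the {achievable} genes "
            "with positive abundance"
        )
    lo, hi = 1, max(threshold, 1)
    while expected_genes_at_coverage(abundance, hi, threshold) < target_genes:
        lo = hi
        hi *= 2
        if hi > 10**13:  # pragma: no cover - guards runaway brackets
            raise ValidationError("bracket expansion exceeded 1e13 reads")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_genes_at_coverage(abundance, mid, threshold) >= target_genes:
            hi = mid
        else:
            lo = mid
    return hi


def multiplex_capacity(lane_reads: int, reads_per_sample: int) -> int:
    """How many samples at a given per-sample depth fit in one lane."""
    if reads_per_sample < 1:
        raise ValidationError("reads_per_sample must be >= 1")
    if reads_per_sample > lane_reads:
        raise ValidationError(
            f"per-sample depth {reads_per_sample} exceeds lane capacity {lane_reads}"
        )
    return lane_reads // reads_per_sample


def saturation_curve(
    abundance: AbundanceProfile,
    read_grid: Sequence[int],
    *,
    n_replicates: int = 10,
    seed: int = 0,
    thresholds: tuple[int, int] = (1, 10),
) -> SaturationCurve:
    """Simulated + analytic genes-at-coverage across a read-depth grid."""
    if n_replicates < 2:
        raise ValidationError("need >= 2 replicates for a spread estimate")
    t_lo, t_hi = thresholds
    rng = np.random.default_rng(seed)
    rows = []
    for reads in sorted(set(int(r) for r in read_grid)):
        ge_lo, ge_hi = [], []
        for _ in range(n_replicates):
            counts = sample_reads(abundance, reads, rng)
            ge_lo.append(genes_at_coverage(counts, t_lo))
            ge_hi.append(genes_at_coverage(counts, t_hi))
        rows.append(
            {
                "reads": reads,
                f"mean_genes_ge_{t_lo}": float(np.mean(ge_lo)),
                f"sd_genes_ge_{t_lo}": float(np.std(ge_lo, ddof=1)),
                f"mean_genes_ge_{t_hi}": float(np.mean(ge_hi)),
                f"sd_genes_ge_{t_hi}": float(np.std(ge_hi, ddof=1)),
                f"expected_genes_ge_{t_lo}": expected_genes_at_coverage(
                    abundance, reads, t_lo
                ),
                f"expected_genes_ge_{t_hi}": expected_genes_at_coverage(
                    abundance, reads, t_hi
                ),
            }
        )
    return SaturationCurve(
        table=pd.DataFrame(rows), n_replicates=n_replicates, seed=int(seed)
    )
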