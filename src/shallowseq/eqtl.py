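"""Information content of eQTL genetic architecture.

An eQTL catalog places expression QTL at centimorgan (cM) positions on a
genetic map.  Binning those positions at a chosen width (1, 5 or 10 cM —
a proxy for the mapping resolution a larger or smaller RIL population
affords) turns the genome into a discrete distribution over bins, whose
Shannon entropy measures how much positional information the experiment
carries.  Restricting to the eQTL of the top-N expressed transcripts
asks how much of that information a shallow-sequencing subset retains;
per-cM "hotspot profiles" across subset sizes make the comparison
visual, and a top-k Jaccard concordance quantifies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .entropy import (
    EntropyResult,
    ExpressionProfile,
    GroupedCounts,
    ValidationError,
    rank_genes,
    shannon_entropy,
    top_subset,
)

__all__ = [
    "GeneticMap",
    "EQTLRecord",
    "EQTLCatalog",
    "HotspotProfile",
    "DEFAULT_CHROMOSOMES",
    "assign_bins",
    "eqtl_subset_entropy",
    "rebin",
    "hotspot_profile",
    "hotspot_concordance",
]

#: Five chromosomes echoing the Arabidopsis genetic-map layout.
DEFAULT_CHROMOSOMES: tuple[tuple[str, float], ...] = (
    ("1", 120.0),
    ("2", 80.0),
    ("3", 90.0),
    ("4", 100.0),
    ("5", 110.0),
)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered chromosomes with lengths in cM, binnable at a given width.

    Bins are half-open ``[start, start + width)``, 0-based from each
    chromosome start; a position exactly on a boundary falls into the
    higher bin.  The last bin of a chromosome may be short.
    """

    chromosomes: tuple[tuple[str, float], ...] = DEFAULT_CHROMOSOMES
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError(f"bin width must be positive, got {self.bin_width}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")

    @property
    def lengths(self) -> dict[str, float]:
        return dict(self.chromosomes)

    def n_bins(self, chromosome: str) -> int:
        return int(math.ceil(self.lengths[chromosome] / self.bin_width))

    def bin_index(self, chromosome: str, position_cm: float) -> int:
        length = self.lengths.get(chromosome)
        if length is None:
            raise ValidationError(f"unknown chromosome {chromosome!r}")
        if not (0.0 <= position_cm < length):
            raise ValidationError(
                f"position {position_cm} cM outside chromosome {chromosome!r} "
                f"[0, {length})"
            )
        return int(position_cm // self.bin_width)

    def bin_label(self, chromosome: str, bin_index: int) -> str:
        return f"{chromosome}:{bin_index}"

    def all_bin_labels(self) -> list[str]:
        """Genome-wide bin labels, concatenated chromosome by chromosome."""
        return [
            self.bin_label(name, i)
            for name, _ in self.chromosomes
            for i in range(self.n_bins(name))
        ]

    def with_width(self, width: float) -> "GeneticMap":
        return GeneticMap(chromosomes=self.chromosomes, bin_width=width)


@dataclass(frozen=True)
class EQTLRecord:
    transcript: str
    chromosome: str
    position_cm: float
    kind: str | None = None  # optional cis/trans tag; never enters the entropy


@dataclass(frozen=True)
class EQTLCatalog:
    """eQTL positions per transcript plus each transcript's mean expression.

    A transcript may carry zero, one or many eQTL records; transcripts
    without records still occupy a slot in expression-ranked subsets.
    """

    records: tuple[EQTLRecord, ...]
    mean_expression: Mapping[str, float]

    def __post_init__(self) -> None:
        for t, v in self.mean_expression.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"invalid mean expression for {t!r}: {v}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def records_for(self, transcripts: set[str]) -> list[EQTLRecord]:
        return [r for r in self.records if r.transcript in transcripts]

    def ranked_transcripts(self) -> list[str]:
        return rank_genes(ExpressionProfile(self.mean_expression))


@dataclass(frozen=True)
class HotspotProfile:
    """Per-subset-size vectors of eQTL counts per genome-wide 1 cM bin."""

    bin_labels: tuple[str, ...]
    counts_by_size: Mapping[int, np.ndarray]

    def counts(self, size: int) -> np.ndarray:
        return self.counts_by_size[size]


def assign_bins(
    catalog: EQTLCatalog, genetic_map: GeneticMap, *, transcripts: set[str] | None = None
) -> GroupedCounts:
    """Tabulate eQTL records into genome-wide cM bins.

    Every record contributes one count to the bin containing its
    position; optionally restricted to a transcript subset.
    """
    counts: dict[str, int] = {}
    records = (
        catalog.records if transcripts is None else catalog.records_for(transcripts)
    )
    for rec in records:
        try:
            idx = genetic_map.bin_index(rec.chromosome, rec.position_cm)
        except ValidationError as e:
            raise ValidationError(f"record for transcript {rec.transcript!r}: {e}") from e
        label = genetic_map.bin_label(rec.chromosome, idx)
        counts[label] = counts.get(label, 0) + 1
    return GroupedCounts(counts)


def eqtl_subset_entropy(
    catalog: EQTLCatalog, n: int, genetic_map: GeneticMap
) -> EntropyResult:
    """Bin entropy of the eQTLs of the top-n transcripts by mean expression.

    Normalisation is over eQTL records in the subset, not transcripts:
    a transcript with three eQTL contributes three counts.
    """
    ranked = catalog.ranked_transcripts()
    subset = top_subset(ranked, n)
    counts = assign_bins(catalog, genetic_map, transcripts=subset)
    if counts.total == 0:
        raise ValidationError(f"no eQTL records among the top-{n} transcripts")
    return shannon_entropy(counts)


def rebin(
    fine_counts: GroupedCounts, coarse_width: float, genetic_map: GeneticMap
) -> GroupedCounts:
    """Merge fine-bin counts into coarser bins of an integer-multiple width.

    Totals are conserved exactly; by the merge inequality the entropy of
    the coarse counts never exceeds the fine entropy.
    """
    w = genetic_map.bin_width
    ratio = coarse_width / w
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValidationError(
            f"coarse width {coarse_width} is not an integer multiple of {w}"
        )
    ratio = int(round(ratio))
    coarse: dict[str, int] = {}
    for label, c in fine_counts.counts.items():
        chrom, _, idx = label.rpartition(":")
        coarse_label = f"{chrom}:{int(idx) // ratio}"
        coarse[coarse_label] = coarse.get(coarse_label, 0) + c
    return GroupedCounts(coarse)


def hotspot_profile(
    catalog: EQTLCatalog,
    sizes: Sequence[int],
    genetic_map: GeneticMap,
) -> HotspotProfile:
    """Unsmoothed per-cM eQTL count vectors, one per subset size.

    The map's own bin width is used (1 cM for the headline profiles);
    vectors are concatenated chromosome by chromosome in map order.
    Sizes are clipped to the transcript total, which is always included.
    """
    ranked = catalog.ranked_transcripts()
    total = len(ranked)
    grid = sorted({min(int(s), total) for s in sizes} | {total})
    labels = tuple(genetic_map.all_bin_labels())
    index = {lab: i for i, lab in enumerate(labels)}
    by_size: dict[int, np.ndarray] = {}
    for s in grid:
        counts = assign_bins(catalog, genetic_map, transcripts=top_subset(ranked, s))
        vec = np.zeros(len(labels), dtype=int)
        for lab, c in counts.counts.items():
            vec[index[lab]] = c
        by_size[s] = vec
    return HotspotProfile(bin_labels=labels, counts_by_size=by_size)


def hotspot_concordance(
    profile_a: np.ndarray, profile_b: np.ndarray, k: int
) -> float:
    """Jaccard index of the top-k bins of two equal-length count vectors.

    Ties are broken by bin order (earlier bins win), so the result is
    deterministic and invariant to how the inputs were produced.
    """
    a = np.asarray(profile_a)
    b = np.asarray(profile_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("profiles must be equal-length 1-D vectors")
    if k < 1 or k > a.size:
        raise ValidationError(f"k must be in [1, {a.size}], got {k}")
    # stable: sort by (-count, bin index)
    top_a = set(np.lexsort((np.arange(a.size), -a))[:k].tolist())
    top_b = set(np.lexsort((np.arange(b.size), -b))[:k].tolist())
    union = top_a | top_b
    return len(top_a & top_b) / len(union)
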