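"""Seeded generators for synthetic transcriptomics inputs.

Every analysis in this package can run end-to-end with no external data:
the generators here emulate the statistical structure the analyses
assume — a scale-free (Zipf-like) co-expression module-size
distribution, modules whose members span orders of magnitude in
expression, trans-eQTL concentrated in planted hotspots on a
five-chromosome genetic map, cosine-shaped circadian expression with
phases uniform over the 24 h cycle, and a long-tailed (log-normal)
transcript abundance distribution.

All generators are pure functions of (config, seed): one master seed
deterministically derives an independent child stream per generator, so
any pipeline stage can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .circadian import PhaseAssignment, TimeCourseMatrix
from .depth import AbundanceProfile
from .entropy import ExpressionProfile, GroupAssignment, ValidationError
from .eqtl import DEFAULT_CHROMOSOMES, EQTLCatalog, EQTLRecord, GeneticMap

import pandas as pd

__all__ = [
    "SimulationConfig",
    "gen_modules",
    "gen_expression_matrix",
    "gen_eqtl_catalog",
    "gen_time_course",
    "gen_abundances",
]

# fixed stream indices so each generator's child seed is stable
_STREAMS = {
    "modules": 0,
    "expression": 1,
    "eqtl": 2,
    "time_course": 3,
    "abundance": 4,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world, with defaults at study scale.

    Sizes default to the scale of the emulated datasets (22,746 ATH1
    transcripts, ~1000 co-expression modules, five chromosomes, a 44 h
    time course sampled every 4 h) but every size shrinks cleanly for
    fast tests.  Expression parameters are on the natural-log scale.
    """

    n_genes: int = 22746
    n_modules: int = 1000
    gamma: float = 1.0  # module-size power-law exponent (size ~ rank^-gamma)
    # expression model: exp(module offset + gene offset + noise)
    expression_mu: float = 5.0
    module_offset_sd: float = 1.0
    gene_spread_sd: float = 1.5  # within-module spread; >= 2 decades per big module
    expression_noise_sd: float = 0.25
    # genetic map and eQTL architecture
    chromosomes: tuple[tuple[str, float], ...] = DEFAULT_CHROMOSOMES
    hotspots: tuple[tuple[str, float], ...] = (("2", 30.0), ("4", 65.0))
    hotspot_weight: float = 20.0  # per-cM weight relative to background 1.0
    cis_fraction: float = 0.3
    eqtl_rate: float = 1.5  # Poisson mean eQTL per transcript
    # circadian clock
    ct_times: tuple[float, ...] = tuple(float(t) for t in range(0, 45, 4))
    n_replicates: int = 2
    mesor_sd: float = 1.5
    amplitude: float = 1.0
    circadian_noise_sd: float = 0.2
    # read-depth abundance profile
    abundance_sigma: float = 2.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_modules < 1:
            raise ValidationError("n_genes and n_modules must be positive")
        if self.n_modules > self.n_genes:
            raise ValidationError("n_modules cannot exceed n_genes")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise ValidationError("cis_fraction must be in [0, 1]")
        if self.eqtl_rate < 0:
            raise ValidationError("eqtl_rate must be >= 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        lengths = dict(self.chromosomes)
        for chrom, pos in self.hotspots:
            if chrom not in lengths or not (0.0 <= pos < lengths[chrom]):
                raise ValidationError(f"hotspot ({chrom!r}, {pos}) is off the map")

    # -- serialisation -------------------------------------------------

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        d["hotspots"] = [list(h) for h in self.hotspots]
        d["ct_times"] = list(self.ct_times)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["chromosomes"] = tuple((str(c), float(l)) for c, l in d["chromosomes"])
        d["hotspots"] = tuple((str(c), float(p)) for c, p in d["hotspots"])
        d["ct_times"] = tuple(float(t) for t in d["ct_times"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def genetic_map(self, bin_width: float = 1.0) -> GeneticMap:
        return GeneticMap(chromosomes=self.chromosomes, bin_width=bin_width)

    def child_rng(self, stream: str, seed: int | None = None) -> np.random.Generator:
        master = self.seed if seed is None else seed
        ss = np.random.SeedSequence([int(master), _STREAMS[stream]])
        return np.random.default_rng(ss)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _module_sizes(n_genes: int, n_modules: int, gamma: float) -> np.ndarray:
    """Module sizes proportional to rank^-gamma, largest-remainder rounded."""
    ranks = np.arange(1, n_modules + 1, dtype=float)
    weights = ranks**-gamma
    quota = n_genes * weights / weights.sum()
    sizes = np.floor(quota).astype(int)
    short = n_genes - sizes.sum()
    if short > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        sizes[order[:short]] += 1
    return sizes


def gen_modules(config: SimulationConfig, seed: int | None = None) -> GroupAssignment:
    """Assign every gene to exactly one module with Zipf-like sizes.

    Sizes sum to ``n_genes`` exactly; which genes land in which module
    is a seeded permutation, so module membership is uncorrelated with
    gene identity.
    """
    if config.gamma < 0:
        raise ValidationError("gamma must be >= 0")
    rng = config.child_rng("modules", seed)
    genes = _gene_ids(config.n_genes)
    sizes = _module_sizes(config.n_genes, config.n_modules, config.gamma)
    perm = rng.permutation(config.n_genes)
    width = max(4, len(str(config.n_modules)))
    membership: dict[str, str] = {}
    pos = 0
    for m, size in enumerate(sizes, start=1):
        label = f"M{m:0{width}d}"
        for j in perm[pos : pos + size]:
            membership[genes[j]] = label
        pos += size
    return GroupAssignment(membership)


def gen_expression_matrix(
    assignment: GroupAssignment,
    config: SimulationConfig,
    seed: int | None = None,
) -> ExpressionProfile:
    """Log-normal expression: exp(module offset + gene offset + noise).

    The within-module spread (``gene_spread_sd``, default 1.5 natural-log
    units) is wide enough that each large module spans well over two
    orders of magnitude, which is what lets small top-N subsets touch
    most modules.
    """
    if config.gene_spread_sd < 0 or config.expression_noise_sd < 0:
        raise ValidationError("spreads must be >= 0")
    rng = config.child_rng("expression", seed)
    genes = sorted(assignment.membership)
    modules = sorted(assignment.groups())
    offsets = {
        m: rng.normal(config.expression_mu, config.module_offset_sd) for m in modules
    }
    gene_off = rng.normal(0.0, config.gene_spread_sd, size=len(genes))
    noise = rng.normal(0.0, config.expression_noise_sd, size=len(genes))
    values = {
        g: float(np.exp(offsets[assignment.membership[g]] + gene_off[i] + noise[i]))
        for i, g in enumerate(genes)
    }
    return ExpressionProfile(values)


def gen_eqtl_catalog(
    config: SimulationConfig, seed: int | None = None
) -> EQTLCatalog:
    """eQTL catalog with hotspot-concentrated trans architecture.

    Each transcript gets a uniform genomic location and a Poisson number
    of eQTL.  An eQTL is cis (at the transcript's own position) with
    probability ``cis_fraction``, otherwise trans, drawn from a mixture
    over genome-wide 1 cM bins where planted hotspot bins carry
    ``hotspot_weight`` times the background weight.  Mean expression is
    log-normal, independent of the genetic architecture.
    """
    rng = config.child_rng("eqtl", seed)
    gmap = config.genetic_map(1.0)
    genes = _gene_ids(config.n_genes)
    lengths = dict(config.chromosomes)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_len = np.array([lengths[c] for c in chrom_names])
    chrom_p = chrom_len / chrom_len.sum()

    # transcript locations, uniform over the map
    t_chrom = rng.choice(len(chrom_names), size=config.n_genes, p=chrom_p)
    t_pos = rng.uniform(0, chrom_len[t_chrom])

    # trans-mixture over 1 cM bins, hotspot bins up-weighted
    bin_labels = gmap.all_bin_labels()
    weights = np.ones(len(bin_labels))
    hotspot_bins = {
        gmap.bin_label(c, gmap.bin_index(c, p)) for c, p in config.hotspots
    }
    if len(hotspot_bins) != len(config.hotspots):
        raise ValidationError("hotspots must fall in distinct 1 cM bins")
    for i, lab in enumerate(bin_labels):
        if lab in hotspot_bins:
            weights[i] = config.hotspot_weight
    bin_p = weights / weights.sum()
    bin_chrom = [lab.rpartition(":")[0] for lab in bin_labels]
    bin_start = np.array([int(lab.rpartition(":")[2]) for lab in bin_labels], float)
    bin_end = np.minimum(
        bin_start + 1.0, np.array([lengths[c] for c in bin_chrom])
    )

    n_eqtl = rng.poisson(config.eqtl_rate, size=config.n_genes)
    records: list[EQTLRecord] = []
    for gi, gene in enumerate(genes):
        for _ in range(n_eqtl[gi]):
            if rng.random() < config.cis_fraction:
                records.append(
                    EQTLRecord(gene, chrom_names[t_chrom[gi]], float(t_pos[gi]), "cis")
                )
            else:
                b = rng.choice(len(bin_labels), p=bin_p)
                pos = rng.uniform(bin_start[b], bin_end[b])
                records.append(EQTLRecord(gene, bin_chrom[b], float(pos), "trans"))

    mean_expr = {
        g: float(np.exp(rng.normal(config.expression_mu, config.gene_spread_sd)))
        for g in genes
    }
    return EQTLCatalog(records=tuple(records), mean_expression=mean_expr)


def gen_time_course(
    config: SimulationConfig, seed: int | None = None
) -> tuple[TimeCourseMatrix, PhaseAssignment]:
    """Cosine-shaped circadian expression with uniform peak phases.

    expression(g, t) = exp(mesor_g + A·cos(2π(t − phase_g)/24) + noise),
    phases uniform on [0, 24).  The default grid is CT 0–44 h every 4 h
    with 2 replicate columns per time point.
    """
    if len(config.ct_times) == 0:
        raise ValidationError("time grid must be nonempty")
    rng = config.child_rng("time_course", seed)
    genes = _gene_ids(config.n_genes)
    phases = rng.uniform(0.0, 24.0, size=config.n_genes)
    mesor = rng.normal(config.expression_mu, config.mesor_sd, size=config.n_genes)
    times = sorted(config.ct_times)
    cols, col_times, col_reps = [], [], []
    for t in times:
        for r in range(config.n_replicates):
            noise = rng.normal(0.0, config.circadian_noise_sd, size=config.n_genes)
            log_expr = (
                mesor
                + config.amplitude * np.cos(2 * np.pi * (t - phases) / 24.0)
                + noise
            )
            cols.append(np.exp(log_expr))
            col_times.append(float(t))
            col_reps.append(r)
    data = pd.DataFrame(
        np.column_stack(cols),
        index=genes,
        columns=[f"CT_{t:g}_rep{r}" for t, r in zip(col_times, col_reps)],
    )
    matrix = TimeCourseMatrix(
        data=data, times=tuple(col_times), replicates=tuple(col_reps)
    )
    assignment = PhaseAssignment({g: float(p) for g, p in zip(genes, phases)})
    return matrix, assignment


def gen_abundances(
    config: SimulationConfig, seed: int | None = None
) -> AbundanceProfile:
    """Long-tailed relative abundances: normalised exp(Normal(0, sigma^2)).

    The default sigma of 2.0 natural-log units concentrates most reads
    in a few thousand transcripts, the regime shallow sequencing
    exploits.
    """
    if config.abundance_sigma < 0:
        raise ValidationError("abundance_sigma must be >= 0")
    rng = config.child_rng("abundance", seed)
    genes = _gene_ids(config.n_genes)
    raw = np.exp(rng.normal(0.0, config.abundance_sigma, size=config.n_genes))
    return AbundanceProfile(genes=tuple(genes), probabilities=raw / raw.sum())
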