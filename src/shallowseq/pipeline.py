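"""End-to-end analysis scenarios over synthetic (or user-supplied) inputs.

Each scenario generates its inputs from a :class:`SimulationConfig`,
runs the corresponding analysis, writes plain tab-delimited outputs plus
a JSON run report, and returns the report.  Reports carry the config
hash and seed so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as sio
from .circadian import (
    ct_group_assign,
    entropy_trajectory,
    group_trajectory,
    oscillation_fidelity,
    time_effect_anova,
)
from .depth import (
    multiplex_capacity,
    reads_needed,
    saturation_curve,
    variance_genes_at_coverage,
)
from .entropy import (
    DEFAULT_SIZE_GRID,
    ValidationError,
    entropy_curve,
    subset_entropy,
)
from .eqtl import eqtl_subset_entropy, hotspot_concordance, hotspot_profile
from .simulate import (
    SimulationConfig,
    gen_abundances,
    gen_eqtl_catalog,
    gen_expression_matrix,
    gen_modules,
    gen_time_course,
)

log = logging.getLogger("shallowseq")

__all__ = [
    "RunReport",
    "REPORT_SCHEMA",
    "validate_report",
    "run_network_scenario",
    "run_eqtl_scenario",
    "run_circadian_scenario",
    "run_saturation_scenario",
]

#: Minimal JSON schema every RunReport serialisation satisfies.
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["scenario", "seed", "config_hash", "config", "files", "summary"],
    "properties": {
        "scenario": {"type": "string"},
        "seed": {"type": "integer"},
        "config_hash": {"type": "string"},
        "config": {"type": "string"},
        "files": {"type": "object"},
        "summary": {"type": "object"},
    },
}

_TYPES = {"object": dict, "string": str, "integer": int}


def validate_report(doc: Mapping) -> None:
    """Check a report document against :data:`REPORT_SCHEMA`.

    Raises :class:`ValidationError` on a missing key or wrong type.
    """
    for key in REPORT_SCHEMA["required"]:
        if key not in doc:
            raise ValidationError(f"report missing required key {key!r}")
    for key, spec in REPORT_SCHEMA["properties"].items():
        if key in doc and not isinstance(doc[key], _TYPES[spec["type"]]):
            raise ValidationError(f"report key {key!r} is not of type {spec['type']}")


@dataclass(frozen=True)
class RunReport:
    """Record of one scenario run: inputs, output files, key numbers."""

    scenario: str
    seed: int
    config_hash: str
    config: str
    files: dict[str, str]
    summary: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        doc = self.to_dict()
        validate_report(doc)
        for f in self.files.values():
            if not Path(f).exists():
                raise ValidationError(f"report names missing file {f}")
        sio.write_json_report(doc, path)


def _finish(report: RunReport, outdir: Path) -> RunReport:
    report.write(outdir / f"report_{report.scenario}.json")
    log.info("scenario %s complete: %s", report.scenario, sorted(report.files))
    return report


def run_network_scenario(
    config: SimulationConfig,
    outdir: str | Path,
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
) -> RunReport:
    """Entropy curve of a module-structured transcriptome (scale-free world).

    Writes the entropy curve and a per-subset summary of the expression
    distribution (decades of expression each subset spans).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("network scenario: seed=%d hash=%s", config.seed, config.config_hash())
    modules = gen_modules(config)
    profile = gen_expression_matrix(modules, config)
    curve = entropy_curve(profile, modules, sizes)
    curve_path = outdir / "network_entropy_curve.tsv"
    sio.write_entropy_curve(curve, curve_path)

    # expression-range summary per subset (how much of the dynamic range
    # each top-N slice covers)
    ranked = sorted(profile.values, key=lambda g: (-profile.values[g], g))
    dist_path = outdir / "network_expression_summary.tsv"
    with open(dist_path, "w") as fh:
        fh.write("subset_size\tmin_expression\tmedian_expression\tmax_expression\tlog10_range\n")
        for s, _, _ in curve.points:
            vals = np.array([profile.values[g] for g in ranked[:s]])
            fh.write(
                f"{s}\t{vals.min():.6g}\t{np.median(vals):.6g}\t{vals.max():.6g}"
                f"\t{np.log10(vals.max() / vals.min()):.4f}\n"
            )

    summary = {
        "n_genes": len(profile),
        "n_modules": len(modules.groups()),
        "full_entropy_bits": curve.points[-1][1],
        "curve": curve.as_records(),
    }
    return _finish(
        RunReport(
            scenario="network",
            seed=config.seed,
            config_hash=config.config_hash(),
            config=config.to_yaml(),
            files={
                "entropy_curve": str(curve_path),
                "expression_summary": str(dist_path),
            },
            summary=summary,
        ),
        outdir,
    )


def run_eqtl_scenario(
    config: SimulationConfig,
    outdir: str | Path,
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
    bin_widths: Sequence[float] = (1.0, 5.0, 10.0),
    concordance_k: int | None = None,
    fraction_denominator_1cm: bool = False,
) -> RunReport:
    """Positional entropy of an eQTL catalog at several map resolutions.

    Per subset size and bin width, the Shannon entropy of the eQTL
    position distribution; plus unsmoothed per-cM hotspot profiles and
    their top-k concordance with the full-catalog profile.  Fractions
    use each resolution's own full-set entropy unless
    ``fraction_denominator_1cm`` switches all series to the 1 cM
    denominator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("eqtl scenario: seed=%d hash=%s", config.seed, config.config_hash())
    if concordance_k is None:
        concordance_k = max(len(config.hotspots), 1)
    catalog = gen_eqtl_catalog(config)
    n_transcripts = len(catalog.mean_expression)
    grid = sorted({min(int(s), n_transcripts) for s in sizes} | {n_transcripts})

    ent_path = outdir / "eqtl_entropy.tsv"
    full_h: dict[float, float] = {}
    rows = []
    for w in bin_widths:
        gmap = config.genetic_map(w)
        full_h[w] = eqtl_subset_entropy(catalog, n_transcripts, gmap).entropy_bits
    for w in bin_widths:
        gmap = config.genetic_map(w)
        denom = full_h[min(bin_widths)] if fraction_denominator_1cm else full_h[w]
        for s in grid:
            h = eqtl_subset_entropy(catalog, s, gmap).entropy_bits
            rows.append((w, s, h, h / denom if denom > 0 else 1.0))
    with open(ent_path, "w") as fh:
        fh.write("bin_width_cM\tsubset_size\tentropy_bits\tfraction_of_full\n")
        for w, s, h, f in rows:
            fh.write(f"{w:g}\t{s}\t{h:.10g}\t{f:.10g}\n")

    gmap1 = config.genetic_map(1.0)
    profile = hotspot_profile(catalog, grid, gmap1)
    prof_path = outdir / "eqtl_hotspot_profile.tsv"
    sio.write_hotspot_profile(profile, gmap1, prof_path)

    full_vec = profile.counts(n_transcripts)
    conc_path = outdir / "eqtl_hotspot_concordance.tsv"
    concordance = {}
    with open(conc_path, "w") as fh:
        fh.write("subset_size\ttop_k\tconcordance_vs_full\n")
        for s in grid:
            c = hotspot_concordance(profile.counts(s), full_vec, concordance_k)
            concordance[s] = c
            fh.write(f"{s}\t{concordance_k}\t{c:.6f}\n")

    cat_path = outdir / "eqtl_catalog.tsv"
    expr_path = outdir / "eqtl_mean_expression.tsv"
    sio.write_eqtl_catalog(catalog, cat_path, expr_path)

    summary = {
        "n_transcripts": n_transcripts,
        "n_eqtl_records": catalog.n_records,
        "full_entropy_bits_by_width": {f"{w:g}": full_h[w] for w in bin_widths},
        "entropy": [
            {"bin_width_cM": w, "subset_size": s, "entropy_bits": h, "fraction_of_full": f}
            for w, s, h, f in rows
        ],
        "concordance_vs_full": {str(s): c for s, c in concordance.items()},
    }
    return _finish(
        RunReport(
            scenario="eqtl",
            seed=config.seed,
            config_hash=config.config_hash(),
            config=config.to_yaml(),
            files={
                "entropy": str(ent_path),
                "hotspot_profile": str(prof_path),
                "concordance": str(conc_path),
                "catalog": str(cat_path),
                "mean_expression": str(expr_path),
            },
            summary=summary,
        ),
        outdir,
    )


def run_circadian_scenario(
    config: SimulationConfig,
    outdir: str | Path,
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
) -> RunReport:
    """Per-time-point entropy under scale-free and CT-group networks.

    Produces entropy trajectories for the module grouping and the 1 h /
    0.25 h CT phase groupings, a one-way ANOVA of the time effect on
    entropy per subset size (replicate columns supply the within-group
    variance), and CT-group oscillation reconstructions with their
    fidelity (Pearson r vs the full transcriptome) per subset size.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("circadian scenario: seed=%d hash=%s", config.seed, config.config_hash())
    matrix, phases = gen_time_course(config)
    modules = gen_modules(config)
    groupings = {
        "scale_free": modules,
        "ct_1h": ct_group_assign(phases, 1.0),
        "ct_quarter_h": ct_group_assign(phases, 0.25),
    }

    n_total = len(matrix.genes)
    grid = sorted({min(int(s), n_total) for s in sizes} | {n_total})

    traj_path = outdir / "circadian_entropy_trajectory.tsv"
    trajectories = {}
    with open(traj_path, "w") as fh:
        fh.write("grouping\ttime\tsubset_size\tentropy_bits\tfraction_of_full\n")
        for name, assignment in groupings.items():
            traj = entropy_trajectory(matrix, assignment, grid)
            trajectories[name] = traj
            for r in traj.table.itertuples(index=False):
                fh.write(
                    f"{name}\t{r.time:g}\t{r.subset_size}"
                    f"\t{r.entropy_bits:.10g}\t{r.fraction_of_full:.10g}\n"
                )

    # time-effect ANOVA per subset size: replicate entropies per CT point
    anova_path = outdir / "circadian_anova.tsv"
    anova = {}
    with open(anova_path, "w") as fh:
        fh.write("subset_size\tF\tp_value\n")
        for s in grid:
            reps_by_time = []
            for t in matrix.unique_times:
                reps = [
                    subset_entropy(p, modules, s).entropy_bits
                    for p in matrix.replicate_profiles(t)
                ]
                reps_by_time.append(reps)
            f_stat, p_val = time_effect_anova(reps_by_time)
            anova[s] = {"F": f_stat, "p_value": p_val}
            fh.write(f"{s}\t{f_stat:.6g}\t{p_val:.6g}\n")

    ct1 = groupings["ct_1h"]
    traj = group_trajectory(matrix, ct1, grid)
    group_path = outdir / "circadian_group_trajectory.tsv"
    sio.write_group_trajectory(traj, group_path)

    fid_path = outdir / "circadian_fidelity.tsv"
    fidelity = {}
    with open(fid_path, "w") as fh:
        fh.write("subset_size\tct_group\tpearson_r\n")
        for s in grid:
            per_group = oscillation_fidelity(
                traj, traj, sub_size=s, full_size=n_total
            )
            fidelity[s] = per_group
            for g, r in per_group.items():
                fh.write(f"{s}\t{g}\t{'NA' if r is None else f'{r:.6f}'}\n")

    summary = {
        "n_genes": n_total,
        "n_time_points": len(matrix.unique_times),
        "n_replicates": config.n_replicates,
        "n_ct_groups_1h": len(ct1.groups()),
        "anova": {str(s): v for s, v in anova.items()},
        "mean_fraction_smallest_subset_ct1h": float(
            trajectories["ct_1h"]
            .table[trajectories["ct_1h"].table["subset_size"] == grid[0]][
                "fraction_of_full"
            ]
            .mean()
        ),
    }
    return _finish(
        RunReport(
            scenario="circadian",
            seed=config.seed,
            config_hash=config.config_hash(),
            config=config.to_yaml(),
            files={
                "entropy_trajectory": str(traj_path),
                "anova": str(anova_path),
                "group_trajectory": str(group_path),
                "fidelity": str(fid_path),
            },
            summary=summary,
        ),
        outdir,
    )


def run_saturation_scenario(
    config: SimulationConfig,
    outdir: str | Path,
    read_grid: Sequence[int] = (
        1000, 2500, 5000, 10000, 25000, 50000, 100000, 250000, 500000, 1000000,
    ),
    target_genes: int = 5000,
    coverage_threshold: int = 10,
    lane_reads: int = 100_000_000,
    n_replicates: int = 10,
) -> RunReport:
    """Read-depth saturation, reads-needed search and multiplexing capacity.

    Simulated (multinomial) and analytic (binomial-tail) genes-at-coverage
    curves across the read grid; the minimal depth at which the expected
    number of genes with ``coverage_threshold`` reads reaches
    ``target_genes``; and how many such samples fit in a lane.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("saturation scenario: seed=%d hash=%s", config.seed, config.config_hash())
    abundance = gen_abundances(config)
    curve = saturation_curve(
        abundance, read_grid, n_replicates=n_replicates, seed=config.seed
    )
    curve_path = outdir / "saturation_curve.tsv"
    sio.write_saturation_curve(curve, curve_path)
    abund_path = outdir / "abundance_profile.tsv"
    sio.write_abundance_profile(abundance, abund_path)

    needed = reads_needed(abundance, target_genes, coverage_threshold)
    capacity = multiplex_capacity(lane_reads, needed)
    benchmark_capacity = multiplex_capacity(lane_reads, 250_000)

    # Monte-Carlo agreement: simulated mean within 3 SE of the analytic
    # expectation at every grid point, for both thresholds; the SE uses
    # the analytic variance bound (stable at small replicate counts)
    t = curve.table
    agree = True
    for thr in (1, 10):
        var = np.array(
            [
                variance_genes_at_coverage(abundance, int(r), thr)
                for r in t["reads"]
            ]
        )
        se = np.sqrt(var / curve.n_replicates)
        diff = (t[f"mean_genes_ge_{thr}"] - t[f"expected_genes_ge_{thr}"]).abs()
        agree &= bool((diff <= 3 * np.maximum(se, 1.0)).all())

    summary = {
        "n_genes": len(abundance),
        "target_genes": target_genes,
        "coverage_threshold": coverage_threshold,
        "reads_needed": needed,
        "lane_reads": lane_reads,
        "multiplex_capacity": capacity,
        "benchmark_capacity_at_250k": benchmark_capacity,
        "simulation_matches_analytic_3se": agree,
        "n_replicates": curve.n_replicates,
    }
    return _finish(
        RunReport(
            scenario="saturation",
            seed=config.seed,
            config_hash=config.config_hash(),
            config=config.to_yaml(),
            files={
                "saturation_curve": str(curve_path),
                "abundance_profile": str(abund_path),
            },
            summary=summary,
        ),
        outdir,
    )
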