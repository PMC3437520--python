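"""Tab-delimited readers and writers for the package's data objects.

All formats are plain TSV so they can be produced by any upstream tool:
expression matrices (gene rows, sample columns), two-column group and
phase tables, eQTL catalogs, genetic maps, abundance profiles, and the
long-format analysis outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circadian import GroupTrajectory, PhaseAssignment, TimeCourseMatrix
from .depth import AbundanceProfile, SaturationCurve
from .entropy import EntropyCurve, ExpressionProfile, GroupAssignment, ValidationError
from .eqtl import EQTLCatalog, EQTLRecord, GeneticMap, HotspotProfile

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_group_assignment",
    "write_group_assignment",
    "read_eqtl_catalog",
    "write_eqtl_catalog",
    "read_genetic_map",
    "write_genetic_map",
    "read_abundance_profile",
    "write_abundance_profile",
    "read_time_course",
    "write_time_course",
    "read_phase_table",
    "write_phase_table",
    "write_entropy_curve",
    "write_hotspot_profile",
    "write_group_trajectory",
    "write_saturation_curve",
    "write_json_report",
]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Expression matrix: header row of sample names, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValidationError(f"{path}: expression values must be finite and >= 0")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def expression_profile_from_matrix(df: pd.DataFrame) -> ExpressionProfile:
    """Average expression across samples (columns) -> one profile."""
    return ExpressionProfile(dict(df.mean(axis=1)))


def read_group_assignment(
    path: str | Path, *, keep_first_duplicate: bool = False
) -> GroupAssignment:
    """Two-column TSV (gene_id, group_label), optional header.

    Genes listed more than once are rejected unless
    ``keep_first_duplicate`` keeps the first listed membership.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    # tolerate a header row: drop it if the first row repeats as column names
    if list(df.iloc[0]) == ["gene_id", "group_label"]:
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected 2 columns, found {df.shape[1]}")
    dup = df.iloc[:, 0].duplicated()
    if dup.any():
        if not keep_first_duplicate:
            genes = sorted(df.iloc[:, 0][dup].unique())[:5]
            raise ValidationError(
                f"{path}: gene(s) listed more than once, e.g. {genes}; "
                "pass keep_first_duplicate=True to keep the first membership"
            )
        df = df[~dup]
    return GroupAssignment(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_group_assignment(assignment: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup_label\n")
        for g in sorted(assignment.membership):
            fh.write(f"{g}\t{assignment.membership[g]}\n")


def read_eqtl_catalog(
    path: str | Path, expression_path: str | Path
) -> EQTLCatalog:
    """Catalog TSV (transcript_id, chromosome, position_cM) plus a
    two-column mean-expression table (transcript_id, mean_expression)."""
    cat = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "chromosome": str})
    expr = pd.read_csv(expression_path, sep="\t", dtype={0: str})
    records = tuple(
        EQTLRecord(
            transcript=str(r.transcript_id),
            chromosome=str(r.chromosome),
            position_cm=float(r.position_cM),
            kind=getattr(r, "kind", None),
        )
        for r in cat.itertuples(index=False)
    )
    mean_expr = dict(zip(expr.iloc[:, 0].astype(str), expr.iloc[:, 1].astype(float)))
    return EQTLCatalog(records=records, mean_expression=mean_expr)


def write_eqtl_catalog(
    catalog: EQTLCatalog, path: str | Path, expression_path: str | Path
) -> None:
    rows = [
        {
            "transcript_id": r.transcript,
            "chromosome": r.chromosome,
            "position_cM": r.position_cm,
            "kind": r.kind or "",
        }
        for r in catalog.records
    ]
    pd.DataFrame(rows, columns=["transcript_id", "chromosome", "position_cM", "kind"]).to_csv(
        path, sep="\t", index=False
    )
    with open(expression_path, "w") as fh:
        fh.write("transcript_id\tmean_expression\n")
        for t in sorted(catalog.mean_expression):
            fh.write(f"{t}\t{catalog.mean_expression[t]:.10g}\n")


def read_genetic_map(path: str | Path, bin_width: float = 1.0) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    chroms = tuple(
        (str(r.chromosome), float(r.length_cM)) for r in df.itertuples(index=False)
    )
    return GeneticMap(chromosomes=chroms, bin_width=bin_width)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tlength_cM\n")
        for name, length in gmap.chromosomes:
            fh.write(f"{name}\t{length:g}\n")


def read_abundance_profile(path: str | Path) -> AbundanceProfile:
    """Two-column TSV (gene_id, abundance); values are auto-normalised."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return AbundanceProfile.from_raw(
        dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    )


def write_abundance_profile(profile: AbundanceProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tabundance\n")
        for g, p in zip(profile.genes, profile.probabilities):
            fh.write(f"{g}\t{p:.10e}\n")


def write_time_course(matrix: TimeCourseMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_time_course(path: str | Path) -> TimeCourseMatrix:
    """Time-course TSV with "CT_<hour>" or "CT_<hour>_rep<k>" columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    times, reps = [], []
    for col in df.columns:
        if not col.startswith("CT_"):
            raise ValidationError(f"{path}: column {col!r} is not CT_<hour>[_rep<k>]")
        body = col[3:]
        if "_rep" in body:
            t_str, _, r_str = body.partition("_rep")
            times.append(float(t_str))
            reps.append(int(r_str))
        else:
            times.append(float(body))
            reps.append(0)
    order = np.lexsort((reps, times))
    df = df.iloc[:, order]
    return TimeCourseMatrix(
        data=df,
        times=tuple(times[i] for i in order),
        replicates=tuple(reps[i] for i in order),
    )


def read_phase_table(path: str | Path) -> PhaseAssignment:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return PhaseAssignment(dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))))


def write_phase_table(phases: PhaseAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpeak_CT_hour\n")
        for g in sorted(phases.phases):
            fh.write(f"{g}\t{phases.phases[g]:.6g}\n")


def write_entropy_curve(curve: EntropyCurve, path: str | Path) -> None:
    """TSV: subset_size, entropy_bits, fraction_of_full."""
    with open(path, "w") as fh:
        fh.write("subset_size\tentropy_bits\tfraction_of_full\n")
        for s, h, f in curve.points:
            fh.write(f"{s}\t{h:.10g}\t{f:.10g}\n")


def write_hotspot_profile(
    profile: HotspotProfile, gmap: GeneticMap, path: str | Path
) -> None:
    """Long TSV: subset_size, chromosome, bin_start_cM, eqtl_count."""
    with open(path, "w") as fh:
        fh.write("subset_size\tchromosome\tbin_start_cM\teqtl_count\n")
        for size in sorted(profile.counts_by_size):
            vec = profile.counts_by_size[size]
            for lab, c in zip(profile.bin_labels, vec):
                chrom, _, idx = lab.rpartition(":")
                start = int(idx) * gmap.bin_width
                fh.write(f"{size}\t{chrom}\t{start:g}\t{int(c)}\n")


def write_group_trajectory(traj: GroupTrajectory, path: str | Path) -> None:
    """Long TSV: ct_group, time, subset_size, mean_expression (NA if absent)."""
    with open(path, "w") as fh:
        fh.write("ct_group\ttime\tsubset_size\tmean_expression\n")
        for g in traj.groups:
            for s in traj.sizes:
                series = traj.values[(g, s)]
                for t, v in zip(traj.times, series):
                    sval = "NA" if not np.isfinite(v) else f"{v:.10g}"
                    fh.write(f"{g}\t{t:g}\t{s}\t{sval}\n")


def write_saturation_curve(curve: SaturationCurve, path: str | Path) -> None:
    curve.table.to_csv(path, sep="\t", index=False)


def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
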