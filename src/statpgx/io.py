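"""Plain-text readers and writers (TSV matrices and tables, YAML configs)."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .ase import SpliceQuant, TraceQuant
from .assoc import CohortRecord
from .prep import PairedExpressionSet
from .synthetic import SimConfig, SimOutput

__all__ = [
    "read_matrix", "write_matrix", "read_config", "write_config",
    "write_sim_output", "cohort_to_frame", "frame_to_cohort",
    "traces_to_frame", "frame_to_traces", "splice_to_frame", "frame_to_splice",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV: first column gene id, header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("factor_loading_range", "hap_freqs"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def write_config(config: SimConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["factor_loading_range"] = list(data["factor_loading_range"])
    data["hap_freqs"] = list(data["hap_freqs"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def cohort_to_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        row = {
            "subject_id": r.subject_id, "study": r.study,
            "baseline_ldl": ";".join(f"{v:.4f}" for v in r.baseline_ldl),
            "on_treatment_ldl": ";".join(f"{v:.4f}" for v in r.on_treatment_ldl),
            "age": r.age, "sex": r.sex, "bmi": r.bmi, "smoking": r.smoking,
        }
        for h, c in r.hap_copies.items():
            row[f"copies_{h}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[CohortRecord]:
    copies_cols = [c for c in df.columns if c.startswith("copies_")]
    out = []
    for _, r in df.iterrows():
        out.append(
            CohortRecord(
                subject_id=str(r["subject_id"]), study=str(r["study"]),
                baseline_ldl=[float(v) for v in str(r["baseline_ldl"]).split(";")],
                on_treatment_ldl=[float(v) for v in str(r["on_treatment_ldl"]).split(";")],
                age=float(r["age"]), sex=int(r["sex"]),
                bmi=float(r["bmi"]), smoking=int(r["smoking"]),
                hap_copies={c.removeprefix("copies_"): int(r[c]) for c in copies_cols},
            )
        )
    return out


def traces_to_frame(traces: list[TraceQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": t.sample_id, "snp_id": t.snp_id,
            "allele_a": t.alleles[0], "allele_b": t.alleles[1],
            "cdna_a": t.cdna_heights[0], "cdna_b": t.cdna_heights[1],
            "gdna_a": t.gdna_heights[0], "gdna_b": t.gdna_heights[1],
        }
        for t in traces
    )


def frame_to_traces(df: pd.DataFrame) -> list[TraceQuant]:
    return [
        TraceQuant(
            sample_id=str(r["sample_id"]), snp_id=str(r["snp_id"]),
            alleles=(str(r["allele_a"]), str(r["allele_b"])),
            cdna_heights=(float(r["cdna_a"]), float(r["cdna_b"])),
            gdna_heights=(float(r["gdna_a"]), float(r["gdna_b"])),
        )
        for _, r in df.iterrows()
    ]


def splice_to_frame(splice: list[SpliceQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": q.sample_id, "exposure": q.exposure,
            "total_q": q.total_q, "exon_q": q.exon_q, "batch": q.batch,
        }
        for q in splice
    )


def frame_to_splice(df: pd.DataFrame) -> list[SpliceQuant]:
    return [
        SpliceQuant(
            sample_id=str(r["sample_id"]), exposure=str(r["exposure"]),
            total_q=float(r["total_q"]), exon_q=float(r["exon_q"]),
            batch=str(r["batch"]),
        )
        for _, r in df.iterrows()
    ]


def write_sim_output(sim: SimOutput, out_dir: str | Path) -> None:
    """Write every simulated input as one-header-line TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(sim.lcl_expression.intensities, out / "lcl_intensities.tsv")
    write_matrix(sim.lcl_expression.detection_p, out / "lcl_detection_p.tsv")
    sim.lcl_expression.pairing.to_csv(out / "lcl_pairing.tsv", sep="\t")
    sim.lcl_expression.covariates.to_csv(out / "lcl_covariates.tsv", sep="\t")
    write_matrix(sim.hepatoma_expression.intensities, out / "hepatoma_intensities.tsv")
    sim.hepatoma_expression.pairing.to_csv(out / "hepatoma_pairing.tsv", sep="\t")
    write_matrix(sim.liver_detection, out / "liver_detection_p.tsv")
    cohort_to_frame(sim.cohort).to_csv(out / "cohort.tsv", sep="\t", index=False)
    traces_to_frame(sim.traces).to_csv(out / "traces.tsv", sep="\t", index=False)
    splice_to_frame(sim.splice).to_csv(out / "splice_qpcr.tsv", sep="\t", index=False)
    for name, table in sim.truth.items():
        table.to_csv(out / f"truth_{name}.tsv", sep="\t")
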