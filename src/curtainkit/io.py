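"""Readers, writers, run configuration and the pipeline driver.

On-disk conventions: TSV for tables, YAML for run configuration, JSON
for reports, TIFF for kymograms, FASTA + BED for substrates.  Times are
always seconds and positions base pairs in every file.  Readers reject
malformed input with row-addressed messages rather than coercing.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .kymo_positions import DNASubstrate, Feature
from .model_survival import (
    FrameSchedule,
    GlobalFitSpec,
    GlobalFitResult,
    SpotDataset,
    fit_global,
    kaplan_meier,
    survival_model,
)

__all__ = [
    "SPOT_COLUMNS",
    "read_spot_table",
    "write_spot_table",
    "read_substrate",
    "write_substrate",
    "read_trajectories",
    "write_trajectories",
    "write_fit_report",
    "write_km_curves",
    "validate_run_config",
    "run_pipeline",
]

SPOT_COLUMNS = [
    "measurement_id",
    "construct_id",
    "dna_id",
    "frame_delay_s",
    "illumination_s",
    "t_disappear_s",
    "censored",
]


class SchemaError(ValueError):
    """Malformed input file."""


def read_spot_table(path, c_overrides: dict[str, float] | None = None) -> list[SpotDataset]:
    """Read a spot disappearance table (TSV) into one dataset per
    measurement_id.

    Columns: measurement_id, construct_id, dna_id, frame_delay_s,
    illumination_s, t_disappear_s, censored (0/1).  The cut-off c
    defaults to the smallest uncensored time of each measurement unless
    overridden.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df["t_disappear_s"].isna().any() or (df["t_disappear_s"] < 0).any():
        rows = df.index[df["t_disappear_s"].isna() | (df["t_disappear_s"] < 0)].tolist()
        raise SchemaError(f"{path}: negative or missing t_disappear_s at rows {rows[:5]}")
    if not df["censored"].isin([0, 1]).all():
        rows = df.index[~df["censored"].isin([0, 1])].tolist()
        raise SchemaError(f"{path}: censored must be 0 or 1, offending rows {rows[:5]}")
    c_overrides = c_overrides or {}
    datasets = []
    for mid, g in df.groupby("measurement_id", sort=True):
        for col in ("construct_id", "dna_id", "frame_delay_s", "illumination_s"):
            if g[col].nunique() != 1:
                raise SchemaError(
                    f"{path}: measurement {mid!r} mixes values in column {col!r}"
                )
        censored = g["censored"].to_numpy().astype(bool)
        times = g["t_disappear_s"].to_numpy(dtype=float)
        if mid in c_overrides:
            c = float(c_overrides[mid])
        else:
            c = float(times[~censored].min()) if (~censored).any() else 0.0
        datasets.append(
            SpotDataset(
                disappearance_times=times,
                censored=censored,
                schedule=FrameSchedule(
                    float(g["illumination_s"].iloc[0]), float(g["frame_delay_s"].iloc[0])
                ),
                construct_id=str(g["construct_id"].iloc[0]),
                dna_id=str(g["dna_id"].iloc[0]),
                measurement_id=str(mid),
                c=c,
            )
        )
    return datasets


def write_spot_table(datasets: list[SpotDataset], path) -> None:
    rows = []
    for d in datasets:
        for t, cen in zip(d.disappearance_times, d.censored):
            rows.append(
                {
                    "measurement_id": d.measurement_id,
                    "construct_id": d.construct_id,
                    "dna_id": d.dna_id,
                    "frame_delay_s": d.schedule.frame_delay,
                    "illumination_s": d.schedule.illumination_time,
                    "t_disappear_s": t,
                    "censored": int(cen),
                }
            )
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_substrate(fasta_path, bed_path=None, n_bins: int = 40) -> DNASubstrate:
    """Single-record FASTA plus optional BED annotations (name column
    carrying the feature kind, CBS or promoter)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise SchemaError(
            f"{fasta_path}: expected a single-record FASTA, found {len(records)} records"
        )
    seq = str(records[0].seq).upper()
    features: list[Feature] = []
    if bed_path is not None:
        bed = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        ) if Path(bed_path).stat().st_size else pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
        for i, row in bed.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if not (0 <= start < end <= len(seq)):
                raise SchemaError(
                    f"{bed_path}: row {i} interval [{start}, {end}) outside "
                    f"sequence of length {len(seq)}"
                )
            kind = "promoter" if "promoter" in str(row["name"]).lower() else "CBS"
            strand = row["strand"] if row["strand"] in ("+", "-") else "+"
            features.append(Feature(start, end, strand, kind))
    return DNASubstrate(
        length=len(seq),
        sequence=seq,
        features=tuple(features),
        n_bins=n_bins,
        name=records[0].id,
    )


def write_substrate(substrate: DNASubstrate, fasta_path, bed_path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{substrate.name}\n")
        seq = substrate.sequence or ""
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for f in substrate.features:
            fh.write(
                f"{substrate.name}\t{f.start}\t{f.end}\t{f.kind}\t0\t{f.strand}\n"
            )


def read_trajectories(path):
    """TSV (traj_id, t_s, pos_bp) -> list of Trajectory."""
    from .tracking import Trajectory

    df = pd.read_csv(path, sep="\t")
    for col in ("traj_id", "t_s", "pos_bp"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = []
    for tid, g in df.groupby("traj_id", sort=True):
        g = g.sort_values("t_s")
        out.append(
            Trajectory(
                times=g["t_s"].to_numpy(dtype=float),
                positions=g["pos_bp"].to_numpy(dtype=float),
                traj_id=int(tid),
            )
        )
    return out


def write_trajectories(trajs, path) -> None:
    rows = []
    for tr in trajs:
        for t, p in zip(tr.times, tr.positions):
            rows.append({"traj_id": tr.traj_id, "t_s": t, "pos_bp": p})
    pd.DataFrame(rows, columns=["traj_id", "t_s", "pos_bp"]).to_csv(
        path, sep="\t", index=False
    )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_fit_report(result: GlobalFitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(asdict(result)), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_km_curves(datasets, result: GlobalFitResult, spec: GlobalFitSpec, path) -> None:
    """Per-dataset Kaplan-Meier points plus the fitted model curve, TSV."""
    from .model_survival import _ParamLayout

    layout = _ParamLayout(datasets, spec)
    rows = []
    for d in datasets:
        cv = kaplan_meier(d)
        params = layout.params_for(d, result.estimates)
        model = survival_model(cv.times, params)
        for t, s, v, m in zip(cv.times, cv.survival, cv.variance, np.atleast_1d(model)):
            rows.append(
                {
                    "measurement_id": d.measurement_id,
                    "t_s": t,
                    "km_survival": s,
                    "km_variance": v,
                    "model_survival": m,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = {"simulate", "fit_survival"}


def validate_run_config(config: dict, base: Path | None = None) -> dict:
    """Schema-validate a run configuration dict (from YAML)."""
    if not isinstance(config, dict):
        raise SchemaError("run config must be a mapping")
    stages = config.get("stages")
    if not stages or not isinstance(stages, list):
        raise SchemaError("run config needs a non-empty 'stages' list")
    for s in stages:
        if s not in _KNOWN_STAGES:
            raise SchemaError(
                f"unknown stage {s!r}; known stages: {sorted(_KNOWN_STAGES)}"
            )
    if "seed" in config and not isinstance(config["seed"], int):
        raise SchemaError("'seed' must be an integer")
    if "fit_survival" in stages and "simulate" not in stages:
        spots = config.get("spots")
        if not spots:
            raise SchemaError("stage fit_survival needs 'spots' (path) or a simulate stage")
        p = (base / spots) if base and not Path(spots).is_absolute() else Path(spots)
        if not p.exists():
            raise SchemaError(f"spots file {p} does not exist")
    return config


def run_pipeline(config: dict, out_dir, base: Path | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Writes per-stage outputs plus a provenance block (version, seed,
    config hash) to ``out_dir``; returns the report dict.
    """
    from .synthetic import five_delay_design

    config = validate_run_config(config, base)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {
        "provenance": {
            "curtainkit_version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(
                json.dumps(_jsonable(config), sort_keys=True).encode()
            ).hexdigest(),
        },
        "stages": {},
    }
    datasets = None
    try:
        if "simulate" in config["stages"]:
            sim = config.get("simulate", {})
            datasets, truth = five_delay_design(
                seed=seed,
                n_spots=int(sim.get("n_spots", 300)),
                tau=float(sim.get("tau", 3000.0)),
                tau_nu=float(sim.get("tau_nu", 30.0)),
                N=int(sim.get("N", 4)),
                l=float(sim.get("l", 0.52)),
            )
            write_spot_table(datasets, out_dir / "spots.tsv")
            with open(out_dir / "truth.json", "w") as fh:
                json.dump(_jsonable(truth), fh, indent=2, sort_keys=True)
            report["stages"]["simulate"] = {
                "n_measurements": len(datasets),
                "spots": "spots.tsv",
            }
        if "fit_survival" in config["stages"]:
            if datasets is None:
                spots = config["spots"]
                p = (base / spots) if base and not Path(spots).is_absolute() else Path(spots)
                datasets = read_spot_table(p, config.get("c_overrides"))
            fit_cfg = config.get("fit", {})
            dna_params = {
                d.dna_id: tuple(fit_cfg.get("dna_params", {}).get(d.dna_id, (4, 0.52)))
                for d in datasets
            }
            spec = GlobalFitSpec(
                dna_params=dna_params,
                tau_nu_init=float(fit_cfg.get("tau_nu_init", 100.0)),
                free_r=bool(fit_cfg.get("free_r", False)),
                free_l=bool(fit_cfg.get("free_l", False)),
                n_starts=int(fit_cfg.get("n_starts", 5)),
                start_seed=seed,
            )
            result = fit_global(datasets, spec)
            write_fit_report(result, out_dir / "fit_report.json")
            write_km_curves(datasets, result, spec, out_dir / "km_curves.tsv")
            report["stages"]["fit_survival"] = {
                "estimates": _jsonable(result.estimates),
                "stderr": _jsonable(result.stderr),
                "converged": result.converged,
            }
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        stage = "fit_survival" if datasets is not None else "simulate"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
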