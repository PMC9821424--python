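"""Readers and writers for subject CSVs, parameter JSON, and result tables.

Subject CSV layout: columns ``time_s`` (or ``time_min``), ``value_mM``,
``sigma_mM``, ``tissue``; all tissues of one subject stacked in one file.
Parameter JSON files are flat name-to-value maps keyed by the dataclass
field names.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SubjectDataset, TimeSeries, ValidationError
from .doseresponse import DoseResponseParams, NLMEFit
from .models import PatlakParams, PerfusionParams, WholeBodyParams
from .translation import TranslationResult, TRANSLATION_DISCLAIMER

__all__ = [
    "read_subject_csv",
    "write_subject_csv",
    "read_params_json",
    "write_params_json",
    "read_cohort_manifest",
    "write_cohort",
    "nlme_to_json",
    "nlme_from_json",
    "decision_table",
]

_PARAM_CLASSES = {
    "patlak": PatlakParams,
    "perfusion": PerfusionParams,
    "wholebody": WholeBodyParams,
    "doseresponse": DoseResponseParams,
}


def write_subject_csv(dataset: SubjectDataset, path) -> None:
    rows = []
    for tissue, ts in dataset.curves.items():
        sig = ts.sigmas if ts.sigmas is not None else np.full(len(ts), np.nan)
        for t, v, s in zip(ts.times, ts.values, sig):
            rows.append({"time_s": t, "value_mM": v, "sigma_mM": s, "tissue": tissue})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subject_csv(
    path,
    subject_id: str | None = None,
    species: str = "rat",
    dose_mg_per_kg: float = 0.0,
    **meta,
) -> SubjectDataset:
    """Read one subject's stacked time-series CSV.

    Accepts ``time_s`` or ``time_min`` (converted to seconds).  Validation
    failures (missing columns, non-monotone times, non-positive sigmas)
    raise :class:`~gadopk.data.ValidationError`.
    """
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        tcol, scale = "time_s", 1.0
    elif "time_min" in df.columns:
        tcol, scale = "time_min", 60.0
    else:
        raise ValidationError(f"{path}: need a time_s or time_min column")
    for col in ("value_mM", "tissue"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    curves = {}
    for tissue, grp in df.groupby("tissue", sort=False):
        sig = grp["sigma_mM"].to_numpy() if "sigma_mM" in grp else None
        if sig is not None and np.all(np.isnan(sig)):
            sig = None
        curves[str(tissue)] = TimeSeries(
            times=grp[tcol].to_numpy() * scale,
            values=grp["value_mM"].to_numpy(),
            sigmas=sig,
            tissue=str(tissue),
        )
    sid = subject_id or Path(path).stem
    return SubjectDataset(subject_id=sid, species=species,
                          dose_mg_per_kg=dose_mg_per_kg, curves=curves, **meta)


def write_params_json(params, path) -> None:
    d = dataclasses.asdict(params)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_params_json(path, model_name: str):
    cls = _PARAM_CLASSES[model_name]
    d = json.loads(Path(path).read_text())
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValidationError(f"{path}: unknown parameter names {sorted(unknown)}")
    return cls(**d)


def write_cohort(cohort: Sequence[SubjectDataset], truth: dict | None,
                 out_dir) -> Path:
    """Write per-subject CSVs, a manifest CSV, and the hidden-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in cohort:
        fname = f"{ds.subject_id}.csv"
        write_subject_csv(ds, out / fname)
        rows.append({"subject_id": ds.subject_id, "species": ds.species,
                     "dose_mg_per_kg": ds.dose_mg_per_kg, "path": fname})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return manifest


def read_cohort_manifest(manifest_path) -> list[SubjectDataset]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    cohort = []
    for _, row in df.iterrows():
        cohort.append(read_subject_csv(
            manifest_path.parent / row["path"],
            subject_id=str(row["subject_id"]),
            species=str(row.get("species", "rat")),
            dose_mg_per_kg=float(row.get("dose_mg_per_kg", 0.0)),
        ))
    return cohort


def nlme_to_json(fit: NLMEFit, path) -> None:
    """Serialize an NLME fit in the dose-response-table layout (rows k_i /
    k_ef; columns Max, Min, IC50, Hill) plus omegas and deviations."""
    d = {
        "table": {
            x: {
                "Max_per_s": p.max_x, "Min_per_s": p.min_x,
                "IC50_mg_per_kg": p.IC50_x, "Hill": p.Hill_x,
                "omega_per_s": p.omega_x,
            }
            for x, p in fit.params.items()
        },
        "individual_deviations": fit.individual_deviations,
        "doses": fit.doses,
        "seed": fit.seed,
        "converged": fit.converged,
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def nlme_from_json(path) -> dict[str, DoseResponseParams]:
    d = json.loads(Path(path).read_text())
    return {
        x: DoseResponseParams(
            min_x=row["Min_per_s"], max_x=row["Max_per_s"],
            IC50_x=row["IC50_mg_per_kg"], Hill_x=row["Hill"],
            omega_x=row.get("omega_per_s", 0.0),
        )
        for x, row in d["table"].items()
    }


def decision_table(results: Sequence[TranslationResult]) -> pd.DataFrame:
    """Dose-planning table (one row per patient) with the mandatory
    translation disclaimer attached as a DataFrame attribute."""
    rows = []
    for r in results:
        rows.append({
            "patient_id": r.patient_id,
            "current_uptake_rate_per_s": r.max_human,
            "maximal_allowed_dose_mg_per_kg":
                r.maximal_allowed_dose if math.isfinite(r.maximal_allowed_dose) else np.inf,
            "minimal_required_dose_mg_per_kg": r.minimal_required_dose,
            "decision": r.decision,
        })
    df = pd.DataFrame(rows)
    df.attrs["disclaimer"] = TRANSLATION_DISCLAIMER
    return df
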