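"""Serialization: ensembles as JSON/YAML, curves and TPC tables as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .feasibility import RichnessCurve
from .thermal import EnsembleTPC
from .tpc import TPCFitResult, TPCMeasurementSet

__all__ = [
    "ensemble_to_dict",
    "ensemble_from_dict",
    "write_ensemble",
    "read_ensemble",
    "write_richness_curve",
    "read_richness_curve",
    "read_tpc_csv",
    "write_tpc_csv",
    "fit_table",
    "load_config",
]

ENSEMBLE_FIELDS = ("mu_b0", "mu_e", "var_b0", "var_e", "cov_b0e")


def ensemble_to_dict(ens: EnsembleTPC) -> dict:
    return {f: float(getattr(ens, f)) for f in ENSEMBLE_FIELDS}


def ensemble_from_dict(d: dict) -> EnsembleTPC:
    missing = [f for f in ENSEMBLE_FIELDS if f not in d]
    if missing:
        raise ValueError(f"ensemble block missing fields: {missing}")
    return EnsembleTPC(**{f: float(d[f]) for f in ENSEMBLE_FIELDS})


def write_ensemble(ens: EnsembleTPC, path: str | Path) -> None:
    path = Path(path)
    d = ensemble_to_dict(ens)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def read_ensemble(path: str | Path) -> EnsembleTPC:
    path = Path(path)
    text = path.read_text()
    d = (
        yaml.safe_load(text)
        if path.suffix in {".yaml", ".yml"}
        else json.loads(text)
    )
    return ensemble_from_dict(d)


def write_richness_curve(curve: RichnessCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_richness_curve(path: str | Path, threshold: float = 0.5) -> RichnessCurve:
    df = pd.read_csv(path)
    return RichnessCurve(
        temperatures=df["temperature_C"].to_numpy() + 273.15,
        predicted_n=df["predicted_richness"].to_numpy(dtype=int),
        pfeas_threshold=threshold,
        simulated_n=(
            df["simulated_richness"].to_numpy(dtype=int)
            if "simulated_richness" in df
            else None
        ),
    )


def read_tpc_csv(path: str | Path) -> list[TPCMeasurementSet]:
    """Long-format CSV (strain_id, temp_C, trait_value) -> measurement sets."""
    df = pd.read_csv(path)
    required = {"strain_id", "temp_C", "trait_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"TPC CSV must have columns {sorted(required)}")
    bad = df[~np.isfinite(df["trait_value"]) | (df["trait_value"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive or non-finite trait_value at row {bad.index[0] + 2} "
            f"(strain {bad.iloc[0]['strain_id']!r})"
        )
    out = []
    for strain, grp in df.groupby("strain_id", sort=True):
        out.append(
            TPCMeasurementSet(
                strain_id=str(strain),
                temps_c=grp["temp_C"].to_numpy(dtype=float),
                values=grp["trait_value"].to_numpy(dtype=float),
            )
        )
    return out


def write_tpc_csv(datasets: list[TPCMeasurementSet], path: str | Path) -> None:
    rows = [
        {"strain_id": d.strain_id, "temp_C": t, "trait_value": v}
        for d in datasets
        for t, v in zip(d.temps_c, d.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_table(fits: list[TPCFitResult]) -> pd.DataFrame:
    """Per-strain fit results as a flat table."""
    rows = []
    for f in fits:
        row = {"strain_id": f.strain_id}
        if f.params is not None:
            row.update(
                log_b0=f.params.log_b0,
                e=f.params.e,
                e_h=f.params.e_h,
                t_h=f.params.t_h,
            )
        else:
            row.update(log_b0=np.nan, e=np.nan, e_h=np.nan, t_h=np.nan)
        for name in ("log_b0", "e", "e_h", "t_h"):
            row[f"p_{name}"] = f.p_values.get(name, np.nan)
        row["converged"] = f.converged
        row["accepted"] = f.accepted
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
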