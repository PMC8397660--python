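"""Configuration, parameter-set and clinical-table I/O plus run manifests.

All user-facing tables are plain CSV (long-format ANC, cohort traits,
scenario summaries); parameter sets are JSON or YAML with units embedded in
the field names.  Every CLI run writes a JSON manifest (seed, config hash,
package version) beside its outputs so any stochastic result can be
replayed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .lifecycle import PatientTraits
from .pkpd import PDParams, PKParams

__all__ = [
    "SchemaError",
    "read_anc_table",
    "load_pk_params",
    "load_pd_params",
    "default_pk",
    "exposure_calibrated_pk",
    "load_disease_set",
    "DiseaseSet",
    "write_manifest",
]

logger = logging.getLogger(__name__)

REQUIRED_ANC_COLUMNS = ("patient_id", "day", "anc_cells_per_l")


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


def read_anc_table(path) -> pd.DataFrame:
    """Read and validate a long-format clinical ANC table.

    Requires columns patient_id, day, anc_cells_per_l (optional gcsf_flag,
    parsed as booleans/0-1).  Malformed rows (non-numeric, negative ANC,
    days outside 1-28) are dropped and reported with their line numbers;
    a missing required column is a :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_ANC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    anc = pd.to_numeric(df["anc_cells_per_l"], errors="coerce")
    day = pd.to_numeric(df["day"], errors="coerce")
    bad = anc.isna() | day.isna() | (anc < 0) | (day < 1)
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path, len(lines), lines)
    out = df.loc[~bad].copy()
    out["anc_cells_per_l"] = anc[~bad]
    out["day"] = day[~bad].astype(int)
    if "gcsf_flag" in out.columns:
        out["gcsf_flag"] = out["gcsf_flag"].fillna(0).astype(int)
    return out.reset_index(drop=True)


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_pk_params(path) -> PKParams:
    """PK parameter set from a JSON/YAML file with unit-suffixed field names."""
    raw = _load_mapping(path)
    return PKParams(
        ka=raw["ka_per_h"],
        cl_over_f=raw["cl_over_f_l_per_h"],
        vc_over_f=raw["vc_over_f_l"],
        q=raw["q_l_per_h"],
        vp=raw["vp_l"],
    )


def load_pd_params(path) -> PDParams:
    raw = _load_mapping(path)
    return PDParams(
        emax=raw["emax"],
        ec50=raw["ec50_ng_per_ml"],
        n_hill=raw["n_hill"],
    )


def _bundled(name: str) -> dict:
    with resources.files("neutrosim.params").joinpath(name).open() as fh:
        return json.load(fh)


def default_pk() -> PKParams:
    """Bundled default PK set (peak-concentration-calibrated); used for
    simulation and virtual-trial screening."""
    raw = _bundled("pk_default.json")
    return PKParams(
        ka=raw["ka_per_h"],
        cl_over_f=raw["cl_over_f_l_per_h"],
        vc_over_f=raw["vc_over_f_l"],
        q=raw["q_l_per_h"],
        vp=raw["vp_l"],
    )


def exposure_calibrated_pk() -> PKParams:
    """Bundled PK set whose cycle-1 AUC reproduces the published exposure
    scale (236.17 ng/mL*h per mg on 5/7)."""
    raw = _bundled("pk_exposure_calibrated.json")
    return PKParams(
        ka=raw["ka_per_h"],
        cl_over_f=raw["cl_over_f_l_per_h"],
        vc_over_f=raw["vc_over_f_l"],
        q=raw["q_l_per_h"],
        vp=raw["vp_l"],
    )


@dataclass(frozen=True)
class DiseaseSet:
    """Median traits plus PD and fixed constants for one disease cohort."""

    name: str
    traits: PatientTraits
    pd_params: PDParams
    beta: float
    t_half: float
    k_d: float


def load_disease_set(name: str) -> DiseaseSet:
    """Bundled median parameter set for 'GBM', 'DLBCL' or 'MM'."""
    sets = _bundled("disease_sets.json")
    key = name.upper()
    if key not in sets:
        raise KeyError(f"unknown disease set {name!r}; have {sorted(k for k in sets if not k.startswith('_'))}")
    raw = sets[key]
    return DiseaseSet(
        name=key,
        traits=PatientTraits(
            circ0=raw["circ0_cells_per_l"],
            ratio_reserv0_circ0=raw["ratio_reserv0_circ0"],
            km_fraction=raw["km_fraction"],
            gamma=raw["gamma"],
        ),
        pd_params=PDParams(
            emax=raw["emax"],
            ec50=raw["ec50_ng_per_ml"],
            n_hill=raw["n_hill"],
        ),
        beta=raw["beta"],
        t_half=raw["t_half_neutrophil_h"],
        k_d=raw["k_d_per_h"],
    )


def write_manifest(out_dir, command: str, seed: int | None, config: dict) -> Path:
    """Write a machine-readable run manifest beside the outputs."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "neutrosim_version": __version__,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
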