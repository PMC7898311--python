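"""Parameter-file and tabular I/O.

Population and drug parameter sets are structured YAML; subject tables,
concentration profiles and PK summaries are CSV with a commented metadata
header (``# key: value`` lines) recording tool version, seed and input
provenance so every output is traceable.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .drugmodel import DrugParameters
from .pbpk import ConcentrationProfile
from .population import (
    PopulationParameters,
    ScrBand,
    SexParameters,
    VirtualSubject,
    subjects_to_frame,
)

__all__ = [
    "load_population", "load_drug", "save_population", "save_drug",
    "bundled_population_path", "bundled_drug_path",
    "list_bundled_populations", "list_bundled_drugs",
    "write_subjects_csv", "read_subjects_csv",
    "write_profile_csv", "write_table_csv", "read_observed_csv",
]

_POP_DIR = "populations"
_DRUG_DIR = "drugs"


def _data_dir(sub: str):
    return resources.files("renalpbpk.data") / sub


def list_bundled_populations() -> list[str]:
    return sorted(p.name[:-5] for p in _data_dir(_POP_DIR).iterdir()
                  if p.name.endswith(".yaml"))


def list_bundled_drugs() -> list[str]:
    return sorted(p.name[:-5] for p in _data_dir(_DRUG_DIR).iterdir()
                  if p.name.endswith(".yaml"))


def bundled_population_path(name: str):
    return _data_dir(_POP_DIR) / f"{name}.yaml"


def bundled_drug_path(name: str):
    return _data_dir(_DRUG_DIR) / f"{name}.yaml"


def _read_yaml(source) -> dict:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        with open(source) as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(source.read_text())


def _sex_params_from_dict(d: dict) -> SexParameters:
    return SexParameters(
        age_range=tuple(d["age_range"]),
        height_age_coeffs=tuple(d["height_age_coeffs"]),
        height_residual_sd=d.get("height_residual_sd", 0.0),
        weight_height_coeffs=tuple(d["weight_height_coeffs"]),
        scr_bands=[ScrBand(**b) for b in d["scr_bands"]],
        hematocrit=tuple(d["hematocrit"]),
        agp=tuple(d["agp"]),
        hsa_coeffs=tuple(d["hsa_coeffs"]),
    )


def load_population(name_or_path: str) -> PopulationParameters:
    """Load a population parameter set: a bundled name or a YAML file path."""
    if not Path(name_or_path).exists():
        candidate = bundled_population_path(name_or_path)
        try:
            raw = _read_yaml(candidate)
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no file {name_or_path!r} and no bundled population of that "
                f"name; bundled: {list_bundled_populations()}"
            ) from None
    else:
        raw = _read_yaml(name_or_path)
    kidney = raw["kidney"]
    return PopulationParameters(
        category=raw["category"],
        sex_ratio_f=raw["sex_ratio_f"],
        male=_sex_params_from_dict(raw["sexes"]["male"]),
        female=_sex_params_from_dict(raw["sexes"]["female"]),
        kidney_volume_coeffs=(
            kidney["volume_coeffs"]["baseline"],
            kidney["volume_coeffs"]["bw"],
            kidney["volume_coeffs"]["bh"],
        ),
        kidney_density_g_L=kidney.get("density_g_L", 1050.0),
        gfr_band=tuple(raw["gfr_band"]) if "gfr_band" in raw else None,
        hsa_form=raw.get("hsa_form", "quadratic_decade"),
        name=raw.get("name", str(name_or_path)),
        provenance=raw.get("provenance", ""),
    )


def save_population(params: PopulationParameters, path: str | Path) -> None:
    def sex_dict(sp: SexParameters) -> dict:
        return {
            "age_range": list(sp.age_range),
            "height_age_coeffs": list(sp.height_age_coeffs),
            "height_residual_sd": sp.height_residual_sd,
            "weight_height_coeffs": list(sp.weight_height_coeffs),
            "scr_bands": [b.model_dump() for b in sp.scr_bands],
            "hematocrit": list(sp.hematocrit),
            "agp": list(sp.agp),
            "hsa_coeffs": list(sp.hsa_coeffs),
        }

    doc = {
        "schema_version": 1,
        "name": params.name,
        "category": params.category,
        "sex_ratio_f": params.sex_ratio_f,
        "gfr_band": list(params.band),
        "hsa_form": params.hsa_form,
        "kidney": {
            "volume_coeffs": dict(zip(("baseline", "bw", "bh"),
                                      params.kidney_volume_coeffs)),
            "density_g_L": params.kidney_density_g_L,
        },
        "sexes": {"male": sex_dict(params.male), "female": sex_dict(params.female)},
        "provenance": params.provenance,
    }
    if params.scr_scale_applied is not None:
        doc["scr_scale_applied"] = params.scr_scale_applied
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_drug(name_or_path: str) -> DrugParameters:
    """Load a drug parameter set: a bundled name or a YAML file path."""
    if not Path(name_or_path).exists():
        candidate = bundled_drug_path(name_or_path)
        try:
            raw = _read_yaml(candidate)
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no file {name_or_path!r} and no bundled drug of that name; "
                f"bundled: {list_bundled_drugs()}"
            ) from None
    else:
        raw = _read_yaml(name_or_path)
    raw.pop("schema_version", None)
    raw.pop("provenance", None)
    return DrugParameters(**raw)


def save_drug(drug: DrugParameters, path: str | Path, provenance: str = "") -> None:
    doc = {"schema_version": 1, **drug.model_dump()}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# CSV with metadata headers
# ---------------------------------------------------------------------------

def _metadata_lines(meta: dict) -> str:
    lines = [f"# renalpbpk_version: {__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_table_csv(df: pd.DataFrame, path: str | Path, meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_lines(meta or {}))
        df.to_csv(fh, index=False)


def write_subjects_csv(
    subjects: Sequence[VirtualSubject], path: str | Path, meta: Optional[dict] = None
) -> None:
    """Subject table, one row per subject.  Units: age y, height cm, weight kg,
    scr umol/L and mg/dL, BSA m^2, GFR mL/min and mL/min/1.73 m^2, hematocrit
    fraction, AGP and HSA g/L, kidney volume mL."""
    write_table_csv(subjects_to_frame(subjects), path, meta)


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_profile_csv(
    profile: ConcentrationProfile, path: str | Path, meta: Optional[dict] = None
) -> None:
    df = pd.DataFrame({
        "time_h": profile.time_h,
        "plasma_conc_mg_L": profile.plasma_mg_L,
        "ae_renal_mg": profile.ae_renal_mg,
        "ae_nonrenal_mg": profile.ae_nonrenal_mg,
    })
    merged = {**profile.metadata, **(meta or {})}
    write_table_csv(df, path, merged)


def read_observed_csv(path: str | Path) -> pd.DataFrame:
    """Observed covariate or PK table (CSV, '#' comment lines allowed)."""
    return pd.read_csv(path, comment="#")
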