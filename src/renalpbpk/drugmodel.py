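"""Drug-dependent parameters, tissue partitioning and clearance scaling.

Tissue:plasma partition coefficients (Kp) are predicted mechanistically from
physicochemistry and tissue composition by either of the two standard schemes:

* lipid/water partitioning with plasma-protein correction (suited to neutral
  and moderately lipophilic compounds), or
* class-specific composition equations that handle ionisation explicitly
  (Henderson-Hasselbalch at tissue and plasma pH), with acidic-phospholipid
  binding for moderate-to-strong bases and albumin/lipoprotein binding for
  acids, neutrals, weak bases and zwitterions.

A single empirical Kp scalar can then be fitted in closed form so that the
predicted steady-state volume of distribution (Vss) matches an observed
clinical value.  Renal clearance scales proportionally with the subject's
glomerular filtration rate (GFR); the non-renal route is left untouched, and
plasma-protein binding is rescaled with the subject's albumin (HSA) or
alpha-1-acid glycoprotein (AGP) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .physiology import (
    REFERENCE_ADULT,
    ReferencePhysiology,
    TissueComposition,
    load_tissue_composition,
)

__all__ = [
    "DrugParameters",
    "KpSet",
    "predict_kp",
    "compute_vss",
    "fit_kp_scalar",
    "adjust_fu",
    "scale_renal_clearance",
    "ionized_fraction",
]

CompoundClass = Literal[
    "neutral", "monoprotic_acid", "monoprotic_base", "zwitterion"
]


class DrugParameters(BaseModel):
    """Physicochemistry, binding and disposition parameters for one compound.

    Clearances refer to the healthy Caucasian adult reference condition from
    which single-dose IV studies were digitised; they are rescaled per subject
    at model-build time.
    """

    name: str
    mw: float = Field(gt=0)  # g/mol
    compound_class: CompoundClass
    pka_values: list[float] = Field(default_factory=list)
    logp: float
    fu_plasma: float = Field(gt=0, le=1)
    bp_ratio: float = Field(gt=0)  # blood:plasma concentration ratio
    vss_obs: float = Field(gt=0)  # L/kg
    cl_iv: float = Field(gt=0)  # L/h, total plasma clearance (reference)
    clr: float = Field(ge=0)  # L/h, renal plasma clearance (reference)
    kp_method: Literal["poulin_theil", "rodgers_rowland"] = "rodgers_rowland"
    kp_scalar: Optional[float] = Field(default=None, gt=0)
    binding_protein: Literal["hsa", "agp"] = "hsa"
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "DrugParameters":
        if self.clr > self.cl_iv:
            raise ValueError("renal clearance cannot exceed total clearance")
        n_pka = len(self.pka_values)
        need = {"neutral": 0, "monoprotic_acid": 1, "monoprotic_base": 1,
                "zwitterion": 2}[self.compound_class]
        if n_pka != need:
            raise ValueError(
                f"{self.compound_class} requires {need} pKa value(s), got {n_pka}"
            )
        return self


@dataclass
class KpSet:
    """Tissue:plasma partition coefficients (unitless) plus the applied scalar."""

    values: dict[str, float]
    method: str
    scalar: float = 1.0

    def scaled(self, scalar: float) -> "KpSet":
        return KpSet(
            {t: kp * scalar for t, kp in self.values.items()},
            self.method,
            self.scalar * scalar,
        )

    def __getitem__(self, tissue: str) -> float:
        return self.values[tissue]


def ionized_fraction(pka: float, ph: float, kind: str) -> float:
    """Henderson-Hasselbalch ionised fraction of a monoprotic acid or base."""
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    raise ValueError(f"kind must be 'acid' or 'base', not {kind!r}")


def _logd(drug: DrugParameters, ph: float) -> float:
    """logD at the given pH from logP and the ionisation state."""
    shift = 0.0
    if drug.compound_class == "monoprotic_acid":
        shift = math.log10(1.0 + 10.0 ** (ph - drug.pka_values[0]))
    elif drug.compound_class == "monoprotic_base":
        shift = math.log10(1.0 + 10.0 ** (drug.pka_values[0] - ph))
    elif drug.compound_class == "zwitterion":
        # acid branch on the acidic pKa dominates for the compounds modelled here
        shift = math.log10(1.0 + 10.0 ** (ph - min(drug.pka_values)))
    return drug.logp - shift


# ---------------------------------------------------------------------------
# Kp prediction
# ---------------------------------------------------------------------------

def _kp_lipid_water(drug: DrugParameters, comp: TissueComposition) -> dict[str, float]:
    """Lipid/water partitioning scheme with unbound-fraction correction.

    Non-adipose tissues partition by octanol:water P of the neutral species;
    adipose uses the vegetable-oil-like D at plasma pH.  Tissue unbound
    fraction is approximated from the plasma one (interstitial protein at half
    plasma concentration).
    """
    p = 10.0 ** drug.logp
    d_adipose = 10.0 ** _logd(drug, comp.ph_plasma)
    fu_p = drug.fu_plasma
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    pl = comp.plasma
    denom = p * (pl["f_nl"] + 0.3 * pl["f_np"]) + (pl["f_w"] + 0.7 * pl["f_np"])
    denom_ad = d_adipose * (pl["f_nl"] + 0.3 * pl["f_np"]) + (
        pl["f_w"] + 0.7 * pl["f_np"]
    )
    out: dict[str, float] = {}
    for tissue, c in comp.tissues.items():
        f_w = c["f_ew"] + c["f_iw"]
        if tissue == "adipose":
            num = d_adipose * (c["f_nl"] + 0.3 * c["f_np"]) + (f_w + 0.7 * c["f_np"])
            out[tissue] = num / denom_ad * fu_p  # fu_adipose ~ 1
        else:
            num = p * (c["f_nl"] + 0.3 * c["f_np"]) + (f_w + 0.7 * c["f_np"])
            out[tissue] = num / denom * fu_p / fu_t
    return out


def _kp_composition_based(
    drug: DrugParameters, comp: TissueComposition
) -> dict[str, float]:
    """Class-specific composition equations with explicit ionisation.

    Moderate-to-strong bases (basic pKa >= 7) bind tissue acidic phospholipids
    with an association constant back-calculated from the blood:plasma ratio;
    acids, neutrals, weak bases and zwitterions bind albumin (neutrals:
    lipoproteins) at the tissue:plasma protein ratio.  Zwitterions take the
    acid branch.
    """
    p = 10.0 ** drug.logp
    fu_p = drug.fu_plasma
    ph_p, ph_iw, ph_bc = comp.ph_plasma, comp.ph_intracellular, comp.ph_blood_cells
    pl, bc = comp.plasma, comp.blood_cells

    basic_pkas = [k for k in drug.pka_values] if drug.compound_class == "monoprotic_base" else []
    strong_base = bool(basic_pkas) and max(basic_pkas) >= 7.0

    def neutral_lipid_term(c: dict[str, float]) -> float:
        return p * c["f_nl"] + (0.3 * p + 0.7) * c["f_np"]

    if strong_base:
        pka = max(basic_pkas)
        y = 1.0 + 10.0 ** (pka - ph_p)
        # acidic-phospholipid association constant from blood-cell partitioning
        hct_free = 0.45  # nominal hematocrit used solely to back out Ka
        kpu_bc = (drug.bp_ratio - (1.0 - hct_free)) / (hct_free * fu_p)
        x_bc = 1.0 + 10.0 ** (pka - ph_bc)
        ka = (
            (kpu_bc - x_bc / y * bc["f_w"] - neutral_lipid_term(bc) / y)
            * y
            / (bc["ap_mg_g"] * 10.0 ** (pka - ph_bc))
        )
        ka = max(ka, 0.0)
        out = {}
        for tissue, c in comp.tissues.items():
            x = 1.0 + 10.0 ** (pka - ph_iw)
            kpu = (
                c["f_ew"]
                + x / y * c["f_iw"]
                + ka * c["ap_mg_g"] * 10.0 ** (pka - ph_iw) / y
                + neutral_lipid_term(c) / y
            )
            out[tissue] = max(kpu * fu_p, 1e-6)
        return out

    # acids / neutrals / weak bases / zwitterions: protein-binding branch
    if drug.compound_class in ("monoprotic_acid", "zwitterion"):
        # zwitterions take the acid branch on their acidic pKa (design choice)
        pka = min(drug.pka_values)
        x_num = 1.0 + 10.0 ** (ph_iw - pka)
        y = 1.0 + 10.0 ** (ph_p - pka)
    elif drug.compound_class == "monoprotic_base":  # weak base
        pka = drug.pka_values[0]
        x_num = 1.0 + 10.0 ** (pka - ph_iw)
        y = 1.0 + 10.0 ** (pka - ph_p)
    else:
        x_num, y = 1.0, 1.0

    plasma_lipid = neutral_lipid_term(pl)
    protein_term_plasma = 1.0 / fu_p - 1.0 - plasma_lipid / y
    out = {}
    for tissue, c in comp.tissues.items():
        ratio_key = "lip_ratio" if drug.compound_class == "neutral" else "alb_ratio"
        kpu = (
            c["f_ew"]
            + x_num / y * c["f_iw"]
            + neutral_lipid_term(c) / y
            + max(protein_term_plasma, 0.0) * c[ratio_key]
        )
        out[tissue] = max(kpu * fu_p, 1e-6)
    return out


def predict_kp(
    drug: DrugParameters,
    composition: Optional[TissueComposition] = None,
    method: Optional[str] = None,
) -> KpSet:
    """Predict plasma-referenced tissue:plasma partition coefficients."""
    comp = composition if composition is not None else load_tissue_composition()
    meth = method or drug.kp_method
    if meth == "poulin_theil":
        values = _kp_lipid_water(drug, comp)
    elif meth == "rodgers_rowland":
        values = _kp_composition_based(drug, comp)
    else:
        raise ValueError(f"unknown Kp method {meth!r}")
    return KpSet(values, meth)


# ---------------------------------------------------------------------------
# Vss and the Kp scalar
# ---------------------------------------------------------------------------

def compute_vss(
    kpset: KpSet,
    physiology: ReferencePhysiology = REFERENCE_ADULT,
    bw_kg: Optional[float] = None,
    tissue_volumes_L: Optional[dict[str, float]] = None,
) -> float:
    """Steady-state volume of distribution (L/kg): (Vp + sum Kp_t * V_t) / BW."""
    bw = bw_kg if bw_kg is not None else physiology.bw_kg
    vols = (
        tissue_volumes_L
        if tissue_volumes_L is not None
        else physiology.scaled_volumes(bw)
    )
    vp = physiology.plasma_volume(bw)
    missing = set(vols) - set(kpset.values)
    if missing:
        raise KeyError(f"KpSet lacks tissues {sorted(missing)}")
    return (vp + sum(kpset[t] * v for t, v in vols.items())) / bw


def fit_kp_scalar(
    kpset_unscaled: KpSet,
    vss_obs: float,
    physiology: ReferencePhysiology = REFERENCE_ADULT,
) -> float:
    """Closed-form scalar bringing predicted Vss onto the observed value.

    Vss is affine in a uniform Kp scalar s:  Vss(s) = Vp/BW + s * (Vss(1) -
    Vp/BW), so s = (Vss_obs - Vp/BW) / (Vss_pred - Vp/BW).
    """
    vp_bw = physiology.plasma_volume(physiology.bw_kg) / physiology.bw_kg
    vss_pred = compute_vss(kpset_unscaled, physiology)
    if abs(vss_pred - vp_bw) < 1e-12:
        raise ValueError("predicted Vss equals plasma volume; scalar undefined")
    scalar = (vss_obs - vp_bw) / (vss_pred - vp_bw)
    if scalar <= 0:
        raise ValueError(
            f"observed Vss {vss_obs} L/kg is at or below the plasma volume "
            f"{vp_bw:.3f} L/kg; a positive Kp scalar cannot reach it"
        )
    return float(scalar)


# ---------------------------------------------------------------------------
# subject-level scaling
# ---------------------------------------------------------------------------

def adjust_fu(fu_ref: float, protein_subject: float, protein_ref: float) -> float:
    """Rescale the unbound plasma fraction for a changed binding-protein level.

    Under linear binding the bound:free ratio is proportional to protein
    concentration:  fu_s = 1 / (1 + ((1 - fu_ref)/fu_ref) * P_s/P_ref).
    """
    if protein_ref <= 0:
        raise ValueError("reference protein concentration must be positive")
    if protein_subject < 0:
        raise ValueError("protein concentration cannot be negative")
    if not (0 < fu_ref <= 1):
        raise ValueError("fu_ref must lie in (0, 1]")
    return 1.0 / (1.0 + (1.0 - fu_ref) / fu_ref * protein_subject / protein_ref)


def scale_renal_clearance(
    clr_ref: float, gfr_subject: float, gfr_ref: float, cl_ref: Optional[float] = None
) -> float | tuple[float, float]:
    """GFR-proportional renal clearance; the non-renal route is untouched.

    Returns CLr_subject, or (CLr_subject, CL_total_subject) when the reference
    total clearance is supplied.
    """
    if gfr_ref <= 0:
        raise ValueError("reference GFR must be positive")
    if clr_ref < 0 or gfr_subject < 0:
        raise ValueError("clearances and GFR cannot be negative")
    clr_s = clr_ref * gfr_subject / gfr_ref
    if cl_ref is None:
        return clr_s
    if cl_ref < clr_ref:
        raise ValueError("total clearance below its renal component")
    return clr_s, clr_s + (cl_ref - clr_ref)
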