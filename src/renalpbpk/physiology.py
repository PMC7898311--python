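"""Reference whole-body physiology and tissue composition.

A reference healthy adult (70 kg, BSA 1.8 m^2) supplies organ volumes and the
fraction of cardiac output perfusing each organ; per-subject models scale
volumes linearly with body weight and blood flows with body surface area.
Tissue composition (water, lipid, phospholipid fractions, acidic-phospholipid
content, binding-protein tissue:plasma ratios) for partition-coefficient
prediction ships as package data transcribed from the published adult
composition tables of the tissue-partitioning literature (see docs/methods.md
for sources).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "TISSUES",
    "ReferencePhysiology",
    "REFERENCE_ADULT",
    "TissueComposition",
    "load_tissue_composition",
]

#: perfusion-limited tissue compartments of the whole-body model
TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "skin", "spleen", "rest",
)

#: tissues whose venous outflow drains into the portal vein (to the liver)
SPLANCHNIC = ("gut", "spleen")


@dataclass(frozen=True)
class ReferencePhysiology:
    """Organ volumes (L) and flow fractions for a reference adult."""

    bw_kg: float = 70.0
    bsa_m2: float = 1.8
    cardiac_output_L_h: float = 336.0  # 5.6 L/min at rest
    volumes_L: dict[str, float] = field(default_factory=lambda: {
        "adipose": 14.5, "bone": 10.5, "brain": 1.45, "gut": 1.65,
        "heart": 0.33, "kidney": 0.31, "liver": 1.80, "lung": 0.53,
        "muscle": 29.0, "skin": 3.41, "spleen": 0.15, "rest": 2.50,
    })
    plasma_L: float = 3.10
    arterial_blood_L: float = 1.70
    venous_blood_L: float = 3.80
    #: fraction of cardiac output; liver entry is the hepatic artery only,
    #: total liver inflow additionally receives the gut and spleen outflow
    flow_fracs: dict[str, float] = field(default_factory=lambda: {
        "adipose": 0.050, "bone": 0.050, "brain": 0.120, "gut": 0.160,
        "heart": 0.040, "kidney": 0.190, "liver": 0.065, "muscle": 0.170,
        "skin": 0.050, "spleen": 0.030, "rest": 0.075,
    })
    reference_gfr_mL_min: float = 120.0
    reference_hsa_g_L: float = 45.0
    reference_agp_g_L: float = 0.80

    def scaled_volumes(self, bw_kg: float) -> dict[str, float]:
        """Organ volumes scaled linearly with body weight."""
        f = bw_kg / self.bw_kg
        return {t: v * f for t, v in self.volumes_L.items()}

    def scaled_flows(self, bsa_m2: float) -> tuple[float, dict[str, float]]:
        """Cardiac output (scaled with BSA) and organ flows in L/h.

        Flow fractions are renormalised to sum exactly to one, so the organ
        flows conserve cardiac output by construction.
        """
        co = self.cardiac_output_L_h * bsa_m2 / self.bsa_m2
        total = sum(self.flow_fracs.values())
        return co, {t: co * f / total for t, f in self.flow_fracs.items()}

    def plasma_volume(self, bw_kg: float) -> float:
        return self.plasma_L * bw_kg / self.bw_kg


REFERENCE_ADULT = ReferencePhysiology()


@dataclass(frozen=True)
class TissueComposition:
    """Fractional composition of each model tissue, plasma and blood cells.

    Per tissue: extracellular/intracellular water, neutral lipid and neutral
    phospholipid volume fractions, acidic phospholipid content (mg/g), and the
    tissue:plasma ratios of albumin and lipoprotein.  pH values of plasma,
    intracellular water and blood cells are carried alongside.
    """

    tissues: dict[str, dict[str, float]]
    plasma: dict[str, float]
    blood_cells: dict[str, float]
    ph_plasma: float = 7.4
    ph_intracellular: float = 7.0
    ph_blood_cells: float = 7.22

    def require(self, tissue: str) -> dict[str, float]:
        if tissue not in self.tissues:
            raise KeyError(
                f"no composition entry for tissue {tissue!r}; "
                f"available: {sorted(self.tissues)}"
            )
        return self.tissues[tissue]


def load_tissue_composition(path: str | None = None) -> TissueComposition:
    """Load the bundled (or a user-supplied) tissue composition table."""
    if path is None:
        ref = resources.files("renalpbpk.data") / "tissue_composition.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return TissueComposition(
        tissues=raw["tissues"],
        plasma=raw["plasma"],
        blood_cells=raw["blood_cells"],
        ph_plasma=raw.get("ph_plasma", 7.4),
        ph_intracellular=raw.get("ph_intracellular", 7.0),
        ph_blood_cells=raw.get("ph_blood_cells", 7.22),
    )
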