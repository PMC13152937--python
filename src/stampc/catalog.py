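"""Canonical catalog of the 16 CT-based parameters for abdominal wall
reconstruction (AWR) planning.

The catalog is the single source of parameter identity for every downstream
stage: documentation audit, survey simulation, MCDA prioritization.  Each
parameter is either *generalizable* (assessable on CT without knowledge of
the patient's surgical history; audited against the whole cohort) or
*patient-specific* (conditional on prior interventions; audited against its
intraoperative occurrence count, so documentation rates may exceed 100% when
radiologists over-call sub-threshold findings).

Seven parameters form the STAMP-C essential panel: Size (defect width),
Tanaka index, Anatomical location (EHS), Mesh presence, Plane of old mesh,
and Concurrent inguinal / parastomal-or-stomal hernias (the letter C covers
two parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Category(str, Enum):
    GENERALIZABLE = "generalizable"
    PATIENT_SPECIFIC = "patient_specific"


@dataclass(frozen=True)
class ParameterDef:
    """One CT-based planning parameter.

    Attributes
    ----------
    id : stable lowercase snake-case slug, used as the join key everywhere.
    name : display name.
    category : generalizable vs patient-specific (decides audit denominator).
    definition : how the feature is read off the CT study.
    stampc_letter : mnemonic letter for essential-panel members, else None.
    """

    id: str
    name: str
    category: Category
    definition: str
    stampc_letter: Optional[str] = None


# Catalog order follows the survey-importance listing (highest-rated first).
CATALOG: tuple[ParameterDef, ...] = (
    ParameterDef(
        "defect_width",
        "Defect width",
        Category.GENERALIZABLE,
        "Transverse distance between the medial fascial edges at the widest "
        "point of the hernia defect on axial CT view",
        "S",
    ),
    ParameterDef(
        "concurrent_parastomal",
        "Concurrent parastomal or old stomal site hernias",
        Category.PATIENT_SPECIFIC,
        "Presence of a hernia adjacent to a stoma or old stomal site",
        "C",
    ),
    ParameterDef(
        "old_mesh_plane",
        "Old mesh plane",
        Category.PATIENT_SPECIFIC,
        "Anatomical layer in which previously placed mesh is located "
        "(onlay, sublay, underlay)",
        "P",
    ),
    ParameterDef(
        "prior_mesh",
        "Presence of prior mesh",
        Category.PATIENT_SPECIFIC,
        "Whether previously placed prosthetic mesh is visualized within the "
        "abdominal wall or peritoneal cavity",
        "M",
    ),
    ParameterDef(
        "concurrent_inguinal",
        "Concurrent inguinal hernias",
        Category.PATIENT_SPECIFIC,
        "Ipsilateral or contralateral inguinal hernias",
        "C",
    ),
    ParameterDef(
        "tanaka_index",
        "Tanaka index",
        Category.GENERALIZABLE,
        "Ratio of hernia sac volume to total peritoneal volume",
        "T",
    ),
    ParameterDef(
        "ehs_location",
        "Hernia location (EHS classification)",
        Category.GENERALIZABLE,
        "Anatomical location of the defect per the European Hernia Society "
        "classification",
        "A",
    ),
    ParameterDef(
        "wall_abnormality",
        "Abdominal wall anatomical abnormalities",
        Category.PATIENT_SPECIFIC,
        "Loss or scarring of native fascial planes, particularly the "
        "posterior rectus sheath, often from prior surgery or infection",
    ),
    ParameterDef(
        "number_of_defects",
        "Number of defects",
        Category.GENERALIZABLE,
        "Total number of discrete fascial defects on axial and coronal views",
    ),
    ParameterDef(
        "rectus_measurements",
        "Rectus muscle measurements",
        Category.GENERALIZABLE,
        "Rectus abdominis width (medial to lateral) and depth (ventral to "
        "dorsal) at the widest part of the hernia, axial view",
    ),
    ParameterDef(
        "patient_habitus",
        "Patient habitus and fat distribution",
        Category.GENERALIZABLE,
        "Predominant adipose distribution, visceral vs subcutaneous, from "
        "skin-to-fascia and fascia-to-bowel-wall distances",
    ),
    ParameterDef(
        "mesh_migration",
        "Mesh migration",
        Category.PATIENT_SPECIFIC,
        "Displacement of mesh from its intended anatomical location",
    ),
    ParameterDef(
        "defect_length",
        "Defect length",
        Category.GENERALIZABLE,
        "Longitudinal distance from the most cephalad to the most caudal "
        "extent of the fascial defect on sagittal view",
    ),
    ParameterDef(
        "mesh_fracture",
        "Central mesh fracture",
        Category.PATIENT_SPECIFIC,
        "Structural discontinuity, segmentation, or tearing of previously "
        "placed mesh",
    ),
    ParameterDef(
        "hernia_content",
        "Hernia content",
        Category.GENERALIZABLE,
        "Abdominal viscera within the hernia sac",
    ),
    ParameterDef(
        "ongoing_sso",
        "Ongoing surgical site occurrences",
        Category.PATIENT_SPECIFIC,
        "Wound-related complications: surgical site infection, seroma, "
        "hematoma, abdominal wall abscess, or enterocutaneous fistula",
    ),
)

PARAMETER_IDS: tuple[str, ...] = tuple(p.id for p in CATALOG)

_BY_ID = {p.id: p for p in CATALOG}


def load_parameter_catalog() -> tuple[ParameterDef, ...]:
    """Return the canonical immutable 16-parameter catalog, in display order."""
    return CATALOG


def get_parameter(param_id: str) -> ParameterDef:
    try:
        return _BY_ID[param_id]
    except KeyError:
        raise KeyError(f"unknown parameter id: {param_id!r}") from None


def generalizable_ids() -> tuple[str, ...]:
    return tuple(p.id for p in CATALOG if p.category is Category.GENERALIZABLE)


def patient_specific_ids() -> tuple[str, ...]:
    return tuple(
        p.id for p in CATALOG if p.category is Category.PATIENT_SPECIFIC
    )


def stampc_ids() -> tuple[str, ...]:
    """The 7-parameter essential panel (letter C maps to two parameters)."""
    return tuple(p.id for p in CATALOG if p.stampc_letter is not None)


def catalog_to_records() -> list[dict]:
    """JSON-serializable view of the catalog (for catalog.json)."""
    return [
        {
            "id": p.id,
            "name": p.name,
            "category": p.category.value,
            "definition": p.definition,
            "stampc_letter": p.stampc_letter,
        }
        for p in CATALOG
    ]
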