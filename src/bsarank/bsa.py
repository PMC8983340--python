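"""Six-component additive score for a broad-spectrum antiviral against a
virus of interest (Voi).

The components, each a dyadic rational so that the sum is exact in binary
floating point:

- ``c_sar``  (1 / 0.5 / 0): the drug itself has been developed against the
  Voi; or it is structurally similar to such a drug; or neither.
- ``c_dds``  (1 / 0.75 / 0.5 / 0.25 / 0): development-status ladder
  (approved-or-phase-4, phase 1-3, in vivo, in vitro, untested) against the
  Voi.  Applies only when ``c_sar == 1``; otherwise forced to 0.
- ``c_tr``   (1 / 0): the drug's confirmed primary target is annotated as
  essential for Voi replication.
- ``c_ic``   (1 / 0): the drug does not interfere with the host immune
  response.  Unknown immunomodulatory status scores 1 (not reported is not
  a demonstrated liability).
- ``c_roa``  (1 / 0): at least one of the drug's administration routes is
  suited to the organ systems the Voi infects.
- ``c_phyl`` (1 / 0.5 / 0.25 / 0): taxonomy ladder between the Voi and the
  viruses the drug has recorded activity against (same genus / same family /
  related family / distant); when the drug has activity against several
  viruses the maximum over those references is taken.

Total = c_sar + c_dds + c_tr + c_ic + c_roa + c_phyl, in [0, 6].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotations import (
    ActivityStatus,
    AnnotationBundle,
    DrugAnnotation,
    Immunomodulatory,
    VirusAnnotation,
    normalize_id,
)
from .config import RunConfig
from .relatedness import C_PHYL_BY_RELATION, relation
from .sar import SimilarityProvider

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "BsaScoreBreakdown",
    "score_sar",
    "score_dds",
    "score_tr",
    "score_ic",
    "score_roa",
    "score_phyl",
    "compute_bsa_score",
    "BSA_COMPONENTS",
    "DDS_LADDER",
]

BSA_COMPONENTS = ("c_sar", "c_dds", "c_tr", "c_ic", "c_roa", "c_phyl")

#: Development-status ladder for c_dds.
DDS_LADDER: dict[ActivityStatus, float] = {
    ActivityStatus.APPROVED_OR_PHASE4: 1.0,
    ActivityStatus.PHASE1_3: 0.75,
    ActivityStatus.IN_VIVO: 0.5,
    ActivityStatus.IN_VITRO: 0.25,
    ActivityStatus.UNTESTED: 0.0,
}


@dataclass(frozen=True)
class BsaScoreBreakdown:
    """The six components, their exact sum, and per-component provenance."""

    drug_id: str
    virus_id: str
    c_sar: float
    c_dds: float
    c_tr: float
    c_ic: float
    c_roa: float
    c_phyl: float
    total: float
    provenance: dict[str, str] = field(default_factory=dict, compare=False)

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BSA_COMPONENTS}

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "virus_id": self.virus_id,
            **self.components(),
            "total": self.total,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BsaScoreBreakdown":
        return cls(
            drug_id=data["drug_id"],
            virus_id=data["virus_id"],
            total=data["total"],
            provenance=dict(data.get("provenance", {})),
            **{k: data[k] for k in BSA_COMPONENTS},
        )


def _sar_detail(
    drug: DrugAnnotation,
    voi: str,
    bundle: AnnotationBundle,
    similarity: Optional[SimilarityProvider],
) -> tuple[float, str]:
    voi = normalize_id(voi)
    status = bundle.activity_status(drug.drug_id, voi)
    if status is not ActivityStatus.UNTESTED:
        return 1.0, f"drug has a {status.value} record against {voi}"
    if similarity is not None:
        developed = bundle.drugs_with_activity(voi)
        developed = [d for d in developed if d != drug.drug_id]
        if developed and similarity.is_similar(drug.drug_id, developed):
            return 0.5, f"structurally similar to a drug developed against {voi}"
    return 0.0, f"no record against {voi} and no qualifying structural similarity"


def score_sar(
    drug: DrugAnnotation,
    voi: str,
    bundle: AnnotationBundle,
    similarity: Optional[SimilarityProvider] = None,
) -> float:
    """C_SAR: 1 for a drug with a development record against the Voi, 0.5 for
    structural similarity to such a drug, 0 otherwise.

    Without a similarity provider (or without a structure for the drug) the
    0.5 rung cannot fire; the component quietly falls to 0.
    """
    return _sar_detail(drug, voi, bundle, similarity)[0]


def score_dds(status: ActivityStatus, c_sar: float) -> float:
    """C_DDS: development-status ladder, gated on c_sar == 1."""
    if c_sar != 1.0:
        return 0.0
    return DDS_LADDER[ActivityStatus(status)]


def score_tr(drug: DrugAnnotation, voi: str) -> float:
    """C_TR: 1 iff the drug's primary target is annotated essential for the Voi."""
    return 1.0 if normalize_id(voi) in drug.target_essential_for else 0.0


def score_ic(drug: DrugAnnotation) -> float:
    """C_IC: 1 unless the drug is annotated immunomodulatory."""
    return 0.0 if drug.immunomodulatory is Immunomodulatory.YES else 1.0


def score_roa(drug: DrugAnnotation, voi: VirusAnnotation, config: Optional[RunConfig] = None) -> float:
    """C_RoA: 1 iff any of the drug's routes suits an infected organ system."""
    config = config or RunConfig()
    if not drug.routes:
        logger.warning("drug %s has no routes; c_roa scored 0", drug.drug_id)
        return 0.0
    suitable = config.suitable_routes(voi.infected_systems)
    return 1.0 if drug.routes & suitable else 0.0


def score_phyl(voi: VirusAnnotation, reference_virus: VirusAnnotation) -> float:
    """C_Phyl for a single reference virus: 1 / 0.5 / 0.25 / 0 down the
    same-genus, same-family, related-family ladder."""
    rel = relation(voi, reference_virus)
    return C_PHYL_BY_RELATION[rel] if rel is not None else 0.0


def _phyl_detail(
    drug: DrugAnnotation, voi: VirusAnnotation, bundle: AnnotationBundle
) -> tuple[float, str]:
    references = bundle.reference_viruses(drug.drug_id)
    best, best_ref = 0.0, None
    for ref_id in references:
        value = score_phyl(voi, bundle.viruses[ref_id])
        if value > best:
            best, best_ref = value, ref_id
    if best_ref is None:
        return 0.0, "no activity record against a virus related to the Voi"
    return best, f"strongest reference {best_ref} (max over {len(references)} reference viruses)"


def compute_bsa_score(
    drug_id: str,
    voi: str,
    bundle: AnnotationBundle,
    config: Optional[RunConfig] = None,
    similarity: Optional[SimilarityProvider] = None,
) -> BsaScoreBreakdown:
    """Compute the full six-component breakdown for a drug against a Voi.

    Manual per-component overrides in ``config.overrides`` (keys
    ``bsa:<drug>:<virus>:<component>``) replace the computed value and are
    recorded in provenance.
    """
    config = config or RunConfig()
    drug = bundle.drug(drug_id)
    virus = bundle.virus(voi)

    provenance: dict[str, str] = {}

    c_sar, note = _sar_detail(drug, virus.virus_id, bundle, similarity)
    provenance["c_sar"] = note

    status = bundle.activity_status(drug.drug_id, virus.virus_id)
    c_dds = score_dds(status, c_sar)
    provenance["c_dds"] = (
        f"status {status.value} -> {c_dds}" if c_sar == 1.0 else "gated to 0 because c_sar != 1"
    )

    c_tr = score_tr(drug, virus.virus_id)
    provenance["c_tr"] = (
        f"target {drug.target_name or 'unnamed'} annotated essential for {virus.virus_id}"
        if c_tr
        else "target not annotated essential for the Voi"
    )

    c_ic = score_ic(drug)
    provenance["c_ic"] = f"immunomodulatory = {drug.immunomodulatory.value}"

    c_roa = score_roa(drug, virus, config)
    provenance["c_roa"] = (
        f"routes {sorted(r.value for r in drug.routes)} vs suitable "
        f"{sorted(r.value for r in config.suitable_routes(virus.infected_systems))}"
    )

    c_phyl, note = _phyl_detail(drug, virus, bundle)
    provenance["c_phyl"] = note

    values = {
        "c_sar": c_sar,
        "c_dds": c_dds,
        "c_tr": c_tr,
        "c_ic": c_ic,
        "c_roa": c_roa,
        "c_phyl": c_phyl,
    }
    for name in BSA_COMPONENTS:
        key = f"bsa:{drug.drug_id}:{virus.virus_id}:{name}"
        if key in config.overrides:
            values[name] = float(config.overrides[key])
            provenance[name] = f"manual override {values[name]} (was {key})"

    total = sum(values[name] for name in BSA_COMPONENTS)
    return BsaScoreBreakdown(
        drug_id=drug.drug_id,
        virus_id=virus.virus_id,
        total=total,
        provenance=provenance,
        **values,
    )
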