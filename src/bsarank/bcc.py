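"""Multiplicative score for two-drug antiviral combinations.

Four coefficients scale the sum of the pair's individual BSA scores:

- ``k_di``  (1 / 0.5): different vs identical mechanism of action — drugs
  with the same mechanism (e.g. two nucleoside analogs) compete rather than
  cooperate.
- ``k_dti`` (1.2 / 1.1 / 1.0): both virus-directed, mixed, or both
  host-directed — fewer host targets, fewer expected side effects.  A drug
  hitting both viral and host factors counts as host-directed here (its host
  target carries the side-effect liability); an unknown target kind floors
  the coefficient at 1.0.
- ``k_drs`` (1.2 / 1.0): both drugs act on the same stage of the viral life
  cycle (entry, replication, exit) or not.
- ``k_roa`` (1.2 / 1.0 / 0.8): the drugs share an administration route that
  suits the infected organ systems; share a route that does not; or share no
  route at all.

    score = k_di * k_dti * k_drs * k_roa * (bsa_1 + bsa_2)

The coefficient product is bounded in [0.4, 1.728].  A combination is called
*effective* when its score exceeds the plain BSA sum by strictly more than 5
points — which requires the product to exceed 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .annotations import (
    AnnotationBundle,
    DrugAnnotation,
    ReplicationStage,
    TargetKind,
    VirusAnnotation,
    canonical_pair,
    normalize_id,
)
from .bsa import BsaScoreBreakdown, compute_bsa_score
from .config import RunConfig
from .sar import SimilarityProvider

logger = logging.getLogger(__name__)

__all__ = [
    "BccScoreBreakdown",
    "coeff_di",
    "coeff_dti",
    "coeff_drs",
    "coeff_roa",
    "compute_bcc_score",
    "rank_combinations",
    "display_score",
    "BCC_COEFFICIENTS",
]

BCC_COEFFICIENTS = ("k_di", "k_dti", "k_drs", "k_roa")

RANK_COLUMNS = [
    "drug_1",
    "drug_2",
    "virus",
    "k_di",
    "k_dti",
    "k_drs",
    "k_roa",
    "bsa_sum",
    "bcc_score",
    "delta",
    "effective",
    "target_class",
    "published",
]


@dataclass(frozen=True)
class BccScoreBreakdown:
    """The four coefficients, pair BSA sum, total score and verdict."""

    drug_id_1: str
    drug_id_2: str
    virus_id: str
    k_di: float
    k_dti: float
    k_drs: float
    k_roa: float
    bsa_sum: float
    bcc_score: float
    delta: float
    effective: bool
    target_class: str
    bsa_breakdowns: tuple[BsaScoreBreakdown, ...] = field(default=(), compare=False)
    provenance: dict[str, str] = field(default_factory=dict, compare=False)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id_1, self.drug_id_2)

    def coefficients(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BCC_COEFFICIENTS}

    def to_dict(self) -> dict:
        return {
            "drug_id_1": self.drug_id_1,
            "drug_id_2": self.drug_id_2,
            "virus_id": self.virus_id,
            **self.coefficients(),
            "bsa_sum": self.bsa_sum,
            "bcc_score": self.bcc_score,
            "delta": self.delta,
            "effective": self.effective,
            "target_class": self.target_class,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BccScoreBreakdown":
        return cls(
            drug_id_1=data["drug_id_1"],
            drug_id_2=data["drug_id_2"],
            virus_id=data["virus_id"],
            bsa_sum=data["bsa_sum"],
            bcc_score=data["bcc_score"],
            delta=data["delta"],
            effective=data["effective"],
            target_class=data["target_class"],
            provenance=dict(data.get("provenance", {})),
            **{k: data[k] for k in BCC_COEFFICIENTS},
        )


def coeff_di(d1: DrugAnnotation, d2: DrugAnnotation) -> float:
    """k_DI: 0.5 when the two mechanisms of action are identical, else 1."""
    return 0.5 if normalize_id(d1.moa_class) == normalize_id(d2.moa_class) else 1.0


def _side_effect_kind(kind: TargetKind) -> TargetKind:
    # A dual virus/host drug still engages a host factor; for side-effect
    # expectations it behaves like a host-directed drug.
    return TargetKind.HOST if kind is TargetKind.BOTH else kind


def coeff_dti(d1: DrugAnnotation, d2: DrugAnnotation) -> tuple[float, str]:
    """k_DTI and the pair's target class.

    virus+virus -> 1.2; virus+host -> 1.1; host+host -> 1.0; any unknown
    target floors the coefficient at 1.0 with target class ``unknown``.
    """
    kinds = {_side_effect_kind(d1.target_kind), _side_effect_kind(d2.target_kind)}
    if TargetKind.UNKNOWN in kinds:
        logger.warning(
            "unknown target kind in pair (%s, %s); k_dti floored at 1.0", d1.drug_id, d2.drug_id
        )
        return 1.0, "unknown"
    if kinds == {TargetKind.VIRUS}:
        return 1.2, "virus_virus"
    if kinds == {TargetKind.HOST}:
        return 1.0, "host_host"
    return 1.1, "virus_host"


def coeff_drs(d1: DrugAnnotation, d2: DrugAnnotation) -> float:
    """k_DRS: 1.2 when both drugs act on the same known life-cycle stage."""
    if (
        d1.replication_stage is not ReplicationStage.UNKNOWN
        and d1.replication_stage is d2.replication_stage
    ):
        return 1.2
    return 1.0


def coeff_roa(
    d1: DrugAnnotation,
    d2: DrugAnnotation,
    voi: VirusAnnotation,
    config: Optional[RunConfig] = None,
) -> float:
    """k_RoA: 1.2 shared suitable route / 1.0 shared unsuitable / 0.8 no shared route."""
    config = config or RunConfig()
    if not d1.routes or not d2.routes:
        logger.warning(
            "missing routes for %s or %s; k_roa scored 0.8", d1.drug_id, d2.drug_id
        )
        return 0.8
    shared = d1.routes & d2.routes
    if not shared:
        return 0.8
    if shared & config.suitable_routes(voi.infected_systems):
        return 1.2
    return 1.0


def compute_bcc_score(
    drug_1: str,
    drug_2: str,
    voi: str,
    bundle: AnnotationBundle,
    config: Optional[RunConfig] = None,
    similarity: Optional[SimilarityProvider] = None,
) -> BccScoreBreakdown:
    """Full combination breakdown for an unordered drug pair against a Voi.

    Symmetric in the drug arguments.  Coefficient overrides in
    ``config.overrides`` (keys ``bcc:<d1>+<d2>:<virus>:<coeff>`` with the
    pair in canonical order) replace computed values with provenance.
    """
    config = config or RunConfig()
    id1, id2 = canonical_pair(drug_1, drug_2)
    d1, d2 = bundle.drug(id1), bundle.drug(id2)
    virus = bundle.virus(voi)

    b1 = compute_bsa_score(id1, virus.virus_id, bundle, config, similarity)
    b2 = compute_bsa_score(id2, virus.virus_id, bundle, config, similarity)
    bsa_sum = b1.total + b2.total

    k_di = coeff_di(d1, d2)
    k_dti, target_class = coeff_dti(d1, d2)
    k_drs = coeff_drs(d1, d2)
    k_roa = coeff_roa(d1, d2, virus, config)

    provenance = {
        "k_di": f"moa {d1.moa_class} vs {d2.moa_class}",
        "k_dti": f"target kinds {d1.target_kind.value} + {d2.target_kind.value} ({target_class})",
        "k_drs": f"stages {d1.replication_stage.value} + {d2.replication_stage.value}",
        "k_roa": f"shared routes {sorted(r.value for r in (d1.routes & d2.routes))}",
    }
    values = {"k_di": k_di, "k_dti": k_dti, "k_drs": k_drs, "k_roa": k_roa}
    for name in BCC_COEFFICIENTS:
        key = f"bcc:{id1}+{id2}:{virus.virus_id}:{name}"
        if key in config.overrides:
            values[name] = float(config.overrides[key])
            provenance[name] = f"manual override {values[name]} (was {key})"

    product = values["k_di"] * values["k_dti"] * values["k_drs"] * values["k_roa"]
    bcc_score = product * bsa_sum
    delta = bcc_score - bsa_sum

    return BccScoreBreakdown(
        drug_id_1=id1,
        drug_id_2=id2,
        virus_id=virus.virus_id,
        bsa_sum=bsa_sum,
        bcc_score=bcc_score,
        delta=delta,
        effective=delta > config.effectiveness_delta,
        target_class=target_class,
        bsa_breakdowns=(b1, b2),
        provenance=provenance,
        **values,
    )


def rank_combinations(
    drug_ids: Iterable[str],
    voi: str,
    bundle: AnnotationBundle,
    config: Optional[RunConfig] = None,
    similarity: Optional[SimilarityProvider] = None,
    effective_only: bool = False,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Score every unordered pair of the given drugs against a Voi.

    Rows are sorted by score, then delta, then canonical pair name, all
    descending on the numeric keys, so output order is reproducible.  The
    ``published`` column joins any matching combination record in the bundle.
    """
    ids = sorted({normalize_id(d) for d in drug_ids})
    if len(ids) < 2:
        raise ValueError("ranking requires at least two drugs")
    config = config or RunConfig()

    rows = []
    for a, b in combinations(ids, 2):
        br = compute_bcc_score(a, b, voi, bundle, config, similarity)
        rows.append(
            {
                "drug_1": br.drug_id_1,
                "drug_2": br.drug_id_2,
                "virus": br.virus_id,
                "k_di": br.k_di,
                "k_dti": br.k_dti,
                "k_drs": br.k_drs,
                "k_roa": br.k_roa,
                "bsa_sum": br.bsa_sum,
                "bcc_score": br.bcc_score,
                "delta": br.delta,
                "effective": br.effective,
                "target_class": br.target_class,
                "published": bundle.combination_published(a, b, voi),
            }
        )
    table = pd.DataFrame(rows, columns=RANK_COLUMNS)
    table = table.sort_values(
        by=["bcc_score", "delta", "drug_1", "drug_2"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if effective_only:
        table = table[table["effective"]].reset_index(drop=True)
    if top is not None:
        table = table.head(top).reset_index(drop=True)
    return table


def display_score(value: float, precision: int = 2) -> str:
    """Render a score for printing: round half away from zero at ``precision``
    decimals.  Comparisons and ranking always use full-precision values;
    rounding is purely presentational."""
    q = Decimal(1).scaleb(-precision)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
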