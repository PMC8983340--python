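"""Taxonomy-based virus relatedness and activity-gap prediction.

Relatedness is read from user-supplied taxonomy columns (genus, family and a
declared related-families adjacency), not from sequence-derived trees: it is
the reproducible core of the phylogeny ladder that feeds the C_Phyl score
component, and it extends to viruses that do not encode their own polymerase
or reverse transcriptase.

An *activity gap* is an untested drug-virus pair made plausible by the drug's
recorded activity against a taxonomic relative of the virus: taxonomically
similar viruses tend to respond to the same drug, so such pairs are natural
candidates for spectrum-expansion experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from itertools import combinations
from typing import Iterable, Optional

from .annotations import (
    ActivityStatus,
    AnnotationBundle,
    VirusAnnotation,
    normalize_id,
)

__all__ = [
    "Relation",
    "C_PHYL_BY_RELATION",
    "relation",
    "GapPrediction",
    "find_activity_gaps",
    "activity_overlap_counts",
]


class Relation(IntEnum):
    """Taxonomic relatedness ladder, ordered by strength."""

    RELATED_FAMILY = 1
    SAME_FAMILY = 2
    SAME_GENUS = 3

    def __str__(self) -> str:  # stable names for reports
        return self.name.lower()


#: C_Phyl value implied by each relation.
C_PHYL_BY_RELATION: dict[Relation, float] = {
    Relation.SAME_GENUS: 1.0,
    Relation.SAME_FAMILY: 0.5,
    Relation.RELATED_FAMILY: 0.25,
}


def relation(voi: VirusAnnotation, other: VirusAnnotation) -> Optional[Relation]:
    """Strongest taxonomic relation between two viruses, or ``None``.

    Same genus beats same family beats declared related family; a virus is in
    the same genus as itself.
    """
    if voi.genus == other.genus:
        return Relation.SAME_GENUS
    if voi.family == other.family:
        return Relation.SAME_FAMILY
    if other.family in voi.related_families or voi.family in other.related_families:
        return Relation.RELATED_FAMILY
    return None


@dataclass(frozen=True)
class GapPrediction:
    """An untested drug-virus pair supported by activity against a relative."""

    drug_id: str
    virus_id: str
    evidence_virus_id: str
    relation: Relation
    implied_c_phyl: float


def find_activity_gaps(
    bundle: AnnotationBundle,
    min_relation: Relation = Relation.RELATED_FAMILY,
    statuses: Optional[Iterable[ActivityStatus]] = None,
) -> list[GapPrediction]:
    """Predict untested drug-virus pairs from activity against related viruses.

    For each drug and each virus the drug is untested against, the strongest
    relation to any evidence virus (a virus with qualifying recorded
    activity) is reported if it is at or above ``min_relation``.  ``statuses``
    restricts what counts as evidence (default: any non-untested status).
    Output is sorted by (drug_id, virus_id).
    """
    allowed = (
        {s for s in ActivityStatus if s is not ActivityStatus.UNTESTED}
        if statuses is None
        else {ActivityStatus(s) for s in statuses}
    )
    predictions: list[GapPrediction] = []
    for drug_id in sorted(bundle.drugs):
        evidence = [
            v
            for v in sorted(bundle.viruses)
            if bundle.activity_status(drug_id, v) in allowed
        ]
        if not evidence:
            continue
        for virus_id in sorted(bundle.viruses):
            if bundle.activity_status(drug_id, virus_id) is not ActivityStatus.UNTESTED:
                continue
            voi = bundle.viruses[virus_id]
            best: Optional[tuple[Relation, str]] = None
            for ev in evidence:
                rel = relation(voi, bundle.viruses[ev])
                if rel is not None and (best is None or rel > best[0]):
                    best = (rel, ev)
            if best is not None and best[0] >= min_relation:
                predictions.append(
                    GapPrediction(
                        drug_id=drug_id,
                        virus_id=virus_id,
                        evidence_virus_id=best[1],
                        relation=best[0],
                        implied_c_phyl=C_PHYL_BY_RELATION[best[0]],
                    )
                )
    return predictions


def activity_overlap_counts(
    bundle: AnnotationBundle,
    family: str,
    viruses: Optional[Iterable[str]] = None,
    statuses: Optional[Iterable[ActivityStatus]] = None,
    max_viruses: int = 5,
) -> dict[frozenset[str], int]:
    """Counts of drugs active against exactly each subset of a family's viruses.

    The classic Venn-diagram tabulation: the returned mapping covers every
    non-empty subset of the considered viruses (zero counts included) and its
    values sum to the number of drugs with at least one qualifying activity in
    the family.  More than ``max_viruses`` viruses require an explicit
    ``viruses`` list (combinatorial cap).
    """
    family = normalize_id(family)
    if viruses is None:
        members = sorted(v for v, ann in bundle.viruses.items() if ann.family == family)
        if not members:
            raise ValueError(f"no viruses with family {family!r} in bundle")
        if len(members) > max_viruses:
            raise ValueError(
                f"family {family!r} has {len(members)} viruses; pass an explicit "
                f"virus list of at most {max_viruses}"
            )
    else:
        members = sorted(normalize_id(v) for v in viruses)
        for v in members:
            bundle.virus(v)

    allowed = (
        {s for s in ActivityStatus if s is not ActivityStatus.UNTESTED}
        if statuses is None
        else {ActivityStatus(s) for s in statuses}
    )

    counts: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(members) + 1)
        for sub in combinations(members, r)
    }
    for drug_id in bundle.drugs:
        active = frozenset(
            v for v in members if bundle.activity_status(drug_id, v) in allowed
        )
        if active:
            counts[active] += 1
    return counts
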