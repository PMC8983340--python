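"""Reproducible synthetic annotation bundles for testing and simulation.

The generator emulates the shape of a curated broad-spectrum-antiviral
database: viruses grouped into families and genera with a sparse
related-family adjacency, drugs drawn from the mechanism-of-action
vocabulary with targets, life-cycle stages and administration routes, and a
sparse drug-virus activity matrix.  Default rates mirror a curated
real-world collection: activity density around 0.15 (most drugs are tested
against few viruses) and an immunomodulatory fraction of 0.23 (58 of 255
catalogued broad-spectrum antivirals carry immunomodulatory annotations).

Generation is a pure function of the spec (including its seed): identical
specs yield byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import (
    ActivityRecord,
    ActivityStatus,
    AnnotationBundle,
    CombinationRecord,
    DrugAnnotation,
    Immunomodulatory,
    OrganSystem,
    ReplicationStage,
    Route,
    TargetKind,
    VirusAnnotation,
    canonical_pair,
)

__all__ = ["SyntheticSpec", "generate_bundle", "SYNTHETIC_SMILES"]

#: Small list of simple, guaranteed-parseable structures assigned round-robin
#: to synthetic drugs (synthetic stand-ins, not real drug structures).
SYNTHETIC_SMILES = [
    "CCO",
    "CC(=O)O",
    "c1ccccc1",
    "c1ccccc1O",
    "CC(C)CO",
    "CCN(CC)CC",
    "c1ccncc1",
    "CC(=O)Nc1ccccc1",
    "OCC(O)CO",
    "c1ccc2ccccc2c1",
    "CC(N)C(=O)O",
    "COc1ccccc1",
]

_MOA_POOL = [
    "nucleoside_analog",
    "protease_inhibitor",
    "polymerase_inhibitor",
    "interferon",
    "impdh_inhibitor",
    "nnrti",
    "entry_inhibitor",
    "kinase_inhibitor",
]
_STATUS_POOL = [
    ActivityStatus.APPROVED_OR_PHASE4,
    ActivityStatus.PHASE1_3,
    ActivityStatus.IN_VIVO,
    ActivityStatus.IN_VITRO,
]
_ROUTE_POOL = [
    Route.ORAL,
    Route.INTRAVENOUS,
    Route.INHALATION,
    Route.TOPICAL,
    Route.SUBCUTANEOUS,
]
_SYSTEM_POOL = [
    OrganSystem.RESPIRATORY,
    OrganSystem.DIGESTIVE,
    OrganSystem.CARDIOVASCULAR,
    OrganSystem.NERVOUS,
    OrganSystem.MULTIPLE,
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic bundle; generation is pure in (spec, seed)."""

    n_drugs: int = 20
    n_viruses: int = 8
    family_count: int = 4
    activity_density: float = 0.15
    immunomodulatory_rate: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_viruses < 1 or self.family_count < 1:
            raise ValueError("n_drugs, n_viruses and family_count must be positive")
        for rate in (self.activity_density, self.immunomodulatory_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def generate_bundle(spec: SyntheticSpec) -> AnnotationBundle:
    """Generate a validated random bundle from the spec, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    bundle = AnnotationBundle()

    # Families on a ring: each family is "closely related" to its neighbours.
    n_fam = min(spec.family_count, spec.n_viruses)
    families = [f"family_{i}" for i in range(n_fam)]
    related: dict[str, set[str]] = {f: set() for f in families}
    if n_fam > 1:
        for i, f in enumerate(families):
            related[f].add(families[(i + 1) % n_fam])
            related[f].add(families[(i - 1) % n_fam])
            related[f].discard(f)

    virus_ids = [f"virus_{i}" for i in range(spec.n_viruses)]
    fam_of = rng.integers(0, n_fam, size=spec.n_viruses)
    # up to two genera per family so same-family/different-genus pairs occur
    genus_of = rng.integers(0, 2, size=spec.n_viruses)
    for i, vid in enumerate(virus_ids):
        fam = families[fam_of[i]]
        n_sys = int(rng.integers(1, 3))
        systems = frozenset(
            rng.choice(np.array(_SYSTEM_POOL, dtype=object), size=n_sys, replace=False)
        )
        bundle.viruses[vid] = VirusAnnotation(
            virus_id=vid,
            name=vid.replace("_", " ").title(),
            genus=f"{fam}_genus_{genus_of[i]}",
            family=fam,
            related_families=frozenset(related[fam]),
            infected_systems=systems,
            case_fatality_rate=float(np.round(rng.uniform(0, 0.9), 3)),
        )

    drug_ids = [f"drug_{i}" for i in range(spec.n_drugs)]
    for i, did in enumerate(drug_ids):
        kind = rng.choice(
            np.array(
                [TargetKind.VIRUS, TargetKind.HOST, TargetKind.BOTH, TargetKind.UNKNOWN],
                dtype=object,
            ),
            p=[0.5, 0.3, 0.1, 0.1],
        )
        essential = frozenset(
            v for v in virus_ids if rng.random() < 0.2
        )
        n_routes = int(rng.integers(1, 3))
        routes = frozenset(
            rng.choice(np.array(_ROUTE_POOL, dtype=object), size=n_routes, replace=False)
        )
        stage = rng.choice(
            np.array(
                [
                    ReplicationStage.ENTRY,
                    ReplicationStage.REPLICATION,
                    ReplicationStage.EXIT,
                    ReplicationStage.UNKNOWN,
                ],
                dtype=object,
            ),
            p=[0.2, 0.5, 0.1, 0.2],
        )
        immuno = (
            Immunomodulatory.YES
            if rng.random() < spec.immunomodulatory_rate
            else rng.choice(np.array([Immunomodulatory.NO, Immunomodulatory.UNKNOWN], dtype=object))
        )
        bundle.drugs[did] = DrugAnnotation(
            drug_id=did,
            name=did.replace("_", " ").title(),
            smiles=SYNTHETIC_SMILES[i % len(SYNTHETIC_SMILES)],
            moa_class=_MOA_POOL[int(rng.integers(0, len(_MOA_POOL)))],
            target_kind=kind,
            target_name=f"target_{int(rng.integers(0, 6))}",
            target_essential_for=essential,
            replication_stage=stage,
            immunomodulatory=immuno,
            routes=routes,
        )

    for did in drug_ids:
        for vid in virus_ids:
            if rng.random() < spec.activity_density:
                status = _STATUS_POOL[int(rng.integers(0, len(_STATUS_POOL)))]
                bundle.activities[(did, vid)] = ActivityRecord(did, vid, status)

    if spec.n_drugs >= 2:
        n_combos = min(3, spec.n_drugs * (spec.n_drugs - 1) // 2)
        seen: set[tuple[str, str]] = set()
        while len(seen) < n_combos:
            a, b = rng.choice(len(drug_ids), size=2, replace=False)
            pair = canonical_pair(drug_ids[int(a)], drug_ids[int(b)])
            if pair in seen:
                continue
            seen.add(pair)
            bundle.combinations.append(
                CombinationRecord(
                    pair[0], pair[1], virus_ids[int(rng.integers(0, len(virus_ids)))],
                    published=bool(rng.random() < 0.5),
                )
            )

    return bundle.validate()
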