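"""Data model for drug, virus, activity and combination annotation tables.

Every other module consumes the :class:`AnnotationBundle` assembled here.
Tables are tab-separated UTF-8 with a header row (comma-separated accepted
via ``sep=","``); set-valued cells (routes, infected organ systems, related
families) are semicolon-delimited to avoid quoting ambiguity with drug names
that contain commas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetKind",
    "ReplicationStage",
    "Immunomodulatory",
    "Route",
    "OrganSystem",
    "ActivityStatus",
    "DrugAnnotation",
    "VirusAnnotation",
    "ActivityRecord",
    "CombinationRecord",
    "AnnotationBundle",
    "BundleValidationError",
    "DegeneratePairError",
    "UnknownIdError",
    "DEFAULT_MOA_VOCABULARY",
    "normalize_id",
    "canonical_pair",
    "load_bundle",
    "write_bundle",
]


class BundleValidationError(ValueError):
    """Raised when a bundle violates referential or structural invariants."""


class DegeneratePairError(ValueError):
    """Raised when a drug pair is formed from a single drug."""


class UnknownIdError(KeyError):
    """Raised when a drug or virus id does not resolve in a bundle."""


class TargetKind(str, Enum):
    VIRUS = "virus"
    HOST = "host"
    BOTH = "both"
    UNKNOWN = "unknown"


class ReplicationStage(str, Enum):
    ENTRY = "entry"
    REPLICATION = "replication"
    EXIT = "exit"
    UNKNOWN = "unknown"


class Immunomodulatory(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Route(str, Enum):
    ORAL = "oral"
    INTRAVENOUS = "intravenous"
    INHALATION = "inhalation"
    TOPICAL = "topical"
    SUBCUTANEOUS = "subcutaneous"
    INTRAMUSCULAR = "intramuscular"
    OTHER = "other"


class OrganSystem(str, Enum):
    RESPIRATORY = "respiratory"
    DIGESTIVE = "digestive"
    CARDIOVASCULAR = "cardiovascular"
    NERVOUS = "nervous"
    INTEGUMENTARY = "integumentary"
    UROGENITAL = "urogenital"
    MULTIPLE = "multiple"


class ActivityStatus(str, Enum):
    APPROVED_OR_PHASE4 = "approved_or_phase4"
    PHASE1_3 = "phase1_3"
    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"
    UNTESTED = "untested"


#: Shipped mechanism-of-action vocabulary.  Editorial and user-extensible:
#: values outside the configured vocabulary are kept, flagged ``other:<text>``.
DEFAULT_MOA_VOCABULARY = frozenset(
    {
        "nucleoside_analog",
        "protease_inhibitor",
        "polymerase_inhibitor",
        "ns5a_inhibitor",
        "interferon",
        "impdh_inhibitor",
        "dhodh_inhibitor",
        "endonuclease_inhibitor",
        "nnrti",
        "entry_inhibitor",
        "integrase_inhibitor",
        "kinase_inhibitor",
        "ion_channel_blocker",
    }
)

_WS = re.compile(r"\s+")


def normalize_id(name: str) -> str:
    """Lower-case, strip and collapse whitespace to underscores.

    Annotation sources use free-text names; joins need a stable key.
    """
    return _WS.sub("_", name.strip().lower())


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Order an unordered drug pair deterministically (lexicographic).

    Raises :class:`DegeneratePairError` if both ids normalize to the same
    drug.
    """
    a, b = normalize_id(drug_a), normalize_id(drug_b)
    if a == b:
        raise DegeneratePairError(f"pair of identical drugs: {a!r}")
    return (a, b) if a < b else (b, a)


def normalize_moa(moa_class: str, vocabulary: Iterable[str] = DEFAULT_MOA_VOCABULARY) -> str:
    value = normalize_id(moa_class) if moa_class else ""
    if not value:
        return "other:unspecified"
    if value in set(vocabulary) or value.startswith("other:"):
        return value
    logger.warning("moa_class %r outside vocabulary; flagged as other:%s", moa_class, value)
    return f"other:{value}"


@dataclass(frozen=True)
class DrugAnnotation:
    """Per-drug mechanism, target, life-cycle stage, immune effect and routes."""

    drug_id: str
    name: str
    moa_class: str
    target_kind: TargetKind = TargetKind.UNKNOWN
    target_name: Optional[str] = None
    target_essential_for: frozenset[str] = frozenset()
    replication_stage: ReplicationStage = ReplicationStage.UNKNOWN
    immunomodulatory: Immunomodulatory = Immunomodulatory.UNKNOWN
    routes: frozenset[Route] = frozenset()
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise BundleValidationError("drug_id must be non-empty")


@dataclass(frozen=True)
class VirusAnnotation:
    """Virus taxonomy (genus/family/related families) and infected organ systems."""

    virus_id: str
    name: str
    genus: str
    family: str
    related_families: frozenset[str] = frozenset()
    infected_systems: frozenset[OrganSystem] = frozenset({OrganSystem.MULTIPLE})
    case_fatality_rate: Optional[float] = None  # metadata only

    def __post_init__(self) -> None:
        if not self.virus_id:
            raise BundleValidationError("virus_id must be non-empty")
        if not self.genus or not self.family:
            raise BundleValidationError(f"virus {self.virus_id!r}: genus and family required")
        if self.family in self.related_families:
            raise BundleValidationError(
                f"virus {self.virus_id!r}: family {self.family!r} listed in its own related_families"
            )
        if not self.infected_systems:
            raise BundleValidationError(f"virus {self.virus_id!r}: infected_systems must be non-empty")
        if self.case_fatality_rate is not None and not 0.0 <= self.case_fatality_rate <= 1.0:
            raise BundleValidationError(
                f"virus {self.virus_id!r}: case_fatality_rate must be in [0,1]"
            )


@dataclass(frozen=True)
class ActivityRecord:
    """Development status of one drug against one virus.

    Pairs absent from the table default to ``untested``.
    """

    drug_id: str
    virus_id: str
    status: ActivityStatus
    source: Optional[str] = None


@dataclass(frozen=True)
class CombinationRecord:
    """A published (or catalogued) two-drug combination against a virus."""

    drug_id_1: str
    drug_id_2: str
    virus_id: str
    published: bool = True
    source: Optional[str] = None

    def __post_init__(self) -> None:
        d1, d2 = canonical_pair(self.drug_id_1, self.drug_id_2)
        object.__setattr__(self, "drug_id_1", d1)
        object.__setattr__(self, "drug_id_2", d2)


@dataclass
class AnnotationBundle:
    """Validated container joining the drug, virus, activity and combination tables."""

    drugs: dict[str, DrugAnnotation] = field(default_factory=dict)
    viruses: dict[str, VirusAnnotation] = field(default_factory=dict)
    activities: dict[tuple[str, str], ActivityRecord] = field(default_factory=dict)
    combinations: list[CombinationRecord] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def drug(self, drug_id: str) -> DrugAnnotation:
        key = normalize_id(drug_id)
        try:
            return self.drugs[key]
        except KeyError:
            raise UnknownIdError(f"unknown drug id: {drug_id!r}") from None

    def virus(self, virus_id: str) -> VirusAnnotation:
        key = normalize_id(virus_id)
        try:
            return self.viruses[key]
        except KeyError:
            raise UnknownIdError(f"unknown virus id: {virus_id!r}") from None

    def activity_status(self, drug_id: str, virus_id: str) -> ActivityStatus:
        rec = self.activities.get((normalize_id(drug_id), normalize_id(virus_id)))
        return rec.status if rec is not None else ActivityStatus.UNTESTED

    def reference_viruses(self, drug_id: str) -> list[str]:
        """Viruses the drug has any non-untested activity record against."""
        d = normalize_id(drug_id)
        return sorted(
            v
            for (dd, v), rec in self.activities.items()
            if dd == d and rec.status is not ActivityStatus.UNTESTED
        )

    def drugs_with_activity(self, virus_id: str) -> list[str]:
        """Drugs with any non-untested record against the virus."""
        v = normalize_id(virus_id)
        return sorted(
            d
            for (d, vv), rec in self.activities.items()
            if vv == v and rec.status is not ActivityStatus.UNTESTED
        )

    def combination_published(self, drug_a: str, drug_b: str, virus_id: str) -> bool:
        pair = canonical_pair(drug_a, drug_b)
        v = normalize_id(virus_id)
        return any(
            (c.drug_id_1, c.drug_id_2) == pair and c.virus_id == v and c.published
            for c in self.combinations
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> "AnnotationBundle":
        problems: list[str] = []
        for (d, v) in self.activities:
            if d not in self.drugs:
                problems.append(f"activity references unknown drug_id {d!r}")
            if v not in self.viruses:
                problems.append(f"activity references unknown virus_id {v!r}")
        for c in self.combinations:
            for d in (c.drug_id_1, c.drug_id_2):
                if d not in self.drugs:
                    problems.append(f"combination references unknown drug_id {d!r}")
            if c.virus_id not in self.viruses:
                problems.append(f"combination references unknown virus_id {c.virus_id!r}")
        if problems:
            raise BundleValidationError("; ".join(problems))
        return self


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

DRUG_COLUMNS = [
    "drug_id",
    "name",
    "smiles",
    "moa_class",
    "target_kind",
    "target_name",
    "target_essential_for",
    "replication_stage",
    "immunomodulatory",
    "routes",
]
VIRUS_COLUMNS = [
    "virus_id",
    "name",
    "genus",
    "family",
    "related_families",
    "infected_systems",
    "case_fatality_rate",
]
ACTIVITY_COLUMNS = ["drug_id", "virus_id", "status", "source"]
COMBINATION_COLUMNS = ["drug_id_1", "drug_id_2", "virus_id", "published", "source"]

_SET_SEP = ";"


def _split_set(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [normalize_id(part) for part in str(cell).split(_SET_SEP) if part.strip()]


def _join_set(values: Iterable[object]) -> str:
    return _SET_SEP.join(sorted(str(getattr(v, "value", v)) for v in values))


def _opt_str(cell: object) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell) == "":
        return None
    return str(cell)


def _coerce_enum(enum_cls, raw: object, *, context: str, fallback: str | None = None):
    """Map a raw cell to an enum member; out-of-vocabulary values fall back
    to the enum's 'unknown' member (or ``fallback``), logged."""
    if fallback is None and "unknown" in enum_cls._value2member_map_:
        fallback = "unknown"
    value = _opt_str(raw)
    if value is None:
        return enum_cls(fallback) if fallback else None
    value = normalize_id(value)
    try:
        return enum_cls(value)
    except ValueError:
        if fallback:
            logger.warning("%s: unknown value %r mapped to %r", context, raw, fallback)
            return enum_cls(fallback)
        raise BundleValidationError(f"{context}: invalid value {raw!r}") from None


def _read_table(path: Path, expected: Sequence[str], sep: str) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in expected if c not in df.columns and c not in ("source", "smiles", "case_fatality_rate")]
    if missing:
        raise BundleValidationError(f"{path}: missing required columns {missing}")
    return df


def load_bundle(
    drugs_path: str | Path,
    viruses_path: str | Path,
    activities_path: str | Path,
    combinations_path: str | Path | None = None,
    *,
    sep: str = "\t",
    moa_vocabulary: Iterable[str] = DEFAULT_MOA_VOCABULARY,
) -> AnnotationBundle:
    """Read the annotation tables and return a validated bundle.

    Unknown enum cells are recorded as ``unknown`` with a logged warning;
    duplicate keys and dangling foreign keys raise
    :class:`BundleValidationError`.
    """
    bundle = AnnotationBundle()

    ddf = _read_table(Path(drugs_path), DRUG_COLUMNS, sep)
    for i, row in ddf.iterrows():
        drug_id = normalize_id(row.get("drug_id") or row.get("name", ""))
        if drug_id in bundle.drugs:
            raise BundleValidationError(f"{drugs_path}: duplicate drug_id {drug_id!r} (row {i + 1})")
        bundle.drugs[drug_id] = DrugAnnotation(
            drug_id=drug_id,
            name=row.get("name", drug_id) or drug_id,
            smiles=_opt_str(row.get("smiles")),
            moa_class=normalize_moa(row.get("moa_class", ""), moa_vocabulary),
            target_kind=_coerce_enum(TargetKind, row.get("target_kind"), context=f"drug {drug_id}"),
            target_name=_opt_str(row.get("target_name")),
            target_essential_for=frozenset(_split_set(row.get("target_essential_for"))),
            replication_stage=_coerce_enum(
                ReplicationStage, row.get("replication_stage"), context=f"drug {drug_id}"
            ),
            immunomodulatory=_coerce_enum(
                Immunomodulatory, row.get("immunomodulatory"), context=f"drug {drug_id}"
            ),
            routes=frozenset(
                _coerce_enum(Route, r, context=f"drug {drug_id} route", fallback="other")
                for r in _split_set(row.get("routes"))
            ),
        )

    vdf = _read_table(Path(viruses_path), VIRUS_COLUMNS, sep)
    for i, row in vdf.iterrows():
        virus_id = normalize_id(row.get("virus_id") or row.get("name", ""))
        if virus_id in bundle.viruses:
            raise BundleValidationError(f"{viruses_path}: duplicate virus_id {virus_id!r} (row {i + 1})")
        cfr = _opt_str(row.get("case_fatality_rate"))
        systems = frozenset(
            s
            for s in (
                _coerce_enum(OrganSystem, x, context=f"virus {virus_id} system")
                for x in _split_set(row.get("infected_systems"))
            )
            if s is not None
        )
        bundle.viruses[virus_id] = VirusAnnotation(
            virus_id=virus_id,
            name=row.get("name", virus_id) or virus_id,
            genus=normalize_id(row.get("genus", "")),
            family=normalize_id(row.get("family", "")),
            related_families=frozenset(_split_set(row.get("related_families"))),
            infected_systems=systems or frozenset({OrganSystem.MULTIPLE}),
            case_fatality_rate=float(cfr) if cfr is not None else None,
        )

    adf = _read_table(Path(activities_path), ACTIVITY_COLUMNS, sep)
    offending: list[int] = []
    for i, row in adf.iterrows():
        d, v = normalize_id(row["drug_id"]), normalize_id(row["virus_id"])
        if (d, v) in bundle.activities:
            raise BundleValidationError(
                f"{activities_path}: duplicate activity record for ({d!r}, {v!r}) at row {i + 1}"
            )
        if d not in bundle.drugs or v not in bundle.viruses:
            offending.append(i + 1)
            continue
        status = _coerce_enum(
            ActivityStatus, row.get("status"), context=f"activity {d}/{v}", fallback="untested"
        )
        bundle.activities[(d, v)] = ActivityRecord(
            drug_id=d, virus_id=v, status=status or ActivityStatus.UNTESTED, source=_opt_str(row.get("source"))
        )
    if offending:
        raise BundleValidationError(
            f"{activities_path}: rows {offending} reference unknown drug or virus ids"
        )

    if combinations_path is not None:
        cdf = _read_table(Path(combinations_path), COMBINATION_COLUMNS, sep)
        for i, row in cdf.iterrows():
            bundle.combinations.append(
                CombinationRecord(
                    drug_id_1=row["drug_id_1"],
                    drug_id_2=row["drug_id_2"],
                    virus_id=normalize_id(row["virus_id"]),
                    published=str(row.get("published", "true")).strip().lower()
                    in ("1", "true", "yes"),
                    source=_opt_str(row.get("source")),
                )
            )

    return bundle.validate()


def write_bundle(bundle: AnnotationBundle, directory: str | Path, *, sep: str = "\t") -> dict[str, Path]:
    """Write the bundle tables under ``directory``; round-trip safe with
    :func:`load_bundle`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    drows = [
        {
            "drug_id": d.drug_id,
            "name": d.name,
            "smiles": d.smiles or "",
            "moa_class": d.moa_class,
            "target_kind": d.target_kind.value,
            "target_name": d.target_name or "",
            "target_essential_for": _join_set(d.target_essential_for),
            "replication_stage": d.replication_stage.value,
            "immunomodulatory": d.immunomodulatory.value,
            "routes": _join_set(d.routes),
        }
        for d in sorted(bundle.drugs.values(), key=lambda d: d.drug_id)
    ]
    paths["drugs"] = directory / "drugs.tsv"
    pd.DataFrame(drows, columns=DRUG_COLUMNS).to_csv(paths["drugs"], sep=sep, index=False)

    vrows = [
        {
            "virus_id": v.virus_id,
            "name": v.name,
            "genus": v.genus,
            "family": v.family,
            "related_families": _join_set(v.related_families),
            "infected_systems": _join_set(v.infected_systems),
            "case_fatality_rate": "" if v.case_fatality_rate is None else repr(v.case_fatality_rate),
        }
        for v in sorted(bundle.viruses.values(), key=lambda v: v.virus_id)
    ]
    paths["viruses"] = directory / "viruses.tsv"
    pd.DataFrame(vrows, columns=VIRUS_COLUMNS).to_csv(paths["viruses"], sep=sep, index=False)

    arows = [
        {
            "drug_id": a.drug_id,
            "virus_id": a.virus_id,
            "status": a.status.value,
            "source": a.source or "",
        }
        for a in sorted(bundle.activities.values(), key=lambda a: (a.drug_id, a.virus_id))
    ]
    paths["activities"] = directory / "activities.tsv"
    pd.DataFrame(arows, columns=ACTIVITY_COLUMNS).to_csv(paths["activities"], sep=sep, index=False)

    if bundle.combinations:
        crows = [
            {
                "drug_id_1": c.drug_id_1,
                "drug_id_2": c.drug_id_2,
                "virus_id": c.virus_id,
                "published": str(c.published).lower(),
                "source": c.source or "",
            }
            for c in sorted(bundle.combinations, key=lambda c: (c.drug_id_1, c.drug_id_2, c.virus_id))
        ]
        paths["combinations"] = directory / "combinations.tsv"
        pd.DataFrame(crows, columns=COMBINATION_COLUMNS).to_csv(
            paths["combinations"], sep=sep, index=False
        )

    return paths
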