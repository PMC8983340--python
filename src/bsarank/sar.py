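"""Structure-activity analysis: ECFP4 fingerprints, Tanimoto similarity,
average-linkage clustering and candidate nomination.

Compounds are desalted (largest covalent fragment kept) and fingerprinted
with hashed circular fingerprints of radius 2 (diameter 4, the standard
realization of ECFP4) on 2048 bits.  Clusters are cut from an average-linkage
dendrogram on Tanimoto distance (1 - similarity); sub-clusters containing two
or more known broad-spectrum antivirals nominate their remaining members as
candidate antivirals.

This module also supplies the structural-similarity providers consumed by
the C_SAR score component: a fingerprint-backed provider for SMILES inputs
and a curated-table provider for similarity relations asserted directly by
the annotator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotations import canonical_pair, normalize_id

logger = logging.getLogger(__name__)

__all__ = [
    "StructureError",
    "Fingerprint",
    "ClusterSet",
    "CandidateNomination",
    "fingerprint",
    "tanimoto",
    "cluster_compounds",
    "nominate_candidates",
    "SimilarityProvider",
    "FingerprintSimilarityProvider",
    "TableSimilarityProvider",
    "read_smi",
    "fingerprints_from_smiles",
]


class StructureError(ValueError):
    """Raised for unparseable or empty chemical structures."""


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular fingerprint as a set of on-bit indices."""

    drug_id: str
    bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError(f"{self.drug_id}: bit indices outside [0, {self.n_bits})")


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Desalt by keeping the largest covalent fragment.

    Ties on heavy-atom count are broken by canonical SMILES so the choice is
    deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def fingerprint(smiles: str, drug_id: str = "", n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """ECFP-style fingerprint of a (desalted) SMILES string.

    Raises :class:`StructureError` for unparseable or empty structures.
    """
    mol = Chem.MolFromSmiles(smiles or "")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureError(f"unparseable or empty structure for {drug_id or smiles!r}")
    mol = _largest_fragment(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(drug_id=drug_id, bits=frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass(frozen=True)
class ClusterSet:
    """A flat partition of compounds cut from a dendrogram."""

    clusters: tuple[frozenset[str], ...]
    linkage_cutoff: float
    method: str = "average"

    def cluster_of(self, drug_id: str) -> int:
        d = normalize_id(drug_id)
        for i, members in enumerate(self.clusters):
            if d in members:
                return i
        raise KeyError(drug_id)

    def members(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)


def cluster_compounds(fingerprints: Sequence[Fingerprint], cutoff: float = 0.6) -> ClusterSet:
    """Average-linkage agglomerative clustering on Tanimoto distance.

    The dendrogram is cut flat at ``cutoff`` (cophenetic distance); the
    result is a partition, deterministic for a given input set (compounds are
    ordered by drug_id before linkage).
    """
    fps = sorted(fingerprints, key=lambda f: f.drug_id)
    if not fps:
        raise ValueError("at least one fingerprint required")
    if len(fps) == 1:
        return ClusterSet(clusters=(frozenset({fps[0].drug_id}),), linkage_cutoff=cutoff)

    n = len(fps)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(fps[i], fps[j])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")

    groups: dict[int, set[str]] = {}
    for fp, lab in zip(fps, labels):
        groups.setdefault(int(lab), set()).add(fp.drug_id)
    ordered = tuple(
        frozenset(members) for members in sorted(groups.values(), key=lambda m: min(m))
    )
    return ClusterSet(clusters=ordered, linkage_cutoff=cutoff)


@dataclass(frozen=True)
class CandidateNomination:
    """A non-antiviral compound nominated by structural kinship to known BSAs."""

    candidate_id: str
    anchor_bsa_ids: frozenset[str]
    cluster_id: int
    max_tanimoto_to_anchor: float

    def __post_init__(self) -> None:
        if len(self.anchor_bsa_ids) < 2:
            raise ValueError("a nomination requires at least two anchor BSAs")
        if self.candidate_id in self.anchor_bsa_ids:
            raise ValueError("a BSA cannot be nominated as its own candidate")


def nominate_candidates(
    clusters: ClusterSet,
    bsa_ids: Iterable[str],
    fingerprints: Mapping[str, Fingerprint] | Sequence[Fingerprint],
) -> list[CandidateNomination]:
    """Nominate candidates from clusters containing two or more known BSAs.

    Every non-BSA member of such a cluster is nominated, with its maximum
    Tanimoto similarity to an in-cluster BSA recorded; nominations are sorted
    by that similarity, descending (ties by candidate id).
    """
    bsa = {normalize_id(b) for b in bsa_ids}
    if not isinstance(fingerprints, Mapping):
        fingerprints = {f.drug_id: f for f in fingerprints}
    nominations: list[CandidateNomination] = []
    for cid, members in enumerate(clusters.clusters):
        anchors = members & bsa
        if len(anchors) < 2:
            continue
        for candidate in sorted(members - bsa):
            best = max(
                tanimoto(fingerprints[candidate], fingerprints[a]) for a in sorted(anchors)
            )
            nominations.append(
                CandidateNomination(
                    candidate_id=candidate,
                    anchor_bsa_ids=frozenset(anchors),
                    cluster_id=cid,
                    max_tanimoto_to_anchor=best,
                )
            )
    nominations.sort(key=lambda n: (-n.max_tanimoto_to_anchor, n.candidate_id))
    return nominations


class SimilarityProvider(Protocol):
    """Answers whether a drug is structurally similar to any drug in a set."""

    def is_similar(self, drug_id: str, candidate_ids: Iterable[str]) -> bool: ...


@dataclass
class FingerprintSimilarityProvider:
    """Similarity provider backed by fingerprints and a Tanimoto threshold.

    A query or candidate without a fingerprint contributes ``False`` (with a
    warning), never an exception — missing structures must not abort scoring.
    """

    fingerprints: Mapping[str, Fingerprint]
    threshold: float = 0.4

    def max_similarity(self, drug_id: str, candidate_ids: Iterable[str]) -> float:
        d = normalize_id(drug_id)
        query = self.fingerprints.get(d)
        if query is None:
            logger.warning("no structure for %r; structural similarity treated as absent", drug_id)
            return 0.0
        best = 0.0
        for other in candidate_ids:
            o = normalize_id(other)
            if o == d:
                continue
            fp = self.fingerprints.get(o)
            if fp is None:
                continue
            best = max(best, tanimoto(query, fp))
        return best

    def is_similar(self, drug_id: str, candidate_ids: Iterable[str]) -> bool:
        return self.max_similarity(drug_id, candidate_ids) >= self.threshold


@dataclass
class TableSimilarityProvider:
    """Similarity provider backed by a curated list of similar drug pairs."""

    pairs: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TableSimilarityProvider":
        return cls(pairs=frozenset(canonical_pair(a, b) for a, b in pairs))

    def is_similar(self, drug_id: str, candidate_ids: Iterable[str]) -> bool:
        d = normalize_id(drug_id)
        for other in candidate_ids:
            o = normalize_id(other)
            if o != d and canonical_pair(d, o) in self.pairs:
                return True
        return False


def read_smi(path: str | Path) -> dict[str, str]:
    """Read a ``.smi`` file (one ``SMILES<tab>drug_id`` record per line)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise StructureError(f"malformed .smi line: {line!r}")
        smiles, drug_id = parts
        mapping[normalize_id(drug_id)] = smiles
    return mapping


def fingerprints_from_smiles(
    smiles_by_id: Mapping[str, str], n_bits: int = 2048, *, skip_invalid: bool = False
) -> dict[str, Fingerprint]:
    """Fingerprint a SMILES mapping; optionally skip (and log) invalid entries."""
    out: dict[str, Fingerprint] = {}
    for drug_id, smi in smiles_by_id.items():
        try:
            out[normalize_id(drug_id)] = fingerprint(smi, drug_id=normalize_id(drug_id), n_bits=n_bits)
        except StructureError:
            if not skip_invalid:
                raise
            logger.warning("skipping unparseable structure for %r", drug_id)
    return out
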