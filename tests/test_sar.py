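"""Fingerprints, Tanimoto, clustering and candidate nomination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsarank import (
    Fingerprint,
    FingerprintSimilarityProvider,
    StructureError,
    TableSimilarityProvider,
    cluster_compounds,
    fingerprint,
    nominate_candidates,
    tanimoto,
)
from bsarank.sar import read_smi

TAMOXIFEN = "CCC(=C(C1=CC=CC=C1)C2=CC=C(C=C2)OCCN(C)C)C3=CC=CC=C3"
TOREMIFENE = "CN(C)CCOC1=CC=C(C=C1)C(=C(CCCl)C2=CC=CC=C2)C3=CC=CC=C3"
OSPEMIFENE = "C1=CC=C(C=C1)C(=C(CCCl)C2=CC=CC=C2)C3=CC=C(C=C3)OCCO"
CAFFEINE = "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"


def test_fingerprint_invariant_to_smiles_spelling():
    a = fingerprint("OCC", "ethanol_a")
    b = fingerprint("C(O)C", "ethanol_b")
    assert a.bits == b.bits and a.bits


def test_different_molecules_differ():
    assert fingerprint("C").bits != fingerprint("CC").bits


def test_desalting_keeps_largest_fragment():
    assert fingerprint("CCO.Cl").bits == fingerprint("CCO").bits
    assert fingerprint("CCO.[Na+].[Cl-]").bits == fingerprint("CCO").bits


def test_unparseable_structure_names_the_drug():
    with pytest.raises(StructureError, match="not_a_drug"):
        fingerprint("c1ccc", drug_id="not_a_drug")
    with pytest.raises(StructureError):
        fingerprint("")


def _fp(did, bits, n_bits=16):
    return Fingerprint(drug_id=did, bits=frozenset(bits), n_bits=n_bits)


def test_tanimoto_set_count_oracle():
    assert tanimoto(_fp("a", {1, 2, 3}), _fp("b", {2, 3, 4})) == 0.5
    assert tanimoto(_fp("a", {1}), _fp("b", {1})) == 1.0
    assert tanimoto(_fp("a", {1}), _fp("b", {2})) == 0.0
    with pytest.raises(ValueError, match="widths"):
        tanimoto(_fp("a", {1}), _fp("b", {1}, n_bits=32))


def test_clustering_groups_identicals_and_isolates_outliers():
    fps = [
        fingerprint(TAMOXIFEN, "a"),
        fingerprint(TAMOXIFEN, "b"),  # same molecule, different id
        fingerprint(CAFFEINE, "c"),
    ]
    cs = cluster_compounds(fps, cutoff=0.6)
    assert sorted(sorted(c) for c in cs.clusters) == [["a", "b"], ["c"]]


def test_single_compound_is_a_singleton_cluster():
    cs = cluster_compounds([fingerprint("CCO", "ethanol")], cutoff=0.6)
    assert cs.clusters == (frozenset({"ethanol"}),)


def test_zero_cutoff_only_merges_exact_duplicates():
    fps = [fingerprint(s, f"m{i}") for i, s in enumerate([TAMOXIFEN, TOREMIFENE, CAFFEINE])]
    cs = cluster_compounds(fps, cutoff=0.0)
    assert len(cs.clusters) == 3


def _random_fp_set(rng, n_compounds, n_bits=64):
    fps = []
    for i in range(n_compounds):
        size = rng.integers(1, n_bits // 2)
        bits = frozenset(int(b) for b in rng.choice(n_bits, size=size, replace=False))
        fps.append(Fingerprint(drug_id=f"c{i:02d}", bits=bits, n_bits=n_bits))
    return fps


def test_clustering_is_a_partition_and_coarsens_with_cutoff():
    rng = np.random.default_rng(42)
    for _ in range(20):
        fps = _random_fp_set(rng, int(rng.integers(2, 12)))
        previous = None
        for cutoff in (0.0, 0.3, 0.6, 0.9, 1.0):
            cs = cluster_compounds(fps, cutoff=cutoff)
            members = [d for c in cs.clusters for d in c]
            assert sorted(members) == sorted(f.drug_id for f in fps)  # disjoint cover
            if previous is not None:
                assert len(cs.clusters) <= previous  # monotone coarsening
            previous = len(cs.clusters)


def test_nomination_from_bsa_rich_cluster():
    fps = {
        "tamoxifen": fingerprint(TAMOXIFEN, "tamoxifen"),
        "toremifene": fingerprint(TOREMIFENE, "toremifene"),
        "ospemifene": fingerprint(OSPEMIFENE, "ospemifene"),
        "caffeine": fingerprint(CAFFEINE, "caffeine"),
    }
    clusters = cluster_compounds(list(fps.values()), cutoff=0.6)
    noms = nominate_candidates(clusters, {"tamoxifen", "toremifene"}, fps)
    assert [n.candidate_id for n in noms] == ["ospemifene"]
    assert noms[0].anchor_bsa_ids == frozenset({"tamoxifen", "toremifene"})
    assert 0.0 < noms[0].max_tanimoto_to_anchor <= 1.0


def test_clusters_with_fewer_than_two_bsas_nominate_nothing():
    fps = {
        "tamoxifen": fingerprint(TAMOXIFEN, "tamoxifen"),
        "ospemifene": fingerprint(OSPEMIFENE, "ospemifene"),
        "caffeine": fingerprint(CAFFEINE, "caffeine"),
    }
    clusters = cluster_compounds(list(fps.values()), cutoff=0.6)
    assert nominate_candidates(clusters, {"tamoxifen"}, fps) == []
    assert nominate_candidates(clusters, set(), fps) == []


def test_fingerprint_provider_threshold_is_inclusive_and_strict():
    fps = {"a": _fp("a", {1, 2, 3, 4}), "b": _fp("b", {1, 2, 3})}  # tanimoto 0.75
    assert FingerprintSimilarityProvider(fps, threshold=0.75).is_similar("a", ["b"])
    assert not FingerprintSimilarityProvider(fps, threshold=0.76).is_similar("a", ["b"])
    assert not FingerprintSimilarityProvider(fps, threshold=1.0).is_similar("a", ["b"])
    assert FingerprintSimilarityProvider(fps, threshold=0.4).is_similar("a", ["a", "b"])


def test_provider_handles_missing_structures_and_empty_sets():
    fps = {"a": _fp("a", {1})}
    provider = FingerprintSimilarityProvider(fps, threshold=0.4)
    assert not provider.is_similar("a", [])
    assert not provider.is_similar("ghost", ["a"])  # no structure: False, not an error
    assert not provider.is_similar("a", ["ghost"])


def test_table_provider_is_symmetric():
    provider = TableSimilarityProvider.from_pairs([("B", "a")])
    assert provider.is_similar("a", ["b"]) and provider.is_similar("b", ["a"])
    assert not provider.is_similar("a", ["c"])
    assert not provider.is_similar("a", ["a"])


def test_read_smi_format(tmp_path):
    path = tmp_path / "compounds.smi"
    path.write_text("CCO\tEthanol\nc1ccccc1 Benzene\n# comment\n")
    assert read_smi(path) == {"ethanol": "CCO", "benzene": "c1ccccc1"}


@settings(deadline=None, max_examples=50)
@given(
    a=st.frozensets(st.integers(0, 63), min_size=1, max_size=20),
    b=st.frozensets(st.integers(0, 63), min_size=1, max_size=20),
)
def test_tanimoto_symmetric_bounded_and_one_iff_equal(a, b):
    fa, fb = _fp("a", a, 64), _fp("b", b, 64)
    s = tanimoto(fa, fb)
    assert s == tanimoto(fb, fa)
    assert 0.0 <= s <= 1.0
    assert (s == 1.0) == (a == b)
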