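"""Taxonomy relations, activity-gap prediction and overlap counts."""

from itertools import chain, combinations

import pytest

from bsarank import (
    ActivityRecord,
    ActivityStatus,
    AnnotationBundle,
    DrugAnnotation,
    Relation,
    VirusAnnotation,
    activity_overlap_counts,
    find_activity_gaps,
    relation,
)


def _virus(vid, genus, family, related=()):
    return VirusAnnotation(
        virus_id=vid, name=vid, genus=genus, family=family, related_families=frozenset(related)
    )


def _bundle(viruses, activities):
    bundle = AnnotationBundle()
    drug_ids = {d for d, _, _ in activities}
    for d in drug_ids:
        bundle.drugs[d] = DrugAnnotation(drug_id=d, name=d, moa_class="nnrti")
    for v in viruses:
        bundle.viruses[v.virus_id] = v
    for d, v, status in activities:
        bundle.activities[(d, v)] = ActivityRecord(d, v, ActivityStatus(status))
    return bundle.validate()


SARS2 = _virus("sars_cov_2", "betacoronavirus", "coronaviridae")
SARS1 = _virus("sars_cov", "betacoronavirus", "coronaviridae")
HCOV = _virus("hcov_229e", "alphacoronavirus", "coronaviridae")
TOROV = _virus("torovirus", "torovirus", "tobaniviridae", related=("coronaviridae",))
HIV = _virus("hiv_1", "lentivirus", "retroviridae")


def test_relation_ladder():
    assert relation(SARS2, SARS1) is Relation.SAME_GENUS
    assert relation(SARS2, HCOV) is Relation.SAME_FAMILY
    assert relation(SARS2, TOROV) is Relation.RELATED_FAMILY  # either direction
    assert relation(TOROV, SARS2) is Relation.RELATED_FAMILY
    assert relation(SARS2, HIV) is None
    assert relation(SARS2, SARS2) is Relation.SAME_GENUS


def test_gap_predicted_from_same_family_evidence():
    bundle = _bundle([SARS2, HCOV], [("remdesivir", "sars_cov_2", "in_vitro")])
    gaps = find_activity_gaps(bundle, Relation.SAME_FAMILY)
    assert len(gaps) == 1
    g = gaps[0]
    assert (g.drug_id, g.virus_id, g.evidence_virus_id) == ("remdesivir", "hcov_229e", "sars_cov_2")
    assert g.relation is Relation.SAME_FAMILY and g.implied_c_phyl == 0.5


def test_strongest_relation_reported():
    bundle = _bundle(
        [SARS2, SARS1, HCOV],
        [("drug_x", "sars_cov", "in_vivo"), ("drug_x", "hcov_229e", "in_vitro")],
    )
    gaps = find_activity_gaps(bundle)
    assert len(gaps) == 1
    assert gaps[0].evidence_virus_id == "sars_cov"  # genus beats family
    assert gaps[0].implied_c_phyl == 1.0


def test_no_gaps_when_everything_tested_or_unrelated():
    full = _bundle([SARS2, SARS1], [("d", "sars_cov_2", "in_vitro"), ("d", "sars_cov", "in_vivo")])
    assert find_activity_gaps(full) == []
    unrelated = _bundle([SARS2, HIV], [("d", "hiv_1", "approved_or_phase4")])
    assert find_activity_gaps(unrelated, Relation.RELATED_FAMILY) == []


def test_tightening_min_relation_never_adds_predictions():
    bundle = _bundle(
        [SARS2, SARS1, HCOV, TOROV, HIV],
        [
            ("a", "sars_cov_2", "in_vitro"),
            ("b", "hcov_229e", "approved_or_phase4"),
            ("c", "torovirus", "in_vivo"),
        ],
    )
    counts = [
        len(find_activity_gaps(bundle, rel))
        for rel in (Relation.RELATED_FAMILY, Relation.SAME_FAMILY, Relation.SAME_GENUS)
    ]
    assert counts == sorted(counts, reverse=True)
    for rel in (Relation.RELATED_FAMILY, Relation.SAME_FAMILY, Relation.SAME_GENUS):
        for g in find_activity_gaps(bundle, rel):
            assert bundle.activity_status(g.drug_id, g.virus_id) is ActivityStatus.UNTESTED


def test_status_filter_restricts_evidence():
    bundle = _bundle([SARS2, SARS1], [("d", "sars_cov_2", "in_vitro")])
    assert len(find_activity_gaps(bundle)) == 1
    assert (
        find_activity_gaps(bundle, statuses=[ActivityStatus.APPROVED_OR_PHASE4]) == []
    )


def test_overlap_counts_match_exhaustive_enumeration():
    bundle = _bundle(
        [SARS2, SARS1, HCOV],
        [
            ("a", "sars_cov_2", "in_vitro"),
            ("a", "sars_cov", "in_vitro"),
            ("b", "sars_cov_2", "approved_or_phase4"),
            ("c", "hcov_229e", "in_vivo"),
        ],
    )
    counts = activity_overlap_counts(bundle, "coronaviridae")
    members = ["hcov_229e", "sars_cov", "sars_cov_2"]
    # independent enumeration over all drugs and subsets
    expected = {
        frozenset(sub): 0
        for sub in chain.from_iterable(combinations(members, r) for r in (1, 2, 3))
    }
    for drug in ("a", "b", "c"):
        active = frozenset(
            v for v in members
            if bundle.activity_status(drug, v) is not ActivityStatus.UNTESTED
        )
        if active:
            expected[active] += 1
    assert counts == expected
    assert sum(counts.values()) == 3  # every drug has >= 1 activity in the family
    assert counts[frozenset({"sars_cov", "sars_cov_2"})] == 1
    assert counts[frozenset({"sars_cov_2"})] == 1
    assert counts[frozenset({"sars_cov"})] == 0


def test_overlap_single_virus_and_empty_family():
    bundle = _bundle([SARS2, HIV], [("a", "sars_cov_2", "in_vitro")])
    counts = activity_overlap_counts(bundle, "retroviridae")
    assert counts == {frozenset({"hiv_1"}): 0}
    with pytest.raises(ValueError, match="no viruses"):
        activity_overlap_counts(bundle, "bunyaviridae")


def test_overlap_requires_explicit_list_above_cap():
    viruses = [_virus(f"v{i}", f"g{i}", "bigfam") for i in range(6)]
    bundle = _bundle(viruses, [("a", "v0", "in_vitro")])
    with pytest.raises(ValueError, match="explicit"):
        activity_overlap_counts(bundle, "bigfam")
    counts = activity_overlap_counts(bundle, "bigfam", viruses=["v0", "v1"])
    assert counts[frozenset({"v0"})] == 1
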