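"""Combination coefficients, score, effectiveness rule, ranking, display."""

import itertools

import pytest
from hypothesis import given, strategies as st

from bsarank import (
    RunConfig,
    coeff_di,
    coeff_drs,
    coeff_dti,
    coeff_roa,
    compute_bcc_score,
    display_score,
    rank_combinations,
)
from bsarank.annotations import (
    DegeneratePairError,
    DrugAnnotation,
    ReplicationStage,
    Route,
    TargetKind,
    VirusAnnotation,
)
from bsarank.bcc import BccScoreBreakdown


def _drug(did="d", moa="nnrti", kind=TargetKind.VIRUS, stage=ReplicationStage.REPLICATION,
          routes=frozenset({Route.ORAL})):
    return DrugAnnotation(
        drug_id=did, name=did, moa_class=moa, target_kind=kind,
        replication_stage=stage, routes=routes,
    )


def test_same_moa_halves_interaction_coefficient():
    assert coeff_di(_drug(moa="nucleoside_analog"), _drug("e", moa="nucleoside_analog")) == 0.5
    assert coeff_di(_drug(moa="nucleoside_analog"), _drug("e", moa="impdh_inhibitor")) == 1.0


@pytest.mark.parametrize(
    "k1,k2,expected_k,expected_class",
    [
        (TargetKind.VIRUS, TargetKind.VIRUS, 1.2, "virus_virus"),
        (TargetKind.VIRUS, TargetKind.HOST, 1.1, "virus_host"),
        (TargetKind.HOST, TargetKind.HOST, 1.0, "host_host"),
        (TargetKind.VIRUS, TargetKind.UNKNOWN, 1.0, "unknown"),
        (TargetKind.BOTH, TargetKind.VIRUS, 1.1, "virus_host"),  # dual drug counts as host
        (TargetKind.BOTH, TargetKind.BOTH, 1.0, "host_host"),
    ],
)
def test_target_interaction_coefficient(k1, k2, expected_k, expected_class):
    k, cls = coeff_dti(_drug(kind=k1), _drug("e", kind=k2))
    assert (k, cls) == (expected_k, expected_class)


def test_stage_coefficient_requires_known_shared_stage():
    assert coeff_drs(_drug(), _drug("e")) == 1.2
    assert coeff_drs(_drug(), _drug("e", stage=ReplicationStage.ENTRY)) == 1.0
    assert coeff_drs(
        _drug(stage=ReplicationStage.UNKNOWN), _drug("e", stage=ReplicationStage.UNKNOWN)
    ) == 1.0


def test_route_coefficient_three_levels(config):
    multi = VirusAnnotation(virus_id="v", name="v", genus="g", family="f")
    resp = VirusAnnotation(
        virus_id="r", name="r", genus="g", family="f",
        infected_systems=frozenset({"respiratory"}),
    )
    oral, iv = _drug(routes=frozenset({Route.ORAL})), _drug("e", routes=frozenset({Route.INTRAVENOUS}))
    oral2 = _drug("f", routes=frozenset({Route.ORAL}))
    iv2 = _drug("g", routes=frozenset({Route.INTRAVENOUS}))
    assert coeff_roa(oral, oral2, multi, config) == 1.2  # shared suitable route
    assert coeff_roa(iv, iv2, resp, config) == 1.0  # shared but unsuitable
    assert coeff_roa(oral, iv, multi, config) == 0.8  # no shared route
    assert coeff_roa(oral, _drug("h", routes=frozenset()), multi, config) == 0.8


def test_worked_example_combinations(ebov_bundle, ebov_provider, config):
    fm = compute_bcc_score("favipiravir", "merimepodib", "ebov", ebov_bundle, config, ebov_provider)
    assert fm.coefficients() == {"k_di": 1.0, "k_dti": 1.1, "k_drs": 1.2, "k_roa": 1.2}
    assert fm.bsa_sum == 10.0
    assert fm.bcc_score == pytest.approx(15.84, abs=1e-12)
    assert display_score(fm.bcc_score, 1) == "15.8"
    assert fm.effective and fm.delta == pytest.approx(5.84)

    fr = compute_bcc_score("favipiravir", "ribavirin", "ebov", ebov_bundle, config, ebov_provider)
    assert fr.coefficients() == {"k_di": 0.5, "k_dti": 1.2, "k_drs": 1.2, "k_roa": 1.2}
    assert fr.bsa_sum == 8.5
    assert display_score(fr.bcc_score, 1) == "7.3"
    assert not fr.effective and fr.delta < 0


def test_combination_score_is_symmetric(ebov_bundle, ebov_provider, config):
    a = compute_bcc_score("favipiravir", "merimepodib", "ebov", ebov_bundle, config, ebov_provider)
    b = compute_bcc_score("merimepodib", "favipiravir", "ebov", ebov_bundle, config, ebov_provider)
    assert a == b


def test_identical_drugs_rejected(ebov_bundle, config):
    with pytest.raises(DegeneratePairError):
        compute_bcc_score("favipiravir", "Favipiravir", "ebov", ebov_bundle, config)


def test_coefficient_override_with_provenance(ebov_bundle, config, ebov_provider):
    cfg = RunConfig(overrides={"bcc:favipiravir+merimepodib:ebov:k_dti": 1.2})
    br = compute_bcc_score("favipiravir", "merimepodib", "ebov", ebov_bundle, cfg, ebov_provider)
    assert br.k_dti == 1.2
    assert br.bcc_score == pytest.approx(17.28)
    assert "override" in br.provenance["k_dti"]


def test_rank_orders_and_filters(ebov_bundle, ebov_provider, config):
    table = rank_combinations(ebov_bundle.drugs, "ebov", ebov_bundle, config, ebov_provider)
    assert len(table) == 3  # C(3,2)
    assert list(table.iloc[0][["drug_1", "drug_2"]]) == ["favipiravir", "merimepodib"]
    fm_pos = table.query("drug_1=='favipiravir' and drug_2=='merimepodib'").index[0]
    fr_pos = table.query("drug_1=='favipiravir' and drug_2=='ribavirin'").index[0]
    assert fm_pos < fr_pos
    assert bool(table.iloc[0]["published"]) is True

    effective = rank_combinations(
        ebov_bundle.drugs, "ebov", ebov_bundle, config, ebov_provider, effective_only=True
    )
    assert len(effective) == 1

    with pytest.raises(ValueError, match="at least two"):
        rank_combinations(["favipiravir"], "ebov", ebov_bundle, config)


@pytest.mark.parametrize(
    "value,precision,expected",
    [
        (15.84, 1, "15.8"),
        (15.84, 2, "15.84"),
        (15.05, 2, "15.05"),
        (14.256, 1, "14.3"),
        (20.736, 1, "20.7"),
        (0.0, 1, "0.0"),
        (-1.156, 2, "-1.16"),  # half away from zero
    ],
)
def test_display_rounds_half_away_from_zero(value, precision, expected):
    assert display_score(value, precision) == expected


_KINDS = [TargetKind.VIRUS, TargetKind.HOST, TargetKind.BOTH, TargetKind.UNKNOWN]
_STAGES = [ReplicationStage.ENTRY, ReplicationStage.REPLICATION, ReplicationStage.UNKNOWN]
_ROUTE_SETS = [
    frozenset({Route.ORAL}),
    frozenset({Route.INTRAVENOUS}),
    frozenset({Route.ORAL, Route.INTRAVENOUS}),
    frozenset({Route.TOPICAL}),
]


def test_coefficient_product_bounds_exhaustively(config):
    """Over every combination of annotations, the multiplier stays in [0.4, 1.728]."""
    virus = VirusAnnotation(virus_id="v", name="v", genus="g", family="f")
    moas = ["nucleoside_analog", "nnrti"]
    for m1, m2, k1, k2, s1, s2, r1, r2 in itertools.product(
        moas, moas, _KINDS, _KINDS, _STAGES, _STAGES, _ROUTE_SETS, _ROUTE_SETS
    ):
        d1 = _drug("a", moa=m1, kind=k1, stage=s1, routes=r1)
        d2 = _drug("b", moa=m2, kind=k2, stage=s2, routes=r2)
        product = (
            coeff_di(d1, d2)
            * coeff_dti(d1, d2)[0]
            * coeff_drs(d1, d2)
            * coeff_roa(d1, d2, virus, config)
        )
        assert 0.4 <= product <= 1.728 + 1e-12


@given(
    product=st.sampled_from(
        [di * dti * drs * roa
         for di in (0.5, 1.0) for dti in (1.0, 1.1, 1.2)
         for drs in (1.0, 1.2) for roa in (0.8, 1.0, 1.2)]
    ),
    bsa_sum=st.floats(min_value=0.0, max_value=12.0),
)
def test_effectiveness_needs_multiplier_above_one(product, bsa_sum):
    delta = product * bsa_sum - bsa_sum
    if product <= 1.0:
        assert delta <= 0 < 5


def test_breakdown_json_round_trip(ebov_bundle, ebov_provider, config):
    br = compute_bcc_score("favipiravir", "merimepodib", "ebov", ebov_bundle, config, ebov_provider)
    assert BccScoreBreakdown.from_dict(br.to_dict()) == br
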