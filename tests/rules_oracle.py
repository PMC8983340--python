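"""Independent brute-force re-derivation of the scoring rules.

Written straight from the rule text with plain dict/set logic, deliberately
sharing no code with the scoring modules: used by the test suite to check
the implementation on arbitrary annotation bundles.
"""

from __future__ import annotations

DDS = {
    "approved_or_phase4": 1.0,
    "phase1_3": 0.75,
    "in_vivo": 0.5,
    "in_vitro": 0.25,
    "untested": 0.0,
}


def _status(bundle, drug_id, virus_id) -> str:
    rec = bundle.activities.get((drug_id, virus_id))
    return rec.status.value if rec is not None else "untested"


def _phyl_pair(voi, other) -> float:
    if voi.genus == other.genus:
        return 1.0
    if voi.family == other.family:
        return 0.5
    if other.family in voi.related_families or voi.family in other.related_families:
        return 0.25
    return 0.0


def oracle_bsa(bundle, drug_id, voi_id, suitability, similar_pairs=frozenset()):
    """Six components + total, re-derived from the stated rules.

    ``suitability`` maps organ-system name -> set of route names;
    ``similar_pairs`` is a set of frozenset({a, b}) curated similar pairs.
    """
    drug = bundle.drugs[drug_id]
    voi = bundle.viruses[voi_id]

    status = _status(bundle, drug_id, voi_id)
    if status != "untested":
        c_sar = 1.0
    else:
        developed = {
            d
            for d in bundle.drugs
            if d != drug_id and _status(bundle, d, voi_id) != "untested"
        }
        c_sar = 0.5 if any(frozenset({drug_id, d}) in similar_pairs for d in developed) else 0.0

    c_dds = DDS[status] if c_sar == 1.0 else 0.0
    c_tr = 1.0 if voi_id in drug.target_essential_for else 0.0
    c_ic = 0.0 if drug.immunomodulatory.value == "yes" else 1.0

    suitable: set[str] = set()
    for system in voi.infected_systems:
        suitable |= set(suitability.get(system.value, set()))
    c_roa = 1.0 if {r.value for r in drug.routes} & suitable else 0.0

    c_phyl = 0.0
    for other_id, other in bundle.viruses.items():
        if _status(bundle, drug_id, other_id) != "untested":
            c_phyl = max(c_phyl, _phyl_pair(voi, other))

    comps = dict(c_sar=c_sar, c_dds=c_dds, c_tr=c_tr, c_ic=c_ic, c_roa=c_roa, c_phyl=c_phyl)
    comps["total"] = sum(comps.values())
    return comps


def oracle_bcc(bundle, drug_a, drug_b, voi_id, suitability, similar_pairs=frozenset()):
    """Four coefficients + score, re-derived from the stated rules."""
    d1 = bundle.drugs[drug_a]
    d2 = bundle.drugs[drug_b]
    voi = bundle.viruses[voi_id]

    k_di = 0.5 if d1.moa_class == d2.moa_class else 1.0

    def kind(d):
        k = d.target_kind.value
        return "host" if k == "both" else k

    kinds = {kind(d1), kind(d2)}
    if "unknown" in kinds:
        k_dti = 1.0
    elif kinds == {"virus"}:
        k_dti = 1.2
    elif kinds == {"host"}:
        k_dti = 1.0
    else:
        k_dti = 1.1

    s1, s2 = d1.replication_stage.value, d2.replication_stage.value
    k_drs = 1.2 if s1 == s2 and s1 != "unknown" else 1.0

    shared = {r.value for r in d1.routes} & {r.value for r in d2.routes}
    suitable: set[str] = set()
    for system in voi.infected_systems:
        suitable |= set(suitability.get(system.value, set()))
    if not shared:
        k_roa = 0.8
    elif shared & suitable:
        k_roa = 1.2
    else:
        k_roa = 1.0

    bsa_sum = (
        oracle_bsa(bundle, drug_a, voi_id, suitability, similar_pairs)["total"]
        + oracle_bsa(bundle, drug_b, voi_id, suitability, similar_pairs)["total"]
    )
    score = k_di * k_dti * k_drs * k_roa * bsa_sum
    return {
        "k_di": k_di,
        "k_dti": k_dti,
        "k_drs": k_drs,
        "k_roa": k_roa,
        "bsa_sum": bsa_sum,
        "bcc_score": score,
        "delta": score - bsa_sum,
        "effective": score - bsa_sum > 5,
    }
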