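# bsarank

Annotation-driven prioritization of **broad-spectrum antivirals (BSAs)** and
two-drug **BSA-containing combinations (BCCs)** for pandemic preparedness.

When a new virus emerges, thousands of approved and investigational antivirals
are candidates for repurposing, but only a handful can enter trials. `bsarank`
implements a transparent, annotation-driven scoring system that ranks both
monotherapies and two-drug cocktails against a virus of interest (Voi) from
curated drug, virus and activity tables — no screening data required. It is a
library for virologists and drug-repurposing researchers, with a thin
command-line wrapper for pipeline use.

## The scoring system

**Monotherapy (BSA) score** — six additive components, each a small rational:

```
BSA = C_SAR + C_DDS + C_TR + C_IC + C_RoA + C_Phyl          (0 ≤ BSA ≤ 6)
```

| component | values | meaning |
|---|---|---|
| C_SAR | 1 / 0.5 / 0 | drug developed against the Voi; structurally similar to such a drug; neither |
| C_DDS | 1 / 0.75 / 0.5 / 0.25 / 0 | development status vs the Voi (approved/phase 4 → in vitro); applies only when C_SAR = 1 |
| C_TR | 1 / 0 | primary target annotated essential for Voi replication |
| C_IC | 1 / 0 | drug does **not** interfere with the host immune response |
| C_RoA | 1 / 0 | an administration route suits the infected organ systems |
| C_Phyl | 1 / 0.5 / 0.25 / 0 | Voi shares genus / family / a related family with a virus the drug is active against |

**Combination (BCC) score** — four multiplicative coefficients on the pair sum:

```
BCC = k_DI · k_DTI · k_DRS · k_RoA · (BSA₁ + BSA₂)
```

with k_DI = 0.5 for identical mechanisms of action (else 1), k_DTI = 1.2 /
1.1 / 1.0 for virus+virus / virus+host / host+host targeting, k_DRS = 1.2 for
a shared life-cycle stage (else 1), and k_RoA = 1.2 / 1.0 / 0.8 for a shared
suitable route / shared unsuitable route / no shared route. A combination is
flagged **effective** when `BCC − (BSA₁ + BSA₂) > 5`, which is only possible
when the coefficient product exceeds 1.

Around the scores, the package provides ECFP4/Tanimoto structure clustering
that nominates new antiviral candidates from clusters containing two or more
known BSAs, and taxonomy-based *activity-gap* prediction (untested drug–virus
pairs supported by activity against a relative).

## Worked example

```bash
python examples/score_worked_examples.py
```

prints

```
Monotherapy (BSA) scores against Ebola virus, 0-6 scale:
  favipiravir  total 5.75  (c_sar=1, c_dds=0.75, c_tr=1, c_ic=1, c_roa=1, c_phyl=1)
  merimepodib  total 4.25  (c_sar=1, c_dds=0.25, c_tr=1, c_ic=0, c_roa=1, c_phyl=1)
  ribavirin    total 2.75  (c_sar=0.5, c_dds=0, c_tr=1, c_ic=0, c_roa=1, c_phyl=0.25)

Combination (BCC) scores against Ebola virus:
  favipiravir+merimepodib    BSA sum 10    BCC 15.8  delta +5.840  -> EFFECTIVE
  favipiravir+ribavirin      BSA sum 8.5   BCC 7.3   delta -1.156  -> not effective
```

Favipiravir scores highly (phase-3 trials against Ebola, oral, viral-polymerase
target); merimepodib loses points for in-vitro-only status and
immunosuppression. Pairing them multiplies the 10-point sum by
1.0·1.1·1.2·1.2 = 1.584 (different mechanisms, viral+host targets, shared
stage and a shared oral route) to 15.84 — more than 5 points above the plain
sum, so the cocktail is flagged promising. Favipiravir+ribavirin instead
*loses* score: two nucleoside analogs compete, so k_DI = 0.5 drags 8.5 down
to 7.3.

Other entry points: `examples/rank_candidate_pairs.py` (rank all pairs
against HIV-1), `examples/cluster_structures.py` (nominate ospemifene from
the tamoxifen/toremifene scaffold), `examples/predict_activity_gaps.py`
(taxonomy-based spectrum expansion), and the `bsarank` CLI
(`score-bsa`, `score-bcc`, `rank`, `sar-cluster`, `gaps`, `overlap`,
`simulate`, `fixtures`, `validate`).

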