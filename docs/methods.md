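# Methods

## Model

`bsarank` scores antiviral repurposing candidates from *annotations*, not from
assay data: the inputs are curated tables of drug properties (mechanism of
action, target and its kind, life-cycle stage, immunomodulation, routes),
virus taxonomy (genus, family, a declared related-families adjacency, infected
organ systems) and per-pair development status. The monotherapy score is the
sum of six components (structure/development identity, development status,
target relevance, immune interference, route suitability, taxonomic
proximity); the combination score multiplies the pair's summed monotherapy
scores by four interaction coefficients (mechanism distinctness, target-kind
pairing, stage sharing, route sharing). Both scores are fully deterministic
functions of the annotation bundle and the run configuration.

Assumptions worth making explicit:

- **Annotations are trusted.** "Target essential for Voi replication" is an
  explicit per-virus annotation (`target_essential_for`), never inferred:
  there is no computable definition of target relevance, and silent inference
  would be worse than an honest blank.
- **Unknowns are scored optimistically for immunity, conservatively for
  interactions.** A drug whose immunomodulatory status is *not reported*
  receives C_IC = 1 (a missing report is not a demonstrated liability),
  while an unknown target kind floors k_DTI at 1.0 and an unknown life-cycle
  stage denies the k_DRS bonus — interaction bonuses require positive
  evidence.
- **A dual virus+host drug counts as host-directed for k_DTI**: its host
  target carries the side-effect liability that the coefficient encodes. The
  pairing rule assigns no explicit value to dual-target drugs, so this is a
  declared design choice (recorded in provenance via the pair's target
  class).
- **C_Phyl aggregates by maximum** over every virus the drug has a
  non-untested activity record against, including the Voi itself. A drug
  "developed against" one virus is in practice active against many; the
  maximum is the optimistic, order-independent choice and reproduces the
  worked examples.
- **C_DDS is gated on C_SAR = 1**: the development-status ladder only applies
  to a drug that itself has a record against the Voi; a merely similar drug
  contributes 0.

## Parameters and defaults

| parameter | default | units / range | rationale |
|---|---|---|---|
| `similarity_threshold` | 0.4 | Tanimoto on ECFP4, (0,1] | conventional similarity floor for 2048-bit circular fingerprints; drives the C_SAR = 0.5 rung |
| `cluster_cutoff` | 0.6 | cophenetic distance, [0,1] | average-linkage cut giving scaffold-sized clusters on ECFP4 distance |
| `effectiveness_delta` | 5 | score points | the published effectiveness bar; exposed for sensitivity analysis |
| `route_suitability` | see below | organ system → routes | clinical common sense fixes a few cells; the rest are declared defaults |
| fingerprint | radius 2, 2048 bits | — | the standard realization of ECFP4; bit width is an implementation convention |

Default route suitability: respiratory → {inhalation, oral}; digestive →
{oral}; cardiovascular → {intravenous}; nervous → {intravenous, oral};
integumentary → {topical, oral}; urogenital → {oral, intravenous}; multiple →
{oral, intravenous}. Only the respiratory-inhalation and
cardiovascular-intravenous cells are anchored in clinical practice; every
cell is overridable in `RunConfig` and the map used is recorded in
provenance.

Effectiveness is *strictly* `delta > 5`. Because the coefficient product is
bounded in [0.4, 1.728] (0.5·1·1·0.8 to 1·1.2·1.2·1.2) and the pair sum in
[0, 12], a product ≤ 1 can never be effective; the bound is enforced as a
test invariant.

## Numerical choices

All component values are dyadic rationals (multiples of 0.25), so binary
floating point represents them and their sums exactly; no rational-arithmetic
type is needed, and score equality in tests is exact. The combination score
involves factors of 1.1/1.2 and is compared at 1e-9 where exactness is not
guaranteed. Display rounding is half-away-from-zero at a caller-chosen
precision (scores are conventionally printed at one decimal, e.g. 15.84 →
15.8) and is purely presentational: ranking and the effectiveness verdict
always use full precision. Ranking ties break deterministically by (score,
delta, canonical pair name); clustering orders compounds by id before linkage
so partitions are order-robust; drug pairs are stored once, in lexicographic
order.

Degenerate inputs: a pair of identical drugs is an error; a drug without
routes scores C_RoA = 0 and forces k_RoA = 0.8 with a logged warning (never
an exception); a drug without a structure simply cannot earn C_SAR = 0.5; an
empty activity table means every pair is untested.

## Structural similarity

Structures are desalted by keeping the largest covalent fragment (ties broken
by canonical SMILES), then fingerprinted with hashed circular fingerprints of
radius 2 on 2048 bits. Clustering is average-linkage agglomerative on
1 − Tanimoto with a flat cut; candidate nomination takes every cluster with
two or more known broad-spectrum antivirals and nominates its remaining
members, reporting each candidate's maximum similarity to an in-cluster
anchor. Two similarity providers feed the C_SAR = 0.5 rule: the default
fingerprint provider (threshold ≥ `similarity_threshold`), and a curated
similar-pairs table for relations asserted directly by the annotator. The
packaged Ebola fixture uses the curated table for the favipiravir–ribavirin
pair: the two drugs are conventionally described as structural analogs
(both heteroaryl carboxamides) although their ECFP4 Tanimoto (0.17) falls
below the default threshold — a reminder that fingerprint similarity is a
proxy, not a definition.

## Taxonomy and gap prediction

Virus relatedness is read from the taxonomy columns — same genus, same
family, or a declared related-families adjacency — rather than from
sequence-derived trees. This is deliberate: polymerase-based trees exclude
viruses that do not encode their own polymerase or reverse transcriptase, and
tree construction would drag in alignment tooling without changing the
ladder the score actually consumes. The cost is that "closely related
family" is whatever the annotator declares; no inference is attempted.

Gap prediction enumerates (drug, untested virus) pairs with at least one
evidence virus at or above a minimum relation, reporting the strongest
relation and an evidence virus achieving it. Tightening the minimum relation
can only shrink the list (tested as an invariant). What counts as evidence
defaults to any non-untested status and is exposed as a status filter, since
in-vitro-only evidence is a legitimately debatable inclusion.

## Synthetic bundles

`SyntheticSpec`/`generate_bundle` produce random annotation bundles that are
pure functions of the spec (including its seed): families on a ring of
related-family adjacencies, up to two genera per family, drugs drawn from the
mechanism vocabulary with random targets, stages and routes, and a Bernoulli
activity matrix. Defaults (20 drugs, 8 viruses, 4 families, activity density
0.15, immunomodulatory rate 0.23) mirror the shape of a curated antiviral
database, where most drugs are tested against few viruses and roughly a
quarter of catalogued broad-spectrum antivirals carry immunomodulatory
annotations. Synthetic drugs carry simple stand-in structures from a packaged
list of parseable SMILES, not realistic pharmacophores.

What the synthetic tests do and do not show: they verify that the rule engine
agrees exactly with an independent straight-from-the-rules re-derivation on
arbitrary annotation combinations (including ones no curated database would
contain), and that bounds and monotonicity invariants hold everywhere. They
say nothing about whether the *annotations* of real drugs are right, and the
score itself is a prioritization heuristic — it encodes curation, not potency.

## Fixtures

The Ebola worked-example bundle annotates favipiravir (oral nucleoside analog
in phase-3 trials against Ebola, polymerase target essential, immunomodulation
not reported → 5.75), merimepodib (oral host IMPDH inhibitor, in vitro
against Ebola, immunosuppressive → 4.25) and ribavirin. Ribavirin's
published constraint is the pair sum of 8.5 with favipiravir, not its own
breakdown; the only decomposition consistent with the scoring rules is
(0.5, 0, 1, 0, 1, 0.25), which the fixture realizes with a Lassa-virus
phase-1-3 record (Arenaviridae declared related to Filoviridae), an essential
polymerase target, documented immunomodulation, oral dosing, and curated
similarity to favipiravir. A circulating favipiravir score of 5.57 is
arithmetically inconsistent with its own printed components and with the pair
sum and is treated as a transcription slip. The wider published-combinations
fixture covers the four rows whose inputs are fully determined by the
coefficient rules; rows whose printed multiplier exceeds the provable maximum
(e.g. an 8.5 → 16.2 row implying a 1.91 multiplier) are shipped flagged
`override_required` with no expected value — they can only be reproduced by
per-row manual coefficient overrides, and guessing the original annotations
would be fabrication.

## Known limitations

- The score is only as good as its annotations; mechanism-of-action classes
  are a shipped, editorial, user-extensible vocabulary.
- Pairs only: the combination formula is two-drug; triples and higher
  cocktails are out of scope.
- No dose, synergy-landscape (Bliss/Loewe), pharmacokinetic or toxicity
  modeling — coefficients are categorical stand-ins for those effects.
- Exact membership of published structure clusters depends on the full
  compound collection and the (unstated) clustering cut used to produce
  them, and is therefore not a reproduction target; the clustering here is
  specified, deterministic, and tested on its invariants instead.
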