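"""Score the packaged Ebola worked examples: two monotherapies and two cocktails.

Run:  python examples/score_worked_examples.py
"""

from bsarank import (
    RunConfig,
    compute_bcc_score,
    compute_bsa_score,
    display_score,
    ebov_fixture,
    ebov_similarity_provider,
)

bundle = ebov_fixture()
provider = ebov_similarity_provider()
config = RunConfig()

print("Monotherapy (BSA) scores against Ebola virus, 0-6 scale:")
for drug in ("favipiravir", "merimepodib", "ribavirin"):
    b = compute_bsa_score(drug, "ebov", bundle, config, provider)
    comps = ", ".join(f"{k}={v:g}" for k, v in b.components().items())
    print(f"  {drug:<12} total {b.total:<5g} ({comps})")

print("\nCombination (BCC) scores against Ebola virus:")
for pair in (("favipiravir", "merimepodib"), ("favipiravir", "ribavirin")):
    r = compute_bcc_score(*pair, "ebov", bundle, config, provider)
    verdict = "EFFECTIVE" if r.effective else "not effective"
    print(
        f"  {'+'.join(pair):<26} BSA sum {r.bsa_sum:<5g} "
        f"BCC {display_score(r.bcc_score, 1):<5} delta {r.delta:+.3f}  -> {verdict}"
    )

print(
    "\nA combination is flagged effective when its multiplicative score exceeds"
    "\nthe plain sum of the two monotherapy scores by more than 5 points:"
    "\nfavipiravir+merimepodib clears the bar (different mechanisms, viral+host"
    "\ntargets, same life-cycle stage, shared oral route); favipiravir+ribavirin"
    "\ndoes not (two nucleoside analogs compete, halving the score)."
)
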