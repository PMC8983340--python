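"""Cluster drug structures and nominate antiviral candidates by kinship.

Triphenylethylene drugs: tamoxifen and toremifene are known broad-spectrum
antivirals (active against filoviruses and coronaviruses); ospemifene shares
their scaffold.  Caffeine and aspirin are structural outliers.

Run:  python examples/cluster_structures.py
"""

from bsarank import cluster_compounds, fingerprints_from_smiles, nominate_candidates

SMILES = {
    "tamoxifen": "CCC(=C(C1=CC=CC=C1)C2=CC=C(C=C2)OCCN(C)C)C3=CC=CC=C3",
    "toremifene": "CN(C)CCOC1=CC=C(C=C1)C(=C(CCCl)C2=CC=CC=C2)C3=CC=CC=C3",
    "ospemifene": "C1=CC=C(C=C1)C(=C(CCCl)C2=CC=CC=C2)C3=CC=C(C=C3)OCCO",
    "caffeine": "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",
    "aspirin": "CC(=O)OC1=CC=CC=C1C(=O)O",
}
KNOWN_BSAS = {"tamoxifen", "toremifene"}

fps = fingerprints_from_smiles(SMILES)
clusters = cluster_compounds(list(fps.values()), cutoff=0.6)

print(f"{len(clusters.clusters)} clusters at average-linkage distance cutoff 0.6:")
for cid, members in enumerate(clusters.clusters):
    tags = [m + ("*" if m in KNOWN_BSAS else "") for m in sorted(members)]
    print(f"  cluster {cid}: {', '.join(tags)}   (* = known antiviral)")

nominations = nominate_candidates(clusters, KNOWN_BSAS, fps)
print("\nCandidates nominated from clusters containing >= 2 known antivirals:")
for n in nominations:
    print(
        f"  {n.candidate_id}: max Tanimoto {n.max_tanimoto_to_anchor:.2f} "
        f"to anchors {sorted(n.anchor_bsa_ids)}"
    )
print(
    "\nOspemifene is pulled in by its triphenylethylene scaffold; a high"
    "\nTanimoto to two established antivirals makes it a testable candidate."
)
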