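"""Build explicit polymer chains from monomer SMILES.

Grows a nylon-6,6 chain and a PET-like polyester, prints the chain SMILES,
the residue sequence and the exact mass balance (chain mass = residue
masses minus one water per condensation linkage).
"""

from polyscreen import (
    PolymerSpec,
    build_replicates,
    classify_monomer,
    expected_molecular_weight,
    polymerize,
)

adipic = classify_monomer("OC(=O)CCCCC(=O)O")
hda = classify_monomer("NCCCCCCN")
spec = PolymerSpec(
    monomers=(adipic, hda),
    chemistry="polyamide",
    degree_of_polymerization=6,
    rng_seed=0,
)
chain = polymerize(spec)
print("nylon-6,6 (DP 6):", chain.smiles)
print("residue sequence (monomer index, orientation):", chain.residue_sequence)
print(
    f"mass balance: built {chain.molecular_weight:.3f} Da vs closed form "
    f"{expected_molecular_weight([adipic, hda], chain.residue_sequence, 'polyamide'):.3f} Da"
)

terephthalic = classify_monomer("OC(=O)c1ccc(C(=O)O)cc1")
eg = classify_monomer("OCCO")
pet = PolymerSpec(
    monomers=(terephthalic, eg),
    chemistry="polyester",
    degree_of_polymerization=8,
    replicate_count=3,
    rng_seed=1,
)
print("\nPET-like polyester, 3 replicate chains (comonomer order varies):")
for rep in build_replicates(pet):
    print(" ", rep.smiles)
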