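"""Count novel substructures of a prediction target vs a training corpus.

A polymer whose chain contains at most 6 radius-<=2 environment hashes not
seen in training is inside the domain of validity; a sulfur-containing
chain is far outside because no training chain contains sulfur at all.
"""

from polyscreen import (
    PolymerSpec,
    classify_monomer,
    collect_hashes,
    generate_fixture_dataset,
    novel_count,
    polymerize,
)

records = generate_fixture_dataset(n_polymers=60, seed=4, dp=6)
hashes = collect_hashes([r.structure for r in records])
print(f"training corpus: {len(records)} chains, {len(hashes.hashes)} distinct hashes")

for label, smiles_pair, chemistry in [
    ("training-like polyester", ("OC(=O)CCCCC(=O)O", "OCCO"), "polyester"),
    ("thioether polyester", ("OC(=O)CCSCC(=O)O", "OCCO"), "polyester"),
]:
    spec = PolymerSpec(
        monomers=tuple(classify_monomer(s) for s in smiles_pair),
        chemistry=chemistry,
        degree_of_polymerization=6,
        rng_seed=0,
    )
    report = novel_count(polymerize(spec), hashes)
    verdict = "inside" if report.inside else "OUTSIDE"
    print(f"{label:25s} novel hashes = {report.novel_count:2d} -> {verdict} the domain of validity")
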