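"""Run the discovery funnel on a small candidate monomer set.

Monomers are prescreened (CHNO, <300 Da, bifunctional), combined into
polyester/polyamide candidates, predicted, gated by domain of validity and
flagged against a Tg performance criterion; the funnel breakdown sums to
the candidate total.
"""

import warnings

from polyscreen import (
    PerformanceCriterion,
    collect_hashes,
    enumerate_candidates,
    filter_monomers,
    funnel_breakdown,
    generate_fixture_dataset,
    screen,
    train_cv,
)
from polyscreen.harness import small_fixture_config

warnings.simplefilter("ignore")

records = generate_fixture_dataset(n_polymers=120, seed=0, dp=6, noise_sd=10.0)
ensemble = train_cv(records, small_fixture_config(seed=0, epochs=80, dp_train=6))
hashes = collect_hashes([r.structure for r in records])

raw = [
    "OC(=O)CCCCC(=O)O",          # adipic acid
    "OC(=O)c1ccc(C(=O)O)cc1",    # terephthalic acid
    "OC(=O)c1ccc(C(=O)O)o1",     # furandicarboxylic acid
    "OCCO",                      # ethylene glycol
    "OCCCCO",                    # 1,4-butanediol
    "NCCCCCCN",                  # hexamethylenediamine
    "OC(=O)CCSCC(=O)O",          # rejected: sulfur
    "c1ccccc1",                  # rejected: no functionality
]
monomers = filter_monomers(raw)
print(f"{len(monomers)} of {len(raw)} monomers pass prescreening")

candidates = enumerate_candidates(monomers, ["polyester", "polyamide"])
criteria = [PerformanceCriterion("tg_c", ">=", threshold=100.0)]
result = screen(candidates, ensemble, hashes, criteria, dp=6, seed=0)

print(f"{len(result)} candidates screened; funnel (inside DoV, passes Tg>=100):")
for key, n in sorted(funnel_breakdown(result).items(), reverse=True):
    print(f"  inside_dov={key[0]!s:5s} passes={key[1]!s:5s} n={n}")
print("\ntop 3 candidates:")
for cand in result[:3]:
    print(
        f"  {'+'.join(m.smiles for m in cand.monomers):45s} "
        f"{cand.chemistry:10s} Tg {cand.prediction.mean['tg_c']:6.1f} degC "
        f"novel {cand.dov.novel_count}"
    )
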