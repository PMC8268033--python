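"""Score a ligand and its binding-site residues, then classify the pair.

Builds metric records by hand (the values a wwPDB validation report would
supply), scores each entity against the seven default checks, and combines
the ligand and site categories into the two-letter pair code.
"""

from ligqc import (
    EntityMetrics,
    GlobalMetrics,
    classify_pair,
    score_binding_site,
    score_entity,
)

# Entry-level statistics shared by every entity of the structure.
entry = GlobalMetrics(resolution=2.3, r_work=0.22, r_free=0.25)

# The bound ligand: poor local fit (high RSR, low RSCC, half occupancy).
ligand = score_entity(
    EntityMetrics(entity_key="A:301", rsr=0.45, rscc=0.61, avg_occupancy=0.5, owab=75.0),
    entry,
)
print(f"ligand  score={ligand.score}  violated={''.join(sorted(ligand.violated_checks))}  "
      f"category={ligand.category}")

# Three binding-site residues; one has a weak side chain (RSCC below 0.9).
residues = [
    score_entity(EntityMetrics(entity_key=k, rsr=rsr, rscc=rscc, avg_occupancy=1.0, owab=owab), entry)
    for k, rsr, rscc, owab in [
        ("A:55", 0.18, 0.95, 30.0),
        ("A:57", 0.28, 0.85, 42.0),
        ("A:112", 0.15, 0.97, 25.0),
    ]
]
site = score_binding_site(residues)
print(f"site    score={site.score}  worst_residues={site.worst_residues}  category={site.category}")

pair = classify_pair(ligand, site)
print(f"pair    code={pair.pair_code}")
# The first letter rates the ligand, the second the site: a 'B?' code means
# the ligand needs serious attention before any structure-based use.
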