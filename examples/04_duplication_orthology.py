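"""Tandem/segmental duplication and BBH orthology.

Finds within-species duplication events (identity >= 80%, e <= 1e-10,
tandem within 5 Mb) and cross-species best-bidirectional-hit orthologs,
then scores both against the planted truth.
"""
from legfam import (
    SyntheticConfig, find_orthologs_bbh, find_paralogs, generate_genomes,
)

fixture = generate_genomes(
    SyntheticConfig(species_count=2, genes_per_species=50, seed=7,
                    planted_tandem_pairs=2, planted_segmental_pairs=4,
                    planted_ortholog_fraction=1.0)
)
family = [
    p for p in fixture.proteins["Ca"]
    if fixture.truth.genes[p.id].subfamily != "background"
]
events = find_paralogs(family, fixture.models["Ca"])
for e in events:
    where = f"{e.distance:,} bp apart" if e.distance is not None \
        else "different chromosomes"
    print(f"{e.gene_a} ~ {e.gene_b}: {e.kind} "
          f"({e.alignment.identity:.1f}% identity, {where})")
planted = {frozenset((a, b)): k for a, b, k in fixture.truth.paralog_pairs}
found = {frozenset((e.gene_a, e.gene_b)): e.kind for e in events}
print(f"duplication events: {len(found)} found, "
      f"{len(planted)} planted, exact match: {found == planted}")

pairs = find_orthologs_bbh(fixture.proteins["Ca"], fixture.proteins["Cc"])
want = set(map(tuple, fixture.truth.ortholog_pairs))
got = {(p.gene_species1, p.gene_species2) for p in pairs}
print(f"BBH orthologs: {len(got)} found, {len(want)} planted, "
      f"exact match: {got == want}")
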