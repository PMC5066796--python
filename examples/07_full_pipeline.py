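"""Run the end-to-end pipeline on a generated fixture directory.

Equivalent to `legfam generate ... && legfam run-all ...`: writes
per-stage TSVs, trees, summaries, a manifest and a log into a run
directory, and prints the Table-1-style summary per species.
"""
from legfam import (
    PipelineConfig, SyntheticConfig, generate_ct_table, generate_expression,
    generate_genomes, run_pipeline, write_fixture,
)

config = SyntheticConfig(species_count=2, genes_per_species=45, seed=7,
                         planted_ortholog_fraction=1.0)
fixture = generate_genomes(config)
expr = generate_expression(fixture.truth, seed=7, species="Ca")
folds = {g: 4.0 for g, t in sorted(fixture.truth.genes.items())
         if t.expression_block == 1 and t.species == "Ca"}
ct = generate_ct_table(fixture.truth, folds, seed=7)
write_fixture(fixture, "example_run_input", expression=expr, ct_table=ct)

result = run_pipeline(PipelineConfig(
    input_dir="example_run_input", output_dir="example_run",
    bootstrap_replicates=100, seed=7,
))
for species, summary in sorted(result.summaries.items()):
    print(f"{species}: family total {summary.family_total} "
          f"(DREB {summary.dreb_total}, ERF-subfamily "
          f"{summary.erf_subfamily_total}, AP2 {summary.ap2}, "
          f"ANT {summary.ant}), HSP90 {summary.hsp90}")
    print(f"  duplication events: "
          f"{len(result.duplications.get(species, []))}")
print("stage outputs, manifest.json and pipeline.log in example_run/")
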