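"""Run the whole analysis in one call and print the summary report."""

from coretrans import PipelineConfig, report, run_pipeline
from conf_small import small

config = PipelineConfig(
    simulate=small(),
    backend="mapeq", n_trials=10, restarts=30,
    k_range_taxon=(2, 12), k_range_general=(2, 8),
    seed=1,
)
bundle = run_pipeline(config, outdir="pipeline_output")
print(report(bundle))
print("flat CSV outputs and the provenance manifest are in pipeline_output/")
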