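"""Run the full pipeline and inspect the report bundle.

Generates the default cohort and executes describe → correlation filter →
discriminant analysis (univariate, stepwise, direct, LOOCV) → feature
ranking → eight-classifier comparison → stacking, writing one JSON report
per stage plus a CSV summary. Identical config and seed reproduce
byte-identical reports.
"""

from patellasex import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, out_dir="pipeline_out")
bundle = run_pipeline(cfg)

print("stages:", list(bundle))
uni = bundle["dfa"]["univariate"]
best = max(uni, key=lambda e: e["cross_validated"]["average_pct"])
print(f"best univariate function: {best['variables'][0]} "
      f"({best['cross_validated']['average_pct']:.1f}% LOOCV average)")
stack = bundle["stack"]["stacking"][0]
print(f"stacking accuracy: {stack['metrics']['accuracy']['value_pct']:.2f}% "
      f"± {stack['metrics']['accuracy']['ci_half_width_pct']:.2f}")
print("reports written to pipeline_out/ (describe.json, dfa.json, ml.json, "
      "stack.json, summary.csv)")
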