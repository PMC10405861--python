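"""One-call reproducible pipeline: simulate -> preprocess -> fit -> stability.

Everything (trial tables, error tables, per-session fits, stability
report, provenance with all seeds) lands in the output directory; the
same config always reproduces the same numbers.
"""

from serialdep import RunConfig, run_pipeline

config = RunConfig(
    study=1,
    n_subjects=4,
    seed=41,
    n_perm=500,
    model_free_range=54.0,
    out_dir="pipeline_demo",
)
bundle = run_pipeline(config)

est = bundle["session_estimates"]
print(est[["subject", "session", "n_trials", "amplitude_deg", "p_perm",
           "model_free_deg"]].to_string(index=False))
print(f"\nlapses removed: {int(bundle['removal_log']['n_removed'].sum())}")
print(f"cohort dispersion: {bundle['performance']['dispersion']:.2f} deg")
print("outputs written to pipeline_demo/ (re-run to verify determinism)")
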