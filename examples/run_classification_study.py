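"""Run a scaled-down classification-accuracy study: hierarchy x Q-design
conditions, each replicated simulate -> fit -> classify -> score.

The full study uses N=1000 and 100 replications per condition; this demo
uses 3 replications so it finishes in under a minute while showing the
report layout (profile CCR by occasion, marginal CCR by attribute).
"""

from longdcm import AttributeHierarchy, StudyConfig, run_study

config = StudyConfig(
    hierarchies=[AttributeHierarchy.linear(3), AttributeHierarchy.independent(3)],
    design_ids=["Q1", "Q2"],
    n_examinees=1000,
    n_reps=3,
    base_seed=1,
)
result = run_study(config)
print(result.to_frame().round(3).to_string())

lin = result.get("linear", "Q2")
print(f"\nlinear/Q2 grand mean profile CCR: {lin.mean_profile_ccr:.3f} "
      f"(MC SE ~{lin.profile_ccr_se.mean():.3f})")
print("Rows: exact profile match rates per occasion, then per-attribute "
      "agreement; linear-hierarchy columns outperform independent ones.")
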