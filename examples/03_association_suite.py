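"""Age-adjusted association between ABR wave V features and cognition.

Scores a synthetic cohort (z-scored measures, direction-adjusted, averaged
into a composite) and fits the key regressions: composite on age (z/year),
and composite on z-scored wave V latency/amplitude before and after age
adjustment. Slopes are in composite-z per predictor unit.
"""

from abrcog import default_params, generate_cohort, build_cognitive_scores
from abrcog.association import RegressionSpec, fit_linear_model

cohort, _ = generate_cohort(default_params(seed=3))
scored = build_cognitive_scores(cohort)

def show(label, spec):
    r = fit_linear_model(scored, spec)
    print(f"{label:35s} B={r.B:+.3f}  95% CI [{r.ci95[0]:+.3f}, {r.ci95[1]:+.3f}]  p={r.p:.4f}  n={r.n}")

show("composite ~ age (z/year)", RegressionSpec("composite_z", "age"))
show("composite ~ PTA (z/dB)", RegressionSpec("composite_z", "pta"))
show("composite ~ wave V latency (z/z)",
     RegressionSpec("composite_z", "wave_v_latency", standardize=("wave_v_latency",)))
show("  ... age-adjusted",
     RegressionSpec("composite_z", "wave_v_latency", covariates=("age",),
                    standardize=("wave_v_latency",)))
show("composite ~ wave V amplitude (z/z)",
     RegressionSpec("composite_z", "wave_v_amplitude", standardize=("wave_v_amplitude",)))
show("  ... age-adjusted",
     RegressionSpec("composite_z", "wave_v_amplitude", covariates=("age",),
                    standardize=("wave_v_amplitude",)))
print("\nage adjustment roughly halves the wave V effect sizes but both "
      "remain nonzero: the generator plants an age-independent coupling.")
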