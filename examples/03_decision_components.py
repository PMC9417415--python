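"""Identify the decision-making component for each growth parameter.

Plants one determinant component per parameter, evaluates a
gradient-boosted-tree regressor under fivefold nested cross-validation,
and shows that the fold-averaged feature importances recover the planted
determinants.
"""

import ecogrowth as eg

design = eg.generate_design(n_components=10, levels_per_gradient=6,
                            n_backgrounds=4, seed=2)
model = eg.ResponseModel(determinant_map={"tau": "alanine", "rate": "glutamine",
                                          "capacity": "glycine"}, noise_sd=0.0)
truth = eg.ground_truth_parameters(design, model)
grid = {"learning_rate": [0.1, 0.3], "max_depth": [2, 3]}

for param, planted in model.determinant_map.items():
    features = eg.build_features(design, truth, param)
    ev = eg.nested_cv_evaluate(features, model="gbdt", grid=grid, seed=0,
                               n_estimators=100)
    profile = eg.gbdt_importance(features, grid=grid, seed=0, n_estimators=100)
    top = profile.mean.sort_values(ascending=False).head(2)
    print(f"{param:9s} planted={planted:10s} mean outer-fold "
          f"R2={ev.fold_metrics['r2'].mean():.3f}  "
          f"top importances: " + ", ".join(f"{c}={v:.2f}" for c, v in top.items()))
print("The planted determinant should carry nearly all importance; the "
      "R2 shows how well medium composition predicts the parameter.")
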