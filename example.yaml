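synthetic:
  n_molecules: 90
  n_features: 120
  n_constant: 20
  n_informative: 4
  n_redundant: 6
  positive_fraction: 0.30
  label_noise: 0.0
  seed: 2
  positive_class_name: lengthener
  negative_class_name: no-changer
families: [decision_tree, gradient_boosting]
k_min: 2
k_max: 8
cv_reps: 5
tune: true
tune_reps: 1
grid_overrides:
  decision_tree: {max_depth: [3, null]}
  gradient_boosting: {max_depth: [3], n_estimators: [30], learning_rate: [0.1]}
prune_extra_steps: 1
final_reps: 50
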