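# Hyperparameter grids for the ligand-only baseline regressors.
# Deliberately small: the baselines exist to expose decoy-set bias, not to be
# state-of-the-art QSAR. Families marked "scale" are fit on standardized
# features inside a pipeline.
lasso:
  scale: true
  grid:
    model__alpha: [0.001, 0.01, 0.1, 1.0]
knn:
  scale: true
  grid:
    model__n_neighbors: [1, 5, 15]
    model__weights: [uniform, distance]
decision_tree:
  scale: false
  grid:
    model__max_depth: [3, 5, 10, null]
    model__min_samples_leaf: [1, 5]
random_forest:
  scale: false
  grid:
    model__n_estimators: [100]
    model__max_features: [sqrt, 1.0]
    model__max_depth: [null, 10]
gradient_boosting:
  scale: false
  grid:
    model__n_estimators: [100]
    model__learning_rate: [0.05, 0.1]
    model__max_depth: [3]
svr:
  scale: true
  grid:
    model__C: [0.1, 1.0, 10.0]
    model__gamma: [scale]
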