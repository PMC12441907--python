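# Default hyperparameter grids for grid_search, one block per classifier
# family. Values are deliberately modest so a 10-fold search stays cheap;
# widen them for production sweeps.
logistic_regression:
  C: [0.1, 1.0, 10.0]
  penalty: ["l2"]
  solver: ["saga"]
svm:
  C: [0.1, 1.0, 10.0]
  kernel: ["linear", "rbf"]
decision_tree:
  max_depth: [3, 6, 12, null]
  min_samples_leaf: [1, 5]
knn:
  n_neighbors: [3, 5, 11]
  p: [1, 2]          # Manhattan and Euclidean metrics
random_forest:
  n_estimators: [100, 300]
  max_depth: [6, 12, null]
extra_trees:
  n_estimators: [100, 300]
  max_depth: [6, 12, null]
adaboost:
  n_estimators: [50, 200]
  learning_rate: [0.05, 0.5]
gradient_boosting:
  n_estimators: [100, 200]
  learning_rate: [0.05, 0.1]
bagging:
  n_estimators: [10, 50]
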