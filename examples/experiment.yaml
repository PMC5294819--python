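# Full experiment: synthetic cohort -> features -> three validation
# protocols for each listed classifier.  Run with
#   accelhar run --config examples/experiment.yaml --out results/
synthetic:
  n_subjects: 13
  clips_per_activity_lab: 15     # 13 x 6 x 15 = 1170 lab clips
  clips_per_activity_home: 14
  total_clips_home: 1089         # spread evenly over (subject, activity)
  seed: 0

classifiers:
  - svm                          # C=10, gamma=1, z-normalised features
  - naive_bayes
  - logistic_regression          # L1, lambda=0.01
  - knn                          # k=5
  - decision_tree                # min_split=10

folds: 10
ci_method: clopper_pearson
seed: 0
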