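# Small end-to-end experiment: 4 synthetic subjects, two-class tagging,
# Hjorth mobility at tau = 1200 ms, all five model families.
synthetic:
  n_subjects: 4
  effect_size_hz: 2.0
schemes: [two_class]
parameters: [mobility]
taus_ms: [1200]
cv_schemes: [kfold5, loso]
model_families: [lda, logistic, knn, svm, random_forest]
importance: true
seed: 1
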