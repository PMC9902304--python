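"""Feature ranking, classifier comparison and the stacking ensemble.

Ranks the six measurements by random-forest impurity importance, evaluates a
random forest on the top-3 features under stratified 5-fold cross-validation
(Z-score normalization fitted per training split), and runs the stacking
ensemble (RF + extra-trees bases, gradient-boosting meta learner trained on
out-of-fold class probabilities).
"""

from patellasex import (
    crossval_evaluate, generate_cohort, pooled_spec, rank_features,
    stack_fit_evaluate,
)

table = generate_cohort(pooled_spec(seed=1))

ranking = rank_features(table, "random-forest-impurity", seed=1)
print("Importance ranking:", ranking.ordered_variables)
top3 = tuple(ranking.top(3))

res = crossval_evaluate(table, "random-forest", top3, k=5, seed=1)
a = res.metrics.accuracy
print(f"\nRandom forest on {top3}: accuracy {a.value:.2f} ± {a.ci_half_width:.2f}%"
      f" (95% CI), AUC {res.metrics.auc.value:.2f}%")
print(f"confusion: TP={res.confusion.tp} FN={res.confusion.fn} "
      f"TN={res.confusion.tn} FP={res.confusion.fp} (male = positive)")

stacked, model = stack_fit_evaluate(
    table, ("random-forest", "extra-trees"), "gradient-boosting", top3, seed=1
)
a = stacked.metrics.accuracy
print(f"\nStacking (RF+ET → GB): accuracy {a.value:.2f} ± {a.ci_half_width:.2f}%, "
      f"AUC {stacked.metrics.auc.value:.2f}%")
print(f"meta-feature matrix {model.meta_features.shape}: one out-of-fold "
      "class-probability pair per base learner and row")
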