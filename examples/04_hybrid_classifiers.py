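"""Train the four hybrid boosted classifiers on a labeled table.

AdaBoost-MULDA boosts a regularized-LDA + 10-NN weak learner;
AdaBoost-RF boosts small random forests; ARIMA-AdaBoost boosts depth-1
regression trees on 0/1 targets; TW-HASVM boosts polynomial-kernel SVMs
with an exponential batch-age weight (a no-op for a single batch).
"""
from bcghyper import SynthTableConfig, generate_feature_table
from bcghyper.classify import (
    arima_adaboost_fit,
    hybrid_adaboost_mulda,
    hybrid_adaboost_rf,
    tw_hasvm_fit,
)

table = generate_feature_table(SynthTableConfig(seed=4))
X, y = table.values, table.labels

mulda = hybrid_adaboost_mulda(table, T=10, seed=0)
rf = hybrid_adaboost_rf(table, T=10, n_trees=10, seed=0)
arima = arima_adaboost_fit(X, y, T=20, seed=0)
twsvm = tw_hasvm_fit(table, eta=0.25, batch_index=1, T=10, seed=0)

for name, model in [("AdaBoost-MULDA", mulda), ("AdaBoost-RF", rf),
                    ("ARIMA-AdaBoost", arima), ("TW-HASVM", twsvm)]:
    acc = 100.0 * float((model.predict(X) == y).mean())
    print(f"{name:15s} training accuracy: {acc:6.2f}%")
# Training accuracy near 100% is expected for boosted ensembles on a
# separable table; generalization is what the cross-validation example
# measures.
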