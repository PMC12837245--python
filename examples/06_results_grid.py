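"""Populate a small extractor x selector x classifier accuracy grid.

Mirrors the one-table-per-selector presentation: rows are extractors,
columns are (selector, classifier) pairs.
"""
from bcghyper import SynthCohortConfig, best_cell, generate_bcg_cohort, results_grid

records = generate_bcg_cohort(
    SynthCohortConfig(n_normal=15, n_hyper=15, duration=60.0, seed=3)
)
grid, _ = results_grid(
    records,
    extractors=["modwt", "kpca"],
    selectors=["ig", "btsa"],
    classifiers=["adaboost_mulda", "tw_hasvm"],
    seed=0, folds=5, window_seconds=60.0,
    selector_params={"pop": 10, "generations": 10},
    classifier_params={"T": 10},
)
print(grid.round(2).to_string())
triple, acc = best_cell(grid)
print(f"\nbest cell: {' + '.join(triple)} at {acc:.2f}%")
# Every cell is a mean 5-fold subject-level CV accuracy; a failed cell
# would appear as NaN without aborting the rest of the grid.
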