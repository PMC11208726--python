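"""Hyperparameter protocol in miniature: CV grid search and the elbow.

Runs a reduced (bn, hl, shape) grid with 5-fold cross-validation on one
block, reads off the best accuracy per bottleneck size, and applies the
marginal-gain elbow rule that balances compression against accuracy.
"""

from haploae import BlockSimConfig, TrainRecipe, elbow_point, grid_search_block, simulate_block

X, _ = simulate_block(BlockSimConfig(n_snps=12, n_founders=4), 800, seed=2)

grid = [(bn, hl, shape)
        for bn in (1, 2, 3, 4)
        for hl in (1, 4)
        for shape in ("elliptic",)]
result = grid_search_block(X, folds=5, grid=grid,
                           recipe=TrainRecipe(epochs=250, seed=2), seed=2)

best = result.best_per_bn()
acc_by_bn = [best[bn].val_acc for bn in sorted(best)]
for bn in sorted(best):
    r = best[bn]
    print(f"bn={bn}: best CV accuracy {r.val_acc:.2%} (hl={r.hl}, {r.shape})")

elbow = elbow_point(acc_by_bn, min_gain=0.002)
print(f"elbow at bn={elbow}: widening the bottleneck past this point "
      "gains < 0.002 accuracy per extra dimension")
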