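"""Hyperparameter protocol: CV grid search, elbow rule, LD-threshold rule.

The grid spans bn 1-10, hl 1-5 and both shapes (100 configurations),
evaluated per block under 5-fold cross-validation.  The elbow over bn is
formalized as the first bn whose marginal accuracy gain drops below a
threshold.  The standardized architecture is elliptic with hl = 4 and a
bottleneck of 2 when the block's average pairwise LD exceeds 0.4, else 3.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .autoencoder import ArchitectureSpec, TrainRecipe, train_block
from .ld_blocks import Haploblock

SHAPES = ("elliptic", "rectangular")


def default_grid() -> list[tuple[int, int, str]]:
    """(bn, hl, shape) cells: bn 1-10, hl 1-5, both shapes."""
    return [(bn, hl, shape)
            for bn, hl, shape in itertools.product(range(1, 11), range(1, 6), SHAPES)]


@dataclass(frozen=True)
class SelectionRule:
    """The standardized-architecture rule conditioned on internal LD."""

    ld_threshold: float = 0.4
    bn_high_ld: int = 2
    bn_low_ld: int = 3
    shape: str = "elliptic"
    hl: int = 4

    def __post_init__(self) -> None:
        if self.ld_threshold <= 0:
            raise ValueError("ld_threshold must be positive")
        if not self.bn_high_ld < self.bn_low_ld:
            raise ValueError("bn_high_ld must be smaller than bn_low_ld")


@dataclass
class ConfigResult:
    bn: int
    hl: int
    shape: str
    val_mse: float
    val_acc: float
    skipped: bool = False


@dataclass
class GridSearchResult:
    """Per-configuration CV metrics for one block, with best-per-bn picks."""

    block_id: str
    results: list[ConfigResult]

    def best_per_bn(self) -> dict[int, ConfigResult]:
        """Highest-accuracy cell for each bn; ties prefer smaller hl, then elliptic."""
        best: dict[int, ConfigResult] = {}
        for r in self.results:
            if r.skipped:
                continue
            cur = best.get(r.bn)
            if cur is None or _rank_key(r) > _rank_key(cur):
                best[r.bn] = r
        return best


def _rank_key(r: ConfigResult) -> tuple:
    # Higher is better: accuracy desc, then cheaper models (smaller hl,
    # elliptic before rectangular).
    return (r.val_acc, -r.hl, r.shape == "elliptic")


def grid_search_block(
    dosages: np.ndarray,
    folds: int = 5,
    grid: Optional[Sequence[tuple[int, int, str]]] = None,
    recipe: TrainRecipe = TrainRecipe(),
    seed: int = 0,
    block_id: str = "block",
) -> GridSearchResult:
    """Cross-validated grid search over (bn, hl, shape) for one block.

    Each configuration trains on ``folds - 1`` folds and is evaluated on
    the held-out fold; metrics are means over folds.  Cells with
    bn > block width are skipped and flagged.
    """
    X = np.asarray(dosages, dtype=float)
    n, width = X.shape
    if n < folds:
        raise ValueError(f"block has {n} samples, fewer than {folds} folds")
    grid = list(grid) if grid is not None else default_grid()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    fold_indices = [val for _, val in kf.split(X)]

    results = []
    for bn, hl, shape in grid:
        if bn > width:
            results.append(ConfigResult(bn, hl, shape, float("nan"), float("nan"),
                                        skipped=True))
            continue
        spec = ArchitectureSpec(input_dim=width, hl=hl, bn=bn, shape=shape)
        mses, accs = [], []
        for k, val_idx in enumerate(fold_indices):
            fit = train_block(spec, X, recipe=recipe, val_index=val_idx,
                              block_id=f"{block_id}:bn{bn}:hl{hl}:{shape}:fold{k}")
            mses.append(fit.val_mse)
            accs.append(fit.val_acc)
        results.append(ConfigResult(bn, hl, shape, float(np.mean(mses)),
                                    float(np.mean(accs))))
    return GridSearchResult(block_id, results)


def elbow_point(acc_by_bn: Sequence[float], min_gain: float = 0.002) -> int:
    """Smallest bn whose next marginal accuracy gain falls below ``min_gain``.

    ``acc_by_bn[k]`` is the accuracy at bn = k + 1.  If every gain stays
    at or above the threshold, the last bn is returned.
    """
    acc = list(acc_by_bn)
    if len(acc) < 2:
        raise ValueError("need accuracies for at least two bottleneck sizes")
    if max(acc) < 0.9:
        warnings.warn(f"maximum accuracy {max(acc):.3f} < 0.9; elbow may be unreliable")
    for k in range(len(acc) - 1):
        if acc[k + 1] - acc[k] < min_gain:
            return k + 1
    return len(acc)


def select_architecture(block: Haploblock, rule: SelectionRule = SelectionRule()
                        ) -> ArchitectureSpec:
    """Standardized spec for a block: elliptic, hl=4, bn by the LD rule.

    bn = 2 when the block's average pairwise LD is strictly above the
    threshold (default 0.4), else 3.  Raises for singleton blocks, which
    are pass-through candidates with no autoencoder.
    """
    if block.size < 2:
        raise ValueError(f"singleton block at {block.first_idx}: pass-through, no autoencoder")
    ld = block.avg_pairwise_ld
    if ld is None or np.isnan(ld):
        raise ValueError("block.avg_pairwise_ld must be computed before selection")
    bn = rule.bn_high_ld if ld > rule.ld_threshold else rule.bn_low_ld
    bn = min(bn, block.size)  # degenerate tiny blocks cannot exceed their width
    return ArchitectureSpec(input_dim=block.size, hl=rule.hl, bn=bn, shape=rule.shape)


def paired_one_tailed_ttest(acc_a: Sequence[float], acc_b: Sequence[float],
                            alpha: float = 0.05) -> tuple[float, float, bool]:
    """Paired one-tailed t-test of mean(a - b) > 0.

    Returns (t, p, significant).  Zero-variance differences are
    degenerate: flagged not significant by convention (t = 0 or nan).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero variance in paired differences; test degenerate")
        return (0.0 if np.allclose(diffs, 0) else float("nan"), float("nan"), False)
    t, p = stats.ttest_rel(a, b, alternative="greater")
    return float(t), float(p), bool(p < alpha)
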