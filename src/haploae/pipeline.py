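"""End-to-end orchestration: filter -> blocks -> train -> embed -> evaluate.

``compress`` runs the full nonlinear pipeline on one panel; per block it
selects the standardized architecture from the internal-LD rule, trains
an autoencoder on the training samples only, emits embeddings for all
samples and scores reconstructions on the held-out samples.
``compare_methods`` additionally fits a matched-dimension PCA per block
and reports both methods side by side, including the block-size-weighted
chromosome reconstruction accuracy

    sum_i a_i * b_i / sum_i b_i

(a_i the SNP accuracy and b_i the width of block i), which equals pooled
per-variant accuracy.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autoencoder import (
    ArchitectureSpec,
    TrainRecipe,
    TrainedBlockModel,
    compression_ratio,
    encode,
    reconstruct,
    round_dosage,
    snp_accuracy,
    train_block,
)
from .genotype_io import GenotypeMatrix
from .ld_blocks import BlockConfig, Haploblock, average_pairwise_ld, find_blocks
from .model_selection import SelectionRule, select_architecture
from .pca_baseline import fit_pca, pca_reconstruct

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible configuration of a compression run.

    The train/test split is either explicit sample-id lists (mirroring a
    held-out stratum) or a seeded random ``test_frac``.  Test samples are
    never seen by any autoencoder fit or PCA basis.
    """

    seed: int = 0
    block_config: BlockConfig = field(default_factory=BlockConfig)
    selection_rule: SelectionRule = field(default_factory=SelectionRule)
    recipe: TrainRecipe = field(default_factory=TrainRecipe)
    test_frac: float = 0.2
    train_samples: Optional[list[str]] = None
    test_samples: Optional[list[str]] = None


@dataclass
class CompressionReport:
    """Per-block metric rows plus chromosome-level aggregates."""

    per_block: pd.DataFrame
    aggregates: dict


def chromosome_reconstruction_accuracy(block_accs: Sequence[float],
                                       block_sizes: Sequence[int]) -> float:
    """Block-size-weighted mean accuracy: sum a_i b_i / sum b_i."""
    a = np.asarray(block_accs, dtype=float)
    b = np.asarray(block_sizes, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need equal-length, non-empty accuracy and size vectors")
    if (b < 1).any():
        raise ValueError("block sizes must be >= 1")
    return float((a * b).sum() / b.sum())


def split_samples(g: GenotypeMatrix, run: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (train_mask, test_mask) over samples; disjoint and exhaustive."""
    n = g.n_samples
    if run.train_samples is not None or run.test_samples is not None:
        if run.train_samples is None or run.test_samples is None:
            raise ValueError("give both train_samples and test_samples, or neither")
        pos = {s: i for i, s in enumerate(g.sample_ids)}
        tr = np.zeros(n, dtype=bool)
        te = np.zeros(n, dtype=bool)
        tr[[pos[s] for s in run.train_samples]] = True
        te[[pos[s] for s in run.test_samples]] = True
        if (tr & te).any():
            raise ValueError("train and test sample lists overlap")
        return tr, te
    rng = np.random.default_rng(run.seed)
    perm = rng.permutation(n)
    n_test = int(round(run.test_frac * n))
    te = np.zeros(n, dtype=bool)
    te[perm[:n_test]] = True
    return ~te, te


def _metric_rows(block: Haploblock, method: str, bn: int, X_tr, X_te, rec_tr, rec_te,
                 phen_tr=None, phen_te=None) -> dict:
    acc_tr = snp_accuracy(rec_tr, X_tr)
    acc_te = snp_accuracy(rec_te, X_te)
    row = {
        "block_id": block.snp_ids[0] + ".." + block.snp_ids[-1],
        "chrom": block.chrom,
        "first_idx": block.first_idx,
        "size": block.size,
        "bn": bn,
        "avg_ld": block.avg_pairwise_ld,
        "method": method,
        "compression_ratio": compression_ratio(bn, block.size),
        "train_mse": float(np.mean((rec_tr - X_tr) ** 2)),
        "test_mse": float(np.mean((rec_te - X_te) ** 2)),
        "train_acc": acc_tr.overall,
        "test_acc": acc_te.overall,
    }
    for d in (0, 1, 2):
        row[f"train_acc_dosage{d}"] = acc_tr.by_dosage[d]
        row[f"test_acc_dosage{d}"] = acc_te.by_dosage[d]
    for name, X, rec, phen in (("train", X_tr, rec_tr, phen_tr),
                               ("test", X_te, rec_te, phen_te)):
        if phen is not None:
            for lab in np.unique(phen):
                mask = phen == lab
                row[f"{name}_acc_pheno{lab}"] = snp_accuracy(rec[mask], X[mask]).overall
    return row


def _aggregate(df: pd.DataFrame, method: str) -> dict:
    sub = df[df["method"] == method]
    return {
        "method": method,
        "n_blocks": int(len(sub)),
        "total_snps": int(sub["size"].sum()),
        "total_bottleneck": int(sub["bn"].sum()),
        "total_compression_ratio": float(sub["bn"].sum() / sub["size"].sum()),
        "chromosome_accuracy_train": chromosome_reconstruction_accuracy(
            sub["train_acc"], sub["size"]),
        "chromosome_accuracy_test": chromosome_reconstruction_accuracy(
            sub["test_acc"], sub["size"]),
        "mean_block_accuracy_train": float(sub["train_acc"].mean()),
        "mean_block_accuracy_test": float(sub["test_acc"].mean()),
        "std_block_accuracy_test": float(sub["test_acc"].std(ddof=1)) if len(sub) > 1 else 0.0,
        "mean_mse_train": float(sub["train_mse"].mean()),
        "mean_mse_test": float(sub["test_mse"].mean()),
    }


def compress(
    run: RunConfig,
    g: GenotypeMatrix,
    blocks: Optional[list[Haploblock]] = None,
    with_pca: bool = False,
) -> tuple[np.ndarray, list[TrainedBlockModel], CompressionReport]:
    """Full pipeline on a filtered single-chromosome panel.

    Blocks are discovered with the confidence-interval block finder
    unless supplied.  Returns (embeddings for all samples, trained
    models, report).  SNPs outside every block pass through uncompressed
    (ratio 1.0) and are appended to the embedding unchanged.
    """
    tr_mask, te_mask = split_samples(g, run)
    if not te_mask.any() or not tr_mask.any():
        raise ValueError("both train and test partitions must be non-empty")
    if blocks is None:
        blocks, singleton_idx = find_blocks(g, run.block_config)
    else:
        covered = set()
        for b in blocks:
            covered.update(range(b.first_idx, b.last_idx + 1))
        singleton_idx = [k for k in range(g.n_snps) if k not in covered]
    for b in blocks:
        if b.avg_pairwise_ld is None or np.isnan(b.avg_pairwise_ld):
            b.avg_pairwise_ld = average_pairwise_ld(g, b)

    phen = g.phenotype
    phen_tr = phen[tr_mask] if phen is not None else None
    phen_te = phen[te_mask] if phen is not None else None

    models: list[TrainedBlockModel] = []
    rows: list[dict] = []
    embed_cols: list[np.ndarray] = []
    column_map: dict[str, tuple[int, int]] = {}
    col_cursor = 0
    recipe = TrainRecipe(
        epochs=run.recipe.epochs, batch_size=run.recipe.batch_size,
        learning_rate=run.recipe.learning_rate, leaky_slope=run.recipe.leaky_slope,
        seed=run.seed,
    )
    for block in blocks:
        Xb = g.dosages[:, block.first_idx:block.last_idx + 1].astype(float)
        X_tr, X_te = Xb[tr_mask], Xb[te_mask]
        block_id = block.snp_ids[0] + ".." + block.snp_ids[-1]
        spec = select_architecture(block, run.selection_rule)
        if spec.bn >= block.size:
            # degenerate: compression impossible; pass block through
            logger.warning("block %s passes through uncompressed (width %d <= bn)",
                           block_id, block.size)
            embed_cols.append(Xb)
            column_map[block_id] = (col_cursor, col_cursor + block.size)
            col_cursor += block.size
            rows.append(_metric_rows(block, "AE", block.size, X_tr, X_te, X_tr, X_te,
                                     phen_tr, phen_te))
            continue
        try:
            # the held-out stratum is scored separately below, so the final
            # per-block fit uses every training sample (no inner val split)
            fitted = train_block(spec, X_tr, recipe=recipe,
                                 val_index=np.empty(0, dtype=np.intp),
                                 block_id=block_id)
        except Exception as exc:  # pragma: no cover - defensive pass-through
            logger.error("block %s failed training (%s); passed through", block_id, exc)
            embed_cols.append(Xb)
            column_map[block_id] = (col_cursor, col_cursor + block.size)
            col_cursor += block.size
            rows.append(_metric_rows(block, "AE", block.size, X_tr, X_te, X_tr, X_te,
                                     phen_tr, phen_te))
            continue
        models.append(fitted)
        embed_cols.append(encode(fitted, Xb))
        column_map[block_id] = (col_cursor, col_cursor + spec.bn)
        col_cursor += spec.bn
        rec_tr = reconstruct(fitted, X_tr)
        rec_te = reconstruct(fitted, X_te)
        rows.append(_metric_rows(block, "AE", spec.bn, X_tr, X_te, rec_tr, rec_te,
                                 phen_tr, phen_te))
        if with_pca:
            k = min(spec.bn, X_tr.shape[0] - 1, block.size)
            pca = fit_pca(X_tr, k, block_id=block_id)
            rows.append(_metric_rows(block, "PCA", k, X_tr, X_te,
                                     pca_reconstruct(pca, X_tr),
                                     pca_reconstruct(pca, X_te),
                                     phen_tr, phen_te))

    # pass-through singletons keep their raw dosages in the embedding
    for k in singleton_idx:
        embed_cols.append(g.dosages[:, k:k + 1].astype(float))
        column_map[g.variants[k].id] = (col_cursor, col_cursor + 1)
        col_cursor += 1

    embeddings = np.hstack(embed_cols) if embed_cols else np.empty((g.n_samples, 0))
    df = pd.DataFrame(rows)
    aggregates = {
        "seed": run.seed,
        "n_samples_train": int(tr_mask.sum()),
        "n_samples_test": int(te_mask.sum()),
        "n_singletons": len(singleton_idx),
        "embedding_width": int(embeddings.shape[1]),
        "column_map": column_map,
        "methods": {m: _aggregate(df, m) for m in df["method"].unique()} if len(df) else {},
    }
    return embeddings, models, CompressionReport(df, aggregates)


def compare_methods(run: RunConfig, g: GenotypeMatrix,
                    blocks: Optional[list[Haploblock]] = None,
                    ) -> tuple[np.ndarray, list[TrainedBlockModel], CompressionReport]:
    """``compress`` plus a matched-dimension PCA row for every block."""
    emb, models, report = compress(run, g, blocks=blocks, with_pca=True)
    df = report.per_block
    ae = df[df["method"] == "AE"].set_index("block_id")
    pca = df[df["method"] == "PCA"].set_index("block_id")
    common = ae.index.intersection(pca.index)
    report.aggregates["paired_test_acc_diff"] = (
        (ae.loc[common, "test_acc"] - pca.loc[common, "test_acc"]).tolist()
    )
    if "AE" in report.aggregates["methods"] and "PCA" in report.aggregates["methods"]:
        gap = (report.aggregates["methods"]["AE"]["chromosome_accuracy_test"]
               - report.aggregates["methods"]["PCA"]["chromosome_accuracy_test"])
        report.aggregates["chromosome_accuracy_gap_test"] = float(gap)
    report.aggregates["moving_average_curves"] = moving_average_curves(df)
    return emb, models, report


def moving_average_curves(df: pd.DataFrame, window: int = 50) -> dict:
    """Accuracy-vs-block-size moving averages (window in blocks) per method."""
    curves: dict[str, dict] = {}
    for method, sub in df.groupby("method"):
        s = sub.sort_values("size")
        curves[str(method)] = {
            "size": s["size"].tolist(),
            "train_acc": s["train_acc"].rolling(window, min_periods=1).mean().tolist(),
            "test_acc": s["test_acc"].rolling(window, min_periods=1).mean().tolist(),
        }
    return curves


def write_report(report: CompressionReport, out_dir: str | Path) -> tuple[Path, Path]:
    """TSV per-block table + JSON summary; numbers round-trippable."""
    if len(report.per_block) == 0:
        raise ValueError("empty report: no blocks to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "per_block.tsv"
    js = out_dir / "summary.json"
    report.per_block.to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(report.aggregates, indent=1, default=float))
    return tsv, js


def read_report(out_dir: str | Path) -> CompressionReport:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "per_block.tsv", sep="\t")
    aggregates = json.loads((out_dir / "summary.json").read_text())
    return CompressionReport(df, aggregates)
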