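"""Matched-dimension PCA baseline for per-block reconstruction.

For every block the linear baseline fits PCA on the training samples at
latent dimension k equal to the autoencoder's bottleneck, reconstructs
from the leading components, and is scored with the same MSE and SNP
accuracy operations as the autoencoder.  Reconstructions are clipped to
[0, 2] before rounding (toggleable) so both methods share the accuracy
operation's domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class PCABlockModel:
    """Top-k principal directions and the training-sample center of a block."""

    block_id: str
    k: int
    component_basis: np.ndarray  # (k, n_snps), orthonormal rows
    center: np.ndarray           # per-SNP training means


def fit_pca(train_dosages: np.ndarray, k: int, block_id: str = "block") -> PCABlockModel:
    """Principal directions of the centered training block."""
    X = np.asarray(train_dosages, dtype=float)
    n, width = X.shape
    if not (1 <= k <= min(n - 1, width)):
        raise ValueError(f"k={k} out of range for {n} samples x {width} SNPs")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCABlockModel(block_id, k, pca.components_.copy(), pca.mean_.copy())


def pca_reconstruct(m: PCABlockModel, dosages: np.ndarray, clip: bool = True) -> np.ndarray:
    """Project onto the basis, back-project and re-center.

    Test samples are centered with the *training* means.  With ``clip``
    the output is limited to [0, 2], the dosage range.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] != m.center.shape[0]:
        raise ValueError(
            f"block {m.block_id}: expected {m.center.shape[0]} columns, got {X.shape[1]}"
        )
    scores = (X - m.center) @ m.component_basis.T
    rec = scores @ m.component_basis + m.center
    return np.clip(rec, 0.0, 2.0) if clip else rec
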