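"""Classical (Torgerson) multidimensional scaling of subject feature vectors.

Classical MDS double-centers the squared Euclidean distance matrix and
eigendecomposes it; for Euclidean input distances the coordinates coincide
with PCA scores of the centered feature matrix, which the tests exploit as an
independent oracle.  Variance fractions come from the positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CerebsigError


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray            # subjects x dims, centered at origin
    variance_fractions: np.ndarray     # per requested dim, of total positive variance
    correction_state: str = "uncorrected"

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


def embed_mds(features: np.ndarray, dims: int = 2,
              correction_state: str = "uncorrected") -> EmbeddingResult:
    """Classical MDS of a subjects-by-voxels matrix via double centering.

    Parameters
    ----------
    features : array, shape (n_subjects, n_features)
        One row per subject (masked voxel vector).
    dims : int
        Number of output dimensions; must be < n_subjects.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise CerebsigError("non-finite values in MDS input")
    n = X.shape[0]
    if n < 3:
        raise CerebsigError(f"MDS needs >= 3 subjects, got {n}")
    if not 1 <= dims < n:
        raise CerebsigError(f"dims must be in [1, {n - 1}], got {dims}")

    sq = (X ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(D2, 0.0, None, out=D2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)                       # symmetrize against roundoff
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    pos[pos < pos.max() * 1e-12] = 0.0        # kill roundoff-level dimensions
    total = pos.sum()
    coords = evecs[:, :dims] * np.sqrt(pos[:dims])
    fractions = pos[:dims] / total if total > 0 else np.zeros(dims)
    return EmbeddingResult(coords, fractions, correction_state)
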