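"""Bi-peptide evolutionary feature extraction from PSSM profiles.

Each window profile (an L x 20 score matrix, L = 21 at the default window
size) is reduced to a fixed 210-element descriptor in three steps:

1. **Column standardization** — every amino-acid column is z-scored across
   the L positions using the population standard deviation (divide by L).
   Constant columns standardize to all zeros rather than NaN, which keeps
   degenerate inputs (e.g. all-padding fixtures) inside the fixed-length
   feature contract.
2. **Gram matrix** — ``G = M.T @ M`` of the standardized L x 20 matrix M, a
   symmetric positive semi-definite 20 x 20 matrix (400 elements) whose
   (a, b) entry measures co-occurrence of substitution propensity toward
   amino acids a and b across window positions.
3. **Triangular vectorization** — because G is symmetric only
   20 + 190 = 210 of its 400 entries are informative: the 20 diagonal
   entries first, then the 190 strict upper-triangle entries in row-major
   order.

The composition is deterministic and invariant to per-column affine maps of
the raw profile (a consequence of z-scoring).
"""

from __future__ import annotations

import numpy as np

from glutsite.pssm import Profile

#: Dimension of the bi-peptide evolutionary descriptor: 20 + 20*19/2.
N_FEATURES = 210

#: Column names used in feature CSVs: f001 .. f210.
FEATURE_NAMES = [f"f{u + 1:03d}" for u in range(N_FEATURES)]


def standardize_profile(profile: Profile | np.ndarray) -> np.ndarray:
    """Column-wise z-score of the score matrix with population SD.

    Columns with zero spread map to all-zero columns.
    """
    m = profile.scores if isinstance(profile, Profile) else np.asarray(profile, float)
    mean = m.mean(axis=0)
    sd = m.std(axis=0)  # population SD: divide by L
    centered = m - mean
    out = np.zeros_like(centered)
    nz = sd > 0
    out[:, nz] = centered[:, nz] / sd[nz]
    return out


def gram_matrix(m: np.ndarray) -> np.ndarray:
    """``M.T @ M`` of a standardized profile; symmetric and PSD by construction."""
    m = np.asarray(m, dtype=float)
    g = m.T @ m
    return (g + g.T) / 2.0  # exact symmetry despite float round-off


def vectorize_symmetric(g: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric d x d matrix to d + d(d-1)/2 values.

    Diagonal entries come first (column order), then the strict upper
    triangle in row-major order.  For d = 20 the result has 210 elements.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {g.shape}")
    asym = np.abs(g - g.T).max() if g.size else 0.0
    if asym > tol:
        raise ValueError(
            f"matrix is asymmetric (max |G - G.T| = {asym:g} > {tol:g}); "
            "upstream Gram computation is broken"
        )
    d = g.shape[0]
    iu = np.triu_indices(d, k=1)
    return np.concatenate([np.diag(g), g[iu]])


def unvectorize_symmetric(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_symmetric` (exact bijection)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    # n = d + d(d-1)/2  =>  d = (sqrt(8n + 1) - 1) / 2
    d = int(round((np.sqrt(8 * n + 1) - 1) / 2))
    if d + d * (d - 1) // 2 != n:
        raise ValueError(f"{n} values do not form a triangular vectorization")
    g = np.zeros((d, d))
    np.fill_diagonal(g, values[:d])
    iu = np.triu_indices(d, k=1)
    g[iu] = values[d:]
    g[(iu[1], iu[0])] = values[d:]
    return g


def extract_features(profile: Profile | np.ndarray) -> np.ndarray:
    """Full descriptor: standardize, Gram matrix, triangular vectorization.

    Returns a length-210 vector for a 20-column profile.
    """
    return vectorize_symmetric(gram_matrix(standardize_profile(profile)))
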