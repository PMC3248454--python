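"""Classical multidimensional scaling of IBS distance matrices.

Torgerson's method: double-center the squared distance matrix,
eigendecompose, and scale the top eigenvectors by the square root of
their eigenvalues.  Used to visualise population structure and to
compare structure with and without close relatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = ["MdsResult", "classical_mds", "mds_table"]


@dataclass
class MdsResult:
    """Embedding coordinates (samples x k) and the top-k eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


def classical_mds(D: np.ndarray, k: int = 2) -> MdsResult:
    """Embed a symmetric zero-diagonal distance matrix in ``k`` dimensions.

    B = -1/2 J (D o D) J with J the centering matrix; coordinates are the
    top-k eigenvectors scaled by sqrt(eigenvalue), eigenvalues returned
    in descending order.  A negative eigenvalue among the top k (the
    distances are then not Euclidean in that direction) zeroes the
    corresponding coordinate with a warning.  The sign of each axis is
    fixed by making its largest-magnitude loading positive.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.shape[0]
    k = min(k, n)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    vals, vecs = scipy.linalg.eigh(B, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    coords = np.zeros((n, k))
    for a in range(k):
        if vals[a] > 0:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
        elif vals[a] < 0:
            warnings.warn(
                f"MDS axis {a + 1} has negative eigenvalue {vals[a]:.3g}; "
                "coordinate set to 0"
            )
        sign_ref = coords[np.argmax(np.abs(coords[:, a])), a]
        if sign_ref < 0:
            coords[:, a] = -coords[:, a]
    return MdsResult(coordinates=coords, eigenvalues=vals)


def mds_table(sample_ids, result: MdsResult) -> pd.DataFrame:
    """Tabulate coordinates as sample_id, C1..Ck."""
    k = result.coordinates.shape[1]
    df = pd.DataFrame({"sample_id": list(sample_ids)})
    for a in range(k):
        df[f"C{a + 1}"] = result.coordinates[:, a]
    return df
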