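"""Classical MDS of scan connectomes and the data-driven drug dimension.

Each scan contributes the linearized upper triangle of its FC matrix; the
scan × scan RMS distance matrix is embedded with classical (Torgerson)
multidimensional scaling.  Multiplying the per-scan dimension scores back
into the centered FC vectors yields per-dimension edge-weight matrices
("eigenweights"); projecting a new scan's centered FC vector onto those
weights recovers its score on the learned dimension, which is how the drug
dimension transfers to held-out scans or external datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MDSEmbedding",
    "fc_vectors",
    "classical_mds",
    "dimension_eigenweights",
    "project_scans",
    "orient_to_condition",
    "top_weight_edges",
    "dimension_threshold_accuracy",
]


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray          # (n_scans, k)
    eigenvalues: np.ndarray          # (k,) positive, descending
    negative_mass: float             # |sum of truncated negative eigenvalues|
    labels: object = None            # optional per-scan metadata (DataFrame)
    mean_vector: np.ndarray | None = None     # centering record for FC vectors
    eigenweights: np.ndarray | None = None    # (k, E) per-dimension edge weights
    n_edges: int | None = None

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def fc_vectors(fcs: list) -> np.ndarray:
    """Stack linearized upper triangles of FC matrices into (n_scans, E)."""
    mats = [f.values if hasattr(f, "values") else np.asarray(f) for f in fcs]
    n = mats[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return np.array([m[iu] for m in mats])


def classical_mds(dist, k: int | None = None, labels=None) -> MDSEmbedding:
    """Torgerson classical MDS of a symmetric zero-diagonal distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix
    and returns eigenvector coordinates scaled by √eigenvalue.  Negative
    eigenvalues (non-Euclidean residual) are truncated and their mass
    reported.
    """
    D = dist.values if hasattr(dist, "values") else np.asarray(dist, float)
    if hasattr(dist, "labels") and labels is None:
        labels = dist.labels
    if isinstance(D, np.ndarray) and hasattr(D, "columns"):
        D = np.asarray(D)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigval[0]), 1.0))
    positive = eigval > tol
    n_pos = int(positive.sum())
    if k is None:
        k = n_pos
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    if k > n_pos:
        raise ValueError(
            f"k={k} exceeds the number of positive eigenvalues ({n_pos})"
        )
    neg_mass = float(-eigval[eigval < -tol].sum())
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(lam)
    return MDSEmbedding(
        coordinates=coords,
        eigenvalues=lam,
        negative_mass=neg_mass,
        labels=labels,
    )


def dimension_eigenweights(
    embedding: MDSEmbedding, vectors: np.ndarray
) -> np.ndarray:
    """Per-dimension edge-weight vectors from coordinates × centered FC.

    ``vectors`` is the (n_scans, E) FC-vector matrix the embedding was built
    from (same scan order).  The scan-mean vector is stored on the embedding
    as the centering record; weight vector d is Σ_scans coord[scan, d] ·
    centered vector[scan].  Returns (k, E) and caches it on the embedding.
    """
    V = np.asarray(vectors, float)
    if V.shape[0] != embedding.coordinates.shape[0]:
        raise ValueError("scan count mismatch between embedding and vectors")
    mean = V.mean(axis=0)
    centered = V - mean
    W = embedding.coordinates.T @ centered
    embedding.mean_vector = mean
    embedding.eigenweights = W
    embedding.n_edges = V.shape[1]
    return W


def weight_matrix(embedding: MDSEmbedding, dim: int, n_parcels: int) -> np.ndarray:
    """Reshape one dimension's edge-weight vector to a symmetric matrix."""
    if embedding.eigenweights is None:
        raise ValueError("compute dimension_eigenweights first")
    iu = np.triu_indices(n_parcels, k=1)
    M = np.zeros((n_parcels, n_parcels))
    M[iu] = embedding.eigenweights[dim]
    return M + M.T


def project_scans(
    embedding: MDSEmbedding, new_vectors: np.ndarray, dims=None
) -> np.ndarray:
    """Score new scans on learned dimensions via the eigenweights.

    score(scan, d) = (v − mean)·w_d / (E·λ_d); with this scale a training
    scan's projection reproduces its own MDS coordinate exactly on
    full-rank data.
    """
    if embedding.eigenweights is None or embedding.mean_vector is None:
        raise ValueError("embedding carries no eigenweights/centering record")
    V = np.atleast_2d(np.asarray(new_vectors, float))
    if V.shape[1] != embedding.n_edges:
        raise ValueError(
            f"edge count mismatch: got {V.shape[1]}, trained on "
            f"{embedding.n_edges}"
        )
    if dims is None:
        dims = range(embedding.k)
    dims = list(dims)
    centered = V - embedding.mean_vector
    scale = embedding.n_edges * embedding.eigenvalues[dims]
    return centered @ embedding.eigenweights[dims].T / scale


def orient_to_condition(
    embedding: MDSEmbedding,
    conditions: np.ndarray,
    positive_condition: str = "psilocybin",
) -> MDSEmbedding:
    """Fix dimension signs so the given condition's mean score is positive.

    Purely presentational, but required for cross-dataset comparability of
    dimension scores.
    """
    conditions = np.asarray(conditions)
    mask = conditions == positive_condition
    if not mask.any():
        return embedding
    flips = np.where(embedding.coordinates[mask].mean(axis=0) < 0, -1.0, 1.0)
    embedding.coordinates = embedding.coordinates * flips
    if embedding.eigenweights is not None:
        embedding.eigenweights = embedding.eigenweights * flips[:, None]
    return embedding


def top_weight_edges(
    embedding: MDSEmbedding, dim: int, n_parcels: int, percentile: float = 99.0
) -> np.ndarray:
    """Edges whose |weight| exceeds the given percentile, as (i, j, w) rows."""
    if embedding.eigenweights is None:
        raise ValueError("compute dimension_eigenweights first")
    w = embedding.eigenweights[dim]
    thresh = np.percentile(np.abs(w), percentile)
    iu = np.triu_indices(n_parcels, k=1)
    keep = np.abs(w) >= thresh
    return np.column_stack([iu[0][keep], iu[1][keep], w[keep]])


def dimension_threshold_accuracy(
    scores: np.ndarray, is_positive: np.ndarray
) -> float:
    """Best in-sample balanced accuracy of a threshold on 1-D scores."""
    scores = np.asarray(scores, float)
    pos = np.asarray(is_positive, bool)
    if pos.all() or (~pos).any() is False:
        raise ValueError("need both classes")
    cuts = np.unique(scores)
    best = 0.0
    for c in np.concatenate([cuts - 1e-12, cuts + 1e-12]):
        pred = scores > c
        tpr = (pred & pos).sum() / pos.sum()
        tnr = (~pred & ~pos).sum() / (~pos).sum()
        best = max(best, (tpr + tnr) / 2)
    return float(best)
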