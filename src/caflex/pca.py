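"""Principal component analysis of Cartesian C-alpha coordinates.

The same machinery serves a superposed structure ensemble (each
structure is one sample) and a superposed trajectory (each frame is one
sample).  The covariance is the population covariance of the flattened
3n-dimensional coordinate vectors,

    C_ij = < (r_i - <r_i>) . (r_j - <r_j>) >,

about the sample mean with 1/S normalization; its eigenvectors are the
principal components and the eigenvalue fractions measure how much of
the total positional variance each component explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh

from .errors import ParameterError, SampleError


@dataclass
class CovarianceMatrix:
    """3n x 3n coordinate covariance (A^2) about the sample mean."""

    matrix: np.ndarray
    mean_coords: np.ndarray  # (n, 3)
    sample_count: int

    def __post_init__(self):
        asym = np.abs(self.matrix - self.matrix.T).max()
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if asym > 1e-9 * scale:
            raise ParameterError("covariance matrix is not symmetric")

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class PCResult:
    """Eigendecomposition of a coordinate covariance.

    Eigenvalues are sorted descending; ``variance_fractions`` sum to 1
    over the full spectrum; ``projections`` are the centered samples
    projected onto the eigenvectors (Angstrom).
    """

    eigenvalues: np.ndarray  # (K,), descending, A^2
    eigenvectors: np.ndarray  # (3n, K), orthonormal columns
    variance_fractions: np.ndarray
    cumulative_fractions: np.ndarray
    projections: np.ndarray | None = None  # (S, K)

    def summary(self, n_components: int = 10) -> str:
        k = min(n_components, len(self.eigenvalues))
        lines = [
            "Principal component analysis of C-alpha coordinates",
            f"  samples: {0 if self.projections is None else len(self.projections)}"
            f"    components: {len(self.eigenvalues)}",
            f"  total variance (trace): {self.eigenvalues.sum():.4f} A^2",
            "",
            f"  {'PC':>4} {'eigenvalue (A^2)':>18} {'fraction':>10} {'cumulative':>11}",
        ]
        for i in range(k):
            lines.append(
                f"  {i + 1:>4} {self.eigenvalues[i]:>18.6f} "
                f"{self.variance_fractions[i]:>10.4f} "
                f"{self.cumulative_fractions[i]:>11.4f}"
            )
        return "\n".join(lines)


def build_covariance(
    samples: np.ndarray, atom_mask: np.ndarray | None = None
) -> CovarianceMatrix:
    """Population covariance of coordinate samples.

    Parameters
    ----------
    samples : ndarray, shape (S, n, 3)
        Superposed coordinate samples (superposition is the caller's
        responsibility — fit the ensemble/trajectory first).
    atom_mask : bool ndarray, shape (n,), optional
        Atoms to include; others are excluded from the covariance.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[2] != 3:
        raise ParameterError(f"samples must be (S, n, 3), got {samples.shape}")
    if atom_mask is not None:
        samples = samples[:, np.asarray(atom_mask, dtype=bool), :]
    S = samples.shape[0]
    if S < 2:
        raise SampleError(f"need >= 2 samples for a covariance, got {S}")
    mean = samples.mean(axis=0)
    X = (samples - mean).reshape(S, -1)
    C = X.T @ X / S
    return CovarianceMatrix(matrix=(C + C.T) / 2, mean_coords=mean, sample_count=S)


def pca(cov: CovarianceMatrix, samples: np.ndarray | None = None) -> PCResult:
    """Diagonalize a coordinate covariance.

    The sign of each eigenvector is fixed so that its largest-magnitude
    component is positive, making projections reproducible.  If
    ``samples`` is given (same atoms as the covariance), the centered
    samples are projected onto the eigenvectors.
    """
    if not np.isfinite(cov.matrix).all():
        raise ParameterError("covariance contains non-finite entries")
    w, V = eigh(cov.matrix)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    proj = None
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        X = (samples - cov.mean_coords).reshape(samples.shape[0], -1)
        proj = X @ V
    return PCResult(
        eigenvalues=w,
        eigenvectors=V,
        variance_fractions=fractions,
        cumulative_fractions=np.cumsum(fractions),
        projections=proj,
    )


class CoordinatePCA:
    """Model-style front end: ``CoordinatePCA(samples).fit()``.

    ``samples`` are superposed coordinates of shape (S, n, 3); the
    returned :class:`PCResult` carries eigenvalues, variance fractions
    and per-sample projections, and prints a ``summary()`` table.
    """

    def __init__(self, samples: np.ndarray, atom_mask: np.ndarray | None = None):
        self.samples = np.asarray(samples, dtype=float)
        self.atom_mask = atom_mask

    def fit(self) -> PCResult:
        cov = build_covariance(self.samples, self.atom_mask)
        samples = self.samples
        if self.atom_mask is not None:
            samples = samples[:, np.asarray(self.atom_mask, dtype=bool), :]
        return pca(cov, samples)


def cluster_pc_space(pcr: PCResult, k: int, dims: int = 3) -> np.ndarray:
    """Hierarchical clustering of samples in PC space.

    Complete-linkage agglomerative clustering (Euclidean) on the first
    ``dims`` projections, cut at ``k`` clusters.  Labels are integers
    starting at 1, renumbered by order of first appearance, so the
    output is deterministic.
    """
    if pcr.projections is None:
        raise ParameterError("PCResult has no projections to cluster")
    S = len(pcr.projections)
    if not 1 <= k <= S:
        raise ParameterError(f"k must be in [1, {S}], got {k}")
    X = pcr.projections[:, : min(dims, pcr.projections.shape[1])]
    if k == 1:
        return np.ones(S, dtype=int)
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    seen: dict[int, int] = {}
    out = np.empty(S, dtype=int)
    for i, lab in enumerate(raw):
        out[i] = seen.setdefault(int(lab), len(seen) + 1)
    return out
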