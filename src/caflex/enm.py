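"""C-alpha elastic-network normal-mode analysis (single and ensemble).

The protein is reduced to its C-alpha beads joined by harmonic springs
(an anisotropic network model).  The 3n x 3n Hessian has, for every
spring (i, j), the off-diagonal block -k(d_ij) * u u^T with u the unit
inter-bead vector, and diagonal blocks that cancel the row sums, so
rigid translations cost nothing by construction.  Its six lowest modes
are the rigid-body motions; the remaining modes give relative
per-residue mean-square fluctuations

    f_i = sum_m |v_m,i|^2 / lambda_m,

the harmonic-ensemble amplitude of residue i summed over internal
modes.  Masses are uniform and k is unitless, so the profile scale is
relative; the ensemble variant normalizes each structure's profile to
mean 1 over shared columns before forming the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .alignment import AlignedEnsemble
from .errors import DisconnectedNetworkError, GeometryError, ParameterError
from .structure_io import CalphaModel

#: Default ANM cutoff in Angstrom.
DEFAULT_CUTOFF = 15.0
#: Pairs closer than this (A) indicate corrupt geometry.
MIN_PAIR_DISTANCE = 0.01
#: Eigenvalues below this fraction of the largest count as trivial.
#: Numerical zeros sit near 1e-14 relative; genuinely soft hinge modes
#: of floppy structures can reach 1e-6 relative, so the bound is tight.
TRIVIAL_TOL = 1e-8


def hinsen_force_constant(d: np.ndarray) -> np.ndarray:
    """Distance-dependent spring constant, Hinsen-style pair decay.

    ``d`` in Angstrom.  Short (bonded-range, < 4 A) pairs follow a
    linear law, longer pairs an r^-6 decay; the two branches meet the
    standard calpha parameterization (units arbitrary — the package
    treats fluctuation scales as relative).
    """
    r = np.asarray(d, dtype=float) / 10.0  # nm
    with np.errstate(divide="ignore"):
        return np.where(r < 0.4, 8.6e5 * r - 2.39e5, 128e-4 / r**6)


def build_hessian(
    model: CalphaModel | np.ndarray,
    force_field: str = "anm",
    cutoff: float = DEFAULT_CUTOFF,
    k: float = 1.0,
) -> np.ndarray:
    """Build the 3n x 3n elastic-network Hessian for a C-alpha trace.

    ``force_field`` is ``"anm"`` (uniform spring k within ``cutoff``)
    or ``"calpha"`` (Hinsen distance-decay, all pairs; ``k`` rescales).
    """
    coords = model.coords if isinstance(model, CalphaModel) else np.asarray(model, float)
    n = len(coords)
    if n < 2:
        raise GeometryError(f"need >= 2 beads, got {n}")
    if k <= 0:
        raise ParameterError(f"spring constant must be positive, got {k}")
    dist = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if (dist[off] < MIN_PAIR_DISTANCE).any():
        i, j = np.argwhere(off & (dist < MIN_PAIR_DISTANCE))[0]
        raise GeometryError(f"coincident C-alpha pair ({i}, {j}), d < {MIN_PAIR_DISTANCE} A")
    if force_field == "anm":
        kmat = np.where(dist <= cutoff, k, 0.0)
    elif force_field == "calpha":
        kmat = k * hinsen_force_constant(dist)
    else:
        raise ParameterError(f"unknown force field {force_field!r}")
    np.fill_diagonal(kmat, 0.0)

    diff = coords[:, None, :] - coords[None, :, :]  # (n, n, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = diff / dist[:, :, None]
    u[np.arange(n), np.arange(n)] = 0.0
    # off-diagonal 3x3 blocks: -k * u u^T
    blocks = -kmat[:, :, None, None] * u[:, :, :, None] * u[:, :, None, :]
    # diagonal blocks cancel the row sums (translational invariance)
    blocks[np.arange(n), np.arange(n)] = -blocks.sum(axis=1)
    H = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return (H + H.T) / 2


def _network_components(hessian: np.ndarray) -> int:
    n = hessian.shape[0] // 3
    blocks = np.abs(hessian.reshape(n, 3, n, 3)).sum(axis=(1, 3))
    np.fill_diagonal(blocks, 0.0)
    n_comp, _ = connected_components(csr_matrix(blocks > 0), directed=False)
    return n_comp


@dataclass
class NormalModeResult:
    """Modes of an elastic-network Hessian.

    Eigenvalues ascend; the first ``n_trivial`` (six for a connected,
    non-degenerate network) are rigid-body modes.  ``fluctuations`` are
    the per-residue internal-mode amplitudes (relative scale).
    """

    eigenvalues: np.ndarray  # (3n,), ascending
    eigenvectors: np.ndarray  # (3n, 3n)
    n_trivial: int
    fluctuations: np.ndarray  # (n,)

    @property
    def n_residues(self) -> int:
        return len(self.fluctuations)

    def summary(self, n_modes: int = 10) -> str:
        nz = self.eigenvalues[self.n_trivial:]
        lines = [
            "Elastic-network normal modes",
            f"  residues: {self.n_residues}    trivial modes: {self.n_trivial}",
            f"  lowest internal eigenvalue: {nz[0]:.6g}",
            f"  fluctuation range: {self.fluctuations.min():.4g} .. "
            f"{self.fluctuations.max():.4g} (relative)",
            "",
            f"  {'mode':>5} {'eigenvalue':>14}",
        ]
        for i in range(min(n_modes, len(nz))):
            lines.append(f"  {i + 7:>5} {nz[i]:>14.6g}")
        return "\n".join(lines)


def normal_modes(hessian: np.ndarray) -> NormalModeResult:
    """Diagonalize a Hessian and derive per-residue fluctuations.

    Raises :class:`DisconnectedNetworkError` when more than six
    near-zero modes appear (disconnected network or collinear beads).
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ParameterError("hessian must be square")
    if np.abs(hessian - hessian.T).max() > 1e-8 * max(np.abs(hessian).max(), 1.0):
        raise ParameterError("hessian must be symmetric")
    n = hessian.shape[0] // 3
    w, V = eigh(hessian)
    wmax = max(w[-1], 0.0)
    trivial = int(np.sum(w < TRIVIAL_TOL * wmax)) if wmax > 0 else len(w)
    if trivial != 6:
        n_comp = _network_components(hessian)
        raise DisconnectedNetworkError(
            f"{trivial} near-zero modes (expected 6): the spring network "
            f"has {n_comp} connected component(s)"
            + ("" if n_comp > 1 else " — geometry may be degenerate (collinear)"),
            n_components=n_comp,
        )
    inv_w = 1.0 / w[6:]
    fluct = (V[:, 6:] ** 2 * inv_w).sum(axis=1).reshape(n, 3).sum(axis=1)
    return NormalModeResult(w, V, 6, fluct)


class ElasticNetworkModel:
    """Model-style front end: ``ElasticNetworkModel(model).fit()``.

    Parameters
    ----------
    model : CalphaModel or (n, 3) array
        C-alpha trace.
    force_field : {"anm", "calpha"}
        Uniform-spring cutoff network (default, cutoff 15 A, k = 1) or
        Hinsen-style distance-decay springs.
    cutoff, k : float
        ANM cutoff (A) and spring-constant scale.
    """

    def __init__(
        self,
        model: CalphaModel | np.ndarray,
        force_field: str = "anm",
        cutoff: float = DEFAULT_CUTOFF,
        k: float = 1.0,
    ):
        self.model = model
        self.force_field = force_field
        self.cutoff = cutoff
        self.k = k

    @property
    def hessian(self) -> np.ndarray:
        return build_hessian(self.model, self.force_field, self.cutoff, self.k)

    def fit(self) -> NormalModeResult:
        return normal_modes(self.hessian)


@dataclass
class EnsembleFluctuations:
    """Per-structure and consensus fluctuation profiles on MSA columns.

    ``per_structure`` rows are scaled to mean 1 over the all-present
    columns before the consensus (their mean) is formed; ``raw`` keeps
    the unscaled profiles.  Values are NaN at gap columns, and the
    consensus is defined only where no structure has a gap.
    """

    labels: list[str]
    per_structure: np.ndarray  # (m, L), scaled, NaN at gaps
    raw: np.ndarray  # (m, L), unscaled, NaN at gaps
    consensus: np.ndarray  # (L,), NaN where any structure is gapped
    present_columns: np.ndarray  # indices of all-present columns


def ensemble_nma(
    ens: AlignedEnsemble,
    force_field: str = "anm",
    cutoff: float = DEFAULT_CUTOFF,
    k: float = 1.0,
) -> EnsembleFluctuations:
    """Normal-mode fluctuation profiles across an aligned ensemble.

    Each structure's modes are computed on its full (ungapped) C-alpha
    set and the per-residue fluctuations are laid out on the alignment
    columns, so homologous residues line up even across indels.
    """
    m, L = ens.n_structures, ens.length
    present = ens.present_columns()
    raw = np.full((m, L), np.nan)
    for s in range(m):
        coords = ens.structure_coords(s)
        try:
            result = ElasticNetworkModel(coords, force_field, cutoff, k).fit()
        except Exception as exc:
            raise type(exc)(f"structure {ens.labels[s]!r}: {exc}") from exc
        raw[s, ~ens.gap_mask[s]] = result.fluctuations
    scales = np.nanmean(raw[:, present], axis=1)
    if np.any(scales <= 0):
        warnings.warn("non-positive mean fluctuation; skipping normalization")
        scaled = raw.copy()
    else:
        scaled = raw / scales[:, None]
    consensus = np.full(L, np.nan)
    consensus[present] = scaled[:, present].mean(axis=0)
    return EnsembleFluctuations(list(ens.labels), scaled, raw, consensus, present)
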