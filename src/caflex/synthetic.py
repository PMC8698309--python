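"""Synthetic inputs with known ground truth.

Three generators cover the statistical structure the analyses assume:

* toy C-alpha geometries (ideal helix, random coil, two-domain hinge),
* homologous ensembles built as a rigid base plus planted orthonormal
  collective modes with Gaussian amplitudes (the oracle for ensemble
  superposition and PCA),
* equilibrium trajectories drawn i.i.d. from a known 3n-dimensional
  Gaussian, returned together with the analytic DCCM and RMSF they
  should converge to (the oracle for the trajectory analytics).

Frames are i.i.d. by design: every statistic in the package is
invariant to frame order, so kinetics are out of scope.  All stochastic
calls take a mandatory seed and are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .alignment import AlignedEnsemble
from .enm import NormalModeResult
from .errors import ParameterError
from .structure_io import CalphaModel, Trajectory
from .trajectory import ANGSTROM_TO_NM

#: Ideal alpha-helix geometry: rise per residue (A), twist (deg), radius (A).
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Declarative recipe for a synthetic dataset (CLI ``simulate``)."""

    n_residues: int = 60
    geometry: str = "ideal-helix"
    planted_mode_sigmas: tuple = (3.0, 1.0)
    noise_sigma: float = 0.0
    n_samples: int = 50
    n_frames: int = 1000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        known.setdefault("extra", {})
        return cls(**known)


def _default_sequence(n: int) -> str:
    return "".join(_AA[i % len(_AA)] for i in range(n))


def make_geometry(
    n_residues: int, geometry: str = "ideal-helix", seed: int = 0
) -> CalphaModel:
    """Build a toy C-alpha trace.

    ``ideal-helix`` uses the canonical alpha-helix parameters (1.5 A
    rise, 100 deg twist, 2.3 A radius), giving consecutive C-alpha
    distances of ~3.8 A.  ``random-coil`` is a 3.8 A fixed-step random
    walk; ``two-domain`` joins two helices with a 3-residue linker,
    producing a natural hinge.
    """
    n = int(n_residues)
    if n < 3:
        raise ParameterError(f"need at least 3 residues, got {n}")
    if geometry == "ideal-helix":
        coords = _helix_coords(n)
    elif geometry == "random-coil":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(3.8 * steps, axis=0)])
    elif geometry == "two-domain":
        n1 = (n - 3) // 2
        n2 = n - 3 - n1
        dom1 = _helix_coords(n1)
        dom2 = _helix_coords(n2) @ Rotation.from_euler("y", 90, degrees=True).as_matrix().T
        end = dom1[-1]
        # zig-zag linker: a collinear one would leave a free torsion
        steps = np.array([[3.0, 1.5, 2.3], [3.0, -1.5, 2.3], [3.0, 1.5, 2.3]])
        linker = end + np.cumsum(steps, axis=0)
        dom2 = dom2 - dom2[0] + linker[-1] + np.array([3.0, -1.5, 2.3])
        coords = np.vstack([dom1, linker, dom2])
    else:
        raise ParameterError(f"unknown geometry {geometry!r}")
    return CalphaModel(
        chain_id="A",
        residue_numbers=np.arange(1, n + 1),
        sequence=_default_sequence(n),
        coords=coords,
    )


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(HELIX_TWIST_DEG)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * np.arange(n)]
    )


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3n x 6) of rigid translations and rotations."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for a in range(3):
        basis[a::3, a] = 1.0
    for a, axis in enumerate(np.eye(3)):
        basis[:, 3 + a] = np.cross(np.broadcast_to(axis, (n, 3)), centered).ravel()
    q, _ = np.linalg.qr(basis)
    return q


def make_planted_ensemble(
    base: CalphaModel,
    n_structures: int = 50,
    mode_sigmas: tuple = (3.0, 1.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[AlignedEnsemble, dict]:
    """Homologous ensemble with planted low-dimensional deformations.

    Each structure is ``base + sum_m a_m * mode_m + noise`` with
    ``a_m ~ Normal(0, sigma_m^2)`` (A) and isotropic per-atom noise.
    Modes are random internal displacement fields: orthonormal and
    orthogonal to the rigid-body subspace, so a perfect analysis
    recovers them as the leading principal components.

    Returns the ensemble (gap-free, shared numbering) plus a ground
    truth dict (modes, amplitudes, sigmas).
    """
    rng = np.random.default_rng(seed)
    n = base.n_residues
    dim = 3 * n
    n_modes = len(mode_sigmas)
    rigid = rigid_body_basis(base.coords)
    raw = rng.normal(size=(dim, n_modes))
    raw -= rigid @ (rigid.T @ raw)
    modes, _ = np.linalg.qr(raw)
    amplitudes = rng.normal(size=(n_structures, n_modes)) * np.asarray(mode_sigmas)
    disp = amplitudes @ modes.T  # (S, 3n)
    coords = base.coords[None, :, :] + disp.reshape(n_structures, n, 3)
    if noise_sigma > 0:
        coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)
    labels = [f"synth{i:03d}" for i in range(n_structures)]
    ens = AlignedEnsemble(
        labels=labels,
        coords=coords,
        gap_mask=np.zeros((n_structures, n), dtype=bool),
        residue_numbers=np.broadcast_to(
            base.residue_numbers, (n_structures, n)
        ).copy(),
        sequences=[base.sequence] * n_structures,
    )
    truth = {
        "modes": modes.T,  # (n_modes, 3n)
        "mode_sigmas": np.asarray(mode_sigmas, dtype=float),
        "amplitudes": amplitudes,
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
    }
    return ens, truth


def covariance_from_modes(
    modes: NormalModeResult, target_mean_rmsf_nm: float | None = None
) -> np.ndarray:
    """Pseudo-inverse covariance of an elastic network's internal modes.

    Sigma = sum_{m>6} v_m v_m^T / lambda_m, optionally rescaled so the
    analytic mean RMSF equals ``target_mean_rmsf_nm``.
    """
    V = modes.eigenvectors[:, modes.n_trivial:]
    inv_w = 1.0 / modes.eigenvalues[modes.n_trivial:]
    cov = (V * inv_w) @ V.T
    if target_mean_rmsf_nm is not None:
        n = modes.n_residues
        msf = np.trace(cov) / n  # mean per-residue MSF, A^2
        cov = cov * (target_mean_rmsf_nm / ANGSTROM_TO_NM) ** 2 / msf
    return cov


def analytic_dccm(cov: np.ndarray) -> np.ndarray:
    """Exact DCCM implied by a 3n x 3n displacement covariance."""
    n = cov.shape[0] // 3
    blocks = cov.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", blocks)
    var = np.diag(inner).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        C = inner / np.sqrt(np.outer(var, var))
    C[var <= 0, :] = np.nan
    C[:, var <= 0] = np.nan
    return C


def analytic_rmsf_nm(cov: np.ndarray) -> np.ndarray:
    """Exact RMSF profile (nm) implied by a displacement covariance."""
    n = cov.shape[0] // 3
    var = np.einsum("iaia->i", cov.reshape(n, 3, n, 3))
    return np.sqrt(var) * ANGSTROM_TO_NM


def sample_gaussian_trajectory(
    mean: CalphaModel,
    covariance: np.ndarray | NormalModeResult,
    n_frames: int = 1000,
    seed: int = 0,
    target_mean_rmsf_nm: float | None = None,
) -> tuple[Trajectory, dict]:
    """Draw i.i.d. frames from a Gaussian with known covariance.

    ``covariance`` is a 3n x 3n PSD matrix (A^2) or a
    :class:`NormalModeResult`, in which case the elastic network's
    internal-mode pseudo-inverse covariance is used (optionally scaled
    to ``target_mean_rmsf_nm``).  Returns the trajectory plus a truth
    dict with the analytic DCCM and RMSF the estimators must recover.
    """
    if isinstance(covariance, NormalModeResult):
        cov = covariance_from_modes(covariance, target_mean_rmsf_nm)
    else:
        cov = np.asarray(covariance, dtype=float)
    n = mean.n_residues
    if cov.shape != (3 * n, 3 * n):
        raise ParameterError(
            f"covariance shape {cov.shape} does not match {n} residues"
        )
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ParameterError(
            f"covariance is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    root = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal(size=(n_frames, 3 * n))
    frames = mean.coords[None, :, :] + (Z @ root.T).reshape(n_frames, n, 3)
    labels = [f"{mean.sequence[i]}{mean.residue_numbers[i]}" for i in range(n)]
    traj = Trajectory(frames, atom_labels=labels)
    truth = {
        "covariance": cov,
        "dccm": analytic_dccm(cov),
        "rmsf_nm": analytic_rmsf_nm(cov),
        "seed": int(seed),
    }
    return traj, truth


def rigid_motion_trajectory(
    base: CalphaModel,
    n_frames: int,
    seed: int = 0,
    translation_sigma: float = 5.0,
) -> Trajectory:
    """Random rigid-body placements of a structure — no internal motion."""
    if n_frames < 1:
        raise ParameterError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, base.n_residues, 3))
    centered = base.coords - base.coords.mean(axis=0)
    for f in range(n_frames):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(scale=translation_sigma, size=3)
        frames[f] = centered @ R.T + t
    labels = [
        f"{base.sequence[i]}{base.residue_numbers[i]}"
        for i in range(base.n_residues)
    ]
    return Trajectory(frames, atom_labels=labels)


def truth_to_json(truth: dict) -> str:
    """Serialize a ground-truth dict (arrays become nested lists)."""
    def convert(v):
        if isinstance(v, np.ndarray):
            return np.where(np.isnan(v), None, v).tolist() if v.dtype.kind == "f" else v.tolist()
        return v

    return json.dumps({k: convert(v) for k, v in truth.items()}, indent=1)
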