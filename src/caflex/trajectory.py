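"""Trajectory analytics: RMSD, RMSF, radius of gyration, DCCM, and the
flexibility/correlation calling rules.

Coordinates come in as Angstrom (the package-internal unit); every
reported deviation/fluctuation here is in nanometres, the unit in which
the calling thresholds are defined: residues with RMSF >= 0.3 nm count
as highly flexible, wild-type-vs-mutant differences >= 0.1 nm are
called, and dynamic cross-correlations are banded at +/-0.5.

The DCCM is the Ichiye-Karplus normalized covariance of residue
displacement vectors,

    C_ij = <dr_i . dr_j> / (<|dr_i|^2> <|dr_j|^2>)^1/2,

with dr the displacement from the time-mean position after rigid-body
superposition of the frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import kabsch_superpose
from .errors import AlignmentError, ParameterError, SampleError, ShapeError
from .structure_io import CalphaModel, Trajectory

ANGSTROM_TO_NM = 0.1

#: RMSF above which a residue counts as highly flexible (nm).
RMSF_HIGH_NM = 0.3
#: Minimum wild-type-vs-mutant RMSF difference to call (nm).
DELTA_CALL_NM = 0.1
#: Correlation band boundary: |C| >= 0.5 is (anti)correlated.
CORR_BAND = 0.5

#: Atoms whose displacement variance falls below this (A^2) are treated
#: as motionless and get undefined (NaN) correlations.
ZERO_VARIANCE_TOL = 1e-12


def _superpose_frames(
    coords: np.ndarray, reference: np.ndarray, fit_mask: np.ndarray | None
) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        sup = kabsch_superpose(coords[f], reference, fit_mask)
        out[f] = sup.apply(coords[f])
    return out


def superpose_to_mean(
    traj: Trajectory, fit_mask: np.ndarray | None = None, n_iter: int = 2
) -> np.ndarray:
    """Fit all frames to the iterated mean structure.

    The reference is bootstrapped from the first frame, then refined
    ``n_iter`` times by re-fitting to the current frame-mean — the
    standard reference for RMSF/DCCM when no crystal structure is
    singled out.
    """
    coords = traj.coords
    fitted = _superpose_frames(coords, coords[0], fit_mask)
    for _ in range(n_iter):
        fitted = _superpose_frames(fitted, fitted.mean(axis=0), fit_mask)
    return fitted


@dataclass
class RmsdResult:
    """Per-frame RMSD (nm) with its Table-style summary mean +/- SE."""

    series: np.ndarray  # (F,), nm
    mean: float  # nm
    se: float  # standard error over frames, nm

    def summary(self) -> str:
        return (
            f"RMSD over {len(self.series)} frames: "
            f"{self.mean:.3f} +/- {self.se:.4f} nm "
            f"(min {self.series.min():.3f}, max {self.series.max():.3f})"
        )


def _reference_coords(reference, traj: Trajectory) -> np.ndarray:
    if isinstance(reference, CalphaModel):
        ref = reference.coords
    elif np.isscalar(reference):
        ref = traj.coords[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ShapeError(
            f"reference shape {ref.shape} does not match trajectory "
            f"({traj.n_atoms} atoms)"
        )
    return ref


def rmsd_series(
    traj: Trajectory,
    reference=0,
    fit_mask: np.ndarray | None = None,
    report_mask: np.ndarray | None = None,
    fit: bool = True,
) -> RmsdResult:
    """RMSD of every frame against a reference, in nm.

    Each frame is least-squares fit to the reference over ``fit_mask``
    (all atoms by default) before the deviation is measured over
    ``report_mask``.  Set ``fit=False`` to measure raw deviations.
    The summary SE is sd/sqrt(F) over frames.
    """
    ref = _reference_coords(reference, traj)
    coords = _superpose_frames(traj.coords, ref, fit_mask) if fit else traj.coords
    if report_mask is None:
        report_mask = np.ones(traj.n_atoms, dtype=bool)
    d = coords[:, report_mask] - ref[report_mask]
    series = np.sqrt(np.mean(np.sum(d**2, axis=2), axis=1)) * ANGSTROM_TO_NM
    F = len(series)
    se = float(series.std(ddof=1) / np.sqrt(F)) if F > 1 else 0.0
    return RmsdResult(series, float(series.mean()), se)


def rmsf_profile(
    traj: Trajectory, fit_mask: np.ndarray | None = None, fit: bool = True
) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the time-mean, nm.

    Frames are superposed onto the iterated mean structure first
    (unless ``fit=False``), so rigid-body drift does not inflate the
    profile.
    """
    if traj.n_frames < 2:
        raise SampleError("RMSF needs at least 2 frames")
    coords = superpose_to_mean(traj, fit_mask) if fit else traj.coords
    d = coords - coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum(d**2, axis=2), axis=0)) * ANGSTROM_TO_NM


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Uniform-mass C-alpha radius of gyration per frame, nm."""
    if traj.n_atoms < 2:
        raise ShapeError("radius of gyration needs >= 2 atoms")
    com = traj.coords.mean(axis=1, keepdims=True)
    sq = np.sum((traj.coords - com) ** 2, axis=2).mean(axis=1)
    return np.sqrt(sq) * ANGSTROM_TO_NM


@dataclass
class CorrelationMatrix:
    """n x n dynamic cross-correlation matrix with residue labels.

    Motionless atoms carry NaN rows/columns (flagged, not silently 0).
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ShapeError("correlation matrix must be square")
        if len(self.labels) != n:
            raise ShapeError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def dccm(
    traj: Trajectory,
    fit_mask: np.ndarray | None = None,
    window: slice | None = None,
    fit: bool = True,
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of residue displacements.

    Frames (optionally restricted to ``window``) are superposed onto
    the iterated mean structure, then C_ij is the normalized covariance
    of the 3-vector displacements from the time-mean.  Atoms with zero
    displacement variance get NaN correlations and a warning.
    """
    work = traj if window is None else Trajectory(
        traj.coords[window], traj.frame_spacing, traj.atom_labels
    )
    if work.n_frames < 2:
        raise SampleError("DCCM needs at least 2 frames")
    coords = superpose_to_mean(work, fit_mask) if fit else work.coords
    delta = coords - coords.mean(axis=0)  # (F, n, 3)
    cov3 = np.einsum("fia,fja->ij", delta, delta) / work.n_frames
    var = np.diag(cov3).copy()
    dead = var < ZERO_VARIANCE_TOL
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} atom(s) with zero displacement variance; "
            "their correlations are undefined (NaN)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        C = np.where(denom > 0, cov3 / np.where(denom > 0, denom, 1.0), np.nan)
    C[dead, :] = np.nan
    C[:, dead] = np.nan
    ok = ~dead
    C[np.ix_(ok, ok)] = np.clip(C[np.ix_(ok, ok)], -1.0, 1.0)
    C[ok, ok] = 1.0
    labels = list(work.atom_labels) or [str(i + 1) for i in range(work.n_atoms)]
    return CorrelationMatrix((C + C.T) / 2, labels)


@dataclass
class FlexibleRegion:
    """A maximal contiguous run of residues at or above the RMSF threshold."""

    start_residue: int
    end_residue: int
    mean_rmsf: float  # nm
    sequence: str

    def __str__(self):
        span = (
            str(self.start_residue)
            if self.start_residue == self.end_residue
            else f"{self.start_residue}-{self.end_residue}"
        )
        return f"{span} {self.sequence} ({self.mean_rmsf:.2f} nm)"


def _contiguous_runs(residue_numbers: np.ndarray, idx: np.ndarray):
    """Split selected profile indices into runs contiguous in numbering."""
    runs = []
    for i in idx:
        if runs and i == runs[-1][-1] + 1 and (
            residue_numbers[i] == residue_numbers[runs[-1][-1]] + 1
        ):
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    return runs


def call_flexible_regions(
    rmsf_nm: np.ndarray,
    residue_numbers: np.ndarray,
    sequence: str | None = None,
    threshold: float = RMSF_HIGH_NM,
) -> list[FlexibleRegion]:
    """Call high-flexibility regions from an RMSF profile.

    A region is a maximal run of residues — contiguous in author
    numbering — whose RMSF is at or above ``threshold`` (0.3 nm by
    default); single-residue regions are allowed.
    """
    rmsf_nm = np.asarray(rmsf_nm, dtype=float)
    residue_numbers = np.asarray(residue_numbers, dtype=int)
    if rmsf_nm.shape != residue_numbers.shape:
        raise ShapeError("rmsf/residue_numbers length mismatch")
    if sequence is not None and len(sequence) != len(rmsf_nm):
        raise ShapeError("sequence length mismatch")
    hot = np.flatnonzero(rmsf_nm >= threshold)
    regions = []
    for run in _contiguous_runs(residue_numbers, hot):
        seq = "".join(sequence[i] for i in run) if sequence else "?" * len(run)
        regions.append(
            FlexibleRegion(
                start_residue=int(residue_numbers[run[0]]),
                end_residue=int(residue_numbers[run[-1]]),
                mean_rmsf=float(rmsf_nm[run].mean()),
                sequence=seq,
            )
        )
    return regions


@dataclass
class ProfileComparison:
    """Residues whose flexibility changed by at least ``delta`` nm."""

    increased: list[tuple[int, int]]  # merged (start, end) residue ranges
    reduced: list[tuple[int, int]]
    increased_residues: np.ndarray
    reduced_residues: np.ndarray
    delta: float


def compare_profiles(
    wt: np.ndarray,
    mutant: np.ndarray,
    residue_numbers: np.ndarray,
    delta: float = DELTA_CALL_NM,
) -> ProfileComparison:
    """Call residues whose RMSF moved by >= ``delta`` nm between profiles.

    Both profiles must live on the same residue mapping (e.g. shared
    MSA columns).  Increased means mutant - wt >= delta; contiguous
    calls are merged into ranges.
    """
    wt = np.asarray(wt, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    residue_numbers = np.asarray(residue_numbers, dtype=int)
    if wt.shape != mutant.shape or wt.shape != residue_numbers.shape:
        raise AlignmentError("profiles are not on a common residue mapping")
    diff = mutant - wt
    inc_idx = np.flatnonzero(diff >= delta)
    red_idx = np.flatnonzero(-diff >= delta)

    def ranges(idx):
        return [
            (int(residue_numbers[r[0]]), int(residue_numbers[r[-1]]))
            for r in _contiguous_runs(residue_numbers, idx)
        ]

    return ProfileComparison(
        increased=ranges(inc_idx),
        reduced=ranges(red_idx),
        increased_residues=residue_numbers[inc_idx],
        reduced_residues=residue_numbers[red_idx],
        delta=delta,
    )


def classify_correlations(
    C: CorrelationMatrix, lo: float = -CORR_BAND, hi: float = CORR_BAND
) -> np.ndarray:
    """Band a DCCM into -1 (anticorrelated), 0 (neutral), +1 (correlated).

    Boundaries are closed toward the extreme bands: C >= hi is
    correlated and C <= lo anticorrelated.  NaN entries stay NaN.
    """
    if not lo < hi:
        raise ParameterError(f"need lo < hi, got {lo} >= {hi}")
    M = C.matrix
    bands = np.zeros_like(M)
    bands[M >= hi] = 1.0
    bands[M <= lo] = -1.0
    bands[np.isnan(M)] = np.nan
    return bands


def block_summary(
    C: CorrelationMatrix,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    residue_numbers: np.ndarray | None = None,
    lo: float = -CORR_BAND,
    hi: float = CORR_BAND,
) -> dict:
    """Mean correlation of a residue-range pair and its band label.

    Regions are inclusive (start, end) ranges in author numbering when
    ``residue_numbers`` is given, otherwise in 1-based matrix position.
    """
    if residue_numbers is None:
        residue_numbers = np.arange(1, C.n + 1)
    residue_numbers = np.asarray(residue_numbers, dtype=int)

    def indices(region):
        start, end = region
        idx = np.flatnonzero((residue_numbers >= start) & (residue_numbers <= end))
        if idx.size == 0:
            raise ParameterError(f"region {region} is outside the matrix")
        return idx

    ia, ib = indices(region_a), indices(region_b)
    block = C.matrix[np.ix_(ia, ib)]
    mean = float(np.nanmean(block))
    band = "correlated" if mean >= hi else "anticorrelated" if mean <= lo else "neutral"
    return {"mean": mean, "band": band, "n_pairs": int(block.size)}


class TrajectoryAnalysis:
    """Convenience front end bundling the per-trajectory analytics.

    Wraps a :class:`Trajectory` (and optional reference) and exposes
    ``rmsd()``, ``rmsf()``, ``rg()``, ``dccm()``, ``pca(window_fraction)``
    and a Table-style ``summary()``.
    """

    def __init__(
        self,
        traj: Trajectory,
        reference=0,
        residue_numbers: np.ndarray | None = None,
        sequence: str | None = None,
    ):
        self.traj = traj
        self.reference = reference
        self.residue_numbers = (
            np.arange(1, traj.n_atoms + 1)
            if residue_numbers is None
            else np.asarray(residue_numbers, dtype=int)
        )
        self.sequence = sequence

    def rmsd(self, **kw) -> RmsdResult:
        return rmsd_series(self.traj, self.reference, **kw)

    def rmsf(self, **kw) -> np.ndarray:
        return rmsf_profile(self.traj, **kw)

    def rg(self) -> np.ndarray:
        return radius_of_gyration(self.traj)

    def dccm(self, **kw) -> CorrelationMatrix:
        return dccm(self.traj, **kw)

    def pca(self, window_fraction: float = 1.0):
        """PCA of the (superposed) frames; optionally only the final
        ``window_fraction`` of the trajectory (e.g. 0.8 to drop the
        initial fifth, the usual equilibration discard)."""
        from .pca import CoordinatePCA

        start = int(round((1.0 - window_fraction) * self.traj.n_frames))
        coords = superpose_to_mean(
            Trajectory(self.traj.coords[start:], self.traj.frame_spacing)
        )
        return CoordinatePCA(coords).fit()

    def flexible_regions(self, threshold: float = RMSF_HIGH_NM):
        return call_flexible_regions(
            self.rmsf(), self.residue_numbers, self.sequence, threshold
        )

    def summary(self, threshold: float = RMSF_HIGH_NM) -> dict:
        """Table-style row: mean RMSD +/- SE and the high-RMSF regions."""
        r = self.rmsd()
        regions = self.flexible_regions(threshold)
        return {
            "n_frames": self.traj.n_frames,
            "n_atoms": self.traj.n_atoms,
            "rmsd_mean_nm": round(r.mean, 4),
            "rmsd_se_nm": round(r.se, 5),
            "high_rmsf_regions": [
                {
                    "start": reg.start_residue,
                    "end": reg.end_residue,
                    "sequence": reg.sequence,
                    "mean_rmsf_nm": round(reg.mean_rmsf, 4),
                }
                for reg in regions
            ],
        }
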