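"""MSA-to-structure mapping, Kabsch superposition and invariant-core search.

Homologous C-alpha traces are mapped onto the columns of a multiple
sequence alignment, the structurally invariant core is found by
iterated variance-based exclusion, and the ensemble is least-squares
superposed over that core.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.transform import Rotation

from .errors import AlignmentError, CoreError, DegenerateFitError, ParameterError
from .structure_io import CalphaModel

GAP = "-"


@dataclass
class Msa:
    """A multiple sequence alignment: labels plus equal-length rows."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels/sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment lengths: {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_fasta_alignment(text: str) -> Msa:
    """Parse a FASTA alignment; '-' is the only gap character recognized."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) < 2:
        raise AlignmentError("an alignment needs at least two records")
    return Msa(
        labels=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
    )


def write_fasta_alignment(msa: Msa) -> str:
    return "".join(f">{l}\n{s}\n" for l, s in zip(msa.labels, msa.sequences))


@dataclass
class AlignedEnsemble:
    """Homologous C-alpha models laid out on alignment columns.

    ``coords[k, j]`` holds structure ``k``'s coordinates at alignment
    column ``j`` (NaN where gapped), ``gap_mask[k, j]`` is True at gaps,
    and ``residue_numbers[k, j]`` maps columns back to author numbering
    (-1 at gaps).  Columns are 0-based internally and reported 1-based
    in all exported files.
    """

    labels: list[str]
    coords: np.ndarray  # (m, L, 3), Angstrom, NaN at gaps
    gap_mask: np.ndarray  # (m, L) bool, True where gapped
    residue_numbers: np.ndarray  # (m, L) int, -1 at gaps
    sequences: list[str] | None = None  # aligned rows, optional

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        m, L = self.gap_mask.shape
        if m < 2:
            raise AlignmentError("an ensemble needs at least two structures")
        if self.coords.shape != (m, L, 3):
            raise AlignmentError("coords/gap_mask shape mismatch")

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return self.coords.shape[1]

    def present_columns(self) -> np.ndarray:
        """Indices of columns where every structure has a residue."""
        return np.flatnonzero(~self.gap_mask.any(axis=0))

    def structure_coords(self, k: int) -> np.ndarray:
        """Structure k's coordinates over its own (ungapped) residues."""
        return self.coords[k][~self.gap_mask[k]]

    def copy(self) -> "AlignedEnsemble":
        return AlignedEnsemble(
            list(self.labels), self.coords.copy(), self.gap_mask.copy(),
            self.residue_numbers.copy(),
            None if self.sequences is None else list(self.sequences),
        )


def map_alignment_to_structures(
    msa: Msa, models: list[CalphaModel], labels: list[str] | None = None
) -> AlignedEnsemble:
    """Place each model's coordinates onto the MSA columns.

    ``models`` must be given in the MSA's record order (or pass
    ``labels`` to reorder).  Each MSA row with gaps removed must equal
    the corresponding model's sequence.
    """
    if labels is not None:
        order = {lab: i for i, lab in enumerate(labels)}
        models = [models[order[lab]] for lab in msa.labels]
    if len(models) != msa.n_sequences:
        raise AlignmentError(
            f"{msa.n_sequences} alignment rows but {len(models)} models"
        )
    m, L = msa.n_sequences, msa.length
    coords = np.full((m, L, 3), np.nan)
    gap_mask = np.ones((m, L), dtype=bool)
    res_nums = np.full((m, L), -1, dtype=int)
    for k, (row, model) in enumerate(zip(msa.sequences, models)):
        ungapped = row.replace(GAP, "")
        if ungapped != model.sequence:
            pos = next(
                (
                    i
                    for i, (a, b) in enumerate(zip(ungapped, model.sequence))
                    if a != b
                ),
                min(len(ungapped), len(model.sequence)),
            )
            a = ungapped[pos] if pos < len(ungapped) else "<end>"
            b = model.sequence[pos] if pos < len(model.sequence) else "<end>"
            raise AlignmentError(
                f"sequence mismatch for {msa.labels[k]!r} at ungapped "
                f"position {pos + 1}: alignment has {a!r}, structure has {b!r}"
            )
        idx = 0
        for j, ch in enumerate(row):
            if ch == GAP:
                continue
            coords[k, j] = model.coords[idx]
            gap_mask[k, j] = False
            res_nums[k, j] = model.residue_numbers[idx]
            idx += 1
    return AlignedEnsemble(list(msa.labels), coords, gap_mask, res_nums,
                           list(msa.sequences))


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile onto a reference point set."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # over the masked points, Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Uses the SVD (Kabsch) solution on the proper-rotation branch
    (reflections excluded).  ``mask`` selects the points used for the
    fit and for the reported RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateFitError(
            f"point sets must share an (n, 3) shape; got {mobile.shape} "
            f"vs {reference.shape}"
        )
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    P = mobile[mask]
    Q = reference[mask]
    if len(P) < 3:
        raise DegenerateFitError(f"need >= 3 points for a fit, got {len(P)}")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    Pc = P - p_mean
    # collinearity check: second singular value of the centered set
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("masked points are (near-)collinear")
    rot, _ = Rotation.align_vectors(Q - q_mean, Pc)
    R = rot.as_matrix()
    t = q_mean - R @ p_mean
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def _column_variances(coords: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Per-column, per-axis positional variance across structures."""
    return coords[:, cols, :].var(axis=0)  # (len(cols), 3)


def _fit_all_to_first(
    ens: AlignedEnsemble, cols: np.ndarray
) -> AlignedEnsemble:
    out = ens.copy()
    ref = ens.coords[0, cols]
    for k in range(1, ens.n_structures):
        sup = kabsch_superpose(ens.coords[k, cols], ref)
        present = ~ens.gap_mask[k]
        out.coords[k, present] = sup.apply(ens.coords[k, present])
    return out


def find_core(
    ens: AlignedEnsemble,
    volume_threshold: float = 0.5,
    min_size: int | None = None,
) -> np.ndarray:
    """Find the structurally invariant core by iterated exclusion.

    Starting from all columns present in every structure, the ensemble
    is repeatedly superposed (onto the first structure) over the current
    candidate core, and the column with the highest total positional
    variance is dropped, until the core's "volume" (product of the
    per-axis variance sums, A^3 — the bio3d core-finding statistic)
    falls below ``volume_threshold`` or the core reaches ``min_size``
    columns (default ``max(10, L // 5)``).  Ties drop the lower column
    index first, so the result is deterministic.
    """
    L = ens.length
    if min_size is None:
        min_size = max(10, L // 5)
    core = ens.present_columns()
    if len(core) < max(3, min_size):
        raise CoreError(
            f"{len(core)} all-present columns; need at least "
            f"{max(3, min_size)} to search for a core"
        )
    core = core.copy()
    while True:
        fitted = _fit_all_to_first(ens, core)
        var = _column_variances(fitted.coords, core)  # (c, 3)
        volume = float(np.prod(var.sum(axis=0)))
        if volume < volume_threshold or len(core) <= min_size:
            return np.sort(core)
        worst = int(np.argmax(var.sum(axis=1)))  # first max -> lowest index
        core = np.delete(core, worst)


def fit_ensemble(ens: AlignedEnsemble, core: np.ndarray) -> AlignedEnsemble:
    """Superpose every structure onto the first over the core columns."""
    core = np.asarray(core, dtype=int)
    if core.size < 3:
        raise CoreError("core must contain at least 3 columns")
    if ens.gap_mask[:, core].any():
        raise CoreError("core columns must be present in every structure")
    return _fit_all_to_first(ens, core)


def pairwise_identity(msa: Msa) -> np.ndarray:
    """Pairwise sequence identity = matches / aligned non-gap pairs."""
    rows = np.array([list(s) for s in msa.sequences])
    m = len(rows)
    ident = np.eye(m)
    nongap = rows != GAP
    for i in range(m):
        for j in range(i + 1, m):
            both = nongap[i] & nongap[j]
            n_pairs = int(both.sum())
            if n_pairs == 0:
                ident[i, j] = ident[j, i] = 0.0
                continue
            matches = int((rows[i][both] == rows[j][both]).sum())
            ident[i, j] = ident[j, i] = matches / n_pairs
    return ident


def group_by_identity(msa: Msa, threshold: float = 0.7) -> np.ndarray:
    """Single-linkage grouping of sequences at an identity threshold.

    Returns integer group labels (0-based, ordered by first appearance).
    Structures end up in the same group iff they are connected by a
    chain of pairs with identity >= ``threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"identity threshold must be in (0, 1], got {threshold}")
    ident = pairwise_identity(msa)
    adj = csr_matrix(ident >= threshold)
    _, labels = connected_components(adj, directed=False)
    # canonicalize: relabel in order of first appearance
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out
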