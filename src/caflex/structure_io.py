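"""Reading and writing of C-alpha structures and trajectories.

PDB is the only structural format handled (parsed through biotite's
fixed-column reader).  Multi-model PDB files double as the trajectory
format; a plain whitespace ``x y z`` table with an ``n=<atoms>`` header
is accepted as a lighter alternative.  Coordinates are kept in Angstrom
internally throughout the package; nanometre conversion happens only at
the reporting boundary of the trajectory analytics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.sequence import ProteinSequence

from .errors import (
    ChainNotFoundError,
    IntegrityError,
    PDBParseError,
    ShapeError,
)

#: Het-residue to standard-residue renames, applied only when
#: ``het_to_standard=True`` (selenomethionine is by far the common case).
HET_TO_STANDARD = {"MSE": "MET"}

#: Default frame spacing in ps: a 50 ns run stored as 5000 frames.
DEFAULT_FRAME_SPACING_PS = 10.0


def three_to_one(res_name: str) -> str:
    """Map a 3-letter residue name to a 1-letter code, 'X' if unknown."""
    try:
        return ProteinSequence.convert_letter_3to1(res_name.upper())
    except (KeyError, ValueError):
        return "X"


def one_to_three(letter: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(letter.upper())
    except (KeyError, ValueError):
        return "UNK"


@dataclass
class CalphaModel:
    """One chain's C-alpha trace.

    Parameters
    ----------
    chain_id : str
        PDB chain identifier.
    residue_numbers : ndarray of int
        Author residue numbering, strictly increasing (gaps allowed).
    sequence : str
        One-letter amino-acid sequence, same length as ``residue_numbers``.
    coords : ndarray, shape (n, 3)
        C-alpha coordinates in Angstrom.
    b_factors : ndarray or None
        Isotropic B-factors (A^2), optional.
    """

    chain_id: str
    residue_numbers: np.ndarray
    sequence: str
    coords: np.ndarray
    b_factors: np.ndarray | None = None

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if len(self.sequence) != n or self.coords.shape != (n, 3):
            raise ShapeError(
                f"inconsistent CalphaModel: {n} residues, sequence of "
                f"{len(self.sequence)}, coords {self.coords.shape}"
            )
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise IntegrityError("residue numbers must be strictly increasing")
        if not np.isfinite(self.coords).all():
            raise IntegrityError("non-finite coordinates")
        if self.b_factors is not None:
            self.b_factors = np.asarray(self.b_factors, dtype=float)
            if self.b_factors.shape != (n,):
                raise ShapeError("b_factors length mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def with_coords(self, coords: np.ndarray) -> "CalphaModel":
        """Copy of this model with replacement coordinates."""
        return CalphaModel(
            self.chain_id, self.residue_numbers.copy(), self.sequence,
            np.asarray(coords, dtype=float),
            None if self.b_factors is None else self.b_factors.copy(),
        )


@dataclass
class Trajectory:
    """Frames of C-alpha coordinates, in Angstrom.

    ``frame_spacing`` (ps) is carried as metadata only; every statistic
    in the package is invariant to frame order.
    """

    coords: np.ndarray
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS
    atom_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(f"trajectory coords must be (F, n, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ShapeError("trajectory needs at least one frame")
        if not np.isfinite(self.coords).all():
            raise IntegrityError("non-finite trajectory coordinates")
        if self.atom_labels and len(self.atom_labels) != self.n_atoms:
            raise ShapeError("atom_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _atoms_to_table(atoms: struc.AtomArray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "atom_name": atoms.atom_name,
            "res_name": atoms.res_name,
            "chain_id": atoms.chain_id,
            "res_id": atoms.res_id,
            "hetero": atoms.hetero,
            "x": atoms.coord[:, 0],
            "y": atoms.coord[:, 1],
            "z": atoms.coord[:, 2],
            "b_factor": atoms.b_factor,
        }
    )


def read_structure(pdb_text: str) -> list[pd.DataFrame]:
    """Parse PDB text into one atom table per MODEL block.

    Atoms with an alternate-location indicator other than the first one
    encountered are dropped; insertion codes are rejected because they
    make residue ordering ambiguous.
    """
    if not any(
        line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()
    ):
        raise PDBParseError("no ATOM/HETATM records found")
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb_file.get_model_count()
    tables = []
    for model in range(1, n_models + 1):
        atoms = pdb_file.get_structure(
            model=model, altloc="first", extra_fields=["b_factor"]
        )
        if np.any(atoms.ins_code != ""):
            bad = atoms.res_id[atoms.ins_code != ""][0]
            raise IntegrityError(
                f"insertion codes are not supported (residue {bad})"
            )
        tables.append(_atoms_to_table(atoms))
    return tables


def extract_calpha(
    atom_table: pd.DataFrame,
    chain_id: str,
    het_to_standard: bool = False,
) -> CalphaModel:
    """Extract one chain's C-alpha trace from an atom table.

    HETATM records are ignored unless ``het_to_standard`` is set, in
    which case the residues in :data:`HET_TO_STANDARD` (e.g. MSE) are
    renamed to their standard counterpart and kept.
    """
    chains = set(atom_table["chain_id"])
    if chain_id not in chains:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found (available: {sorted(chains)})"
        )
    sel = atom_table[
        (atom_table["chain_id"] == chain_id) & (atom_table["atom_name"] == "CA")
    ].copy()
    if het_to_standard:
        renameable = sel["res_name"].isin(HET_TO_STANDARD)
        sel.loc[renameable, "res_name"] = sel.loc[renameable, "res_name"].map(
            HET_TO_STANDARD
        )
        sel.loc[renameable, "hetero"] = False
    sel = sel[~sel["hetero"].astype(bool)]
    if sel["res_id"].duplicated().any():
        dup = int(sel["res_id"][sel["res_id"].duplicated()].iloc[0])
        raise IntegrityError(f"duplicate CA atom for residue {dup}")
    sel = sel.sort_values("res_id", kind="stable")
    sequence = "".join(three_to_one(r) for r in sel["res_name"])
    return CalphaModel(
        chain_id=chain_id,
        residue_numbers=sel["res_id"].to_numpy(),
        sequence=sequence,
        coords=sel[["x", "y", "z"]].to_numpy(),
        b_factors=sel["b_factor"].to_numpy(),
    )


def _looks_like_pdb(text: str) -> bool:
    return any(
        line.startswith(("ATOM", "HETATM", "MODEL"))
        for line in text.splitlines()[:200]
    )


def read_trajectory(
    source: str,
    n_atoms: int | None = None,
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS,
) -> Trajectory:
    """Load a trajectory from multi-model PDB text or a plain xyz table.

    The plain format is whitespace-separated ``x y z`` rows, one atom
    per row, frames concatenated; the atom count comes from a leading
    ``n=<atoms>`` header line or the ``n_atoms`` argument.
    """
    if _looks_like_pdb(source):
        tables = read_structure(source)
        counts = {len(t) for t in tables}
        if len(counts) != 1:
            raise ShapeError(
                f"models have differing atom counts {sorted(counts)}; "
                "cannot be treated as a trajectory"
            )
        coords = np.stack([t[["x", "y", "z"]].to_numpy() for t in tables])
        first = tables[0]
        labels = [
            f"{rn}{ri}" for rn, ri in zip(first["res_name"], first["res_id"])
        ]
        return Trajectory(coords, frame_spacing, labels)

    lines = [ln.strip() for ln in source.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if lines and lines[0].replace(" ", "").startswith("n="):
        n_atoms = int(lines[0].split("=", 1)[1])
        lines = lines[1:]
    if n_atoms is None:
        raise ShapeError("atom count unknown: provide an 'n=<atoms>' header or n_atoms")
    try:
        flat = np.array([[float(v) for v in ln.split()] for ln in lines])
    except ValueError as exc:
        raise PDBParseError(f"unparseable coordinate table: {exc}") from exc
    if flat.size == 0 or flat.shape[1] != 3:
        raise ShapeError("coordinate table must have exactly 3 columns")
    if flat.shape[0] % n_atoms != 0:
        raise ShapeError(
            f"{flat.shape[0]} rows is not a multiple of n_atoms={n_atoms}"
        )
    coords = flat.reshape(-1, n_atoms, 3)
    return Trajectory(coords, frame_spacing)


def write_multimodel(traj: Trajectory, template: CalphaModel) -> str:
    """Render a trajectory as multi-model PDB text using a template chain.

    Round-trips through :func:`read_trajectory` at PDB fixed-width
    precision (1e-3 A).
    """
    if traj.n_atoms != template.n_residues:
        raise ShapeError(
            f"trajectory has {traj.n_atoms} atoms, template has "
            f"{template.n_residues} residues"
        )
    n = template.n_residues
    atoms = struc.AtomArray(n)
    atoms.chain_id[:] = template.chain_id or "A"
    atoms.res_id[:] = template.residue_numbers
    atoms.res_name[:] = [one_to_three(c) for c in template.sequence]
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    stack = struc.from_template(atoms, traj.coords)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()
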