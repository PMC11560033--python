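"""Coordinate I/O, Ballesteros–Weinstein numbering, and atom selection.

A :class:`Trajectory` is a time-ordered list of :class:`MolecularFrame`
objects sharing one atom roster, typically read from a multi-model PDB file
standing in for an MD trajectory (e.g. 12 equidistant snapshots of a 90 ns
run merged into one file).

Residues are addressed through Ballesteros–Weinstein (BW) labels ``h.xx``:
``h`` is the transmembrane helix number (1–7) and ``xx`` an offset around
the conserved ``x.50`` anchor of that helix.  Helix-8 residues are numbered
by their distance from the 7.50 anchor, so labels like ``7.58`` may lie
beyond the structural end of TM7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

#: Default x.50 anchor residues of the AT1 receptor.
DEFAULT_ANCHORS = {1: 46, 2: 74, 3: 126, 4: 153, 5: 207, 6: 255, 7: 299}

#: Residue names recognized as lipids (PC = phosphatidylcholine,
#: PG = phosphatidylglycerol; palmitoyl-oleoyl or dioleoyl chains).
LIPID_RESNAMES = ("POPC", "DOPC", "POPG", "DOPG")

_BW_RE = re.compile(r"^([1-7])\.(\d{2})$")

#: 4-character lipid residue names exceed the strict PDB 3-column field;
#: they are stored in files under these codes and restored on read.
_PDB_RESNAME = {"POPC": "PPC", "DOPC": "DPC", "POPG": "PPG", "DOPG": "DPG"}
_PDB_RESNAME_INV = {v: k for k, v in _PDB_RESNAME.items()}


class RosterError(ValueError):
    """Atom roster inconsistent across models of a multi-model file."""


@dataclass(frozen=True)
class BWScheme:
    """Ballesteros–Weinstein anchor table: helix number → x.50 residue."""

    anchors: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))

    def __post_init__(self) -> None:
        if sorted(self.anchors) != list(range(1, 8)):
            raise ValueError("BW scheme requires exactly seven anchors, helices 1-7")
        seq = [self.anchors[h] for h in range(1, 8)]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("anchor residue numbers must increase with helix number")

    def resolve(self, label: str | tuple[int, int]) -> int:
        """Residue sequence number for BW label ``h.xx`` (pure arithmetic)."""
        helix, pos = parse_bw(label) if isinstance(label, str) else label
        if helix not in self.anchors:
            raise KeyError(f"unknown helix number {helix!r} in BW label")
        return self.anchors[helix] + (pos - 50)


def parse_bw(label: str) -> tuple[int, int]:
    """Parse ``"6.34"`` into ``(6, 34)``; H8 labels like ``"7.61"`` parse the same."""
    m = _BW_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed BW label {label!r}; expected 'h.xx' with h in 1-7")
    return int(m.group(1)), int(m.group(2))


def bw_to_residue(scheme: BWScheme, label: str) -> int:
    """Map a BW label to its residue sequence number: ``anchor + (xx - 50)``."""
    return scheme.resolve(label)


@dataclass
class MolecularFrame:
    """One labeled coordinate set: protein Cα (and optional side-chain
    pseudo-atoms) plus lipid head-group atoms.

    Coordinate convention: z is the membrane normal, the bilayer center at
    z = 0, the intracellular side at positive z.
    """

    time: float  # ns
    res_id: np.ndarray  # (n,) int
    res_name: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str
    chain: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, Å
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.box is not None and any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    def lipid_mask(self) -> np.ndarray:
        return np.isin(self.res_name, LIPID_RESNAMES)

    def protein_mask(self) -> np.ndarray:
        return ~self.lipid_mask()

    def leaflet(self, z_center: float = 0.0) -> np.ndarray:
        """Leaflet tag per atom: +1 intracellular (z > center), -1 extracellular."""
        return np.where(self.coords[:, 2] > z_center, 1, -1)


@dataclass
class Trajectory:
    """Time-ordered frames sharing one atom roster, with condition metadata."""

    frames: list[MolecularFrame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if self.frames:
            ref = self.frames[0].atom_name
            for i, f in enumerate(self.frames):
                if f.n_atoms != len(ref) or not np.array_equal(f.atom_name, ref):
                    raise RosterError(f"frame {i} does not share the common atom roster")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def select_calpha(frame: MolecularFrame, residues: list[int]) -> np.ndarray:
    """Cα coordinates for the requested residues, in the requested order."""
    out = np.empty((len(residues), 3))
    prot = frame.protein_mask()
    for i, res in enumerate(residues):
        hit = (frame.res_id == res) & (frame.atom_name == "CA") & prot
        n = int(hit.sum())
        if n == 0:
            if not np.any((frame.res_id == res) & prot):
                raise KeyError(f"residue {res} absent from frame")
            raise KeyError(f"residue {res} lacks a CA atom")
        if n > 1:
            raise KeyError(f"residue {res} has {n} CA atoms; expected exactly one")
        out[i] = frame.coords[hit][0]
    return out


def _model_atom_counts(path: str) -> list[tuple[int, int, int]]:
    """(model number, first line number, atom-record count) per MODEL block."""
    blocks: list[tuple[int, int, int]] = []
    model_no, start_line, count = 1, 1, 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                model_no = int(line.split()[1]) if len(line.split()) > 1 else len(blocks) + 1
                start_line, count = lineno, 0
            elif rec in ("ATOM", "HETATM"):
                count += 1
            elif rec == "ENDMDL":
                blocks.append((model_no, start_line, count))
                in_model, count = False, 0
    if not blocks:
        # single implicit model
        blocks.append((1, 1, count))
    elif in_model or count:
        blocks.append((model_no, start_line, count))
    return blocks


def load_multimodel_pdb(
    path: str,
    frame_dt_ns: float = 7.5,
    metadata: dict | None = None,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Frame times are assigned as ``0, dt, 2*dt, ...`` (``frame_dt_ns``
    defaults to 7.5 ns: 12 snapshots spanning a 90 ns run).

    Raises :class:`RosterError` naming the offending model if the atom
    roster differs between models, and ``ValueError`` with the line number
    for an unparseable coordinate line.
    """
    blocks = _model_atom_counts(path)
    counts = {c for _, _, c in blocks}
    if len(counts) > 1:
        ref = blocks[0][2]
        for model_no, line, c in blocks:
            if c != ref:
                raise RosterError(
                    f"model {model_no} (line {line}) has {c} atom records; "
                    f"model {blocks[0][0]} has {ref}"
                )
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises its own hierarchy
        raise ValueError(f"failed to parse coordinate records in {path}: {exc}") from exc
    if isinstance(stack, AtomArray):
        stack = AtomArrayStack(1, stack.array_length())  # pragma: no cover
    frames = []
    box = None
    if stack.box is not None:
        lx, ly, lz = np.diag(stack.box[0])
        if lx > 0 and ly > 0 and lz > 0:
            box = (float(lx), float(ly), float(lz))
    res_name = np.array([_PDB_RESNAME_INV.get(r, r) for r in stack.res_name])
    for i in range(stack.stack_depth()):
        frames.append(
            MolecularFrame(
                time=i * frame_dt_ns,
                res_id=np.asarray(stack.res_id),
                res_name=res_name,
                atom_name=np.asarray(stack.atom_name),
                chain=np.asarray(stack.chain_id),
                coords=stack.coord[i],
                box=box,
            )
        )
    return Trajectory(frames=frames, metadata=metadata or {})


def write_multimodel_pdb(path: str, traj: Trajectory) -> None:
    """Write a :class:`Trajectory` as a standard MODEL/ENDMDL multi-model PDB."""
    f0 = traj.frames[0]
    n = f0.n_atoms
    stack = AtomArrayStack(len(traj), n)
    stack.res_id = np.asarray(f0.res_id, dtype=int)
    stack.res_name = np.array([_PDB_RESNAME.get(r, r) for r in f0.res_name], dtype="U5")
    stack.atom_name = np.asarray(f0.atom_name, dtype="U6")
    stack.chain_id = np.asarray(f0.chain, dtype="U4")
    stack.hetero = np.isin(f0.res_name, LIPID_RESNAMES)
    stack.element = np.array(
        [("P" if a.startswith("P") else a[0]) for a in f0.atom_name], dtype="U2"
    )
    for i, frame in enumerate(traj):
        stack.coord[i] = frame.coords
    if f0.box is not None:
        stack.box = np.tile(np.diag(f0.box), (len(traj), 1, 1))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
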