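"""Reading and writing receptor structures, trajectories, BW maps and labels.

The in-memory structure container is :class:`StructureFrame`, a flat list of
atoms keyed by author residue numbering (insertion codes included).  PDB
files are parsed with Biopython, trajectory pairs (topology PDB + XTC/DCD)
with mdtraj; coordinates are always stored in angstrom regardless of the
source format (mdtraj's nm are scaled by 10 on read).

Ballesteros-Weinstein (BW) maps translate generic GPCR positions such as
"3.50" into concrete residues of one structure; they are supplied as
4-column TSV (bw, chain, resnum, aa) in GPCRdb author numbering.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ConsistencyError,
    FormatError,
    InsufficientAnchorsError,
    OutOfRangeError,
)

__all__ = [
    "Atom",
    "StructureFrame",
    "BWMap",
    "LabelRecord",
    "ACTIVATION_STATES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "load_bw_map",
    "extract_tm_domain",
    "superpose",
    "load_labels",
]

#: The three-class activation vocabulary, in ascending order of activation.
ACTIVATION_STATES = ("inactive", "intermediate", "active")

_BW_RE = re.compile(r"^[1-8]\.\d{2}$")


@dataclass(frozen=True)
class Atom:
    """One atom with author numbering.  ``icode`` is '' when absent."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    altloc: str
    occupancy: float
    xyz: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass
class StructureFrame:
    """A single structural snapshot: an ordered list of atoms.

    Invariants: coordinates finite and in angstrom; after altloc
    resolution each (chain, resnum, icode, atom name) occurs once.
    """

    atoms: list[Atom]
    frame_id: str = "frame"
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ConsistencyError(f"{self.frame_id}: non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def _build_index(self):
        idx = {}
        for i, a in enumerate(self.atoms):
            idx[(a.residue_key, a.name)] = i
        object.__setattr__(self, "_index", idx)

    def get_atom(self, chain: str, resnum: int, name: str, icode: str = "") -> Atom:
        if self._index is None:
            self._build_index()
        i = self._index.get(((chain, resnum, icode), name))
        if i is None:
            raise KeyError(f"atom {name} of {chain}:{resnum}{icode} not in frame")
        return self.atoms[i]

    def has_atom(self, chain: str, resnum: int, name: str, icode: str = "") -> bool:
        if self._index is None:
            self._build_index()
        return ((chain, resnum, icode), name) in self._index

    def residue_keys(self) -> list[tuple[str, int, str]]:
        seen, keys = set(), []
        for a in self.atoms:
            k = a.residue_key
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    def with_coords(self, coords: np.ndarray, frame_id: str | None = None) -> "StructureFrame":
        """Copy of the frame with replaced coordinates (same atom metadata)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coordinate array {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, xyz=tuple(c)) for a, c in zip(self.atoms, coords)]
        return StructureFrame(atoms, frame_id or self.frame_id)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class BWMap:
    """Ballesteros-Weinstein position -> (chain, author resnum, one-letter aa)."""

    entries: dict[str, tuple[str, int, str]]
    structure_id: str = ""

    def __post_init__(self):
        for bw in self.entries:
            if not _BW_RE.match(bw):
                raise FormatError(f"malformed BW position {bw!r} (expected H.NN, helix 1-8)")
        targets = list(self.entries.values())
        if len(set(targets)) != len(targets):
            raise ConsistencyError("two BW positions map to the same residue")

    def resolve(self, bw: str) -> tuple[str, int, str]:
        if bw not in self.entries:
            raise KeyError(f"BW position {bw} not in map for {self.structure_id or 'structure'}")
        return self.entries[bw]

    def __contains__(self, bw: str) -> bool:
        return bw in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LabelRecord:
    """Activation-state and activity-level annotation for one structure."""

    structure_id: str
    state: str
    activity: float

    def __post_init__(self):
        if self.state not in ACTIVATION_STATES:
            raise FormatError(
                f"{self.structure_id}: unknown state {self.state!r}; "
                f"expected one of {ACTIVATION_STATES}"
            )
        if not 0.0 <= self.activity <= 100.0:
            raise OutOfRangeError(
                f"{self.structure_id}: activity {self.activity} outside [0, 100]"
            )


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    # keep, per (residue, atom name), the highest-occupancy altloc; ties -> 'A'
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in raw_atoms:
        k = (a.residue_key, a.name)
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, -ord(a.altloc or "Z")) > (b.occupancy, -ord(b.altloc or "Z")):
                best[k] = a
    return [best[k] for k in order]


def read_structure(path, model_index: int | None = None, include_het: bool = False) -> StructureFrame:
    """Read one model of a PDB file into a :class:`StructureFrame`.

    Parameters
    ----------
    path
        PDB file (ATOM/HETATM/MODEL records).
    model_index
        Zero-based model to select in multi-model files; default first.
    include_het
        Keep HETATM residues (default: drop them, waters included).

    Altlocs are resolved to the highest-occupancy conformer (ties go to
    label 'A'); coordinates are returned in angstrom.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:  # Biopython raises various types on bad input
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise FormatError(f"{path}: no models found")
    idx = 0 if model_index is None else model_index
    if not 0 <= idx < len(models):
        raise OutOfRangeError(
            f"{path}: model_index {idx} out of range (file has {len(models)} model(s))"
        )
    model = models[idx]

    raw: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if hetflag.strip() and not include_het:
                continue
            for atom in residue.get_unpacked_list():
                x, y, z = (float(v) for v in atom.coord)
                raw.append(
                    Atom(
                        chain=chain.id,
                        resnum=int(resnum),
                        icode=icode.strip(),
                        resname=residue.resname.strip(),
                        name=atom.get_name(),
                        altloc=(atom.get_altloc() or "").strip(),
                        occupancy=float(atom.get_occupancy() or 1.0),
                        xyz=(x, y, z),
                    )
                )
    if not raw:
        raise FormatError(f"{path}: no ATOM records parsed")
    return StructureFrame(_resolve_altlocs(raw), frame_id=f"{path}:{idx}")


def write_structure(frame: StructureFrame, path) -> None:
    """Write a frame as minimal fixed-width PDB ATOM records (%8.3f coords)."""
    with open(path, "w") as fh:
        for i, a in enumerate(frame.atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            element = (a.name.strip() or "X")[0]
            fh.write(
                f"ATOM  {i:5d} {name:<4s}{a.altloc or ' ':1s}{a.resname:<3s} "
                f"{a.chain:1s}{a.resnum:4d}{a.icode or ' ':1s}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {element:>2s}\n"
            )
        fh.write("END\n")


def read_trajectory(topology, trajectory, stride: int = 1) -> list[StructureFrame]:
    """Read an MD trajectory (topology PDB + XTC/DCD) as StructureFrames.

    Frames are yielded in file order; ``stride`` >= 1 subsamples (frames
    0, stride, 2*stride, ...).  mdtraj's nm coordinates are converted to
    angstrom.
    """
    import mdtraj

    if stride < 1:
        raise OutOfRangeError(f"stride must be >= 1, got {stride}")
    try:
        traj = mdtraj.load(str(trajectory), top=str(topology), stride=stride)
    except Exception as exc:
        raise ConsistencyError(
            f"could not load {trajectory} with topology {topology}: {exc}"
        ) from exc

    top = traj.topology
    meta = []
    for atom in top.atoms:
        res = atom.residue
        chain_id = res.chain.chain_id or "A"
        meta.append((chain_id, int(res.resSeq), res.name, atom.name))

    frames = []
    for f in range(traj.n_frames):
        xyz = traj.xyz[f] * 10.0  # nm -> angstrom
        atoms = [
            Atom(chain=c, resnum=rn, icode="", resname=rname, name=aname,
                 altloc="", occupancy=1.0, xyz=(float(p[0]), float(p[1]), float(p[2])))
            for (c, rn, rname, aname), p in zip(meta, xyz)
        ]
        frames.append(StructureFrame(atoms, frame_id=f"{trajectory}:{f * stride}"))
    return frames


def load_bw_map(path, structure_id: str = "") -> BWMap:
    """Load a BW map from 4-column TSV (bw, chain, resnum, aa).

    Duplicate BW positions are a consistency error; malformed BW strings a
    format error.  A header row starting with 'bw' is tolerated.
    """
    entries: dict[str, tuple[str, int, str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "bw":
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            bw, chain, resnum, aa = (c.strip() for c in row[:4])
            if not _BW_RE.match(bw):
                raise FormatError(f"{path}:{lineno}: malformed BW position {bw!r}")
            if bw in entries:
                raise ConsistencyError(f"{path}:{lineno}: duplicate BW position {bw}")
            try:
                entries[bw] = (chain, int(resnum), aa)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad residue number {resnum!r}") from exc
    return BWMap(entries, structure_id=structure_id or str(path))


def extract_tm_domain(
    frame: StructureFrame, tm_ranges: list[tuple[str, int, int]]
) -> StructureFrame:
    """Keep only residues inside the transmembrane ranges.

    ``tm_ranges`` is a list of (chain, first resnum, last resnum),
    inclusive, non-overlapping per chain.  Atom order is preserved; an
    empty result is a warning, not an error.
    """
    by_chain: dict[str, list[tuple[int, int]]] = {}
    for chain, start, end in tm_ranges:
        if end < start:
            raise OutOfRangeError(f"range ({chain},{start},{end}) has end < start")
        by_chain.setdefault(chain, []).append((start, end))
    for chain, ranges in by_chain.items():
        ranges.sort()
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ConsistencyError(
                    f"overlapping TM ranges on chain {chain}: ({s1},{e1}) and ({s2},{e2})"
                )

    def _inside(a: Atom) -> bool:
        return any(s <= a.resnum <= e for s, e in by_chain.get(a.chain, ()))

    kept = [a for a in frame.atoms if _inside(a)]
    if not kept:
        warnings.warn(
            f"{frame.frame_id}: TM extraction produced an empty frame", stacklevel=2
        )
    return StructureFrame(kept, frame_id=frame.frame_id)


def superpose(
    mobile: StructureFrame,
    reference: StructureFrame,
    mobile_map: BWMap,
    reference_map: BWMap,
    positions: list[str] | None = None,
) -> tuple[StructureFrame, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Anchors are the C-alpha atoms of BW positions present in both maps
    (optionally restricted to ``positions``) and resolvable in both
    frames; at least three are required.  Returns the transformed mobile
    frame and the anchor C-alpha RMSD in angstrom.
    """
    shared = sorted(set(mobile_map.entries) & set(reference_map.entries), key=_bw_sort_key)
    if positions is not None:
        shared = [bw for bw in shared if bw in positions]

    mob_pts, ref_pts = [], []
    for bw in shared:
        mc, mr, _ = mobile_map.resolve(bw)
        rc, rr, _ = reference_map.resolve(bw)
        if mobile.has_atom(mc, mr, "CA") and reference.has_atom(rc, rr, "CA"):
            mob_pts.append(mobile.get_atom(mc, mr, "CA").xyz)
            ref_pts.append(reference.get_atom(rc, rr, "CA").xyz)
    if len(mob_pts) < 3:
        raise InsufficientAnchorsError(
            f"only {len(mob_pts)} shared C-alpha anchors; need at least 3"
        )

    mob = np.asarray(mob_pts)
    ref = np.asarray(ref_pts)
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    transformed = rot.apply(mobile.coords - mob_c) + ref_c
    anchors = rot.apply(mob - mob_c) + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((anchors - ref) ** 2, axis=1))))
    return mobile.with_coords(transformed), rmsd


def load_labels(path) -> list[LabelRecord]:
    """Load structure labels from CSV with columns structure_id, state, activity."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"structure_id", "state", "activity"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            activity = float(row.activity)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric activity {row.activity!r}") from exc
        records.append(LabelRecord(str(row.structure_id), str(row.state), activity))
    return records


def _bw_sort_key(bw: str) -> tuple[int, int]:
    helix, pos = bw.split(".")
    return int(helix), int(pos)
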