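"""The conserved-feature schema: polar-network distances and NPxxY angles.

Activation of a class-A GPCR rearranges a conserved network of polar
residues spanning TM1/2/3/6/7 and the NPxxY motif at the cytoplasmic end
of TM7.  The schema measures, for a chosen set of n polar-network
positions, all n(n-1)/2 pairwise C-alpha distances (angstrom), followed
by one backbone O-C-N angle (radian, vertex at the carbonyl carbon) per
NPxxY residue.  With the default 11-residue polar network this gives the
55 + 3 = 58 features the activity models are trained on.

The H3-H6 distance (C-alpha 3.50 to 6.34; ~8.4 A inactive, ~14.1 A
active in the beta-2 adrenergic receptor) is deliberately NOT part of any
training schema: it is reserved as an independent validation coordinate
for model predictions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    MissingFeatureError,
)
from .structure_io import BWMap, StructureFrame, _bw_sort_key

__all__ = [
    "DEFAULT_POLAR_NETWORK",
    "NPXXY_POSITIONS",
    "H3H6_POSITIONS",
    "FeatureSchema",
    "FeatureVector",
    "build_schema",
    "default_schema",
    "ca_distance",
    "ocn_angle",
    "h3h6_distance",
    "featurize_frame",
]

#: Default polar-network positions (11 conserved polar residues across
#: TM1/2/3/6/7 plus the TM7/H8 elbow); configurable per study.
DEFAULT_POLAR_NETWORK = (
    "1.50", "2.40", "2.45", "2.50", "3.32", "3.39",
    "6.48", "7.45", "7.49", "7.53", "8.47",
)

#: The NPxxY motif positions carrying the three backbone-angle features.
NPXXY_POSITIONS = ("7.49", "7.50", "7.53")

#: The classic activation coordinate: helix-3 / helix-6 C-alpha pair.
H3H6_POSITIONS = ("3.50", "6.34")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature definition: distance pairs then angle residues.

    Distance pairs are unordered-unique and canonically sorted by
    (helix, position) of the smaller then larger BW label, so feature
    order — and therefore model inputs and importance rankings — is
    reproducible.
    """

    distance_pairs: tuple[tuple[str, str], ...]
    angle_residues: tuple[str, ...]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"d_{a}_{b}" for a, b in self.distance_pairs) + tuple(
            f"ang_{r}" for r in self.angle_residues
        )

    @property
    def n_distances(self) -> int:
        return len(self.distance_pairs)

    @property
    def n_angles(self) -> int:
        return len(self.angle_residues)

    def __len__(self) -> int:
        return self.n_distances + self.n_angles

    @property
    def fingerprint(self) -> str:
        """Stable hash of the ordered feature names; stored in trained
        models and checked at prediction time."""
        return hashlib.sha256("|".join(self.feature_names).encode()).hexdigest()[:16]

    def positions(self) -> tuple[str, ...]:
        """All BW positions the schema touches, sorted."""
        pos = {p for pair in self.distance_pairs for p in pair}
        pos.update(self.angle_residues)
        return tuple(sorted(pos, key=_bw_sort_key))


@dataclass(frozen=True)
class FeatureVector:
    """One evaluated schema: distances (angstrom) then angles (radian)."""

    values: np.ndarray
    schema: FeatureSchema
    frame_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.schema),):
            raise ConsistencyError(
                f"feature vector length {v.shape} does not match schema size {len(self.schema)}"
            )


def build_schema(
    polar_residues=DEFAULT_POLAR_NETWORK, npxxy_residues=NPXXY_POSITIONS
) -> FeatureSchema:
    """Build the schema from a polar-network residue list and angle residues.

    All unordered pairs of polar residues become distance features, in
    canonical (helix, position) order; each angle residue contributes one
    O-C-N angle feature, in the given order.
    """
    polar = list(polar_residues)
    if not polar:
        raise ConsistencyError("polar-network residue list is empty")
    if len(set(polar)) != len(polar):
        raise ConsistencyError("duplicate BW position in polar-network list")
    if len(set(npxxy_residues)) != len(tuple(npxxy_residues)):
        raise ConsistencyError("duplicate BW position in angle-residue list")

    polar_sorted = sorted(polar, key=_bw_sort_key)
    pairs = tuple(combinations(polar_sorted, 2))
    return FeatureSchema(distance_pairs=pairs, angle_residues=tuple(npxxy_residues))


def default_schema() -> FeatureSchema:
    """The 58-feature schema: 55 polar-network distances + 3 NPxxY angles."""
    return build_schema()


def _resolve_ca(frame: StructureFrame, bw: str, bwmap: BWMap) -> np.ndarray:
    if bw not in bwmap:
        raise MissingFeatureError([bw], f"BW position {bw} absent from map")
    chain, resnum, _ = bwmap.resolve(bw)
    if not frame.has_atom(chain, resnum, "CA"):
        raise MissingFeatureError([bw], f"no C-alpha for BW {bw} ({chain}:{resnum})")
    return np.asarray(frame.get_atom(chain, resnum, "CA").xyz)


def ca_distance(frame: StructureFrame, a: str, b: str, bwmap: BWMap) -> float:
    """Euclidean C-alpha distance (angstrom) between two BW positions."""
    missing = []
    pts = []
    for bw in (a, b):
        try:
            pts.append(_resolve_ca(frame, bw, bwmap))
        except MissingFeatureError:
            missing.append(bw)
    if missing:
        raise MissingFeatureError(missing)
    return float(np.linalg.norm(pts[0] - pts[1]))


def ocn_angle(frame: StructureFrame, res: str, bwmap: BWMap) -> float:
    """Backbone O-C-N angle (radian) of one residue.

    The vertex is the carbonyl carbon C; the angle is between the C->O
    and C->N vectors of the same residue, arccos of the normalised dot
    product, in (0, pi].
    """
    if res not in bwmap:
        raise MissingFeatureError([res], f"BW position {res} absent from map")
    chain, resnum, _ = bwmap.resolve(res)
    coords = {}
    for name in ("O", "C", "N"):
        if not frame.has_atom(chain, resnum, name):
            raise MissingFeatureError([res], f"no backbone {name} for BW {res}")
        coords[name] = np.asarray(frame.get_atom(chain, resnum, name).xyz)
    v1 = coords["O"] - coords["C"]
    v2 = coords["N"] - coords["C"]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError(f"zero-length O-C or N-C vector at BW {res}")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(cosang))


def h3h6_distance(frame: StructureFrame, bwmap: BWMap) -> float:
    """The H3-H6 validation coordinate: C-alpha distance 3.50-6.34.

    Never included in a training FeatureVector; used to sanity-check
    predicted activity against the best-characterised activation
    coordinate (~8.4 A inactive, ~14.1 A active in beta-2 AR).
    """
    return ca_distance(frame, *H3H6_POSITIONS, bwmap)


def featurize_frame(
    frame: StructureFrame,
    schema: FeatureSchema,
    bwmap: BWMap,
    on_missing: str = "error",
) -> FeatureVector | None:
    """Evaluate the schema on one frame.

    ``on_missing='error'`` (default, training data) raises a
    :class:`MissingFeatureError` listing every unresolvable BW position;
    ``on_missing='skip'`` (trajectory scoring) returns None instead.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError(f"on_missing must be 'error' or 'skip', got {on_missing!r}")

    missing: list[str] = []
    distance_positions = sorted(
        {p for pair in schema.distance_pairs for p in pair}, key=_bw_sort_key
    )
    for bw in distance_positions:
        try:
            _ = _resolve_ca(frame, bw, bwmap)
        except MissingFeatureError:
            missing.append(bw)
    for bw in schema.angle_residues:
        if bw in missing:
            continue
        chain, resnum, _ = bwmap.resolve(bw) if bw in bwmap else (None, None, None)
        if chain is None or not all(
            frame.has_atom(chain, resnum, n) for n in ("O", "C", "N")
        ):
            missing.append(bw)
    if missing:
        if on_missing == "skip":
            return None
        raise MissingFeatureError(sorted(set(missing), key=_bw_sort_key))

    values = np.empty(len(schema))
    for i, (a, b) in enumerate(schema.distance_pairs):
        values[i] = ca_distance(frame, a, b, bwmap)
    for j, res in enumerate(schema.angle_residues):
        values[schema.n_distances + j] = ocn_angle(frame, res, bwmap)
    return FeatureVector(values=values, schema=schema, frame_id=frame.frame_id)
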