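"""Synthetic ground-truth data for every stage of the pipeline.

A scalar latent activation coordinate lambda in [0, 1] plays the role of
the receptor's progress from inactive (0) to active (1).  Three
generators expose it at different levels of realism:

* :func:`make_feature_dataset` — labeled 58-feature vectors whose
  distances and angles vary linearly (hence monotonically) in lambda
  with Gaussian noise; activity = 100*lambda (+ noise, clamped), state
  from thresholds on lambda.  Emulates a GPCRdb-style training table.
* :func:`make_toy_structures` — 3D toy receptor frames interpolated
  between an inactive and an active template whose H3-H6 C-alpha
  endpoints are 8.4 and 14.1 angstrom (the crystallographic values for
  the beta-2 adrenergic receptor); exercises the structural I/O and
  featurization path.
* :func:`make_langevin_trajectory` — overdamped Langevin (Euler-
  Maruyama) dynamics on a multi-well 2D potential in (lambda, y), the
  stand-in for an MD ensemble hopping between metastable activation
  states with a known well ordering.

Defaults model three wells at lambda = 0.1 / 0.5 / 0.9 (activities
10/50/90 %), mirroring the inactive / intermediate / active picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, OutOfRangeError, StabilityError
from .features import FeatureSchema, default_schema
from .model import LabeledDataset
from .structure_io import Atom, BWMap, StructureFrame

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "TrajectoryResult",
    "default_loadings",
    "features_from_lam",
    "h3h6_from_lam",
    "state_from_lam",
    "make_feature_dataset",
    "toy_bw_map",
    "make_toy_structures",
    "make_langevin_trajectory",
]

#: H3-H6 C-alpha endpoints (angstrom) at lambda = 0 and 1.
H3H6_INACTIVE = 8.4
H3H6_ACTIVE = 14.1


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic generators.

    Wells are Gaussian depressions on the latent coordinate; depths are
    in units of the Langevin temperature, widths in lambda units.
    ``state_thresholds`` partition [0, 1] into the three activation
    states.  ``sigma_feature`` is the per-feature Gaussian noise
    (angstrom for distances, radian for angles), ``sigma_activity`` the
    label noise in activity percentage points.
    """

    n_samples: int = 555
    well_centers: tuple[float, ...] = (0.1, 0.5, 0.9)
    well_depths: tuple[float, ...] = (2.0, 2.0, 2.0)
    well_widths: tuple[float, ...] = (0.08, 0.08, 0.08)
    sigma_feature: float = 0.2
    sigma_activity: float = 5.0
    state_thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise OutOfRangeError(f"n_samples must be >= 1, got {self.n_samples}")
        if not (len(self.well_centers) == len(self.well_depths) == len(self.well_widths)):
            raise ConsistencyError("well centers, depths and widths must align")
        if any(not 0.0 <= c <= 1.0 for c in self.well_centers):
            raise OutOfRangeError("well centers must lie in [0, 1]")
        if self.sigma_feature < 0 or self.sigma_activity < 0:
            raise OutOfRangeError("noise sigmas must be >= 0")
        t1, t2 = self.state_thresholds
        if not 0.0 < t1 < t2 < 1.0:
            raise OutOfRangeError("state thresholds must satisfy 0 < t1 < t2 < 1")


@dataclass
class GroundTruth:
    """The latent truth behind a generated dataset or trajectory."""

    lam: np.ndarray
    activity: np.ndarray        # 100 * lam, before noise
    state: np.ndarray
    well_index: np.ndarray | None = None
    well_order: tuple[int, ...] | None = None  # wells sorted by true activity


def state_from_lam(lam, thresholds=(1.0 / 3.0, 2.0 / 3.0)) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    t1, t2 = thresholds
    states = np.where(lam < t1, "inactive", np.where(lam < t2, "intermediate", "active"))
    return states.astype(object)


def default_loadings(schema: FeatureSchema) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-feature (baseline, span) arrays.

    Distances span a realistic 3-17 angstrom envelope with alternating
    sign of motion; angle baselines/spans keep values inside
    (0.5, 2.8) rad so clipping at the (0, pi] boundary never triggers.
    """
    nd, na = schema.n_distances, schema.n_angles
    baseline = np.empty(nd + na)
    span = np.empty(nd + na)
    for i in range(nd):
        baseline[i] = 7.0 + (i % 7)
        span[i] = (2.0 + (i % 3)) * (1.0 if i % 2 == 0 else -1.0)
    angle_base = (1.0, 1.2, 1.4, 1.1, 1.6)
    angle_span = (0.9, -0.5, 0.8, 0.6, -0.7)
    for j in range(na):
        baseline[nd + j] = angle_base[j % len(angle_base)]
        span[nd + j] = angle_span[j % len(angle_span)]
    return baseline, span


def features_from_lam(
    lam, schema: FeatureSchema, sigma: float = 0.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Feature matrix baseline + lam*span + N(0, sigma^2); angle columns
    clipped to (0, pi]."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    baseline, span = default_loadings(schema)
    X = baseline[None, :] + lam[:, None] * span[None, :]
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        X = X + rng.normal(0.0, sigma, size=X.shape)
    nd = schema.n_distances
    X[:, :nd] = np.maximum(X[:, :nd], 1e-6)
    X[:, nd:] = np.clip(X[:, nd:], 1e-6, np.pi)
    return X


def h3h6_from_lam(lam, sigma: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """The validation coordinate: 8.4 angstrom at lambda=0, 14.1 at 1."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    h = H3H6_INACTIVE + lam * (H3H6_ACTIVE - H3H6_INACTIVE)
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        h = h + rng.normal(0.0, sigma, size=h.shape)
    return h


def _sample_lam(config: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    depths = np.asarray(config.well_depths, dtype=float)
    weights = depths / depths.sum()
    wells = rng.choice(len(weights), size=config.n_samples, p=weights)
    lam = np.clip(
        rng.normal(np.asarray(config.well_centers)[wells],
                   np.asarray(config.well_widths)[wells]),
        0.0, 1.0,
    )
    return lam, wells


def make_feature_dataset(
    config: GeneratorConfig = GeneratorConfig(),
    schema: FeatureSchema | None = None,
    lam: np.ndarray | None = None,
) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a labeled feature dataset with known latent truth.

    ``lam`` overrides the well-mixture sampling with explicit latent
    values (used by tests that pin the activation coordinate).
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed)
    if lam is None:
        lam, wells = _sample_lam(config, rng)
    else:
        lam = np.asarray(lam, dtype=float)
        wells = np.argmin(
            np.abs(lam[:, None] - np.asarray(config.well_centers)[None, :]), axis=1
        )
    X = features_from_lam(lam, schema, sigma=config.sigma_feature, rng=rng)
    activity = np.clip(
        100.0 * lam
        + (rng.normal(0.0, config.sigma_activity, size=lam.shape)
           if config.sigma_activity > 0 else 0.0),
        0.0, 100.0,
    )
    states = state_from_lam(lam, config.state_thresholds)
    dataset = LabeledDataset(X, states, activity, schema=schema)
    order = tuple(np.argsort(config.well_centers))
    truth = GroundTruth(lam=lam, activity=100.0 * lam, state=states,
                        well_index=wells, well_order=order)
    return dataset, truth


# ---------------------------------------------------------------------------
# toy 3D structures

#: Toy receptor residue table in beta-2-AR-like author numbering:
#: BW position -> (chain, resnum, one-letter aa, three-letter resname).
_TOY_RESIDUES = {
    "1.50": ("A", 51, "N", "ASN"),
    "2.40": ("A", 69, "N", "ASN"),
    "2.45": ("A", 74, "S", "SER"),
    "2.50": ("A", 79, "D", "ASP"),
    "3.32": ("A", 113, "D", "ASP"),
    "3.39": ("A", 120, "S", "SER"),
    "3.50": ("A", 131, "R", "ARG"),
    "6.34": ("A", 272, "L", "LEU"),
    "6.48": ("A", 286, "W", "TRP"),
    "7.45": ("A", 318, "N", "ASN"),
    "7.49": ("A", 322, "N", "ASN"),
    "7.50": ("A", 323, "P", "PRO"),
    "7.53": ("A", 326, "Y", "TYR"),
    "8.47": ("A", 329, "S", "SER"),
}

#: O-C-N angle (rad) of selected residues in the inactive / active
#: templates; residues not listed keep 2.0 in both.
_TOY_ANGLES = {
    "7.49": (1.9, 2.3),
    "7.50": (2.0, 1.6),
    "7.53": (1.7, 2.1),
    "8.47": (1.8, 2.2),
    "2.40": (2.4, 2.0),
}


def toy_bw_map() -> BWMap:
    """BW map of the 14-residue toy receptor."""
    return BWMap(
        {bw: (chain, resnum, aa) for bw, (chain, resnum, aa, _) in _TOY_RESIDUES.items()},
        structure_id="toy-receptor",
    )


def _toy_templates() -> tuple[dict, dict]:
    """Per-atom coordinates of the inactive and active templates.

    C-alpha positions are a fixed pseudo-random bundle except for the
    H3-H6 pair, which is pinned to 8.4 / 14.1 angstrom separation.
    Backbone N and C sit at fixed offsets from C-alpha; O is placed in
    the xy-plane so the O-C-N angle matches the template value.
    """
    rng = np.random.default_rng(20230410)
    inactive, active = {}, {}
    n_off = np.array([-1.2, 0.8, 0.0])
    c_off = np.array([1.2, 0.5, 0.0])

    for bw, (chain, resnum, _, resname) in _TOY_RESIDUES.items():
        if bw == "3.50":
            ca_i = ca_a = np.zeros(3)
        elif bw == "6.34":
            ca_i = np.array([H3H6_INACTIVE, 0.0, 0.0])
            ca_a = np.array([H3H6_ACTIVE, 0.0, 0.0])
        else:
            ca_i = rng.uniform(-12.0, 12.0, size=3)
            ca_a = ca_i + rng.normal(0.0, 1.5, size=3)
        th_i, th_a = _TOY_ANGLES.get(bw, (2.0, 2.0))
        for tmpl, ca, theta in ((inactive, ca_i, th_i), (active, ca_a, th_a)):
            n = ca + n_off
            c = ca + c_off
            u_n = (n - c) / np.linalg.norm(n - c)
            rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                            [np.sin(theta), np.cos(theta), 0.0],
                            [0.0, 0.0, 1.0]])
            o = c + 1.23 * (rot @ u_n)
            tmpl[bw] = {"N": n, "CA": ca, "C": c, "O": o,
                        "chain": chain, "resnum": resnum, "resname": resname}
    return inactive, active


def make_toy_structures(
    lams, jitter_sigma: float = 0.0, seed: int = 0
) -> tuple[list[StructureFrame], BWMap]:
    """Toy receptor frames at given lambda values.

    Coordinates interpolate linearly between the inactive (lambda=0) and
    active (lambda=1) templates, plus isotropic Gaussian jitter of
    ``jitter_sigma`` angstrom per atom.
    """
    inactive, active = _toy_templates()
    rng = np.random.default_rng(seed)
    frames = []
    for k, lam in enumerate(np.atleast_1d(np.asarray(lams, dtype=float))):
        atoms = []
        for bw in _TOY_RESIDUES:
            res_i, res_a = inactive[bw], active[bw]
            for name in ("N", "CA", "C", "O"):
                xyz = (1.0 - lam) * res_i[name] + lam * res_a[name]
                if jitter_sigma > 0:
                    xyz = xyz + rng.normal(0.0, jitter_sigma, size=3)
                atoms.append(Atom(
                    chain=res_i["chain"], resnum=res_i["resnum"], icode="",
                    resname=res_i["resname"], name=name, altloc="",
                    occupancy=1.0, xyz=tuple(float(v) for v in xyz),
                ))
        frames.append(StructureFrame(atoms, frame_id=f"toy:{k}:lam={lam:.4f}"))
    return frames, toy_bw_map()


# ---------------------------------------------------------------------------
# Langevin dynamics


@dataclass
class TrajectoryResult:
    """A Langevin trajectory with its ground truth.

    ``lam``/``y`` are the sampled coordinates (after the optional
    stride); ``features``/``h3h6`` are present in fast (feature-space)
    mode.  ``truth.well_index`` assigns each frame to its nearest well.
    """

    lam: np.ndarray
    y: np.ndarray
    truth: GroundTruth
    features: np.ndarray | None = None
    h3h6: np.ndarray | None = None
    config: GeneratorConfig | None = None


def _well_gradient(lam: float, centers, depths, widths) -> tuple[float, float]:
    u, du = 0.0, 0.0
    for c, d, w in zip(centers, depths, widths):
        g = np.exp(-((lam - c) ** 2) / (2.0 * w * w))
        u -= d * g
        du += d * g * (lam - c) / (w * w)
    return u, du


def make_langevin_trajectory(
    config: GeneratorConfig = GeneratorConfig(),
    n_steps: int = 50_000,
    dt: float = 2e-3,
    temperature: float = 0.6,
    y_stiffness: float = 4.0,
    lam0: float | None = None,
    stride: int = 10,
    schema: FeatureSchema | None = None,
    emit_features: bool = True,
    seed: int | None = None,
) -> TrajectoryResult:
    """Overdamped Langevin sampling of the multi-well latent potential.

    U(lambda, y) = sum_k -d_k exp(-(lambda-c_k)^2 / 2 w_k^2)
                   + y_stiffness/2 * y^2,

    integrated by Euler-Maruyama, z <- z - grad U dt + sqrt(2 T dt) eta,
    with lambda clipped to [0, 1] each step.  Every ``stride``-th point
    is kept.  In fast mode the kept points are mapped straight to the
    58-feature space (plus the H3-H6 coordinate) with the configured
    feature noise; pass the result of ``lam`` to
    :func:`make_toy_structures` for the 3D integration mode instead.
    """
    if n_steps < 1:
        raise OutOfRangeError("n_steps must be >= 1")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    centers = np.asarray(config.well_centers, dtype=float)
    depths = np.asarray(config.well_depths, dtype=float)
    widths = np.asarray(config.well_widths, dtype=float)

    lam = float(centers[0]) if lam0 is None else float(lam0)
    y = 0.0
    amp = np.sqrt(2.0 * temperature * dt)
    noise = rng.normal(size=(n_steps, 2))
    lam_out = np.empty(n_steps)
    y_out = np.empty(n_steps)
    for t in range(n_steps):
        _, du = _well_gradient(lam, centers, depths, widths)
        lam = lam - du * dt + amp * noise[t, 0]
        y = y - y_stiffness * y * dt + amp * noise[t, 1]
        if not (np.isfinite(lam) and np.isfinite(y)) or abs(lam) > 1e3 or abs(y) > 1e3:
            raise StabilityError(f"Langevin integration diverged at step {t}; reduce dt")
        lam = min(max(lam, 0.0), 1.0)
        lam_out[t] = lam
        y_out[t] = y

    lam_s = lam_out[::stride]
    y_s = y_out[::stride]
    wells = np.argmin(np.abs(lam_s[:, None] - centers[None, :]), axis=1)
    truth = GroundTruth(
        lam=lam_s, activity=100.0 * lam_s,
        state=state_from_lam(lam_s, config.state_thresholds),
        well_index=wells, well_order=tuple(np.argsort(centers)),
    )
    features = h3h6 = None
    if emit_features:
        schema = schema or default_schema()
        features = features_from_lam(lam_s, schema, sigma=config.sigma_feature, rng=rng)
        h3h6 = h3h6_from_lam(lam_s, sigma=config.sigma_feature, rng=rng)
    return TrajectoryResult(lam=lam_s, y=y_s, truth=truth,
                            features=features, h3h6=h3h6, config=config)
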