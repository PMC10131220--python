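"""Activity-annotated density histograms over structural coordinates.

Frames of an MD ensemble are scored with a fitted structure-activity
model, then binned over one or two structural coordinates (typically the
H3-H6 distance on one axis and a backbone O-C-N angle on the other).
The resulting :class:`DensityLandscape` is a probability-density
histogram — interpretable as a population / free-energy-like map — in
which each occupied cell also carries the mean predicted activity of its
frames.  Re-binning at the small fixed cell area used for activity
averaging (3e-3 rad*angstrom by default elsewhere) is exact because the
landscape retains its source samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, OutOfRangeError
from .features import featurize_frame, h3h6_distance, ca_distance, ocn_angle

__all__ = [
    "FrameScores",
    "Landscape1D",
    "DensityLandscape",
    "score_frames",
    "histogram1d",
    "histogram2d",
    "cell_activity_map",
    "state_conditional_correlation",
]


@dataclass
class FrameScores:
    """Per-frame model predictions plus structural coordinates.

    ``table`` has one row per scored frame with columns ``frame_id``,
    ``activity`` (%), ``state``, and one column per requested axis
    (e.g. ``h3h6`` in angstrom, ``angle:8.47`` in radian).  ``skipped``
    records (frame_id, reason) for frames that could not be featurized.
    """

    table: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def axis(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    @property
    def activities(self) -> np.ndarray:
        return self.table["activity"].to_numpy(dtype=float)


def _axis_value(frame, bwmap, axis: str, vector=None, schema=None) -> float:
    """Evaluate one axis spec on a frame.

    Accepted specs: ``h3h6``; ``angle:BW`` (O-C-N angle of any mapped
    residue); ``dist:BW-BW``; or a schema feature name (``d_a_b`` /
    ``ang_r``) taken from an already-computed feature vector.
    """
    if axis == "h3h6":
        return h3h6_distance(frame, bwmap)
    if axis.startswith("angle:"):
        return ocn_angle(frame, axis.split(":", 1)[1], bwmap)
    if axis.startswith("dist:"):
        a, b = axis.split(":", 1)[1].split("-")
        return ca_distance(frame, a, b, bwmap)
    if vector is not None and schema is not None and axis in schema.feature_names:
        return float(vector.values[schema.feature_names.index(axis)])
    raise KeyError(f"unrecognised axis spec {axis!r}")


def score_frames(results, frames, schema, bwmap, axes=("h3h6",)) -> FrameScores:
    """Score every frame of a trajectory with a fitted model.

    Frames whose schema features cannot all be resolved are skipped and
    logged with a reason; an entirely unscorable input is an error.
    """
    rows, skipped = [], []
    for frame in frames:
        vec = featurize_frame(frame, schema, bwmap, on_missing="skip")
        if vec is None:
            skipped.append((frame.frame_id, "unresolvable schema features"))
            continue
        try:
            axis_vals = {ax: _axis_value(frame, bwmap, ax, vec, schema) for ax in axes}
        except KeyError as exc:
            skipped.append((frame.frame_id, str(exc)))
            continue
        rows.append({
            "frame_id": frame.frame_id,
            "activity": results.predict_activity(vec),
            "state": results.predict_state(vec),
            **axis_vals,
        })
    if not rows:
        raise EmptyResultError("no frame could be scored")
    return FrameScores(pd.DataFrame(rows), skipped=skipped)


@dataclass
class Landscape1D:
    """1D density histogram with per-bar mean predicted activity."""

    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    activity_mean: np.ndarray  # NaN where a bar is empty
    n_total: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def histogram1d(values, activities, bins=50) -> Landscape1D:
    """Density histogram of one coordinate, bars annotated with the mean
    activity of their member frames (activity is never imputed for empty
    bars)."""
    values = np.asarray(values, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if values.size == 0:
        raise EmptyResultError("histogram1d: empty input")
    if values.shape != activities.shape:
        raise OutOfRangeError("values and activities must have the same length")

    counts, edges = np.histogram(values, bins=bins)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    act_sum, _ = np.histogram(values, bins=edges, weights=activities)
    with np.errstate(invalid="ignore"):
        activity_mean = np.where(counts > 0, act_sum / np.maximum(counts, 1), np.nan)
    return Landscape1D(edges=edges, counts=counts, density=density,
                       activity_mean=activity_mean, n_total=int(counts.sum()))


@dataclass
class DensityLandscape:
    """2D probability-density histogram with per-cell mean activity.

    Invariants: sum(density * cell_area) == 1; mean activity defined only
    where the cell count is positive (NaN elsewhere).  ``samples`` keeps
    the underlying (x, y, activity) points so re-binning conserves counts
    exactly.
    """

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray          # (nx, ny)
    density: np.ndarray
    activity_mean: np.ndarray   # NaN where empty
    n_total: int
    n_filtered: int = 0
    samples: tuple | None = None  # (x, y, activities) after filtering

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def cell_area(self, i: int, j: int) -> float:
        return float(np.diff(self.x_edges)[i] * np.diff(self.y_edges)[j])

    def to_frame(self) -> pd.DataFrame:
        """Long-form per-cell table (cell indices, centers, count, density,
        mean activity) for CSV export."""
        ii, jj = np.meshgrid(range(self.shape[0]), range(self.shape[1]), indexing="ij")
        return pd.DataFrame({
            "i": ii.ravel(),
            "j": jj.ravel(),
            self.x_name: self.x_centers[ii.ravel()],
            self.y_name: self.y_centers[jj.ravel()],
            "count": self.counts.ravel(),
            "density": self.density.ravel(),
            "activity_mean": self.activity_mean.ravel(),
        })


def histogram2d(x, y, activities, bins=50, x_name="x", y_name="y") -> DensityLandscape:
    """Build a 2D density landscape with per-cell mean predicted activity.

    ``bins`` is anything :func:`numpy.histogram2d` accepts (int, pair of
    ints, or explicit edge arrays).  Non-finite points are filtered out
    and counted in ``n_filtered``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if not (x.shape == y.shape == activities.shape):
        raise OutOfRangeError("x, y and activities must have equal length")
    if x.size == 0:
        raise EmptyResultError("histogram2d: empty input")

    finite = np.isfinite(x) & np.isfinite(y) & np.isfinite(activities)
    n_filtered = int(np.sum(~finite))
    x, y, activities = x[finite], y[finite], activities[finite]
    if x.size == 0:
        raise EmptyResultError("histogram2d: no finite points")

    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    areas = np.outer(np.diff(x_edges), np.diff(y_edges))
    density = counts / (counts.sum() * areas)
    act_sum, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=activities)
    with np.errstate(invalid="ignore"):
        activity_mean = np.where(counts > 0, act_sum / np.maximum(counts, 1), np.nan)
    return DensityLandscape(
        x_name=x_name, y_name=y_name, x_edges=x_edges, y_edges=y_edges,
        counts=counts, density=density, activity_mean=activity_mean,
        n_total=int(counts.sum()), n_filtered=n_filtered,
        samples=(x, y, activities),
    )


def cell_activity_map(
    landscape: DensityLandscape, cell_area: float = 3e-3, aspect: float = 0.3
) -> DensityLandscape:
    """Re-bin a landscape so every cell has the given area.

    ``cell_area`` is in x-unit * y-unit (rad*angstrom for the default
    angle-vs-distance axes; the conventional averaging area is 3e-3).
    ``aspect`` fixes the cell shape as dx/dy (default 0.3, i.e.
    dx = 0.03 rad by dy = 0.1 angstrom at the default area).  Counts are
    conserved exactly because re-binning uses the stored samples.
    """
    if cell_area <= 0:
        raise OutOfRangeError(f"cell_area must be > 0, got {cell_area}")
    if landscape.samples is None:
        raise EmptyResultError("landscape does not retain samples; rebuild with histogram2d")
    x, y, activities = landscape.samples

    dx = float(np.sqrt(cell_area * aspect))
    dy = cell_area / dx
    x_lo, x_hi = landscape.x_edges[0], landscape.x_edges[-1]
    y_lo, y_hi = landscape.y_edges[0], landscape.y_edges[-1]
    nx = max(1, int(np.ceil((x_hi - x_lo) / dx - 1e-9)))
    ny = max(1, int(np.ceil((y_hi - y_lo) / dy - 1e-9)))
    if nx == 1 and ny == 1:
        warnings.warn("cell_area covers the whole domain: single-cell grid", stacklevel=2)
    x_edges = x_lo + dx * np.arange(nx + 1)
    y_edges = y_lo + dy * np.arange(ny + 1)
    # widen the last edge minutely so boundary points stay binned
    x_edges[-1] = max(x_edges[-1], x_hi) + 1e-12
    y_edges[-1] = max(y_edges[-1], y_hi) + 1e-12
    return histogram2d(x, y, activities, bins=(x_edges, y_edges),
                       x_name=landscape.x_name, y_name=landscape.y_name)


def save_landscape(landscape: DensityLandscape, path) -> None:
    """Write a landscape as a grid file: '#'-prefixed axis metadata
    (names and bin edges) followed by the per-cell CSV table."""
    with open(path, "w") as fh:
        fh.write(f"# x_name={landscape.x_name}\n")
        fh.write(f"# y_name={landscape.y_name}\n")
        fh.write("# x_edges=" + ",".join(repr(float(e)) for e in landscape.x_edges) + "\n")
        fh.write("# y_edges=" + ",".join(repr(float(e)) for e in landscape.y_edges) + "\n")
        fh.write(f"# n_total={landscape.n_total}\n")
        landscape.to_frame().to_csv(fh, index=False)


def load_landscape(path) -> DensityLandscape:
    """Read a grid file written by :func:`save_landscape`.

    The reloaded landscape carries no raw samples, so it supports peak
    finding and pathway construction but not exact re-binning.
    """
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh)
    x_edges = np.array([float(v) for v in meta["x_edges"].split(",")])
    y_edges = np.array([float(v) for v in meta["y_edges"].split(",")])
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    counts = np.zeros((nx, ny))
    activity = np.full((nx, ny), np.nan)
    counts[table["i"], table["j"]] = table["count"]
    activity[table["i"], table["j"]] = table["activity_mean"]
    areas = np.outer(np.diff(x_edges), np.diff(y_edges))
    density = counts / (counts.sum() * areas)
    return DensityLandscape(
        x_name=meta.get("x_name", "x"), y_name=meta.get("y_name", "y"),
        x_edges=x_edges, y_edges=y_edges, counts=counts, density=density,
        activity_mean=activity, n_total=int(counts.sum()),
    )


def state_conditional_correlation(
    scores: FrameScores, axis: str = "h3h6"
) -> dict[str, float | None]:
    """Pearson correlation between one coordinate and predicted activity,
    separately per predicted state.

    States with fewer than two frames are omitted; zero-variance inputs
    make the correlation undefined and are reported as None.
    """
    from scipy.stats import pearsonr

    out: dict[str, float | None] = {}
    for state, group in scores.table.groupby("state", sort=False):
        if len(group) < 2:
            continue
        v = group[axis].to_numpy(dtype=float)
        a = group["activity"].to_numpy(dtype=float)
        if np.std(v) == 0.0 or np.std(a) == 0.0:
            out[str(state)] = None
            continue
        out[str(state)] = float(pearsonr(v, a).statistic)
    return out
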