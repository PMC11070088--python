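"""Infiltration and marker-ratio metrics on projected assembloid images.

All intensity metrics are ratios against the DAPI (nuclear) channel:

* per-shell infiltration: mean(eGFP) / mean(DAPI) over the pixels of each
  concentric shell (ratio of means over the same pixel set, robust to
  isolated zero-DAPI pixels);
* total infiltration past a threshold: the same ratio over the union of
  interior pixels at depth >= threshold (µm or percent of max depth);
* marker ratio: total marker signal / total DAPI signal over a region
  (whole image, organoid interior, or an interface band of given width),
  then normalized within each group to its untreated arm;
* per-cell H3K27M infiltration distances: threshold + connected components
  + centroid, then minimum Euclidean distance of each interior centroid to
  the boundary (for a smooth boundary, the foot of the orthogonal from the
  boundary to the cell is its nearest boundary point, so this matches a
  hand-drawn orthogonal-line measurement up to polygon discretization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .geometry import (
    DistanceField,
    Projection2D,
    ShellBinning,
    distances_to_boundary,
    percent_depth,
    points_in_polygon,
)
from .io import BoundaryROI, ExperimentManifest

PAST_UM = "past_um"
PAST_PERCENT = "past_percent"


class EmptyRegionError(ValueError):
    """No pixels qualify for the requested region/threshold."""


@dataclass
class ShellProfile:
    """Per-shell pixel counts and per-channel mean intensities."""

    table: pd.DataFrame          # columns: shell, count, mean_<channel>...
    mode: str
    edges: np.ndarray
    channels: list[str]


@dataclass
class MarkerRatioResult:
    """Per-image marker/DAPI ratios with within-group control normalization."""

    per_image: pd.DataFrame      # image, group, treatment, ratio, relative
    marker: str
    region: str


# --------------------------------------------------------------------------
# shell profiles and infiltration metrics
# --------------------------------------------------------------------------

def shell_profile(
    projection: Projection2D,
    binning: ShellBinning,
    channels: list[str] | None = None,
) -> ShellProfile:
    """Arithmetic per-shell, per-channel means over pixel centers."""
    if binning.shell_label.shape != projection.shape:
        raise ValueError("binning shape does not match projection shape")
    if channels is None:
        channels = list(projection.channel_names)
    labels = binning.shell_label
    interior = labels >= 0
    lab = labels[interior]
    counts = np.bincount(lab, minlength=binning.n_shells)
    rows = {"shell": np.arange(binning.n_shells), "count": counts}
    for ch in channels:
        img = projection.channel(ch)  # raises KeyError if absent
        sums = np.bincount(lab, weights=img[interior], minlength=binning.n_shells)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows[f"mean_{ch}"] = means
    return ShellProfile(
        table=pd.DataFrame(rows), mode=binning.mode,
        edges=binning.edges, channels=list(channels),
    )


def infiltration_metric(
    profile: ShellProfile,
    tumor_channel: str = "eGFP",
    nuclear_channel: str = "DAPI",
) -> pd.Series:
    """Per-shell mean(tumor) / mean(nuclear); NaN where the nuclear mean is
    zero or the shell is empty (never 0 or inf)."""
    for ch in (tumor_channel, nuclear_channel):
        if f"mean_{ch}" not in profile.table.columns:
            raise KeyError(f"channel {ch!r} not profiled")
    num = profile.table[f"mean_{tumor_channel}"].to_numpy(dtype=float)
    den = profile.table[f"mean_{nuclear_channel}"].to_numpy(dtype=float)
    ok = np.isfinite(den) & (den > 0)
    if not ok.any():
        raise EmptyRegionError("all shells have zero nuclear signal")
    metric = np.full(len(num), np.nan)
    metric[ok] = num[ok] / den[ok]
    return pd.Series(metric, index=profile.table["shell"], name="infiltration")


def total_infiltration(
    projection: Projection2D,
    fld: DistanceField,
    threshold: float = 0.0,
    mode: str = PAST_UM,
    tumor_channel: str = "eGFP",
    nuclear_channel: str = "DAPI",
) -> float:
    """mean(tumor)/mean(nuclear) over interior pixels past a depth threshold.

    ``mode="past_um"`` thresholds on absolute depth (µm); ``"past_percent"``
    on depth as a fraction of the image's maximum depth (threshold in
    [0, 1]). Threshold 0 covers the whole interior.
    """
    if mode == PAST_UM:
        depth = fld.depth_um
        if not 0 <= threshold <= fld.max_depth_um:
            raise ValueError(
                f"threshold {threshold} outside [0, {fld.max_depth_um}] µm"
            )
    elif mode == PAST_PERCENT:
        depth = percent_depth(fld)
        if not 0 <= threshold <= 1:
            raise ValueError("percent threshold must be in [0, 1]")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qualifying = fld.interior_mask & (depth >= threshold)
    n = int(qualifying.sum())
    if n == 0:
        raise EmptyRegionError(f"no interior pixels at depth >= {threshold}")
    num = float(projection.channel(tumor_channel)[qualifying].mean())
    den = float(projection.channel(nuclear_channel)[qualifying].mean())
    if den <= 0:
        raise EmptyRegionError("zero nuclear signal in qualifying region")
    return num / den


def fit_decay_length(
    projection: Projection2D,
    fld: DistanceField,
    thresholds_um: np.ndarray | None = None,
    tumor_channel: str = "eGFP",
    nuclear_channel: str = "DAPI",
) -> float:
    """Estimate the exponential depth-decay scale (µm) of infiltration.

    For cells whose depth is Exp(lambda), the total tumor signal past depth
    T decays as exp(-T/lambda) while the nuclear signal tracks the
    qualifying area, so log(metric(T) * area(T)) is linear in T with slope
    -1/lambda. The fit pools (sum tumor, sum nuclear, count) over a
    threshold grid; see :func:`pooled_decay_curve` for multi-scene pooling.
    """
    curve = decay_curve(projection, fld, thresholds_um, tumor_channel,
                        nuclear_channel)
    return decay_length_from_curve(curve)


def decay_curve(
    projection: Projection2D,
    fld: DistanceField,
    thresholds_um: np.ndarray | None = None,
    tumor_channel: str = "eGFP",
    nuclear_channel: str = "DAPI",
) -> pd.DataFrame:
    """Per-threshold (sum tumor, sum nuclear, pixel count) table."""
    if thresholds_um is None:
        # reach close to the maximum depth: the deepest thresholds carry
        # almost pure background and anchor the background coefficient
        thresholds_um = np.linspace(0.0, 0.9 * fld.max_depth_um, 19)
    tumor = projection.channel(tumor_channel)
    nuclear = projection.channel(nuclear_channel)
    rows = []
    for t in thresholds_um:
        q = fld.interior_mask & (fld.depth_um >= t)
        n = int(q.sum())
        if n == 0:
            continue
        rows.append({
            "threshold_um": float(t),
            "sum_tumor": float(tumor[q].sum()),
            "sum_nuclear": float(nuclear[q].sum()),
            "count": n,
            "max_depth_um": fld.max_depth_um,
        })
    return pd.DataFrame(rows)


def pooled_decay_length(
    scenes: list[tuple[Projection2D, DistanceField]],
    tumor_channel: str = "eGFP",
    nuclear_channel: str = "DAPI",
) -> float:
    """Decay length pooled over several scenes on a shared threshold grid.

    Sums (tumor signal, nuclear signal, pixel count) across scenes at each
    threshold before fitting, which averages out per-scene sampling noise.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    shallowest = min(fld.max_depth_um for _, fld in scenes)
    grid = np.linspace(0.0, 0.9 * shallowest, 19)
    curves = [
        decay_curve(proj, fld, thresholds_um=grid,
                    tumor_channel=tumor_channel,
                    nuclear_channel=nuclear_channel)
        for proj, fld in scenes
    ]
    pooled = (
        pd.concat(curves)
        .groupby("threshold_um", as_index=False)
        .agg({"sum_tumor": "sum", "sum_nuclear": "sum", "count": "sum",
              "max_depth_um": "mean"})
    )
    return decay_length_from_curve(pooled)


def decay_length_from_curve(
    curve: pd.DataFrame, max_depth_um: float | None = None
) -> float:
    """Fit the infiltration decay length (µm) from a threshold curve.

    Model: cells at exponential depth cannot lie deeper than the organoid's
    maximum depth D, so the tumor signal past threshold T is

        s(T) = a * (exp(-T/lambda) - exp(-D/lambda)) + b * count(T),

    where the second term is the constant per-pixel background (camera
    offset plus noise floor) carried by every qualifying pixel. For fixed
    lambda the model is linear in (a, b), so lambda is found by a global
    grid scan with per-lambda non-negative linear solves, then refined —
    no local-minimum risk from the a/b collinearity.
    """
    t = curve["threshold_um"].to_numpy(dtype=float)
    s = curve["sum_tumor"].to_numpy(dtype=float)
    n = curve["count"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 thresholds to fit a decay length")
    if max_depth_um is None:
        max_depth_um = float(curve.get("max_depth_um", pd.Series([np.inf])).max())
    D = max_depth_um
    w = 1.0 / np.maximum(s, 1.0)

    def sse(lam: float) -> tuple[float, np.ndarray]:
        shape = np.exp(-t / lam) - (np.exp(-D / lam) if np.isfinite(D) else 0.0)
        X = np.column_stack([shape, n]) * np.sqrt(w)[:, None]
        y = s * np.sqrt(w)
        coef, rnorm = optimize.nnls(X, y)
        return float(rnorm**2), coef

    grid = np.geomspace(max(t[1] - t[0], 1.0) / 2.0, 10.0 * (t[-1] - t[0]), 120)
    errs = [sse(l)[0] for l in grid]
    i = int(np.argmin(errs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda l: sse(l)[0], bounds=(lo, hi),
                                   method="bounded")
    return float(res.x)


# --------------------------------------------------------------------------
# marker ratios
# --------------------------------------------------------------------------

def _region_mask(
    projection: Projection2D, region, fld: DistanceField | None
) -> np.ndarray:
    if region == "whole_image":
        return np.ones(projection.shape, dtype=bool)
    if fld is None:
        raise ValueError(f"region {region!r} requires a DistanceField")
    if region == "interior":
        return fld.interior_mask
    if isinstance(region, tuple) and region[0] == "interface_band":
        width_um = float(region[1])
        return fld.interior_mask & (fld.depth_um <= width_um)
    raise ValueError(f"unknown region {region!r}")


def marker_ratio(
    projection: Projection2D,
    marker_channel: str,
    region="whole_image",
    fld: DistanceField | None = None,
    nuclear_channel: str = "DAPI",
    background=None,
) -> float:
    """Total marker signal / total DAPI signal over the region's pixels.

    ``region`` is ``"whole_image"``, ``"interior"``, or
    ``("interface_band", width_um)`` — interior pixels within ``width_um``
    of the boundary, emulating fields of view at the fusion interface.

    ``background`` optionally subtracts a constant per-pixel offset from
    each channel before summing: a number, ``"median"`` (each channel's
    image median, a robust offset estimate when most pixels are
    unstained), or None (raw sums; note a nonzero camera offset then
    attenuates between-group ratio differences toward 1).
    """
    mask = _region_mask(projection, region, fld)
    if not mask.any():
        raise EmptyRegionError(f"region {region!r} contains no pixels")

    def channel_sum(name: str) -> float:
        img = projection.channel(name)
        if background is None:
            offset = 0.0
        elif background == "median":
            offset = float(np.median(img))
        else:
            offset = float(background)
        return float(np.clip(img[mask] - offset, 0.0, None).sum())

    marker_sum = channel_sum(marker_channel)
    dapi_sum = channel_sum(nuclear_channel)
    if dapi_sum <= 0:
        raise EmptyRegionError("total DAPI signal is zero in region")
    return marker_sum / dapi_sum


def normalize_to_control(
    ratios: pd.DataFrame,
    marker: str = "",
    region: str = "",
) -> MarkerRatioResult:
    """Within-group normalization to the untreated arm.

    ``ratios`` needs columns ``group``, ``is_untreated`` and ``ratio``
    (plus any identifiers). Each image's relative value is its ratio
    divided by the mean ratio of the *same group's* untreated images, so
    every group's untreated mean is exactly 1. Normalization never crosses
    groups.
    """
    df = ratios.copy()
    for col in ("group", "is_untreated", "ratio"):
        if col not in df.columns:
            raise ValueError(f"ratios table missing column {col!r}")
    rel = np.full(len(df), np.nan)
    for g, sub in df.groupby("group", sort=False):
        untreated = sub.loc[sub["is_untreated"].astype(bool), "ratio"]
        if len(untreated) == 0:
            raise ValueError(f"group {g!r} has no untreated images")
        rel[sub.index.to_numpy()] = sub["ratio"].to_numpy() / untreated.mean()
    df["relative"] = rel
    return MarkerRatioResult(per_image=df, marker=marker, region=str(region))


# --------------------------------------------------------------------------
# per-cell H3K27M infiltration distances
# --------------------------------------------------------------------------

@dataclass
class CellDistanceResult:
    """Per-cell infiltration distances for detected marker+ cells."""

    distances_um: np.ndarray
    centroids: np.ndarray          # (n, 2) interior centroids as (y, x)
    n_exterior: int
    threshold: float


def h3k27m_distances(
    projection: Projection2D,
    roi: BoundaryROI,
    marker_channel: str = "H3K27M",
    threshold_method: str = "otsu",
    min_area_px: int = 4,
) -> CellDistanceResult:
    """Detect marker+ cells and measure each one's infiltration distance.

    Pipeline: global threshold (Otsu by default) -> connected components of
    at least ``min_area_px`` pixels -> intensity-weighted centroid -> for
    centroids inside the boundary, minimum Euclidean distance to the
    boundary in µm. Exterior centroids are excluded and counted. An image
    with no detected components returns an empty result, not an error.
    """
    img = projection.channel(marker_channel)
    if threshold_method == "otsu":
        if np.ptp(img) == 0:
            return CellDistanceResult(np.empty(0), np.empty((0, 2)), 0, np.nan)
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold_method)  # numeric threshold accepted
    mask = img > thr
    labels = cc_label(mask)
    centroids = []
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < min_area_px:
            continue
        cy, cx = prop.centroid_weighted
        centroids.append((cy, cx))
    if not centroids:
        return CellDistanceResult(np.empty(0), np.empty((0, 2)), 0, thr)
    cyx = np.asarray(centroids)
    xy = cyx[:, ::-1]
    inside = points_in_polygon(xy, roi)
    d_px = distances_to_boundary(xy[inside], roi)
    return CellDistanceResult(
        distances_um=d_px * projection.pixel_size_um,
        centroids=cyx[inside],
        n_exterior=int((~inside).sum()),
        threshold=thr,
    )


# --------------------------------------------------------------------------
# manifest-level driver
# --------------------------------------------------------------------------

def quantify_manifest_markers(
    manifest: ExperimentManifest,
    marker: str,
    region="whole_image",
    reader=None,
    background=None,
) -> MarkerRatioResult:
    """Compute per-image marker ratios for every manifest record and
    normalize within groups to the untreated arm."""
    from .geometry import interior_distance_field, max_project
    from .io import read_roi, read_stack

    reader = reader or read_stack
    rows = []
    for _, rec in manifest.records.iterrows():
        stack = reader(manifest.resolve(str(rec["image"])))
        proj = max_project(stack)
        fld = None
        if region != "whole_image":
            roi = read_roi(manifest.resolve(str(rec["roi"])))
            fld = interior_distance_field(roi, proj.shape, proj.pixel_size_um)
        rows.append({
            "image": rec["image"],
            "group": rec["group"],
            "treatment": rec["treatment"],
            "is_untreated": bool(rec["is_untreated"]),
            "ratio": marker_ratio(proj, marker, region=region, fld=fld,
                                  background=background),
        })
    return normalize_to_control(pd.DataFrame(rows), marker=marker,
                                region=str(region))
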