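"""Synthetic assembloid scenes, migration time-lapses and dose–viability
tables with known ground truth.

The generator emulates the statistical structure the analysis assumes, not
the optics of a confocal microscope:

* an organoid region enclosed by a simple polygon (a jittered ellipse by
  default, matching hand-drawn boundaries around roughly round organoids);
* infiltrating GFP+ tumor cells whose depth inward from the boundary is
  exponentially distributed (scale = ``decay_length_um``) and whose position
  along the boundary is uniform in arc length;
* DAPI+ nuclei filling the organoid interior at a constant areal density
  (tumor cells also carry a nucleus);
* optional marker channels (CC3, gH2AX, Ki67 on all nuclei; H3K27M on tumor
  cells only) whose amplitude scales with a per-group treatment effect;
* Poisson–Gaussian acquisition noise on a constant background.

Cells are rendered as Gaussian blobs of sigma = cell_radius_um / 2 (support
truncated at 4 sigma); the smooth profile avoids aliasing artifacts in shell
means. Stacks are 2D-dominant (few z planes carrying the same signal with
independent noise) because the analysis starts from a maximum projection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import distances_to_boundary, points_in_polygon
from .io import BoundaryROI, ImageStack, write_roi, write_stack

#: markers rendered on every nucleus (treatment-responsive stains)
NUCLEAR_MARKERS = ("CC3", "gH2AX", "Ki67")
#: markers rendered on tumor cells only
TUMOR_MARKERS = ("H3K27M",)

_DEFAULT_GAINS = {
    "DAPI": 120.0, "eGFP": 150.0,
    "CC3": 100.0, "gH2AX": 100.0, "Ki67": 100.0, "H3K27M": 100.0,
}


def ellipse_polygon(
    cx: float, cy: float, rx: float, ry: float,
    n_vertices: int = 64, jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vertices of a (jittered) ellipse, counterclockwise, as (x, y) pairs.

    ``jitter`` perturbs each radius multiplicatively by U(-jitter, +jitter);
    the result is star-shaped about the center, hence always simple.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    scale = np.ones(n_vertices)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale += rng.uniform(-jitter, jitter, n_vertices)
    return np.column_stack([cx + rx * scale * np.cos(theta),
                            cy + ry * scale * np.sin(theta)])


@dataclass
class SceneParams:
    """Parameters of one synthetic assembloid scene.

    Defaults describe a 40-µm cryosection of an assembloid imaged at 10X:
    1 µm/pixel, an organoid ~180 µm in radius, a few hundred infiltrating
    tumor cells with a 50 µm depth-decay scale, and moderate shot/read
    noise on a small constant background.
    """

    image_shape: tuple[int, int, int] = (2, 420, 420)   # (z, y, x)
    pixel_size_um: float = 1.0
    organoid_polygon: np.ndarray | str | None = None    # vertices or recipe
    n_cells: int = 400
    decay_length_um: float = 50.0
    cell_radius_um: float = 5.0
    nuclear_radius_um: float = 3.5
    nuclear_density: float = 0.008        # nuclei per µm^2 of interior
    channel_gains: dict = field(default_factory=dict)
    marker_effect: dict = field(default_factory=dict)   # marker -> multiplier
    noise: tuple[float, float, float] = (1.0, 2.0, 5.0)
    # (poisson_scale, gaussian_sd, background_offset)
    min_cell_separation_um: float = 0.0
    seed: int = 0

    def gains(self) -> dict:
        g = dict(_DEFAULT_GAINS)
        g.update(self.channel_gains)
        return g

    def polygon_vertices(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.organoid_polygon
        if spec is None:
            _, ny, nx = self.image_shape
            r = 0.43 * min(ny, nx)
            spec = f"ellipse({nx / 2}, {ny / 2}, {r}, {r}, 64, 0.03)"
        if isinstance(spec, str):
            inner = spec.strip()
            if not (inner.startswith("ellipse(") and inner.endswith(")")):
                raise ValueError(f"unknown polygon recipe {spec!r}")
            args = [float(a) for a in inner[len("ellipse("):-1].split(",")]
            cx, cy, rx, ry, n_vertices, jitter = args
            return ellipse_polygon(cx, cy, rx, ry, int(n_vertices), jitter, rng)
        return np.asarray(spec, dtype=float)


@dataclass
class SceneGroundTruth:
    """Generator-side truth accompanying every synthetic output."""

    polygon: np.ndarray | None = None
    cell_positions: np.ndarray | None = None     # (n, 2) as (y, x)
    cell_depths_um: np.ndarray | None = None
    nuclei_positions: np.ndarray | None = None   # (n, 2) as (y, x)
    true_decay_length_um: float | None = None
    true_marker_effect: dict | None = None
    true_areas_um2: dict | None = None           # for migration series
    true_ic50: float | None = None               # for dose tables

    def to_json(self, path: str | Path) -> Path:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {k: conv(v) for k, v in asdict(self).items()}
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------

def _stamp_blobs(
    canvas: np.ndarray, positions: np.ndarray, amplitude, sigma_px: float
) -> None:
    """Add truncated Gaussian blobs (support 4 sigma) in place."""
    if len(positions) == 0:
        return
    ny, nx = canvas.shape
    r = max(1, int(math.ceil(4.0 * sigma_px)))
    amps = np.broadcast_to(np.asarray(amplitude, dtype=float), (len(positions),))
    for (y, x), a in zip(positions, amps):
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(0, iy - r), min(ny, iy + r + 1)
        x0, x1 = max(0, ix - r), min(nx, ix + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        rr2 = yy * yy + xx * xx
        patch = a * np.exp(-rr2 / (2.0 * sigma_px**2))
        patch[rr2 > (4.0 * sigma_px) ** 2] = 0.0
        canvas[y0:y1, x0:x1] += patch


def _apply_noise(
    plane: np.ndarray, noise: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson–Gaussian camera model: variance ≈ poisson_scale·s + sd²."""
    poisson_scale, gaussian_sd, background = noise
    out = plane.astype(float)
    if poisson_scale > 0:
        out = rng.poisson(out / poisson_scale).astype(float) * poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, out.shape)
    out = out + background
    return np.clip(out, 0.0, None)


def _point_at_depth(
    poly, d_px: float, u: float
) -> np.ndarray | None:
    """Uniform-arclength point on the iso-depth contour at depth ``d_px``.

    The contour of points at exact distance d inside a polygon is the
    boundary of its erosion by d; sampling uniformly along it realizes the
    "uniform in the boundary-parallel direction" placement. Returns None
    when the erosion is empty (depth exceeds the inradius).
    """
    eroded = poly.buffer(-d_px)
    if eroded.is_empty:
        return None
    parts = list(eroded.geoms) if hasattr(eroded, "geoms") else [eroded]
    rings = [p.exterior for p in parts]
    lengths = np.array([r.length for r in rings])
    total = lengths.sum()
    if total <= 0:
        return None
    s = u * total
    idx = int(np.searchsorted(np.cumsum(lengths), s, side="right"))
    idx = min(idx, len(rings) - 1)
    offset = s - (np.cumsum(lengths)[idx] - lengths[idx])
    pt = rings[idx].interpolate(offset)
    return np.array([pt.x, pt.y])


def _sample_cells(
    roi: BoundaryROI, params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Tumor-cell centers (y, x) with exponential depth law.

    Depth from the boundary is Exp(decay_length), realized exactly by
    placing each cell uniformly along the inward-offset contour at its
    drawn depth. Depths beyond the polygon inradius have no contour and
    are redrawn, so the recorded distribution is the exponential truncated
    at the organoid's maximum depth. Recorded depths are the realized
    minimum boundary distances (equal to the draw up to the offset-contour
    discretization, well below one pixel).
    """
    from shapely.geometry import Polygon

    px = params.pixel_size_um
    poly = Polygon(roi.vertices)
    sep2 = (params.min_cell_separation_um / px) ** 2
    accepted_xy: list[np.ndarray] = []
    depths_drawn: list[float] = []
    attempts = 0
    max_attempts = 200 * max(params.n_cells, 1)
    while len(accepted_xy) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {params.n_cells} cells "
                f"(placed {len(accepted_xy)}); polygon too small or "
                "separation constraint too strict"
            )
        d_um = float(rng.exponential(params.decay_length_um))
        u = float(rng.uniform())
        xy = _point_at_depth(poly, d_um / px, u)
        if xy is None:
            continue
        if sep2 > 0 and accepted_xy:
            arr = np.asarray(accepted_xy)
            if np.min((arr[:, 0] - xy[0]) ** 2 + (arr[:, 1] - xy[1]) ** 2) < sep2:
                continue
        accepted_xy.append(xy)
        depths_drawn.append(d_um)
    xy = np.asarray(accepted_xy)
    positions = np.column_stack([xy[:, 1], xy[:, 0]])  # (y, x)
    realized = distances_to_boundary(xy, roi) * px
    return positions, realized


def _sample_nuclei(
    roi: BoundaryROI, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Uniform nuclei centers (y, x) inside the polygon at nuclear_density."""
    area_um2 = roi.area * params.pixel_size_um**2
    n = int(rng.poisson(params.nuclear_density * area_um2))
    if n == 0:
        return np.empty((0, 2))
    v = roi.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    out: list[np.ndarray] = []
    while len(out) < n:
        m = max(64, 2 * (n - len(out)))
        cand = rng.uniform(lo, hi, (m, 2))
        keep = cand[points_in_polygon(cand, roi)]
        out.extend(keep[: n - len(out)])
    xy = np.asarray(out)
    return np.column_stack([xy[:, 1], xy[:, 0]])


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------

def generate_assembloid_scene(
    params: SceneParams,
) -> tuple[ImageStack, BoundaryROI, SceneGroundTruth]:
    """Render one synthetic assembloid section with ground truth.

    Returns the image stack (channels DAPI, eGFP, plus any marker named in
    ``params.marker_effect``), the boundary ROI, and the generator truth.
    """
    rng = np.random.default_rng(params.seed)
    verts = params.polygon_vertices(rng)
    roi = BoundaryROI(verts)  # validates simplicity / area

    cell_area = math.pi * (params.cell_radius_um / params.pixel_size_um) ** 2
    if params.n_cells > 0 and roi.area < params.n_cells * cell_area:
        raise ValueError(
            f"organoid area {roi.area:.0f} px^2 too small to hold "
            f"{params.n_cells} cells of radius {params.cell_radius_um} µm"
        )

    nz, ny, nx = params.image_shape
    gains = params.gains()
    markers = list(params.marker_effect)
    channel_names = ["DAPI", "eGFP"] + markers

    if params.n_cells > 0:
        cell_pos, cell_depths = _sample_cells(roi, params, rng)
    else:
        cell_pos = np.empty((0, 2))
        cell_depths = np.empty(0)
    nuc_pos = _sample_nuclei(roi, params, rng)

    px = params.pixel_size_um
    sigma_cell = (params.cell_radius_um / 2.0) / px
    sigma_nuc = (params.nuclear_radius_um / 2.0) / px

    render = np.zeros((len(channel_names), ny, nx))
    # DAPI: organoid nuclei + tumor-cell nuclei
    _stamp_blobs(render[0], nuc_pos, gains["DAPI"], sigma_nuc)
    _stamp_blobs(render[0], cell_pos, gains["DAPI"], sigma_nuc)
    # eGFP: tumor cells
    _stamp_blobs(render[1], cell_pos, gains["eGFP"], sigma_cell)
    for k, marker in enumerate(markers, start=2):
        amp = gains.get(marker, 100.0) * params.marker_effect[marker]
        if marker in TUMOR_MARKERS:
            _stamp_blobs(render[k], cell_pos, amp, sigma_cell)
        else:
            _stamp_blobs(render[k], nuc_pos, amp, sigma_nuc)
            _stamp_blobs(render[k], cell_pos, amp, sigma_nuc)

    data = np.empty((len(channel_names), nz, ny, nx))
    for c in range(len(channel_names)):
        for z in range(nz):
            data[c, z] = _apply_noise(render[c], params.noise, rng)

    stack = ImageStack(
        data=data, channel_names=channel_names, pixel_size_um=px
    )
    truth = SceneGroundTruth(
        polygon=verts,
        cell_positions=cell_pos,
        cell_depths_um=cell_depths,
        nuclei_positions=nuc_pos,
        true_decay_length_um=params.decay_length_um,
        true_marker_effect=dict(params.marker_effect),
    )
    return stack, roi, truth


# --------------------------------------------------------------------------
# migration series
# --------------------------------------------------------------------------

def generate_migration_series(
    r0_um: float,
    r24_um: float,
    frame_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    noise: tuple[float, float, float] = (1.0, 2.0, 5.0),
    seed: int = 0,
    amplitude: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, SceneGroundTruth]:
    """Two intensity-disk frames emulating a spheroid at 0 h and its spread
    area at 24 h, plus analytic true areas (pi * r^2, µm^2)."""
    if not (r24_um >= r0_um > 0):
        raise ValueError("need r24_um >= r0_um > 0")
    ny, nx = frame_shape
    cy, cx = ny / 2.0, nx / 2.0
    r24_px = r24_um / pixel_size_um
    if r24_px > min(cy, cx, ny - cy, nx - cx):
        raise ValueError("disk exceeds frame bounds")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - cy, xx - cx)
    frames = []
    for r_um in (r0_um, r24_um):
        disk = amplitude * (rr <= r_um / pixel_size_um)
        frames.append(_apply_noise(disk, noise, rng))
    truth = SceneGroundTruth(
        true_areas_um2={
            "0h": math.pi * r0_um**2,
            "24h": math.pi * r24_um**2,
        }
    )
    return frames[0], frames[1], truth


# --------------------------------------------------------------------------
# dose-response tables
# --------------------------------------------------------------------------

def four_param_logistic(
    dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float
) -> np.ndarray:
    """r(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def generate_dose_response(
    true_ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    doses: np.ndarray | list | None = None,
    cv: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SceneGroundTruth]:
    """Dose–viability table: 4PL mean response times (1 + N(0, cv)) noise,
    floored at 0. Default doses span 0.1 nM to 100 µM (half-log steps)."""
    if doses is None:
        doses = np.geomspace(0.1, 1e5, 13)  # nM: 0.1 nM .. 100 µM
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if not (0 <= bottom < top):
        raise ValueError("need 0 <= bottom < top")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mu = four_param_logistic(d, top, bottom, true_ic50, hill)
        for rep in range(replicates):
            v = mu * (1.0 + rng.normal(0.0, cv)) if cv > 0 else mu
            rows.append({"dose": d, "replicate": rep, "viability": max(v, 0.0)})
    table = pd.DataFrame(rows)
    return table, SceneGroundTruth(true_ic50=float(true_ic50))


# --------------------------------------------------------------------------
# grouped datasets
# --------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental arm (group x treatment) of a grouped dataset."""

    params: SceneParams
    n_images: int = 5
    infiltration_effect: float = 1.0   # multiplies n_cells
    marker_effects: dict = field(default_factory=dict)
    is_control: bool = False
    treatment: str = "untreated"
    group: str | None = None           # defaults to the arm's dict key


def _derive_seed(base_seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_group_dataset(
    groups: dict[str, GroupSpec], base_seed: int = 0
) -> list[dict]:
    """Deterministic collection of scenes for a multi-group experiment.

    Each record is ``{group, treatment, replicate, stack, roi, truth}``;
    scene seeds derive from (base_seed, group index, replicate index) so any
    record is reproducible in isolation. Exactly one group must be flagged
    as control.
    """
    group_labels = {spec.group or key for key, spec in groups.items()}
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    controls = {spec.group or key for key, spec in groups.items()
                if spec.is_control}
    if len(controls) != 1:
        raise ValueError("exactly one group must be designated control")
    records = []
    for gi, (key, spec) in enumerate(groups.items()):
        label = spec.group or key
        for rep in range(spec.n_images):
            p = SceneParams(**{**asdict_shallow(spec.params)})
            p.n_cells = int(round(spec.params.n_cells * spec.infiltration_effect))
            p.marker_effect = {**spec.params.marker_effect, **spec.marker_effects}
            p.seed = _derive_seed(base_seed, gi, rep)
            stack, roi, truth = generate_assembloid_scene(p)
            records.append({
                "group": label,
                "treatment": spec.treatment,
                "replicate": rep,
                "is_control_group": label in controls,
                "stack": stack,
                "roi": roi,
                "truth": truth,
            })
    return records


def asdict_shallow(params: SceneParams) -> dict:
    """Field dict of SceneParams without deep-copying array fields."""
    return {f: getattr(params, f) for f in params.__dataclass_fields__}


def write_group_dataset(
    records: list[dict], out_dir: str | Path,
    untreated_label: str = "untreated",
) -> Path:
    """Write scenes as OME-TIFF + JSON ROI + truth sidecars and a manifest
    CSV loadable by :func:`assembloid_quant.io.load_manifest`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        tag = f"{rec['group']}_{rec['treatment']}_{rec['replicate']}"
        img = f"{tag}.ome.tif"
        roi_file = f"{tag}.roi.json"
        write_stack(rec["stack"], out_dir / img)
        write_roi(rec["roi"], out_dir / roi_file, dialect="json")
        rec["truth"].to_json(out_dir / f"{tag}.truth.json")
        rows.append({
            "image": img,
            "roi": roi_file,
            "group": rec["group"],
            "treatment": rec["treatment"],
            "replicate": rec["replicate"],
            "channels": ";".join(rec["stack"].channel_names),
            "is_control_group": bool(rec["is_control_group"]),
            "is_untreated": rec["treatment"] == untreated_label,
        })
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
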