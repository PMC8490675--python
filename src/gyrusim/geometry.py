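"""Synthetic labeled 2D gyrus geometry and its conforming triangulation.

The cortical fold is modeled as a band of configurable thickness around a
smooth Gaussian-bump centerline, subdivided radially into the six
neocortical layers (L1 outermost, facing CSF) and tangentially into
segments of equal arc length.  The band is embedded in a rectangular
domain with white matter below and CSF above.  All interfaces are graphs
y(x) ("vertical offset scaled by the local secant of the slope"), which
keeps the construction free of self-intersections for moderate folds and
allows an exactly conforming structured triangulation: every layer
interface and every segment edge is a mesh line, so each element carries
exactly one region/segment label.

Coordinates are in millimetres; x is the tangential/lateral direction and
y the depth axis with the pial surface at larger y.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import shapely.wkt
from shapely.geometry import LineString, Polygon

__all__ = [
    "GyrusConfig", "GyrusGeometry", "Mesh",
    "generate_gyrus", "load_boundary_file", "save_boundary_file",
    "triangulate", "region_area", "mean_edge_length",
    "CORTICAL_LAYERS", "REGION_LABELS",
]

#: Cortical layer labels, outermost (pial side) first.
CORTICAL_LAYERS = ("L1", "L2", "L3", "L4", "L5", "L6")

#: All region labels a geometry may carry.
REGION_LABELS = ("CSF",) + CORTICAL_LAYERS + ("WM", "GM_surround")

# Bottom-up stacking order of the bands used by the structured mesher.
_BAND_ORDER = ("WM", "L6", "L5", "L4", "L3", "L2", "L1", "CSF")

_CURVE_SAMPLES = 2001  # dense sampling of interface polylines


@dataclass(frozen=True)
class GyrusConfig:
    """Parameters of the synthetic gyrus generator.

    Lengths in mm.  The defaults reproduce the reference study geometry:
    an 8.5 mm x 15.3 mm coronal patch containing one folded gyrus with a
    2.5 mm thick cortex split into six layers.
    """

    domain_width: float = 8.5
    domain_height: float = 15.3
    cortical_thickness: float = 2.5
    fold_amplitude: float = 4.0
    fold_wavelength: float = 7.2
    layer_fractions: tuple[float, ...] = (0.10, 0.10, 0.25, 0.15, 0.20, 0.20)
    n_segments_per_layer: int = 12
    seed: int = 0
    #: y-coordinate of the GM/WM interface away from the fold.
    base_height: float = 4.0

    def __post_init__(self) -> None:
        if len(self.layer_fractions) != 6:
            raise ValueError("layer_fractions must have 6 entries")
        if abs(sum(self.layer_fractions) - 1.0) > 1e-12:
            raise ValueError("layer_fractions must sum to 1 within 1e-12")
        for name in ("domain_width", "domain_height", "cortical_thickness",
                     "fold_wavelength", "base_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if min(self.layer_fractions) <= 0:
            raise ValueError("layer_fractions must be positive")
        if self.n_segments_per_layer < 1:
            raise ValueError("n_segments_per_layer must be >= 1")


@dataclass
class GyrusGeometry:
    """Labeled 2D gyrus geometry.

    ``regions`` maps region labels to simple polygons; ``segments`` maps
    ``(layer_index, segment_index)`` (both 1-based, layer 1 outermost,
    segments numbered from the left flank) to polygons.  ``interface_x`` /
    ``interface_y`` hold the seven band interfaces (GM/WM first, pial
    last) as dense graphs shared by the mesher and the rasterizer.
    """

    regions: dict[str, Polygon]
    outer_boundary: np.ndarray          # (N, 2) pial polyline
    inner_boundary: np.ndarray          # (N, 2) GM/WM polyline
    segments: dict[tuple[int, int], Polygon]
    crown_point: np.ndarray             # (2,) apex of the pial surface
    interface_x: np.ndarray             # (N,)
    interface_y: np.ndarray             # (7, N), bottom-up (GM/WM .. pial)
    segment_edges: np.ndarray           # (n_segments + 1,) x-coordinates
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    config: GyrusConfig | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segment_edges) - 1

    @property
    def domain_polygon(self) -> Polygon:
        xmin, ymin, xmax, ymax = self.bounds
        return Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])

    def validate(self) -> None:
        """Check the geometric invariants; raise ValueError on violation."""
        for label, poly in self.regions.items():
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"region {label!r} polygon is not simple/valid")
        labels = list(self.regions)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                inter = self.regions[a].intersection(self.regions[b]).area
                ref = min(self.regions[a].area, self.regions[b].area)
                if inter > 1e-6 * ref:
                    raise ValueError(f"regions {a!r} and {b!r} overlap")
        for (layer, seg), poly in self.segments.items():
            label = CORTICAL_LAYERS[layer - 1]
            if label not in self.regions:
                raise ValueError(f"segment ({layer},{seg}) references missing layer")
            outside = poly.difference(self.regions[label].buffer(1e-9)).area
            if outside > 1e-6 * poly.area:
                raise ValueError(f"segment ({layer},{seg}) is not inside layer {label}")
        d = np.min(np.hypot(self.outer_boundary[:, 0] - self.crown_point[0],
                            self.outer_boundary[:, 1] - self.crown_point[1]))
        if d > 1e-9:
            raise ValueError("crown_point does not lie on the outer boundary")


@dataclass
class Mesh:
    """Conforming triangulation of a :class:`GyrusGeometry`.

    Triangles are positively oriented; ``element_labels`` carries one
    region label per triangle, ``element_layer``/``element_segment`` the
    1-based cortical layer/segment indices (0 outside the cortex).
    ``element_tangent`` is the unit vector along the cortical band
    (defined for cortical elements, zero elsewhere).
    """

    nodes: np.ndarray                   # (n_nodes, 2)
    triangles: np.ndarray               # (n_elems, 3) int
    element_labels: np.ndarray          # (n_elems,) str
    element_layer: np.ndarray           # (n_elems,) int
    element_segment: np.ndarray         # (n_elems,) int
    boundary_tags: dict[str, np.ndarray]
    element_tangent: np.ndarray         # (n_elems, 2)
    target_edge: float
    crown_point: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        """Signed triangle areas (positive for the stored orientation)."""
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        h.update("|".join(self.element_labels.tolist()).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _fold_functions(config: GyrusConfig):
    """Analytic inner-boundary curve f(x) and its first two derivatives."""
    A = config.fold_amplitude
    W = config.domain_width
    sigma = config.fold_wavelength / 4.0
    rng = np.random.default_rng(config.seed)
    # Smooth long-wavelength seeded irregularity emulating a hand-traced
    # boundary; it scales with the fold so a zero-amplitude config is an
    # exactly flat slab, and stays gentle enough that the curvature guard
    # below holds for every seed.
    amps = rng.uniform(0.0, 0.004, 2) * A
    phases = rng.uniform(0.0, 2.0 * np.pi, 2)
    ks = 2.0 * np.pi * np.arange(1, 3) / W

    def f(x):
        x = np.asarray(x, dtype=float)
        out = config.base_height + A * np.exp(-x**2 / (2 * sigma**2))
        for a, k, p in zip(amps, ks, phases):
            out = out + a * np.sin(k * x + p)
        return out

    def fp(x):
        x = np.asarray(x, dtype=float)
        out = A * np.exp(-x**2 / (2 * sigma**2)) * (-x / sigma**2)
        for a, k, p in zip(amps, ks, phases):
            out = out + a * k * np.cos(k * x + p)
        return out

    def fpp(x):
        x = np.asarray(x, dtype=float)
        out = A * np.exp(-x**2 / (2 * sigma**2)) * (x**2 - sigma**2) / sigma**4
        for a, k, p in zip(amps, ks, phases):
            out = out - a * k**2 * np.sin(k * x + p)
        return out

    return f, fp, fpp


def generate_gyrus(config: GyrusConfig) -> GyrusGeometry:
    """Generate a single folded gyrus (one crown, two flanks).

    The cortical band of the configured thickness follows a Gaussian-bump
    centerline; the band is divided into six layers by ``layer_fractions``
    (L1 outermost) and each layer into ``n_segments_per_layer`` tangential
    segments of equal mid-surface arc length, numbered from the left
    flank.  Deterministic given ``config.seed``.
    """
    W, H = config.domain_width, config.domain_height
    t = config.cortical_thickness
    f, fp, fpp = _fold_functions(config)

    x = np.linspace(-W / 2, W / 2, _CURVE_SAMPLES)
    y_in = f(x)
    slope = fp(x)
    sec = np.sqrt(1.0 + slope**2)

    # Reject folds whose outward normal offset by the cortical thickness
    # would self-intersect (concave-up loci with curvature radius < t).
    curvature = fpp(x) / sec**3
    k_plus = float(np.max(curvature))
    if k_plus > 0 and t * k_plus >= 1.0:
        raise ValueError(
            "offset curves self-intersect: cortical thickness "
            f"{t:.3g} mm exceeds the minimal concave curvature radius "
            f"{1.0 / k_plus:.3g} mm; reduce fold_amplitude or "
            "cortical_thickness, or increase fold_wavelength")

    # Interfaces bottom-up: normal offsets of the GM/WM curve at
    # q-fractions of the cortical thickness, re-expressed as graphs y(x).
    # layer_fractions are ordered L1..L6 (outermost first), so the
    # bottom-up stack uses them reversed.
    q = np.concatenate([[0.0], np.cumsum(config.layer_fractions[::-1])])
    q[-1] = 1.0
    interface_y = np.empty((7, len(x)))
    for k, qk in enumerate(q):
        d = qk * t
        xo = x - d * slope / sec
        yo = y_in + d / sec
        interface_y[k] = np.interp(x, xo, yo)
    y_out = interface_y[6]
    if np.max(y_out) >= H - 1e-9:
        raise ValueError("fold exceeds the domain height; reduce "
                         "fold_amplitude or base_height")
    if np.min(y_in) <= 1e-9:
        raise ValueError("inner boundary reaches the domain bottom")

    # Tangential segmentation: equal arc length along the band mid-surface.
    y_mid = 0.5 * (interface_y[0] + interface_y[6])
    seg_len = np.hypot(np.diff(x), np.diff(y_mid))
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_seg = config.n_segments_per_layer
    s_targets = np.linspace(0.0, s[-1], n_seg + 1)
    segment_edges = np.interp(s_targets, s, x)
    segment_edges[0], segment_edges[-1] = -W / 2, W / 2

    geom = _assemble_geometry(x, interface_y, segment_edges, (W, H), config)
    return geom


def _band_polygon(x, y_lo, y_hi) -> Polygon:
    pts = np.concatenate([
        np.column_stack([x, y_lo]),
        np.column_stack([x[::-1], y_hi[::-1]]),
    ])
    return Polygon(pts)


def _assemble_geometry(x, interface_y, segment_edges, size, config) -> GyrusGeometry:
    W, H = size
    regions: dict[str, Polygon] = {}
    # WM: domain bottom up to the GM/WM interface.
    regions["WM"] = Polygon(
        [(-W / 2, 0.0), (W / 2, 0.0)]
        + list(zip(x[::-1], interface_y[0][::-1])))
    # Cortical layers, bottom-up L6..L1.
    for k, label in enumerate(_BAND_ORDER[1:7]):
        regions[label] = _band_polygon(x, interface_y[k], interface_y[k + 1])
    # CSF: pial surface up to the domain top.
    regions["CSF"] = Polygon(
        list(zip(x, interface_y[6])) + [(W / 2, H), (-W / 2, H)])

    # Per-layer tangential segments.
    segments: dict[tuple[int, int], Polygon] = {}
    for layer in range(1, 7):
        lo = interface_y[6 - layer]
        hi = interface_y[7 - layer]
        for si in range(len(segment_edges) - 1):
            x0, x1 = segment_edges[si], segment_edges[si + 1]
            mask = (x > x0) & (x < x1)
            xs = np.concatenate([[x0], x[mask], [x1]])
            lo_s = np.interp(xs, x, lo)
            hi_s = np.interp(xs, x, hi)
            segments[(layer, si + 1)] = _band_polygon(xs, lo_s, hi_s)

    outer = np.column_stack([x, interface_y[6]])
    inner = np.column_stack([x, interface_y[0]])
    crown = outer[int(np.argmax(outer[:, 1]))].copy()
    return GyrusGeometry(
        regions=regions,
        outer_boundary=outer,
        inner_boundary=inner,
        segments=segments,
        crown_point=crown,
        interface_x=np.asarray(x, dtype=float),
        interface_y=np.asarray(interface_y, dtype=float),
        segment_edges=np.asarray(segment_edges, dtype=float),
        bounds=(-W / 2, 0.0, W / 2, H),
        config=config,
    )


# ---------------------------------------------------------------------------
# boundary file I/O
# ---------------------------------------------------------------------------

def save_boundary_file(geom: GyrusGeometry, path: str | Path,
                       fmt: str | None = None) -> None:
    """Write region and segment polygons to CSV or WKT.

    CSV dialect: header ``label,ring,x_mm,y_mm``; one row per vertex, rings
    explicitly closed (first vertex repeated).  Segment polygons use labels
    ``L<layer>_S<segment>``.  WKT dialect: one ``label<TAB>POLYGON(...)``
    per line.  Both store full double precision and round-trip exactly.
    """
    path = Path(path)
    fmt = fmt or ("wkt" if path.suffix.lower() == ".wkt" else "csv")
    items = [(label, poly) for label, poly in geom.regions.items()]
    items += [(f"L{layer}_S{seg:02d}", poly)
              for (layer, seg), poly in geom.segments.items()]
    if fmt == "csv":
        buf = _io.StringIO()
        buf.write("label,ring,x_mm,y_mm\n")
        for label, poly in items:
            xs, ys = poly.exterior.coords.xy
            for xi, yi in zip(xs, ys):
                buf.write(f"{label},0,{xi!r},{yi!r}\n")
        path.write_text(buf.getvalue())
    elif fmt == "wkt":
        with open(path, "w") as fh:
            for label, poly in items:
                fh.write(f"{label}\t{shapely.wkt.dumps(poly, trim=False)}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _parse_boundary_file(path: Path) -> dict[str, np.ndarray]:
    """Read the documented CSV/WKT dialect into label -> ring vertex arrays."""
    rings: dict[str, np.ndarray] = {}
    text = path.read_text()
    first = text.splitlines()[0] if text else ""
    if "\t" in first and "POLYGON" in text:
        for line in text.splitlines():
            if not line.strip():
                continue
            label, wkt = line.split("\t", 1)
            poly = shapely.wkt.loads(wkt)
            rings[label] = np.asarray(poly.exterior.coords)
    else:
        import csv as _csv
        rows = list(_csv.reader(_io.StringIO(text)))
        if rows and rows[0][:2] == ["label", "ring"]:
            rows = rows[1:]
        current: dict[str, list] = {}
        for label, _ring, xs, ys in rows:
            current.setdefault(label, []).append((float(xs), float(ys)))
        rings = {k: np.asarray(v) for k, v in current.items()}
    return rings


def load_boundary_file(path: str | Path) -> GyrusGeometry:
    """Load a labeled gyrus geometry from a CSV or WKT boundary file.

    Validates closure, simplicity, label names and mutual non-overlap, and
    reconstructs the band interfaces required by the structured mesher by
    vertical-line sampling of the region polygons.
    """
    path = Path(path)
    rings = _parse_boundary_file(path)
    regions: dict[str, Polygon] = {}
    seg_rings: dict[tuple[int, int], np.ndarray] = {}
    for label, ring in rings.items():
        if label.startswith("L") and "_S" in label:
            layer = int(label[1:label.index("_")])
            seg = int(label[label.index("_S") + 2:])
            seg_rings[(layer, seg)] = ring
            continue
        if label not in REGION_LABELS:
            raise ValueError(f"unknown region label {label!r}")
        regions[label] = _ring_to_polygon(label, ring)
    required = set(CORTICAL_LAYERS) | {"WM", "CSF"}
    missing = required - set(regions)
    if missing:
        raise ValueError(f"boundary file missing regions: {sorted(missing)}")

    segments = {key: _ring_to_polygon(f"L{key[0]}_S{key[1]:02d}", ring)
                for key, ring in seg_rings.items()}

    # Reconstruct interfaces by vertical sampling of the band polygons.
    xs = np.unique(np.asarray(regions["L1"].exterior.coords)[:, 0])
    all_pts = np.concatenate([np.asarray(p.exterior.coords)
                              for p in regions.values()])
    xmin, ymin = all_pts.min(axis=0)
    xmax, ymax = all_pts.max(axis=0)
    interface_y = np.empty((7, len(xs)))
    for k, label in enumerate(_BAND_ORDER[1:7]):  # L6 .. L1 bottom-up
        lo, hi = _band_extent(regions[label], xs, ymin, ymax)
        if k == 0:
            interface_y[0] = lo
        interface_y[k + 1] = hi

    if segments:
        n_seg = max(s for (_l, s) in segments)
        edges = sorted({np.asarray(p.exterior.coords)[:, 0].min()
                        for p in segments.values()}
                       | {np.asarray(p.exterior.coords)[:, 0].max()
                          for p in segments.values()})
        segment_edges = np.asarray(edges)
        if len(segment_edges) != n_seg + 1:
            raise ValueError("segment polygons do not form a clean "
                             "tangential partition")
    else:
        segment_edges = np.array([xmin, xmax])

    geom = GyrusGeometry(
        regions=regions,
        outer_boundary=np.column_stack([xs, interface_y[6]]),
        inner_boundary=np.column_stack([xs, interface_y[0]]),
        segments=segments,
        crown_point=None,  # set below
        interface_x=xs,
        interface_y=interface_y,
        segment_edges=segment_edges,
        bounds=(float(xmin), float(ymin), float(xmax), float(ymax)),
        config=None,
    )
    geom.crown_point = geom.outer_boundary[
        int(np.argmax(geom.outer_boundary[:, 1]))].copy()
    geom.validate()
    return geom


def _ring_to_polygon(label: str, ring: np.ndarray) -> Polygon:
    if len(ring) < 4 or not np.allclose(ring[0], ring[-1], atol=0.0):
        raise ValueError(f"polygon {label!r} is open (ring not closed)")
    poly = Polygon(ring)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError(f"polygon {label!r} is self-intersecting or invalid")
    return poly


def _band_extent(poly: Polygon, xs: np.ndarray, ymin: float, ymax: float):
    """Lower/upper boundary of a vertically convex band polygon at xs."""
    lo = np.empty(len(xs))
    hi = np.empty(len(xs))
    pad = 1.0
    for i, xi in enumerate(xs):
        cut = poly.intersection(LineString([(xi, ymin - pad), (xi, ymax + pad)]))
        if cut.is_empty:
            # Sampling line grazes the polygon end; fall back to vertices.
            mask = np.isclose(np.asarray(poly.exterior.coords)[:, 0], xi)
            ys = np.asarray(poly.exterior.coords)[mask, 1]
            lo[i], hi[i] = ys.min(), ys.max()
        else:
            lo[i], hi[i] = cut.bounds[1], cut.bounds[3]
    return lo, hi


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def triangulate(geom: GyrusGeometry, target_edge: float,
                surround_coarsening: float = 1.0) -> Mesh:
    """Structured conforming triangulation of the layered gyrus.

    Columns follow the tangential segmentation (uniform in band arc
    length), rows follow the band interfaces, so all region and segment
    boundaries are mesh lines.  ``target_edge`` is the requested *average*
    element edge length (mm); the cell size is calibrated internally so
    the mesh-wide mean edge length tracks it.  ``surround_coarsening`` > 1
    coarsens the WM/CSF row spacing (adaptive refinement of the gyrus
    region relative to the surround).  Layers thinner than the local
    target are refined to at least one row (with a warning).
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be > 0")
    a = target_edge
    for _ in range(3):
        mesh = _build_mesh(geom, a, surround_coarsening)
        mean = mean_edge_length(mesh)
        if abs(mean / target_edge - 1.0) < 0.02:
            break
        a *= target_edge / mean
    mesh.target_edge = target_edge
    areas = mesh.areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise ValueError(f"triangulation produced an inverted element {bad}")
    return mesh


def _build_mesh(geom: GyrusGeometry, a: float,
                surround_coarsening: float) -> Mesh:
    import warnings

    xmin, ymin, xmax, ymax = geom.bounds
    x_if, y_if = geom.interface_x, geom.interface_y
    target_edge = a

    # --- columns: uniform in mid-surface arc length inside each segment ---
    y_mid = 0.5 * (y_if[0] + y_if[6])
    seg_len = np.hypot(np.diff(x_if), np.diff(y_mid))
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    cols = [x_if[0]]
    for si in range(len(geom.segment_edges) - 1):
        x0, x1 = geom.segment_edges[si], geom.segment_edges[si + 1]
        s0, s1 = np.interp([x0, x1], x_if, s)
        n_cols = max(1, int(round((s1 - s0) / a)))
        s_sub = np.linspace(s0, s1, n_cols + 1)[1:]
        cols.extend(np.interp(s_sub, s, x_if))
    cols = np.asarray(cols)
    cols[-1] = xmax

    # --- rows: per band, constant count across columns ---
    band_lo = [np.full_like(x_if, ymin)] + [y_if[k] for k in range(7)]
    band_hi = [y_if[0]] + [y_if[k + 1] for k in range(6)] + [np.full_like(x_if, ymax)]
    thin = []
    n_rows = []
    for b, label in enumerate(_BAND_ORDER):
        mean_th = float(np.mean(band_hi[b] - band_lo[b]))
        spacing = a * (surround_coarsening if label in ("WM", "CSF") else 1.0)
        n_b = max(1, int(round(mean_th / spacing)))
        if label in CORTICAL_LAYERS and mean_th < target_edge:
            thin.append(label)
        n_rows.append(n_b)
    if thin:
        warnings.warn(
            f"target_edge {target_edge:.3g} mm exceeds the mean thickness of "
            f"layer(s) {thin}; refining locally to one row per layer",
            stacklevel=2)

    # --- nodes ---
    ncol = len(cols)
    lo_cols = [np.interp(cols, x_if, lo) for lo in band_lo]
    hi_cols = [np.interp(cols, x_if, hi) for hi in band_hi]
    ys_parts = []
    band_row0 = []   # first row index of each band
    row = 0
    for b in range(8):
        band_row0.append(row)
        fr = np.linspace(0.0, 1.0, n_rows[b] + 1)
        block = lo_cols[b][None, :] * (1 - fr[:, None]) + hi_cols[b][None, :] * fr[:, None]
        ys_parts.append(block if b == 0 else block[1:])
        row += n_rows[b]
    ys = np.concatenate(ys_parts, axis=0)      # (nrow+1, ncol)
    nrow = ys.shape[0] - 1
    X = np.broadcast_to(cols[None, :], ys.shape)
    nodes = np.column_stack([X.ravel(), ys.ravel()])

    def nid(j, i):
        return j * ncol + i

    # --- triangles with alternating diagonals ---
    jj, ii = np.meshgrid(np.arange(nrow), np.arange(ncol - 1), indexing="ij")
    n00 = nid(jj, ii).ravel()
    n10 = nid(jj, ii + 1).ravel()
    n01 = nid(jj + 1, ii).ravel()
    n11 = nid(jj + 1, ii + 1).ravel()
    even = ((jj + ii) % 2 == 0).ravel()
    tri_a = np.where(even[:, None], np.column_stack([n00, n10, n11]),
                     np.column_stack([n00, n10, n01]))
    tri_b = np.where(even[:, None], np.column_stack([n00, n11, n01]),
                     np.column_stack([n10, n11, n01]))
    triangles = np.empty((2 * len(n00), 3), dtype=np.int64)
    triangles[0::2] = tri_a
    triangles[1::2] = tri_b

    # --- labels per element ---
    cell_band = np.zeros(nrow, dtype=int)
    for b in range(8):
        r0 = band_row0[b]
        r1 = band_row0[b + 1] if b < 7 else nrow
        cell_band[r0:r1] = b
    band_of_cell = np.repeat(cell_band, ncol - 1)        # per quad
    band_of_elem = np.repeat(band_of_cell, 2)
    labels = np.asarray(_BAND_ORDER, dtype=object)[band_of_elem]
    layer_of_band = np.array([0, 6, 5, 4, 3, 2, 1, 0])
    element_layer = layer_of_band[band_of_elem]

    x_cell = 0.5 * (cols[:-1] + cols[1:])
    seg_of_col = np.clip(
        np.searchsorted(geom.segment_edges, x_cell, side="right") - 1,
        0, geom.n_segments - 1) + 1
    seg_of_cell = np.tile(seg_of_col, nrow)
    element_segment = np.where(element_layer > 0, np.repeat(seg_of_cell, 2), 0)

    # --- band tangent per cortical element ---
    cent = nodes[triangles].mean(axis=1)
    slope_mid = np.gradient(y_mid, x_if)
    sl = np.interp(cent[:, 0], x_if, slope_mid)
    tang = np.column_stack([np.ones_like(sl), sl])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    tang[element_layer == 0] = 0.0

    # --- boundary tags ---
    rows_idx = np.arange(nrow + 1)
    gmwm_row = band_row0[1]
    pial_row = band_row0[7]
    gm_wm = np.array([nid(gmwm_row, i) for i in range(ncol)])
    pial = np.array([nid(pial_row, i) for i in range(ncol)])
    ext = set()
    for i in range(ncol):
        ext.add(nid(0, i))
        ext.add(nid(nrow, i))
    for j in rows_idx:
        ext.add(nid(j, 0))
        ext.add(nid(j, ncol - 1))
    boundary_tags = {
        "pial": pial,
        "gm_wm": gm_wm,
        "domain_exterior": np.asarray(sorted(ext), dtype=np.int64),
    }

    mesh = Mesh(
        nodes=nodes,
        triangles=triangles,
        element_labels=labels,
        element_layer=element_layer,
        element_segment=element_segment,
        boundary_tags=boundary_tags,
        element_tangent=tang,
        target_edge=target_edge,
        crown_point=None if geom.crown_point is None else geom.crown_point.copy(),
    )
    return mesh


def mean_edge_length(mesh: Mesh) -> float:
    """Mean length over the unique edges of the triangulation."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    p = mesh.nodes[edges]
    return float(np.mean(np.hypot(p[:, 1, 0] - p[:, 0, 0],
                                  p[:, 1, 1] - p[:, 0, 1])))


def region_area(mesh: Mesh, label) -> float:
    """Total area (mm^2) of a region label or a ``(layer, segment)`` pair."""
    areas = mesh.areas()
    if isinstance(label, tuple):
        layer, seg = label
        mask = (mesh.element_layer == layer) & (mesh.element_segment == seg)
        if not mask.any():
            raise KeyError(f"no elements for segment {label!r}")
    elif label == "domain":
        mask = np.ones(mesh.n_elements, dtype=bool)
    else:
        mask = mesh.element_labels == label
        if not mask.any():
            raise KeyError(f"unknown region label {label!r}")
    return float(areas[mask].sum())
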