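"""Per-sheath morphometry: thickness, g-ratio and axon diameter.

For each accepted ring-shaped sheath the pipeline

1. traces the inner (lumen-facing) and outer contours at sub-pixel precision
   (the boundary is located on the half-pixel midline between the last
   foreground and first background pixel);
2. fits an ellipse to the inner contour by direct algebraic least squares;
3. casts ``n_positions`` rays (default 10) from the fitted center at equally
   spaced angles and records, per ray, the distance to the inner-contour
   crossing ``d_in`` and to the nearest outer-contour crossing beyond it,
   ``d_out``; the thickness sample is ``d_out - d_in``;
4. pairs opposite rays into inner/outer diameters and takes the g-ratio as the
   mean of the per-pair inner/outer diameter ratios;
5. reports the axon diameter as the full short axis (``2 b``) of the
   inner-boundary ellipse, converted to nm with the pixel size.

Angles are measured from the image row axis; with 10 rays, ray ``i`` pairs
with ray ``i + 5``. All coordinates are (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .exceptions import BrokenRingError, EllipseFitError, InvertedRingError
from .layering import LayerSpec, UNASSIGNED, assign_layer
from .segmentation import SheathLabelMap, _HOLE_STRUCTURE

G_RATIO_MODES = ("mean_ratio", "equivalent_diameter")

#: g-ratio above which a sheath is flagged as acutely demyelinated (strict).
DEMYELINATION_G_THRESHOLD = 0.8


@dataclass(frozen=True)
class EllipseFit:
    """Geometric ellipse parameters: center, semi-axes (a >= b), orientation.

    ``orientation`` is the angle of the major axis from the image row axis,
    canonicalized to [0, pi). ``residual_rms`` is the rms Sampson (first-order
    geometric) distance of the fitted points, in pixels.
    """

    center: tuple[float, float]
    a: float
    b: float
    orientation: float
    residual_rms: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise EllipseFitError(f"semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Fit an ellipse to boundary points by direct least squares.

    Solves the ellipse-constrained algebraic fit (4ac - b^2 = 1) via the
    numerically stable block decomposition of the constrained eigenproblem,
    with coordinate centering for conditioning. Requires at least 6
    non-degenerate points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError(f"points must be (N, 2), got shape {pts.shape}")
    if pts.shape[0] < 6:
        raise EllipseFitError(f"ellipse underdetermined: need >= 6 points, got {pts.shape[0]}")
    mean = pts.mean(axis=0)
    x = pts[:, 0] - mean[0]
    y = pts[:, 1] - mean[1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("ellipse underdetermined: degenerate point set") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C1) for the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.isfinite(eigval) & (np.abs(eigval.imag) < 1e-9) & (cond.real > 0)
    if not np.any(valid):
        raise EllipseFitError("ellipse underdetermined: no elliptical solution")
    a1 = eigvec[:, valid].real[:, 0]
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F in centered coords
    fit = _conic_to_ellipse(coeffs, offset=mean)
    residual = _sampson_rms(coeffs, x, y)
    return EllipseFit(
        center=fit[0], a=fit[1], b=fit[2], orientation=fit[3], residual_rms=residual
    )


def _conic_to_ellipse(coeffs: np.ndarray, offset: np.ndarray):
    A, B, C, D, E, F = coeffs
    den = B * B - 4 * A * C
    if den >= 0:
        raise EllipseFitError("ellipse underdetermined: conic is not an ellipse")
    xc = (2 * C * D - B * E) / den
    yc = (2 * A * E - B * D) / den
    # centered conic: A x'^2 + B x'y' + C y'^2 + Fc = 0
    Fc = F + (D * xc + E * yc) / 2.0
    M2 = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(M2)
    axes2 = -Fc / lam
    if np.any(axes2 <= 0):
        raise EllipseFitError("ellipse underdetermined: degenerate axes")
    semi = np.sqrt(axes2)
    order = np.argsort(semi)[::-1]  # major first
    a, b = semi[order]
    major_vec = vec[:, order[0]]
    theta = float(np.arctan2(major_vec[1], major_vec[0])) % np.pi
    return (float(xc + offset[0]), float(yc + offset[1])), float(a), float(b), theta


def _sampson_rms(coeffs: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    A, B, C, D, E, F = coeffs
    q = A * x * x + B * x * y + C * y * y + D * x + E * y + F
    gx = 2 * A * x + B * y + D
    gy = B * x + 2 * C * y + E
    grad = np.hypot(gx, gy)
    grad[grad == 0] = np.finfo(float).eps
    return float(np.sqrt(np.mean((q / grad) ** 2)))


def trace_boundaries(label_map: SheathLabelMap, sheath_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Trace the inner and outer contours of an accepted sheath.

    Returns ordered (N, 2) sub-pixel point arrays in image (row, col)
    coordinates; contours run along the 0.5-level of the binary rasters, i.e.
    the half-pixel midline between foreground and background.
    """
    if sheath_id not in label_map.accepted_ids:
        raise ValueError(f"sheath id {sheath_id} is not an accepted label")
    rec = label_map.records.loc[label_map.records.sheath_id == sheath_id].iloc[0]
    r0, c0, r1, c1 = rec.bbox
    component = label_map.labels[r0:r1, c0:c1] == sheath_id
    padded = np.pad(component, 1)
    filled = ndimage.binary_fill_holes(padded, structure=_HOLE_STRUCTURE)
    lumen = filled & ~padded
    outer = _longest_contour(filled)
    inner = _longest_contour(lumen)
    shift = np.array([r0 - 1, c0 - 1], dtype=float)
    return inner + shift, outer + shift


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    contours = skmeasure.find_contours(mask.astype(float), 0.5, fully_connected="high")
    if not contours:
        raise BrokenRingError("no contour found")
    return max(contours, key=len)


def _ray_crossings(origin: np.ndarray, direction: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Distances (sorted, > 0) at which a ray crosses a closed polyline."""
    p = polygon
    q = np.roll(polygon, -1, axis=0)
    edge = q - p
    rel = p - origin
    denom = direction[0] * edge[:, 1] - direction[1] * edge[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0]) / denom
        s = (rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / denom
    ok = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s < 1.0) & (t > 1e-9)
    return np.sort(t[ok])


def measure_thickness(
    inner_fit: EllipseFit,
    inner_points: np.ndarray,
    outer_points: np.ndarray,
    n_positions: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample sheath thickness at ``n_positions`` ray angles.

    Rays start at angle 0 (the image row axis) and advance in equal steps of
    ``2 pi / n_positions`` from the fitted inner-ellipse center. Per ray the
    thickness sample is ``d_out - d_in``. Opposite rays are paired into
    ``n_positions / 2`` inner and outer diameters (``n_positions`` must be
    even). A ray that misses either contour marks the ring as broken.
    """
    if n_positions < 2 or n_positions % 2:
        raise ValueError(f"n_positions must be a positive even number, got {n_positions}")
    origin = np.asarray(inner_fit.center, dtype=float)
    angles = 2 * np.pi * np.arange(n_positions) / n_positions
    d_in = np.empty(n_positions)
    d_out = np.empty(n_positions)
    for i, theta in enumerate(angles):
        direction = np.array([np.cos(theta), np.sin(theta)])
        inner_cross = _ray_crossings(origin, direction, inner_points)
        if inner_cross.size == 0:
            raise BrokenRingError(f"ray {i} (angle {theta:.3f} rad) misses the inner contour")
        d_in[i] = inner_cross[0]
        outer_cross = _ray_crossings(origin, direction, outer_points)
        outer_cross = outer_cross[outer_cross > d_in[i] + 1e-9]
        if outer_cross.size == 0:
            raise BrokenRingError(f"ray {i} (angle {theta:.3f} rad) has no outer crossing beyond the inner")
        d_out[i] = outer_cross[0]
    half = n_positions // 2
    thickness = d_out - d_in
    inner_diameters = d_in[:half] + d_in[half:]
    outer_diameters = d_out[:half] + d_out[half:]
    return thickness, inner_diameters, outer_diameters


def compute_g_ratio(inner_diameters: np.ndarray, outer_diameters: np.ndarray) -> float:
    """g-ratio as the mean of paired inner/outer diameter ratios.

    Each opposite-ray diameter pair contributes one inner/outer ratio through
    the center point; the g-ratio is their mean, constrained to (0, 1).
    """
    inner = np.asarray(inner_diameters, dtype=float)
    outer = np.asarray(outer_diameters, dtype=float)
    if inner.shape != outer.shape or inner.size == 0:
        raise ValueError("inner and outer diameters must be non-empty and paired")
    if np.any(inner <= 0):
        raise ValueError("diameters must be positive")
    if np.any(outer <= inner):
        raise InvertedRingError("inverted ring geometry: outer diameter <= inner diameter")
    g = float(np.mean(inner / outer))
    assert 0.0 < g < 1.0
    return g


def equivalent_diameter_g_ratio(inner_points: np.ndarray, outer_points: np.ndarray) -> float:
    """Alternative g-ratio: ratio of equivalent diameters, sqrt(area_in/area_out)."""
    area_in = _polygon_area(inner_points)
    area_out = _polygon_area(outer_points)
    if not area_out > area_in > 0:
        raise InvertedRingError("inverted ring geometry: outer area <= inner area")
    return float(np.sqrt(area_in / area_out))


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def measure_axon_diameter(inner_region_points: np.ndarray) -> float:
    """Axon diameter in pixels: full short axis of the inner-boundary ellipse."""
    fit = fit_ellipse(inner_region_points)
    return 2.0 * fit.b


def to_physical_units(value_px: float, px_size_nm: float) -> float:
    """Convert a pixel measurement to nm (default imaging scale: 12 nm/pixel)."""
    if not px_size_nm > 0:
        raise ValueError(f"px_size_nm must be positive, got {px_size_nm}")
    return value_px * px_size_nm


def flag_demyelination(g: float, threshold: float = DEMYELINATION_G_THRESHOLD) -> bool:
    """True iff the g-ratio strictly exceeds the acute-demyelination threshold.

    Healthy white matter sits near g = 0.7; values above 0.8 indicate acute
    demyelination. The comparison is strict: g exactly at the threshold is not
    flagged.
    """
    if not 0.0 < g < 1.0:
        raise ValueError(f"g must lie in (0, 1), got {g}")
    return g > threshold


def measure_sheaths(
    label_map: SheathLabelMap,
    px_size_nm: float = 12.0,
    n_positions: int = 10,
    layer_spec: LayerSpec | None = None,
    g_mode: str = "mean_ratio",
    demyelination_threshold: float = DEMYELINATION_G_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every accepted sheath in a label map.

    Returns ``(measurements, exclusions)``: one row per successfully measured
    sheath (thickness samples t1..tN in px, mean thickness in px and nm,
    g-ratio, axon diameter in px and nm, layer, demyelination flag) and a log
    of sheaths excluded during measurement with the reason.
    """
    if g_mode not in G_RATIO_MODES:
        raise ValueError(f"g_mode must be one of {G_RATIO_MODES}, got {g_mode!r}")
    rows = []
    excluded = []
    for sheath_id in label_map.accepted_ids:
        try:
            inner_pts, outer_pts = trace_boundaries(label_map, sheath_id)
            inner_fit = fit_ellipse(inner_pts)
            thickness, inner_d, outer_d = measure_thickness(
                inner_fit, inner_pts, outer_pts, n_positions=n_positions
            )
            if g_mode == "mean_ratio":
                g = compute_g_ratio(inner_d, outer_d)
            else:
                g = equivalent_diameter_g_ratio(inner_pts, outer_pts)
            diameter_px = 2.0 * inner_fit.b
        except (BrokenRingError, EllipseFitError, InvertedRingError) as exc:
            excluded.append({"sheath_id": sheath_id, "reason": f"{type(exc).__name__}: {exc}"})
            continue
        depth = inner_fit.center[0]
        layer = assign_layer(max(depth, 0.0), layer_spec) if layer_spec is not None else UNASSIGNED
        row = {"sheath_id": sheath_id, "layer": layer}
        row.update({f"t{i + 1}": thickness[i] for i in range(n_positions)})
        thickness_mean = float(thickness.mean())
        row.update(
            {
                "thickness_mean_px": thickness_mean,
                "thickness_mean_nm": to_physical_units(thickness_mean, px_size_nm),
                "g_ratio": g,
                "axon_diameter_px": diameter_px,
                "axon_diameter_nm": to_physical_units(diameter_px, px_size_nm),
                "depth_px": depth,
                "center_col_px": inner_fit.center[1],
                "demyelination_flag": flag_demyelination(g, demyelination_threshold),
                "qc": "",
            }
        )
        rows.append(row)
    columns = (
        ["sheath_id", "layer"]
        + [f"t{i + 1}" for i in range(n_positions)]
        + [
            "thickness_mean_px",
            "thickness_mean_nm",
            "g_ratio",
            "axon_diameter_px",
            "axon_diameter_nm",
            "depth_px",
            "center_col_px",
            "demyelination_flag",
            "qc",
        ]
    )
    measurements = pd.DataFrame(rows, columns=columns)
    exclusions = pd.DataFrame(excluded, columns=["sheath_id", "reason"])
    return measurements, exclusions
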