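"""Synthetic EM scene generator with exact ground truth.

Emulates osmium-stained cortical cross-sections: dark annular myelin sheaths
(low gray value) wrapping lighter elliptical axon lumina on a light background,
with additive Gaussian sensor noise. Every rendered axon carries its true
g-ratio, ring thickness and lumen diameter, so segmentation and morphometry can
be validated against known values without real acquisitions.

Geometry model per axon:

* the inner (lumen) boundary is an ellipse with semi-axes ``a_in >= b_in``;
* the myelin ring has uniform width ``thickness_true`` along the boundary
  normal, i.e. the outer boundary is the offset curve of the inner ellipse;
* ``thickness_true`` is derived from the drawn g-ratio via the mean inner
  radius ``r_eff = (a_in + b_in) / 2`` as ``t = r_eff * (1 - g) / g``, which for
  circular axons makes ``g = r_in / (r_in + t)`` hold exactly.

Scenes are cortical-depth layouts: depth is the image row, the layer-1 band
occupies the top quarter of the default image and layers 2/3 the remaining
three quarters (3:1 depth proportion).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, stats

from .exceptions import SceneDensityError
from .layering import LayerSpec, assign_layer

#: truncation bounds for sampled g-ratios — spans the biologically meaningful
#: range (healthy ~0.7, acutely demyelinated >0.8) without degenerate rings.
G_TRUNC = (0.40, 0.95)

#: per-axon placement retry budget before declaring the scene infeasible.
PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class AxonSpec:
    """Ground-truth geometry of one myelinated axon cross-section."""

    axon_id: int
    center: tuple[float, float]          # (row, col), pixels
    inner_semi_axes: tuple[float, float]  # (a_in, b_in), a_in >= b_in, pixels
    orientation: float                    # radians in [0, pi)
    g_true: float
    thickness_true: float                 # uniform ring width, pixels

    def __post_init__(self) -> None:
        a_in, b_in = self.inner_semi_axes
        if not (a_in >= b_in >= 3.0):
            raise ValueError(f"semi-axes must satisfy a_in >= b_in >= 3 px, got {self.inner_semi_axes}")
        if not 0.0 < self.g_true < 1.0:
            raise ValueError(f"g_true must lie in (0, 1), got {self.g_true}")
        if not self.thickness_true > 0:
            raise ValueError("thickness_true must be positive")

    @property
    def depth(self) -> float:
        """Depth from the cortical surface (row 0), pixels."""
        return self.center[0]

    @property
    def outer_extent(self) -> float:
        """Radius of the bounding circle of the outer boundary."""
        return self.inner_semi_axes[0] + self.thickness_true


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic cortical EM scene.

    Defaults encode the study conditions the analysis assumes: 12 nm/pixel
    sampling, a healthy g-ratio distribution centered at 0.7 (sd 0.05),
    myelinated-axon lumen diameters around 1 um, and a layer-1 band occupying
    the top quarter of the image so that layers 2/3 span three times its depth.
    """

    image_shape: tuple[int, int] = (1536, 1536)
    px_size_nm: float = 12.0
    n_axons: int = 25
    layer1_depth_px: float = 384.0
    g_mean: float = 0.70
    g_sd: float = 0.05
    diameter_mean_nm: float = 1000.0
    diameter_sd_nm: float = 200.0
    aspect_ratio_range: tuple[float, float] = (1.0, 1.3)
    myelin_gray: float = 60.0
    background_gray: float = 180.0
    lumen_gray: float = 160.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML/JSON round-trips deliver lists; normalize so spec equality holds
        object.__setattr__(self, "image_shape", tuple(int(v) for v in self.image_shape))
        object.__setattr__(self, "aspect_ratio_range", tuple(float(v) for v in self.aspect_ratio_range))
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if not self.layer1_depth_px > 0:
            raise ValueError("layer1_depth_px must be positive")
        if 4 * self.layer1_depth_px > rows:
            raise ValueError(
                f"4*layer1_depth_px ({4 * self.layer1_depth_px}) exceeds image rows ({rows}); "
                "no room for the layer-1 + layer-2/3 bands"
            )
        if self.n_axons < 0:
            raise ValueError("n_axons must be non-negative")
        if not self.px_size_nm > 0:
            raise ValueError("px_size_nm must be positive")
        if not (G_TRUNC[0] > 0 and G_TRUNC[1] < 1):
            raise ValueError("g truncation bounds must lie inside (0, 1)")
        if not 0 < self.g_mean < 1 or self.g_sd <= 0:
            raise ValueError("g_mean must lie in (0,1) and g_sd be positive")
        lo = max(self.g_mean - 3 * self.g_sd, G_TRUNC[0])
        hi = min(self.g_mean + 3 * self.g_sd, G_TRUNC[1])
        if not (0 < lo < hi < 1):
            raise ValueError("g_mean +/- 3*g_sd must stay inside (0, 1) after truncation")
        a_lo, a_hi = self.aspect_ratio_range
        if not 1.0 <= a_lo <= a_hi:
            raise ValueError("aspect_ratio_range must satisfy 1 <= lo <= hi")

    @property
    def layer_spec(self) -> LayerSpec:
        return LayerSpec(layer1_depth_px=self.layer1_depth_px)

    def diameter_bounds_nm(self) -> tuple[float, float]:
        """Truncation bounds for lumen (short-axis) diameters in nm.

        Lower bound keeps the minor semi-axis resolvable (b_in >= 3 px, with a
        safety margin) and within 3 sd of the mean.
        """
        floor = max(self.diameter_mean_nm - 3 * self.diameter_sd_nm, 8 * self.px_size_nm)
        ceil = self.diameter_mean_nm + 3 * self.diameter_sd_nm
        if not floor < ceil:
            raise ValueError("degenerate diameter truncation bounds")
        return floor, ceil

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)


def _truncnorm(mean: float, sd: float, lo: float, hi: float) -> stats.rv_continuous:
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def g_distribution(spec: SceneSpec) -> stats.rv_continuous:
    """Frozen truncated-normal distribution of true g-ratios for ``spec``."""
    return _truncnorm(spec.g_mean, spec.g_sd, *G_TRUNC)


def sample_truth_metrics(
    spec: SceneSpec, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw ``n`` axon morphologies (no spatial placement) with depths.

    Returns the marginal distribution of the scene's per-axon ground truth —
    g-ratio, ring thickness, lumen diameter, cortical depth and layer — as a
    DataFrame. Used for large-scale statistical calibration where rendering
    every axon would be pointless: under identical specs the two groups are
    exchangeable regardless of the imaging stage.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = g_distribution(spec).rvs(size=n, random_state=rng)
    d_lo, d_hi = spec.diameter_bounds_nm()
    diam_nm = _truncnorm(spec.diameter_mean_nm, spec.diameter_sd_nm, d_lo, d_hi).rvs(
        size=n, random_state=rng
    )
    aspect = rng.uniform(*spec.aspect_ratio_range, size=n)
    orientation = rng.uniform(0.0, np.pi, size=n)
    b_in = diam_nm / (2 * spec.px_size_nm)
    a_in = aspect * b_in
    r_eff = (a_in + b_in) / 2
    thickness = r_eff * (1 - g) / g
    depth = rng.uniform(0.0, 4 * spec.layer1_depth_px, size=n)
    layer = [assign_layer(d, spec.layer_spec) for d in depth]
    return pd.DataFrame(
        {
            "g_true": g,
            "thickness_true_px": thickness,
            "thickness_true_nm": thickness * spec.px_size_nm,
            "diameter_true_nm": 2 * b_in * spec.px_size_nm,
            "a_in_px": a_in,
            "b_in_px": b_in,
            "orientation": orientation,
            "depth": depth,
            "layer_true": layer,
        }
    )


def sample_axon_population(
    spec: SceneSpec, rng: np.random.Generator | None = None
) -> list[AxonSpec]:
    """Place ``spec.n_axons`` non-overlapping axons inside the image.

    Placement is rejection sampling on bounding circles of the outer
    boundaries with a 2 px clearance; no outer boundary touches the image
    border. Deterministic given ``spec.seed``.

    Raises
    ------
    SceneDensityError
        If any axon cannot be placed within the retry budget.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    morph = sample_truth_metrics(spec, spec.n_axons, rng)
    rows, cols = spec.image_shape
    placed_centers = np.empty((0, 2))
    placed_radii = np.empty(0)
    axons: list[AxonSpec] = []
    for i in range(spec.n_axons):
        a_in = float(morph.a_in_px[i])
        b_in = float(morph.b_in_px[i])
        t = float(morph.thickness_true_px[i])
        r_out = a_in + t
        # must cover the render patch: ceil(outer extent) + 3 around the
        # rounded center, plus rounding slack
        margin = float(np.ceil(r_out)) + 4.0
        if 2 * margin >= min(rows, cols):
            raise SceneDensityError(
                f"density infeasible: axon {i} (outer radius {r_out:.1f} px) cannot fit "
                f"inside a {rows}x{cols} image"
            )
        for _ in range(PLACEMENT_RETRIES):
            center = rng.uniform([margin, margin], [rows - margin, cols - margin])
            if placed_centers.size:
                d = np.hypot(*(placed_centers - center).T)
                if np.any(d < placed_radii + r_out + 2.0):
                    continue
            break
        else:
            raise SceneDensityError(
                f"density infeasible: could not place axon {i} of {spec.n_axons} "
                f"after {PLACEMENT_RETRIES} retries"
            )
        placed_centers = np.vstack([placed_centers, center])
        placed_radii = np.append(placed_radii, r_out)
        axons.append(
            AxonSpec(
                axon_id=i,
                center=(float(center[0]), float(center[1])),
                inner_semi_axes=(a_in, b_in),
                orientation=float(morph.orientation[i]),
                g_true=float(morph.g_true[i]),
                thickness_true=t,
            )
        )
    return axons


def ground_truth_table(axons: Sequence[AxonSpec], spec: SceneSpec) -> pd.DataFrame:
    """Tabulate the per-axon ground truth in physical units."""
    layer_spec = spec.layer_spec
    rows = [
        {
            "axon_id": ax.axon_id,
            "g_true": ax.g_true,
            "thickness_true_nm": ax.thickness_true * spec.px_size_nm,
            "diameter_true_nm": 2 * ax.inner_semi_axes[1] * spec.px_size_nm,
            "layer_true": assign_layer(ax.depth, layer_spec),
            "depth": ax.depth,
        }
        for ax in axons
    ]
    columns = ["axon_id", "g_true", "thickness_true_nm", "diameter_true_nm", "layer_true", "depth"]
    return pd.DataFrame(rows, columns=columns)


_SUPERSAMPLE = 5  # odd, so every pixel center lies on the fine grid


def _render_axon(ax: AxonSpec, image: np.ndarray, truth_mask: np.ndarray, spec: SceneSpec) -> None:
    rows, cols = image.shape
    half = int(np.ceil(ax.outer_extent)) + 3
    r0, c0 = int(round(ax.center[0])), int(round(ax.center[1]))
    rlo, rhi = r0 - half, r0 + half + 1
    clo, chi = c0 - half, c0 + half + 1
    if rlo < 0 or clo < 0 or rhi > rows or chi > cols:
        raise ValueError(f"axon {ax.axon_id} extends outside the image")
    # classify on a 5x supersampled grid so the uniform-width ring (an offset
    # curve of the inner ellipse, resolved by an EDT) is accurate to ~0.1 px
    f = _SUPERSAMPLE
    n = rhi - rlo
    fine = rlo - 0.5 + (np.arange(n * f) + 0.5) / f
    rr = fine[:, None]
    cc = (clo - 0.5 + (np.arange((chi - clo) * f) + 0.5) / f)[None, :]
    dr = rr - ax.center[0]
    dc = cc - ax.center[1]
    # rotate into the ellipse frame; orientation measured from the row axis
    ct, st = np.cos(ax.orientation), np.sin(ax.orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a_in, b_in = ax.inner_semi_axes
    inner_fine = (u / a_in) ** 2 + (v / b_in) ** 2 <= 1.0
    dist = ndimage.distance_transform_edt(~inner_fine)
    myelin_fine = (dist > 0) & (dist <= ax.thickness_true * f)
    # pixel centers sit at fine index f*i + f//2
    inner = inner_fine[f // 2 :: f, f // 2 :: f]
    myelin = myelin_fine[f // 2 :: f, f // 2 :: f]
    patch_img = image[rlo:rhi, clo:chi]
    patch_img[inner] = spec.lumen_gray
    patch_img[myelin] = spec.myelin_gray
    truth_mask[rlo:rhi, clo:chi] |= myelin


def render_scene(
    axons: Sequence[AxonSpec], spec: SceneSpec
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a scene to (8-bit image, boolean truth mask, ground-truth table).

    The image is background gray everywhere, lumen gray inside inner ellipses
    and myelin gray in the rings, plus Gaussian noise of sd ``spec.noise_sd``
    clipped to [0, 255]. The truth mask is the noiseless binary myelin raster.
    """
    image = np.full(spec.image_shape, float(spec.background_gray))
    truth_mask = np.zeros(spec.image_shape, dtype=bool)
    for ax in axons:
        _render_axon(ax, image, truth_mask, spec)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x6E6F6973])
        image = image + noise_rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, truth_mask, ground_truth_table(axons, spec)


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    control_spec: SceneSpec,
    treated_spec: SceneSpec,
    n_images_per_group: int,
    out_dir: str | Path,
    seed: int = 0,
    overwrite: bool = False,
) -> Path:
    """Write a two-group image cohort (images, truth masks, tables, manifest).

    Per-image seeds are derived deterministically from ``seed``. Refuses to
    write into an existing non-empty directory unless ``overwrite`` is set.
    Returns the path to ``manifest.json``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "images": []}
    index = 0
    for group, spec in (("control", control_spec), ("treated", treated_spec)):
        for i in range(n_images_per_group):
            img_seed = _child_seed(seed, index)
            index += 1
            img_spec = spec.replace(seed=img_seed)
            axons = sample_axon_population(img_spec)
            image, truth_mask, table = render_scene(axons, img_spec)
            stem = f"{group}_{i:03d}"
            tifffile.imwrite(out / f"{stem}.tif", image)
            tifffile.imwrite(out / f"{stem}_truth_mask.tif", (truth_mask * np.uint8(255)))
            table.to_csv(out / f"{stem}_truth.csv", index=False)
            manifest["images"].append(
                {
                    "image": f"{stem}.tif",
                    "truth_mask": f"{stem}_truth_mask.tif",
                    "truth_table": f"{stem}_truth.csv",
                    "group": group,
                    "seed": img_seed,
                    "px_size_nm": img_spec.px_size_nm,
                    "layer1_depth_px": img_spec.layer1_depth_px,
                }
            )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
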