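"""Cortical layer stratification.

Measured marmoset/human prefrontal cortex proportions put the combined depth of
layers 2 and 3 at three times the depth of layer 1, so a single parameter — the
layer-1 band depth ``d1`` in pixels from the cortical surface (image row 0) —
fixes both bands:

    L1   = [0, d1)
    L2/3 = [d1, 4*d1)

Depths at or beyond ``4*d1`` fall outside the analysed laminae and are labelled
``unassigned`` (excluded from group statistics). A sheath's depth is the row
coordinate of its fitted inner-ellipse center.
"""

from __future__ import annotations

from dataclasses import dataclass

LAYER_1 = "L1"
LAYER_2_3 = "L2_3"
UNASSIGNED = "unassigned"

#: Depth of the layer-2/3 band relative to layer 1.
L23_TO_L1_RATIO = 3


@dataclass(frozen=True)
class LayerSpec:
    """Layer bands derived from the layer-1 depth ``d1`` (pixels)."""

    layer1_depth_px: float

    def __post_init__(self) -> None:
        if not self.layer1_depth_px > 0:
            raise ValueError(f"layer1_depth_px must be positive, got {self.layer1_depth_px}")

    @property
    def l1_band(self) -> tuple[float, float]:
        return (0.0, float(self.layer1_depth_px))

    @property
    def l2_3_band(self) -> tuple[float, float]:
        d1 = float(self.layer1_depth_px)
        return (d1, (1 + L23_TO_L1_RATIO) * d1)


def build_layer_bands(layer1_depth_px: float) -> LayerSpec:
    """Build the half-open L1 / L2-3 bands from the layer-1 depth in pixels."""
    return LayerSpec(layer1_depth_px=float(layer1_depth_px))


def assign_layer(center_depth_px: float, spec: LayerSpec) -> str:
    """Map a depth (pixels from the cortical surface) to a layer label.

    Bands are half-open, so a depth exactly at ``d1`` belongs to L2/3.
    """
    depth = float(center_depth_px)
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    if depth < spec.layer1_depth_px:
        return LAYER_1
    if depth < spec.l2_3_band[1]:
        return LAYER_2_3
    return UNASSIGNED
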