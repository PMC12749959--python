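"""2D raster projection of neuron morphologies for CNN classification.

Three representation styles mirror the three visualization conventions the
image classifier is trained on:

- ``original``       — unit-width dark strokes (plain skeleton);
- ``diameter_enhanced`` — stroke width proportional to compartment diameter;
- ``soma_focused``   — the soma is drawn as a filled polygon enlarged by a
  configurable factor, emphasizing cell-body shape.

All styles are xy orthographic projections (no rotation), dark ink on a
white background, auto-fitted with a 5% margin.  Masking occludes either a
disc around the projected soma centroid (``soma_masked``) or everything
outside it (``dendrite_masked``); the disc radius defaults to 1.5× the
projected soma bounding radius.  :func:`normalize` applies the ImageNet
per-channel statistics (mean [0.485, 0.456, 0.406], std [0.229, 0.224,
0.225]) expected by transfer-learning backbones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from PIL import Image, ImageDraw

from .swc_io import NeuronTree

__all__ = [
    "RenderedImage",
    "STYLES",
    "MASKS",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "render",
    "apply_mask",
    "normalize",
    "denormalize",
    "render_dataset",
]

STYLES = ("original", "diameter_enhanced", "soma_focused")
MASKS = ("none", "soma_masked", "dendrite_masked")

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

#: anti-aliasing supersampling factor
_SS = 4


@dataclass(frozen=True)
class RenderedImage:
    """A rendered projection with the metadata downstream stages need.

    ``soma_center_px`` / ``soma_mask_radius_px`` locate the soma disc used
    by masking and by Grad-CAM region summaries; ``scale`` is µm per pixel.
    """

    pixels: np.ndarray  # H×W×3 float in [0, 1]
    style: str
    mask: str
    cell_id: str
    scale: float
    soma_center_px: tuple[float, float]
    soma_mask_radius_px: float

    def __post_init__(self) -> None:
        h, w, c = self.pixels.shape
        if h != w or c != 3:
            raise ValueError(f"expected square H×W×3 pixels, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def ink(self) -> np.ndarray:
        """Per-pixel ink amount (1 = black stroke, 0 = background)."""
        return 1.0 - self.pixels.mean(axis=2)

    def to_pil(self) -> Image.Image:
        return Image.fromarray((self.pixels * 255).round().astype(np.uint8))


def _fit_transform(
    tree: NeuronTree, size: int, margin: float = 0.05,
    extent_um: float | None = None,
    center_on_soma: bool = False,
):
    """Map xy µm coordinates to pixel coordinates with a 5% margin.

    ``extent_um`` overrides the per-cell bounding extent so a cohort can be
    rendered at one common scale (µm per pixel); ``center_on_soma`` centers
    the frame on the soma centroid instead of the bounding-box center (the
    cell may then clip at the borders)."""
    xs = np.array([n.x for n in tree.nodes])
    ys = np.array([n.y for n in tree.nodes])
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    extent = max(x1 - x0, y1 - y0, 1e-9)
    if extent_um is not None:
        extent = max(extent_um, extent * 1e-9)
    usable = size * (1.0 - 2.0 * margin)
    scale_px_per_um = usable / extent
    if center_on_soma and tree.soma_nodes:
        soma = tree.soma_nodes
        cx = float(np.mean([n.x for n in soma]))
        cy = float(np.mean([n.y for n in soma]))
    else:
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0

    def to_px(x: float, y: float) -> tuple[float, float]:
        # image y axis points down
        return (
            size / 2.0 + (x - cx) * scale_px_per_um,
            size / 2.0 - (y - cy) * scale_px_per_um,
        )

    return to_px, 1.0 / scale_px_per_um


def render(
    tree: NeuronTree,
    style: str = "original",
    size: int = 224,
    stroke_scale: float = 1.0,
    soma_enlargement: float = 2.0,
    mask_radius_factor: float = 1.5,
    extent_um: float | None = None,
    center_on_soma: bool = False,
) -> RenderedImage:
    """Project a tree to a ``size``×``size`` RGB raster in the given style.

    ``stroke_scale`` converts compartment diameter (px) to stroke width in
    the diameter_enhanced style; ``soma_enlargement`` scales the filled soma
    polygon in the soma_focused style.  Deterministic for fixed inputs.
    """
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    if not tree.nodes:
        raise ValueError("cannot render an empty tree")

    to_px, um_per_px = _fit_transform(
        tree, size, extent_um=extent_um, center_on_soma=center_on_soma
    )
    ss = _SS
    canvas = Image.new("L", (size * ss, size * ss), color=255)
    draw = ImageDraw.Draw(canvas)

    def px(x, y):
        u, v = to_px(x, y)
        return (u * ss, v * ss)

    soma = tree.soma_nodes
    soma_pts = [px(n.x, n.y) for n in soma]
    if soma_pts:
        cx = float(np.mean([p[0] for p in soma_pts]))
        cy = float(np.mean([p[1] for p in soma_pts]))
        bound_r = max(
            (float(np.hypot(p[0] - cx, p[1] - cy)) for p in soma_pts),
            default=0.0,
        )
        if len(soma) == 1:
            bound_r = soma[0].radius / um_per_px * ss
        if style == "soma_focused":
            # the enlarged polygon must stay inside the soma mask disc
            bound_r *= soma_enlargement
    else:
        cx = cy = size * ss / 2.0
        bound_r = 0.0

    # strokes for every compartment
    for n in tree.nodes:
        p = tree.parent(n.id)
        if p is None:
            continue
        if style == "diameter_enhanced":
            diam_px = 2.0 * n.radius / um_per_px
            width = max(1, int(round(stroke_scale * diam_px * ss)))
        else:
            width = max(1, int(round(stroke_scale * ss)))
        draw.line([px(p.x, p.y), px(n.x, n.y)], fill=0, width=width)

    if style == "soma_focused" and soma:
        if len(soma) >= 3:
            pts = [
                (cx + soma_enlargement * (p[0] - cx),
                 cy + soma_enlargement * (p[1] - cy))
                for p in soma_pts
            ]
            draw.polygon(pts, fill=0)
        else:
            r = max(bound_r, ss)  # bound_r already carries the enlargement
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=0)

    img = canvas.resize((size, size), Image.LANCZOS)
    gray = np.asarray(img, dtype=np.float64) / 255.0
    pixels = np.clip(np.repeat(gray[:, :, None], 3, axis=2), 0.0, 1.0)

    return RenderedImage(
        pixels=pixels,
        style=style,
        mask="none",
        cell_id=tree.provenance or "unknown",
        scale=um_per_px,
        soma_center_px=(cx / ss, cy / ss),
        soma_mask_radius_px=max(bound_r / ss * mask_radius_factor, 1.0),
    )


def _disc_mask(image: RenderedImage) -> np.ndarray:
    """Boolean H×W array, True inside the soma disc."""
    size = image.size
    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = image.soma_center_px
    r = image.soma_mask_radius_px
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def apply_mask(image: RenderedImage, mask: str) -> RenderedImage:
    """Occlude the soma disc (``soma_masked``) or its complement
    (``dendrite_masked``) with the background color."""
    if mask not in ("soma_masked", "dendrite_masked"):
        raise ValueError(f"unknown mask {mask!r}")
    inside = _disc_mask(image)
    pixels = image.pixels.copy()
    if mask == "soma_masked":
        pixels[inside] = 1.0
    else:
        pixels[~inside] = 1.0
    return dc_replace(image, pixels=pixels, mask=mask)


def normalize(image: RenderedImage | np.ndarray) -> np.ndarray:
    """Per-channel ImageNet normalization: (x − mean) / std.

    Accepts a RenderedImage or a raw H×W×3 array in [0, 1]; returns C×H×W
    float array ready for a CNN.
    """
    pixels = image.pixels if isinstance(image, RenderedImage) else np.asarray(image)
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("pixels must lie in [0, 1] before normalization")
    normed = (pixels - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(normed.transpose(2, 0, 1))


def denormalize(tensor: np.ndarray) -> np.ndarray:
    """Invert :func:`normalize` back to H×W×3 pixels in [0, 1]."""
    pixels = tensor.transpose(1, 2, 0) * IMAGENET_STD + IMAGENET_MEAN
    return pixels


def render_dataset(
    trees: dict[str, NeuronTree],
    labels: dict[str, str],
    style: str = "original",
    size: int = 224,
    mask: str = "none",
    common_scale: bool = False,
    **render_kw,
) -> tuple[list[RenderedImage], np.ndarray]:
    """Render a labeled cohort; returns (images, binary labels) with the
    positive class VEN = 1.

    ``common_scale`` renders every cell at the cohort-maximum extent so all
    images share one µm-per-pixel scale (removes cell-size cues).
    """
    if common_scale and "extent_um" not in render_kw:
        extents = []
        for tree in trees.values():
            xs = [n.x for n in tree.nodes]
            ys = [n.y for n in tree.nodes]
            extents.append(max(max(xs) - min(xs), max(ys) - min(ys)))
        render_kw["extent_um"] = max(extents)
    images, y = [], []
    for cid, tree in trees.items():
        img = render(tree, style=style, size=size, **render_kw)
        img = dc_replace(img, cell_id=cid)
        if mask != "none":
            img = apply_mask(img, mask)
        images.append(img)
        y.append(1 if labels[cid] == "VEN" else 0)
    return images, np.array(y, dtype=int)
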