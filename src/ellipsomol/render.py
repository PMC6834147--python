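"""Software glyph ray caster with illustrative post-processing.

Spheres and ellipsoids are rendered as implicit surfaces by per-pixel
ray-quadric intersection rather than as meshes.  An ellipsoid glyph is
intersected in its own glyph space: the ray is translated by −c and
rotated by Vᵀ, the canonical quadric x²/a² + y²/b² + z²/c² = 1 is solved,
and the glyph-space normal (x/a², y/b², z/c²) is rotated back.  The
rotation preserves ray-parameter length, so depth is correct without
further correction.  Per glyph, only the pixels inside the screen-space
projection of a concentric agent sphere of radius λmax are tested.

Post-processing on the frame buffer: Lambertian diffuse (or constant)
shading, depth-dependent silhouettes from 8-neighbour depth
discontinuities, and screen-space ambient occlusion (SSAO) from
normal-oriented hemisphere samples against the depth buffer.

The depth buffer stores the eye-space ray parameter t in Å (∞ for
background), which makes the silhouette threshold and test oracles direct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .bounding import Ellipsoid
from .hierarchy import NodeLevel, Sphere

__all__ = [
    "Camera",
    "Ray",
    "Hit",
    "FrameBuffer",
    "RenderSettings",
    "LEVEL_PALETTE",
    "generate_ray",
    "ray_sphere_intersect",
    "ray_ellipsoid_intersect",
    "screen_bound",
    "render_frame",
    "shade_diffuse",
    "silhouette_pass",
    "ssao_pass",
    "composite",
    "write_image",
]

_EPS_T = 1e-12

#: Default per-level glyph colors (RGB in [0,1]).
LEVEL_PALETTE: dict[NodeLevel, tuple[float, float, float]] = {
    NodeLevel.ATOM: (0.35, 0.55, 0.85),
    NodeLevel.RESIDUE_INTERIOR: (0.40, 0.75, 0.45),
    NodeLevel.RESIDUE: (0.95, 0.75, 0.25),
    NodeLevel.RESIDUE_LINK: (0.85, 0.45, 0.30),
    NodeLevel.MOLECULE: (0.70, 0.40, 0.70),
}


@dataclass(frozen=True)
class Camera:
    """Right-handed pinhole camera; pixel (0, 0) is top-left, y runs down."""

    position: np.ndarray
    target: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    vertical_fov: float = 45.0  # degrees
    width: int = 512
    height: int = 512

    def __post_init__(self) -> None:
        for name in ("position", "target", "up"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (0.0 < self.vertical_fov < 180.0):
            raise ValueError("vertical_fov must be in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        f = self.target - self.position
        nf = np.linalg.norm(f)
        if nf == 0 or np.linalg.norm(np.cross(f / nf, self.up)) < 1e-12:
            raise ValueError("up vector must not be parallel to the view direction")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(forward, right, up) orthonormal frame."""
        f = self.target - self.position
        f = f / np.linalg.norm(f)
        r = np.cross(f, self.up)
        r = r / np.linalg.norm(r)
        u = np.cross(r, f)
        return f, r, u

    @property
    def tan_half_fov(self) -> float:
        return math.tan(math.radians(self.vertical_fov) / 2.0)

    @property
    def aspect(self) -> float:
        return self.width / self.height


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray  # unit

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise ValueError("ray direction must be unit length")


@dataclass(frozen=True)
class Hit:
    t: float  # ray parameter = eye-space distance, Å
    point: np.ndarray
    normal: np.ndarray  # unit, outward
    node_id: int = -1


@dataclass
class FrameBuffer:
    """Per-pixel color, eye-space depth (∞ = background), and surface normal."""

    color: np.ndarray  # (H, W, 3) float in [0, 1]
    depth: np.ndarray  # (H, W) float, Å
    normal: np.ndarray  # (H, W, 3) float, unit where depth finite
    albedo: np.ndarray  # (H, W, 3) float, pre-shading glyph color
    node_id: np.ndarray  # (H, W) int, -1 = background

    @classmethod
    def empty(cls, width: int, height: int,
              background: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> "FrameBuffer":
        color = np.tile(np.asarray(background, dtype=float), (height, width, 1))
        return cls(
            color=color,
            depth=np.full((height, width), np.inf),
            normal=np.zeros((height, width, 3)),
            albedo=color.copy(),
            node_id=np.full((height, width), -1, dtype=int),
        )

    @property
    def foreground(self) -> np.ndarray:
        return np.isfinite(self.depth)


@dataclass(frozen=True)
class RenderSettings:
    shading: str = "diffuse"  # "diffuse" | "constant"
    contours: bool = True
    ssao: bool = True
    light_direction: Optional[np.ndarray] = None  # None = headlight (toward camera)
    ambient: float = 0.2
    ssao_samples: int = 16
    ssao_radius: float = 3.0  # Å
    ssao_seed: int = 0
    silhouette_threshold: float = 1.0  # Å
    silhouette_depth_scale: float = 0.01  # per Å
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.shading not in ("diffuse", "constant"):
            raise ValueError("shading must be 'diffuse' or 'constant'")
        if self.ssao and self.ssao_samples < 1:
            raise ValueError("ssao_samples must be >= 1 when SSAO is on")
        if self.silhouette_threshold <= 0 or self.silhouette_depth_scale < 0:
            raise ValueError("invalid silhouette parameters")
        if self.light_direction is not None:
            ld = np.asarray(self.light_direction, dtype=float)
            object.__setattr__(self, "light_direction", ld / np.linalg.norm(ld))


# --------------------------------------------------------------------------
# Ray generation and intersection
# --------------------------------------------------------------------------

def _pixel_directions(camera: Camera, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Unit directions through pixel centers; px/py broadcastable arrays."""
    f, r, u = camera.basis()
    th = camera.tan_half_fov
    sx = (2.0 * (px + 0.5) / camera.width - 1.0) * th * camera.aspect
    sy = (1.0 - 2.0 * (py + 0.5) / camera.height) * th
    d = (f[None, :] + np.multiply.outer(sx, r) + np.multiply.outer(sy, u)
         if np.ndim(sx) == 1 else f + sx * r + sy * u)
    d = np.atleast_2d(d)
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def generate_ray(camera: Camera, px: int, py: int) -> Ray:
    """Ray through the center of pixel (px, py)."""
    if not (0 <= px < camera.width and 0 <= py < camera.height):
        raise ValueError(f"pixel ({px}, {py}) outside {camera.width}x{camera.height}")
    d = _pixel_directions(camera, np.array([float(px)]), np.array([float(py)]))[0]
    return Ray(origin=camera.position, direction=d)


def _smallest_positive_root(a: float, b: float, c: float) -> Optional[float]:
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    if t1 > _EPS_T:
        return t1
    if t2 > _EPS_T:
        return t2
    return None


def ray_sphere_intersect(ray: Ray, s: Sphere, node_id: int = -1) -> Optional[Hit]:
    """Nearest positive intersection with a sphere; outward normal."""
    oc = ray.origin - s.center
    b = 2.0 * float(np.dot(oc, ray.direction))
    c = float(np.dot(oc, oc)) - s.radius**2
    t = _smallest_positive_root(1.0, b, c)
    if t is None:
        return None
    point = ray.origin + t * ray.direction
    return Hit(t=t, point=point, normal=(point - s.center) / s.radius, node_id=node_id)


def ray_ellipsoid_intersect(ray: Ray, e: Ellipsoid, node_id: int = -1) -> Optional[Hit]:
    """Nearest positive intersection with an ellipsoid via its glyph space.

    The ray is moved into the frame where the ellipsoid is the canonical
    quadric; the rotation is rigid so the returned t is the eye-space depth.
    """
    V = e.axes
    inv_sq = 1.0 / e.semi_axes**2
    o = V.T @ (ray.origin - e.center)
    d = V.T @ ray.direction
    a = float(np.dot(d * inv_sq, d))
    b = 2.0 * float(np.dot(o * inv_sq, d))
    c = float(np.dot(o * inv_sq, o)) - 1.0
    t = _smallest_positive_root(a, b, c)
    if t is None:
        return None
    p_glyph = o + t * d
    n_glyph = p_glyph * inv_sq
    n = V @ n_glyph
    n = n / np.linalg.norm(n)
    return Hit(t=t, point=ray.origin + t * ray.direction, normal=n, node_id=node_id)


def screen_bound(center: np.ndarray, lam_max: float,
                 camera: Camera) -> Optional[tuple[int, int, int, int]]:
    """Conservative pixel rectangle covering the agent sphere's projection.

    The agent sphere is the concentric sphere of radius λmax.  Returns
    (x0, y0, x1, y1) half-open pixel bounds, or None when the glyph is
    entirely behind the camera.  When the camera is inside or beside the
    agent sphere the whole frame is returned.
    """
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")
    f, r, u = camera.basis()
    q = np.asarray(center, dtype=float) - camera.position
    z = float(np.dot(q, f))
    if z + lam_max <= 0:
        return None
    near = 1e-6
    if z - lam_max <= near:
        return (0, 0, camera.width, camera.height)
    # Project the 8 corners of the camera-space AABB of the agent sphere;
    # the hull of the corners bounds the sphere's projection.
    x = float(np.dot(q, r))
    y = float(np.dot(q, u))
    th = camera.tan_half_fov
    xs, ys = [], []
    for dx in (-lam_max, lam_max):
        for dy in (-lam_max, lam_max):
            for dz in (-lam_max, lam_max):
                cz = z + dz
                sx = (x + dx) / (cz * th * camera.aspect)
                sy = (y + dy) / (cz * th)
                xs.append((sx + 1.0) * 0.5 * camera.width)
                ys.append((1.0 - sy) * 0.5 * camera.height)
    x0 = max(0, int(math.floor(min(xs))) - 1)
    x1 = min(camera.width, int(math.ceil(max(xs))) + 2)
    y0 = max(0, int(math.floor(min(ys))) - 1)
    y1 = min(camera.height, int(math.ceil(max(ys))) + 2)
    if x0 >= x1 or y0 >= y1:
        return None
    return (x0, y0, x1, y1)


# --------------------------------------------------------------------------
# Frame rendering
# --------------------------------------------------------------------------

def _raster_glyph(fb: FrameBuffer, camera: Camera, node_id: int,
                  center: np.ndarray, axes: np.ndarray, semi: np.ndarray,
                  albedo: np.ndarray) -> None:
    """Vectorised depth-tested rasterisation of one ellipsoidal glyph."""
    rect = screen_bound(center, float(semi.max()), camera)
    if rect is None:
        return
    x0, y0, x1, y1 = rect
    pxs = np.arange(x0, x1, dtype=float)
    pys = np.arange(y0, y1, dtype=float)
    gx, gy = np.meshgrid(pxs, pys)  # (h, w)
    dirs = _pixel_directions(camera, gx.ravel(), gy.ravel())  # (N, 3)

    inv_sq = 1.0 / semi**2
    o = axes.T @ (camera.position - center)  # (3,)
    d = dirs @ axes  # rows are glyph-space directions
    a = np.einsum("ij,j,ij->i", d, inv_sq, d)
    b = 2.0 * d @ (o * inv_sq)
    c = float(np.dot(o * inv_sq, o)) - 1.0
    disc = b * b - 4.0 * a * c
    ok = disc >= 0
    if not ok.any():
        return
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    t = np.where(t1 > _EPS_T, t1, np.where(t2 > _EPS_T, t2, np.inf))
    t = np.where(ok, t, np.inf)

    h, w = gy.shape
    t = t.reshape(h, w)
    sub_depth = fb.depth[y0:y1, x0:x1]
    win = t < sub_depth
    if not win.any():
        return
    tw = t[win]
    dirs = dirs.reshape(h, w, 3)
    dw = dirs[win]
    p_glyph = (o[None, :] + tw[:, None] * (dw @ axes))
    n = (p_glyph * inv_sq[None, :]) @ axes.T
    n /= np.linalg.norm(n, axis=1, keepdims=True)

    sub_depth[win] = tw
    fb.normal[y0:y1, x0:x1][win] = n
    fb.albedo[y0:y1, x0:x1][win] = albedo
    fb.node_id[y0:y1, x0:x1][win] = node_id


def render_frame(geometry: list[tuple[int, str, object, tuple[float, float, float]]],
                 camera: Camera, settings: RenderSettings) -> FrameBuffer:
    """Ray-cast a list of glyphs into a fresh frame buffer.

    ``geometry`` entries are (node_id, kind, shape, color) with kind
    "sphere" (shape is a :class:`Sphere`) or "ellipsoid" (an
    :class:`Ellipsoid`).  The nearest hit per pixel wins; shading fills the
    color buffer afterwards according to ``settings.shading``.
    """
    fb = FrameBuffer.empty(camera.width, camera.height, settings.background)
    for node_id, kind, shape, color in geometry:
        if kind == "sphere":
            center = shape.center
            axes = np.eye(3)
            semi = np.full(3, float(shape.radius))
        elif kind == "ellipsoid":
            center, axes, semi = shape.center, shape.axes, shape.semi_axes
        else:
            raise ValueError(f"unknown glyph kind {kind!r}")
        _raster_glyph(fb, camera, node_id, center, axes, np.asarray(semi, float),
                      np.asarray(color, float))

    fg = fb.foreground
    if settings.shading == "constant":
        fb.color[fg] = fb.albedo[fg]
    else:
        light = settings.light_direction
        if light is None:
            f, _, _ = camera.basis()
            light = -f  # headlight: points from the surface toward the camera
        ndotl = np.clip(fb.normal @ light, 0.0, None)
        intensity = settings.ambient + (1.0 - settings.ambient) * ndotl
        fb.color[fg] = np.clip(fb.albedo[fg] * intensity[fg, None], 0.0, 1.0)
    return fb


def shade_diffuse(normal: np.ndarray, light: np.ndarray, albedo: np.ndarray,
                  ambient: float = 0.2, constant: bool = False) -> np.ndarray:
    """Lambert with an ambient floor; constant mode returns the albedo."""
    albedo = np.asarray(albedo, dtype=float)
    if constant:
        return albedo
    ndotl = max(0.0, float(np.dot(normal, light)))
    return np.clip(albedo * (ambient + (1.0 - ambient) * ndotl), 0.0, 1.0)


# --------------------------------------------------------------------------
# Post-processing
# --------------------------------------------------------------------------

def _shift(a: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(a, fill)
    h, w = a.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def silhouette_pass(fb: FrameBuffer, settings: RenderSettings) -> np.ndarray:
    """Depth-dependent silhouette mask.

    A foreground pixel is marked when the largest absolute depth difference
    to any of its 8 neighbours exceeds threshold × (1 + depth_scale × depth);
    a foreground pixel adjacent to background is always marked.
    """
    depth = fb.depth
    fg = fb.foreground
    max_diff = np.zeros_like(depth)
    next_to_bg = np.zeros(depth.shape, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            nd = _shift(depth, dy, dx, np.inf)
            nfg = np.isfinite(nd)
            next_to_bg |= fg & ~nfg
            # background depths replaced by 0 so no inf-inf; the diff is
            # only consumed where both pixels are foreground.
            diff = np.abs(np.where(nfg, nd, 0.0) - np.where(fg, depth, 0.0))
            both = fg & nfg
            max_diff[both] = np.maximum(max_diff[both], diff[both])
    threshold = settings.silhouette_threshold * (
        1.0 + settings.silhouette_depth_scale * np.where(fg, depth, 0.0))
    return (fg & (max_diff > threshold)) | next_to_bg


def _hemisphere_offsets(n: int, radius: float, seed: int) -> np.ndarray:
    """Deterministic cosine-weighted hemisphere sample offsets (local +z up).

    A golden-ratio low-discrepancy sequence with a seeded Cranley–Patterson
    rotation; sample lengths grow with index so the kernel fills the ball.
    """
    rng = np.random.default_rng(seed)
    shift = rng.random(2)
    i = np.arange(n)
    u1 = (i / max(n, 1) + shift[0]) % 1.0
    u2 = (i * 0.6180339887498949 + shift[1]) % 1.0
    z = np.sqrt(1.0 - u1)  # cosine-weighted elevation
    rho = np.sqrt(u1)
    phi = 2.0 * math.pi * u2
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    scale = radius * (0.1 + 0.9 * (i + 1) / n)
    return dirs * scale[:, None]


def ssao_pass(fb: FrameBuffer, camera: Camera, settings: RenderSettings) -> np.ndarray:
    """Screen-space ambient occlusion in [0, 1]; background pixels are 0.

    For each foreground pixel, offsets in the normal-oriented hemisphere of
    radius ``ssao_radius`` are projected back to the screen; the occlusion
    is the fraction of samples whose stored depth is closer than the sample
    point, subject to a range check at twice the radius.
    """
    fg = fb.foreground
    occlusion = np.zeros(fb.depth.shape)
    if not fg.any() or not settings.ssao:
        return occlusion

    h, w = fb.depth.shape
    f, r, u = camera.basis()
    th = camera.tan_half_fov

    ys, xs = np.nonzero(fg)
    dirs = _pixel_directions(camera, xs.astype(float), ys.astype(float))
    points = camera.position + fb.depth[ys, xs][:, None] * dirs
    normals = fb.normal[ys, xs]

    # Per-pixel tangent frame around the normal.
    helper = np.where(np.abs(normals[:, 0:1]) < 0.9,
                      np.tile([1.0, 0.0, 0.0], (len(normals), 1)),
                      np.tile([0.0, 1.0, 0.0], (len(normals), 1)))
    tangent = np.cross(helper, normals)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    bitangent = np.cross(normals, tangent)

    offsets = _hemisphere_offsets(settings.ssao_samples, settings.ssao_radius,
                                  settings.ssao_seed)
    bias = 0.02  # Å, avoids self-occlusion on curved surfaces
    hits = np.zeros(len(points))
    for off in offsets:
        sample = (points + off[0] * tangent + off[1] * bitangent
                  + off[2] * normals)
        q = sample - camera.position
        z = q @ f
        valid = z > 1e-6
        sx = np.where(valid, (q @ r) / np.where(valid, z, 1.0) / (th * camera.aspect), 0.0)
        sy = np.where(valid, (q @ u) / np.where(valid, z, 1.0) / th, 0.0)
        px = np.round((sx + 1.0) * 0.5 * w - 0.5).astype(int)
        py = np.round((1.0 - sy) * 0.5 * h - 0.5).astype(int)
        inside = valid & (px >= 0) & (px < w) & (py >= 0) & (py < h)
        px_c = np.clip(px, 0, w - 1)
        py_c = np.clip(py, 0, h - 1)
        stored = fb.depth[py_c, px_c]
        sample_dist = np.linalg.norm(q, axis=1)
        occluded = (inside & np.isfinite(stored)
                    & (stored < sample_dist - bias)
                    & (sample_dist - stored < 2.0 * settings.ssao_radius))
        hits += occluded
    occlusion[ys, xs] = hits / settings.ssao_samples
    return occlusion


def composite(fb: FrameBuffer, camera: Camera, settings: RenderSettings) -> np.ndarray:
    """Apply the enabled post-processing passes; returns the final RGB image."""
    rgb = fb.color.copy()
    if settings.ssao:
        occ = ssao_pass(fb, camera, settings)
        rgb *= (1.0 - occ)[:, :, None]
    if settings.contours:
        mask = silhouette_pass(fb, settings)
        rgb[mask] = 0.0
    return np.clip(rgb, 0.0, 1.0)


# --------------------------------------------------------------------------
# Image output
# --------------------------------------------------------------------------

def _to_bytes(rgb: np.ndarray) -> np.ndarray:
    """Round-half-up quantisation of a float RGB buffer to 8 bits."""
    return np.floor(np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def write_image(image: np.ndarray | FrameBuffer, path: str | Path,
                format: str | None = None) -> None:
    """Write an 8-bit RGB image as PNG or binary PPM (P6)."""
    if isinstance(image, FrameBuffer):
        image = image.color
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper() or "PNG"
    format = format.upper()
    data = _to_bytes(np.asarray(image, dtype=float))
    if data.ndim != 3 or data.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB buffer")
    if format == "PPM":
        h, w, _ = data.shape
        with open(path, "wb") as fh:
            fh.write(f"P6\n{w} {h}\n255\n".encode("ascii"))
            fh.write(data.tobytes())
    elif format == "PNG":
        from PIL import Image

        Image.fromarray(data, mode="RGB").save(path, format="PNG")
    else:
        raise ValueError(f"unknown image format {format!r}; use PNG or PPM")
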