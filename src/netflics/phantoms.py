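"""Synthetic ground-truth scenes for compressed-sensing lifetime imaging.

Scenes pair a 32x32 photon-count (intensity) image with a 32x32 lifetime
image (ns).  Foreground objects are glyph-like shapes — procedurally drawn
strokes, ellipses and bars on a 28x28 canvas — standing in for handwritten
digit/letter images; an IDX-format loader accepts a real glyph bank
(e.g. EMNIST files) as an alternative raw-material source.

Per-pixel maximum counts are stratified in photon levels:

=======  ==============
level    max CW counts
=======  ==============
``1``    25 – 100
``2``    100 – 400
``3``    400 – 1600
``full``  25 – 1600
=======  ==============

and lifetimes are drawn uniformly in 0.3–1.5 ns, one value per glyph
(each object emulates a single dye).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PHOTON_LEVELS",
    "LIFETIME_RANGE",
    "FRAME_SIDE",
    "LifetimeScene",
    "make_glyph",
    "load_idx_glyphs",
    "make_scene",
    "make_dataset",
]

#: photon-level tag -> (low, high) bound on the per-glyph maximum CW intensity
PHOTON_LEVELS: dict[str, tuple[float, float]] = {
    "1": (25.0, 100.0),
    "2": (100.0, 400.0),
    "3": (400.0, 1600.0),
    "full": (25.0, 1600.0),
}

#: uniform sampling range for ground-truth lifetimes, ns
LIFETIME_RANGE: tuple[float, float] = (0.3, 1.5)

#: side of the reconstructed image frame
FRAME_SIDE: int = 32

_SPLIT_STREAMS = {"train": 0, "val": 1, "test": 2}


@dataclass
class LifetimeScene:
    """Paired ground-truth intensity and lifetime images with foreground mask.

    Invariants (checked by :meth:`validate`): intensity is nonnegative and
    zero exactly off the mask; lifetime lies in ``LIFETIME_RANGE`` on the
    mask and is exactly zero off it.
    """

    intensity: np.ndarray
    lifetime: np.ndarray
    mask: np.ndarray
    scene_id: str = ""
    level: str | None = None

    def validate(self) -> None:
        if self.intensity.shape != self.lifetime.shape or self.intensity.shape != self.mask.shape:
            raise ValueError("intensity, lifetime and mask shapes differ")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        m = self.mask.astype(bool)
        if np.any(self.intensity[~m] != 0) or np.any(self.lifetime[~m] != 0):
            raise ValueError("background pixels must carry zero intensity and lifetime")
        if np.any(self.intensity[m] == 0):
            raise ValueError("mask-true pixels must carry photons")
        lo, hi = LIFETIME_RANGE
        if m.any() and (self.lifetime[m].min() < lo or self.lifetime[m].max() > hi):
            raise ValueError("foreground lifetime outside the generator range")
        if self.level is not None and m.any():
            llo, lhi = PHOTON_LEVELS[self.level]
            peak = self.intensity.max()
            if not (llo <= peak <= lhi):
                raise ValueError(
                    f"scene peak intensity {peak:.3g} outside level {self.level} "
                    f"range [{llo}, {lhi}]"
                )

    @property
    def total_counts(self) -> float:
        return float(self.intensity.sum())


# ---------------------------------------------------------------------------
# glyph drawing
# ---------------------------------------------------------------------------

def _stamp_disk(img: np.ndarray, r: int, c: int, radius: float, value: float) -> None:
    h, w = img.shape
    rr = int(np.ceil(radius))
    r0, r1 = max(0, r - rr), min(h, r + rr + 1)
    c0, c1 = max(0, c - rr), min(w, c + rr + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, np.where(d2 <= radius**2, value, 0.0), out=patch)


def _draw_stroke(img: np.ndarray, rng: np.random.Generator) -> None:
    """Quadratic-Bezier stroke with a random thickness, stamped as disks."""
    h, w = img.shape
    pts = rng.uniform([2, 2], [h - 3, w - 3], size=(3, 2))
    radius = rng.uniform(0.8, 1.8)
    ts = np.linspace(0.0, 1.0, 4 * max(h, w))
    curve = (
        np.outer((1 - ts) ** 2, pts[0])
        + np.outer(2 * ts * (1 - ts), pts[1])
        + np.outer(ts**2, pts[2])
    )
    for r, c in curve:
        _stamp_disk(img, int(round(r)), int(round(c)), radius, 1.0)


def _draw_ellipse(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    cy, cx = rng.uniform([h * 0.3, w * 0.3], [h * 0.7, w * 0.7])
    ay, ax = rng.uniform(3.0, h * 0.35, size=2)
    phase = rng.uniform(0, np.pi)
    radius = rng.uniform(0.8, 1.5)
    span = rng.uniform(0.6, 1.0) * 2 * np.pi  # allow open arcs
    ts = np.linspace(0.0, span, 6 * max(h, w))
    for t in ts:
        r = cy + ay * np.sin(t + phase)
        c = cx + ax * np.cos(t + phase)
        _stamp_disk(img, int(round(r)), int(round(c)), radius, 1.0)


def _draw_bar(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    r0, c0 = rng.uniform([2, 2], [h - 3, w - 3])
    length = rng.uniform(0.3, 0.8) * max(h, w)
    angle = rng.uniform(0, np.pi)
    radius = rng.uniform(0.8, 2.0)
    ts = np.linspace(0, 1, 4 * max(h, w))
    for t in ts:
        r = r0 + t * length * np.sin(angle)
        c = c0 + t * length * np.cos(angle)
        _stamp_disk(img, int(round(r)), int(round(c)), radius, 1.0)


_PRIMITIVES = (_draw_stroke, _draw_ellipse, _draw_bar)


def make_glyph(shape_seed: int, canvas: tuple[int, int] = (28, 28)) -> np.ndarray:
    """Draw one grayscale glyph with values in [0, 1].

    The glyph is a union of 1–3 stroke/ellipse/bar primitives, lightly
    blurred so the interior carries shading, with a nonzero fraction
    guaranteed to lie in [0.05, 0.6] of the canvas.  Deterministic in
    ``shape_seed``.
    """
    h, w = canvas
    if h < 8 or w < 8:
        raise ValueError(f"canvas {canvas} too small; need at least 8x8")
    rng = np.random.default_rng(shape_seed)
    for _attempt in range(20):
        img = np.zeros((h, w))
        n_prim = rng.integers(1, 4)
        for _ in range(n_prim):
            prim = _PRIMITIVES[rng.integers(len(_PRIMITIVES))]
            prim(img, rng)
        img = ndimage.gaussian_filter(img, sigma=0.7)
        peak = img.max()
        if peak <= 0:
            continue
        img /= peak
        img[img < 0.08] = 0.0
        frac = np.count_nonzero(img) / img.size
        if 0.05 <= frac <= 0.6:
            return img
    raise RuntimeError(f"could not draw a glyph within bounds for seed {shape_seed}")


def load_idx_glyphs(path: str) -> np.ndarray:
    """Load a bank of grayscale glyphs from an idx3-ubyte file.

    Returns an array of shape (n, rows, cols) scaled to [0, 1].  Malformed
    files raise :class:`ValueError` naming the byte offset of the problem.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 16:
        raise ValueError(f"IDX file truncated: header needs 16 bytes, got {len(raw)} (offset 0)")
    magic = struct.unpack(">I", raw[:4])[0]
    if magic != 0x00000803:
        raise ValueError(f"bad IDX magic 0x{magic:08x} at offset 0 (expected 0x00000803)")
    n, rows, cols = struct.unpack(">III", raw[4:16])
    expected = 16 + n * rows * cols
    if len(raw) != expected:
        raise ValueError(
            f"IDX payload length mismatch at offset 16: expected {expected - 16} "
            f"bytes, got {len(raw) - 16}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=16).reshape(n, rows, cols)
    return data.astype(np.float64) / 255.0


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _rotate_glyph(glyph: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate by a random multiple of 90 deg plus U(-15, 15) deg.

    Nearest-neighbour resampling; values below 0.1 are zeroed afterwards so
    rotation artefacts do not leak into the support.
    """
    k = int(rng.integers(4))
    out = np.rot90(glyph, k)
    angle = rng.uniform(-15.0, 15.0)
    out = ndimage.rotate(out, angle, reshape=False, order=0, mode="constant", cval=0.0)
    out = out.copy()
    out[out < 0.1] = 0.0
    return out


def make_scene(
    glyphs: Sequence[np.ndarray],
    level: str,
    rng_seed: int,
    scene_id: str = "",
    per_pixel_lifetime: bool = False,
) -> LifetimeScene:
    """Compose 1–3 glyphs into a 32x32 ground-truth scene.

    Each glyph is independently rotated, placed at a random offset, scaled
    so its peak CW intensity is uniform in the photon level's range, and
    assigned a single lifetime uniform in 0.3–1.5 ns (or per-pixel values
    when ``per_pixel_lifetime``).  Overlaps sum intensities and average
    lifetimes weighted by intensity; the summed scene is clipped at the
    level maximum.
    """
    if len(glyphs) == 0:
        raise ValueError("make_scene requires at least one glyph")
    if level not in PHOTON_LEVELS:
        raise ValueError(f"unknown photon level {level!r}; choose from {sorted(PHOTON_LEVELS)}")
    lo, hi = PHOTON_LEVELS[level]
    rng = np.random.default_rng(rng_seed)
    side = FRAME_SIDE
    intensity = np.zeros((side, side))
    tau_weighted = np.zeros((side, side))
    n_contrib = np.zeros((side, side), dtype=int)
    tau_single = np.zeros((side, side))
    for glyph in glyphs:
        g = _rotate_glyph(np.asarray(glyph, dtype=np.float64), rng)
        gh, gw = g.shape
        if gh > side or gw > side:
            raise ValueError(f"glyph of shape {g.shape} does not fit in a {side}x{side} frame")
        if g.max() <= 0:
            continue
        r0 = int(rng.integers(0, side - gh + 1))
        c0 = int(rng.integers(0, side - gw + 1))
        peak = rng.uniform(lo, hi)
        contrib = np.zeros((side, side))
        contrib[r0 : r0 + gh, c0 : c0 + gw] = g / g.max() * peak
        tlo, thi = LIFETIME_RANGE
        if per_pixel_lifetime:
            tau = rng.uniform(tlo, thi, size=contrib.shape)
        else:
            tau = rng.uniform(tlo, thi)
        intensity += contrib
        tau_weighted += contrib * tau
        hit = contrib > 0
        n_contrib += hit
        tau_single[hit] = np.broadcast_to(tau, contrib.shape)[hit] if per_pixel_lifetime else tau
    mask = intensity > 0
    # weights for the lifetime average are the pre-clip intensities; pixels
    # touched by a single glyph take that glyph's lifetime exactly
    lifetime = np.zeros_like(intensity)
    overlap = n_contrib > 1
    tlo, thi = LIFETIME_RANGE
    # convex combination; clip guards 1-ulp excursions from the division
    lifetime[overlap] = np.clip(tau_weighted[overlap] / intensity[overlap], tlo, thi)
    single = n_contrib == 1
    lifetime[single] = tau_single[single]
    np.clip(intensity, 0.0, hi, out=intensity)
    scene = LifetimeScene(intensity, lifetime, mask, scene_id=scene_id, level=level)
    scene.validate()
    return scene


def make_dataset(
    n: int,
    split: str,
    level_mix: dict[str, float] | None = None,
    rng_seed: int = 0,
    glyph_bank: np.ndarray | None = None,
    per_pixel_lifetime: bool = False,
) -> list[LifetimeScene]:
    """Generate a reproducible sequence of scenes for one data split.

    The three splits draw from disjoint seed streams spawned off
    ``rng_seed``, so train/val/test never share a scene.  ``level_mix``
    maps photon-level tags to sampling probabilities (default: all scenes
    at level ``full``).  ``glyph_bank`` optionally supplies pre-loaded
    glyph images (e.g. from :func:`load_idx_glyphs`) instead of the
    procedural generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if split not in _SPLIT_STREAMS:
        raise ValueError(f"unknown split {split!r}; choose from {sorted(_SPLIT_STREAMS)}")
    mix = level_mix or {"full": 1.0}
    for lvl in mix:
        if lvl not in PHOTON_LEVELS:
            raise ValueError(f"unknown photon level {lvl!r} in level_mix")
    tags = sorted(mix)
    probs = np.array([mix[t] for t in tags], dtype=float)
    probs /= probs.sum()

    root = np.random.SeedSequence(rng_seed, spawn_key=(_SPLIT_STREAMS[split],))
    scenes: list[LifetimeScene] = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        level = tags[rng.choice(len(tags), p=probs)]
        n_glyphs = int(rng.integers(1, 4))
        if glyph_bank is not None:
            idx = rng.integers(len(glyph_bank), size=n_glyphs)
            glyphs = [glyph_bank[j] for j in idx]
        else:
            glyphs = [make_glyph(int(rng.integers(2**31))) for _ in range(n_glyphs)]
        scenes.append(
            make_scene(
                glyphs,
                level,
                rng_seed=int(rng.integers(2**31)),
                scene_id=f"{split}-{i:05d}",
                per_pixel_lifetime=per_pixel_lifetime,
            )
        )
    return scenes


def scene_digest(scene: LifetimeScene) -> str:
    """Stable content hash of a scene, used to check split disjointness."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(scene.intensity).tobytes())
    h.update(np.ascontiguousarray(scene.lifetime).tobytes())
    return h.hexdigest()
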