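"""Rendering synthetic CandyCode images and detecting particles in them.

Closes the photograph-to-coordinates loop without physical pills: a
simulated code is drawn as colored disks on a pill-colored disk, and the
detector recovers (x, y, color) records from such an image by
nearest-palette-color pixel classification followed by connected-component
centroids.  This is a functional stand-in for photographing real pills;
color constancy, shadows and perspective are out of scope.

Detected coordinates are pixel centroids in the y-down image frame, the
same convention the rest of the package uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from PIL import Image
from scipy import ndimage

from .core import CandyCode, CandyCodeError, ColorAlphabet, Particle
from .simulator import default_particle_radius

__all__ = [
    "Palette",
    "DetectionError",
    "default_palette",
    "render_candycode",
    "detect_particles",
]


class DetectionError(CandyCodeError):
    pass


#: Minimum pairwise Euclidean RGB distance between palette entries (particle
#: colors, pill face and image background) for unambiguous classification.
MIN_PALETTE_DISTANCE = 40.0

_LETTER_RGB: Mapping[str, tuple[int, int, int]] = {
    "D": (0, 0, 160),  # dark blue
    "G": (0, 140, 0),  # green
    "L": (90, 200, 255),  # light blue
    "O": (255, 140, 0),  # orange
    "P": (255, 105, 180),  # pink
    "R": (220, 0, 30),  # red
    "W": (255, 255, 255),  # white
    "Y": (255, 230, 0),  # yellow
    "B": (0, 0, 0),  # black
    "F": (0, 80, 0),  # dark (forest) green
    "K": (90, 90, 90),  # dark gray
    "M": (255, 0, 255),  # magenta
    "N": (140, 70, 20),  # brown
    "S": (175, 175, 175),  # light gray (silver)
    "V": (130, 0, 200),  # purple (violet)
}


@dataclass(frozen=True)
class Palette:
    """Display colors for an alphabet plus pill and background colors."""

    colors: Mapping[str, tuple[int, int, int]]
    pill_color: tuple[int, int, int] = (235, 220, 200)
    background_color: tuple[int, int, int] = (40, 40, 40)

    def __post_init__(self) -> None:
        entries = list(self.colors.values()) + [self.pill_color, self.background_color]
        arr = np.asarray(entries, dtype=float)
        d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < MIN_PALETTE_DISTANCE:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"palette entries {i} and {j} are only {d.min():.0f} apart "
                f"in RGB (minimum {MIN_PALETTE_DISTANCE})"
            )


def default_palette(alphabet: ColorAlphabet) -> Palette:
    """Well-separated default palette covering the given alphabet."""
    try:
        colors = {c: _LETTER_RGB[c] for c in alphabet.letters}
    except KeyError as exc:
        raise KeyError(f"no default display color for letter {exc}") from exc
    return Palette(colors)


def render_candycode(
    code: CandyCode,
    palette: Palette | None = None,
    pixels_per_unit: float = 400.0,
    pill_radius: float = 1.0,
    particle_radius: float | None = None,
) -> Image.Image:
    """Draw a CandyCode as a raster image (deterministic for fixed inputs).

    The pill is a filled disk centered in the image; each particle is a
    filled circle of its palette color at its scaled coordinates.
    Particles are drawn at 90% of ``particle_radius`` so that near-tangent
    same-colored particles remain separable connected components.

    Disks are rasterized directly (a pixel is filled iff its center lies
    inside the disk, no anti-aliasing), so component centroids recover
    particle positions to a small fraction of a pixel — PIL's integer
    rounding of ellipse bounding boxes would otherwise shift centers by up
    to a pixel and occasionally flip near-degenerate Delaunay edges.
    """
    if pixels_per_unit <= 0:
        raise ValueError("pixels_per_unit must be positive")
    if palette is None:
        palette = default_palette(code.alphabet)
    if particle_radius is None:
        particle_radius = default_particle_radius(max(len(code), 1), pill_radius)
    r_px = 0.9 * particle_radius * pixels_per_unit
    if r_px < 2.0:
        raise ValueError(
            f"scale too small: particle radius {r_px:.2f} px (< 2 px)"
        )
    margin = int(0.05 * pill_radius * pixels_per_unit) + 2
    half = int(round(pill_radius * pixels_per_unit)) + margin
    size = 2 * half
    arr = np.empty((size, size, 3), dtype=np.uint8)
    arr[:, :] = palette.background_color

    # pixel (i, j) has center (j + 0.5, i + 0.5) in continuous coordinates
    centers = np.arange(size) + 0.5
    rp = pill_radius * pixels_per_unit
    dx = centers - half
    pill = dx[None, :] ** 2 + dx[:, None] ** 2 <= rp * rp
    arr[pill] = palette.pill_color

    for p in code.particles:
        x = half + p.x * pixels_per_unit
        y = half + p.y * pixels_per_unit
        j0 = max(int(x - r_px) - 1, 0)
        j1 = min(int(x + r_px) + 2, size)
        i0 = max(int(y - r_px) - 1, 0)
        i1 = min(int(y + r_px) + 2, size)
        wx = centers[j0:j1] - x
        wy = centers[i0:i1] - y
        disk = wy[:, None] ** 2 + wx[None, :] ** 2 <= r_px * r_px
        arr[i0:i1, j0:j1][disk] = palette.colors[p.color]
    return Image.fromarray(arr, "RGB")


def detect_particles(
    image: Image.Image | np.ndarray,
    palette: Palette,
    alphabet: ColorAlphabet,
    min_component_pixels: int = 4,
    code_id: str = "detected",
) -> CandyCode:
    """Recover (x, y, color) particle records from a rendered image.

    Every pixel is classified to its nearest palette entry (particle
    colors, pill, background); connected components of particle-classified
    pixels become particles, each reported at its centroid with the
    component's letter.  Components use 4-connectivity so tangent disks do
    not merge diagonally.

    Raises DetectionError if the image contains no pill and no particles.
    """
    arr = np.asarray(image, dtype=np.int16)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise DetectionError("expected an RGB image")
    arr = arr[:, :, :3]
    letters = [c for c in alphabet.letters]
    entries = [palette.colors[c] for c in letters]
    entries.append(palette.pill_color)
    entries.append(palette.background_color)
    ref = np.asarray(entries, dtype=np.int16)  # (k, 3)
    d2 = ((arr[:, :, None, :] - ref[None, None, :, :]).astype(np.int32) ** 2).sum(
        axis=-1
    )
    nearest = np.argmin(d2, axis=-1)
    pill_idx = len(letters)
    if not (nearest == pill_idx).any() and not (nearest < pill_idx).any():
        raise DetectionError("no pill found in image")

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    particles: list[Particle] = []
    for li, letter in enumerate(letters):
        mask = nearest == li
        if not mask.any():
            continue
        labels, n_comp = ndimage.label(mask, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        centroids = ndimage.center_of_mass(mask, labels, np.arange(1, n_comp + 1))
        for (cy, cx), sz in zip(centroids, sizes):
            if sz >= min_component_pixels:
                # index centroid + 0.5 = centroid of pixel centers
                particles.append(Particle(float(cx) + 0.5, float(cy) + 0.5, letter))
    if not particles:
        raise DetectionError("no particles detected")
    return CandyCode(code_id, particles, alphabet)
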