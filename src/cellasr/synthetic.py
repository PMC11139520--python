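"""Synthetic data generators: image phantoms and worm-like point sets.

Two families of fixtures are produced:

* ``make_phantom`` — 3D intensity volumes of densely packed, blurred
  ellipsoidal nuclei with ground-truth instance masks, emulating nuclear
  fluorescence stacks of small larvae.
* ``make_synthetic_atlas`` / ``make_synthetic_worm`` — identity-annotated
  centroid point sets inside an elongated bent tube, emulating the
  stereotyped whole-body cell layout of an L1 larva and its per-individual
  variability (bounded affine pose change, smooth axial bending, per-cell
  Gaussian jitter, optional cell dropout).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 64, 64)
    n_cells: int = 20
    radius_range: tuple[float, float] = (3.0, 5.0)
    min_separation: float = 9.0
    blur_sigma: float = 1.0
    noise_sigma: float = 0.03
    intensity_range: tuple[float, float] = (0.6, 1.0)
    axis_ratio_max: float = 2.0  # ellipsoid elongation bound, near-spherical nuclei
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius_range")


@dataclass
class WormConfig:
    n_cells: int = 100
    tube_length: float = 400.0
    tube_radius: float = 15.0
    n_samples: int = 20
    affine_magnitude: float = 0.1
    translation_magnitude: float = 10.0
    bend_amplitude: float = 20.0
    jitter_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dropout: float = 0.0
    min_point_separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")


@dataclass
class PointSet:
    """Ordered 3D centroids in (x, y, z) coordinates with optional identities."""

    points: np.ndarray  # (N, 3) float, columns x, y, z
    ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.ids is not None:
            self.ids = list(self.ids)
            if len(self.ids) != len(self.points):
                raise ValueError("ids and points length mismatch")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("duplicate ids in point set")

    def __len__(self) -> int:
        return len(self.points)


def make_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom volume and its ground-truth instance mask.

    Cell centers are rejection-sampled to honour ``min_separation``; each
    cell is a randomly oriented ellipsoid label.  The image is the sum of
    per-cell Gaussian intensity blobs, Gaussian-blurred, plus additive
    noise, min-max scaled to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    r_lo, r_hi = cfg.radius_range

    centers: list[np.ndarray] = []
    margins = [min(r_hi + 1.0, dim / 2.0 - 0.5) for dim in (nz, ny, nx)]
    max_tries = 200 * max(cfg.n_cells, 1)
    tries = 0
    while len(centers) < cfg.n_cells and tries < max_tries:
        tries += 1
        c = rng.uniform(margins, [nz - margins[0], ny - margins[1], nx - margins[2]])
        if all(np.linalg.norm(c - p) >= cfg.min_separation for p in centers):
            centers.append(c)
    if len(centers) < cfg.n_cells:
        warnings.warn(
            f"placed only {len(centers)}/{cfg.n_cells} cells after {max_tries} tries"
        )

    mask = np.zeros(cfg.shape, dtype=np.int32)
    image = np.zeros(cfg.shape, dtype=np.float64)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    for k, c in enumerate(centers, start=1):
        r = rng.uniform(r_lo, r_hi)
        ratios = rng.uniform(1.0, cfg.axis_ratio_max, size=3)
        ratios /= ratios.prod() ** (1 / 3)  # keep volume comparable to sphere r
        semi = np.clip(r * ratios, 1.5, None)
        rot = _random_rotation(rng)
        rel = np.stack([zz - c[0], yy - c[1], xx - c[2]], axis=-1) @ rot.T
        q = (rel / semi) ** 2
        inside = q.sum(axis=-1) <= 1.0
        mask[inside & (mask == 0)] = k
        amp = rng.uniform(*cfg.intensity_range)
        image += amp * np.exp(-0.5 * (q.sum(axis=-1)) * 2.0)

    image = ndi.gaussian_filter(image, cfg.blur_sigma)
    image = image + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    lo, hi = image.min(), image.max()
    if hi > lo:
        image = (image - lo) / (hi - lo)
    return image, mask


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_synthetic_atlas(cfg: WormConfig) -> PointSet:
    """Reference point set: K identified cells inside a bent elongated tube.

    Points are sampled along a tube whose axis runs along x with a gentle
    sinusoidal bend in y, with a minimum pairwise separation so that shape
    contexts are informative.  Identities are ``c000 .. c{K-1}``.
    """
    rng = np.random.default_rng(cfg.seed)
    pts: list[np.ndarray] = []
    max_tries = 500 * cfg.n_cells
    tries = 0
    while len(pts) < cfg.n_cells and tries < max_tries:
        tries += 1
        t = rng.uniform(0.0, cfg.tube_length)
        rad = cfg.tube_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        y = rad * np.cos(theta) + 0.15 * cfg.tube_radius * np.sin(
            2 * np.pi * t / cfg.tube_length
        )
        z = rad * np.sin(theta)
        p = np.array([t, y, z])
        if all(np.linalg.norm(p - q) >= cfg.min_point_separation for q in pts):
            pts.append(p)
    if len(pts) < cfg.n_cells:
        raise RuntimeError(
            f"could not place {cfg.n_cells} cells with separation "
            f"{cfg.min_point_separation} in the tube; lower the separation or count"
        )
    pts_arr = np.array(pts)
    order = np.argsort(pts_arr[:, 0])  # head-to-tail ordering
    pts_arr = pts_arr[order]
    ids = [f"c{k:03d}" for k in range(cfg.n_cells)]
    return PointSet(pts_arr, ids)


def make_synthetic_worm(
    atlas_points: PointSet, cfg: WormConfig, seed: int | None = None
) -> PointSet:
    """One simulated individual: atlas geometry under pose + deformation + noise.

    Applies, in order: a random affine with entries within
    ``affine_magnitude`` of the identity plus a bounded translation, a
    smooth single-frequency sinusoidal bend of the body axis (amplitude
    ``bend_amplitude``), per-cell Gaussian jitter with per-axis sigma, and
    optional random dropout.  Ground-truth identities ride along.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pts = atlas_points.points.copy()
    ids = list(atlas_points.ids) if atlas_points.ids is not None else None

    # bend along the elongated (x) axis, displacing y
    span = pts[:, 0].max() - pts[:, 0].min()
    if span > 0 and cfg.bend_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = (pts[:, 0] - pts[:, 0].min()) / span
        pts[:, 1] += cfg.bend_amplitude * np.sin(np.pi * t + phase)

    a = np.eye(3) + rng.uniform(-cfg.affine_magnitude, cfg.affine_magnitude, (3, 3))
    shift = rng.uniform(-cfg.translation_magnitude, cfg.translation_magnitude, 3)
    pts = pts @ a.T + shift

    sig = np.asarray(cfg.jitter_sigma, dtype=float)
    pts = pts + rng.normal(0.0, 1.0, pts.shape) * sig

    if cfg.dropout > 0:
        keep = rng.uniform(size=len(pts)) >= cfg.dropout
        if keep.sum() < 4:
            raise ValueError("dropout left fewer than 4 cells")
        pts = pts[keep]
        if ids is not None:
            ids = [i for i, k in zip(ids, keep) if k]

    return PointSet(pts, ids)
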