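"""Three-part statistical cell atlas: ASP, SPV and TSV.

The atlas summarises a population of identity-annotated centroid point
sets ("samples") of the same stereotyped anatomy:

* **ASP** (average spatial positions) — per-identity mean position after
  iterative group-wise alignment.  Samples are affine-aligned to the
  current ASP and averaged; the mean residual displacement is subtracted
  (the pointwise inverse of the average deformation) to remove the bias
  toward the initial reference sample; iterate to convergence, then
  refine with a piecewise-affine (PWA) mapping along the body axis.
* **SPV** (spatial position variation) — per-identity, per-axis standard
  deviation of the PWA-mapped sample positions.
* **TSV** (topological structure variation) — per-identity mean chi-square
  distance between the shape context of the ASP cell and the shape
  contexts of the corresponding cells in the PWA-mapped samples.

Shape contexts are log-polar histograms (R radial shells x F angular
sectors) of neighbouring centroids, computed in the point set's PCA body
frame so that they are pose-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import PointSet

EPS = 1e-12


# ---------------------------------------------------------------------------
# transforms


@dataclass
class AffineTransform:
    """x -> A @ x + t on (x, y, z) row vectors."""

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.matrix.T + self.translation

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine A, t minimising sum ||A s + t - d||^2.

    ``src`` and ``dst`` are (N, 3) corresponding points, N >= 4 and not
    coplanar.  Recovery is exact when the correspondences are
    affine-consistent.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src/dst must be matching (N, 3) arrays")
    if len(src) < 4:
        raise ValueError("need at least 4 correspondences for a 3D affine fit")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate (coplanar or collinear) correspondences")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform(sol[:3].T.copy(), sol[3].copy())


@dataclass
class PWATransform:
    """Piecewise-affine map: per-segment affines along one axis, cross-faded.

    Segments partition the data range of the projection onto ``axis`` (a
    unit vector, normally the longest PCA axis of the source points).
    Between segment centres the two neighbouring affines are blended
    linearly, which makes the overall map continuous.
    """

    axis: np.ndarray  # (3,) unit vector
    centers: np.ndarray  # (S,) segment centres along the axis
    affines: list[AffineTransform]

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        proj = points @ self.axis
        out = np.zeros_like(points)
        c = self.centers
        idx = np.searchsorted(c, proj)
        for n, (p, t, i) in enumerate(zip(points, proj, idx)):
            if i == 0:
                out[n] = self.affines[0].apply(p)
            elif i >= len(c):
                out[n] = self.affines[-1].apply(p)
            else:
                w = (t - c[i - 1]) / max(c[i] - c[i - 1], EPS)
                out[n] = (1 - w) * self.affines[i - 1].apply(p) + w * self.affines[
                    i
                ].apply(p)
        return out


def fit_pwa(src: np.ndarray, dst: np.ndarray, n_segments: int = 8) -> PWATransform:
    """Fit a piecewise-affine map from corresponding point sets.

    Points are partitioned into ``n_segments`` equal-count bins along the
    longest PCA axis of ``src``; each bin gets its own least-squares
    affine fitted on the bin's points extended by a 20% overlap margin on
    each side.  Bins with fewer than 4 (or degenerate) points are merged
    into their neighbour.  ``n_segments=1`` reduces to the global affine.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape:
        raise ValueError("src/dst shape mismatch")
    centered = src - src.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = src @ axis
    lo, hi = proj.min(), proj.max()
    if hi - lo < EPS or n_segments <= 1:
        aff = fit_affine(src, dst)
        return PWATransform(axis, np.array([(lo + hi) / 2.0]), [aff])

    edges = np.linspace(lo, hi, n_segments + 1)
    overlap = 0.2 * (edges[1] - edges[0])
    centers: list[float] = []
    affines: list[AffineTransform] = []
    for s in range(n_segments):
        a, b = edges[s] - overlap, edges[s + 1] + overlap
        sel = (proj >= a) & (proj <= b)
        grow = overlap
        while sel.sum() < 8 and grow < (hi - lo):
            grow *= 2.0
            sel = (proj >= edges[s] - grow) & (proj <= edges[s + 1] + grow)
        try:
            aff = fit_affine(src[sel], dst[sel])
        except ValueError:
            warnings.warn(f"PWA segment {s} degenerate; using global affine")
            aff = fit_affine(src, dst)
        centers.append(0.5 * (edges[s] + edges[s + 1]))
        affines.append(aff)
    return PWATransform(axis, np.asarray(centers), affines)


# ---------------------------------------------------------------------------
# shape context


@dataclass(frozen=True)
class ShapeContextParams:
    """Log-polar 3D shape-context binning.

    ``n_shells`` log-spaced radial shells between ``r_min`` and ``r_max``
    (voxels); each shell is divided into ``n_azimuth x n_polar`` angular
    sectors, so the histogram has R*F bins with F = n_azimuth * n_polar.
    """

    n_shells: int = 5
    n_azimuth: int = 6
    n_polar: int = 2
    r_min: float = 2.0
    r_max: float = 100.0

    def __post_init__(self) -> None:
        if self.n_shells < 1 or self.n_azimuth < 1 or self.n_polar < 1:
            raise ValueError("bin counts must be >= 1")
        if not 0 < self.r_min < self.r_max:
            raise ValueError("require 0 < r_min < r_max")

    @property
    def n_sectors(self) -> int:
        return self.n_azimuth * self.n_polar

    @property
    def n_bins(self) -> int:
        return self.n_shells * self.n_sectors


def pca_frame(points: np.ndarray) -> np.ndarray:
    """Deterministic PCA body frame: rows are principal axes.

    Signs are fixed so each axis has a non-negative skew (falls back to a
    positive largest-coordinate convention for symmetric clouds) and the
    frame is a proper rotation.
    """
    points = np.asarray(points, dtype=np.float64)
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered  # 3x3 regardless of the point count
    evals, evecs = np.linalg.eigh(cov)
    frame = evecs[:, ::-1].T.copy()  # rows = axes, descending variance
    for k in range(3):
        proj = centered @ frame[k]
        skew = (proj**3).mean()
        if abs(skew) < 1e-9:
            j = np.argmax(np.abs(proj))
            skew = proj[j]
        if skew < 0:
            frame[k] = -frame[k]
    if np.linalg.det(frame) < 0:
        frame[2] = -frame[2]
    return frame


def shape_context(
    points: np.ndarray,
    index: int,
    params: ShapeContextParams = ShapeContextParams(),
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized log-polar histogram of neighbours around ``points[index]``.

    Neighbours beyond ``r_max`` are ignored; neighbours inside ``r_min``
    are counted in the innermost shell.  With ``frame=None`` the PCA body
    frame of the whole set is used, making the descriptor invariant to
    rigid pose.  Returns an (R*F,) histogram summing to 1 (all-zero with a
    warning if no neighbour is in range).
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise ValueError("shape context needs at least one other point")
    if frame is None:
        frame = pca_frame(points)
    rel = np.delete(points, index, axis=0) - points[index]
    rel = rel @ frame.T
    r = np.linalg.norm(rel, axis=1)
    keep = (r <= params.r_max) & (r > EPS)
    hist = np.zeros(params.n_bins, dtype=np.float64)
    if not keep.any():
        warnings.warn("shape_context: no neighbour within r_max; zero histogram")
        return hist
    rel, r = rel[keep], r[keep]
    log_r = np.log(np.clip(r, params.r_min, params.r_max) / params.r_min)
    log_span = np.log(params.r_max / params.r_min)
    shell = np.minimum(
        (log_r / log_span * params.n_shells).astype(int), params.n_shells - 1
    )
    az = np.arctan2(rel[:, 1], rel[:, 0])  # [-pi, pi)
    az_bin = np.minimum(
        ((az + np.pi) / (2 * np.pi) * params.n_azimuth).astype(int),
        params.n_azimuth - 1,
    )
    pol = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))  # [0, pi]
    pol_bin = np.minimum(
        (pol / np.pi * params.n_polar).astype(int), params.n_polar - 1
    )
    bins = (shell * params.n_azimuth + az_bin) * params.n_polar + pol_bin
    np.add.at(hist, bins, 1.0)
    return hist / hist.sum()


def shape_contexts_all(
    points: np.ndarray, params: ShapeContextParams = ShapeContextParams()
) -> np.ndarray:
    """Shape contexts of every point, sharing one PCA frame. (N, R*F)."""
    frame = pca_frame(points)
    return np.array(
        [shape_context(points, i, params, frame=frame) for i in range(len(points))]
    )


def chi_square(h1: np.ndarray, h2: np.ndarray, eps: float = 1e-10) -> float:
    """Chi-square distance between two histograms: 0.5 * sum (a-b)^2/(a+b)."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("histogram length mismatch")
    return float(0.5 * np.sum((h1 - h2) ** 2 / (h1 + h2 + eps)))


# ---------------------------------------------------------------------------
# atlas construction


@dataclass
class StatisticalAtlas:
    ids: list[str]
    asp: np.ndarray  # (K, 3) average positions, (x, y, z)
    spv: np.ndarray  # (K, 3) per-axis standard deviations
    tsv: np.ndarray  # (K,) mean chi-square shape-context distance
    sc_params: ShapeContextParams = field(default_factory=ShapeContextParams)
    sc_ref: np.ndarray | None = None  # (K, R*F) ASP shape contexts

    def __post_init__(self) -> None:
        self.asp = np.asarray(self.asp, dtype=np.float64)
        self.spv = np.asarray(self.spv, dtype=np.float64)
        self.tsv = np.asarray(self.tsv, dtype=np.float64)
        k = len(self.ids)
        if self.asp.shape != (k, 3) or self.spv.shape != (k, 3) or self.tsv.shape != (k,):
            raise ValueError("atlas arrays must share the identity count K")
        if (self.spv < 0).any() or (self.tsv < 0).any():
            raise ValueError("SPV and TSV must be non-negative")

    @property
    def pointset(self) -> PointSet:
        return PointSet(self.asp.copy(), list(self.ids))


@dataclass
class AtlasConfig:
    tol_fraction: float = 1e-3  # convergence tol as a fraction of body length
    max_iter: int = 20
    pwa_segments: int = 8
    sc_params: ShapeContextParams = field(default_factory=ShapeContextParams)


def _stack_samples(samples: list[PointSet]) -> tuple[list[str], list[dict[str, np.ndarray]]]:
    if len(samples) < 2:
        raise ValueError("atlas construction needs at least 2 samples")
    ids: list[str] = []
    seen: set[str] = set()
    for s in samples:
        if s.ids is None:
            raise ValueError("atlas samples must carry identity labels")
        for i in s.ids:
            if i not in seen:
                seen.add(i)
                ids.append(i)
    maps = [dict(zip(s.ids, s.points)) for s in samples]
    return ids, maps


def _aligned_matrix(
    ids: list[str], maps: list[dict[str, np.ndarray]], transforms
) -> np.ndarray:
    """(S, K, 3) aligned positions with NaN where a cell is absent."""
    out = np.full((len(maps), len(ids), 3), np.nan)
    for s, (m, tf) in enumerate(zip(maps, transforms)):
        present = [k for k, i in enumerate(ids) if i in m]
        if present:
            pts = np.array([m[ids[k]] for k in present])
            out[s, present] = tf.apply(pts)
    return out


def build_asp(
    samples: list[PointSet], cfg: AtlasConfig = AtlasConfig()
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Iterative average-position construction.

    Returns ``(asp, ids, pwa_aligned)`` where ``pwa_aligned`` is the
    (S, K, 3) array of PWA-mapped sample positions (NaN for cells missing
    from a sample) used downstream by SPV/TSV.

    Algorithm: initialise the ASP with the first sample; repeat {affine-
    align every sample to the ASP by its shared cells; average; subtract
    the mean per-cell displacement of the aligned samples from the new ASP
    (pointwise inversion of the average deformation, removing the bias
    toward the initial sample)} until the ASP moves less than
    ``tol_fraction x body length`` or ``max_iter``; finally PWA-map every
    sample to the converged ASP and average the mapped positions.
    """
    ids, maps = _stack_samples(samples)
    k = len(ids)
    asp = np.full((k, 3), np.nan)
    for i, key in enumerate(ids):
        asp[i] = maps[0].get(key, np.nan)
    # cells absent from the seed sample start at the mean over samples that have them
    for i, key in enumerate(ids):
        if np.isnan(asp[i]).any():
            vals = [m[key] for m in maps if key in m]
            asp[i] = np.mean(vals, axis=0)

    body_len = np.linalg.norm(asp.max(axis=0) - asp.min(axis=0))
    tol = cfg.tol_fraction * max(body_len, EPS)

    converged = False
    for _ in range(cfg.max_iter):
        transforms = []
        for m in maps:
            common = [i for i, key in enumerate(ids) if key in m]
            src = np.array([m[ids[i]] for i in common])
            dst = asp[common]
            transforms.append(fit_affine(src, dst))
        aligned = _aligned_matrix(ids, maps, transforms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            new_asp = np.nanmean(aligned, axis=0)
        # Barycentric bias correction: the averaged shape lives in the pose of
        # the seed sample.  Evaluate the inverse alignment of every sample at
        # the ASP points (a pointwise average deformation field from atlas
        # space back to the samples) and move the ASP by its mean, so that at
        # convergence the ASP sits at the pose barycenter of the population.
        disp = np.zeros_like(new_asp)
        for tf in transforms:
            inv = np.linalg.inv(tf.matrix)
            back = (new_asp - tf.translation) @ inv.T
            disp += back - new_asp
        new_asp = new_asp + disp / len(transforms)
        move = np.nanmax(np.linalg.norm(new_asp - asp, axis=1))
        asp = new_asp
        if move < tol:
            converged = True
            break
    if not converged:
        warnings.warn("build_asp: not converged within max_iter; returning best ASP")

    # final refinement: PWA-map every sample to the converged ASP and average
    pwa_transforms = []
    for m in maps:
        common = [i for i, key in enumerate(ids) if key in m]
        src = np.array([m[ids[i]] for i in common])
        dst = asp[common]
        pwa_transforms.append(fit_pwa(src, dst, cfg.pwa_segments))
    pwa_aligned = _aligned_matrix(ids, maps, pwa_transforms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        asp = np.nanmean(pwa_aligned, axis=0)
    return asp, ids, pwa_aligned


def build_spv(asp: np.ndarray, pwa_aligned: np.ndarray) -> np.ndarray:
    """Per-cell per-axis standard deviation of the PWA-mapped positions."""
    if pwa_aligned.ndim != 3 or pwa_aligned.shape[2] != 3:
        raise ValueError("pwa_aligned must be (S, K, 3)")
    counts = np.sum(~np.isnan(pwa_aligned[:, :, 0]), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spv = np.nanstd(pwa_aligned, axis=0, ddof=1)
    sparse = counts < 2
    if sparse.any():
        fill = np.nanmedian(spv[~sparse]) if (~sparse).any() else 1.0
        warnings.warn(f"{int(sparse.sum())} cells present in <2 samples; SPV set to median")
        spv[sparse] = fill
    return spv


def build_tsv(
    asp: np.ndarray,
    pwa_aligned: np.ndarray,
    params: ShapeContextParams = ShapeContextParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean chi-square distance between ASP and sample shape contexts.

    Returns ``(tsv, sc_ref)`` where ``sc_ref`` holds the ASP cells' shape
    contexts (the reference descriptors used at recognition time).
    """
    sc_ref = shape_contexts_all(asp, params)
    k = asp.shape[0]
    sums = np.zeros(k)
    counts = np.zeros(k)
    for s in range(pwa_aligned.shape[0]):
        present = ~np.isnan(pwa_aligned[s, :, 0])
        if present.sum() < 2:
            continue
        pts = pwa_aligned[s, present]
        frame = pca_frame(pts)
        idx = np.nonzero(present)[0]
        for local, k_global in enumerate(idx):
            h = shape_context(pts, local, params, frame=frame)
            sums[k_global] += chi_square(sc_ref[k_global], h)
            counts[k_global] += 1
    tsv = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    if (counts == 0).any():
        warnings.warn("some cells had no sample shape context; TSV set to 0")
    return tsv, sc_ref


def build_atlas(
    samples: list[PointSet], cfg: AtlasConfig = AtlasConfig()
) -> StatisticalAtlas:
    """Full atlas construction: ASP, then SPV and TSV from the PWA-aligned samples."""
    asp, ids, pwa_aligned = build_asp(samples, cfg)
    spv = build_spv(asp, pwa_aligned)
    tsv, sc_ref = build_tsv(asp, pwa_aligned, cfg.sc_params)
    return StatisticalAtlas(
        ids=ids, asp=asp, spv=spv, tsv=tsv, sc_params=cfg.sc_params, sc_ref=sc_ref
    )
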