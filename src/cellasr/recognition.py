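"""Identity assignment: iterative statistical-structural point matching.

Pipeline (subject = segmented-cell centroids, target = atlas ASP):

1. extract centroids from the label mask;
2. PCA-align subject to target (scale + proper rotation, best of the four
   axis-sign choices by symmetric Chamfer distance);
3. robust point matching (RPM) under deterministic annealing with a
   similarity combining spatial distance and shape-context chi-square
   distance, ``f = 1/(alpha*beta) * exp(-(d/alpha + g/beta))`` — alpha
   decays (spatial term dominates early), beta grows (shape term
   fine-tunes late);
4. map the subject by global affine then piecewise affine (PWA) fitted on
   the current correspondences;
5. refine via bipartite assignment: per-pair anisotropic-Gaussian
   similarities built from the atlas SPV (``f_spv``) and TSV (``f_tsv``)
   priors, Hungarian on each separately, keep the consensus pairs;
6. iterate 4-5 until stable; final assignment by Hungarian on
   ``F_spv + F_tsv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .atlas import (
    AffineTransform,
    ShapeContextParams,
    StatisticalAtlas,
    chi_square,
    fit_affine,
    fit_pwa,
    shape_contexts_all,
)
from .synthetic import PointSet

BIG_COST = 1e9
F_FLOOR = 1e-300


@dataclass
class RecognitionConfig:
    """Knobs of the matching pipeline.

    ``alpha0`` defaults to the mean squared nearest-neighbour distance of
    the target set (set at run time when left None); ``beta0`` is chosen
    so the spatial and shape exponent terms start with equal median
    magnitude.  ``anneal_rate`` multiplies alpha (and divides beta) each
    annealing step; annealing stops when alpha < ``alpha_final``.
    """

    alpha0: float | None = None
    beta0: float | None = None
    anneal_rate: float = 0.93
    alpha_final: float = 0.1
    omega: float = 1.0
    rescue_score: float = 2.0  # mean -log f above which shifted restarts kick in
    max_outer_iter: int = 20
    pwa_segments: int = 8
    use_spv: bool = True
    use_tsv: bool = True
    sc_params: ShapeContextParams = field(default_factory=ShapeContextParams)

    def __post_init__(self) -> None:
        if not 0 < self.anneal_rate < 1:
            raise ValueError("anneal_rate must be in (0, 1)")


@dataclass
class MatchState:
    correspondences: list[tuple[int, int]]
    soft: np.ndarray | None = None
    alpha: float = 0.0
    beta: float = 0.0
    iterations: int = 0


def extract_centroids(mask: np.ndarray) -> tuple[PointSet, list[int]]:
    """Per-instance mean voxel coordinate, ordered by label.

    Returns the centroids as an (x, y, z) point set plus the label order.
    The mask is (z, y, x); centroids are converted to (x, y, z).
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no instances")
    coms = ndi.center_of_mass(mask > 0, mask, labels)  # (z, y, x) tuples
    pts = np.array(coms, dtype=np.float64)[:, ::-1]  # -> (x, y, z)
    return PointSet(pts), [int(l) for l in labels]


def _chamfer(a: np.ndarray, b: np.ndarray) -> float:
    ta, tb = cKDTree(a), cKDTree(b)
    return float(tb.query(a)[0].mean() + ta.query(b)[0].mean())


def pca_align_candidates(subject: PointSet, target: PointSet) -> list[AffineTransform]:
    """The four proper-rotation PCA alignments, sorted by Chamfer distance."""
    s, t = subject.points, target.points
    if len(s) < 4 or len(t) < 4:
        raise ValueError("PCA alignment needs at least 4 points per set")
    ms, mt = s.mean(axis=0), t.mean(axis=0)
    cs, ct = s - ms, t - mt
    _, sing_s, vs = np.linalg.svd(cs, full_matrices=False)
    _, sing_t, vt = np.linalg.svd(ct, full_matrices=False)
    if sing_s[-1] < 1e-9 * sing_s[0] or sing_t[-1] < 1e-9 * sing_t[0]:
        raise ValueError("rank-deficient point covariance; PCA frame undefined")
    # make both bases proper rotations so every sign combination below is proper
    if np.linalg.det(vs) < 0:
        vs = vs.copy()
        vs[2] = -vs[2]
    if np.linalg.det(vt) < 0:
        vt = vt.copy()
        vt[2] = -vt[2]
    scale = (sing_t / np.maximum(sing_s, 1e-12))  # per-axis std ratio
    scored: list[tuple[float, AffineTransform]] = []
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        a = vt.T @ np.diag(np.asarray(signs) * scale) @ vs
        tf = AffineTransform(a, mt - a @ ms)
        scored.append((_chamfer(tf.apply(s), t), tf))
    scored.sort(key=lambda x: x[0])
    return [tf for _, tf in scored]


def pca_align(subject: PointSet, target: PointSet) -> AffineTransform:
    """Rigid+scale alignment of PCA frames, proper rotations only.

    Centers both sets, rotates the subject's principal axes onto the
    target's, scales per principal axis by the standard-deviation ratio,
    and among the four proper axis-sign flips returns the transform with
    the smallest symmetric Chamfer distance.  Reflections are never
    produced, so a mirror-image subject stays mirrored.
    """
    return pca_align_candidates(subject, target)[0]


def _similarity_matrix(
    s_pts: np.ndarray,
    v_pts: np.ndarray,
    g: np.ndarray | None,
    alpha: float,
    beta: float | None,
) -> np.ndarray:
    """Pairwise density f(s_n | v_m) = 1/(alpha beta) exp(-(d/alpha + g/beta)).

    ``d`` is the squared Euclidean distance: alpha is the deterministic-
    annealing temperature and carries voxel^2 units, as in classic robust
    point matching.
    """
    d = ((s_pts[:, None] - v_pts[None]) ** 2).sum(axis=2)
    expo = d / alpha
    norm = alpha
    if g is not None and beta is not None and np.isfinite(beta):
        expo = expo + g / beta
        norm = alpha * beta
    f = np.exp(-expo) / norm
    return np.maximum(f, F_FLOOR)


def _soft_assign(f: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Alternating row/column normalization with an outlier slack row/column."""
    n, m = f.shape
    p = np.empty((n + 1, m + 1))
    p[:n, :m] = f
    p[n, :m] = np.exp(-1.0)
    p[:n, m] = np.exp(-1.0)
    p[n, m] = np.exp(-1.0)
    for _ in range(n_iter):
        p[:n] /= p[:n].sum(axis=1, keepdims=True)
        p[:, :m] /= p[:, :m].sum(axis=0, keepdims=True)
    return p[:n, :m]


def hard_assignment(f: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one matching maximizing the product of similarities (min sum -log f)."""
    cost = -np.log(np.maximum(f, F_FLOOR))
    n, m = cost.shape
    size = max(n, m)
    if n != m:
        padded = np.full((size, size), BIG_COST)
        padded[:n, :m] = cost
        cost = padded
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m]


def rpm_match(
    subject: PointSet,
    target: PointSet,
    sc_target: np.ndarray | None,
    cfg: RecognitionConfig = RecognitionConfig(),
) -> MatchState:
    """Deterministic-annealing robust point matching.

    Alternates soft correspondence estimation (with outlier slack) and
    affine re-fitting while alpha anneals down and beta anneals up, so the
    spatial term drives the early, coarse stage and the shape-context term
    the late, fine stage.  Subject shape contexts are recomputed whenever
    the pose update is applied.  Ends with a hard assignment on the final
    similarity matrix.
    """
    s = subject.points.copy()
    v = target.points
    use_shape = sc_target is not None
    if cfg.alpha0 is not None:
        alpha = cfg.alpha0
    else:
        # hot enough that true pairs are visible through both the target's
        # own crowding and the residual misalignment of the initial pose
        nn_t = cKDTree(v).query(v, k=2)[0][:, 1]
        init_mis = cKDTree(v).query(s)[0]
        alpha = 5.0 * float(max((nn_t**2).mean(), (init_mis**2).mean()))
    alpha_start = alpha
    iters = 0
    beta = cfg.beta0
    g = None
    while alpha > cfg.alpha_final:
        if sc_target is not None:
            sc_s = shape_contexts_all(s, cfg.sc_params)
            g = _chi_square_matrix(sc_s, sc_target)
            if beta is None:
                # equalize median exponent magnitudes at the start
                d0 = ((s[:, None] - v[None]) ** 2).sum(axis=2)
                med_d = np.median(d0) / alpha
                med_g = np.median(g)
                beta = float(med_g / max(med_d, 1e-12))
        f = _similarity_matrix(s, v, g if use_shape else None, alpha, beta)
        p = _soft_assign(f)
        w = p.sum(axis=1, keepdims=True)
        targets = p @ v / np.maximum(w, 1e-12)
        keep = w[:, 0] > 1e-6
        if keep.sum() >= 4:
            tf = fit_affine(subject.points[keep], targets[keep])
            s = tf.apply(subject.points)
            if alpha < 0.05 * alpha_start:
                # late, cold stage: allow a piecewise-affine update so smooth
                # non-affine body bending can be followed
                n_seg = _effective_segments(int(keep.sum()), cfg.pwa_segments)
                if n_seg > 1:
                    pwa = fit_pwa(s[keep], targets[keep], n_seg)
                    s = pwa.apply(s)
        alpha *= cfg.anneal_rate
        if beta is not None:
            beta /= cfg.anneal_rate
        iters += 1
        if iters > 500:  # pragma: no cover - safety
            break
    f = _similarity_matrix(s, v, g if use_shape else None, max(alpha, 1e-6), beta)
    pairs = hard_assignment(f)
    return MatchState(correspondences=pairs, soft=f, alpha=alpha,
                      beta=beta if beta is not None else 0.0, iterations=iters)


def _chi_square_matrix(h_a: np.ndarray, h_b: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    num = (h_a[:, None] - h_b[None]) ** 2
    den = h_a[:, None] + h_b[None] + eps
    return 0.5 * (num / den).sum(axis=2)


def _effective_segments(n_corr: int, n_segments: int) -> int:
    # keep >= ~25 correspondences per piecewise-affine segment so the
    # per-segment fits stay well conditioned under partially wrong matches
    return max(1, min(n_segments, n_corr // 25))


def map_subject(
    subject: PointSet,
    correspondences: list[tuple[int, int]],
    target: PointSet,
    n_segments: int = 8,
) -> np.ndarray:
    """Map subject points by global affine then PWA fitted on correspondences.

    The piecewise-affine stage uses at most one segment per ~25
    correspondences, so sparse or unreliable matches fall back toward a
    single global affine.
    """
    if not correspondences:
        raise ValueError("no correspondences to fit a mapping on")
    sn = np.array([subject.points[n] for n, _ in correspondences])
    vm = np.array([target.points[m] for _, m in correspondences])
    aff = fit_affine(sn, vm)
    mapped_all = aff.apply(subject.points)
    pwa = fit_pwa(aff.apply(sn), vm, _effective_segments(len(correspondences), n_segments))
    return pwa.apply(mapped_all)


def spv_similarity(
    s_n: np.ndarray, v_m: np.ndarray, sigma_m: np.ndarray, omega: float = 1.0
) -> float:
    """Anisotropic-Gaussian positional similarity exp(-||(s-v)/sigma||^2 / (2 omega^2))."""
    sigma = np.maximum(np.asarray(sigma_m, dtype=float), 1e-6)
    d = float(np.sum(((np.asarray(s_n) - np.asarray(v_m)) / sigma) ** 2))
    return float(np.exp(-d / (2.0 * omega**2)))


def tsv_similarity(g_nm: float, gamma_m: float, omega: float = 1.0) -> float:
    """Shape-context similarity exp(-g^2 / (2 omega^2 gamma^2))."""
    gamma = max(float(gamma_m), 1e-6)
    return float(np.exp(-(g_nm**2) / (2.0 * omega**2 * gamma**2)))


def _prior_matrices(
    mapped: np.ndarray,
    sc_subject: np.ndarray,
    atlas: StatisticalAtlas,
    cfg: RecognitionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    sigma = np.maximum(atlas.spv, 1e-6)
    if not cfg.use_spv:
        sigma = np.ones_like(sigma) * np.median(sigma)  # isotropic, uninformative
    diff = mapped[:, None] - atlas.asp[None]
    d = ((diff / sigma[None]) ** 2).sum(axis=2)
    f_spv = np.exp(-d / (2.0 * cfg.omega**2))
    if atlas.sc_ref is None:
        raise ValueError("atlas has no reference shape contexts")
    g = _chi_square_matrix(sc_subject, atlas.sc_ref)
    gamma = np.maximum(atlas.tsv, 1e-6)
    f_tsv = np.exp(-(g**2) / (2.0 * cfg.omega**2 * gamma[None] ** 2))
    return np.maximum(f_spv, F_FLOOR), np.maximum(f_tsv, F_FLOOR)


def refine_bipartite(
    mapped: np.ndarray,
    sc_subject: np.ndarray,
    atlas: StatisticalAtlas,
    cfg: RecognitionConfig = RecognitionConfig(),
) -> list[tuple[int, int]]:
    """Consensus of the SPV-based and TSV-based Hungarian assignments.

    Solves the assignment problem separately on ``F_spv`` and ``F_tsv``
    and keeps only pairs present in both solutions; if TSV is disabled or
    the consensus is empty, falls back to the SPV assignment alone.
    """
    f_spv, f_tsv = _prior_matrices(mapped, sc_subject, atlas, cfg)
    a_spv = set(hard_assignment(f_spv))
    if not cfg.use_tsv:
        return sorted(a_spv)
    a_tsv = set(hard_assignment(f_tsv))
    consensus = sorted(a_spv & a_tsv)
    if len(consensus) < 4:  # too few pairs to fit the next mapping on
        warnings.warn(
            "refine_bipartite: consensus below 4 pairs; falling back to SPV assignment"
        )
        return sorted(a_spv)
    return consensus


@dataclass
class RecognitionResult:
    assignment: dict[int, str | None]  # subject index -> atlas id (or None)
    confidence: dict[int, float]
    mapped_points: np.ndarray
    iterations: int


def _recognize_from_pose(
    subject: PointSet,
    aligned: PointSet,
    atlas: StatisticalAtlas,
    cfg: RecognitionConfig,
) -> tuple[float, RecognitionResult]:
    """Run RPM + iterative refinement from one initial pose.

    Returns (score, result) where score is the mean assignment cost
    -log(f) of the final pairing (lower is better) for comparing
    alternative initial poses.
    """
    target = atlas.pointset
    sc_target = atlas.sc_ref if cfg.use_tsv else None
    state = rpm_match(aligned, target, sc_target, cfg)
    corr = state.correspondences

    def evaluate(corr_in):
        """Map on corr_in, build prior matrices, score the final assignment."""
        mapped = map_subject(aligned, corr_in, target, cfg.pwa_segments)
        sc_subject = shape_contexts_all(mapped, cfg.sc_params)
        f_spv, f_tsv = _prior_matrices(mapped, sc_subject, atlas, cfg)
        f_sum = f_spv + f_tsv if cfg.use_tsv else f_spv
        final = hard_assignment(f_sum)
        score = float(np.mean([-np.log(max(f_sum[n, m], F_FLOOR)) for n, m in final]))
        return score, mapped, sc_subject, f_sum, final

    best_eval = evaluate(corr)
    seen = {frozenset(corr)}
    iterations = 0
    for _ in range(cfg.max_outer_iter):
        iterations += 1
        _, mapped, sc_subject, _, _ = best_eval if iterations == 1 else cur_eval  # noqa: F821
        new_corr = refine_bipartite(mapped, sc_subject, atlas, cfg)
        key = frozenset(new_corr)
        if key in seen:
            break
        seen.add(key)
        cur_eval = evaluate(new_corr)
        # keep the best-scoring state: refinement must never end worse
        # than the matching it started from
        if cur_eval[0] < best_eval[0]:
            best_eval = cur_eval

    score, mapped, _, f_sum, final = best_eval
    assignment: dict[int, str | None] = {n: None for n in range(len(subject))}
    confidence: dict[int, float] = {}
    row_tot = f_sum.sum(axis=1)
    for n, m in final:
        assignment[n] = atlas.ids[m]
        confidence[n] = float(f_sum[n, m] / max(row_tot[n], F_FLOOR))
    return score, RecognitionResult(assignment, confidence, mapped, iterations)


def recognize(
    subject: PointSet,
    atlas: StatisticalAtlas,
    cfg: RecognitionConfig = RecognitionConfig(),
) -> RecognitionResult:
    """Full recognition pipeline: align, RPM, iterate map/refine, assign.

    The initial PCA alignment has a four-fold proper-rotation sign
    ambiguity; the pipeline is run from every candidate pose and the
    result with the lowest mean assignment cost is returned, which guards
    against locking onto a flipped body axis.  Deterministic given inputs
    and config.  Subjects with fewer than 4 points are rejected;
    unassigned subject points map to ``None``.
    """
    if len(subject) < 4:
        raise ValueError("recognition needs at least 4 subject points")
    target = atlas.pointset
    best: tuple[float, RecognitionResult] | None = None
    candidates = pca_align_candidates(subject, target)
    for tf0 in candidates:
        aligned = PointSet(tf0.apply(subject.points))
        score, result = _recognize_from_pose(subject, aligned, atlas, cfg)
        if best is None or score < best[0]:
            best = (score, result)
    assert best is not None
    if best[0] > cfg.rescue_score:
        # Every pose converged to a poor fit (typically an axial frame
        # shift where each cell locks onto a neighbour's identity).
        # Restart from the best PCA pose shifted along the body axis.
        nn = float(np.median(cKDTree(target.points).query(target.points, k=2)[0][:, 1]))
        _, _, vt = np.linalg.svd(target.points - target.points.mean(axis=0), full_matrices=False)
        axis = vt[0]
        base = candidates[0].apply(subject.points)
        for shift in (-2.0, -1.0, 1.0, 2.0):
            aligned = PointSet(base + shift * nn * axis)
            score, result = _recognize_from_pose(subject, aligned, atlas, cfg)
            if score < best[0]:
                best = (score, result)
    return best[1]
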