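"""Multimodal affine registration of a T2 slice onto its T1 counterpart.

The discrepancy between the fixed and the transformed moving image is the
negative mutual information of their joint intensity histogram (computed
with linear partial-volume binning, in the spirit of Mattes' metric), and
is minimized over 6-parameter affine transforms by a (1+1)-Evolution
Strategy with adaptive per-parameter step sizes, run coarse-to-fine over a
Gaussian pyramid.  Because mutual information is invariant to intensity
recoding, the same machinery aligns contrast-inverted modalities.

Images are plain 2-D float arrays indexed ``[row, col]``; transform
parameters live in pixel units of the full-resolution grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "AffineTransform2D",
    "ESConfig",
    "RegistrationResult",
    "correct_bias",
    "es_minimize",
    "image_center",
    "joint_histogram",
    "mi_discrepancy",
    "register_pair",
    "transform_image",
]


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineTransform2D:
    """6-parameter affine map acting about an image-center fixed point.

    A content point ``q`` (x = column, y = row) maps to
    ``p = R(rotation) @ Shear @ Scale @ (q - c) + c + (tx, ty)``,
    i.e. the linear part acts about the center ``c`` and the translation is
    in pixels.  The identity transform has ``tx = ty = rotation = shear = 0``
    and unit scales.
    """

    tx: float = 0.0
    ty: float = 0.0
    rotation: float = 0.0  # radians
    scale_x: float = 1.0
    scale_y: float = 1.0
    shear: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)  # (cx, cy) in pixels

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scales must be strictly positive")

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear part R @ H @ S (x-first convention)."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        sh = np.array([[1.0, self.shear], [0.0, 1.0]])
        sc = np.diag([self.scale_x, self.scale_y])
        return rot @ sh @ sc

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 forward matrix in (x, y, 1) coordinates."""
        m = np.eye(3)
        lin = self.linear
        c = np.asarray(self.center, dtype=float)
        m[:2, :2] = lin
        m[:2, 2] = self.translation + c - lin @ c
        return m

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, center: tuple[float, float] = (0.0, 0.0)
    ) -> "AffineTransform2D":
        """Decompose a homogeneous matrix back into the 6 parameters.

        Uses the unique R @ (upper triangular, positive diagonal)
        factorization of the linear block.
        """
        lin = np.asarray(m, dtype=float)[:2, :2]
        theta = np.arctan2(lin[1, 0], lin[0, 0])
        c, s = np.cos(theta), np.sin(theta)
        upper = np.array([[c, s], [-s, c]]) @ lin  # R^T @ lin
        sx = upper[0, 0]
        sy = upper[1, 1]
        if sx <= 0 or sy <= 0:
            raise ValueError("matrix is not decomposable with positive scales")
        shear = upper[0, 1] / sy
        cvec = np.asarray(center, dtype=float)
        t = np.asarray(m, dtype=float)[:2, 2] - cvec + lin @ cvec
        return cls(
            tx=float(t[0]), ty=float(t[1]), rotation=float(theta),
            scale_x=float(sx), scale_y=float(sy), shear=float(shear),
            center=(float(cvec[0]), float(cvec[1])),
        )

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return AffineTransform2D.from_matrix(
            self.matrix() @ other.matrix(), center=self.center
        )

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D.from_matrix(
            np.linalg.inv(self.matrix()), center=self.center
        )

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.matrix(), np.eye(3), atol=atol, rtol=0.0))

    @staticmethod
    def identity(center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform2D":
        return AffineTransform2D(center=center)

    def as_vector(self) -> np.ndarray:
        """(tx, ty, rotation, scale_x, scale_y, shear)."""
        return np.array([self.tx, self.ty, self.rotation,
                         self.scale_x, self.scale_y, self.shear])

    @classmethod
    def from_vector(
        cls, v: np.ndarray, center: tuple[float, float] = (0.0, 0.0)
    ) -> "AffineTransform2D":
        return cls(tx=float(v[0]), ty=float(v[1]), rotation=float(v[2]),
                   scale_x=float(v[3]), scale_y=float(v[4]), shear=float(v[5]),
                   center=center)


def image_center(img: np.ndarray) -> tuple[float, float]:
    """Center of the pixel grid in (x, y) = (col, row) coordinates."""
    h, w = img.shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def _modal_background(img: np.ndarray, bins: int = 64) -> float:
    """Modal intensity, used to fill samples that fall outside the domain."""
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi <= lo:
        return lo
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def transform_image(
    img: np.ndarray,
    t: AffineTransform2D,
    interpolation: str = "linear",
    cval: float | None = None,
) -> np.ndarray:
    """Resample ``img`` under the affine transform ``t``.

    The output at pixel ``p`` is ``img`` sampled at ``t^{-1}(p)`` so that
    image content moves forward by ``t``.  Out-of-domain samples are filled
    with ``cval`` (default: the modal background intensity of ``img``).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if t.is_identity():
        return img.copy()
    order = 0 if interpolation == "nearest" else 1
    if cval is None:
        cval = _modal_background(img)
    inv = np.linalg.inv(t.matrix())
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w]
    sx = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2]
    sy = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2]
    return ndimage.map_coordinates(
        img, [sy, sx], order=order, mode="constant", cval=float(cval),
        prefilter=False,
    )


# ---------------------------------------------------------------------------
# Mutual-information discrepancy
# ---------------------------------------------------------------------------

def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = 50,
                    range_a: tuple[float, float] | None = None,
                    range_b: tuple[float, float] | None = None) -> np.ndarray:
    """Joint intensity probability table with linear partial-volume binning.

    Each image is affinely mapped onto ``[0, bins - 1]`` using its own
    intensity range (or an explicit ``range_a``/``range_b``, which keeps the
    bin edges fixed while an image is being warped); every pixel pair
    distributes unit mass bilinearly over the four neighboring
    (bin_a, bin_b) cells.  Entries are nonnegative and sum to one, and the
    marginals equal the single-image histograms computed with the same
    linear weighting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a common shape")
    if bins < 2:
        raise ValueError("need at least 2 bins")

    def _scaled(x: np.ndarray, rng) -> np.ndarray:
        lo, hi = (float(np.min(x)), float(np.max(x))) if rng is None else rng
        if hi <= lo:
            return np.zeros(x.size)
        return np.clip((x.ravel() - lo) * ((bins - 1) / (hi - lo)),
                       0.0, bins - 1.0)

    fa, fb = _scaled(a, range_a), _scaled(b, range_b)
    ia = np.minimum(fa.astype(np.int64), bins - 2)
    ib = np.minimum(fb.astype(np.int64), bins - 2)
    wa = fa - ia
    wb = fb - ib

    flat = np.zeros(bins * bins)
    base = ia * bins + ib
    np.add.at(flat, base, (1 - wa) * (1 - wb))
    np.add.at(flat, base + 1, (1 - wa) * wb)
    np.add.at(flat, base + bins, wa * (1 - wb))
    np.add.at(flat, base + bins + 1, wa * wb)
    return flat.reshape(bins, bins) / a.size


def mi_discrepancy(a: np.ndarray, b: np.ndarray, bins: int = 50,
                   range_a: tuple[float, float] | None = None,
                   range_b: tuple[float, float] | None = None) -> float:
    """Negative mutual information (bits) of the joint histogram.

    ``S = -sum_ij p(i,j) log2( p(i,j) / (p(i) q(j)) ) <= 0``; smaller is
    better aligned.  When ``b`` is a bijective recoding of ``a`` this equals
    ``-H(a)``.
    """
    p = joint_histogram(a, b, bins=bins, range_a=range_a, range_b=range_b)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(pa, pb)
    mi = float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))
    return -mi


# ---------------------------------------------------------------------------
# (1+1)-Evolution Strategy
# ---------------------------------------------------------------------------

@dataclass
class ESConfig:
    """Settings of the (1+1)-Evolution Strategy.

    On an accepted mutation every step size grows by ``growth_factor``; on
    a rejection it shrinks by ``shrink_factor`` (default
    ``growth_factor**-1``, which keeps the step size stationary at a 50%
    acceptance rate and decays it smoothly near an optimum).  The search
    stops at ``max_iter`` evaluations or once every step size falls below
    ``min_step``.
    """

    max_iter: int = 300
    growth_factor: float = 1.05
    shrink_factor: float | None = None  # defaults to growth_factor ** -1
    initial_step: float | np.ndarray = 1.0
    min_step: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.shrink_factor is None:
            self.shrink_factor = self.growth_factor ** -1


def es_minimize(objective, init, config: ESConfig | None = None):
    """Minimize ``objective`` over a real vector with a (1+1)-ES.

    Returns ``(best_point, trace)`` where ``trace`` is the best-so-far
    objective value after each iteration (non-increasing).  The best point
    is the smallest objective value ever evaluated, including the start.
    """
    config = config or ESConfig()
    mu = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    f_mu = float(objective(mu))
    if not np.isfinite(f_mu):
        raise ValueError("objective is not finite at the initial point")
    steps = np.broadcast_to(
        np.asarray(config.initial_step, dtype=float), mu.shape
    ).copy()
    rng = np.random.default_rng(config.seed)
    best, f_best = mu.copy(), f_mu
    trace = []
    for _ in range(config.max_iter):
        cand = mu + steps * rng.standard_normal(mu.shape)
        f_cand = float(objective(cand))
        if np.isfinite(f_cand) and f_cand < f_mu:
            mu, f_mu = cand, f_cand
            steps *= config.growth_factor
            if f_cand < f_best:
                best, f_best = cand.copy(), f_cand
        else:
            steps *= config.shrink_factor
        trace.append(f_best)
        if np.all(steps < config.min_step):
            break
    return best, np.asarray(trace)


# ---------------------------------------------------------------------------
# Pairwise registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    final_discrepancy: float
    initial_discrepancy: float
    iterations: int
    converged: bool
    trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    return sm[::factor, ::factor]


def _entropy(img: np.ndarray, bins: int) -> float:
    p = joint_histogram(img, img, bins=bins).sum(axis=1)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# per-level restart step ladders, coarsest -> finest, in ES units
# (one unit ~ 1 px of corner displacement at full resolution)
_RESTART_LADDERS = (
    (1.0, 0.3, 0.1),
    (0.7, 0.2, 0.07),
    (0.5, 0.15, 0.05, 0.02),
)


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    es: ESConfig | None = None,
    bins: int = 50,
    pyramid_levels: int = 3,
    mi_floor: float = 0.05,
    grid_init: bool = True,
) -> RegistrationResult:
    """Align ``moving`` onto ``fixed`` by MI-minimizing affine search.

    The (1+1)-ES runs coarse-to-fine over a factor-2 Gaussian pyramid with
    ``es.max_iter`` objective evaluations *per level* (mirroring the usual
    per-level iteration semantics of pyramid registration).  ES steps are
    expressed in units of roughly one pixel of corner displacement so a
    single step-size scale is meaningful across translation, rotation,
    scale and shear.  Within a level, whenever the step sizes collapse the
    search restarts from the incumbent with the next (smaller) radius of a
    fixed ladder until the level budget is spent — the restart is the
    mechanism for escaping non-optimal local minima and for sub-pixel
    polishing.  At the coarsest level an optional translation x rotation
    grid seeds the search.  Histogram bin edges are frozen per level from
    the unwarped image ranges so the objective does not drift as the warp
    moves.

    The search always returns the best transform found; failure to
    converge is signaled via ``converged=False``.  Convergence requires
    the finest-level steps to have collapsed, the discrepancy not to have
    worsened, and the final mutual information to reach at least
    ``mi_floor`` of the smaller marginal entropy — an absolute-similarity
    test that also accepts pairs which start out aligned and rejects
    unrelated images.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a shape (resample first)")
    es = es or ESConfig()
    center = image_center(fixed)
    half_diag = 0.5 * float(np.hypot(*fixed.shape))
    # parameter scaling: one ES unit ~ 1 px displacement at the image corner
    scales = np.array([1.0, 1.0, 1.0 / half_diag, 1.0 / half_diag,
                       1.0 / half_diag, 1.0 / half_diag])

    def from_units(u: np.ndarray, ctr, factor) -> AffineTransform2D:
        v = u * scales
        return AffineTransform2D(
            tx=v[0] / factor, ty=v[1] / factor, rotation=v[2],
            scale_x=max(1.0 + v[3], 1e-3), scale_y=max(1.0 + v[4], 1e-3),
            shear=v[5], center=ctr,
        )

    levels = [2 ** k for k in range(pyramid_levels - 1, -1, -1)]
    u = np.zeros(6)
    s0 = mi_discrepancy(fixed, moving, bins=bins)
    total_iters = 0
    final_trace = np.empty(0)
    final_steps_collapsed = False
    for li, factor in enumerate(levels):
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        ctr = image_center(fx)
        fill = _modal_background(mv)
        range_f = (float(fx.min()), float(fx.max()))
        range_m = (float(mv.min()), float(mv.max()))

        def obj(uu, fx=fx, mv=mv, ctr=ctr, factor=factor, fill=fill,
                range_f=range_f, range_m=range_m):
            t = from_units(uu, ctr, factor)
            warped = transform_image(mv, t, cval=fill)
            return mi_discrepancy(fx, warped, bins=bins,
                                  range_a=range_f, range_b=range_m)

        best_u = u
        f_best = obj(u)
        total_iters += 1
        if li == 0 and grid_init:
            # coarse seeding over translation x rotation
            span = 0.125 * min(fixed.shape)
            for dtx in (-span, 0.0, span):
                for dty in (-span, 0.0, span):
                    for drot in (-0.15, 0.0, 0.15):
                        cand = u + np.array(
                            [dtx, dty, drot * half_diag, 0, 0, 0])
                        f_cand = obj(cand)
                        total_iters += 1
                        if f_cand < f_best:
                            best_u, f_best = cand, f_cand
        ladder = _RESTART_LADDERS[min(li, len(_RESTART_LADDERS) - 1)]
        remaining = es.max_iter
        k = 0
        while remaining > 5:
            run_cfg = ESConfig(
                max_iter=remaining,
                growth_factor=es.growth_factor,
                shrink_factor=es.shrink_factor,
                initial_step=(np.asarray(es.initial_step, float)
                              * factor * ladder[min(k, len(ladder) - 1)]),
                min_step=es.min_step,
                seed=es.seed + 31 * factor + k,
            )
            cand, tr = es_minimize(obj, best_u, run_cfg)
            f_cand = obj(cand)
            total_iters += len(tr) + 1
            if f_cand < f_best:
                best_u, f_best = cand, f_cand
            collapsed = len(tr) < remaining
            remaining -= len(tr) + 1
            k += 1
            if li == len(levels) - 1:
                final_trace = tr
                final_steps_collapsed = final_steps_collapsed or collapsed
        u = best_u

    best = from_units(u, center, 1.0)
    warped = transform_image(moving, best)
    sf = mi_discrepancy(fixed, warped, bins=bins)
    h_min = min(_entropy(fixed, bins), _entropy(moving, bins))
    normalized_mi = (-sf) / h_min if h_min > 0 else 0.0
    converged = bool(
        final_steps_collapsed and sf <= s0 + 1e-12 and normalized_mi >= mi_floor
    )
    return RegistrationResult(
        transform=best,
        final_discrepancy=float(sf),
        initial_discrepancy=float(s0),
        iterations=total_iters,
        converged=converged,
        trace=final_trace,  # last finest-level run; non-increasing
    )


# ---------------------------------------------------------------------------
# Bias-field correction
# ---------------------------------------------------------------------------

def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    """Design matrix of 2-D monomials x^i y^j, i + j <= order, on [-1, 1]^2."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    xn = 2.0 * x / max(w - 1, 1) - 1.0
    yn = 2.0 * y / max(h - 1, 1) - 1.0
    cols = [
        (xn ** i * yn ** j).ravel()
        for d in range(order + 1)
        for i in range(d + 1)
        for j in [d - i]
    ]
    return np.column_stack(cols)


def evaluate_bias_field(
    shape: tuple[int, int], coefficients: np.ndarray
) -> np.ndarray:
    """Evaluate a polynomial bias field on the pixel grid.

    Coefficients are ordered by total degree then by x-power:
    ``1, x, y, x^2, xy, y^2, ...`` over coordinates normalized to [-1, 1].
    """
    coefficients = np.atleast_1d(np.asarray(coefficients, dtype=float))
    n = len(coefficients)
    order = 0
    while (order + 1) * (order + 2) // 2 < n:
        order += 1
    if (order + 1) * (order + 2) // 2 != n:
        raise ValueError(
            "coefficient count must be a triangular number (1, 3, 6, 10, ...)"
        )
    design = _poly_design(shape, order)
    return (design @ coefficients).reshape(shape)


def apply_bias_field(img: np.ndarray, coefficients) -> np.ndarray:
    """Multiply an image by a low-frequency polynomial field (forward model)."""
    img = np.asarray(img, dtype=float)
    fieldv = evaluate_bias_field(img.shape, coefficients)
    if np.any(fieldv <= 0):
        raise ValueError("bias field must be strictly positive over the image")
    return img * fieldv


def correct_bias(img: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a low-frequency multiplicative inhomogeneity field.

    A polynomial surface of the given order is least-squares fitted to the
    log-intensities of the foreground (pixels above 2% of the maximum) as a
    smooth surrogate of the multiplicative field, the image is divided by
    the exponentiated fit, and the result is rescaled to preserve the mean
    intensity.  A degenerate (non-positive) fit falls back to the identity
    with a warning.
    """
    img = np.asarray(img, dtype=float)
    if order < 0:
        raise ValueError("order must be nonnegative")
    fg = img > 0.02 * float(np.max(img)) if np.max(img) > 0 else np.zeros(
        img.shape, dtype=bool
    )
    if fg.sum() < (order + 1) * (order + 2) // 2:
        warnings.warn("too little foreground to fit a bias field; returning input")
        return img.copy()
    design = _poly_design(img.shape, order)
    logv = np.log(np.maximum(img, 1e-8))
    rows = fg.ravel()
    coef, *_ = np.linalg.lstsq(design[rows], logv.ravel()[rows], rcond=None)
    fieldv = np.exp((design @ coef).reshape(img.shape))
    if not np.all(np.isfinite(fieldv)) or np.any(fieldv <= 0):
        warnings.warn("degenerate bias-field fit; returning input unchanged")
        return img.copy()
    fieldv = fieldv / fieldv[fg].mean()
    out = img / fieldv
    mean_in = img[fg].mean()
    mean_out = out[fg].mean()
    if mean_out > 0:
        out *= mean_in / mean_out
    return out
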