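"""Objective image-quality evaluation: Hotelling-observer SNR and Fréchet
distance between image ensembles.

The detection task is signal-known-exactly / background-known-statistically:
a noisy image ``g_t = f (+ s) + n_t`` is classified as signal-absent or
signal-present, where ``f`` is a random background, ``s`` a fixed compact
signal, and ``n_t`` i.i.d. Gaussian task noise.  The Hotelling observer is
the optimal linear discriminant; within a region of interest around the
signal its figure of merit is

    SNR_HO = sqrt( s_ROI^T K^{-1} s_ROI ),

with ``K = K_background + sigma_t^2 I`` the ROI data covariance decomposed
into the empirical background covariance and the exact task-noise diagonal.
The quadratic form itself is also exposed; every report states which
convention a number uses.  The linear system is solved with a symmetric
positive-definite (Cholesky) solve, never an explicit inverse.

The Fréchet distance between two Gaussians fitted to feature embeddings of
two image sets is the FID construction,

    d^2 = |mu_1 - mu_2|^2 + tr(S_1 + S_2 - 2 (S_1 S_2)^{1/2}),

reported on the squared scale as is conventional.  The default feature
extractor is a deterministic pixel-pooling embedding (block-average to
8 x 8, flatten); a pretrained-network extractor can be plugged in through
the same interface but is never required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .object_simulator import ObjectEnsemble, SignalImage

__all__ = [
    "DetectionTask",
    "CovarianceModel",
    "PixelPoolExtractor",
    "extract_roi",
    "embed_roi",
    "estimate_covariance_decomposed",
    "covariance_from_autocovariance",
    "compute_snr_ho",
    "hotelling_quadratic_form",
    "gaussian_frechet_distance",
    "compute_fid",
]


@dataclass(frozen=True)
class DetectionTask:
    """Signal-known-exactly detection task on an ROI around the signal.

    ``task_noise_std`` is the i.i.d. Gaussian measurement noise of the task
    (not the imaging system), as a fraction of the [0, 1] intensity range.
    """

    signal: SignalImage
    roi_center: tuple[int, int]
    roi_size: int = 16
    task_noise_std: float = 0.02

    def __post_init__(self):
        if self.task_noise_std <= 0:
            raise ValueError("task_noise_std must be > 0")
        n = self.signal.values.shape[0]
        r0, c0 = self.roi_origin
        if r0 < 0 or c0 < 0 or r0 + self.roi_size > n or c0 + self.roi_size > n:
            raise ValueError(
                f"ROI of size {self.roi_size} at center {self.roi_center} "
                f"exceeds the {n}x{n} grid"
            )
        sup = self.signal.values != 0
        rows, cols = np.nonzero(sup)
        if rows.size and (
            rows.min() < r0 or rows.max() >= r0 + self.roi_size
            or cols.min() < c0 or cols.max() >= c0 + self.roi_size
        ):
            raise ValueError("signal support must be contained in the ROI")

    @property
    def roi_origin(self) -> tuple[int, int]:
        return (self.roi_center[0] - self.roi_size // 2,
                self.roi_center[1] - self.roi_size // 2)

    def signal_roi_vector(self) -> np.ndarray:
        return extract_roi(self.signal.values, self).ravel()


def extract_roi(image, task: DetectionTask) -> np.ndarray:
    """Exact sub-grid copy of the task ROI (row-major vectorization order)."""
    img = np.asarray(image, dtype=float)
    r0, c0 = task.roi_origin
    s = task.roi_size
    if img.ndim == 2:
        if r0 + s > img.shape[0] or c0 + s > img.shape[1]:
            raise ValueError("ROI exceeds image bounds")
        return img[r0:r0 + s, c0:c0 + s].copy()
    if img.ndim == 3:
        return img[:, r0:r0 + s, c0:c0 + s].copy()
    raise ValueError("expected a 2-D image or a 3-D stack")


def embed_roi(image, roi: np.ndarray, task: DetectionTask) -> np.ndarray:
    """Place an ROI back at its location (round-trip inverse of extract)."""
    img = np.array(image, dtype=float)
    r0, c0 = task.roi_origin
    s = task.roi_size
    img[r0:r0 + s, c0:c0 + s] = roi
    return img


@dataclass
class CovarianceModel:
    """ROI data covariance decomposed as background + task-noise diagonal."""

    matrix: np.ndarray
    task_noise_std: float
    n_samples: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = self.matrix.shape[0]
        if self.matrix.shape != (d, d):
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def estimate_covariance_decomposed(background_rois, task_noise_std: float) -> CovarianceModel:
    """K = empirical covariance of vectorized ROIs + task_noise_std^2 I."""
    rois = np.asarray(background_rois, dtype=float)
    if rois.ndim == 3:
        rois = rois.reshape(rois.shape[0], -1)
    if rois.ndim != 2 or rois.shape[0] < 2:
        raise ValueError("need at least 2 background ROIs")
    centered = rois - rois.mean(axis=0, keepdims=True)
    k_bg = centered.T @ centered / (rois.shape[0] - 1)
    k = k_bg + task_noise_std**2 * np.eye(rois.shape[1])
    return CovarianceModel(matrix=k, task_noise_std=task_noise_std,
                           n_samples=rois.shape[0])


def covariance_from_autocovariance(autocov: np.ndarray, task: DetectionTask) -> CovarianceModel:
    """Analytic ROI covariance of a stationary periodic field.

    ``autocov[dy, dx]`` is the field autocovariance at wrapped lag (dy, dx);
    the ROI covariance is read off at pairwise pixel lags, then the
    task-noise diagonal is added.
    """
    n = autocov.shape[0]
    s = task.roi_size
    idx = np.arange(s)
    ry, rx = np.meshgrid(idx, idx, indexing="ij")
    pix = np.stack([ry.ravel(), rx.ravel()], axis=1)
    dy = (pix[:, None, 0] - pix[None, :, 0]) % n
    dx = (pix[:, None, 1] - pix[None, :, 1]) % n
    k = autocov[dy, dx] + task.task_noise_std**2 * np.eye(s * s)
    return CovarianceModel(matrix=k, task_noise_std=task.task_noise_std,
                           n_samples=0)


def hotelling_quadratic_form(task: DetectionTask, cov: CovarianceModel) -> float:
    """s_ROI^T K^{-1} s_ROI via an SPD (Cholesky) solve."""
    s = task.signal_roi_vector()
    if s.size != cov.dim:
        raise ValueError(f"signal dim {s.size} != covariance dim {cov.dim}")
    c, low = sla.cho_factor(cov.matrix)
    return float(s @ sla.cho_solve((c, low), s))


def compute_snr_ho(task: DetectionTask, background_rois=None,
                   covariance: CovarianceModel | None = None) -> float:
    """Hotelling-observer SNR: sqrt(s_ROI^T K^{-1} s_ROI).

    ``K`` is built from signal-absent background ROIs (empirical covariance
    plus the exact task-noise diagonal) unless an explicit
    :class:`CovarianceModel` is supplied (e.g. an analytic oracle).
    """
    if covariance is None:
        if background_rois is None:
            raise ValueError("provide background_rois or an explicit covariance")
        covariance = estimate_covariance_decomposed(background_rois, task.task_noise_std)
    return float(np.sqrt(hotelling_quadratic_form(task, covariance)))


# -- Frechet distance --------------------------------------------------------

def gaussian_frechet_distance(mean1, cov1, mean2, cov2) -> float:
    """Squared Fréchet distance between two Gaussians (the FID formula).

    The matrix square root of the product is computed by eigendecomposition
    of the symmetrized product; tiny negative eigenvalues (numerical) are
    clipped, larger ones raise.
    """
    mu1, mu2 = np.atleast_1d(np.asarray(mean1, float)), np.atleast_1d(np.asarray(mean2, float))
    s1, s2 = np.atleast_2d(np.asarray(cov1, float)), np.atleast_2d(np.asarray(cov2, float))
    if mu1.shape != mu2.shape or s1.shape != s2.shape or s1.shape[0] != mu1.size:
        raise ValueError("moment dimensions do not match")
    for s in (s1, s2):
        if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
            raise ValueError("covariance matrices must be symmetric")
    # sqrt(S1) via eigendecomposition, then sqrt(sqrt(S1) S2 sqrt(S1))
    w1, v1 = np.linalg.eigh((s1 + s1.T) / 2)
    w1 = np.clip(w1, 0.0, None)
    root1 = (v1 * np.sqrt(w1)) @ v1.T
    m = root1 @ ((s2 + s2.T) / 2) @ root1
    wm = np.linalg.eigh((m + m.T) / 2)[0]
    tol = 1e-8 * max(1.0, np.abs(wm).max())
    if wm.min() < -tol:
        raise ValueError("product covariance has significantly negative spectrum")
    trace_sqrt = np.sqrt(np.clip(wm, 0.0, None)).sum()
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1) + np.trace(s2) - 2.0 * trace_sqrt)
    return max(d2, 0.0)


@dataclass(frozen=True)
class PixelPoolExtractor:
    """Deterministic pixel-pooling feature embedding.

    Block-averages each image down to ``out_size`` x ``out_size`` and
    flattens row-major; images must be square with side a power-of-two
    multiple of ``out_size``.
    """

    out_size: int = 8

    @property
    def name(self) -> str:
        return f"pixel_pool_{self.out_size}"

    def __call__(self, images) -> np.ndarray:
        stack = images.images if isinstance(images, ObjectEnsemble) else np.asarray(images, float)
        if stack.ndim == 2:
            stack = stack[None]
        n, h, w = stack.shape
        if h != w or h % self.out_size:
            raise ValueError(f"images ({h}x{w}) must be square multiples of {self.out_size}")
        f = h // self.out_size
        pooled = stack.reshape(n, self.out_size, f, self.out_size, f).mean(axis=(2, 4))
        return pooled.reshape(n, -1)


def compute_fid(images_a, images_b, extractor=None) -> float:
    """FID between two image sets under a feature extractor.

    Fits a Gaussian (mean, covariance) to the features of each set and
    returns their squared Fréchet distance.  Deterministic given inputs and
    extractor.
    """
    extractor = extractor or PixelPoolExtractor()
    try:
        fa, fb = extractor(images_a), extractor(images_b)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - extractor plumbing
        raise RuntimeError(f"feature extractor {extractor!r} failed") from exc
    dim = fa.shape[1]
    for name, f in (("a", fa), ("b", fb)):
        if f.shape[0] < dim + 1:
            warnings.warn(
                f"image set {name} has {f.shape[0]} samples for {dim}-dim features; "
                "covariance is rank-deficient", stacklevel=2)
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    cov_a = np.cov(fa, rowvar=False)
    cov_b = np.cov(fb, rowvar=False)
    return gaussian_frechet_distance(mu_a, cov_a, mu_b, cov_b)
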