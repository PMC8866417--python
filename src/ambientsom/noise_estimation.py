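"""Noise-model calibration and blind image-noise estimation.

Two estimators:

* **k-space noise from magnitude backgrounds.**  Outside the object support
  a magnitude image reconstructed from fully sampled k-space with i.i.d.
  complex Gaussian noise (per-component std ``sigma``) follows a Rayleigh
  distribution with scale ``sigma / N`` (N x N grid, inverse DFT carrying
  1/N^2).  Pooling background pixels across images and applying the Rayleigh
  maximum-likelihood estimator ``sigma_R = sqrt(mean(x^2) / 2)`` and the
  ``N`` rescaling recovers the k-space noise level — the calibration loop
  used to specify a measurement model for experimentally acquired data.

* **blind image-domain noise.**  The white-noise standard deviation of an
  image is estimated as the median absolute deviation of the finest
  diagonal wavelet detail coefficients divided by 0.6745 (the classic
  robust estimator); per-image estimates are averaged over the ensemble.
  This is the metric used to compare how much measurement noise generative
  models baked into their samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .object_simulator import ObjectEnsemble

__all__ = [
    "BackgroundRegionSpec",
    "NoiseEstimate",
    "fit_rayleigh_sigma",
    "estimate_kspace_noise",
    "estimate_image_noise_std",
]


@dataclass(frozen=True)
class BackgroundRegionSpec:
    """Rectangular patches (row/col ranges, 0-based, half-open) asserted to
    lie outside the object support."""

    patches: tuple[tuple[int, int, int, int], ...]  # (r0, r1, c0, c1)

    def __post_init__(self):
        if not self.patches:
            raise ValueError("at least one background patch is required")
        for r0, r1, c0, c1 in self.patches:
            if r0 >= r1 or c0 >= c1 or r0 < 0 or c0 < 0:
                raise ValueError(f"malformed patch ({r0},{r1},{c0},{c1})")

    def validate(self, grid_size: int) -> None:
        for r0, r1, c0, c1 in self.patches:
            if r1 > grid_size or c1 > grid_size:
                raise ValueError(
                    f"patch ({r0},{r1},{c0},{c1}) exceeds grid size {grid_size}"
                )

    @classmethod
    def whole_image(cls, grid_size: int) -> "BackgroundRegionSpec":
        return cls(patches=((0, grid_size, 0, grid_size),))

    @classmethod
    def corners(cls, grid_size: int, size: int) -> "BackgroundRegionSpec":
        n, s = grid_size, size
        return cls(patches=(
            (0, s, 0, s), (0, s, n - s, n), (n - s, n, 0, s), (n - s, n, n - s, n),
        ))


@dataclass
class NoiseEstimate:
    """A noise standard-deviation estimate with its provenance.

    ``scale`` is ``kspace_per_component`` or ``image_domain``; for
    image-domain estimates on [0, 1]-normalized data, ``percent`` expresses
    sigma relative to the unit range.
    """

    sigma: float
    scale: str
    n_pixels_used: int
    method: str
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return 100.0 * self.sigma

    def to_json_record(self) -> dict:
        return {
            "sigma": self.sigma,
            "scale": self.scale,
            "n_pixels_used": self.n_pixels_used,
            "method": self.method,
            "degenerate": self.degenerate,
            **self.extra,
        }


def fit_rayleigh_sigma(samples) -> float:
    """Closed-form Rayleigh scale MLE: sqrt(mean(x^2) / 2)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if np.any(x < 0):
        raise ValueError("Rayleigh samples must be nonnegative")
    return float(np.sqrt(np.mean(x**2) / 2.0))


def _image_stack(images) -> np.ndarray:
    if isinstance(images, ObjectEnsemble):
        return images.images
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def estimate_kspace_noise(magnitude_images, regions: BackgroundRegionSpec) -> NoiseEstimate:
    """Recover the per-component k-space noise std from magnitude backgrounds.

    Background pixels are pooled across all images and patches, fitted with
    the Rayleigh MLE, and rescaled by the grid side N (background magnitude
    ~ Rayleigh(sigma/N) under the package DFT convention).
    """
    stack = _image_stack(magnitude_images)
    n = stack.shape[-1]
    if stack.shape[-2] != n:
        raise ValueError("magnitude images must be square")
    regions.validate(n)
    pooled = np.concatenate(
        [stack[:, r0:r1, c0:c1].ravel() for r0, r1, c0, c1 in regions.patches]
    )
    sigma_r = fit_rayleigh_sigma(pooled) if np.any(pooled > 0) else 0.0
    return NoiseEstimate(
        sigma=float(sigma_r * n),
        scale="kspace_per_component",
        n_pixels_used=int(pooled.size),
        method="rayleigh_mle_pooled",
        extra={"rayleigh_scale_image_domain": float(sigma_r), "grid_size": n},
    )


def estimate_image_noise_std(images) -> NoiseEstimate:
    """Blind white-noise std of an image ensemble (wavelet-MAD, averaged).

    Scale-equivariant: scaling the images by c scales the estimate by c.
    Constant images yield 0 with the ``degenerate`` flag set.
    """
    stack = _image_stack(images)
    if stack.shape[0] < 1:
        raise ValueError("need at least one image")
    per_image = []
    degenerate = True
    for img in stack:
        if np.ptp(img) < 1e-300:
            per_image.append(0.0)
            continue
        degenerate = False
        _, (_, _, diag) = pywt.dwt2(img, "db2", mode="periodization")
        per_image.append(float(np.median(np.abs(diag)) / 0.6745))
    n_coeff = (stack.shape[1] // 2) * (stack.shape[2] // 2)
    return NoiseEstimate(
        sigma=float(np.mean(per_image)),
        scale="image_domain",
        n_pixels_used=int(len(per_image) * n_coeff),
        method="wavelet_mad_db2",
        degenerate=degenerate,
    )
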