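"""Stylized MRI measurement and reconstruction operators.

The imaging system is the discrete-to-discrete model ``g = H f + n`` with
``H`` a (possibly row-subsampled) 2-D DFT and ``n`` i.i.d. zero-mean complex
Gaussian noise applied independently to the real and imaginary components of
each *sampled* k-space entry.

Conventions, fixed package-wide:

* non-unitary DFT: ``F`` carries no scale factor, ``F^-1`` carries
  ``1/(H*W)``.  A per-component k-space noise standard deviation ``sigma``
  then propagates to an image-domain standard deviation ``sigma / N`` on an
  N x N grid, so sigma = 4 (resp. 16) on a [0, 1]-normalized 256 x 256 image
  gives 1.5625% (resp. 6.25%) image-domain noise;
* k-space arrays are stored with DC at the centered position
  (``fftshift`` layout), so sampling masks are expressed in natural
  centered phase-encode coordinates; shifts are applied internally;
* Cartesian undersampling removes whole phase-encode lines (rows); the
  readout direction is fully sampled and the DC line is always kept.

Reconstruction operators: ``pseudoinverse_reconstruct`` is the zero-filling
Moore-Penrose pseudoinverse followed by the real part,
``magnitude_reconstruct`` takes the complex modulus instead, and
``corrected_fake_reconstruct`` is the training-time magnitude correction

    f_r = f + e,   e = abs(F^-1(F(ReLU(f)) + n)) - ReLU(f),

which equals the true magnitude reconstruction for nonnegative objects but
leaves negative excursions visible to the discriminator, so adversarial
training drives generated objects nonnegative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .object_simulator import ObjectImage

__all__ = [
    "SamplingMask",
    "NoiseModel",
    "KSpaceData",
    "ForwardModel",
    "Reconstructor",
    "make_cartesian_mask",
    "forward_measure",
    "pseudoinverse_reconstruct",
    "magnitude_reconstruct",
    "corrected_fake_reconstruct",
    "measurement_component",
    "UnsupportedConfigurationError",
]


class UnsupportedConfigurationError(ValueError):
    """Operation called outside its supported operator configuration."""


# -- sampling mask -----------------------------------------------------------

@dataclass(frozen=True)
class SamplingMask:
    """Cartesian phase-encode sampling pattern in centered coordinates.

    ``kept_lines`` are row indices k_y in [-N/2, N/2 - 1]; the DC line
    (k_y = 0) is always present and the mask is constant along k_x.
    """

    grid_size: int
    kept_lines: tuple[int, ...]
    scheme: str = "full"
    seed: int = 0

    def __post_init__(self):
        n = self.grid_size
        lines = tuple(sorted(int(k) for k in self.kept_lines))
        object.__setattr__(self, "kept_lines", lines)
        if len(set(lines)) != len(lines):
            raise ValueError("kept_lines contains duplicates")
        if any(k < -n // 2 or k > n // 2 - 1 for k in lines):
            raise ValueError("kept_lines outside centered range")
        if 0 not in lines:
            raise ValueError("the DC line (k_y = 0) must be kept")

    @property
    def acceleration(self) -> float:
        """R = grid_size / |kept_lines| (R = 1 iff fully sampled)."""
        return self.grid_size / len(self.kept_lines)

    def as_bool_grid(self, centered: bool = True) -> np.ndarray:
        """Boolean (N, N) mask; ``centered=False`` gives numpy FFT layout."""
        n = self.grid_size
        rows = np.zeros(n, dtype=bool)
        rows[[k + n // 2 for k in self.kept_lines]] = True
        grid = np.repeat(rows[:, None], n, axis=1)
        return grid if centered else np.fft.ifftshift(grid, axes=0)

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.as_bool_grid() * 255).astype(np.uint8)).save(path)


def make_cartesian_mask(grid_size: int, R: float, scheme: str = "uniform_random",
                        seed: int = 0) -> SamplingMask:
    """Select ``round(grid_size / R)`` phase-encode lines, always keeping DC.

    Lines are selected in conjugate-symmetric units — the two self-mirrored
    lines (DC and the Nyquist line ``-N/2``) and mirror pairs ``{k, -k}``.
    For real-valued objects this makes the masked spectrum Hermitian, so the
    zero-filled-IDFT + real-part reconstruction is the exact Moore-Penrose
    pseudoinverse on real image space and ``H^dagger H`` an orthogonal
    projector.

    Schemes: ``full`` (all lines; requires R = 1), ``uniform_random``
    (uniform over mirror pairs), ``center_band_random`` (central ~8% of
    lines kept, remaining pairs uniform at random).
    """
    n = grid_size
    if not (1 <= R <= n):
        raise ValueError(f"acceleration factor must satisfy 1 <= R <= {n}, got {R}")
    n_keep = int(round(n / R))
    n_keep = max(1, min(n, n_keep))
    all_lines = np.arange(-(n // 2), n // 2)
    if scheme == "full" or n_keep == n:
        if scheme == "full" and n_keep != n:
            raise ValueError("scheme 'full' requires R = 1")
        return SamplingMask(n, tuple(all_lines), scheme="full", seed=seed)
    if scheme not in ("uniform_random", "center_band_random"):
        raise ValueError(f"unknown sampling scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    lines = [0]
    budget = n_keep - 1
    if budget % 2 == 1:  # odd remainder: the self-mirrored Nyquist line
        lines.append(-(n // 2))
        budget -= 1
    n_pairs = budget // 2
    pair_ks = np.arange(1, n // 2)  # {k, -k} candidates
    forced_pairs = np.array([], dtype=int)
    if scheme == "center_band_random":
        half_band = max(1, int(round(0.08 * n)) // 2)
        forced_pairs = pair_ks[pair_ks <= half_band]
        if len(forced_pairs) > n_pairs:
            forced_pairs = forced_pairs[:n_pairs]
    rest = np.setdiff1d(pair_ks, forced_pairs)
    extra = rng.choice(rest, size=n_pairs - len(forced_pairs), replace=False)
    for k in np.concatenate([forced_pairs, extra]):
        lines += [int(k), -int(k)]
    return SamplingMask(n, tuple(lines), scheme=scheme, seed=seed)


# -- noise and data containers ----------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. complex Gaussian k-space noise, per-component std ``kspace_std``."""

    kspace_std: float = 0.0

    def __post_init__(self):
        if self.kspace_std < 0:
            raise ValueError(f"kspace_std must be >= 0, got {self.kspace_std}")


@dataclass
class KSpaceData:
    """Complex k-space values in centered layout, zero on unsampled lines."""

    values: np.ndarray
    mask: SamplingMask
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        n = self.mask.grid_size
        if self.values.shape != (n, n):
            raise ValueError(f"k-space shape {self.values.shape} != mask grid {n}")
        off = ~self.mask.as_bool_grid()
        if np.any(self.values[off] != 0):
            raise ValueError("k-space values must be exactly zero on unsampled lines")
        if not np.all(np.isfinite(self.values[~off].view(float))):
            raise ValueError("k-space contains non-finite values")

    # ---- persistence ------------------------------------------------------
    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            d = h5.create_dataset("kspace", data=self.values.astype(np.complex64))
            h5.create_dataset("mask", data=self.mask.as_bool_grid())
            d.attrs["R"] = self.mask.acceleration
            d.attrs["scheme"] = self.mask.scheme
            d.attrs["mask_seed"] = self.mask.seed
            d.attrs["kept_lines"] = json.dumps(list(self.mask.kept_lines))
            d.attrs["kspace_std"] = self.noise.kspace_std
            d.attrs["seed"] = -1 if self.seed is None else self.seed
            d.attrs["dft_convention"] = "forward unscaled, inverse 1/(H*W), centered storage"

    @classmethod
    def load_hdf5(cls, path) -> "KSpaceData":
        import h5py

        with h5py.File(path, "r") as h5:
            d = h5["kspace"]
            mask = SamplingMask(
                grid_size=d.shape[0],
                kept_lines=tuple(json.loads(d.attrs["kept_lines"])),
                scheme=str(d.attrs["scheme"]),
                seed=int(d.attrs["mask_seed"]),
            )
            seed = int(d.attrs["seed"])
            return cls(values=np.asarray(d[...], dtype=complex), mask=mask,
                       noise=NoiseModel(float(d.attrs["kspace_std"])),
                       seed=None if seed < 0 else seed)


@dataclass(frozen=True)
class ForwardModel:
    """The measurement operator H_n: masked 2-D DFT plus k-space noise."""

    mask: SamplingMask
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def grid_size(self) -> int:
        return self.mask.grid_size


# -- operator applications ---------------------------------------------------

def _as_values(f) -> np.ndarray:
    return f.values if isinstance(f, ObjectImage) else np.asarray(f, dtype=float)


def _centered_fft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(x), axes=(-2, -1))


def _centered_ifft2(x: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)))


def draw_kspace_noise(mask: SamplingMask, std: float, seed: int) -> np.ndarray:
    """Complex noise on sampled entries (centered layout), zero elsewhere."""
    n = mask.grid_size
    rng = np.random.default_rng(seed)
    grid = mask.as_bool_grid()
    m = int(grid.sum())
    noise = np.zeros((n, n), dtype=complex)
    draws = rng.normal(scale=std, size=(2, m)) if std > 0 else np.zeros((2, m))
    noise[grid] = draws[0] + 1j * draws[1]
    return noise


def forward_measure(f, model: ForwardModel, seed: int = 0) -> KSpaceData:
    """g = mask o (DFT(f)) + n, with fresh noise from ``seed``."""
    values = _as_values(f)
    n = model.grid_size
    if values.shape != (n, n):
        raise ValueError(f"object shape {values.shape} != operator grid {n}")
    spectrum = _centered_fft2(values)
    grid = model.mask.as_bool_grid()
    spectrum = np.where(grid, spectrum, 0.0)
    spectrum += draw_kspace_noise(model.mask, model.noise.kspace_std, seed)
    return KSpaceData(values=spectrum, mask=model.mask, noise=model.noise, seed=seed)


def pseudoinverse_reconstruct(g: KSpaceData) -> np.ndarray:
    """Zero-filled pseudoinverse + real part: Re(F^-1(g))."""
    return _centered_ifft2(g.values).real


def magnitude_reconstruct(g: KSpaceData) -> np.ndarray:
    """Magnitude image |F^-1(g)| (elementwise modulus, nonnegative)."""
    return np.abs(_centered_ifft2(g.values))


def corrected_fake_reconstruct(f_hat, model: ForwardModel, seed: int = 0) -> np.ndarray:
    """Magnitude-corrected fake reconstruction f_hat + e.

    ``e = abs(F^-1(F(ReLU(f_hat)) + n)) - ReLU(f_hat)``: for f_hat >= 0 this
    is exactly the magnitude reconstruction of a noisy measurement of f_hat
    (bitwise, for a shared noise draw); where f_hat < 0 the negative values
    pass through and acquire ``abs(F^-1(n))``.
    """
    values = _as_values(f_hat)
    if float(model.mask.acceleration) != 1.0:
        raise UnsupportedConfigurationError(
            "the magnitude correction is defined for fully sampled measurements"
        )
    clipped = np.maximum(values, 0.0)
    g = forward_measure(clipped, model, seed=seed)
    # (values - clipped) + |...| rather than values + (|...| - clipped):
    # algebraically identical, but exactly |F^-1(F(f)+n)| when f >= 0
    return (values - clipped) + magnitude_reconstruct(g)


def measurement_component(f, mask: SamplingMask) -> np.ndarray:
    """f_meas = H^dagger H f: the part of f visible through the mask."""
    values = _as_values(f)
    n = mask.grid_size
    if values.shape != (n, n):
        raise ValueError(f"object shape {values.shape} != mask grid {n}")
    spectrum = np.where(mask.as_bool_grid(), _centered_fft2(values), 0.0)
    return _centered_ifft2(spectrum).real


@dataclass(frozen=True)
class Reconstructor:
    """Measurement -> image operator O.

    ``mode``: ``real_part`` (zero-filled pseudoinverse + Re),
    ``magnitude`` (modulus), or ``corrected_magnitude`` (training-time
    correction; applied to generated objects, not to measured data).
    """

    mode: str = "real_part"

    def __post_init__(self):
        if self.mode not in ("real_part", "magnitude", "corrected_magnitude"):
            raise ValueError(f"unknown reconstruction mode: {self.mode!r}")

    def __call__(self, g: KSpaceData) -> np.ndarray:
        if self.mode == "real_part":
            return pseudoinverse_reconstruct(g)
        # measured data are reconstructed identically in both magnitude modes
        return magnitude_reconstruct(g)

    def apply_stack(self, values: np.ndarray, mask: SamplingMask) -> np.ndarray:
        """Vectorized reconstruction of a stack of centered k-space grids."""
        imgs = _centered_ifft2(values)
        return imgs.real if self.mode == "real_part" else np.abs(imgs)
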