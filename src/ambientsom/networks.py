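"""Small dense multiresolution GAN networks and their optimizer.

The generator and discriminator are deliberately compact fully-connected
re-implementations of two multiresolution training ideas:

* **progressive growing** — the generator owns one block per resolution in
  the doubling chain 4, 8, ..., final; during training only the blocks up to
  the current stage are active and a new stage is faded in by blending its
  output image with the upsampled image of the previous stage;
* **skip summation** — all blocks are always active and the output image is
  the sum of per-resolution images upsampled (bilinearly) to the final
  resolution, with a residual discriminator; this variant trains in a single
  stage.

Both generators optionally inject a fresh standard-normal noise map at each
resolution, scaled by a learned per-resolution gain (initialized at zero).
This gives the generator an explicit channel through which it can represent
pixelwise stochastic texture — e.g. measurement noise present in training
images — which a deterministic smooth mapping of a low-dimensional latent
cannot otherwise reproduce.

Layers use the equalized-learning-rate trick: weights are stored as unit
normals and rescaled by ``gain / sqrt(fan_in)`` at call time, which keeps
Adam's effective step size uniform across layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Dense",
    "Adam",
    "MultiResGenerator",
    "MultiResDiscriminator",
    "upsample2",
    "downsample2",
    "resolution_chain",
]


def resolution_chain(base: int, final: int) -> list[int]:
    """The doubling chain ``base, 2*base, ..., final``."""
    if base < 1 or final < base or (final & (final - 1)) or (base & (base - 1)):
        raise ValueError(f"resolutions must be powers of two with base <= final, got {base}..{final}")
    chain = []
    r = base
    while r <= final:
        chain.append(r)
        r *= 2
    if chain[-1] != final:
        raise ValueError(f"{final} is not a power-of-two multiple of {base}")
    return chain


# -- differentiable resampling ---------------------------------------------

def upsample2(x: Tensor) -> Tensor:
    """Factor-2 bilinear upsampling of (B, H, W) with periodic boundary.

    Implemented as nearest-neighbour duplication followed by a separable
    [1/4, 1/2, 1/4] smoothing; on periodic grids this is the standard
    bilinear interpolation up to the half-pixel phase convention.
    """
    b, h, w = x.shape
    y = ag.reshape(x, (b, h, 1, w, 1))
    y = ag.broadcast_to(y, (b, h, 2, w, 2))
    y = ag.reshape(y, (b, 2 * h, 2 * w))
    for axis in (1, 2):
        y = 0.5 * y + 0.25 * ag.roll(y, 1, axis) + 0.25 * ag.roll(y, -1, axis)
    return y


def downsample2(x: Tensor) -> Tensor:
    """Factor-2 average-pool downsampling of (B, H, W)."""
    b, h, w = x.shape
    y = ag.reshape(x, (b, h // 2, 2, w // 2, 2))
    return ag.tmean(y, axis=(2, 4))


def upsample_to(x: Tensor, final: int) -> Tensor:
    while x.shape[-1] < final:
        x = upsample2(x)
    return x


def downsample_to(x: Tensor, res: int) -> Tensor:
    while x.shape[-1] > res:
        x = downsample2(x)
    return x


# -- layers -----------------------------------------------------------------

class Dense:
    """Fully connected layer with equalized learning rate."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 gain: float = math.sqrt(2.0)):
        self.weight = Tensor(rng.standard_normal((fan_in, fan_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(fan_out), requires_grad=True)
        self.scale = gain / math.sqrt(fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) * self.scale + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Adam:
    """Adam with the (beta1=0, beta2=0.99) defaults common in GAN training."""

    def __init__(self, params: list[Tensor], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.0, 0.99), eps: float = 1e-8,
                 lr_mults: list[float] | None = None):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.lr_mults = lr_mults or [1.0] * len(params)
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[Tensor]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, g, m, v, mult in zip(self.params, grads, self.m, self.v,
                                    self.lr_mults):
            gd = g.data
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - mult * self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- generator ---------------------------------------------------------------

@dataclass
class _GenBlocks:
    trunk: Dense
    blocks: dict[int, Dense] = field(default_factory=dict)
    to_image: dict[int, Dense] = field(default_factory=dict)
    noise_gain: dict[int, Tensor] = field(default_factory=dict)


class MultiResGenerator:
    """Latent -> image generator with per-resolution blocks.

    ``architecture`` is ``"progressive"`` (stage/fade semantics) or
    ``"skip_sum"`` (all resolutions summed into the final image).
    """

    def __init__(self, latent_dim: int, final_resolution: int, width: int = 128,
                 base_resolution: int = 4, architecture: str = "progressive",
                 noise_injection: bool = True, smooth_image_head: int = 1,
                 rng: np.random.Generator | None = None):
        if architecture not in ("progressive", "skip_sum"):
            raise ValueError(f"unknown generator architecture: {architecture}")
        rng = rng or np.random.default_rng(0)
        self.smooth_image_head = int(smooth_image_head)
        self.latent_dim = latent_dim
        self.final_resolution = final_resolution
        self.base_resolution = base_resolution
        self.width = width
        self.architecture = architecture
        self.noise_injection = noise_injection
        self.resolutions = resolution_chain(base_resolution, final_resolution)
        net = _GenBlocks(trunk=Dense(latent_dim, width, rng))
        for r in self.resolutions:
            net.blocks[r] = Dense(width, width, rng)
            net.to_image[r] = Dense(width, r * r, rng, gain=1.0)
            net.noise_gain[r] = Tensor(np.zeros(()), requires_grad=True)
        self.net = net

    # ---- parameters -------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = self.net.trunk.parameters()
        for r in self.resolutions:
            ps += self.net.blocks[r].parameters()
            ps += self.net.to_image[r].parameters()
            if self.noise_injection:
                ps.append(self.net.noise_gain[r])
        return ps

    # ---- forward ----------------------------------------------------------
    def _image_at(self, h: Tensor, r: int, rng: np.random.Generator | None,
                  inject: bool) -> Tensor:
        b = h.shape[0]
        img = ag.reshape(self.net.to_image[r](h), (b, r, r))
        for _ in range(self.smooth_image_head):
            # dense image heads lack the local-smoothness bias of learned
            # convolutions; separable [1,2,1]/4 filter passes (periodic)
            # supply it, leaving pixelwise texture to the noise-injection path
            for axis in (1, 2):
                img = 0.5 * img + 0.25 * ag.roll(img, 1, axis) + 0.25 * ag.roll(img, -1, axis)
        if inject and self.noise_injection and rng is not None:
            eps = Tensor(rng.standard_normal((b, r, r)))
            img = img + self.net.noise_gain[r] * eps
        return img

    def forward(self, z: Tensor, stage: int | None = None, alpha: float = 1.0,
                noise_rng: np.random.Generator | None = None) -> Tensor:
        """Generate images at resolution ``stage`` (default: final).

        ``alpha`` in [0, 1] is the progressive fade-in weight of the newest
        stage; it is ignored by the skip_sum architecture, whose stages are
        always all active.
        """
        stage = stage or self.final_resolution
        if stage not in self.resolutions:
            raise ValueError(f"stage {stage} not in {self.resolutions}")
        h = ag.leaky_relu(self.net.trunk(z))
        # noise is injected only at the rendered (output) resolution: it
        # models pixelwise stochastic texture at the scale the discriminator
        # sees, not extra latent dimensions at coarser scales
        if self.architecture == "skip_sum":
            total = None
            for r in self.resolutions:
                h = ag.leaky_relu(self.net.blocks[r](h))
                img = upsample_to(
                    self._image_at(h, r, noise_rng, inject=(r == self.final_resolution)),
                    self.final_resolution)
                total = img if total is None else total + img
            return downsample_to(total, stage)
        # progressive
        prev_img = None
        for r in self.resolutions:
            h = ag.leaky_relu(self.net.blocks[r](h))
            if r == stage:
                img = self._image_at(h, r, noise_rng, inject=True)
                if alpha < 1.0 and prev_img is not None:
                    img = alpha * img + (1.0 - alpha) * upsample2(prev_img)
                return img
            if 2 * r == stage and alpha < 1.0:
                prev_img = self._image_at(h, r, noise_rng, inject=False)
        raise AssertionError("unreachable")

    def __call__(self, z, **kw):
        return self.forward(z, **kw)


# -- discriminator -----------------------------------------------------------

class MultiResDiscriminator:
    """Image -> score critic mirroring the generator's resolution chain.

    ``architecture`` is ``"progressive"`` (per-stage input heads with fade-in)
    or ``"residual"`` (fixed final-resolution input, residual dense trunk).

    With ``highpass_input`` (default) each input head sees the image
    together with its fine-detail residual ``x - blur(x)``.  A dense critic
    otherwise struggles to register pixel-scale noise statistics; the
    explicit high-pass channel makes fine-scale amplitude mismatches between
    real and generated images directly visible.
    """

    def __init__(self, final_resolution: int, width: int = 128,
                 base_resolution: int = 4, architecture: str = "progressive",
                 highpass_input: bool = True,
                 rng: np.random.Generator | None = None):
        if architecture not in ("progressive", "residual"):
            raise ValueError(f"unknown discriminator architecture: {architecture}")
        rng = rng or np.random.default_rng(0)
        self.final_resolution = final_resolution
        self.base_resolution = base_resolution
        self.width = width
        self.architecture = architecture
        self.highpass_input = highpass_input
        self.resolutions = resolution_chain(base_resolution, final_resolution)
        in_mult = 2 if highpass_input else 1
        self.from_image = {r: Dense(in_mult * r * r, width, rng)
                           for r in self.resolutions}
        self.blocks = {r: Dense(width, width, rng) for r in self.resolutions}
        if architecture == "residual":
            self.blocks2 = {r: Dense(width, width, rng) for r in self.resolutions}
        self.head = Dense(width, 1, rng, gain=1.0)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for r in self.resolutions:
            ps += self.from_image[r].parameters()
            ps += self.blocks[r].parameters()
            if self.architecture == "residual":
                ps += self.blocks2[r].parameters()
        ps += self.head.parameters()
        return ps

    def _head_input(self, x: Tensor) -> Tensor:
        b, r = x.shape[0], x.shape[-1]
        flat = ag.reshape(x, (b, r * r))
        if not self.highpass_input:
            return flat
        smooth = x
        for axis in (1, 2):
            smooth = (0.5 * smooth + 0.25 * ag.roll(smooth, 1, axis)
                      + 0.25 * ag.roll(smooth, -1, axis))
        detail = ag.reshape(x - smooth, (b, r * r))
        return ag.concatenate([flat, detail], axis=1)

    def forward(self, x: Tensor, stage: int | None = None, alpha: float = 1.0) -> Tensor:
        stage = stage or self.final_resolution
        b = x.shape[0]
        if x.shape[-1] != stage:
            raise ValueError(f"discriminator stage {stage} but input resolution {x.shape[-1]}")
        if self.architecture == "residual":
            if stage != self.final_resolution:
                raise ValueError("residual discriminator operates at the final resolution")
            h = ag.leaky_relu(self.from_image[self.final_resolution](
                self._head_input(x)))
            for r in reversed(self.resolutions):
                delta = self.blocks2[r](ag.leaky_relu(self.blocks[r](h)))
                h = (h + delta) * (1.0 / math.sqrt(2.0))
            return self.head(ag.leaky_relu(h))
        # progressive
        h = ag.leaky_relu(self.from_image[stage](self._head_input(x)))
        if alpha < 1.0 and stage > self.base_resolution:
            prev = stage // 2
            hprev = ag.leaky_relu(self.from_image[prev](
                self._head_input(downsample2(x))))
            h = alpha * h + (1.0 - alpha) * hprev
        r = stage
        while r >= self.base_resolution:
            h = ag.leaky_relu(self.blocks[r](h))
            r //= 2
        return self.head(h)

    def __call__(self, x, **kw):
        return self.forward(x, **kw)
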