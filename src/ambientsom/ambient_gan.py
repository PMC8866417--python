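"""Adversarial learning of stochastic object models from measurements.

A stochastic object model (SOM) is a generator ``G(z)`` mapping latent
vectors to objects.  Training it directly on reconstructed images bakes
measurement noise and reconstruction artifacts into the model.  The ambient
strategy instead inserts the measurement operator ``H_n`` *and* a
reconstruction operator ``O`` between the generator and the discriminator:

    fake branch:  z -> G -> f_hat -> H_n (fresh noise) -> O -> f_hat_r
    real branch:  stored measurements g -> O -> f_r

so the discriminator compares distributions in reconstructed-image space
while the generator, sitting upstream of the noise, is pushed toward clean
objects.  Because both branches live in the same (image) Hilbert space, the
multiresolution training schedules of modern GANs apply: at a progressive
stage below the final resolution, generated objects are upsampled to full
resolution, measured, reconstructed, and the reconstruction is downsampled
back to the stage resolution before the discriminator.

A plain (non-ambient) GAN is the identical loop with the identity channel:
it trains directly on the reconstructed images and serves as the baseline
that *does* learn the noise.

Gradients flow through ``O o H_n`` into the generator; the measurement noise
realization is freshly drawn per generated sample per step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .imaging_operators import (
    ForwardModel,
    KSpaceData,
    Reconstructor,
)
from .networks import (
    Adam,
    MultiResDiscriminator,
    MultiResGenerator,
    downsample_to,
    resolution_chain,
    upsample_to,
)
from .object_simulator import ObjectEnsemble

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainingConfig",
    "GeneratorModel",
    "StagePlan",
    "IdentityChannel",
    "FourierChannel",
    "progressive_schedule",
    "train_ambientgan",
    "train_plain_gan",
    "sample_objects",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, stage: int, step: int, message: str):
        super().__init__(f"training diverged at stage {stage}, step {step}: {message}")
        self.stage, self.step = stage, step


# -- specs -------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the object generator.

    The latent prior is standard normal.  512 latent dimensions is the
    usual full-scale choice of multiresolution GAN frameworks; 64 is the
    desk default used throughout the synthetic studies.
    """

    latent_dim: int = 64
    final_resolution: int = 32
    base_resolution: int = 4
    width: int = 128
    architecture: str = "progressive"  # or "skip_sum"
    noise_injection: bool = True
    smooth_image_head: int = 2

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        resolution_chain(self.base_resolution, self.final_resolution)


@dataclass(frozen=True)
class DiscriminatorSpec:
    width: int = 128
    architecture: str = "progressive"  # or "residual"
    highpass_input: bool = True


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization recipe.

    ``images_per_stage`` is the images-seen budget of each progressive stage
    (a single stage for the skip_sum architecture); ``fade_fraction`` of each
    non-initial stage's budget is spent fading the new resolution in.
    Separate named seed streams (init / latents / measurement noise / data
    order / penalty interpolants) are derived from ``seed``.
    """

    loss: str = "logistic_r1"  # or "wgan_gp"
    lr: float = 2e-3
    betas: tuple[float, float] = (0.0, 0.99)
    batch_size: int = 16
    images_per_stage: int = 12_000
    fade_fraction: float = 0.5
    seed: int = 0
    gp_weight: float = 10.0
    r1_gamma: float = 1.0
    drift_weight: float = 1e-3
    noise_gain_decay: float = 1e-2
    noise_gain_lr_mult: float = 1.0
    log_every: int = 50

    def __post_init__(self):
        if self.loss not in ("wgan_gp", "logistic_r1"):
            raise ValueError(f"unknown loss: {self.loss!r}")
        if self.images_per_stage <= 0 or self.batch_size < 1:
            raise ValueError("budgets must be positive")
        if not 0.0 <= self.fade_fraction <= 1.0:
            raise ValueError("fade_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class StagePlan:
    resolution: int
    images: int
    fade_fraction: float


def progressive_schedule(gspec: GeneratorSpec, config: TrainingConfig) -> list[StagePlan]:
    """Stage plan: 4, 8, ..., final for progressive growing; one final-
    resolution stage for the skip_sum architecture."""
    chain = resolution_chain(gspec.base_resolution, gspec.final_resolution)
    if gspec.architecture == "skip_sum":
        return [StagePlan(gspec.final_resolution, config.images_per_stage, 0.0)]
    plans = []
    for i, r in enumerate(chain):
        fade = 0.0 if i == 0 else config.fade_fraction
        plans.append(StagePlan(r, config.images_per_stage, fade))
    return plans


# -- measurement channels ----------------------------------------------------

class IdentityChannel:
    """The trivial operator bundle: measurements are the images themselves."""

    mode = "identity"

    def reconstruct_fake(self, f_hat: Tensor, rng: np.random.Generator) -> Tensor:
        return f_hat

    def reconstruct_real(self, images: np.ndarray) -> np.ndarray:
        return np.asarray(images, dtype=float)


class FourierChannel:
    """Differentiable ``O o H_n``: masked 2-D DFT + fresh complex Gaussian
    noise, followed by the reconstruction operator."""

    def __init__(self, forward_model: ForwardModel, reconstructor: Reconstructor):
        self.forward_model = forward_model
        self.reconstructor = reconstructor
        self.mode = reconstructor.mode
        n = forward_model.grid_size
        self.grid_size = n
        # numpy (unshifted) FFT layout
        self._mask = np.fft.ifftshift(forward_model.mask.as_bool_grid(), axes=0)
        if self.mode == "corrected_magnitude" and forward_model.mask.acceleration != 1.0:
            raise ValueError(
                "the corrected-magnitude channel requires full sampling"
            )

    def _noise(self, batch: int, rng: np.random.Generator) -> np.ndarray:
        std = self.forward_model.noise.kspace_std
        if std == 0.0:
            return np.zeros((batch, self.grid_size, self.grid_size), dtype=complex)
        draws = rng.normal(scale=std, size=(2, batch, self.grid_size, self.grid_size))
        return np.where(self._mask, draws[0] + 1j * draws[1], 0.0)

    def reconstruct_fake(self, f_hat: Tensor, rng: np.random.Generator) -> Tensor:
        batch = f_hat.shape[0]
        noise = self._noise(batch, rng)
        if self.mode == "real_part":
            spectrum = ag.mul(ag.fft2(f_hat), Tensor(self._mask.astype(float)))
            clean = ag.real(ag.ifft2(spectrum))
            return clean + Tensor(np.fft.ifft2(noise).real)
        if self.mode == "corrected_magnitude":
            clipped = ag.relu(f_hat)
            complex_img = ag.add(ag.ifft2(ag.fft2(clipped)), Tensor(np.fft.ifft2(noise)))
            return f_hat + ag.cabs(complex_img) - clipped
        # plain magnitude of the noisy zero-filled reconstruction
        spectrum = ag.add(ag.mul(ag.fft2(f_hat), Tensor(self._mask.astype(float))),
                          Tensor(noise))
        return ag.cabs(ag.ifft2(spectrum))

    def reconstruct_real(self, kspace_stack: np.ndarray) -> np.ndarray:
        return self.reconstructor.apply_stack(np.asarray(kspace_stack, dtype=complex),
                                              self.forward_model.mask)


def _as_channel(operators) -> IdentityChannel | FourierChannel:
    if operators is None or isinstance(operators, (IdentityChannel, FourierChannel)):
        return operators or IdentityChannel()
    forward_model, reconstructor = operators
    return FourierChannel(forward_model, reconstructor)


# -- trained model -----------------------------------------------------------

@dataclass
class GeneratorModel:
    """A trained SOM: the generator, its spec, and the training manifest."""

    generator: MultiResGenerator
    spec: GeneratorSpec
    manifest: dict = field(default_factory=dict)

    def sample(self, n: int, seed: int, batch: int = 256) -> ObjectEnsemble:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        out = []
        with ag.no_grad():
            for start in range(0, n, batch):
                b = min(batch, n - start)
                z = Tensor(rng.standard_normal((b, self.spec.latent_dim)))
                imgs = self.generator.forward(z, stage=self.spec.final_resolution,
                                              alpha=1.0, noise_rng=rng)
                out.append(imgs.data.copy())
        images = np.concatenate(out, axis=0)
        return ObjectEnsemble(images=images, manifest={
            "generator": "ambientsom",
            "sample_seed": int(seed),
            "n": int(n),
            "spec": asdict(self.spec),
            "training_seed": self.manifest.get("config", {}).get("seed"),
        })

    # ---- persistence ------------------------------------------------------
    def save(self, path) -> None:
        params = {f"param_{i:04d}": p.data for i, p in
                  enumerate(self.generator.parameters())}
        np.savez(path, spec=json.dumps(asdict(self.spec)),
                 manifest=json.dumps(self.manifest), **params)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        with np.load(path, allow_pickle=False) as data:
            spec = GeneratorSpec(**json.loads(str(data["spec"])))
            manifest = json.loads(str(data["manifest"]))
            gen = _build_generator(spec, np.random.default_rng(0))
            keys = sorted(k for k in data.files if k.startswith("param_"))
            params = gen.parameters()
            if len(keys) != len(params):
                raise ValueError("checkpoint does not match generator spec")
            for key, p in zip(keys, params):
                p.data = np.asarray(data[key])
        return cls(generator=gen, spec=spec, manifest=manifest)


def sample_objects(model: GeneratorModel, n: int, seed: int) -> ObjectEnsemble:
    """Draw ``n`` objects from a trained (or freshly initialized) SOM."""
    return model.sample(n, seed)


# -- training ----------------------------------------------------------------

def _build_generator(gspec: GeneratorSpec, rng: np.random.Generator) -> MultiResGenerator:
    return MultiResGenerator(
        latent_dim=gspec.latent_dim, final_resolution=gspec.final_resolution,
        width=gspec.width, base_resolution=gspec.base_resolution,
        architecture=gspec.architecture, noise_injection=gspec.noise_injection,
        smooth_image_head=gspec.smooth_image_head, rng=rng)


def _build_discriminator(gspec: GeneratorSpec, dspec: DiscriminatorSpec,
                         rng: np.random.Generator) -> MultiResDiscriminator:
    return MultiResDiscriminator(
        final_resolution=gspec.final_resolution, width=dspec.width,
        base_resolution=gspec.base_resolution, architecture=dspec.architecture,
        highpass_input=dspec.highpass_input, rng=rng)


def _real_pyramid(images: np.ndarray, resolutions: list[int]) -> dict[int, np.ndarray]:
    out = {}
    final = images.shape[-1]
    cur = images
    for r in sorted(resolutions, reverse=True):
        while cur.shape[-1] > r:
            n, h, w = cur.shape
            cur = cur.reshape(n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
        out[r] = cur
    return out


def train_ambientgan(real_measurements, operators, gspec: GeneratorSpec,
                     dspec: DiscriminatorSpec, config: TrainingConfig,
                     fid_reference: np.ndarray | None = None) -> GeneratorModel:
    """Train an ambient GAN on measured data through an operator bundle.

    ``real_measurements``: a sequence of :class:`KSpaceData` (or a complex
    stack) sharing the operator's mask; ``operators``: a
    ``(ForwardModel, Reconstructor)`` pair, a channel object, or ``None``
    for the identity channel (in which case the measurements are images).
    """
    channel = _as_channel(operators)
    if isinstance(channel, IdentityChannel):
        stack = np.asarray(
            real_measurements.images if isinstance(real_measurements, ObjectEnsemble)
            else real_measurements, dtype=float)
        reals = channel.reconstruct_real(stack)
    else:
        if len(real_measurements) and isinstance(real_measurements[0], KSpaceData):
            for m in real_measurements:
                if m.mask.kept_lines != channel.forward_model.mask.kept_lines:
                    raise ValueError("measurement mask does not match operator mask")
            stack = np.stack([m.values for m in real_measurements])
        else:  # already a centered complex stack
            stack = np.asarray(real_measurements, dtype=complex)
        reals = channel.reconstruct_real(stack)
    if reals.shape[-1] != gspec.final_resolution:
        raise ValueError(
            f"data resolution {reals.shape[-1]} != generator final resolution "
            f"{gspec.final_resolution}")
    return _adversarial_train(reals, channel, gspec, dspec, config, fid_reference)


def train_plain_gan(recon_images, gspec: GeneratorSpec, dspec: DiscriminatorSpec,
                    config: TrainingConfig,
                    fid_reference: np.ndarray | None = None) -> GeneratorModel:
    """Baseline GAN trained directly on reconstructed images.

    This is literally the ambient loop with the identity channel, so the two
    trainers agree step-for-step when the ambient operator bundle is the
    identity.
    """
    return train_ambientgan(recon_images, None, gspec, dspec, config, fid_reference)


def _adversarial_train(reals: np.ndarray, channel, gspec: GeneratorSpec,
                       dspec: DiscriminatorSpec, config: TrainingConfig,
                       fid_reference: np.ndarray | None = None) -> GeneratorModel:
    ss = np.random.SeedSequence(config.seed)
    s_init, s_lat, s_noise, s_data, s_pen = ss.spawn(5)
    rng_init = np.random.default_rng(s_init)
    rng_lat = np.random.default_rng(s_lat)
    rng_noise = np.random.default_rng(s_noise)
    rng_data = np.random.default_rng(s_data)
    rng_pen = np.random.default_rng(s_pen)

    gen = _build_generator(gspec, rng_init)
    disc = _build_discriminator(gspec, dspec, rng_init)
    g_params, d_params = gen.parameters(), disc.parameters()
    gain_ids = {id(t) for t in gen.net.noise_gain.values()}
    # scalar noise gains get a reduced step size: Adam's sign-like updates
    # would otherwise random-walk them with amplitude lr * sqrt(steps),
    # swamping the (weak) amplitude-matching gradient signal
    g_mults = [config.noise_gain_lr_mult if id(t) in gain_ids else 1.0
               for t in g_params]
    opt_g = Adam(g_params, lr=config.lr, betas=config.betas, lr_mults=g_mults)
    opt_d = Adam(d_params, lr=config.lr, betas=config.betas)

    schedule = progressive_schedule(gspec, config)
    pyramid = _real_pyramid(reals, [p.resolution for p in schedule])
    n_real = reals.shape[0]
    batch = config.batch_size
    final = gspec.final_resolution

    log: list[dict] = []
    stage_history = []
    for plan in schedule:
        res = plan.resolution
        steps = max(1, math.ceil(plan.images / batch))
        fade_steps = int(round(plan.fade_fraction * steps))
        stage_reals = pyramid[res]
        for step in range(steps):
            alpha = 1.0 if fade_steps == 0 else min(1.0, (step + 1) / fade_steps)

            def fake_batch() -> Tensor:
                z = Tensor(rng_lat.standard_normal((batch, gspec.latent_dim)))
                f_hat = gen.forward(z, stage=res, alpha=alpha, noise_rng=rng_noise)
                f_full = upsample_to(f_hat, final)
                f_rec = channel.reconstruct_fake(f_full, rng_noise)
                return downsample_to(f_rec, res)

            idx = rng_data.integers(0, n_real, size=batch)
            real_t = Tensor(stage_reals[idx])

            # ---- discriminator step
            fake_det = fake_batch().detach()
            d_loss, d_real_mean, d_fake_mean = _disc_loss(
                disc, real_t, fake_det, res, alpha, config, rng_pen)
            if not np.isfinite(d_loss.data):
                raise TrainingDivergedError(res, step, "non-finite discriminator loss")
            opt_d.step(ag.grad(d_loss, d_params))

            # ---- generator step (fresh latents and fresh measurement noise)
            fake_g = fake_batch()
            scores = disc.forward(fake_g, stage=res, alpha=alpha)
            if config.loss == "wgan_gp":
                g_loss = -scores.mean()
            else:
                g_loss = ag.softplus(-scores).mean()
            if not np.isfinite(g_loss.data):
                raise TrainingDivergedError(res, step, "non-finite generator loss")
            opt_g.step(ag.grad(g_loss, g_params))
            if gspec.noise_injection and config.noise_gain_decay > 0:
                # noise-gain amplitudes enter the sample variance in
                # quadrature, so their loss gradient vanishes at zero and the
                # gains would otherwise random-walk; a weak multiplicative
                # decay prefers the deterministic explanation unless the data
                # actively demand stochastic texture
                for gain in gen.net.noise_gain.values():
                    gain.data = gain.data * (1.0 - config.noise_gain_decay)

            if step % config.log_every == 0 or step == steps - 1:
                log.append({
                    "stage": res, "step": step, "alpha": round(alpha, 4),
                    "d_loss": float(d_loss.data), "g_loss": float(g_loss.data),
                    "d_real": d_real_mean, "d_fake": d_fake_mean,
                })
        stage_history.append({"resolution": res, "steps": steps,
                              "images": steps * batch, "fade_steps": fade_steps})

    manifest = {
        "config": asdict(config),
        "generator_spec": asdict(gspec),
        "discriminator_spec": asdict(dspec),
        "channel": getattr(channel, "mode", "identity"),
        "n_real": int(n_real),
        "stages": stage_history,
        "log": log,
        "seed_streams": ["init", "latent", "measurement_noise", "data_order",
                         "penalty"],
    }
    model = GeneratorModel(generator=gen, spec=gspec, manifest=manifest)
    if fid_reference is not None:
        from .iq_evaluation import compute_fid

        fake = model.sample(min(512, len(fid_reference)), seed=config.seed + 1)
        manifest["final_fid"] = compute_fid(fid_reference[:512], fake.images)
    return model


def _disc_loss(disc, real_t: Tensor, fake_t: Tensor, res: int, alpha: float,
               config: TrainingConfig, rng_pen: np.random.Generator):
    d_real = disc.forward(real_t, stage=res, alpha=alpha)
    d_fake = disc.forward(fake_t, stage=res, alpha=alpha)
    if config.loss == "wgan_gp":
        base = d_fake.mean() - d_real.mean() + config.drift_weight * (d_real**2.0).mean()
        eps = rng_pen.uniform(size=(real_t.shape[0], 1, 1))
        interp = Tensor(eps * real_t.data + (1 - eps) * fake_t.data, requires_grad=True)
        scores = disc.forward(interp, stage=res, alpha=alpha)
        (gin,) = ag.grad(scores.sum(), [interp], create_graph=True)
        norms = ag.sqrt((gin**2.0).sum(axis=(1, 2)) + 1e-12)
        penalty = ((norms - 1.0)**2.0).mean()
        loss = base + config.gp_weight * penalty
    else:
        base = ag.softplus(d_fake).mean() + ag.softplus(-d_real).mean()
        real_rg = Tensor(real_t.data, requires_grad=True)
        scores = disc.forward(real_rg, stage=res, alpha=alpha)
        (gin,) = ag.grad(scores.sum(), [real_rg], create_graph=True)
        r1 = (gin**2.0).sum(axis=(1, 2)).mean()
        loss = base + 0.5 * config.r1_gamma * r1
    return loss, float(d_real.data.mean()), float(d_fake.data.mean())
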