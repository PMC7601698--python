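"""Adversarial training: the :class:`CapGAN` model object and its results.

Usage follows the model/results convention of statistical modelling
packages::

    model = CapGAN(images)                 # images: (n, H, W[, 1]), any range
    res = model.fit(steps=2000, seed=0)    # alternating least-squares updates
    res.summary()                          # text report
    samples = res.sample(16, seed=1)       # uint8 images in [0, 255]
    res.save("run_dir/checkpoint")         # portable npz + JSON sidecar

Training alternates one discriminator update (minimise
½E[(D(x)−1)²] + ½E[D(G(z))²]) with one generator update (minimise
½E[(D(G(z))−1)²]) under Adam.  A master seed fans out to parameter
initialisation, latent sampling and data shuffling through named
substreams, so runs are exactly reproducible and checkpoints resume
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._tensor import Tensor, no_grad, default_dtype
from ._layers import Adam
from .networks import (
    Generator, GeneratorConfig, CapsuleDiscriminator, DiscriminatorConfig,
    ConvDiscriminator, to_pixels, from_pixels, sample_latent,
)
from . import objectives

__all__ = ["TrainConfig", "CapGAN", "CapGANResults", "train", "warm_start", "generate_samples"]


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5              # Adam momentum (DCGAN convention)
    beta2: float = 0.999
    batch_size: int = 64
    steps: int = 50_000             # generator-update steps; desk-scale runs use far fewer
    d_steps_per_g_step: int = 1
    seed: int = 0
    loss_mode: str = "least_squares"     # or 'cross_entropy'
    discriminator: str = "capsule"       # or 'conv'
    log_every: int = 10
    dtype: str = "float32"               # training precision

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.steps, self.d_steps_per_g_step) <= 0:
            raise ValueError("learning_rate, batch_size, steps, d_steps_per_g_step must be positive")
        if self.loss_mode not in ("least_squares", "cross_entropy"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.discriminator not in ("capsule", "conv"):
            raise ValueError(f"unknown discriminator {self.discriminator!r}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"unknown dtype {self.dtype!r}")


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def _as_model_range(images: np.ndarray, pixel_range: str) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[-1] != 1:
        raise ValueError(f"expected (n, H, W[, 1]) grayscale images, got {images.shape}")
    if pixel_range == "auto":
        pixel_range = "file" if (images.dtype == np.uint8 or x.max() > 1.0 + 1e-9) else "model"
    if pixel_range == "file":
        return from_pixels(x)
    if pixel_range == "model":
        if x.min() < -1 - 1e-9 or x.max() > 1 + 1e-9:
            raise ValueError("model-range images must lie in [-1, 1]")
        return x
    raise ValueError(f"unknown pixel_range {pixel_range!r}")


class CapGAN:
    """Least-squares GAN with a capsule-network discriminator, as a model
    object bound to a training image set."""

    def __init__(self, images, gen_config: GeneratorConfig | None = None,
                 disc_config: DiscriminatorConfig | None = None,
                 train_config: TrainConfig | None = None,
                 pixel_range: str = "auto"):
        self.images = _as_model_range(images, pixel_range)
        if self.images.shape[0] == 0:
            raise ValueError("training set is empty")
        size = self.images.shape[1]
        if self.images.shape[2] != size:
            raise ValueError("images must be square")
        self.gen_config = gen_config or GeneratorConfig(image_size=size)
        self.disc_config = disc_config or DiscriminatorConfig(image_size=size)
        self.train_config = train_config or TrainConfig()
        for cfg in (self.gen_config, self.disc_config):
            if cfg.image_size != size:
                raise ValueError(
                    f"config image_size {cfg.image_size} does not match data size {size}"
                )

    # -- construction helpers ----------------------------------------------
    def _build(self, seed: int):
        ss = np.random.SeedSequence(seed)
        s_g, s_d, s_lat, s_shuf = ss.spawn(4)
        G = Generator(replace(self.gen_config, seed=_seed_int(s_g)))
        if self.train_config.discriminator == "capsule":
            D = CapsuleDiscriminator(replace(self.disc_config, seed=_seed_int(s_d)))
        else:
            head = "sigmoid" if self.train_config.loss_mode == "cross_entropy" else "linear"
            D = ConvDiscriminator(image_size=self.gen_config.image_size,
                                  head=head, seed=_seed_int(s_d))
        latent_rng = np.random.default_rng(s_lat)
        shuffle_rng = np.random.default_rng(s_shuf)
        return G, D, latent_rng, shuffle_rng

    def _losses(self, D, x_real, fake, train_d: bool):
        mode = self.train_config.loss_mode
        if train_d:
            d_real = D.forward(x_real, training=True)
            d_fake = D.forward(fake, training=True)
            if mode == "least_squares":
                return objectives.ls_discriminator_loss(d_real, d_fake)
            p_real, p_fake = self._as_prob(D, d_real), self._as_prob(D, d_fake)
            return -objectives.gan_value(p_real, p_fake)
        d_fake = D.forward(fake, training=True)
        if mode == "least_squares":
            return objectives.ls_generator_loss(d_fake)
        # minimax-form generator objective: minimise E[log(1 - D(G(z)))]
        from . import _tensor as T
        p_fake = self._as_prob(D, d_fake)
        return T.tmean(T.log(T.clip(1.0 - p_fake, 1e-7, 1.0)))

    @staticmethod
    def _as_prob(D, score):
        from . import _tensor as T
        if isinstance(D, ConvDiscriminator) and D.head == "sigmoid":
            return score
        if isinstance(D, CapsuleDiscriminator):
            # capsule length plays the probability role (classic convention)
            return T.clip(score, 1e-7, 1.0 - 1e-7)
        return T.sigmoid(score)

    # -- fitting -------------------------------------------------------------
    def fit(self, steps: int | None = None, seed: int | None = None,
            warm_start_from: str | Path | None = None,
            resume_from: str | Path | None = None,
            checkpoint_dir: str | Path | None = None,
            checkpoint_every: int | None = None,
            verbose: bool = False) -> "CapGANResults":
        """Train for ``steps`` generator updates and return the results.

        ``warm_start_from`` initialises network parameters from a
        checkpoint (optimiser state reset: the transfer-learning path).
        ``resume_from`` restores parameters, optimiser and RNG state and
        continues the same run up to ``steps`` total updates.
        """
        with default_dtype(np.dtype(self.train_config.dtype)):
            return self._fit(steps, seed, warm_start_from, resume_from,
                             checkpoint_dir, checkpoint_every, verbose)

    def _fit(self, steps, seed, warm_start_from, resume_from,
             checkpoint_dir, checkpoint_every, verbose) -> "CapGANResults":
        cfg = self.train_config
        steps = int(steps if steps is not None else cfg.steps)
        seed = int(cfg.seed if seed is None else seed)
        n = self.images.shape[0]
        batch = min(cfg.batch_size, n)

        step0 = 0
        trace_d: list[float] = []
        trace_g: list[float] = []
        if resume_from is not None:
            G, D, latent_rng, shuffle_rng = self._build(seed)
            adam_g = Adam(G.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
            adam_d = Adam(D.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
            state = _load_checkpoint(resume_from, G, D, adam_g, adam_d)
            latent_rng.bit_generator.state = state["latent_rng_state"]
            shuffle_rng.bit_generator.state = state["shuffle_rng_state"]
            step0 = state["step"]
            trace_d = list(state.get("trace_d", []))
            trace_g = list(state.get("trace_g", []))
            seed = state.get("seed", seed)
        else:
            G, D, latent_rng, shuffle_rng = self._build(seed)
            if warm_start_from is not None:
                warm_start(G, warm_start_from, "G")
                warm_start(D, warm_start_from, "D")
            adam_g = Adam(G.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
            adam_d = Adam(D.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)

        latent_dim = self.gen_config.latent_dim
        prior = self.gen_config.prior
        for step in range(step0, steps):
            for _ in range(cfg.d_steps_per_g_step):
                idx = shuffle_rng.choice(n, size=batch, replace=batch > n)
                x = Tensor(self.images[idx])
                z = sample_latent(latent_rng, batch, latent_dim, prior)
                with no_grad():
                    fake = G.forward(Tensor(z), training=True).data
                loss_d = self._losses(D, x, Tensor(fake), train_d=True)
                adam_d.zero_grad()
                loss_d.backward()
                adam_d.step()
            z = sample_latent(latent_rng, batch, latent_dim, prior)
            fake = G.forward(Tensor(z), training=True)
            loss_g = self._losses(D, None, fake, train_d=False)
            adam_g.zero_grad()
            loss_g.backward()
            adam_g.step()

            ld, lg = float(loss_d.data), float(loss_g.data)
            trace_d.append(ld)
            trace_g.append(lg)
            if not (np.isfinite(ld) and np.isfinite(lg)):
                snapshot = {"step": step + 1, "loss_d": ld, "loss_g": lg,
                            "recent_d": trace_d[-20:], "recent_g": trace_g[-20:]}
                if checkpoint_dir is not None:
                    Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
                    (Path(checkpoint_dir) / "nan_abort.json").write_text(json.dumps(snapshot))
                raise RuntimeError(f"non-finite loss at step {step + 1}: {snapshot}")
            if verbose and (step + 1) % cfg.log_every == 0:
                print(f"step {step + 1:>6d}  V_D={ld:.4f}  V_G={lg:.4f}")
            if checkpoint_dir is not None and checkpoint_every and (step + 1) % checkpoint_every == 0:
                self._checkpoint(checkpoint_dir, G, D, adam_g, adam_d,
                                 latent_rng, shuffle_rng, step + 1, seed, trace_d, trace_g)

        results = CapGANResults(
            generator=G, discriminator=D, seed=seed, steps=steps,
            gen_config=self.gen_config, disc_config=self.disc_config, train_config=cfg,
            history=pd.DataFrame({"step": np.arange(1, len(trace_d) + 1),
                                  "loss_d": trace_d, "loss_g": trace_g}),
            _runtime=(adam_g, adam_d, latent_rng, shuffle_rng),
        )
        if checkpoint_dir is not None:
            results.save(Path(checkpoint_dir) / "final")
        return results

    def _checkpoint(self, out_dir, G, D, adam_g, adam_d, latent_rng, shuffle_rng,
                    step, seed, trace_d, trace_g):
        _save_checkpoint(Path(out_dir) / f"step_{step:06d}", G, D, adam_g, adam_d,
                         latent_rng, shuffle_rng, step, seed, trace_d, trace_g,
                         self.gen_config, self.disc_config, self.train_config)


@dataclass
class CapGANResults:
    """Fitted generator/discriminator pair plus training diagnostics."""

    generator: Generator
    discriminator: object
    seed: int
    steps: int
    gen_config: GeneratorConfig
    disc_config: DiscriminatorConfig
    train_config: TrainConfig
    history: pd.DataFrame
    _runtime: tuple | None = None

    def sample(self, n: int, seed: int = 0, file_range: bool = True) -> np.ndarray:
        """Generate ``n`` images deterministically from ``seed``.

        Returns uint8 images in [0, 255] (or model-range floats with
        ``file_range=False``).
        """
        rng = np.random.default_rng(seed)
        z = sample_latent(rng, n, self.gen_config.latent_dim, self.gen_config.prior)
        imgs = self.generator.forward(z, training=False)
        return to_pixels(imgs) if file_range else imgs

    def summary(self) -> str:
        h = self.history
        tail = h.tail(min(50, len(h)))
        n_g = sum(p.data.size for p in self.generator.parameters())
        n_d = sum(p.data.size for p in self.discriminator.parameters())
        lines = [
            "CapGAN results",
            "=" * 46,
            f"discriminator:        {self.train_config.discriminator}",
            f"loss mode:            {self.train_config.loss_mode}",
            f"image size:           {self.gen_config.image_size}",
            f"latent prior/dim:     {self.gen_config.prior}/{self.gen_config.latent_dim}",
            f"steps trained:        {self.steps}",
            f"seed:                 {self.seed}",
            f"generator params:     {n_g}",
            f"discriminator params: {n_d}",
            f"final V_D (mean@50):  {tail['loss_d'].mean():.4f}",
            f"final V_G (mean@50):  {tail['loss_g'].mean():.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        if self._runtime is None:
            raise ValueError("results were loaded without runtime state; cannot checkpoint")
        adam_g, adam_d, latent_rng, shuffle_rng = self._runtime
        return _save_checkpoint(path, self.generator, self.discriminator, adam_g, adam_d,
                                latent_rng, shuffle_rng, self.steps, self.seed,
                                list(self.history["loss_d"]), list(self.history["loss_g"]),
                                self.gen_config, self.disc_config, self.train_config)

    @classmethod
    def load(cls, path: str | Path) -> "CapGANResults":
        meta = json.loads((Path(path) / "state.json").read_text())
        gen_config = GeneratorConfig(**meta["gen_config"])
        disc_config = DiscriminatorConfig(**meta["disc_config"])
        train_config = TrainConfig(**meta["train_config"])
        G = Generator(gen_config)
        if train_config.discriminator == "capsule":
            D = CapsuleDiscriminator(disc_config)
        else:
            head = "sigmoid" if train_config.loss_mode == "cross_entropy" else "linear"
            D = ConvDiscriminator(image_size=gen_config.image_size, head=head)
        adam_g = Adam(G.parameters(), train_config.learning_rate, train_config.beta1, train_config.beta2)
        adam_d = Adam(D.parameters(), train_config.learning_rate, train_config.beta1, train_config.beta2)
        state = _load_checkpoint(path, G, D, adam_g, adam_d)
        history = pd.DataFrame({
            "step": np.arange(1, len(state.get("trace_d", [])) + 1),
            "loss_d": state.get("trace_d", []), "loss_g": state.get("trace_g", []),
        })
        latent_rng = np.random.default_rng(0)
        shuffle_rng = np.random.default_rng(0)
        latent_rng.bit_generator.state = state["latent_rng_state"]
        shuffle_rng.bit_generator.state = state["shuffle_rng_state"]
        return cls(generator=G, discriminator=D, seed=state["seed"], steps=state["step"],
                   gen_config=gen_config, disc_config=disc_config, train_config=train_config,
                   history=history, _runtime=(adam_g, adam_d, latent_rng, shuffle_rng))


# ---------------------------------------------------------------------------
# checkpoint plumbing
# ---------------------------------------------------------------------------

def _save_checkpoint(path, G, D, adam_g, adam_d, latent_rng, shuffle_rng,
                     step, seed, trace_d, trace_g, gen_config, disc_config, train_config) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, net in (("G", G), ("D", D)):
        for name, val in net.state_dict().items():
            arrays[f"{prefix}.{name}"] = val
    for prefix, adam in (("adamG", adam_g), ("adamD", adam_d)):
        sd = adam.state_dict()
        for i, m in enumerate(sd["m"]):
            arrays[f"{prefix}.m.{i}"] = m
        for i, v in enumerate(sd["v"]):
            arrays[f"{prefix}.v.{i}"] = v
    np.savez(path / "params.npz", **arrays)
    meta = {
        "step": int(step), "seed": int(seed),
        "adamG_t": adam_g.t, "adamD_t": adam_d.t,
        "gen_config": asdict(gen_config), "disc_config": asdict(disc_config),
        "train_config": asdict(train_config),
        "latent_rng_state": latent_rng.bit_generator.state,
        "shuffle_rng_state": shuffle_rng.bit_generator.state,
        "trace_d": [float(v) for v in trace_d], "trace_g": [float(v) for v in trace_g],
    }
    (path / "state.json").write_text(json.dumps(meta))
    return path


def _load_checkpoint(path, G, D, adam_g, adam_d) -> dict:
    path = Path(path)
    with np.load(path / "params.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    G.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("G.")})
    D.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("D.")})
    meta = json.loads((path / "state.json").read_text())
    for prefix, adam, t in (("adamG", adam_g, meta["adamG_t"]), ("adamD", adam_d, meta["adamD_t"])):
        ms = [arrays[f"{prefix}.m.{i}"] for i in range(len(adam.params))]
        vs = [arrays[f"{prefix}.v.{i}"] for i in range(len(adam.params))]
        adam.load_state_dict({"t": t, "m": ms, "v": vs})
    return meta


def warm_start(network, checkpoint: str | Path, prefix: str) -> None:
    """Load network parameters exactly from a checkpoint (optimiser state is
    the caller's to reset); raises naming the offending layer on mismatch."""
    with np.load(Path(checkpoint) / "params.npz") as npz:
        state = {k[len(prefix) + 1:]: npz[k] for k in npz.files if k.startswith(prefix + ".")}
    if not state:
        raise ValueError(f"checkpoint has no parameters under prefix {prefix!r}")
    network.load_state_dict(state)


def train(dataset, gen_config=None, disc_config=None, train_config=None, **fit_kwargs):
    """Functional wrapper: build a :class:`CapGAN` on ``dataset`` and fit it."""
    return CapGAN(dataset, gen_config, disc_config, train_config).fit(**fit_kwargs)


def generate_samples(checkpoint: str | Path, n: int, seed: int = 0,
                     out_dir: str | Path | None = None) -> np.ndarray:
    """Sample ``n`` uint8 images from a checkpointed generator; optionally
    write them as 8-bit grayscale PNGs."""
    results = CapGANResults.load(checkpoint)
    imgs = results.sample(n, seed=seed)
    if out_dir is not None:
        from PIL import Image
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(imgs):
            Image.fromarray(img[..., 0] if img.ndim == 3 else img, mode="L").save(
                out / f"sample_{i:05d}.png")
    return imgs
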