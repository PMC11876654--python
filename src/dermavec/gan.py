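"""Compact style-based GAN with an analytic oracle-decoder mode.

The generator follows the two-network style architecture: a *mapping*
network carries the sampled latent z into an intermediate style space w, and
a *synthesis* network carries w into an image through style-modulated
convolutions.  Training is non-saturating logistic adversarial training with
an R1 gradient penalty on real batches, and both real and generated
discriminator inputs pass through the same stochastic augmentation pipeline
whose probability p adapts to a discriminator-overfitting statistic
(adaptive discriminator augmentation).

The *oracle* mode replaces the trained synthesis network with an analytic
w -> image decoder built on :mod:`dermavec.simulate`: w[0] drives severity,
w[1] drives plaque area fraction, and the remaining coordinates drive skin
tone, hair, illumination and texture deterministically.  Because the
ground-truth factor axes are literally the first two basis vectors of
w-space, latent-direction recovery can be tested exactly, with no training.

Networks are implemented in numpy (see :mod:`dermavec.nn`); the R1 term uses
a finite-difference Hessian-vector product, exact almost everywhere for
these piecewise-linear networks.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from . import nn, simulate
from .evaluate import default_features, frechet_from_features
from .nn import F32

__all__ = [
    "TrainConfig",
    "GeneratorHandle",
    "AdaController",
    "sample_z",
    "oracle_generator",
    "decode_w",
    "encode_factors",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; desk defaults train a 32x32 model on one CPU.

    ``full_scale()`` gives the reference full-scale settings (256x256,
    channel_base 16384, 5000 kimg); acceptance-scale work never runs them.
    """

    lr_generator: float = 0.0025
    lr_discriminator: float = 0.0025
    batch_size: int = 64
    z_dim: int = 512
    w_dim: int = 512
    resolution: int = 32
    channel_base: int = 128
    channel_max: int = 32
    r1_gamma: float = 0.2048
    total_kimg: int = 10
    ada_target: float = 0.6
    ada_adjust_interval: int = 4
    ada_step: float = 0.05
    seed: int = 0

    @staticmethod
    def full_scale() -> "TrainConfig":
        return TrainConfig(
            resolution=256, channel_base=16384, channel_max=512, total_kimg=5000
        )

    def validate(self) -> None:
        r = self.resolution
        if r < 16 or (r & (r - 1)) != 0:
            raise ValueError(f"resolution={r} must be a power of two >= 16")
        for name in ("lr_generator", "lr_discriminator", "r1_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.ada_target < 1.0):
            raise ValueError("ada_target must lie in (0, 1)")

    def nf(self, res: int) -> int:
        return int(min(self.channel_max, max(self.channel_base // res, 4)))


def sample_z(n: int, config: TrainConfig, seed: int) -> np.ndarray:
    """n standard-normal latent z vectors, shape (n, z_dim)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    return rng.standard_normal((n, config.z_dim)).astype(np.float64)


# ---------------------------------------------------------------------------
# networks

class Mapping:
    """z -> w: per-sample normalisation followed by two dense+lrelu layers."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        self.l0 = nn.Dense(config.z_dim, config.w_dim, rng)
        self.l1 = nn.Dense(config.w_dim, config.w_dim, rng)
        self.layers = [self.l0, self.l1]

    def forward(self, z: np.ndarray) -> np.ndarray:
        z = z.astype(F32)
        self._norm = np.sqrt((z * z).mean(axis=1, keepdims=True) + 1e-8)
        zn = z / self._norm
        self._a0 = self.l0.forward(zn)
        h = nn.lrelu(self._a0)
        self._a1 = self.l1.forward(h)
        return nn.lrelu(self._a1)

    def backward(self, dw: np.ndarray) -> None:
        d = self.l1.backward(nn.lrelu_grad(self._a1, dw))
        self.l0.backward(nn.lrelu_grad(self._a0, d))


class Synthesis:
    """w -> image: learned 4x4 constant, modulated 3x3 convs, 2x upsampling."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        self.config = config
        c4 = config.nf(4)
        self.const = (rng.standard_normal((c4, 4, 4)) * 0.1).astype(F32)
        self.const_grad = np.zeros_like(self.const)
        self.blocks: list[nn.ModConv3x3] = [nn.ModConv3x3(c4, c4, config.w_dim, rng)]
        self.resolutions = [4]
        res = 4
        while res < config.resolution:
            res *= 2
            self.blocks.append(
                nn.ModConv3x3(config.nf(res // 2), config.nf(res), config.w_dim, rng)
            )
            self.resolutions.append(res)
        self.to_rgb = nn.Conv1x1(config.nf(config.resolution), 3, rng, w_scale=0.05)
        self.layers = [*self.blocks, self.to_rgb]

    def forward(self, w: np.ndarray) -> np.ndarray:
        w = w.astype(F32)
        self._w = w
        b = w.shape[0]
        x = np.broadcast_to(self.const, (b, *self.const.shape)).copy()
        self._acts = []
        for res, blk in zip(self.resolutions, self.blocks):
            if res > 4:
                x = nn.upsample2(x)
            a = blk.forward(x, w)
            self._acts.append(a)
            x = nn.lrelu(a)
        return self.to_rgb.forward(x)

    def backward(self, dimg: np.ndarray) -> np.ndarray:
        dw = np.zeros_like(self._w)
        dx = self.to_rgb.backward(dimg.astype(F32))
        for res, blk, a in zip(
            self.resolutions[::-1], self.blocks[::-1], self._acts[::-1]
        ):
            dx, dwi = blk.backward(nn.lrelu_grad(a, dx))
            dw += dwi
            if res > 4:
                dx = nn.upsample2_grad(dx)
        self.const_grad = dx.sum(axis=0)
        return dw


class Discriminator:
    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        self.config = config
        res = config.resolution
        self.from_rgb = nn.Conv1x1(3, config.nf(res), rng)
        self.convs: list[nn.Conv3x3] = []
        self.res_seq = []
        while res > 4:
            self.convs.append(nn.Conv3x3(config.nf(res), config.nf(res // 2), rng))
            self.res_seq.append(res)
            res //= 2
        feat = config.nf(4) * 16
        self.fc0 = nn.Dense(feat, 128, rng)
        self.fc1 = nn.Dense(128, 1, rng)
        self.layers = [self.from_rgb, *self.convs, self.fc0, self.fc1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._a_rgb = self.from_rgb.forward(x.astype(F32))
        h = nn.lrelu(self._a_rgb)
        self._acts = []
        for conv in self.convs:
            a = conv.forward(h)
            self._acts.append(a)
            h = nn.avgpool2(nn.lrelu(a))
        b = h.shape[0]
        self._flat_shape = h.shape
        self._a0 = self.fc0.forward(h.reshape(b, -1))
        self._a1 = self.fc1.forward(nn.lrelu(self._a0))
        return self._a1[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.fc1.backward(dy[:, None].astype(F32))
        d = self.fc0.backward(nn.lrelu_grad(self._a0, d))
        d = d.reshape(self._flat_shape)
        for conv, a in zip(self.convs[::-1], self._acts[::-1]):
            d = nn.avgpool2_grad(d)
            d = conv.backward(nn.lrelu_grad(a, d))
        return self.from_rgb.backward(nn.lrelu_grad(self._a_rgb, d))


# ---------------------------------------------------------------------------
# oracle decoder

# coordinate contract of the oracle w -> factors map
_ORACLE_DOC = {
    0: "severity: affine [-3,3] -> [0,4], clamped",
    1: "area_fraction: logistic -> [0.05, 0.9]",
    2: "skin tone red", 3: "skin tone green", 4: "skin tone blue",
    5: "hair density", 6: "illumination", 7: "eccentricity",
    8: "texture seed (hashed, with 9..13)",
}


def decode_w(w: np.ndarray) -> simulate.LesionFactors:
    """Analytic w -> LesionFactors map (the oracle synthesis contract)."""
    w = np.asarray(w, dtype=np.float64).ravel()
    if w.size < 14 or not np.all(np.isfinite(w)):
        raise ValueError("oracle decoding needs >= 14 finite w coordinates")
    seed = zlib.crc32(np.round(w[8:14], 1).astype(np.float32).tobytes())
    return simulate.LesionFactors(
        severity=float(np.clip((w[0] + 3.0) * 4.0 / 6.0, 0.0, 4.0)),
        area_fraction=float(0.05 + 0.85 * expit(w[1])),
        skin_tone=(
            float(196 + 18 * np.tanh(w[2] / 2)),
            float(158 + 14 * np.tanh(w[3] / 2)),
            float(138 + 12 * np.tanh(w[4] / 2)),
        ),
        hair_density=float(0.5 * expit(w[5])),
        illumination=float(1.0 + 0.2 * np.tanh(w[6] / 2)),
        center=None,
        eccentricity=float(0.6 * expit(w[7])),
        seed=int(seed % (2**31 - 1)),
    )


def encode_factors(severity: float, area_fraction: float, w_rest: np.ndarray) -> np.ndarray:
    """Inverse of the first two decode_w coordinates; w_rest fills w[2:]."""
    w = np.empty(2 + len(w_rest), dtype=np.float64)
    w[0] = 1.5 * float(severity) - 3.0
    w[1] = float(logit(np.clip((area_fraction - 0.05) / 0.85, 1e-6, 1 - 1e-6)))
    w[2:] = w_rest
    return w


# ---------------------------------------------------------------------------
# generator handle

@dataclass
class GeneratorHandle:
    """A generator in ``trained`` or ``oracle`` mode."""

    config: TrainConfig
    mode: str = "oracle"
    mapping: Mapping | None = None
    synthesis: Synthesis | None = None
    step: int = 0

    def map_z_to_w(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        zb = z[None] if single else z
        if zb.shape[1] != self.config.z_dim:
            raise ValueError(f"z has length {zb.shape[1]}, expected {self.config.z_dim}")
        if self.mode == "oracle":
            w = zb.copy()
        else:
            w = self.mapping.forward(zb).astype(np.float64)
        return w[0] if single else w

    def synthesize(self, w: np.ndarray) -> np.ndarray:
        """One image (H,W,3 uint8) from one w vector."""
        w = np.asarray(w, dtype=np.float64).ravel()
        if w.size != self.config.w_dim:
            raise ValueError(f"w has length {w.size}, expected {self.config.w_dim}")
        if not np.all(np.isfinite(w)):
            raise ValueError("w contains non-finite entries")
        if self.mode == "oracle":
            return simulate.render(decode_w(w), self.config.resolution)
        img = self.synthesis.forward(w[None].astype(F32))[0]
        return _to_uint8(img)

    def synthesize_batch(self, w: np.ndarray) -> list[np.ndarray]:
        return [self.synthesize(wi) for wi in np.atleast_2d(w)]


def _to_uint8(img_chw: np.ndarray) -> np.ndarray:
    x = np.clip((img_chw.transpose(1, 2, 0) + 1.0) * 127.5, 0, 255)
    return np.rint(x).astype(np.uint8)


def oracle_generator(
    resolution: int = 32, z_dim: int = 512, seed: int = 0
) -> GeneratorHandle:
    cfg = TrainConfig(resolution=resolution, z_dim=z_dim, w_dim=z_dim, seed=seed)
    cfg.validate()
    return GeneratorHandle(config=cfg, mode="oracle")


# ---------------------------------------------------------------------------
# adaptive discriminator augmentation

class AdaController:
    """p moves up by ``step`` when the real-logit sign-rate exceeds the
    target, down otherwise; clamped to [0, 1]."""

    def __init__(self, target: float, step: float = 0.05, p: float = 0.0):
        self.target, self.step, self.p = target, step, p

    def update(self, sign_rate: float) -> float:
        self.p += self.step if sign_rate > self.target else -self.step
        self.p = float(np.clip(self.p, 0.0, 1.0))
        return self.p


class _AdaAugment:
    """Stochastic flips / 90-degree rotations / integer translations /
    per-channel gains applied with probability p per image; invertible so
    generator gradients pass back through exactly."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def draw(self, batch: int, p: float) -> list[dict]:
        ops = []
        for _ in range(batch):
            op = {
                "k": int(self.rng.integers(0, 4)) if self.rng.random() < p else 0,
                "hflip": bool(self.rng.random() < p and self.rng.random() < 0.5),
                "shift": (
                    (int(self.rng.integers(-4, 5)), int(self.rng.integers(-4, 5)))
                    if self.rng.random() < p
                    else (0, 0)
                ),
                "gain": (
                    self.rng.uniform(0.8, 1.25, 3).astype(F32)
                    if self.rng.random() < p
                    else None
                ),
            }
            ops.append(op)
        return ops

    @staticmethod
    def apply(x: np.ndarray, ops: list[dict]) -> np.ndarray:
        out = np.empty_like(x)
        for i, op in enumerate(ops):
            y = x[i]
            if op["k"]:
                y = np.rot90(y, op["k"], axes=(1, 2))
            if op["hflip"]:
                y = y[:, :, ::-1]
            if op["shift"] != (0, 0):
                y = np.roll(y, op["shift"], axis=(1, 2))
            if op["gain"] is not None:
                y = y * op["gain"][:, None, None]
            out[i] = y
        return out

    @staticmethod
    def backward(dy: np.ndarray, ops: list[dict]) -> np.ndarray:
        out = np.empty_like(dy)
        for i, op in enumerate(ops):
            d = dy[i]
            if op["gain"] is not None:
                d = d * op["gain"][:, None, None]
            if op["shift"] != (0, 0):
                d = np.roll(d, (-op["shift"][0], -op["shift"][1]), axis=(1, 2))
            if op["hflip"]:
                d = d[:, :, ::-1]
            if op["k"]:
                d = np.rot90(d, -op["k"], axes=(1, 2))
            out[i] = d
        return out


# ---------------------------------------------------------------------------
# training

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def train(
    images: Sequence[np.ndarray],
    config: TrainConfig,
    eval_interval: int | None = None,
    n_eval: int = 256,
) -> tuple[GeneratorHandle, list[dict]]:
    """Adversarial training on uint8 images; returns (handle, log).

    The log holds one record per step (losses, ADA probability) plus
    Fréchet-feature-distance evaluations at the first and final step (and
    every ``eval_interval`` steps when given).
    """
    config.validate()
    if len(images) < config.batch_size:
        raise ValueError(
            f"need >= batch_size={config.batch_size} images, got {len(images)}"
        )
    res = config.resolution
    for img in images[:4]:
        if img.shape[:2] != (res, res):
            raise ValueError(f"image shape {img.shape} != configured resolution {res}")

    x_all = (
        np.stack([im.transpose(2, 0, 1) for im in images]).astype(F32) / 127.5 - 1.0
    )
    ss = np.random.SeedSequence([int(config.seed), 71])
    r_init, r_batch, r_z, r_ada, r_eval = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    gen = GeneratorHandle(
        config=config,
        mode="trained",
        mapping=Mapping(config, r_init),
        synthesis=Synthesis(config, r_init),
    )
    disc = Discriminator(config, r_init)
    g_layers = gen.mapping.layers + gen.synthesis.layers
    opt_g = nn.Adam(g_layers, lr=config.lr_generator)
    opt_d = nn.Adam(disc.layers, lr=config.lr_discriminator)
    # the synthesis constant is optimised alongside (manual Adam state)
    const_m = np.zeros_like(gen.synthesis.const)
    const_v = np.zeros_like(gen.synthesis.const)

    ada = AdaController(config.ada_target, config.ada_step)
    aug = _AdaAugment(r_ada)
    b = config.batch_size
    n_steps = max(1, config.total_kimg * 1000 // b)
    log: list[dict] = []
    sign_acc: list[float] = []

    # exponential moving average of generator weights; samples and the
    # final handle use the averaged weights (the raw weights keep training)
    ema_decay = 0.5 ** (b / 2000.0)
    ema = {
        f"{i}_{k}": lay.params[k].copy()
        for i, lay in enumerate(g_layers)
        for k in lay.params
    }
    ema["const"] = gen.synthesis.const.copy()

    def ema_update():
        for i, lay in enumerate(g_layers):
            for k in lay.params:
                key = f"{i}_{k}"
                ema[key] += (1.0 - ema_decay) * (lay.params[k] - ema[key])
        ema["const"] += (1.0 - ema_decay) * (gen.synthesis.const - ema["const"])

    def ema_swap():
        for i, lay in enumerate(g_layers):
            for k in lay.params:
                key = f"{i}_{k}"
                lay.params[k], ema[key] = ema[key], lay.params[k]
        gen.synthesis.const, ema["const"] = ema["const"], gen.synthesis.const

    eval_feats_real = default_features(
        [_to_uint8(x_all[i]) for i in r_batch.choice(len(x_all), min(n_eval, len(x_all)), replace=False)]
    )

    def eval_ffd(step: int) -> float:
        # dedicated rng so evaluation cadence never perturbs training draws
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 83, step]))
        z = rng.standard_normal((min(n_eval, len(x_all)), config.z_dim))
        ema_swap()
        try:
            w = gen.mapping.forward(z.astype(F32))
            imgs = gen.synthesis.forward(w)
        finally:
            ema_swap()
        feats = default_features([_to_uint8(im) for im in imgs])
        return frechet_from_features(feats, eval_feats_real)

    ffd0 = eval_ffd(0)
    log.append({"step": 0, "event": "eval", "ffd": ffd0, "p": ada.p})

    for step in range(1, n_steps + 1):
        # --- discriminator update
        idx = r_batch.choice(len(x_all), b, replace=len(x_all) < b)
        real = x_all[idx]
        z = r_z.standard_normal((b, config.z_dim))
        fake = gen.synthesis.forward(gen.mapping.forward(z.astype(F32)))
        ops_r = aug.draw(b, ada.p)
        ops_f = aug.draw(b, ada.p)
        real_aug = _AdaAugment.apply(real, ops_r)
        fake_aug = _AdaAugment.apply(fake, ops_f)

        y_r = disc.forward(real_aug)
        disc.backward(-_sigmoid(-y_r) / b)
        grads = nn.collect_grads(disc.layers)
        y_f = disc.forward(fake_aug)
        disc.backward(_sigmoid(y_f) / b)
        grads = nn.add_grad_lists(grads, nn.collect_grads(disc.layers))

        # R1 penalty (gamma/2)*mean ||grad_x D||^2 via finite-difference HVP
        disc.forward(real_aug)
        g_x = disc.backward(np.ones(b, dtype=F32))
        disc.grads_snapshot = nn.collect_grads(disc.layers)
        gnorm = float(np.sqrt((g_x.astype(np.float64) ** 2).mean()) + 1e-12)
        epsd = 1e-3 / gnorm
        disc.forward(real_aug + F32(epsd) * g_x)
        disc.backward(np.ones(b, dtype=F32))
        r1_grads = [
            (g2 - g1) * (config.r1_gamma / (b * epsd))
            for g1, g2 in zip(disc.grads_snapshot, nn.collect_grads(disc.layers))
        ]
        grads = nn.add_grad_lists(grads, r1_grads)
        opt_d.step(grads)

        loss_d = float(_softplus(-y_r).mean() + _softplus(y_f).mean())
        sign_acc.append(float((y_r > 0).mean()))

        # --- generator update
        z = r_z.standard_normal((b, config.z_dim))
        w = gen.mapping.forward(z.astype(F32))
        fake = gen.synthesis.forward(w)
        ops_g = aug.draw(b, ada.p)
        y_g = disc.forward(_AdaAugment.apply(fake, ops_g))
        dx = disc.backward(-_sigmoid(-y_g) / b)
        dimg = _AdaAugment.backward(dx, ops_g)
        dw = gen.synthesis.backward(dimg)
        gen.mapping.backward(dw)
        opt_g.step()
        # Adam on the synthesis constant
        gconst = gen.synthesis.const_grad
        const_m = opt_g.b1 * const_m + (1 - opt_g.b1) * gconst
        const_v = opt_g.b2 * const_v + (1 - opt_g.b2) * gconst * gconst
        bc1 = 1.0 - opt_g.b1**opt_g.t
        bc2 = 1.0 - opt_g.b2**opt_g.t
        gen.synthesis.const -= (
            opt_g.lr * (const_m / bc1) / (np.sqrt(const_v / bc2) + opt_g.eps)
        ).astype(F32)

        loss_g = float(_softplus(-y_g).mean())
        ema_update()

        if step % config.ada_adjust_interval == 0:
            ada.update(float(np.mean(sign_acc)))
            sign_acc.clear()

        rec = {"step": step, "loss_d": loss_d, "loss_g": loss_g, "p": ada.p}
        if eval_interval and step % eval_interval == 0 and step < n_steps:
            rec["ffd"] = eval_ffd(step)
        log.append(rec)

    gen.step = n_steps
    ffd_final = eval_ffd(n_steps)
    log.append({"step": n_steps, "event": "eval", "ffd": ffd_final, "p": ada.p})
    # hand back the averaged weights: they are what sampling should use
    ema_swap()
    return gen, log


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(gen: GeneratorHandle, path) -> None:
    """Single-file npz archive: parameters + config + step counter."""
    arrays: dict[str, np.ndarray] = {}
    if gen.mode == "trained":
        for i, lay in enumerate(gen.mapping.layers):
            for k, v in lay.params.items():
                arrays[f"map_{i}_{k}"] = v
        for i, lay in enumerate(gen.synthesis.layers):
            for k, v in lay.params.items():
                arrays[f"syn_{i}_{k}"] = v
        arrays["syn_const"] = gen.synthesis.const
    meta = json.dumps({"config": asdict(gen.config), "mode": gen.mode, "step": gen.step})
    arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> GeneratorHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = TrainConfig(**meta["config"])
        gen = GeneratorHandle(config=config, mode=meta["mode"], step=meta["step"])
        if meta["mode"] == "trained":
            rng = np.random.default_rng(0)
            gen.mapping = Mapping(config, rng)
            gen.synthesis = Synthesis(config, rng)
            for i, lay in enumerate(gen.mapping.layers):
                for k in lay.params:
                    lay.params[k] = data[f"map_{i}_{k}"].copy()
            for i, lay in enumerate(gen.synthesis.layers):
                for k in lay.params:
                    lay.params[k] = data[f"syn_{i}_{k}"].copy()
            gen.synthesis.const = data["syn_const"].copy()
    return gen
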