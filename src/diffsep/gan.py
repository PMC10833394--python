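"""Parallel conditional image-translation networks for component separation.

Two conditional GANs are trained side by side on normalized scattering
planes: one maps the total scattering to the form-factor component, the
other to the short-range-order component.  Each follows the pix2pix recipe:

* generator G: U-Net encoder-decoder with skip connections; stochasticity
  enters through 50% dropout (the noise source z), active during training
  and available as a sampling mode at inference;
* discriminator D: a convolutional patch classifier that sees the candidate
  image concatenated channel-wise with the conditioning scattering plane;
* loss: the conditional GAN objective plus a pixel-wise L1 term weighted by
  lambda = 100.

Discriminators are conditioned on the *clean* (artefact-free) scattering so
they cannot anchor on dead-zone patterns; generators receive the
artefact-stained input.  After each iteration an extra step multiplies the
two generated components and penalizes their smooth-L1 deviation from the
product of the normalized ground-truth components, coupling the two
generators through the factorization identity I_D = I_FF * I_SRO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import DatasetSample

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "UNetGenerator",
    "PatchDiscriminator",
    "TrainState",
    "TrainConfig",
    "adversarial_loss",
    "l1_loss",
    "generator_total_loss",
    "smooth_l1_loss",
    "product_consistency_loss",
    "init_train_state",
    "train_epoch",
    "decompose",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "diffsep-ckpt-1"


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net shape: depth halvings, base width, dropout rate."""

    grid_size: int = 64
    base_channels: int = 16
    depth: int | None = None  # default: log2(grid) - 2, capped at 8
    dropout_rate: float = 0.5

    @property
    def resolved_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        return min(int(np.log2(self.grid_size)) - 2, 8)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch discriminator shape."""

    base_channels: int = 16
    n_strided: int = 2  # stride-2 stages before the two stride-1 heads


@dataclass(frozen=True)
class LossWeights:
    lambda_l1: float = 100.0
    smooth_l1_beta: float = 1.0
    adversarial: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_l1, self.smooth_l1_beta, self.adversarial) < 0:
            raise ValueError("loss weights must be non-negative")


class UNetGenerator(nn.Layer):
    """Encoder-decoder with skip connections at matched resolutions.

    Output passes through tanh so generated planes always lie in [-1, 1],
    matching the normalization of the training data.
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        depth = spec.resolved_depth
        if depth < 2:
            raise ValueError("U-Net needs at least 2 resolution levels")
        nf = spec.base_channels
        widths = [min(nf * 2**i, nf * 8) for i in range(depth)]
        self.depth = depth
        self.grid_size = spec.grid_size
        self.enc: list[nn.Sequential] = []
        c_prev = 1
        for i, c in enumerate(widths):
            block: list[nn.Layer] = []
            if i > 0:
                block.append(nn.LeakyReLU(0.2))
            block.append(nn.Conv2d(c_prev, c, rng=rng))
            if 0 < i < depth - 1:
                block.append(nn.InstanceNorm2d(c))
            self.enc.append(nn.Sequential(*block))
            c_prev = c
        self.dec: list[nn.Sequential] = []
        self.dropouts: list[nn.Dropout] = []
        for i in range(depth - 1, -1, -1):
            c_out = 1 if i == 0 else widths[i - 1]
            c_in = widths[i] if i == depth - 1 else widths[i] * 2
            block = [nn.ReLU(), nn.ConvTranspose2d(c_in, c_out, rng=rng)]
            if i > 0:
                block.append(nn.InstanceNorm2d(c_out))
                if len(self.dec) < 3:  # dropout on the innermost decoder stages
                    drop = nn.Dropout(spec.dropout_rate, rng=dropout_rng)
                    block.append(drop)
                    self.dropouts.append(drop)
            else:
                block.append(nn.Tanh())
            self.dec.append(nn.Sequential(*block))

    def parameters(self):
        return [p for b in self.enc + self.dec for p in b.parameters()]

    def set_dropout(self, active: bool) -> None:
        for d in self.dropouts:
            d.active = active

    def forward(self, x):
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
        y = skips[-1]
        for i, block in enumerate(self.dec):
            if i > 0:
                y = np.concatenate([y, skips[self.depth - 1 - i]], axis=1)
            y = block(y)
        self._skip_channels = [s.shape[1] for s in skips]
        return y

    def backward(self, grad):
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(self.depth - 1, -1, -1):
            g = self.dec[i].backward(grad)
            if i > 0:
                level = self.depth - 1 - i  # encoder level concatenated here
                c_main = g.shape[1] - self._skip_channels[level]
                grad = g[:, :c_main]
                skip_grads[level] = g[:, c_main:]
            else:
                grad = g
        # grad now flows into the innermost encoder output
        g = grad
        for i in range(self.depth - 1, -1, -1):
            if i in skip_grads and i != self.depth - 1:
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


class PatchDiscriminator(nn.Layer):
    """Convolutional real/fake classifier over overlapping patches.

    Input is the candidate plane concatenated channel-wise with the
    conditioning plane; output is a grid of per-patch probabilities in
    (0, 1).
    """

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        nf = spec.base_channels
        layers: list[nn.Layer] = [nn.Conv2d(2, nf, rng=rng), nn.LeakyReLU(0.2)]
        c = nf
        for i in range(1, spec.n_strided):
            layers += [nn.Conv2d(c, 2 * c, rng=rng), nn.InstanceNorm2d(2 * c),
                       nn.LeakyReLU(0.2)]
            c *= 2
        layers += [nn.Conv2d(c, 2 * c, kernel=4, stride=1, pad=1, rng=rng),
                   nn.InstanceNorm2d(2 * c), nn.LeakyReLU(0.2)]
        c *= 2
        layers += [nn.Conv2d(c, 1, kernel=4, stride=1, pad=1, rng=rng), nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    def parameters(self):
        return self.net.parameters()

    def forward(self, candidate, condition):
        return self.net(np.concatenate([candidate, condition], axis=1))

    def __call__(self, candidate, condition):
        return self.forward(candidate, condition)

    def backward(self, grad):
        g = self.net.backward(grad)
        return g[:, :1], g[:, 1:]  # gradients w.r.t. candidate and condition


# --------------------------------------------------------------------------
# losses


_EPS = 1e-12


def _check_probability(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("discriminator outputs must be probabilities in (0, 1)")
    return np.clip(p, _EPS, 1.0 - _EPS)


def adversarial_loss(disc_out_real, disc_out_fake) -> tuple[float, float]:
    """Conditional GAN objective: (discriminator loss, generator loss).

    D maximizes log D(real) + log(1 - D(fake)); its loss is the negation,
    averaged per patch (so two coin-flip outputs give 2 ln 2).  G minimizes
    -log D(fake).
    """
    r = _check_probability(disc_out_real)
    f = _check_probability(disc_out_fake)
    d_loss = float(-np.log(r).mean() - np.log(1.0 - f).mean())
    g_loss = float(-np.log(f).mean())
    return d_loss, g_loss


def _adv_grads(disc_out_real, disc_out_fake):
    r = _check_probability(disc_out_real)
    f = _check_probability(disc_out_fake)
    d_grad_real = -1.0 / (r * r.size)
    d_grad_fake = 1.0 / ((1.0 - f) * f.size)
    g_grad_fake = -1.0 / (f * f.size)
    return d_grad_real, d_grad_fake, g_grad_fake


def l1_loss(generated, gt) -> float:
    """Mean absolute pixel difference."""
    generated, gt = np.asarray(generated), np.asarray(gt)
    if generated.shape != gt.shape:
        raise ValueError("shape mismatch in L1 loss")
    return float(np.abs(generated - gt).mean())


def generator_total_loss(adv_term: float, l1_term: float,
                         weights: LossWeights = LossWeights()) -> float:
    """Per-head generator objective: adversarial + lambda * L1."""
    if not (np.isfinite(adv_term) and np.isfinite(l1_term)):
        raise ValueError("loss terms must be finite")
    return weights.adversarial * adv_term + weights.lambda_l1 * l1_term


def smooth_l1_loss(pred, target, beta: float = 1.0) -> float:
    """Huber-style loss: quadratic below *beta*, linear above, C1-continuous."""
    d = np.asarray(pred) - np.asarray(target)
    a = np.abs(d)
    return float(np.where(a < beta, 0.5 * d**2 / beta, a - 0.5 * beta).mean())


def _smooth_l1_grad(pred, target, beta):
    d = np.asarray(pred) - np.asarray(target)
    return np.where(np.abs(d) < beta, d / beta, np.sign(d)) / d.size


def product_consistency_loss(gen_ff, gen_sro, gt_ff, gt_sro,
                             weights: LossWeights = LossWeights()) -> float:
    """Smooth-L1 between the product of generated components and the product
    of the normalized ground truths (the factorization constraint)."""
    if not (gen_ff.shape == gen_sro.shape == gt_ff.shape == gt_sro.shape):
        raise ValueError("shape mismatch in product-consistency loss")
    return smooth_l1_loss(gen_ff * gen_sro, gt_ff * gt_sro, weights.smooth_l1_beta)


# --------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    lr: float = 2e-4
    beta1: float = 0.5
    weights: LossWeights = field(default_factory=LossWeights)
    product_step: bool = True


@dataclass
class TrainState:
    """Everything needed to continue (or replay) training bit-exactly."""

    gen_ff: UNetGenerator
    gen_sro: UNetGenerator
    disc_ff: PatchDiscriminator
    disc_sro: PatchDiscriminator
    opt_gen_ff: nn.Adam
    opt_gen_sro: nn.Adam
    opt_disc_ff: nn.Adam
    opt_disc_sro: nn.Adam
    rng: np.random.Generator
    seed: int
    grid_size: int
    epoch: int = 0
    loss_history: list[dict] = field(default_factory=list)

    def generators(self):
        return {"ff": self.gen_ff, "sro": self.gen_sro}

    def discriminators(self):
        return {"ff": self.disc_ff, "sro": self.disc_sro}


def init_train_state(
    seed: int,
    grid_size: int = 64,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    config: TrainConfig = TrainConfig(),
) -> TrainState:
    gen_spec = gen_spec or GeneratorSpec(grid_size=grid_size)
    disc_spec = disc_spec or DiscriminatorSpec()
    root = np.random.default_rng(seed)
    init_rng = np.random.default_rng(root.integers(2**31 - 1))
    drop_rng = np.random.default_rng(root.integers(2**31 - 1))
    batch_rng = np.random.default_rng(root.integers(2**31 - 1))
    gen_ff = UNetGenerator(gen_spec, init_rng, drop_rng)
    gen_sro = UNetGenerator(gen_spec, init_rng, drop_rng)
    disc_ff = PatchDiscriminator(disc_spec, init_rng)
    disc_sro = PatchDiscriminator(disc_spec, init_rng)
    mk = lambda net: nn.Adam(net.parameters(), lr=config.lr, beta1=config.beta1)
    return TrainState(
        gen_ff=gen_ff, gen_sro=gen_sro, disc_ff=disc_ff, disc_sro=disc_sro,
        opt_gen_ff=mk(gen_ff), opt_gen_sro=mk(gen_sro),
        opt_disc_ff=mk(disc_ff), opt_disc_sro=mk(disc_sro),
        rng=batch_rng, seed=seed, grid_size=grid_size,
    )


def _as_batch(arrs) -> np.ndarray:
    return np.stack(arrs)[:, None, :, :]


def train_epoch(
    state: TrainState,
    samples: list[DatasetSample],
    config: TrainConfig = TrainConfig(),
    epochs: int = 1,
) -> list[dict]:
    """Run *epochs* epochs of the three-phase protocol; returns epoch logs.

    Per batch and per head: (a) update D on (ground truth | clean input) as
    real vs (G(artefact input, z) | clean input) as fake, generator frozen;
    (b) update G on the adversarial + lambda L1 objective, discriminator
    frozen; then (c) one joint generator step on the product-consistency
    loss.  "Frozen" means the opponent's optimizer never steps on the
    gradients accumulated in that phase; its parameters are untouched.
    """
    if not samples:
        raise ValueError("dataset is empty")
    w = config.weights
    logs = []
    for _ in range(epochs):
        order = state.rng.permutation(len(samples))
        sums = {k: 0.0 for k in
                ("d_ff", "d_sro", "adv_ff", "adv_sro", "l1_ff", "l1_sro",
                 "total_ff", "total_sro", "product")}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [samples[i] for i in idx]
            x_art = _as_batch([s.input for s in batch])
            x_clean = _as_batch([s.input_clean for s in batch])
            gts = {"ff": _as_batch([s.gt_ff for s in batch]),
                   "sro": _as_batch([s.gt_sro for s in batch])}
            opts_g = {"ff": state.opt_gen_ff, "sro": state.opt_gen_sro}
            opts_d = {"ff": state.opt_disc_ff, "sro": state.opt_disc_sro}
            for head in ("ff", "sro"):
                gen = state.generators()[head]
                disc = state.discriminators()[head]
                gen.set_dropout(True)
                # ---- (a) discriminator update, generator frozen
                fake = gen(x_art)
                opts_d[head].zero_grad()
                # real and fake terms use separate forward passes, so the
                # real-term gradient is propagated before the fake forward
                # overwrites the discriminator's caches
                d_real = disc(gts[head], x_clean)
                r = _check_probability(d_real)
                disc.backward(-1.0 / (r * r.size))
                d_fake = disc(fake, x_clean)
                d_loss, _ = adversarial_loss(d_real, d_fake)
                f = _check_probability(d_fake)
                disc.backward(1.0 / ((1.0 - f) * f.size))
                opts_d[head].step()
                # ---- (b) generator update, discriminator frozen
                opts_g[head].zero_grad()
                fake = gen(x_art)
                d_fake2 = disc(fake, x_clean)
                f2 = _check_probability(d_fake2)
                g_adv = float(-np.log(f2).mean())
                l1 = l1_loss(fake, gts[head])
                total = generator_total_loss(g_adv, l1, w)
                if not np.isfinite(total):
                    raise FloatingPointError(f"non-finite generator loss ({head})")
                dcand, _ = disc.backward(-1.0 / (f2 * f2.size))
                dl1 = np.sign(fake - gts[head]) / fake.size
                gen.backward(w.adversarial * dcand + w.lambda_l1 * dl1)
                opts_g[head].step()
                sums[f"d_{head}"] += d_loss
                sums[f"adv_{head}"] += g_adv
                sums[f"l1_{head}"] += l1
                sums[f"total_{head}"] += total
            # ---- (c) joint product-consistency step
            if config.product_step:
                state.opt_gen_ff.zero_grad()
                state.opt_gen_sro.zero_grad()
                fake_ff = state.gen_ff(x_art)
                fake_sro = state.gen_sro(x_art)
                target = gts["ff"] * gts["sro"]
                prod = fake_ff * fake_sro
                p_loss = smooth_l1_loss(prod, target, w.smooth_l1_beta)
                if not np.isfinite(p_loss):
                    raise FloatingPointError("non-finite product-consistency loss")
                gprod = _smooth_l1_grad(prod, target, w.smooth_l1_beta)
                state.gen_ff.backward(gprod * fake_sro)
                state.gen_sro.backward(gprod * fake_ff)
                state.opt_gen_ff.step()
                state.opt_gen_sro.step()
                sums["product"] += p_loss
            n_batches += 1
        log = {k: v / n_batches for k, v in sums.items()}
        state.epoch += 1
        log["epoch"] = state.epoch
        state.loss_history.append(log)
        logs.append(log)
    return logs


class InputSizeError(ValueError):
    """Input plane does not match the network grid; resize upstream."""


def decompose(
    state: TrainState, input_plane: np.ndarray, sample_dropout: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Separate one normalized scattering plane into (I_FF, I_SRO) images.

    The input must already be square-root normalized to [-1, 1] and match
    the trained grid size.  With *sample_dropout* false (default) the
    output is deterministic; true re-enables the dropout noise source to
    draw decomposition samples.
    """
    x = np.asarray(input_plane, dtype=float)
    if x.shape != (state.grid_size, state.grid_size):
        raise InputSizeError(
            f"input is {x.shape}, expected "
            f"({state.grid_size}, {state.grid_size}); resize upstream"
        )
    xb = x[None, None]
    outs = []
    for gen in (state.gen_ff, state.gen_sro):
        gen.set_dropout(sample_dropout)
        outs.append(gen(xb)[0, 0])
        gen.set_dropout(True)
    return outs[0], outs[1]


# --------------------------------------------------------------------------
# checkpointing


def _collect_params(state: TrainState) -> dict[str, np.ndarray]:
    out = {}
    for name, net in (("gff", state.gen_ff), ("gsro", state.gen_sro),
                      ("dff", state.disc_ff), ("dsro", state.disc_sro)):
        for i, p in enumerate(net.parameters()):
            out[f"{name}_p{i}"] = p.value
    for name, opt in (("ogff", state.opt_gen_ff), ("ogsro", state.opt_gen_sro),
                      ("odff", state.opt_disc_ff), ("odsro", state.opt_disc_sro)):
        for k, v in opt.state_arrays().items():
            out[f"{name}_{k}"] = v
    return out


def save_checkpoint(state: TrainState, path) -> None:
    arrays = _collect_params(state)
    meta = {
        "version": CHECKPOINT_VERSION,
        "seed": state.seed,
        "grid_size": state.grid_size,
        "epoch": state.epoch,
        "loss_history": state.loss_history,
        "rng_state": state.rng.bit_generator.state,
        "dropout_rng_state": state.gen_ff.dropouts[0].rng.bit_generator.state
        if state.gen_ff.dropouts else None,
    }
    np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path, gen_spec: GeneratorSpec | None = None,
                    disc_spec: DiscriminatorSpec | None = None,
                    config: TrainConfig = TrainConfig()) -> TrainState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        state = init_train_state(
            meta["seed"], grid_size=meta["grid_size"],
            gen_spec=gen_spec, disc_spec=disc_spec, config=config,
        )
        for name, net in (("gff", state.gen_ff), ("gsro", state.gen_sro),
                          ("dff", state.disc_ff), ("dsro", state.disc_sro)):
            for i, p in enumerate(net.parameters()):
                p.value[...] = z[f"{name}_p{i}"]
        for name, opt in (("ogff", state.opt_gen_ff), ("ogsro", state.opt_gen_sro),
                          ("odff", state.opt_disc_ff), ("odsro", state.opt_disc_sro)):
            opt.load_state_arrays(
                {k[len(name) + 1 :]: z[k] for k in z.files if k.startswith(name + "_")}
            )
        state.epoch = meta["epoch"]
        state.loss_history = meta["loss_history"]
        state.rng.bit_generator.state = meta["rng_state"]
        if meta["dropout_rng_state"] is not None and state.gen_ff.dropouts:
            state.gen_ff.dropouts[0].rng.bit_generator.state = meta["dropout_rng_state"]
        return state
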