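"""Adversarial autoencoder: architectures and three-phase training.

An encoder f maps a (possibly corrupted) feature vector x to a latent
code z; a decoder g maps z (optionally concatenated with a one-hot
label vector y) back to feature space through a sigmoid output; a
discriminator D is trained to tell standard-normal prior draws from
encoder outputs.  Each minibatch runs three sequential updates:

1. reconstruction — encoder+decoder minimize the per-feature binary
   cross-entropy between the clean input and the reconstruction of its
   corrupted version;
2. regularization — the discriminator minimizes the usual GAN loss on
   prior draws (real) versus latent codes (fake);
3. generator — the encoder minimizes the non-saturating −log D(z) so
   the aggregated posterior over z drifts toward the prior.

Two stock configurations are provided: a *reconstruction* model
(3×128-unit encoder/decoder, 128-d latent, trained on structured-noise
corruptions) and a label-conditioned *synthesis* model (128→10 encoder,
10-d latent, noise-free input, dropout 0.2 on z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corruption import NoiseConfig, corrupt
from .data import MultimodalDataset, ModalitySchema
from .nn import EPS, MLP, Adam, bce_with_logits, sigmoid, softplus


@dataclass(frozen=True)
class PriorSpec:
    """Target latent distribution: i.i.d. standard normal per dimension."""

    family: str = "standard_normal"
    dim: int = 128

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.dim))


@dataclass
class TrainConfig:
    """Optimization settings for one AAE variant.

    Learning rates are per loss stream (adversarial / reconstruction /
    classification); Adam moments stay at conventional defaults.
    Weight decay (1e-5) applies to encoder and classifier weights only.
    """

    lr_reconstruction: float = 5e-4
    lr_adversarial: float = 3e-4
    lr_classification: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    weight_decay: float = 1e-5
    latent_dropout: float = 0.0
    val_fraction: float = 0.2
    adversarial: bool = True
    # numerical stabilizers for the adversarial game: reduced first-moment
    # decay on the adversarial Adam streams, and Gaussian instance noise
    # added to both discriminator inputs, annealed over the first half of
    # training (mean matching is exact under instance noise; it removes
    # the discriminator's incentive to win on latent-manifold geometry)
    adv_beta1: float = 0.5
    instance_noise: float = 1.0
    instance_noise_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_reconstruction, self.lr_adversarial, self.lr_classification) <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")

    @classmethod
    def reconstruction_defaults(cls, **overrides) -> "TrainConfig":
        return cls(
            lr_adversarial=3e-4, lr_reconstruction=5e-4, lr_classification=5e-4,
            **overrides,
        )

    @classmethod
    def synthesis_defaults(cls, **overrides) -> "TrainConfig":
        overrides.setdefault("latent_dropout", 0.2)
        return cls(
            lr_reconstruction=1e-3, lr_adversarial=1e-3, lr_classification=5e-4,
            **overrides,
        )

    def to_mapping(self) -> dict:
        return {
            "lr_reconstruction": self.lr_reconstruction,
            "lr_adversarial": self.lr_adversarial,
            "lr_classification": self.lr_classification,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "weight_decay": self.weight_decay,
            "latent_dropout": self.latent_dropout,
            "val_fraction": self.val_fraction,
            "adversarial": self.adversarial,
            "adv_beta1": self.adv_beta1,
            "instance_noise": self.instance_noise,
            "instance_noise_floor": self.instance_noise_floor,
            "seed": self.seed,
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "TrainConfig":
        return cls(**m)


@dataclass
class AAEModel:
    """Trained (or initialized) encoder/decoder/discriminator triple."""

    encoder: MLP
    decoder: MLP
    discriminator: MLP
    latent_dim: int
    n_features: int
    label_conditioned: bool = False
    n_labels: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec)
    trained: bool = False
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.encoder.out_width != self.latent_dim:
            raise ValueError("encoder output width must equal latent_dim")
        expect = self.latent_dim + (self.n_labels if self.label_conditioned else 0)
        if self.decoder.in_width != expect:
            raise ValueError("decoder input width mismatch")
        if self.decoder.out_width != self.n_features:
            raise ValueError("decoder output width must equal n_features")

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        arrays.update(self.encoder.to_arrays("enc"))
        arrays.update(self.decoder.to_arrays("dec"))
        arrays.update(self.discriminator.to_arrays("disc"))
        meta = {
            "latent_dim": self.latent_dim,
            "n_features": self.n_features,
            "label_conditioned": self.label_conditioned,
            "n_labels": self.n_labels,
            "prior_dim": self.prior.dim,
            "trained": self.trained,
        }
        arrays["model_meta"] = np.array([json.dumps(meta, sort_keys=True)])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "AAEModel":
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(str(arrays["model_meta"][0]))
        return cls(
            encoder=MLP.from_arrays(arrays, "enc"),
            decoder=MLP.from_arrays(arrays, "dec"),
            discriminator=MLP.from_arrays(arrays, "disc"),
            latent_dim=int(meta["latent_dim"]),
            n_features=int(meta["n_features"]),
            label_conditioned=bool(meta["label_conditioned"]),
            n_labels=int(meta["n_labels"]),
            prior=PriorSpec(dim=int(meta["prior_dim"])),
            trained=bool(meta["trained"]),
        )


def build_reconstruction_model(
    n_features: int,
    rng: np.random.Generator,
    latent_dim: int = 128,
    hidden: int = 128,
) -> AAEModel:
    """Unsupervised denoising model: 3-layer encoder and decoder with
    128 units per layer and a 128-dimensional latent code."""
    enc = MLP([n_features, hidden, hidden, latent_dim], rng)
    dec = MLP([latent_dim, hidden, hidden, n_features], rng, out_activation="sigmoid")
    disc = MLP([latent_dim, 128, 128, 1], rng, out_activation="sigmoid")
    return AAEModel(enc, dec, disc, latent_dim, n_features,
                    prior=PriorSpec(dim=latent_dim))


def build_synthesis_model(
    n_features: int,
    n_labels: int,
    rng: np.random.Generator,
    latent_dim: int = 10,
    hidden: int = 128,
) -> AAEModel:
    """Label-conditioned model: 2 hidden layers (128 then 10 latent);
    the decoder consumes z concatenated with the C-length label vector."""
    enc = MLP([n_features, hidden, latent_dim], rng)
    dec = MLP([latent_dim + n_labels, hidden, n_features], rng,
              out_activation="sigmoid")
    disc = MLP([latent_dim, 128, 128, 1], rng, out_activation="sigmoid")
    return AAEModel(enc, dec, disc, latent_dim, n_features,
                    label_conditioned=True, n_labels=n_labels,
                    prior=PriorSpec(dim=latent_dim))


# ---------------------------------------------------------------------------
# Stateless operations


def encode(x: np.ndarray, model: AAEModel) -> np.ndarray:
    """Deterministic latent code of x (evaluation mode)."""
    s, _ = model.encoder.forward(np.atleast_2d(x), train=False)
    return s


def decode(
    z: np.ndarray, model: AAEModel, y: np.ndarray | None = None
) -> np.ndarray:
    """Decoder output in (0,1)^n; a label-conditioned model requires y
    (unreported entries encoded as 0)."""
    z = np.atleast_2d(z)
    if model.label_conditioned:
        if y is None:
            raise ValueError("label-conditioned decoder requires y")
        y = np.nan_to_num(np.atleast_2d(y), nan=0.0)
        z = np.concatenate([z, y], axis=1)
    elif y is not None:
        raise ValueError("unconditioned decoder does not accept y")
    s, _ = model.decoder.forward(z, train=False)
    return model.decoder.output(s)


def discriminate(z: np.ndarray, model: AAEModel) -> np.ndarray:
    """Probability that z is a draw from the prior."""
    s, _ = model.discriminator.forward(np.atleast_2d(z), train=False)
    return model.discriminator.output(s).ravel()


def reconstruction_loss(x_target: np.ndarray, x_pred: np.ndarray) -> float:
    """Per-feature binary cross-entropy averaged over all entries.

    Targets must lie in [0,1]; predictions are clamped away from {0,1}.
    """
    x_target = np.asarray(x_target, dtype=np.float64)
    x_pred = np.asarray(x_pred, dtype=np.float64)
    if np.any((x_target < 0) | (x_target > 1)):
        raise ValueError("reconstruction targets must lie in [0,1]")
    p = np.clip(x_pred, EPS, 1.0 - EPS)
    per = -(x_target * np.log(p) + (1.0 - x_target) * np.log1p(-p))
    return float(per.mean())


def adversarial_losses(
    z_fake: np.ndarray, z_real: np.ndarray, discriminator: MLP
) -> tuple[float, float]:
    """(d_loss, g_loss): the discriminator's cross-entropy on real prior
    draws vs fake codes, and the encoder's non-saturating generator loss."""
    s_real, _ = discriminator.forward(np.atleast_2d(z_real), train=False)
    s_fake, _ = discriminator.forward(np.atleast_2d(z_fake), train=False)
    d_loss = float((softplus(-s_real) + softplus(s_fake)).mean())
    g_loss = float(softplus(-s_fake).mean())
    return d_loss, g_loss


# ---------------------------------------------------------------------------
# Training


def _as_features(data) -> np.ndarray:
    if isinstance(data, MultimodalDataset):
        return data.features
    return np.asarray(data, dtype=np.float64)


def _train_aae(
    X: np.ndarray,
    Y: np.ndarray | None,
    model: AAEModel,
    cfg: TrainConfig,
    noise: NoiseConfig | None,
    schema: ModalitySchema | None,
) -> AAEModel:
    m = X.shape[0]
    if m == 0:
        raise ValueError("empty training set")
    if np.any((X < 0) | (X > 1)):
        raise ValueError("training features must be normalized to [0,1]")
    rng = np.random.default_rng(cfg.seed)

    # internal 80/20 validation split
    n_val = max(1, int(round(cfg.val_fraction * m))) if m > 1 else 0
    perm = rng.permutation(m)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = perm, perm
    Xtr, Xval = X[tr_idx], X[val_idx]
    Ytr = Y[tr_idx] if Y is not None else None
    Yval = Y[val_idx] if Y is not None else None

    # validation input corrupted once with a fixed stream, so the early
    # stopping criterion is a deterministic function of the epoch
    if noise is not None:
        val_rng = np.random.default_rng(cfg.seed + 1)
        Xval_in = corrupt(Xval, schema, noise, val_rng)
    else:
        Xval_in = Xval

    opt_enc_rec = Adam(model.encoder, cfg.lr_reconstruction, cfg.weight_decay)
    opt_dec = Adam(model.decoder, cfg.lr_reconstruction)
    opt_disc = Adam(model.discriminator, cfg.lr_adversarial, beta1=cfg.adv_beta1)
    opt_enc_adv = Adam(model.encoder, cfg.lr_adversarial, beta1=cfg.adv_beta1)

    d = model.latent_dim
    best_loss = np.inf
    best_params = None
    best_epoch = -1
    stale = 0

    def val_loss() -> float:
        z = encode(Xval_in, model)
        xv = decode(z, model, Yval if model.label_conditioned else None)
        return reconstruction_loss(Xval, xv)

    model.history.append({"epoch": -1, "val_recon": val_loss()})

    n_tr = Xtr.shape[0]
    anneal_span = max(1, cfg.max_epochs // 2)
    for epoch in range(cfg.max_epochs):
        sigma = max(
            cfg.instance_noise_floor,
            cfg.instance_noise * (1.0 - epoch / anneal_span),
        )
        order = rng.permutation(n_tr)
        ep_rec, ep_d, ep_g, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Xtr[idx]
            y = Ytr[idx] if Ytr is not None else None
            xin = corrupt(x, schema, noise, rng) if noise is not None else x
            B = x.shape[0]

            # -- phase 1: reconstruction ---------------------------------
            z, c_enc = model.encoder.forward(xin, train=True)
            if cfg.latent_dropout > 0:
                keep = 1.0 - cfg.latent_dropout
                zmask = (rng.random(z.shape) < keep) / keep
                z_in = z * zmask
            else:
                zmask = None
                z_in = z
            dec_in = (
                np.concatenate([z_in, y], axis=1)
                if model.label_conditioned
                else z_in
            )
            s_x, c_dec = model.decoder.forward(dec_in, train=True)
            rec, d_sx = bce_with_logits(s_x, x)
            g_dec, d_in = model.decoder.backward(d_sx, c_dec)
            d_z = d_in[:, :d]
            if zmask is not None:
                d_z = d_z * zmask
            g_enc, _ = model.encoder.backward(d_z, c_enc)
            opt_dec.step(g_dec)
            opt_enc_rec.step(g_enc)
            ep_rec += rec

            if cfg.adversarial:
                # -- phase 2: discriminator ------------------------------
                z_fake = encode(xin, model)
                z_real = model.prior.sample(B, rng)
                if sigma > 0:
                    z_fake = z_fake + sigma * rng.standard_normal(z_fake.shape)
                    z_real = z_real * np.sqrt(1.0 + sigma**2)
                s_r, c_r = model.discriminator.forward(z_real, train=True)
                s_f, c_f = model.discriminator.forward(z_fake, train=True)
                d_loss = float((softplus(-s_r) + softplus(s_f)).mean())
                g_r, _ = model.discriminator.backward(-sigmoid(-s_r) / B, c_r)
                g_f, _ = model.discriminator.backward(sigmoid(s_f) / B, c_f)
                g_disc = [
                    (gw1 + gw2, gb1 + gb2)
                    for (gw1, gb1), (gw2, gb2) in zip(g_r, g_f)
                ]
                opt_disc.step(g_disc)
                ep_d += d_loss

                # -- phase 3: generator (encoder fools D) ----------------
                z, c_enc = model.encoder.forward(xin, train=True)
                if sigma > 0:
                    z = z + sigma * rng.standard_normal(z.shape)
                s_g, c_g = model.discriminator.forward(z, train=False)
                g_loss = float(softplus(-s_g).mean())
                _, d_zg = model.discriminator.backward(-sigmoid(-s_g) / B, c_g)
                g_enc, _ = model.encoder.backward(d_zg, c_enc)
                opt_enc_adv.step(g_enc)
                ep_g += g_loss
            n_batches += 1

        vloss = val_loss()
        model.history.append({
            "epoch": epoch,
            "train_recon": ep_rec / n_batches,
            "d_loss": ep_d / n_batches if cfg.adversarial else float("nan"),
            "g_loss": ep_g / n_batches if cfg.adversarial else float("nan"),
            "val_recon": vloss,
        })
        if vloss < best_loss - 1e-9:
            best_loss = vloss
            best_params = (
                model.encoder.get_params(),
                model.decoder.get_params(),
                model.discriminator.get_params(),
            )
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if best_params is not None:
        model.encoder.set_params(best_params[0])
        model.decoder.set_params(best_params[1])
        model.discriminator.set_params(best_params[2])
    model.trained = True
    model.history.append({"epoch": best_epoch, "best_val_recon": best_loss})
    return model


def train_reconstruction_model(
    clean_train: MultimodalDataset | np.ndarray,
    noise: NoiseConfig,
    cfg: TrainConfig,
    schema: ModalitySchema | None = None,
) -> AAEModel:
    """Train the denoising reconstruction AAE on fully-observed,
    normalized instances with structured-noise corruption."""
    X = _as_features(clean_train)
    if isinstance(clean_train, MultimodalDataset):
        if clean_train.missing_mask.any():
            raise ValueError("reconstruction training requires clean instances")
        schema = clean_train.schema
    if schema is None:
        raise ValueError("schema required when passing a bare feature matrix")
    rng = np.random.default_rng(cfg.seed)
    model = build_reconstruction_model(X.shape[1], rng)
    return _train_aae(X, None, model, cfg, noise, schema)


def train_synthesis_model(
    clean_train: MultimodalDataset | np.ndarray,
    labels: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
) -> AAEModel:
    """Train the label-conditioned synthesis AAE on clean, noise-free
    inputs; unreported label entries are presented to the decoder as 0."""
    X = _as_features(clean_train)
    if isinstance(clean_train, MultimodalDataset):
        if clean_train.missing_mask.any():
            raise ValueError("synthesis training requires clean instances")
        if labels is None:
            labels = clean_train.labels
    if labels is None:
        raise ValueError("labels are required for the synthesis model")
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels are not aligned with instances")
    if cfg is None:
        cfg = TrainConfig.synthesis_defaults()
    Y = np.nan_to_num(labels, nan=0.0)
    rng = np.random.default_rng(cfg.seed)
    model = build_synthesis_model(X.shape[1], labels.shape[1], rng)
    return _train_aae(X, Y, model, cfg, None, None)
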