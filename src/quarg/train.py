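"""Calibrated hybrid training of the fusion model.

The loss is natural-log cross-entropy plus ``lambda_cal`` times a
soft-binned differentiable surrogate of the expected calibration error
(triangular kernel memberships over M equal-width confidence bins on
[0.5, 1]); the hard ECE is always what gets *reported*.  Classical
parameters train by reverse-mode autodiff; the VQC angles train by the
parameter-shift rule chained with the loss gradient at the quantum features.
Early stopping monitors the composite validation score AUC - w * ECE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from . import evalsplit, qenc
from .autodiff import Adam, Tensor, concat
from .encoders import (
    FusionHead,
    GenomicEncoder,
    GenomicEncoderConfig,
    ImageEncoder,
    ImageEncoderConfig,
)

PROB_CLAMP = 1e-7


@dataclass
class TrainConfig:
    lambda_cal: float = 0.1
    ece_bins: int = 10
    lr: float = 0.01
    lr_theta: float = 0.05
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    early_stop_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_cal < 0:
            raise ValueError("lambda_cal must be >= 0")
        if self.ece_bins < 2:
            raise ValueError("ece_bins must be >= 2")


# --------------------------------------------------------------------------
# hybrid loss
# --------------------------------------------------------------------------


def _soft_ece_tensor(p: Tensor, y: np.ndarray, M: int) -> Tensor:
    """Differentiable ECE surrogate with triangular bin memberships."""
    n = y.size
    conf = p.maximum(1.0 - p).reshape(n, 1)
    correct = ((p.data >= 0.5).astype(int) == y).astype(float)[:, None]
    w = 0.5 / M
    centers = Tensor((0.5 + w * (np.arange(M) + 0.5)).reshape(1, M))
    member = (1.0 - (conf - centers).abs() * (1.0 / w)).maximum(0.0)  # (n, M)
    weight = member.sum(axis=0)  # (M,)
    eps = 1e-12
    conf_m = (member * conf).sum(axis=0) / (weight + eps)
    acc_m = (member * Tensor(correct)).sum(axis=0) / (weight + eps)
    total = weight.sum() + eps
    return (weight * (acc_m - conf_m).abs()).sum() / total


def hybrid_loss_tensor(p: Tensor, y: np.ndarray, lambda_cal: float, M: int) -> Tensor:
    y = np.asarray(y, dtype=float)
    if np.any(p.data <= PROB_CLAMP) or np.any(p.data >= 1.0 - PROB_CLAMP):
        warnings.warn("probabilities clamped away from {0, 1} for the log loss")
    pc = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    ce = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).mean()
    if lambda_cal == 0.0:
        return ce
    return ce + lambda_cal * _soft_ece_tensor(pc, y.astype(int), M)


def hybrid_loss(p, y, lambda_cal: float = 0.1, M: int = 10) -> float:
    """Scalar loss on plain arrays: mean cross-entropy (nats) + lambda * soft-ECE."""
    return float(hybrid_loss_tensor(Tensor(np.asarray(p, float)), np.asarray(y), lambda_cal, M).data)


def soft_ece(p, y, M: int = 10) -> float:
    return float(_soft_ece_tensor(Tensor(np.asarray(p, float)), np.asarray(y, int), M).data)


# --------------------------------------------------------------------------
# fusion model
# --------------------------------------------------------------------------


class FusionModel:
    """Image encoder + genomic encoder + VQC angles + fusion head."""

    def __init__(
        self,
        image_config: ImageEncoderConfig,
        genomic_config: GenomicEncoderConfig,
        vqc_config: qenc.VqcConfig,
        head_hidden: int = 32,
        seed: int = 0,
    ):
        self.image_config = image_config
        self.genomic_config = genomic_config
        self.vqc_config = vqc_config
        self.head_hidden = head_hidden
        self.seed = seed
        self.image_encoder = ImageEncoder(image_config)
        self.genomic_encoder = GenomicEncoder(genomic_config)
        d_in = image_config.d_img + genomic_config.d_gen + vqc_config.Q
        self.head = FusionHead(d_in, hidden=head_hidden, seed=seed + 17)
        self.theta = qenc.init_params(vqc_config)

    def classical_params(self) -> list[Tensor]:
        out = list(self.image_encoder.params.values())
        out += list(self.genomic_encoder.params.values())
        out += list(self.head.params.values())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.classical_params()) + self.theta.size

    def forward(self, patches: np.ndarray, gvec: np.ndarray, angles: np.ndarray):
        """Returns (probability Tensor (B,), quantum-feature leaf Tensor)."""
        z_img = self.image_encoder.forward(patches)
        z_gen = self.genomic_encoder.forward(gvec)
        zq_np = qenc.quantum_embed(angles, self.theta, self.vqc_config)
        z_q = Tensor(np.atleast_2d(zq_np), requires_grad=True)
        prob = self.head.forward(concat([z_img, z_gen, z_q], axis=-1)).sigmoid()
        return prob, z_q

    def predict_proba(self, patches: np.ndarray, gvec: np.ndarray, angles: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(patches, gvec, angles)
        return prob.data

    # ---- checkpointing ----

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {"theta": self.theta}
        for prefix, params in (
            ("img", self.image_encoder.params),
            ("gen", self.genomic_encoder.params),
            ("head", self.head.params),
        ):
            for name, t in params.items():
                arrays[f"{prefix}.{name}"] = t.data
        return arrays

    def save(self, path) -> None:
        """Single-archive checkpoint: every parameter array + config + seed."""
        meta = {
            "image_config": asdict(self.image_config),
            "genomic_config": asdict(self.genomic_config),
            "vqc_config": asdict(self.vqc_config),
            "head_hidden": self.head_hidden,
            "seed": self.seed,
        }
        np.savez(path, _meta=json.dumps(meta, sort_keys=True), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["_meta"]))
            model = cls(
                ImageEncoderConfig(**meta["image_config"]),
                GenomicEncoderConfig(**meta["genomic_config"]),
                qenc.VqcConfig(**meta["vqc_config"]),
                head_hidden=meta["head_hidden"],
                seed=meta["seed"],
            )
            model.theta = np.array(npz["theta"])
            for prefix, params in (
                ("img", model.image_encoder.params),
                ("gen", model.genomic_encoder.params),
                ("head", model.head.params),
            ):
                for name, t in params.items():
                    t.data = np.array(npz[f"{prefix}.{name}"])
        return model


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------


@dataclass
class TrainData:
    """One split's aligned arrays; patches (N, H, W), gvec (N, G),
    angles (N, Q) already scaled to [0, pi], labels (N,)."""

    patches: np.ndarray
    gvec: np.ndarray
    angles: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.patches) == len(self.gvec) == len(self.angles) == n):
            raise ValueError("all arrays must have the same number of patients")
        if n == 0:
            raise ValueError("empty split")


def train(
    model: FusionModel,
    train_data: TrainData,
    val_data: TrainData,
    config: TrainConfig,
) -> tuple[FusionModel, list[dict]]:
    """Minibatch Adam on the hybrid loss with parameter-shift theta updates.

    Returns the model restored to the best checkpoint (highest validation
    AUC - w * hard ECE) and a per-epoch history.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.classical_params(), lr=config.lr)
    theta_t = Tensor(model.theta, requires_grad=True)
    opt_theta = Adam([theta_t], lr=config.lr_theta)
    n = len(train_data.y)
    history: list[dict] = []
    best_score = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            prob, z_q = model.forward(
                train_data.patches[idx], train_data.gvec[idx], train_data.angles[idx]
            )
            loss = hybrid_loss_tensor(prob, train_data.y[idx], config.lambda_cal, config.ece_bins)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if model.theta.size:
                theta_t.grad = qenc.parameter_shift_grad(
                    train_data.angles[idx], model.theta, model.vqc_config, z_q.grad
                )
                opt_theta.step()
                model.theta = theta_t.data
            epoch_losses.append(loss.item())

        val_prob = model.predict_proba(val_data.patches, val_data.gvec, val_data.angles)
        val_auc = evalsplit.auc(val_prob, val_data.y)
        val_ece = evalsplit.expected_calibration_error(val_prob, val_data.y, config.ece_bins)
        score = val_auc - config.early_stop_weight * val_ece
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_auc": float(val_auc),
                "val_ece": float(val_ece),
                "score": float(score),
            }
        )
        if score > best_score + 1e-12:
            best_score = score
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_state is not None:
        model.theta = best_state["theta"]
        for prefix, params in (
            ("img", model.image_encoder.params),
            ("gen", model.genomic_encoder.params),
            ("head", model.head.params),
        ):
            for name, t in params.items():
                t.data = best_state[f"{prefix}.{name}"]
    return model, history


def save_history_csv(path, history: list[dict]) -> None:
    cols = ["epoch", "train_loss", "val_auc", "val_ece", "score"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in history:
            fh.write(",".join(repr(row[c]) for c in cols) + "\n")
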