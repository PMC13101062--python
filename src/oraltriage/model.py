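"""The three-branch referral classifier and its training procedures.

Architecture: two independent convolutional image branches (white-light and
autofluorescence), each ending in global average pooling and a linear
projection to ``image_feature_dim`` features; a small MLP over the
risk-factor vector; the three feature vectors are concatenated and a linear
head emits two logits whose softmax gives the referral probability.

Training is staged for continual learning under prevalence shift: ``prime``
fits the model on the prior (high-prevalence + healthy) data; the rehearsal
stage re-initializes from the primed weights and trains on the combined
dataset with prior samples shuffled into every epoch (full replay), so the
model keeps its prior-domain competence while adapting to the deployment
population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import nnet
from .encoding import EncoderSpec
from .evaluation import aggregate_site_scores, roc_auc
from .nnet import (
    Adam,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Linear,
    ReLU,
    Sequential,
    cross_entropy,
    get_weights,
    set_weights,
    softmax,
)
from .preprocessing import Standardizer

BACKBONES = ("small_cnn", "tiny_cnn", "oneconv")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``small_cnn`` is the default four-block backbone; ``tiny_cnn`` is a
    two-block variant for fast CPU runs and tests; ``oneconv`` is a
    single-convolution backbone used by attribution unit tests.
    """

    backbone: str = "small_cnn"
    image_feature_dim: int = 1024
    mlp_hidden_dim: int = 64
    mlp_out_dim: int = 32
    dropout: float = 0.2
    n_risk_features: int = 0  # set from the fitted encoder
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.image_feature_dim <= 0:
            raise ValueError("image_feature_dim must be positive")

    @property
    def concat_dim(self) -> int:
        return 2 * self.image_feature_dim + self.mlp_out_dim


@dataclass
class TrainConfig:
    max_epochs: int = 120
    min_epochs_before_stability: int = 60
    batch_size: int = 5
    lr: float = 1e-4
    patience: int = 15
    class_weights: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs_before_stability > self.max_epochs:
            raise ValueError("min_epochs_before_stability must not exceed max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _backbone_layers(config: ModelConfig, rng, name: str) -> tuple[list[nnet.Layer], int]:
    c = [
        lambda cin, cout, s, i: Conv2d(cin, cout, 3, rng, stride=s, pad=1, name=f"{name}.conv{i}")
    ][0]
    if config.backbone == "small_cnn":
        layers = [
            c(3, 16, 2, 0), ReLU(),
            c(16, 32, 2, 1), ReLU(),
            c(32, 64, 2, 2), ReLU(),
            c(64, 128, 1, 3), ReLU(),
        ]
        return layers, 128
    if config.backbone == "tiny_cnn":
        layers = [c(3, 8, 2, 0), ReLU(), c(8, 16, 2, 1), ReLU()]
        return layers, 16
    # oneconv
    return [c(3, 4, 1, 0), ReLU()], 4


class MultiInputNet:
    """Fused WL + AF + risk-vector network with explicit backward pass."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        branches = {}
        for modality in ("wl", "af"):
            layers, c_last = _backbone_layers(config, rng, modality)
            layers += [
                GlobalAvgPool(),
                Linear(c_last, config.image_feature_dim, rng, name=f"{modality}.feat"),
                ReLU(),
            ]
            branches[modality] = Sequential(layers)
        self.wl_branch = branches["wl"]
        self.af_branch = branches["af"]
        self.mlp = Sequential(
            [
                Linear(config.n_risk_features, config.mlp_hidden_dim, rng, name="mlp.fc0"),
                ReLU(),
                Linear(config.mlp_hidden_dim, config.mlp_out_dim, rng, name="mlp.fc1"),
                ReLU(),
            ]
        )
        self.head = Sequential(
            [
                Dropout(config.dropout, rng),
                Linear(config.concat_dim, 2, rng, name="head.fc"),
            ]
        )

    def params(self) -> list[nnet.Param]:
        return (
            self.wl_branch.params()
            + self.af_branch.params()
            + self.mlp.params()
            + self.head.params()
        )

    def forward(
        self, wl: np.ndarray, af: np.ndarray, risk: np.ndarray, train: bool = False
    ) -> np.ndarray:
        if risk.shape[1] != self.config.n_risk_features:
            raise ValueError(
                f"risk vector has {risk.shape[1]} features; "
                f"model was built for {self.config.n_risk_features}"
            )
        f_wl = self.wl_branch.forward(wl, train=train)
        f_af = self.af_branch.forward(af, train=train)
        f_r = self.mlp.forward(risk, train=train)
        return self.head.forward(np.concatenate([f_wl, f_af, f_r], axis=1), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        fdim = self.config.image_feature_dim
        self.wl_branch.backward(g[:, :fdim])
        self.af_branch.backward(g[:, fdim : 2 * fdim])
        self.mlp.backward(g[:, 2 * fdim :])

    def conv_activation_and_grad(self, branch: str) -> tuple[np.ndarray, np.ndarray]:
        """Feature maps entering the branch's global pool and their gradient
        from the most recent forward/backward pass (GradCAM hook point)."""
        seq = self.wl_branch if branch == "wl" else self.af_branch
        gap_idx = next(
            i for i, l in enumerate(seq.layers) if isinstance(l, GlobalAvgPool)
        )
        acts = seq.activations[gap_idx - 1]
        grads = seq.output_grads[gap_idx - 1]
        if acts is None or grads is None:
            raise RuntimeError("run a forward and backward pass first")
        return acts, grads


def build_model(config: ModelConfig) -> MultiInputNet:
    return MultiInputNet(config)


@dataclass
class Samples:
    """Image-level training samples (one row per capture)."""

    wl: np.ndarray          # N x 3 x H x W, standardized
    af: np.ndarray
    risk: np.ndarray        # N x n_risk_features
    y: np.ndarray           # N, in {0, 1}
    site_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.wl) == len(self.af) == len(self.risk) == len(self.site_ids) == n):
            raise ValueError("sample arrays disagree in length")

    @property
    def n(self) -> int:
        return len(self.y)

    @classmethod
    def concatenate(cls, a: "Samples", b: "Samples") -> "Samples":
        return cls(
            wl=np.concatenate([a.wl, b.wl]),
            af=np.concatenate([a.af, b.af]),
            risk=np.concatenate([a.risk, b.risk]),
            y=np.concatenate([a.y, b.y]),
            site_ids=a.site_ids + b.site_ids,
        )


@dataclass
class TrainedModel:
    """A trained network bundled with its preprocessing references."""

    weights: dict[str, np.ndarray]
    config: ModelConfig
    train_config: TrainConfig
    history: dict
    selected_epoch: int
    stage: str  # "priming" | "rehearsal"
    standardizer: Optional[Standardizer] = None
    encoder_spec: Optional[EncoderSpec] = None
    initial_weights: Optional[dict[str, np.ndarray]] = None

    def build_net(self) -> MultiInputNet:
        net = MultiInputNet(self.config)
        set_weights(net.params(), self.weights)
        return net

    def save(self, dir_path: str | Path) -> Path:
        root = Path(dir_path)
        root.mkdir(parents=True, exist_ok=True)
        np.savez(root / "weights.npz", **self.weights)
        meta = {
            "config": asdict(self.config),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "selected_epoch": self.selected_epoch,
            "stage": self.stage,
        }
        (root / "meta.json").write_text(json.dumps(meta, indent=2))
        if self.standardizer is not None:
            self.standardizer.to_json(root / "standardizer.json")
        if self.encoder_spec is not None:
            self.encoder_spec.to_json(root / "encoder.json")
        return root

    @classmethod
    def load(cls, dir_path: str | Path) -> "TrainedModel":
        root = Path(dir_path)
        if not (root / "meta.json").exists():
            raise FileNotFoundError(f"no model bundle at {root}")
        meta = json.loads((root / "meta.json").read_text())
        with np.load(root / "weights.npz") as z:
            weights = {k: z[k] for k in z.files}
        tc = meta["train_config"]
        if tc.get("class_weights") is not None:
            tc["class_weights"] = tuple(tc["class_weights"])
        return cls(
            weights=weights,
            config=ModelConfig(**meta["config"]),
            train_config=TrainConfig(**tc),
            history=meta["history"],
            selected_epoch=meta["selected_epoch"],
            stage=meta["stage"],
            standardizer=(
                Standardizer.from_json(root / "standardizer.json")
                if (root / "standardizer.json").exists()
                else None
            ),
            encoder_spec=(
                EncoderSpec.from_json(root / "encoder.json")
                if (root / "encoder.json").exists()
                else None
            ),
        )


def _forward_in_batches(net: MultiInputNet, data: Samples, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, data.n, batch):
        out.append(net.forward(data.wl[i : i + batch], data.af[i : i + batch],
                               data.risk[i : i + batch], train=False))
    return np.concatenate(out)


def _site_level_auc(scores: np.ndarray, data: Samples) -> Optional[float]:
    by_site: dict[str, list[float]] = {}
    truth: dict[str, int] = {}
    for s, sid, y in zip(scores, data.site_ids, data.y):
        by_site.setdefault(sid, []).append(float(s))
        truth[sid] = int(y)
    agg = aggregate_site_scores(by_site, truth)
    truths = np.array([ss.truth for ss in agg])
    vals = np.array([ss.site_score for ss in agg])
    if len(np.unique(truths)) < 2:
        return None
    return roc_auc(vals, truths)


def train(
    model: MultiInputNet,
    train_data: Samples,
    val_data: Samples,
    config: TrainConfig,
    stage: str = "priming",
    augment_fn: Optional[Callable[[np.ndarray, np.ndarray, np.random.Generator], tuple]] = None,
    initial_weights: Optional[dict[str, np.ndarray]] = None,
) -> TrainedModel:
    """Mini-batch Adam training with AUC checkpointing and early stopping.

    Early stopping is gated: at least ``min_epochs_before_stability`` epochs
    run before ``patience`` epochs without validation-loss improvement can
    halt training.  The checkpoint with the best site-level validation AUC is
    kept (validation loss when AUC is undefined because the validation set is
    single-class).  Fully deterministic from ``config.seed`` on CPU.
    """
    if train_data.n == 0 or val_data.n == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = Adam(params, lr=config.lr)
    cw = np.asarray(config.class_weights) if config.class_weights else None

    n_pos = int(train_data.y.sum())
    history: dict = {
        "train_loss": [],
        "val_loss": [],
        "val_auc": [],
        "train_class_counts": {"refer": n_pos, "do_not_refer": train_data.n - n_pos},
    }
    best_weights = get_weights(params)
    best_metric = (-np.inf, -np.inf)  # (val AUC, -val loss); loss breaks AUC ties
    best_epoch = -1
    best_val_loss = np.inf
    since_improve = 0
    auc_warned = False

    for epoch in range(config.max_epochs):
        perm = rng.permutation(train_data.n)
        losses = []
        for i in range(0, train_data.n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            wl, af = train_data.wl[idx], train_data.af[idx]
            if augment_fn is not None:
                wl, af = augment_fn(wl, af, rng)
            opt.zero_grad()
            logits = model.forward(wl, af, train_data.risk[idx], train=True)
            loss, dlogits = cross_entropy(logits, train_data.y[idx], cw)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        val_logits = _forward_in_batches(model, val_data)
        val_loss, _ = cross_entropy(val_logits, val_data.y, cw)
        val_scores = softmax(val_logits)[:, 1]
        val_auc = _site_level_auc(val_scores, val_data)
        history["val_loss"].append(float(val_loss))
        history["val_auc"].append(val_auc)

        if val_auc is None:
            if not auc_warned:
                warnings.warn(
                    "validation set is single-class: AUC undefined, "
                    "selecting checkpoint by validation loss"
                )
                auc_warned = True
            metric = (0.0, -val_loss)
        else:
            metric = (val_auc, -val_loss)
        if metric > best_metric:
            best_metric = metric
            best_weights = get_weights(params)
            best_epoch = epoch

        if val_loss < best_val_loss - 1e-9:
            best_val_loss = val_loss
            since_improve = 0
        else:
            since_improve += 1
        if epoch + 1 >= config.min_epochs_before_stability and since_improve >= config.patience:
            break

    set_weights(params, best_weights)
    return TrainedModel(
        weights=best_weights,
        config=model.config,
        train_config=config,
        history=history,
        selected_epoch=best_epoch,
        stage=stage,
        initial_weights=initial_weights,
    )


def prime(
    prior_train: Samples,
    prior_val: Samples,
    model_config: ModelConfig,
    train_config: TrainConfig,
    augment_fn=None,
) -> TrainedModel:
    """Stage 1: fit the multi-input model on the prior-study data."""
    model = build_model(model_config)
    return train(model, prior_train, prior_val, train_config, stage="priming",
                 augment_fn=augment_fn)


def rehearsal_train(
    primed: TrainedModel,
    combined_train: Samples,
    combined_val: Samples,
    train_config: TrainConfig,
    augment_fn=None,
) -> TrainedModel:
    """Stage 2: continue from the primed weights on prior ∪ new data.

    The network is initialized with the primed weights (verified tensor-wise
    before any update); each epoch's shuffle interleaves prior and new
    samples uniformly, giving the model replay of previously seen data.
    """
    if primed is None or not primed.weights:
        raise ValueError("rehearsal requires a primed model with weights")
    model = build_model(primed.config)
    set_weights(model.params(), primed.weights)
    init = get_weights(model.params())
    for name, value in primed.weights.items():
        if not np.array_equal(init[name], value):
            raise AssertionError(f"rehearsal initialization mismatch for {name}")
    out = train(
        model,
        combined_train,
        combined_val,
        train_config,
        stage="rehearsal",
        augment_fn=augment_fn,
        initial_weights=init,
    )
    return out


def predict(
    model: TrainedModel | MultiInputNet,
    wl: np.ndarray,
    af: np.ndarray,
    risk: np.ndarray,
) -> np.ndarray:
    """Referral probability for one or more preprocessed samples.

    Deterministic: augmentation and dropout are off in evaluation mode.
    """
    net = model.build_net() if isinstance(model, TrainedModel) else model
    if wl.ndim == 3:
        wl, af, risk = wl[None], af[None], risk[None]
    if max(np.abs(wl).max(), np.abs(af).max()) > 50:
        warnings.warn(
            "image intensities look like raw 8-bit values; "
            "inputs should be standardized before prediction"
        )
    logits = net.forward(wl, af, risk, train=False)
    return softmax(logits)[:, 1]
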