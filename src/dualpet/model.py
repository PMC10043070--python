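"""The dual-phase AD-positivity classifier.

Architecture (aggregated network):

* **Early-phase encoder** — two LSTM layers (hidden width D = 6), each
  followed by layer normalization; the last-time-step output passes through
  one fully connected layer with the standard block (batch normalization,
  ReLU, dropout), giving the phase feature ``h_e``.
* **Delay-phase encoder** — four fully connected layers of width 6, each with
  the standard block, giving ``h_d``.
* **First aggregation** — ``h' = block(FC(concat(h_e, h_d)))``.
* **Phase attention** — per phase i, ``x_i = concat(h_i, h')``,
  ``e_i = tanh(x_i W + b_i)``, ``a = softmax(e)``, context ``C = sum a_i h_i``.
  The attention weights form a convex combination, letting the model lean on
  whichever acquisition phase is the more reliable witness for a subject.
* **Diagnosis head** — ``softmax(FC(concat(C, h')))`` over {CN, AD}; the AD
  class probability is the AD positivity score.

Training minimizes cross-entropy + L2 (weight 0.01 on kernels) with Adam,
early stopping on validation loss (patience 200) and learning-rate decay
activated after a 100-epoch plateau. Single-phase ablations (early-only /
delay-only) share the same encoders, recipe and interface.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, log_softmax, softmax
from .datatypes import FeatureSet, MinMaxParams, TARGET_REGIONS
from .features import minmax_apply, minmax_fit

__all__ = [
    "ModelConfig",
    "ADPositivityNet",
    "TrainedModel",
    "train_model",
    "attention_pool",
]

PHASES = ("dual", "early", "delay")


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its training recipe."""

    hidden: int = 6
    lstm_layers: int = 2
    dfbb_fc_layers: int = 4
    dropout: float = 0.2
    l2: float = 0.01
    lr: float = 1e-5
    max_epochs: int = 10_000
    early_stop_patience: int = 200
    lr_decay_patience: int = 100
    lr_decay_value: float = 0.001
    lr_decay_mode: str = "time"  # "time": lr0/(1+v*k) along a plateau; "factor": lr0*v
    batch_size: int | None = None  # None = full batch
    aggregate_block: bool = True  # pass h' through BN/ReLU/dropout
    seed: int = 0

    def __post_init__(self):
        if self.hidden <= 0 or self.max_epochs <= 0 or self.lr <= 0:
            raise ValueError("hidden, max_epochs and lr must be positive")
        if self.early_stop_patience <= 0 or self.lr_decay_patience <= 0:
            raise ValueError("patience values must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def attention_pool(h_list, h_prime, W, b):
    """Phase attention as plain arrays (single subject or batch).

    x_i = concat(h_i, h'); e_i = tanh(x_i . W + b_i); a = softmax(e);
    C = sum_i a_i h_i. Returns (a, C).
    """
    hs = [np.atleast_2d(np.asarray(h, float)) for h in h_list]
    hp = np.atleast_2d(np.asarray(h_prime, float))
    W = np.asarray(W, float).reshape(-1, 1)
    b = np.asarray(b, float).reshape(-1)
    if len(b) != len(hs):
        raise ValueError("bias length must equal the number of phases")
    D = hp.shape[1]
    if W.shape[0] != 2 * D:
        raise ValueError("W must have length 2D")
    e = np.concatenate(
        [np.tanh(np.concatenate([h, hp], axis=1) @ W + b[i]) for i, h in enumerate(hs)],
        axis=1,
    )
    e = e - e.max(axis=1, keepdims=True)
    a = np.exp(e) / np.exp(e).sum(axis=1, keepdims=True)
    C = sum(a[:, i : i + 1] * h for i, h in enumerate(hs))
    if np.asarray(h_list[0]).ndim == 1:
        return a[0], C[0]
    return a, C


class _EarlyEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        D = cfg.hidden
        self.lstms = [self.add_module(nn.LSTM(6 if i == 0 else D, D, rng))
                      for i in range(cfg.lstm_layers)]
        self.lns = [self.add_module(nn.LayerNorm(D)) for _ in range(cfg.lstm_layers)]
        self.fc = self.add_module(nn.Dense(D, D, rng))
        self.bn = self.add_module(nn.BatchNorm(D))
        self.drop = self.add_module(nn.Dropout(cfg.dropout, drop_rng))

    def __call__(self, steps: list[Tensor]) -> Tensor:
        seq = steps
        for lstm, ln in zip(self.lstms, self.lns):
            seq = [ln(h) for h in lstm(seq)]
        h = seq[-1]
        return self.drop(self.bn(self.fc(h)).relu())


class _DelayEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        D = cfg.hidden
        self.layers = []
        for i in range(cfg.dfbb_fc_layers):
            fc = self.add_module(nn.Dense(6 if i == 0 else D, D, rng))
            bn = self.add_module(nn.BatchNorm(D))
            dr = self.add_module(nn.Dropout(cfg.dropout, drop_rng))
            self.layers.append((fc, bn, dr))

    def __call__(self, x: Tensor) -> Tensor:
        for fc, bn, dr in self.layers:
            x = dr(bn(fc(x)).relu())
        return x


class _Attention(nn.Module):
    def __init__(self, D: int, n_phases: int, rng):
        super().__init__()
        self.W = self.add_param(
            nn.Parameter(nn.glorot_uniform(rng, 2 * D, 1, (2 * D, 1)), kernel=True)
        )
        self.b = self.add_param(nn.Parameter(np.zeros(n_phases)))

    def __call__(self, h_list: list[Tensor], h_prime: Tensor):
        es = []
        for i, h in enumerate(h_list):
            x = concat([h, h_prime], axis=1)
            es.append((x @ self.W + self.b[i]).tanh())
        e = concat(es, axis=1)  # (B, N)
        a = softmax(e, axis=1)
        C = None
        for i, h in enumerate(h_list):
            term = a[:, i : i + 1] * h
            C = term if C is None else C + term
        return a, C


class ADPositivityNet(nn.Module):
    """The aggregated network, or a single-phase ablation of it."""

    def __init__(self, phase: str, cfg: ModelConfig):
        super().__init__()
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        self.phase = phase
        self.cfg = cfg
        root = np.random.default_rng(cfg.seed)
        init_rng, self.drop_rng, self.shuffle_rng = root.spawn(3)
        D = cfg.hidden
        if phase in ("dual", "early"):
            self.enc_e = self.add_module(_EarlyEncoder(cfg, init_rng, self.drop_rng))
        if phase in ("dual", "delay"):
            self.enc_d = self.add_module(_DelayEncoder(cfg, init_rng, self.drop_rng))
        if phase == "dual":
            self.agg = self.add_module(nn.Dense(2 * D, D, init_rng))
            self.agg_bn = self.add_module(nn.BatchNorm(D))
            self.agg_drop = self.add_module(nn.Dropout(cfg.dropout, self.drop_rng))
            self.attn = self.add_module(_Attention(D, 2, init_rng))
            self.out = self.add_module(nn.Dense(2 * D, 2, init_rng))
        else:
            self.out = self.add_module(nn.Dense(D, 2, init_rng))

    def __call__(self, tac_steps, suvr, return_state: bool = False):
        state: dict = {}
        if self.phase == "early":
            h = self.enc_e(tac_steps)
            logits = self.out(h)
            state["h_e"] = h
        elif self.phase == "delay":
            h = self.enc_d(suvr)
            logits = self.out(h)
            state["h_d"] = h
        else:
            h_e = self.enc_e(tac_steps)
            h_d = self.enc_d(suvr)
            h_prime = self.agg(concat([h_e, h_d], axis=1))
            if self.cfg.aggregate_block:
                h_prime = self.agg_drop(self.agg_bn(h_prime).relu())
            a, C = self.attn([h_e, h_d], h_prime)
            logits = self.out(concat([C, h_prime], axis=1))
            state.update(h_e=h_e, h_d=h_d, h_prime=h_prime, a=a, C=C)
        if return_state:
            return logits, state
        return logits


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _nll(logits: Tensor, y: np.ndarray) -> Tensor:
    lp = log_softmax(logits, axis=1)
    return -(lp[np.arange(len(y)), y].mean())


def _l2_penalty(net: nn.Module, weight: float) -> Tensor:
    total = Tensor(0.0)
    for p in net.parameters():
        if getattr(p, "kernel", False):
            total = total + (p**2).sum()
    return total * weight


@dataclass
class TrainedModel:
    """A trained classifier with its scaling parameters and history.

    Prediction accepts raw (unscaled) features and applies the stored
    min-max parameters, so train-time and predict-time scaling cannot drift
    apart.
    """

    net: ADPositivityNet
    phase: str
    config: ModelConfig
    mm_tac: MinMaxParams | None
    mm_suvr: MinMaxParams | None
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    n_frames: int = 0

    def _scaled_inputs(self, fs: FeatureSet):
        tac_steps = None
        suvr_t = None
        if self.phase in ("dual", "early"):
            if not np.all(np.isfinite(fs.tac)):
                raise ValueError("TAC input contains non-finite values")
            flat = fs.tac.reshape(len(fs), -1)
            scaled = minmax_apply(self.mm_tac, flat).reshape(fs.tac.shape)
            tac_steps = [Tensor(scaled[:, :, t]) for t in range(scaled.shape[2])]
        if self.phase in ("dual", "delay"):
            if not np.all(np.isfinite(fs.suvr)):
                raise ValueError("SUVr input contains non-finite values")
            suvr_t = Tensor(minmax_apply(self.mm_suvr, fs.suvr))
        return tac_steps, suvr_t

    def predict_scores(self, fs: FeatureSet) -> np.ndarray:
        """AD positivity score (softmax AD-class probability) per subject."""
        self.net.eval()
        tac_steps, suvr_t = self._scaled_inputs(fs)
        logits = self.net(tac_steps, suvr_t)
        probs = softmax(logits, axis=1).data
        return probs[:, 1]

    def predict_labels(self, fs: FeatureSet, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(fs) >= threshold).astype(int)

    def attention_weights(self, fs: FeatureSet) -> np.ndarray:
        """Per-subject phase-attention weights (dual-phase model only)."""
        if self.phase != "dual":
            raise ValueError("attention weights exist only for the dual-phase model")
        self.net.eval()
        tac_steps, suvr_t = self._scaled_inputs(fs)
        _, state = self.net(tac_steps, suvr_t, return_state=True)
        return state["a"].data

    # -- checkpoint ----------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "phase": self.phase,
            "config": asdict(self.config),
            "state": [a.tolist() for a in self.net.state_arrays()],
            "mm_tac": None if self.mm_tac is None else
                {"min": self.mm_tac.minimum.tolist(), "max": self.mm_tac.maximum.tolist()},
            "mm_suvr": None if self.mm_suvr is None else
                {"min": self.mm_suvr.minimum.tolist(), "max": self.mm_suvr.maximum.tolist()},
            "history": self.history,
            "best_epoch": self.best_epoch,
            "n_frames": self.n_frames,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = ModelConfig(**payload["config"])
        net = ADPositivityNet(payload["phase"], cfg)
        net.load_state_arrays([np.asarray(a) for a in payload["state"]])

        def mm(d):
            return None if d is None else MinMaxParams(np.asarray(d["min"]), np.asarray(d["max"]))

        return cls(
            net=net,
            phase=payload["phase"],
            config=cfg,
            mm_tac=mm(payload["mm_tac"]),
            mm_suvr=mm(payload["mm_suvr"]),
            history=payload["history"],
            best_epoch=payload["best_epoch"],
            n_frames=payload["n_frames"],
        )


def train_model(
    train: FeatureSet,
    val: FeatureSet,
    config: ModelConfig = ModelConfig(),
    phase: str = "dual",
) -> TrainedModel:
    """Train the classifier with cross-entropy + L2, Adam, early stopping.

    Min-max scaling is fitted on the training split only and stored in the
    returned model. Runs are deterministic given (data, config.seed).
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    for name, fs in (("train", train), ("validation", val)):
        if len(np.unique(fs.y)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    if set(train.ids) & set(val.ids):
        raise ValueError("train and validation sets overlap")

    net = ADPositivityNet(phase, config)
    mm_tac = mm_suvr = None
    tac_tr = tac_va = suvr_tr = suvr_va = None
    if phase in ("dual", "early"):
        mm_tac = minmax_fit(train.tac.reshape(len(train), -1))
        tac_tr = minmax_apply(mm_tac, train.tac.reshape(len(train), -1)).reshape(train.tac.shape)
        tac_va = minmax_apply(mm_tac, val.tac.reshape(len(val), -1)).reshape(val.tac.shape)
    if phase in ("dual", "delay"):
        mm_suvr = minmax_fit(train.suvr)
        suvr_tr = minmax_apply(mm_suvr, train.suvr)
        suvr_va = minmax_apply(mm_suvr, val.suvr)

    def forward(idx, tac, suvr):
        steps = None if tac is None else [Tensor(tac[idx, :, t]) for t in range(tac.shape[2])]
        sv = None if suvr is None else Tensor(suvr[idx])
        return net(steps, sv)

    opt = nn.Adam(net.parameters(), lr=config.lr)
    n = len(train)
    all_idx = np.arange(n)
    batch = config.batch_size or n
    best_val = np.inf
    best_state = net.state_arrays()
    best_epoch = -1
    history = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.max_epochs):
        net.train()
        order = net.shuffle_rng.permutation(n) if batch < n else all_idx
        epoch_losses = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            logits = forward(idx, tac_tr, suvr_tr)
            loss = _nll(logits, train.y[idx]) + _l2_penalty(net, config.l2)
            net.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        net.eval()
        val_logits = forward(np.arange(len(val)), tac_va, suvr_va)
        val_loss = float(_nll(val_logits, val.y).data)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state_arrays()
            best_epoch = epoch
            opt.lr = config.lr
        else:
            since = epoch - best_epoch
            if since >= config.lr_decay_patience:
                if config.lr_decay_mode == "time":
                    k = since - config.lr_decay_patience + 1
                    opt.lr = config.lr / (1.0 + config.lr_decay_value * k)
                else:
                    opt.lr = config.lr * config.lr_decay_value
            if since >= config.early_stop_patience:
                break

    net.load_state_arrays(best_state)
    net.eval()
    return TrainedModel(
        net=net,
        phase=phase,
        config=config,
        mm_tac=mm_tac,
        mm_suvr=mm_suvr,
        history=history,
        best_epoch=best_epoch,
        n_frames=train.tac.shape[2] if train.tac is not None else 0,
    )
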