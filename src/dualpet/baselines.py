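"""Comparison classifiers: linear SVM, shallow random forest, plain FFN.

All baselines consume the same min-max-scaled feature matrices and splits as
the aggregated model, so performance comparisons differ only in the
classifier. SVM and RF are the established scikit-learn implementations
(linear kernel; depth-2 forest with 1000 trees and Gini impurity); the FFN is
two hidden layers of six units with the standard block, trained with the same
recipe as the main model.

Non-sequential baselines see the dynamic TAC either flattened row-major
(6 x 27 -> 162 features) or summarized as the 2-7 min static early SUVr
(6 features); the static mode is the default for early-phase input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from ._autodiff import Tensor, log_softmax, softmax
from .datatypes import FeatureSet
from .features import EARLY_STATIC_WINDOW, minmax_apply, minmax_fit
from .model import ModelConfig

__all__ = ["BaselineConfig", "fit_baseline", "phase_matrix", "static_early_suvr"]


@dataclass
class BaselineConfig:
    kind: str  # "svm_linear" | "random_forest" | "ffn"
    seed: int = 0
    rf_max_depth: int = 2
    rf_n_estimators: int = 1000
    ffn_hidden_layers: int = 2
    ffn_width: int = 6

    def __post_init__(self):
        if self.kind not in ("svm_linear", "random_forest", "ffn"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def static_early_suvr(fs: FeatureSet, window=EARLY_STATIC_WINDOW,
                      frame_schedule=None) -> np.ndarray:
    """Duration-weighted 2-7 min average of each region's TAC (static eFBB SUVr).

    If the acquisition schedule is given, frames are weighted by their true
    durations; otherwise durations are approximated from midpoint spacing.
    """
    mid = fs.frame_mid
    sel = (mid >= window[0]) & (mid <= window[1])
    if not sel.any():
        raise ValueError("static window selects no frames")
    if frame_schedule is not None:
        w = np.asarray(frame_schedule, float)[sel, 1]
    else:
        w = np.gradient(mid)[sel]
    return np.tensordot(fs.tac[:, :, sel], w, axes=([2], [0])) / w.sum()


def phase_matrix(fs: FeatureSet, phase: str, early_mode: str = "static") -> np.ndarray:
    """Raw (unscaled) feature matrix for a baseline.

    phase: "early" | "delay" | "dual"; early_mode: "static" (6 features) or
    "tac" (row-major flattened 6 x T = 162 features).
    """
    if phase == "delay":
        return fs.suvr.copy()
    if early_mode == "static":
        early = static_early_suvr(fs)
    elif early_mode == "tac":
        early = fs.tac.reshape(len(fs), -1)
    else:
        raise ValueError("early_mode must be 'static' or 'tac'")
    if phase == "early":
        return early
    if phase == "dual":
        return np.hstack([early, fs.suvr])
    raise ValueError("phase must be early, delay or dual")


class _SklearnBaseline:
    def __init__(self, est, kind: str):
        self.est = est
        self.kind = kind

    def score(self, X: np.ndarray) -> np.ndarray:
        """Continuous AD score in (0, 1)."""
        if self.kind == "svm_linear":
            # logistic link on the signed margin; rank metrics are invariant
            return 1.0 / (1.0 + np.exp(-self.est.decision_function(X)))
        return self.est.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0.5).astype(int)


class _FFNBaseline:
    """2 hidden layers x `width` with FC -> BN -> ReLU -> dropout, softmax head."""

    def __init__(self, n_features: int, config: BaselineConfig, train_cfg: ModelConfig):
        self.cfg = train_cfg
        root = np.random.default_rng(train_cfg.seed)
        init_rng, self.drop_rng, self.shuffle_rng = root.spawn(3)
        net = nn.Module()
        self.blocks = []
        w = config.ffn_width
        for i in range(config.ffn_hidden_layers):
            fc = net.add_module(nn.Dense(n_features if i == 0 else w, w, init_rng))
            bn = net.add_module(nn.BatchNorm(w))
            dr = net.add_module(nn.Dropout(train_cfg.dropout, self.drop_rng))
            self.blocks.append((fc, bn, dr))
        self.out = net.add_module(nn.Dense(w, 2, init_rng))
        self.net = net

    def _forward(self, X: np.ndarray) -> Tensor:
        x = Tensor(X)
        for fc, bn, dr in self.blocks:
            x = dr(bn(fc(x)).relu())
        return self.out(x)

    def fit(self, X, y, Xval, yval):
        cfg = self.cfg
        opt = nn.Adam(self.net.parameters(), lr=cfg.lr)
        n = len(X)
        batch = cfg.batch_size or n
        best_val, best_state, best_epoch = np.inf, self.net.state_arrays(), -1
        for epoch in range(cfg.max_epochs):
            self.net.train()
            order = self.shuffle_rng.permutation(n) if batch < n else np.arange(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                logits = self._forward(X[idx])
                lp = log_softmax(logits, axis=1)
                loss = -(lp[np.arange(len(idx)), y[idx]].mean())
                for p in self.net.parameters():
                    if getattr(p, "kernel", False):
                        loss = loss + (p**2).sum() * cfg.l2
                self.net.zero_grad()
                loss.backward()
                opt.step()
            self.net.eval()
            vl = float(
                -(log_softmax(self._forward(Xval), axis=1)[np.arange(len(yval)), yval].mean()).data
            )
            if vl < best_val - 1e-12:
                best_val, best_state, best_epoch = vl, self.net.state_arrays(), epoch
                opt.lr = cfg.lr
            else:
                since = epoch - best_epoch
                if since >= cfg.lr_decay_patience:
                    if cfg.lr_decay_mode == "time":
                        opt.lr = cfg.lr / (1.0 + cfg.lr_decay_value * (since - cfg.lr_decay_patience + 1))
                    else:
                        opt.lr = cfg.lr * cfg.lr_decay_value
                if since >= cfg.early_stop_patience:
                    break
        self.net.load_state_arrays(best_state)
        self.net.eval()
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        self.net.eval()
        return softmax(self._forward(X), axis=1).data[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0.5).astype(int)


def fit_baseline(
    config: BaselineConfig,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    train_cfg: ModelConfig | None = None,
):
    """Fit one baseline on min-max-scaled features.

    The FFN uses (X_val, y_val) for early stopping, mirroring the main model's
    recipe; SVM and RF ignore the validation data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if config.kind == "svm_linear":
        est = SVC(kernel="linear", random_state=config.seed)
        est.fit(X, y)
        return _SklearnBaseline(est, config.kind)
    if config.kind == "random_forest":
        est = RandomForestClassifier(
            max_depth=config.rf_max_depth,
            n_estimators=config.rf_n_estimators,
            criterion="gini",
            random_state=config.seed,
        )
        est.fit(X, y)
        return _SklearnBaseline(est, config.kind)
    # FFN
    if X_val is None or y_val is None:
        raise ValueError("the FFN baseline requires a validation set for early stopping")
    tcfg = train_cfg or ModelConfig(seed=config.seed)
    ffn = _FFNBaseline(X.shape[1], config, tcfg)
    return ffn.fit(X, y, np.asarray(X_val, float), np.asarray(y_val, int))


def scale_train_apply(train_X: np.ndarray, *others):
    """Fit min-max on the training matrix, apply to it and any other splits."""
    params = minmax_fit(train_X)
    return (params,) + tuple(minmax_apply(params, X) for X in (train_X,) + others)
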