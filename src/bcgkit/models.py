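"""The four classifier families compared on the BCG feature tables.

* :class:`FCLSTMClassifier` — two fully connected layers (512, 256 units with
  ReLU after the first) feeding a two-layer, 128-unit LSTM whose final hidden
  state passes through a 64-unit layer, dropout 0.1 and a linear output head.
  Trained with cross-entropy, Adam at lr 0.001, and a step schedule that
  multiplies the learning rate by 0.1 every 10 epochs.
* :class:`TransformerClassifier` — linear embedding to 256 dimensions,
  dropout 0.1, a three-layer encoder with four attention heads and 512-unit
  feed-forward blocks, mean pooling over tokens and a linear head. Trained
  with Adam at lr 0.0005 and a plateau schedule (factor 0.5, patience 3,
  monitored on training loss).
* stacking — random forest, gradient boosting and XGBoost bases whose
  out-of-fold probability predictions train a logistic-regression meta-model.
* soft voting — the same three bases with uniform probability averaging.

Both neural models treat the per-segment feature vector as a single token
(sequence length 1) by default; ``seq_len`` splits the 256-dimensional
projection into that many tokens instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from xgboost import XGBClassifier

from bcgkit.nn import (
    Adam,
    Dropout,
    Linear,
    LSTM,
    Module,
    ReduceLROnPlateau,
    StepLR,
    Tensor,
    TransformerEncoderLayer,
    cross_entropy,
)

__all__ = [
    "TrainConfig",
    "EnsembleConfig",
    "FCLSTMClassifier",
    "TransformerClassifier",
    "train_fclstm",
    "train_transformer",
    "fit_stacking",
    "fit_voting",
    "fit_xgb",
    "predict_proba",
    "make_model",
    "MODEL_NAMES",
]


@dataclass
class TrainConfig:
    """Optimisation settings for the neural classifiers."""

    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    scheduler: str = "step"  # "step" | "plateau"
    step_size: int = 10
    step_gamma: float = 0.1
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.scheduler not in ("step", "plateau"):
            raise ValueError("scheduler must be 'step' or 'plateau'")


@dataclass
class EnsembleConfig:
    """Base-learner and meta-learner settings for stacking / voting."""

    n_estimators: int = 100
    max_depth: int | None = None
    learning_rate: float = 0.1  # boosting models
    stacking_folds: int = 5
    seed: int = 0
    base_learners: tuple = ("random_forest", "gradient_boosting", "xgboost")

    def __post_init__(self) -> None:
        if len(self.base_learners) < 2:
            raise ValueError("need at least 2 base learners")
        if self.stacking_folds < 2:
            raise ValueError("stacking_folds must be >= 2")


# --------------------------------------------------------------- neural nets


class FCLSTMClassifier(Module):
    """FC(512) -> ReLU -> FC(256) -> 2-layer LSTM(128) -> FC(64) -> Dropout(0.1)
    -> FC(n_classes)."""

    def __init__(self, n_features: int, n_classes: int = 2, seq_len: int = 1,
                 dropout: float = 0.1, seed: int = 0):
        super().__init__()
        if 256 % seq_len != 0:
            raise ValueError("seq_len must divide 256")
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.n_classes = n_classes
        self.seq_len = seq_len
        self.fc1 = Linear(n_features, 512, rng)
        self.fc2 = Linear(512, 256, rng)
        self.lstm = LSTM(256 // seq_len, 128, num_layers=2, rng=rng)
        self.fc3 = Linear(128, 64, rng)
        self.drop = Dropout(dropout, rng)
        self.fc4 = Linear(64, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """Class scores (logits) for a batch ``x`` of shape (B, n_features)."""
        h2 = self.fc2(self.fc1(x).relu())
        tokens = h2.reshape(h2.shape[0], self.seq_len, 256 // self.seq_len)
        h_final = self.lstm(tokens)
        return self.fc4(self.drop(self.fc3(h_final)))


class TransformerClassifier(Module):
    """Linear embed(256) -> Dropout(0.1) -> 3x encoder(4 heads, ff 512)
    -> mean pool -> FC(n_classes)."""

    def __init__(self, n_features: int, n_classes: int = 2, seq_len: int = 1,
                 d_model: int = 256, n_heads: int = 4, n_layers: int = 3,
                 d_ff: int = 512, dropout: float = 0.1, seed: int = 0):
        super().__init__()
        if n_features % seq_len != 0:
            raise ValueError("seq_len must divide n_features")
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.n_classes = n_classes
        self.seq_len = seq_len
        self.d_model = d_model
        self.embed = Linear(n_features // seq_len, d_model, rng)
        self.drop = Dropout(dropout, rng)
        self.layers = [
            TransformerEncoderLayer(d_model, n_heads, d_ff, dropout, rng)
            for _ in range(n_layers)
        ]

        self.head = Linear(d_model, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        batch = x.shape[0]
        tokens = x.reshape(batch, self.seq_len, self.n_features // self.seq_len)
        h = self.drop(self.embed(tokens))
        for layer in self.layers:
            h = layer(h)
        pooled = h.mean(axis=1)  # mean across the sequence dimension
        return self.head(pooled)


def _train_neural(model: Module, X: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    """Mini-batch Adam training shared by both neural models."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream, distinct from init
    opt = Adam(model.parameters(), lr=cfg.lr)
    if cfg.scheduler == "step":
        sched = StepLR(opt, step_size=cfg.step_size, gamma=cfg.step_gamma)
    else:
        sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                  patience=cfg.plateau_patience)
    n = X.shape[0]
    loss_history: list[float] = []
    lr_history: list[float] = []
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            scores = model(Tensor(X[idx]))
            loss = cross_entropy(scores, y[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
        epoch_loss = float(np.sum(epoch_losses) / n)
        loss_history.append(epoch_loss)
        lr_history.append(opt.lr)
        sched.step(epoch_loss)
    model.eval()
    model.loss_history_ = loss_history
    model.lr_history_ = lr_history
    model.classes_ = np.unique(y)
    return model


def train_fclstm(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
                 seq_len: int = 1) -> FCLSTMClassifier:
    """Fit the FC+LSTM classifier; deterministic given ``cfg.seed``.

    Features should be standardized (zero mean, unit variance) beforehand.
    """
    cfg = cfg or TrainConfig(lr=0.001, scheduler="step")
    model = FCLSTMClassifier(np.asarray(X).shape[1], seq_len=seq_len, seed=cfg.seed)
    return _train_neural(model, X, y, cfg)


def train_transformer(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
                      seq_len: int = 1) -> TransformerClassifier:
    """Fit the Transformer classifier; deterministic given ``cfg.seed``."""
    cfg = cfg or TrainConfig(lr=0.0005, scheduler="plateau")
    model = TransformerClassifier(np.asarray(X).shape[1], seq_len=seq_len, seed=cfg.seed)
    return _train_neural(model, X, y, cfg)


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def neural_predict_proba(model: Module, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities in eval mode (dropout disabled)."""
    model.eval()
    scores = model(Tensor(np.asarray(X, dtype=float)))
    return _softmax(scores.data)


# ----------------------------------------------------------------- ensembles


def _build_bases(cfg: EnsembleConfig) -> list[tuple[str, object]]:
    registry = {
        "random_forest": RandomForestClassifier(
            n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
            random_state=cfg.seed,
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=cfg.n_estimators, learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
        ),
        "xgboost": XGBClassifier(
            n_estimators=cfg.n_estimators, learning_rate=cfg.learning_rate,
            random_state=cfg.seed, eval_metric="logloss", verbosity=0,
        ),
    }
    return [(name, registry[name]) for name in cfg.base_learners]


class StackingModel:
    """Stacking: logistic regression over out-of-fold base probabilities.

    Base learners are refitted on the full training set for inference; the
    meta-learner only ever sees cross-fitted predictions, so it is never
    trained on probabilities produced by a model that saw the same rows.
    """

    def __init__(self, cfg: EnsembleConfig):
        self.cfg = cfg
        self.bases: list[tuple[str, object]] | None = None
        self.meta: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackingModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        cv = StratifiedKFold(self.cfg.stacking_folds, shuffle=True,
                             random_state=self.cfg.seed)
        self.bases = _build_bases(self.cfg)
        oof = [
            cross_val_predict(est, X, y, cv=cv, method="predict_proba")
            for _, est in self.bases
        ]
        meta_features = np.hstack(oof)  # n x (n_bases * n_classes)
        self.meta = LogisticRegression(max_iter=1000, random_state=self.cfg.seed)
        self.meta.fit(meta_features, y)
        for _, est in self.bases:
            est.fit(X, y)
        self.classes_ = np.unique(y)
        return self

    def _meta_features(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([est.predict_proba(X) for _, est in self.bases])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.meta is None:
            raise RuntimeError("model is not fitted")
        return self.meta.predict_proba(self._meta_features(np.asarray(X, float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class VotingModel:
    """Soft voting: uniform average of base probabilities, argmax label
    (ties resolved toward the lower class index)."""

    def __init__(self, cfg: EnsembleConfig):
        self.cfg = cfg
        self.bases: list[tuple[str, object]] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VotingModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.bases = _build_bases(self.cfg)
        for _, est in self.bases:
            est.fit(X, y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.bases is None:
            raise RuntimeError("model is not fitted")
        probs = [est.predict_proba(np.asarray(X, float)) for _, est in self.bases]
        return np.mean(probs, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax returns the first maximum -> ties break toward class 0
        return np.argmax(self.predict_proba(X), axis=1)


def fit_stacking(X: np.ndarray, y: np.ndarray,
                 cfg: EnsembleConfig | None = None) -> StackingModel:
    return StackingModel(cfg or EnsembleConfig()).fit(X, y)


def fit_voting(X: np.ndarray, y: np.ndarray,
               cfg: EnsembleConfig | None = None) -> VotingModel:
    return VotingModel(cfg or EnsembleConfig()).fit(X, y)


def fit_xgb(X: np.ndarray, y: np.ndarray,
            cfg: EnsembleConfig | None = None) -> XGBClassifier:
    """Standalone XGBoost baseline with the ensemble hyperparameters."""
    cfg = cfg or EnsembleConfig()
    est = XGBClassifier(n_estimators=cfg.n_estimators, learning_rate=cfg.learning_rate,
                        random_state=cfg.seed, eval_metric="logloss", verbosity=0)
    est.fit(np.asarray(X, float), np.asarray(y, int))
    return est


# ------------------------------------------------------------ uniform facade


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Probability matrix (n, n_classes) for any fitted bcgkit model.

    Neural models go through softmax in eval mode; sklearn-style models use
    their own ``predict_proba``. Rows sum to 1.
    """
    if isinstance(model, Module):
        return neural_predict_proba(model, X)
    if hasattr(model, "predict_proba"):
        if not hasattr(model, "classes_"):
            raise RuntimeError("model is not fitted")
        return model.predict_proba(np.asarray(X, float))
    raise TypeError(f"unsupported model type: {type(model)!r}")


MODEL_NAMES = ("fclstm", "transformer", "stacking", "voting", "xgb")


class _NeuralEstimator:
    """sklearn-style fit/predict facade over the neural training loops."""

    def __init__(self, kind: str, train_cfg: TrainConfig):
        self.kind = kind
        self.train_cfg = train_cfg
        self.model_: Module | None = None

    def fit(self, X, y):
        trainer = train_fclstm if self.kind == "fclstm" else train_transformer
        self.model_ = trainer(X, y, self.train_cfg)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return neural_predict_proba(self.model_, X)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


def make_model(name: str, seed: int = 0,
               train_cfg: TrainConfig | None = None,
               ensemble_cfg: EnsembleConfig | None = None):
    """Unfitted estimator (``fit`` / ``predict_proba`` / ``predict``) by name.

    Names: ``fclstm``, ``transformer``, ``stacking``, ``voting``, ``xgb``.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if name == "fclstm":
        cfg = train_cfg or TrainConfig(lr=0.001, scheduler="step", seed=seed)
        return _NeuralEstimator("fclstm", cfg)
    if name == "transformer":
        cfg = train_cfg or TrainConfig(lr=0.0005, scheduler="plateau", seed=seed)
        return _NeuralEstimator("transformer", cfg)
    ecfg = ensemble_cfg or EnsembleConfig(seed=seed)
    if name == "stacking":
        return StackingModel(ecfg)
    if name == "voting":
        return VotingModel(ecfg)
    return XGBClassifier(n_estimators=ecfg.n_estimators, learning_rate=ecfg.learning_rate,
                         random_state=ecfg.seed, eval_metric="logloss", verbosity=0)
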