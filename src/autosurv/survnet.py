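"""Prognostic network: latent features + clinical covariates -> prognostic index.

A single tanh hidden layer (with dropout) followed by a bias-free linear
output produces the prognostic index PI, an estimate of the log relative
hazard.  Training minimizes the average negative log Cox partial likelihood

    l = -(1/n_events) sum_{i: E_i=1} [ PI_i - log sum_{j: T_j >= T_i} e^{PI_j} ]
        + lambda2 * ||theta||^2

with Breslow-style risk sets {j: T_j >= T_i} (patient i included; censored
patients tied at T_i included).  The output has no bias because a constant
shift of PI cancels inside the partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from ._nn import Adam, Dense, Dropout, Param, Sequential, Tanh, add_l2_gradients, l2_penalty

__all__ = ["SurvConfig", "LFSurv", "cox_loss"]


@dataclass
class SurvConfig:
    hidden_width: int = 16
    dropout_rate: float = 0.2
    lambda2: float = 1e-3
    learning_rate: float = 0.01
    epochs: int = 400

    def __post_init__(self):
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def _risk_matrix(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows: event subjects; columns: all subjects; 1 where T_j >= T_i."""
    ev = np.flatnonzero(events == 1)
    if ev.size == 0:
        raise ValueError("partial likelihood undefined: no observed events")
    return ev, (times[None, :] >= times[ev, None]).astype(float)


def cox_loss(pi, times, events, lambda2: float = 0.0, params: list[Param] | None = None) -> float:
    """Average negative log partial likelihood, plus optional L2 penalty."""
    pi = np.asarray(pi, dtype=float).reshape(-1)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ev, risk = _risk_matrix(t, e)
    lse = logsumexp(np.where(risk > 0, pi[None, :], -np.inf), axis=1)
    loss = -np.mean(pi[ev] - lse)
    if params is not None:
        loss += l2_penalty(params, lambda2)
    return float(loss)


def _cox_loss_grad(pi: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss (without penalty) and gradient w.r.t. PI."""
    ev, risk = _risk_matrix(times, events)
    masked = np.where(risk > 0, pi[None, :], -np.inf)
    lse = logsumexp(masked, axis=1)
    loss = -np.mean(pi[ev] - lse)
    w = softmax(masked, axis=1)  # softmax over each risk set
    grad = w.sum(axis=0)
    grad[ev] -= 1.0
    return float(loss), grad / ev.size


class LFSurv:
    """One-hidden-layer Cox partial-likelihood network."""

    def __init__(self, n_features: int, config: SurvConfig | None = None, seed: int = 0):
        self.config = config or SurvConfig()
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        self._dropout = Dropout(self.config.dropout_rate)
        self.net = Sequential(
            Dense(n_features, self.config.hidden_width, rng, name="hidden"),
            Tanh(),
            self._dropout,
            Dense(self.config.hidden_width, 1, rng, bias=False, name="output"),
        )
        self.feature_names: list[str] | None = None

    # -- forward ------------------------------------------------------------
    def forward(self, features, training: bool = False) -> np.ndarray:
        X = self._check_features(features)
        return self.net.forward(X, training=training)[:, 0]

    predict = forward

    def _check_features(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if self.feature_names is not None:
                if list(features.columns) != self.feature_names:
                    raise ValueError(
                        "feature column order differs from training order; expected "
                        f"{self.feature_names[:5]}..., got {list(features.columns)[:5]}..."
                    )
            features = features.to_numpy(dtype=float)
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) features, got {X.shape}")
        return X

    # -- training -----------------------------------------------------------
    def fit(
        self,
        features,
        times,
        events,
        seed: int = 0,
        verbose: bool = False,
    ) -> pd.DataFrame:
        """Full-batch Adam on the regularized partial likelihood.

        Risk sets are global, so the loss is computed over the full cohort at
        every step (a mini-batch Cox loss would be biased).
        """
        if isinstance(features, pd.DataFrame):
            self.feature_names = list(features.columns)
        X = self._check_features(features)
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._dropout.rng = rng
        params = self.net.params()
        opt = Adam(params, lr=cfg.learning_rate)
        history = []
        for epoch in range(cfg.epochs):
            opt.zero_grad()
            pi = self.net.forward(X, training=True)[:, 0]
            loss, dpi = _cox_loss_grad(pi, t, e)
            loss += l2_penalty(params, cfg.lambda2)
            self.net.backward(dpi[:, None])
            add_l2_gradients(params, cfg.lambda2)
            opt.step()
            history.append({"epoch": epoch, "loss": loss})
            if verbose and epoch % 50 == 0:
                print(f"epoch {epoch}: loss {loss:.4f}")
        return pd.DataFrame(history)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {p.name: p.value for p in self.net.params()}
        np.savez(
            path,
            __meta__=np.array(
                [repr({
                    "n_features": self.n_features,
                    "config": vars(self.config),
                    "feature_names": self.feature_names,
                })],
                dtype=object,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "LFSurv":
        data = np.load(path, allow_pickle=True)
        meta = eval(data["__meta__"][0])  # noqa: S307 - our own checkpoint format
        model = cls(meta["n_features"], SurvConfig(**meta["config"]))
        model.feature_names = meta["feature_names"]
        for p in model.net.params():
            p.value[...] = data[p.name]
        return model
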