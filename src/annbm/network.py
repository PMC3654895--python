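"""Three-layer feed-forward network trained with resilient backpropagation.

Topology is input -> hidden -> single output, sigmoid activations on both
the hidden and output layers; the output approximates the log-scaled
binding affinity in [0, 1].  Training minimises the mean squared error

    E = sum_i (o_i - t_i)^2 / (2 N)

over the full batch each epoch, with RPROP weight updates: every weight
carries its own step size, multiplied by eta_plus (default 1.2) whenever
the error gradient keeps its sign between epochs and by eta_minus
(default 0.5) when it flips, clamped to [delta_min, delta_max]; the
weight then moves one step against the current gradient sign, ignoring
its magnitude.  The default variant performs no weight backtracking and
clears the gradient-sign memory after a flip; set ``rprop_variant`` to
``"rprop+"`` for the backtracking variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)


def sigmoid(x):
    """Logistic 1/(1+exp(-x)), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass
class NetworkConfig:
    n_input: int
    n_hidden: int = 9
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    max_epochs: int = 2000
    patience: int = 50
    val_fraction: float = 0.2
    rprop_variant: str = "rprop-"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta_minus < 1 < self.eta_plus:
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not self.delta_min < self.delta_init < self.delta_max:
            raise ValueError("require delta_min < delta_init < delta_max")
        if self.rprop_variant not in ("rprop-", "rprop+"):
            raise ValueError(f"unknown variant {self.rprop_variant!r}")


@dataclass
class TrainingTrace:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


class Network:
    """Weights plus per-weight RPROP state.

    ``weights_ih``: (n_hidden, n_input+1), last column is the hidden bias;
    ``weights_ho``: (1, n_hidden+1), last entry is the output bias.
    """

    def __init__(self, config: NetworkConfig, rng=None):
        self.config = config
        rng = np.random.default_rng(config.seed) if rng is None else rng
        self.weights_ih = rng.uniform(-0.5, 0.5,
                                      (config.n_hidden, config.n_input + 1))
        self.weights_ho = rng.uniform(-0.5, 0.5, (1, config.n_hidden + 1))
        self.reset_rprop_state()

    def reset_rprop_state(self) -> None:
        self.delta_ih = np.full_like(self.weights_ih, self.config.delta_init)
        self.delta_ho = np.full_like(self.weights_ho, self.config.delta_init)
        self.prev_grad_ih = np.zeros_like(self.weights_ih)
        self.prev_grad_ho = np.zeros_like(self.weights_ho)
        self.prev_step_ih = np.zeros_like(self.weights_ih)
        self.prev_step_ho = np.zeros_like(self.weights_ho)

    # -- forward ----------------------------------------------------------

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        return sigmoid(Xb @ self.weights_ih.T)

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.n_input:
            raise ValueError(f"feature length {X.shape[1]} != configured "
                             f"input size {self.config.n_input}")
        H = self._hidden(X)
        Hb = np.hstack([H, np.ones((H.shape[0], 1))])
        return sigmoid(Hb @ self.weights_ho.T)[:, 0]

    def forward(self, features) -> float:
        return float(self.forward_batch(np.asarray(features)[None, :])[0])

    # -- backprop ---------------------------------------------------------

    def gradients(self, X: np.ndarray, t: np.ndarray):
        """Exact gradients of E = sum (o-t)^2 / (2N) w.r.t. both layers."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.asarray(t, dtype=float).ravel()
        if X.shape[0] == 0:
            raise ValueError("empty batch")
        if X.shape[1] != self.config.n_input:
            raise ValueError(f"feature length {X.shape[1]} != configured "
                             f"input size {self.config.n_input}")
        n = X.shape[0]
        Xb = np.hstack([X, np.ones((n, 1))])
        H = sigmoid(Xb @ self.weights_ih.T)          # (n, n_hidden)
        Hb = np.hstack([H, np.ones((n, 1))])
        o = sigmoid(Hb @ self.weights_ho.T)[:, 0]    # (n,)

        d_out = (o - t) * o * (1.0 - o) / n          # dE/dz_out
        g_ho = (d_out[None, :] @ Hb)                 # (1, n_hidden+1)
        d_hid = (d_out[:, None] * self.weights_ho[:, :-1]) * H * (1.0 - H)
        g_ih = d_hid.T @ Xb                          # (n_hidden, n_input+1)
        return g_ih, g_ho

    def mse(self, X: np.ndarray, t: np.ndarray) -> float:
        o = self.forward_batch(X)
        t = np.asarray(t, dtype=float).ravel()
        return float(np.mean((o - t) ** 2))

    # -- RPROP ------------------------------------------------------------

    def rprop_step(self, g_ih: np.ndarray, g_ho: np.ndarray) -> None:
        """One resilient-backpropagation update on both layers, in place."""
        for w, delta, gp, g, sp in (
                (self.weights_ih, self.delta_ih, self.prev_grad_ih, g_ih,
                 self.prev_step_ih),
                (self.weights_ho, self.delta_ho, self.prev_grad_ho, g_ho,
                 self.prev_step_ho)):
            cfg = self.config
            prod = gp * g
            grew = prod > 0
            flipped = prod < 0
            delta[grew] = np.minimum(delta[grew] * cfg.eta_plus,
                                     cfg.delta_max)
            delta[flipped] = np.maximum(delta[flipped] * cfg.eta_minus,
                                        cfg.delta_min)
            if cfg.rprop_variant == "rprop+":
                step = -np.sign(g) * delta
                step[flipped] = -sp[flipped]     # backtrack
                w += step
                sp[:] = step
                gp[:] = g
                gp[flipped] = 0.0
            else:
                step = -np.sign(g) * delta
                w += step
                sp[:] = step
                gp[:] = g
                gp[flipped] = 0.0

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "weights_ih": self.weights_ih.tolist(),
            "weights_ho": self.weights_ho.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Network":
        net = cls(NetworkConfig(**payload["config"]))
        net.weights_ih = np.array(payload["weights_ih"], dtype=float)
        net.weights_ho = np.array(payload["weights_ho"], dtype=float)
        net.reset_rprop_state()
        return net


def _split(n: int, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    if val_fraction > 0:
        n_val = max(1, min(n - 1, n_val))
    return idx[n_val:], idx[:n_val]


def train(X, t, config: NetworkConfig) -> tuple[Network, TrainingTrace]:
    """Full-batch RPROP training with early stopping.

    A ``val_fraction`` split (seeded) monitors generalisation; training
    stops when validation MSE has not improved for ``patience`` epochs or
    at ``max_epochs``, and the best-validation weights are restored.
    Deterministic for a fixed config seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("targets must lie in [0, 1]")
    if np.ptp(t) == 0:
        logger.warning("all training targets identical; model will be flat")

    rng = np.random.default_rng(config.seed)
    net = Network(config, rng=rng)
    tr_idx, va_idx = _split(X.shape[0], config.val_fraction, rng)
    Xtr, ttr = X[tr_idx], t[tr_idx]
    Xva, tva = (X[va_idx], t[va_idx]) if len(va_idx) else (Xtr, ttr)

    trace = TrainingTrace()
    best = (np.inf, None, None)
    since_best = 0
    for epoch in range(config.max_epochs):
        g_ih, g_ho = net.gradients(Xtr, ttr)
        net.rprop_step(g_ih, g_ho)
        trace.train_mse.append(net.mse(Xtr, ttr))
        val = net.mse(Xva, tva)
        trace.val_mse.append(val)
        if val < best[0]:
            best = (val, net.weights_ih.copy(), net.weights_ho.copy())
            trace.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                trace.stop_reason = "patience"
                break
    else:
        trace.stop_reason = "max_epochs"
    if best[1] is not None:
        net.weights_ih, net.weights_ho = best[1], best[2]
    return net, trace


def select_hidden_size(X, t, config: NetworkConfig,
                       candidates=range(2, 13)) -> int:
    """Pick the hidden-layer size minimising validation MSE.

    Each candidate is trained on the same seeded split; ties break toward
    the smaller network.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("no candidate hidden sizes")
    best_size, best_mse = None, np.inf
    for n_hidden in candidates:
        cfg = NetworkConfig(**{**asdict(config), "n_hidden": n_hidden})
        net, trace = train(X, t, cfg)
        val = min(trace.val_mse)
        logger.info("hidden=%d validation MSE=%.5f", n_hidden, val)
        if val < best_mse:
            best_size, best_mse = n_hidden, val
    return best_size
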