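"""Compact numpy implementations of the 1-D CNN and LSTM regressors.

Both networks read the feature vector of a sample as a length-J sequence with
one channel, train full-batch with stochastic gradient descent with momentum
(SGDM, learning rate 0.01, momentum 0.9), use a 20% dropout during training,
and standardize inputs and target internally.  The CNN uses a single valid
convolution with kernel size ceil(J/2) and ReLU followed by a dense output;
the LSTM uses one recurrent layer read out at the last step.  These are
deliberately small architectures for tables of a few dozen screened features,
not image networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _standardize_fit(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _SGDM:
    """Momentum SGD over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, v, g in zip(self.params, self.vel, grads):
            v *= self.momentum
            v -= self.lr * g
            p += v


@dataclass
class CNN1DRegressor:
    """One-block 1-D convolutional regressor."""

    n_filters: int = 8
    dropout: float = 0.2
    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 300
    seed: int = 42

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNN1DRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        self._xmu, self._xsd = _standardize_fit(X)
        self._ymu, self._ysd = float(y.mean()), float(y.std()) or 1.0
        Xs = (X - self._xmu) / self._xsd
        ys = (y - self._ymu) / self._ysd
        B, J = Xs.shape
        k = max(1, int(np.ceil(J / 2)))
        L = J - k + 1
        F = self.n_filters
        W1 = rng.normal(0, np.sqrt(2.0 / k), (F, k))
        b1 = np.zeros(F)
        W2 = rng.normal(0, np.sqrt(1.0 / (L * F)), L * F)
        b2 = np.zeros(1)
        opt = _SGDM([W1, b1, W2, b2], self.lr, self.momentum)
        keep = 1.0 - self.dropout
        for _ in range(self.epochs):
            Xc = sliding_window_view(Xs, k, axis=1)       # (B, L, k)
            z = Xc @ W1.T + b1                            # (B, L, F)
            relu = np.maximum(z, 0.0)
            if self.dropout > 0:
                mask = (rng.random(relu.shape) < keep) / keep
                act = relu * mask
            else:
                mask = 1.0
                act = relu
            flat = act.reshape(B, -1)
            pred = flat @ W2 + b2[0]
            err = pred - ys
            dpred = 2.0 * err / B
            gW2 = flat.T @ dpred
            gb2 = np.array([dpred.sum()])
            dflat = np.outer(dpred, W2)
            dact = dflat.reshape(B, L, F) * mask
            dz = dact * (z > 0)
            gW1 = np.einsum("blf,blk->fk", dz, Xc)
            gb1 = dz.sum(axis=(0, 1))
            opt.step([gW1, gb1, gW2, gb2])
        self._params = (W1, b1, W2, b2, k)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2, k = self._params
        Xs = (np.asarray(X, dtype=float) - self._xmu) / self._xsd
        Xc = sliding_window_view(Xs, k, axis=1)
        act = np.maximum(Xc @ W1.T + b1, 0.0)
        pred = act.reshape(Xs.shape[0], -1) @ W2 + b2[0]
        return pred * self._ysd + self._ymu


@dataclass
class LSTMRegressor:
    """Single-layer LSTM read out at the final step."""

    hidden: int = 16
    dropout: float = 0.2
    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 300
    seed: int = 42

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        self._xmu, self._xsd = _standardize_fit(X)
        self._ymu, self._ysd = float(y.mean()), float(y.std()) or 1.0
        Xs = (X - self._xmu) / self._xsd
        ys = (y - self._ymu) / self._ysd
        B, J = Xs.shape
        H = self.hidden
        s = np.sqrt(1.0 / H)
        Wx = rng.normal(0, s, (1, 4 * H))
        Wh = rng.normal(0, s, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        wo = rng.normal(0, s, H)
        bo = np.zeros(1)
        opt = _SGDM([Wx, Wh, b, wo, bo], self.lr, self.momentum)
        keep = 1.0 - self.dropout
        sl = [slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H), slice(3 * H, 4 * H)]
        for _ in range(self.epochs):
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            cache = []
            for t in range(J):
                xt = Xs[:, t:t + 1]
                z = xt @ Wx + h @ Wh + b
                i, f, g, o = (_sigmoid(z[:, sl[0]]), _sigmoid(z[:, sl[1]]),
                              np.tanh(z[:, sl[2]]), _sigmoid(z[:, sl[3]]))
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                cache.append((xt, h, c, i, f, g, o, tc))
                h, c = h_new, c_new
            if self.dropout > 0:
                mask = (rng.random(h.shape) < keep) / keep
                hd = h * mask
            else:
                mask = 1.0
                hd = h
            pred = hd @ wo + bo[0]
            err = pred - ys
            dpred = 2.0 * err / B
            gwo = hd.T @ dpred
            gbo = np.array([dpred.sum()])
            dh = np.outer(dpred, wo) * mask
            dc = np.zeros((B, H))
            gWx = np.zeros_like(Wx)
            gWh = np.zeros_like(Wh)
            gb = np.zeros_like(b)
            for t in reversed(range(J)):
                xt, h_prev, c_prev, i, f, g, o, tc = cache[t]
                do = dh * tc
                dc = dc + dh * o * (1 - tc**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.empty((B, 4 * H))
                dz[:, sl[0]] = di * i * (1 - i)
                dz[:, sl[1]] = df * f * (1 - f)
                dz[:, sl[2]] = dg * (1 - g**2)
                dz[:, sl[3]] = do * o * (1 - o)
                gWx += xt.T @ dz
                gWh += h_prev.T @ dz
                gb += dz.sum(axis=0)
                dh = dz @ Wh.T
                dc = dc * f
            opt.step([gWx, gWh, gb, gwo, gbo])
        self._params = (Wx, Wh, b, wo, bo)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Wx, Wh, b, wo, bo = self._params
        H = self.hidden
        sl = [slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H), slice(3 * H, 4 * H)]
        Xs = (np.asarray(X, dtype=float) - self._xmu) / self._xsd
        B, J = Xs.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for t in range(J):
            z = Xs[:, t:t + 1] @ Wx + h @ Wh + b
            i, f, g, o = (_sigmoid(z[:, sl[0]]), _sigmoid(z[:, sl[1]]),
                          np.tanh(z[:, sl[2]]), _sigmoid(z[:, sl[3]]))
            c = f * c + i * g
            h = o * np.tanh(c)
        return (h @ wo + bo[0]) * self._ysd + self._ymu
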