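"""Minimal 1-D convolutional network on one-hot DNA, implemented with NumPy.

Forward/backward passes are vectorized with stride tricks; optimization is
Adam on minibatches with binary cross-entropy loss.  Everything is driven by
a single seeded Generator, so training is bit-reproducible for a given seed,
data, and architecture.

Layer stack: [conv(k) -> ReLU -> maxpool(p)] * n  ->  flatten
             -> dense -> ReLU -> (dropout) -> dense(1) -> sigmoid
Pooling truncates any remainder (valid pooling, no padding anywhere).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_len(length: int, kernel: int, pool: int) -> int:
    conv_len = length - kernel + 1
    if conv_len < 1:
        return 0
    return conv_len // pool if pool > 1 else conv_len


class ConvNet:
    """Binary sequence classifier: stacked 1-D convolutions + dense head."""

    def __init__(
        self,
        input_len: int,
        channels: list[int],
        kernels: list[int],
        pools: list[int],
        dense_units: int,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if len(channels) != len(kernels) or len(channels) != len(pools):
            raise ValueError("channels, kernels, pools must have equal length")
        self.input_len = input_len
        self.channels = list(channels)
        self.kernels = list(kernels)
        self.pools = list(pools)
        self.dense_units = dense_units
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)

        self.W: list[np.ndarray] = []  # conv weights, shape (k*c_in, c_out)
        self.b: list[np.ndarray] = []
        length, c_in = input_len, 4
        for c_out, k, p in zip(channels, kernels, pools):
            fan_in = k * c_in
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)))
            self.b.append(np.zeros(c_out))
            length = conv_out_len(length, k, p)
            if length < 1:
                raise ValueError(
                    f"architecture collapses the sequence to length 0 at a "
                    f"conv({k})/pool({p}) layer; shorten kernels/pools or "
                    f"lengthen input_len ({input_len})"
                )
            c_in = c_out
        flat = length * c_in
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, dense_units))
        self.b1 = np.zeros(dense_units)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / dense_units), (dense_units, 1))
        self.b2 = np.zeros(1)
        self.final_len = length

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.W1, self.b1, self.W2, self.b2]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n : 2 * n]]
        self.W1, self.b1, self.W2, self.b2 = (p.copy() for p in params[2 * n :])

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """X: (N, L, 4).  Returns (probabilities, cache for backprop)."""
        cache: list[dict] = []
        A = X
        for W, b, k, p in zip(self.W, self.b, self.kernels, self.pools):
            N, L, C = A.shape
            win = sliding_window_view(A, k, axis=1)  # (N, L-k+1, C, k)
            win = win.transpose(0, 1, 3, 2).reshape(N, L - k + 1, k * C)
            Z = win @ W + b
            R = np.maximum(Z, 0.0)
            if p > 1:
                L_out = R.shape[1] // p
                Rt = R[:, : L_out * p].reshape(N, L_out, p, -1)
                arg = Rt.argmax(axis=2)
                P = np.take_along_axis(Rt, arg[:, :, None, :], axis=2)[:, :, 0, :]
            else:
                arg, P = None, R
            cache.append({"A": A, "win": win, "Z": Z, "arg": arg, "R_shape": R.shape})
            A = P
        N = A.shape[0]
        flat = A.reshape(N, -1)
        H = flat @ self.W1 + self.b1
        Hr = np.maximum(H, 0.0)
        if train_rng is not None and self.dropout > 0.0:
            mask = (train_rng.random(Hr.shape) >= self.dropout) / (1.0 - self.dropout)
            Hd = Hr * mask
        else:
            mask, Hd = None, Hr
        logit = (Hd @ self.W2 + self.b2)[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache.append({"flat": flat, "H": H, "Hd": Hd, "mask": mask, "A_shape": A.shape})
        return prob, cache

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i in range(0, X.shape[0], batch_size):
            out[i : i + batch_size] = self._forward(X[i : i + batch_size])[0]
        return out

    def _backward(self, prob: np.ndarray, y: np.ndarray, cache: list[dict]):
        """Gradients of mean BCE loss w.r.t. parameters (same order as parameters())."""
        N = y.shape[0]
        head = cache[-1]
        dlogit = (prob - y) / N  # (N,)
        dW2 = head["Hd"].T @ dlogit[:, None]
        db2 = np.array([dlogit.sum()])
        dHd = dlogit[:, None] @ self.W2.T
        if head["mask"] is not None:
            dHd = dHd * head["mask"]
        dH = dHd * (head["H"] > 0)
        dW1 = head["flat"].T @ dH
        db1 = dH.sum(axis=0)
        dA = (dH @ self.W1.T).reshape(head["A_shape"])

        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            c = cache[li]
            k, p = self.kernels[li], self.pools[li]
            if p > 1:
                Nn, L_out, C_out = dA.shape
                dRt = np.zeros((Nn, L_out, p, C_out))
                np.put_along_axis(dRt, c["arg"][:, :, None, :], dA[:, :, None, :], axis=2)
                dR = np.zeros(c["R_shape"])
                dR[:, : L_out * p] = dRt.reshape(Nn, L_out * p, C_out)
            else:
                dR = dA
            dZ = dR * (c["Z"] > 0)
            gW[li] = c["win"].reshape(-1, c["win"].shape[-1]).T @ dZ.reshape(-1, dZ.shape[-1])
            gb[li] = dZ.sum(axis=(0, 1))
            # scatter-add the window gradient back onto the input
            A_prev = c["A"]
            dA_prev = np.zeros_like(A_prev, dtype=float)
            dwin = dZ @ self.W[li].T  # (N, L_conv, k*C_in)
            L_conv = dwin.shape[1]
            C_in = A_prev.shape[2]
            dwin = dwin.reshape(dwin.shape[0], L_conv, k, C_in)
            for j in range(k):
                dA_prev[:, j : j + L_conv, :] += dwin[:, :, j, :]
            dA = dA_prev
        return [*gW, *gb, dW1, db1, dW2, db2]

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int = 20,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        patience: int = 5,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        """Adam + early stopping on validation loss; restores the best epoch."""
        rng = np.random.default_rng(seed)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = -1
        history = []
        n = X.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                prob, cache = self._forward(X[idx], train_rng=rng)
                grads = self._backward(prob, y[idx], cache)
                t += 1
                for p_arr, g, m_i, v_i in zip(params, grads, m, v):
                    m_i *= beta1
                    m_i += (1 - beta1) * g
                    v_i *= beta2
                    v_i += (1 - beta2) * g * g
                    mhat = m_i / (1 - beta1**t)
                    vhat = v_i / (1 - beta2**t)
                    p_arr -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_prob = self.predict(X_val)
            val_loss = _bce(y_val, val_prob)
            history.append(float(val_loss))
            if verbose:
                print(f"epoch {epoch}: val_loss={val_loss:.4f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                best_epoch = epoch
            elif epoch - best_epoch >= patience:
                break
        self.set_parameters(best_params)
        return {"best_val_loss": float(best_val), "val_history": history,
                "best_epoch": best_epoch}

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            out[f"conv{i}_W"], out[f"conv{i}_b"] = w, b
        out.update({"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.W = [np.asarray(state[f"conv{i}_W"]) for i in range(len(self.W))]
        self.b = [np.asarray(state[f"conv{i}_b"]) for i in range(len(self.b))]
        self.W1 = np.asarray(state["W1"])
        self.b1 = np.asarray(state["b1"])
        self.W2 = np.asarray(state["W2"])
        self.b2 = np.asarray(state["b2"])


def _bce(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
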