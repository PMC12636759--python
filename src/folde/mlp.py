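"""A small feed-forward ranker implemented directly on numpy.

Architecture: input → 100 → 50 → 1 with batch normalization after each
hidden linear layer, ReLU activations, dropout, and a final linear layer
without bias (Bradley-Terry training is translation invariant, so a final
bias is unidentifiable). Optimized with Adam plus decoupled-from-nothing
plain L2 weight decay on the weight matrices.

The forward/backward passes are hand-derived; tests check the analytic
gradients against central finite differences.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

_EPS = 1e-5          # batch-norm variance floor
_BN_MOMENTUM = 0.1   # running-statistics update rate


class MLPRanker:
    """MLP scoring model for pairwise (Bradley-Terry) ranking."""

    def __init__(self, input_dim: int, hidden_dims: Sequence[int] = (100, 50),
                 dropout: float = 0.2, seed: int = 0) -> None:
        self.input_dim = int(input_dim)
        self.hidden_dims = tuple(int(h) for h in hidden_dims)
        self.dropout = float(dropout)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.blocks: list[dict[str, np.ndarray]] = []
        d = self.input_dim
        for h in self.hidden_dims:
            # He initialization for ReLU layers
            self.blocks.append({
                "W": self.rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
                "b": np.zeros(h),
                "gamma": np.ones(h),
                "beta": np.zeros(h),
                "run_mean": np.zeros(h),
                "run_var": np.ones(h),
            })
            d = h
        self.W_out = self.rng.normal(0.0, np.sqrt(1.0 / d), size=(d, 1))
        self._adam: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ----- forward / backward -------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """Scores for rows of X; returns (scores, cache)."""
        X = np.asarray(X, dtype=float)
        h = X
        caches = []
        for blk in self.blocks:
            z = h @ blk["W"] + blk["b"]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                blk["run_mean"] = (1 - _BN_MOMENTUM) * blk["run_mean"] + _BN_MOMENTUM * mu
                blk["run_var"] = (1 - _BN_MOMENTUM) * blk["run_var"] + _BN_MOMENTUM * var
            else:
                mu, var = blk["run_mean"], blk["run_var"]
            std = np.sqrt(var + _EPS)
            zhat = (z - mu) / std
            a = blk["gamma"] * zhat + blk["beta"]
            r = np.maximum(a, 0.0)
            if training and self.dropout > 0:
                mask = (self.rng.random(r.shape) >= self.dropout) / (1.0 - self.dropout)
                out = r * mask
            else:
                mask = None
                out = r
            caches.append({"h_in": h, "zhat": zhat, "std": std, "a": a,
                           "mask": mask, "training": training})
            h = out
        scores = (h @ self.W_out).ravel()
        caches.append({"h_last": h})
        return scores, caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Eval-mode scores (running batch-norm stats, no dropout)."""
        scores, _ = self.forward(X, training=False)
        return scores

    def backward(self, caches, dscores: np.ndarray) -> list[dict[str, np.ndarray]]:
        """Parameter gradients given d(loss)/d(scores). Training mode only."""
        h_last = caches[-1]["h_last"]
        ds = np.asarray(dscores, dtype=float)[:, None]
        grads: list[dict[str, np.ndarray]] = [dict() for _ in self.blocks]
        gW_out = h_last.T @ ds
        dh = ds @ self.W_out.T
        for i in range(len(self.blocks) - 1, -1, -1):
            blk, cache = self.blocks[i], caches[i]
            if cache["mask"] is not None:
                dr = dh * cache["mask"]
            else:
                dr = dh
            da = dr * (cache["a"] > 0)
            grads[i]["gamma"] = (da * cache["zhat"]).sum(axis=0)
            grads[i]["beta"] = da.sum(axis=0)
            dzhat = da * blk["gamma"]
            zhat = cache["zhat"]
            # fused batch-norm backward
            dz = (dzhat - dzhat.mean(axis=0)
                  - zhat * (dzhat * zhat).mean(axis=0)) / cache["std"]
            grads[i]["W"] = cache["h_in"].T @ dz
            grads[i]["b"] = dz.sum(axis=0)
            dh = dz @ blk["W"].T
        return grads + [{"W_out": gW_out}]

    # ----- optimization --------------------------------------------------

    def _params(self):
        for i, blk in enumerate(self.blocks):
            for name in ("W", "b", "gamma", "beta"):
                yield (i, name), blk, name
        yield (len(self.blocks), "W_out"), self.__dict__, "W_out"

    def adam_step(self, grads, lr: float = 3e-4, weight_decay: float = 1e-5,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for key, container, name in self._params():
            i, pname = key
            if pname == "W_out":
                g = grads[-1]["W_out"]
                p = self.W_out
            else:
                g = grads[i][pname]
                p = container[name]
            if pname in ("W", "W_out") and weight_decay > 0:
                g = g + weight_decay * p
            if key not in self._adam:
                self._adam[key] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._adam[key]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # ----- state ---------------------------------------------------------

    def get_state(self) -> dict:
        """Deep copy of all weights and batch-norm running statistics."""
        return {"blocks": copy.deepcopy(self.blocks),
                "W_out": self.W_out.copy()}

    def set_state(self, state: dict) -> None:
        self.blocks = copy.deepcopy(state["blocks"])
        self.W_out = state["W_out"].copy()
        self._adam = {}
        self._adam_t = 0

    def clone_from_state(self, state: dict, seed: int) -> "MLPRanker":
        """Fresh ranker (own rng/optimizer) initialized at ``state``."""
        other = MLPRanker(self.input_dim, self.hidden_dims, self.dropout, seed)
        other.set_state(state)
        return other
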