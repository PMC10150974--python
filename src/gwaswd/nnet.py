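"""Seeded feed-forward networks for genotype classification.

A single implementation covers the three architectures used here: a
wide network (one large hidden layer), a deep network (a stack of small
hidden layers) and a wide-and-deep network, where a curated "wide"
block of inputs skips the deep stack and is concatenated with the last
hidden representation just before the sigmoid output unit.

Training is plain minibatch Adam on binary cross-entropy with ReLU
hidden units, an internal stratified validation split and early
stopping with best-weight restore.  Everything is driven by one
``numpy`` generator, so a fixed seed reproduces the weights bit for
bit on a single thread.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class WideDeepNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier with an optional wide input shortcut.

    The first ``n_wide`` columns of ``X`` form the wide block and feed
    the output unit directly; the remaining columns run through the
    ReLU stack in ``hidden_layer_sizes``.  With ``n_wide=0`` this is an
    ordinary multilayer perceptron.  The positive class is the larger
    of the two labels (PLINK coding 1/2 makes 2 = case positive).

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the deep stack (may be empty: logistic output over
        the wide block alone).
    n_wide : int
        Number of leading wide columns bypassing the stack.
    learning_rate, batch_size, max_epochs : Adam step size / minibatch
        size / epoch cap.
    patience : early-stopping patience, in epochs without validation
        improvement; best weights are restored.
    validation_fraction : share of the training data held out
        (stratified) for early stopping.
    random_state : seed for initialisation, shuffling and the split.
    """

    def __init__(self, hidden_layer_sizes=(64, 32, 16), n_wide: int = 0,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 200, patience: int = 20,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_wide = n_wide
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, weights) -> tuple[np.ndarray, list]:
        Ws, bs, w_out, b_out = weights
        deep = X[:, self.n_wide:]
        wide = X[:, : self.n_wide]
        acts = [deep]
        h = deep
        for W, b in zip(Ws, bs):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        joined = np.hstack([h, wide]) if self.n_wide else h
        p = expit(joined @ w_out + b_out)
        return p, acts

    # -- training ---------------------------------------------------------

    def _stack(self) -> tuple[int, ...]:
        return tuple(self.hidden_layer_sizes)

    def _init_weights(self, n_deep: int, rng: np.random.Generator):
        stack = self._stack()
        sizes = [n_deep, *stack]
        Ws = [rng.normal(0.0, np.sqrt(2.0 / max(sizes[i], 1)),
                         size=(sizes[i], sizes[i + 1]))
              for i in range(len(stack))]
        bs = [np.zeros(w.shape[1]) for w in Ws]
        n_join = (stack[-1] if stack else 0) + self.n_wide
        if n_join == 0:
            raise ValueError("network has no inputs to the output unit")
        w_out = rng.normal(0.0, np.sqrt(1.0 / n_join), size=n_join)
        return Ws, bs, w_out, 0.0

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in X")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        if not 0 <= self.n_wide <= X.shape[1]:
            raise ValueError("n_wide outside the column range of X")
        t = (y == self.classes_[1]).astype(np.float64)
        rng = np.random.default_rng(self.random_state)
        Ws, bs, w_out, b_out = self._init_weights(X.shape[1] - self.n_wide, rng)

        if self.max_epochs > 0 and self.validation_fraction > 0 and len(y) >= 10:
            idx_tr, idx_val = train_test_split(
                np.arange(len(y)), test_size=self.validation_fraction,
                stratify=t, random_state=int(rng.integers(2**31)),
            )
        else:
            idx_tr, idx_val = np.arange(len(y)), np.array([], dtype=int)

        params = [*Ws, *bs, w_out]
        opt = _Adam(params, self.learning_rate)
        best_val = np.inf
        best = None
        stale = 0
        self.n_epochs_ = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(idx_tr)
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                grads, gb_out = self._gradients(X[sel], t[sel], (Ws, bs, w_out, b_out))
                opt.step(params, grads)
                b_out -= self.learning_rate * gb_out  # scalar, plain SGD step
            self.n_epochs_ = epoch + 1
            if len(idx_val):
                p_val, _ = self._forward(X[idx_val], (Ws, bs, w_out, b_out))
                val = _bce(p_val, t[idx_val])
                if val < best_val - 1e-6:
                    best_val = val
                    best = ([w.copy() for w in Ws], [b.copy() for b in bs],
                            w_out.copy(), b_out)
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best is not None:
            Ws, bs, w_out, b_out = best
        self.weights_ = (Ws, bs, w_out, b_out)
        return self

    def _gradients(self, Xb, tb, weights):
        Ws, bs, w_out, b_out = weights
        p, acts = self._forward(Xb, weights)
        h_last = acts[-1]
        wide = Xb[:, : self.n_wide]
        joined = np.hstack([h_last, wide]) if self.n_wide else h_last
        n = len(tb)
        delta_out = (p - tb) / n  # dL/d(logit)
        g_w_out = joined.T @ delta_out
        g_b_out = float(delta_out.sum())

        gWs = [None] * len(Ws)
        gbs = [None] * len(bs)
        if Ws:
            n_h = Ws[-1].shape[1]
            delta = np.outer(delta_out, w_out[:n_h])
            for l in range(len(Ws) - 1, -1, -1):
                delta = delta * (acts[l + 1] > 0)
                gWs[l] = acts[l].T @ delta
                gbs[l] = delta.sum(axis=0)
                if l:
                    delta = delta @ Ws[l].T
        return [*gWs, *gbs, g_w_out], g_b_out

    # -- prediction -------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        p, _ = self._forward(np.asarray(X, dtype=np.float64), self.weights_)
        return p

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        # strict > 0.5: a tied score falls to the negative (control) class
        p = self.decision_function(X)
        return np.where(p > 0.5, self.classes_[1], self.classes_[0])


class WideNNClassifier(WideDeepNetClassifier):
    """Wide network: a single large hidden layer (default width 256)."""

    def __init__(self, hidden_width: int = 256, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200, patience: int = 20,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.hidden_width = hidden_width
        self.hidden_layer_sizes = ()
        self.n_wide = 0
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _stack(self) -> tuple[int, ...]:
        return (self.hidden_width,)


class DeepNNClassifier(WideDeepNetClassifier):
    """Deep network: a stack of small hidden layers (default 64-32-16)."""

    def __init__(self, hidden_layer_sizes=(64, 32, 16), learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200, patience: int = 20,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.n_wide = 0
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
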