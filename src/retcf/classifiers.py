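"""Plain and adversarially robust K-class image classifiers.

Both variants share a small convolutional network trained with SGD and a
cosine learning-rate schedule.  The robust variant minimizes the TRADES
objective: cross-entropy on clean images plus a weighted KL divergence
between the predictive distributions at the clean image and at an
adversarial perturbation found by projected gradient ascent (PGD) inside
an lp ball.  Targeted/untargeted PGD is also exposed directly; it is the
inner maximizer of TRADES and the engine of the sparse-counterfactual
baseline's robustness evaluation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score

from .nn import SGDMomentum, SmallCNN, log_softmax, softmax

_SUPPORTED_P = (1.5, 2.0, 4.0, np.inf)


# ---------------------------------------------------------------------------
# attacks

def _lp_norm(d: np.ndarray, p: float) -> np.ndarray:
    flat = d.reshape(d.shape[0], -1)
    if np.isinf(p):
        return np.abs(flat).max(axis=1)
    return (np.abs(flat) ** p).sum(axis=1) ** (1.0 / p)


def _project_ball(delta: np.ndarray, eps: float, p: float) -> np.ndarray:
    """Keep delta inside the lp ball of radius eps.

    Exact projection for p=2 and p=inf; radial rescaling onto the sphere for
    p in {1.5, 4} (the exact projection has no closed form there).
    """
    if np.isinf(p):
        return np.clip(delta, -eps, eps)
    norms = _lp_norm(delta, p)
    scale = np.minimum(1.0, eps / np.maximum(norms, 1e-12))
    return delta * scale.reshape((-1,) + (1,) * (delta.ndim - 1))


def pgd_attack(classifier, x0: np.ndarray, *, eps: float, p: float = 2.0,
               steps: int = 10, step_size: float | None = None,
               targeted: bool = False, target: int | np.ndarray | None = None,
               y: np.ndarray | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Projected-gradient attack inside an lp ball, box-constrained to [0,1].

    Targeted mode maximizes log p(target|x); untargeted mode maximizes the
    cross-entropy of the true label ``y``.
    """
    if float(p) not in (1.5, 2.0, 4.0) and not np.isinf(p):
        raise ValueError(f"unsupported norm order p={p}; use 1.5, 2, 4 or inf")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    x0 = np.asarray(x0, dtype=np.float32)
    single = x0.ndim == 3
    if single:
        x0 = x0[None]
    n = x0.shape[0]
    if targeted:
        if target is None:
            raise ValueError("targeted attack needs a target class")
        tgt = np.full(n, target, dtype=int) if np.isscalar(target) else np.asarray(target)
    else:
        if y is None:
            raise ValueError("untargeted attack needs true labels y")
        y = np.full(n, y, dtype=int) if np.isscalar(y) else np.asarray(y)
    if eps == 0 or steps == 0:
        return x0[0] if single else x0.copy()
    step = step_size if step_size is not None else 2.5 * eps / steps
    rng = rng or np.random.default_rng(0)
    delta = rng.normal(0, 1e-3, size=x0.shape).astype(np.float32)
    delta = _project_ball(delta, eps, p)
    for _ in range(steps):
        x = np.clip(x0 + delta, 0.0, 1.0)
        logits = classifier.decision_function(x)
        probs = softmax(logits)
        if targeted:
            dlogits = -probs.copy()
            dlogits[np.arange(n), tgt] += 1.0     # grad of log p(target)
        else:
            dlogits = probs.copy()
            dlogits[np.arange(n), y] -= 1.0       # grad of CE(true)
        g = classifier.input_grad(dlogits)
        # steepest-ascent direction, per-sample l2 normalized
        gn = np.sqrt((g.reshape(n, -1) ** 2).sum(axis=1)).reshape((-1,) + (1,) * (g.ndim - 1))
        delta = delta + step * g / np.maximum(gn, 1e-12)
        delta = _project_ball(delta, eps, p)
        delta = np.clip(x0 + delta, 0.0, 1.0) - x0
    x_adv = np.clip(x0 + delta, 0.0, 1.0).astype(np.float32)
    return x_adv[0] if single else x_adv


def trades_loss(classifier, X: np.ndarray, y: np.ndarray, *, eps: float,
                p: float = 2.0, beta_trades: float = 6.0, attack_steps: int = 5,
                rng: np.random.Generator | None = None,
                return_parts: bool = False):
    """CE(clean) + beta * KL(p(.|x) || p(.|x_adv)) with the inner PGD
    maximizing the KL term.  Returns the scalar loss (and optionally the
    pieces and x_adv)."""
    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    logits = classifier.decision_function(X)
    logp = log_softmax(logits)
    probs = np.exp(logp)
    ce = float(-logp[np.arange(n), y].mean())
    if eps == 0:
        out = ce
        return (out, ce, 0.0, X.copy()) if return_parts else out
    rng = rng or np.random.default_rng(0)
    # inner maximization of KL(p_clean || p_adv) over the lp ball
    step = 2.5 * eps / max(attack_steps, 1)
    delta = rng.normal(0, 1e-3, size=X.shape).astype(np.float32)
    delta = _project_ball(delta, eps, p)
    for _ in range(attack_steps):
        x = np.clip(X + delta, 0.0, 1.0)
        la = classifier.decision_function(x)
        pa = softmax(la)
        g = classifier.input_grad(pa - probs)     # d KL / d logits_adv = p_adv - p_clean
        gn = np.sqrt((g.reshape(n, -1) ** 2).sum(axis=1)).reshape((-1,) + (1,) * (g.ndim - 1))
        delta = delta + step * g / np.maximum(gn, 1e-12)
        delta = _project_ball(delta, eps, p)
        delta = np.clip(X + delta, 0.0, 1.0) - X
    x_adv = np.clip(X + delta, 0.0, 1.0)
    logp_adv = log_softmax(classifier.decision_function(x_adv))
    kl = float((probs * (logp - logp_adv)).sum(axis=1).mean())
    loss = ce + beta_trades * max(kl, 0.0)
    return (loss, ce, kl, x_adv) if return_parts else loss


# ---------------------------------------------------------------------------
# estimator

class ConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Small CNN classifier over (N,C,H,W) images in [0,1].

    ``mode='plain'`` trains with cross-entropy; ``mode='robust'`` with the
    TRADES objective at radius ``eps`` in the lp norm.  Training uses SGD
    with momentum 0.9 and a cosine learning-rate decay.  The kept checkpoint
    maximizes validation balanced accuracy (plain mode) or the mean of clean
    and adversarial validation balanced accuracy (robust mode) -- selecting a
    robust model by clean accuracy alone can return an epoch with no
    robustness.
    """

    def __init__(self, mode: str = "plain", epochs: int = 60, lr: float = 0.01,
                 batch_size: int = 16, channels=(8, 16, 32), eps: float = 0.25,
                 p: float = 2.0, beta_trades: float = 6.0, attack_steps: int = 8,
                 val_fraction: float = 0.15, random_state: int = 0):
        self.mode = mode
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.channels = channels
        self.eps = eps
        self.p = p
        self.beta_trades = beta_trades
        self.attack_steps = attack_steps
        self.val_fraction = val_fraction
        self.random_state = random_state

    # network plumbing ------------------------------------------------------
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.net_.forward(np.asarray(X, dtype=np.float32))

    def input_grad(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the input of the last decision_function call,
        for the given logits cotangent."""
        return self.net_.backward(np.asarray(dlogits, dtype=np.float32),
                                  param_grads=False)

    def log_prob_grad(self, X: np.ndarray, k: int | np.ndarray):
        """(log p(k|x), d log p(k|x) / dx) for each row of X."""
        X = np.asarray(X, dtype=np.float32)
        n = X.shape[0]
        kk = np.full(n, k, dtype=int) if np.isscalar(k) else np.asarray(k)
        logits = self.decision_function(X)
        logp = log_softmax(logits)
        dlogits = -np.exp(logp)
        dlogits[np.arange(n), kk] += 1.0
        return logp[np.arange(n), kk], self.input_grad(dlogits)

    # sklearn surface -------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4:
            raise ValueError("X must be (N,C,H,W)")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        if self.mode not in ("plain", "robust"):
            raise ValueError("mode must be 'plain' or 'robust'")
        yi = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng([self.random_state, 301])
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, yv = X[val_idx], yi[val_idx]
            X, yi = X[tr_idx], yi[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            yv = np.searchsorted(self.classes_, np.asarray(y_val, dtype=int))
        self.net_ = SmallCNN(X.shape[1], self.classes_.size, self.channels, rng=rng)
        opt = SGDMomentum(self.net_.parameters(), lr=self.lr)
        n = X.shape[0]
        steps_per_epoch = max(1, n // self.batch_size)
        total = self.epochs * steps_per_epoch
        best = (-1.0, None)
        self.history_ = []
        it = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for b in range(steps_per_epoch):
                idx = order[b * self.batch_size:(b + 1) * self.batch_size]
                xb, yb = X[idx], yi[idx]
                opt.lr = 0.5 * self.lr * (1.0 + np.cos(np.pi * it / max(total - 1, 1)))
                opt.zero_grad()
                if self.mode == "plain":
                    logits = self.net_.forward(xb)
                    probs = softmax(logits)
                    d = (probs - np.eye(self.classes_.size, dtype=np.float32)[yb]) / len(yb)
                    self.net_.backward(d)
                else:
                    # linear beta warm-up over the first third of training
                    # stabilizes TRADES on small models (high beta from the
                    # start locks the predictions at uniform)
                    beta_eff = self.beta_trades * min(1.0, (epoch + 1) / max(1, self.epochs // 3))
                    _, _, _, x_adv = trades_loss(
                        self, xb, yb, eps=self.eps, p=self.p,
                        beta_trades=beta_eff,
                        attack_steps=self.attack_steps, rng=rng, return_parts=True)
                    m = len(yb)
                    logp_adv = log_softmax(self.net_.forward(x_adv))
                    # clean pass last so the cache matches the clean cotangent
                    logp = log_softmax(self.net_.forward(xb))
                    probs = np.exp(logp)
                    kl_col = (probs * (logp - logp_adv)).sum(axis=1, keepdims=True)
                    d_ce = probs - np.eye(self.classes_.size, dtype=np.float32)[yb]
                    d_kl_clean = probs * ((logp - logp_adv) - kl_col)
                    self.net_.backward((d_ce + beta_eff * d_kl_clean) / m)
                    # adversarial pass for the KL cotangent at the perturbed point
                    logp_adv2 = log_softmax(self.net_.forward(x_adv))
                    d_kl_adv = np.exp(logp_adv2) - probs
                    self.net_.backward(beta_eff * d_kl_adv / m)
                opt.step()
                it += 1
            bacc = balanced_accuracy_score(yv, np.argmax(self.decision_function(X_val), axis=1))
            if self.mode == "robust" and (epoch % 2 == 1 or epoch == self.epochs - 1):
                # select for robustness: average of clean and adversarial
                # validation balanced accuracy (clean-only selection can keep
                # an epoch with no robustness at all)
                x_adv = pgd_attack(self, X_val, eps=self.eps, p=self.p, steps=10,
                                   y=yv, rng=np.random.default_rng([self.random_state, 771]))
                bacc_adv = balanced_accuracy_score(
                    yv, np.argmax(self.decision_function(x_adv), axis=1))
                score = 0.5 * (bacc + bacc_adv)
            elif self.mode == "robust":
                score = -1.0   # only adversarially-scored epochs are eligible
            else:
                score = bacc
            self.history_.append((epoch, float(score)))
            if score > best[0]:
                best = (score, self.net_.get_state())
        if best[1] is not None:
            self.net_.set_state(best[1])
        self.best_val_balanced_accuracy_ = float(best[0])
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def get_state(self) -> dict:
        return self.net_.get_state()

    def set_state(self, state: dict, in_channels=None, n_classes=None) -> None:
        if not hasattr(self, "net_"):
            rng = np.random.default_rng([self.random_state, 301])
            self.net_ = SmallCNN(in_channels, n_classes, self.channels, rng=rng)
            self.classes_ = np.arange(n_classes)
        self.net_.set_state(state)


# ---------------------------------------------------------------------------
# wrappers + metrics

def train_plain(X, y, *, epochs: int = 60, lr: float = 0.01, rng_seed: int = 0,
                **kw) -> ConvNetClassifier:
    return ConvNetClassifier(mode="plain", epochs=epochs, lr=lr,
                             random_state=rng_seed, **kw).fit(X, y)


def train_robust(X, y, *, eps: float = 0.25, p: float = 2.0,
                 beta_trades: float = 6.0, epochs: int = 100, lr: float = 0.01,
                 rng_seed: int = 0, **kw) -> ConvNetClassifier:
    return ConvNetClassifier(mode="robust", eps=eps, p=p, beta_trades=beta_trades,
                             epochs=epochs, lr=lr, random_state=rng_seed, **kw).fit(X, y)


def evaluate(classifier, X: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy, balanced accuracy and quadratic-weighted Cohen's kappa."""
    pred = classifier.predict(X)
    y = np.asarray(y)
    return {
        "accuracy": float(np.mean(pred == y)),
        "balanced_accuracy": float(balanced_accuracy_score(y, pred)),
        "quadratic_kappa": float(cohen_kappa_score(y, pred, weights="quadratic"))
        if np.unique(np.concatenate([y, pred])).size > 1 else 1.0,
    }


def referable_labels(labels: np.ndarray, threshold_class: int = 2) -> np.ndarray:
    """Binary grouping of ordinal DR grades: disease onset at 'moderate'
    (grade index 2), i.e. {healthy, mild} -> 0, {moderate+} -> 1."""
    return (np.asarray(labels) >= threshold_class).astype(int)
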