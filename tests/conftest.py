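import numpy as np
import pytest

from retcf.classifiers import ConvNetClassifier
from retcf.experiment import ExperimentConfig, run_desk_experiment


def make_toy_images(n_per_class: int, size: int = 16, seed: int = 0):
    """Trivially separable two-class images: class 1 has a bright square."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in (0, 1):
        for _ in range(n_per_class):
            img = rng.uniform(0.2, 0.4, (3, size, size)).astype(np.float32)
            if c == 1:
                img[:, 4:9, 4:9] += 0.5
            X.append(np.clip(img, 0, 1))
            y.append(c)
    return np.stack(X), np.array(y)


class LinearImageClassifier:
    """Linear-logit map over flattened pixels; exposes the same gradient
    surface as the trained CNNs and serves as an analytic oracle."""

    def __init__(self, W: np.ndarray, b: np.ndarray | None = None):
        self.W = np.asarray(W, dtype=np.float32)          # (K, d)
        self.b = np.zeros(self.W.shape[0], dtype=np.float32) if b is None else b
        self.classes_ = np.arange(self.W.shape[0])

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float32)
        self._shape = X.shape
        return X.reshape(X.shape[0], -1) @ self.W.T + self.b

    def input_grad(self, dlogits):
        return (np.asarray(dlogits, dtype=np.float32) @ self.W).reshape(self._shape)

    def predict_proba(self, X):
        z = self.decision_function(X)
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return np.argmax(self.decision_function(X), axis=1)

    def log_prob_grad(self, X, k):
        n = np.asarray(X).shape[0]
        kk = np.full(n, k, dtype=int) if np.isscalar(k) else np.asarray(k)
        z = self.decision_function(X)
        zs = z - z.max(axis=1, keepdims=True)
        logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
        d = -np.exp(logp)
        d[np.arange(n), kk] += 1.0
        return logp[np.arange(n), kk], self.input_grad(d)


@pytest.fixture(scope="session")
def toy_classifiers():
    """Small CNN plain+robust pair trained on the separable toy task."""
    X, y = make_toy_images(24, size=16, seed=3)
    plain = ConvNetClassifier(mode="plain", epochs=40, channels=(4, 8, 8),
                              random_state=0).fit(X, y)
    robust = ConvNetClassifier(mode="robust", eps=0.25, epochs=15,
                               channels=(4, 8, 8), attack_steps=3,
                               random_state=0).fit(X, y)
    return {"plain": plain, "robust": robust}, (X, y)


@pytest.fixture(scope="session")
def desk_experiment():
    """The full desk-scale pipeline (trains the diffusion model and both
    classifiers, then runs the lambda_d sweep); shared across the
    acceptance tests."""
    return run_desk_experiment(ExperimentConfig(seed=0))
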