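"""Sparse Visual Counterfactuals (SVCs): the generative-model-free baseline.

Maximize the target-class log-probability within an lp ball (default p=4)
around the original image using Frank-Wolfe iterations: the linear
maximization over the ball has a closed form, iterates are convex
combinations (hence stay inside the ball), the step size follows the
classic 2/(t+2) schedule, and the [0,1] box is enforced by clipping (which
can only move coordinates toward the original, so feasibility is kept).
When the ensemble flag is set, the objective is the sum of the plain and
robust classifiers' log-probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvc import CounterfactualResult

_SUPPORTED_P = (1.5, 2.0, 4.0)


@dataclass
class SvcConfig:
    target_class: int = 1
    eps: float = 4.0            # ball radius, in the chosen lp norm
    p: float = 4.0
    steps: int = 50
    ensemble: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if float(self.p) not in _SUPPORTED_P:
            raise ValueError(f"unsupported norm order p={self.p}; use one of {_SUPPORTED_P}")


def fw_linear_oracle(gradient: np.ndarray, eps: float, p: float) -> np.ndarray:
    """argmax <s, g> over ||s||_p <= eps:
    s_i = eps * sign(g_i) |g_i|^(1/(p-1)) / |||g|^(1/(p-1))||_p."""
    if float(p) not in _SUPPORTED_P:
        raise ValueError(f"unsupported norm order p={p}")
    g = np.asarray(gradient, dtype=np.float64)
    a = np.abs(g) ** (1.0 / (p - 1.0))
    denom = (a ** p).sum() ** (1.0 / p)
    if denom < 1e-30:
        return np.zeros_like(g, dtype=np.float32)
    return (eps * np.sign(g) * a / denom).astype(np.float32)


def _objective_grad(classifiers: list, x: np.ndarray, k: np.ndarray):
    """Sum over classifiers of (log p(k|x), gradient)."""
    logp_total = 0.0
    grad_total = np.zeros_like(x)
    for clf in classifiers:
        lp, g = clf.log_prob_grad(x, k)
        logp_total = logp_total + lp
        grad_total = grad_total + g
    return logp_total, grad_total


def generate_svc_batch(x0: np.ndarray, config: SvcConfig,
                       classifiers: dict) -> list[CounterfactualResult]:
    """Frank-Wolfe sparse counterfactuals for a batch (N,C,H,W in [0,1])."""
    x0 = np.asarray(x0, dtype=np.float32)
    if x0.ndim != 4:
        raise ValueError("x0 must be (N,C,H,W)")
    n = x0.shape[0]
    k = np.full(n, config.target_class, dtype=int)
    if config.ensemble:
        clfs = [classifiers[m] for m in ("plain", "robust") if m in classifiers]
    else:
        clfs = [classifiers.get("robust") or classifiers["plain"]]
    ref = classifiers.get("plain") or clfs[0]
    x = x0.copy()
    for it in range(config.steps):
        _, g = _objective_grad(clfs, x, k)
        gamma = 2.0 / (it + 2.0)
        for i in range(n):
            vertex = x0[i] + fw_linear_oracle(g[i], config.eps, config.p)
            x[i] = (1.0 - gamma) * x[i] + gamma * vertex
        x = np.clip(x, 0.0, 1.0)
    probs = ref.predict_proba(x)
    out = []
    for i in range(n):
        conf = float(probs[i, k[i]])
        out.append(CounterfactualResult(
            image=x[i], target_class=int(k[i]), target_confidence=conf,
            l2_distance=float(np.linalg.norm((x[i] - x0[i]).ravel())),
            flipped=int(np.argmax(probs[i])) == int(k[i])))
    return out


def generate_svc(x0: np.ndarray, config: SvcConfig, classifiers: dict) -> CounterfactualResult:
    return generate_svc_batch(x0[None], config, classifiers)[0]
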