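"""Diffusion Visual Counterfactuals (DVCs).

A counterfactual for image x0 toward class k is generated by noising x0 to
step ceil(T * start_fraction) and running the guided reverse diffusion back
to step 0.  At every step the reverse-transition mean is shifted by a
weighted sum of

* the classifier guidance gradient  d log p(k | x0_hat) / d x_t  taken
  through the denoised estimate x0_hat (clamped to the value range), and
* a distance-regularization gradient  -d ||x0_hat - x0||_2 / d x_t,

each normalized to unit l2 norm (adaptive parameterization, so the
weights s and lambda_d act consistently across images), weighted by the
guidance scale s and the regularization strength lambda_d respectively,
and scaled per step in proportion to the reverse-step noise standard
deviation.

In ``cone`` mode the guidance direction is the Euclidean projection of the
adversarially robust classifier's gradient onto the convex cone of vectors
within angle alpha of the plain classifier's gradient — combining the
robust model's perceptually aligned gradients with the plain model's
accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import diffusion as dff
from .diffusion import NoisyState, predict_x0, q_sample

logger = logging.getLogger(__name__)


@dataclass
class GuidanceConfig:
    """Settings of the guided reverse process."""

    target_class: int = 1
    lambda_d: float = 0.5          # distance-regularization strength
    distance_norm: float = 2.0
    cone_alpha_deg: float = 30.0   # cone half-angle around the plain gradient
    start_fraction: float = 0.5    # begin the reverse pass at T * this
    mode: str = "cone"             # plain | robust | cone
    guidance_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.start_fraction <= 1.0):
            raise ValueError("start_fraction must be in (0, 1]")
        if self.lambda_d < 0:
            raise ValueError("lambda_d must be >= 0")
        if not (0.0 < self.cone_alpha_deg < 90.0):
            raise ValueError("cone half-angle must be in (0, 90) degrees")
        if self.mode not in ("plain", "robust", "cone"):
            raise ValueError("mode must be plain, robust or cone")


@dataclass
class CounterfactualResult:
    image: np.ndarray              # (C,H,W) in [0,1]
    target_class: int
    target_confidence: float
    l2_distance: float
    flipped: bool
    confidence_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# cone projection

def cone_project(g_robust: np.ndarray, g_plain: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Euclidean projection of g_robust onto {v : angle(v, g_plain) <= alpha}.

    Inside the cone the vector is returned unchanged; otherwise the
    projection lies on the cone boundary within span{g_plain, g_robust}
    (or is zero when g_robust lies in the polar cone).  A zero g_plain
    leaves the cone undefined; g_robust is returned with a warning.
    """
    shape = g_robust.shape
    r = np.asarray(g_robust, dtype=np.float64).ravel()
    p = np.asarray(g_plain, dtype=np.float64).ravel()
    pn = np.linalg.norm(p)
    if pn < 1e-30:
        logger.warning("cone_project: zero plain gradient; returning the robust gradient")
        return g_robust.copy()
    rn = np.linalg.norm(r)
    if rn < 1e-30:
        return g_robust.copy()
    alpha = math.radians(alpha_deg)
    phat = p / pn
    r_par = float(r @ phat)
    r_perp = r - r_par * phat
    r_perp_n = np.linalg.norm(r_perp)
    theta = math.atan2(r_perp_n, r_par)
    if theta <= alpha:
        return g_robust.copy()
    if theta - alpha >= math.pi / 2:
        return np.zeros(shape, dtype=g_robust.dtype)
    qhat = r_perp / r_perp_n if r_perp_n > 1e-30 else np.zeros_like(r)
    boundary = math.cos(alpha) * phat + math.sin(alpha) * qhat
    proj = float(r @ boundary) * boundary
    return proj.reshape(shape).astype(g_robust.dtype)


# ---------------------------------------------------------------------------
# per-step gradients

def _classifier_cotangents(classifier, x_unit: np.ndarray, k) -> np.ndarray:
    """d log p(k|x) / dx at x in [0,1], for a batch."""
    _, g = classifier.log_prob_grad(x_unit, k)
    return g


def guidance_gradient(diffusion_model, classifiers: dict, state: NoisyState,
                      k, config: GuidanceConfig,
                      return_parts: bool = False):
    """d log p(k | clamp(x0_hat)) / d x_t, per sample.

    ``classifiers`` maps {"plain": ..., "robust": ...}; which are used
    depends on ``config.mode``.  The chain goes through the predict_x0 map
    (including the denoiser Jacobian) and the [-1,1] clamp.
    """
    sched = diffusion_model.schedule_
    x_t, t = state.x_t, state.t
    n = x_t.shape[0]
    K = list(classifiers.values())[0].classes_.size
    kk = np.full(n, k, dtype=int) if np.isscalar(k) else np.asarray(k)
    if np.any(kk >= K) or np.any(kk < 0):
        raise ValueError("target class out of range")
    eps = diffusion_model.predict_eps(x_t, np.full(n, t, dtype=np.int64))
    x0h = predict_x0(x_t, t, eps, sched)
    clamp_mask = (x0h > -1.0) & (x0h < 1.0)
    x_unit = dff.to_unit(x0h)

    def through(cot_unit: np.ndarray) -> np.ndarray:
        # chain: [0,1] -> [-1,1] clamp -> predict_x0 -> x_t
        cot = 0.5 * cot_unit * clamp_mask
        ab = sched.alpha_bar(t)
        a = 1.0 / np.sqrt(ab)
        b = np.sqrt(1.0 - ab) / np.sqrt(ab)
        return (a * cot - b * diffusion_model.eps_vjp(cot)).astype(np.float32)

    modes = {"plain": ("plain",), "robust": ("robust",), "cone": ("plain", "robust")}
    grads = {m: through(_classifier_cotangents(classifiers[m], x_unit, kk))
             for m in modes[config.mode]}
    if config.mode == "cone":
        g = np.stack([cone_project(grads["robust"][i], grads["plain"][i],
                                   config.cone_alpha_deg) for i in range(n)])
    else:
        g = grads[config.mode]
    if return_parts:
        return g, x0h, through, eps
    return g


def distance_gradient(x0_hat: np.ndarray, x0_internal: np.ndarray,
                      lambda_d: float, through=None,
                      norm_order: float = 2.0) -> np.ndarray:
    """-lambda_d * d ||x0_hat - x0|| / d x_t (l2 distance by default).

    ``through`` is the VJP mapping cotangents at x0_hat to gradients at
    x_t; identity when omitted (then the result is the gradient at x0_hat).
    """
    if norm_order != 2.0:
        raise NotImplementedError("only the l2 distance is implemented")
    n = x0_hat.shape[0]
    diff = (x0_hat - x0_internal).reshape(n, -1)
    norms = np.linalg.norm(diff, axis=1).reshape((-1,) + (1,) * (x0_hat.ndim - 1))
    cot = -lambda_d * (x0_hat - x0_internal) / np.maximum(norms, 1e-12)
    cot = cot.astype(np.float32)
    return through(cot) if through is not None else cot


def _unit(g: np.ndarray) -> np.ndarray:
    n = g.shape[0]
    norms = np.linalg.norm(g.reshape(n, -1), axis=1).reshape((-1,) + (1,) * (g.ndim - 1))
    return np.where(norms > 1e-12, g / np.maximum(norms, 1e-12), 0.0).astype(np.float32)


SHIFT_TO_NOISE = 3.0   # per-step shift magnitude in units of the reverse-step noise sd


def total_shift(g_guidance: np.ndarray, g_distance: np.ndarray,
                schedule, t: int, config: GuidanceConfig) -> np.ndarray:
    """Weighted sum of unit-normalized gradient terms, scaled per step.

    The scale follows the reverse-step noise standard deviation
    (SHIFT_TO_NOISE * sqrt(beta_tilde_t)); with unit-normalized gradients
    this keeps the deterministic drift commensurate with the stochastic
    part of the transition at every step, so the guidance neither vanishes
    at low-noise steps nor swamps the sampler at high-noise ones.
    """
    sd = float(np.sqrt(schedule.posterior_variance(t)))
    w = (config.guidance_scale * _unit(g_guidance)
         + config.lambda_d * _unit(g_distance))
    # cap the combined weight so extreme lambda_d cannot overshoot the pull
    # toward the original within a single step (inactive for lambda_d <= 1)
    n = w.shape[0]
    norms = np.linalg.norm(w.reshape(n, -1), axis=1).reshape(
        (-1,) + (1,) * (w.ndim - 1))
    w = w * np.minimum(1.0, 2.0 / np.maximum(norms, 1e-12))
    return (SHIFT_TO_NOISE * sd * w).astype(np.float32)


# ---------------------------------------------------------------------------
# generation

def generate_dvc_batch(x0: np.ndarray, k, diffusion_model, classifiers: dict,
                       config: GuidanceConfig) -> list[CounterfactualResult]:
    """Guided reverse diffusion for a batch of originals (N,C,H,W in [0,1])."""
    x0 = np.asarray(x0, dtype=np.float32)
    if x0.ndim != 4:
        raise ValueError("x0 must be (N,C,H,W)")
    if x0.shape[0] == 0:
        return []
    if x0.shape[1:] != diffusion_model.image_shape_:
        raise ValueError(f"image shape {x0.shape[1:]} does not match the "
                         f"diffusion model {diffusion_model.image_shape_}")
    sched = diffusion_model.schedule_
    rng = np.random.default_rng([config.seed, 555])
    n = x0.shape[0]
    kk = np.full(n, k, dtype=int) if np.isscalar(k) else np.asarray(k)
    x0_int = dff.to_internal(x0)
    t_start = max(1, math.ceil(sched.T * config.start_fraction))
    noise = rng.standard_normal(x0.shape).astype(np.float32)
    state = NoisyState(x_t=q_sample(x0_int, t_start, noise, sched), t=t_start)
    traces = [[] for _ in range(n)]
    ref = classifiers.get("plain") or next(iter(classifiers.values()))
    while state.t > 0:
        t = state.t
        g_guid, x0h, through, eps = guidance_gradient(
            diffusion_model, classifiers, state, kk, config, return_parts=True)
        g_dist = distance_gradient(x0h, x0_int, 1.0, through=through,
                                   norm_order=config.distance_norm)
        shift = total_shift(g_guid, g_dist, sched, t, config)
        beta, alpha = sched.betas[t - 1], sched.alphas[t - 1]
        ab = sched.alpha_bar(t)
        mu = (state.x_t - beta / np.sqrt(1.0 - ab) * eps) / np.sqrt(alpha) + shift
        if t > 1:
            var = float(sched.posterior_variance(t))
            x_prev = mu + np.sqrt(var) * rng.standard_normal(x0.shape).astype(np.float32)
        else:
            x_prev = mu
        probs = ref.predict_proba(dff.to_unit(x0h))
        for i in range(n):
            traces[i].append(float(probs[i, kk[i]]))
        state = NoisyState(x_t=x_prev.astype(np.float32), t=t - 1, x0_hat=x0h)
    final = dff.to_unit(state.x_t)
    probs = ref.predict_proba(final)
    results = []
    for i in range(n):
        conf = float(probs[i, kk[i]])
        flipped = int(np.argmax(probs[i])) == int(kk[i])
        l2 = float(np.linalg.norm((final[i] - x0[i]).ravel()))
        results.append(CounterfactualResult(
            image=final[i], target_class=int(kk[i]), target_confidence=conf,
            l2_distance=l2, flipped=flipped, confidence_trace=traces[i]))
    return results


def generate_dvc(x0: np.ndarray, k: int, diffusion_model, classifiers: dict,
                 config: GuidanceConfig) -> CounterfactualResult:
    """Counterfactual for a single original image (C,H,W in [0,1])."""
    return generate_dvc_batch(x0[None], k, diffusion_model, classifiers, config)[0]
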