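"""Denoising diffusion probabilistic model (DDPM) at desk scale.

Forward process: x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps with a linear
beta schedule.  Reverse process: Gaussian transitions whose mean is the
standard DDPM posterior mean, optionally shifted by an externally supplied
``mean_shift`` (used for classifier guidance).  The reverse variance is the
fixed posterior variance by default; a denoiser may return a second output
channel interpreted as the per-pixel interpolation coefficient between
log(beta_t) and log(beta_tilde_t), in which case that learned variance is
used instead.

Images live in [0,1] at the module boundary and in [-1,1] internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Adam, SmallUNet


# ---------------------------------------------------------------------------
# schedule

@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step variances of the forward process; index t runs 1..T."""

    T: int
    betas: np.ndarray          # shape (T,), betas[t-1] = beta_t
    alphas: np.ndarray         # 1 - beta
    alpha_bars: np.ndarray     # cumulative products, abar[t-1] = abar_t

    def alpha_bar(self, t) -> np.ndarray:
        """abar_t with the convention abar_0 = 1; accepts scalars or arrays."""
        t = np.asarray(t)
        ab = np.concatenate([[1.0], self.alpha_bars])
        return ab[t]

    def posterior_variance(self, t) -> np.ndarray:
        """beta_tilde_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t."""
        t = np.asarray(t)
        ab_prev = self.alpha_bar(t - 1)
        ab = self.alpha_bar(t)
        return (1.0 - ab_prev) / (1.0 - ab) * self.betas[t - 1]


def make_linear_schedule(T: int, beta_min: float = 1e-4, beta_max: float = 0.02) -> NoiseSchedule:
    if T < 2:
        raise ValueError("T must be >= 2")
    if not (0.0 < beta_min < beta_max < 1.0):
        raise ValueError("need 0 < beta_min < beta_max < 1")
    betas = np.linspace(beta_min, beta_max, T, dtype=np.float64)
    alphas = 1.0 - betas
    return NoiseSchedule(T=T, betas=betas, alphas=alphas,
                         alpha_bars=np.cumprod(alphas))


def default_schedule(T: int = 250) -> NoiseSchedule:
    """Linear schedule whose endpoint noise level matches the T=1000
    reference (beta bounds scaled by 1000/T; capped below 1 so very short
    test schedules stay valid)."""
    scale = 1000.0 / T
    return make_linear_schedule(T, min(1e-4 * scale, 0.05), min(0.02 * scale, 0.35))


# ---------------------------------------------------------------------------
# forward / reverse primitives

def _bcast(a: np.ndarray, ndim: int) -> np.ndarray:
    return np.asarray(a, dtype=np.float32).reshape((-1,) + (1,) * (ndim - 1))


def q_sample(x0: np.ndarray, t, noise: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward marginal x_t | x0."""
    t = np.atleast_1d(np.asarray(t))
    if np.any(t < 0) or np.any(t > schedule.T):
        raise ValueError("t out of range")
    ab = _bcast(schedule.alpha_bar(t), x0.ndim)
    return (np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise).astype(np.float32)


def predict_x0(x_t: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Denoised estimate x0_hat = (x_t - sqrt(1-abar_t) eps) / sqrt(abar_t)."""
    t = np.atleast_1d(np.asarray(t))
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError("t out of range (need 1 <= t <= T)")
    ab = _bcast(schedule.alpha_bar(t), x_t.ndim)
    if np.any(ab <= 0):
        raise ValueError("alpha_bar must be positive")
    return ((x_t - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab)).astype(np.float32)


@dataclass
class NoisyState:
    """The reverse-process state at step t (internal [-1,1] value range)."""

    x_t: np.ndarray
    t: int
    x0_hat: np.ndarray | None = None


def reverse_step(state: NoisyState, denoiser, schedule: NoiseSchedule,
                 mean_shift: np.ndarray | float = 0.0,
                 rng: np.random.Generator | None = None) -> NoisyState:
    """One guided DDPM reverse transition t -> t-1.

    ``denoiser(x_t, t_array)`` returns eps_hat, or a tuple ``(eps_hat, v)``
    where v in [0,1] interpolates the log-variance between beta_tilde_t and
    beta_t.  ``mean_shift`` is added to the posterior mean (zero for plain
    unconditional sampling).  No noise is added at t=1.
    """
    t = state.t
    if t < 1:
        raise ValueError("reverse_step needs t >= 1")
    rng = rng or np.random.default_rng()
    x_t = state.x_t
    n = x_t.shape[0]
    out = denoiser(x_t, np.full(n, t, dtype=np.int64))
    if isinstance(out, tuple):
        eps, v = out
        logvar = (np.clip(v, 0.0, 1.0) * np.log(schedule.betas[t - 1])
                  + (1.0 - np.clip(v, 0.0, 1.0))
                  * np.log(max(schedule.posterior_variance(t), 1e-20)))
        var = np.exp(logvar).astype(np.float32)
    else:
        eps = out
        var = np.float32(schedule.posterior_variance(t))
    beta = schedule.betas[t - 1]
    alpha = schedule.alphas[t - 1]
    ab = schedule.alpha_bar(t)
    mu = (x_t - beta / np.sqrt(1.0 - ab) * eps) / np.sqrt(alpha)
    mu = mu + mean_shift
    if t > 1:
        x_prev = mu + np.sqrt(var) * rng.standard_normal(x_t.shape).astype(np.float32)
    else:
        x_prev = mu
    x0_hat = predict_x0(x_t, t, eps, schedule)
    return NoisyState(x_t=x_prev.astype(np.float32), t=t - 1, x0_hat=x0_hat)


# ---------------------------------------------------------------------------
# trainable model

def to_internal(x01: np.ndarray) -> np.ndarray:
    return (2.0 * np.asarray(x01, dtype=np.float32) - 1.0)


def to_unit(x: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(x, dtype=np.float32) + 1.0) / 2.0, 0.0, 1.0)


class DenoisingDiffusion(BaseEstimator):
    """Unconditional DDPM with a small UNet noise predictor.

    Parameters
    ----------
    T : number of diffusion steps (linear beta schedule, endpoint-matched
        to the T=1000 reference).
    base_channels : width of the UNet at full resolution.
    n_iter : training minibatch iterations.
    batch_size, lr : optimizer settings (Adam).
    random_state : seed for init, batch order and noise draws.

    Fitted attributes: ``net_``, ``schedule_``, ``loss_history_``.
    """

    def __init__(self, T: int = 250, base_channels: int = 8, n_iter: int = 2000,
                 batch_size: int = 16, lr: float = 2e-3, log_every: int = 100,
                 random_state: int = 0):
        self.T = T
        self.base_channels = base_channels
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.lr = lr
        self.log_every = log_every
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "DenoisingDiffusion":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty (N,C,H,W) array in [0,1]")
        rng = np.random.default_rng([self.random_state, 101])
        self.schedule_ = default_schedule(self.T)
        self.net_ = SmallUNet(X.shape[1], self.base_channels, rng=rng)
        opt = Adam(self.net_.parameters(), lr=self.lr)
        data = to_internal(X)
        n = data.shape[0]
        self.loss_history_ = []
        run = None
        for it in range(self.n_iter):
            idx = rng.integers(0, n, size=self.batch_size)
            x0 = data[idx]
            t = rng.integers(1, self.T + 1, size=self.batch_size)
            noise = rng.standard_normal(x0.shape).astype(np.float32)
            x_t = q_sample(x0, t, noise, self.schedule_)
            eps = self.net_.forward(x_t, t)
            resid = eps - noise
            loss = float(np.mean(resid ** 2))
            run = loss if run is None else 0.98 * run + 0.02 * loss
            opt.zero_grad()
            self.net_.backward((2.0 / resid.size) * resid)
            opt.step()
            if (it + 1) % self.log_every == 0 or it == 0:
                self.loss_history_.append((it + 1, run))
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.image_shape_ = X.shape[1:]
        return self

    # denoiser protocol -----------------------------------------------------
    def predict_eps(self, x_t: np.ndarray, t: np.ndarray) -> np.ndarray:
        return self.net_.forward(x_t, np.asarray(t, dtype=np.int64))

    def eps_vjp(self, cotangent: np.ndarray) -> np.ndarray:
        """Vector-Jacobian product d(eps)/d(x_t)^T @ cotangent for the most
        recent ``predict_eps`` call (cache reuse; may be called repeatedly)."""
        return self.net_.backward(cotangent, param_grads=False)

    def sample(self, n: int, rng: np.random.Generator | int | None = None,
               return_trajectory: bool = False):
        """Unconditional samples mapped back to [0,1]."""
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        c, h, w = self.image_shape_
        state = NoisyState(
            x_t=rng.standard_normal((n, c, h, w)).astype(np.float32),
            t=self.schedule_.T)
        traj = []
        while state.t > 0:
            state = reverse_step(state, self.predict_eps, self.schedule_, 0.0, rng)
            if return_trajectory:
                traj.append(state)
        imgs = to_unit(state.x_t)
        return (imgs, traj) if return_trajectory else imgs

    def get_state(self) -> dict:
        return self.net_.get_state()

    def set_state(self, state: dict, image_shape=None) -> None:
        if image_shape is not None and not hasattr(self, "net_"):
            rng = np.random.default_rng([self.random_state, 101])
            self.schedule_ = default_schedule(self.T)
            self.net_ = SmallUNet(image_shape[0], self.base_channels, rng=rng)
            self.image_shape_ = tuple(image_shape)
        self.net_.set_state(state)


def train_denoiser(dataset, schedule_T: int = 250, iterations: int = 2000,
                   batch_size: int = 16, lr: float = 2e-3,
                   rng_seed: int = 0, base_channels: int = 8) -> DenoisingDiffusion:
    """Functional wrapper: train an epsilon-predictor on a list of
    ``LabeledImage`` or an (N,C,H,W) array."""
    if hasattr(dataset, "__len__") and len(dataset) == 0:
        raise ValueError("empty dataset")
    if isinstance(dataset, np.ndarray):
        X = dataset
    else:
        X = np.stack([im.pixels for im in dataset])
    model = DenoisingDiffusion(T=schedule_T, n_iter=iterations, batch_size=batch_size,
                               lr=lr, random_state=rng_seed, base_channels=base_channels)
    return model.fit(X)


def sample_unconditional(model: DenoisingDiffusion, n: int, rng_seed: int = 0) -> np.ndarray:
    return model.sample(n, rng=np.random.default_rng([rng_seed, 77]))
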