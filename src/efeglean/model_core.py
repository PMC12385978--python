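"""PV-RNN generative model core.

A predictive-coding-inspired variational RNN with, per layer, deterministic
units ``d = tanh(h)`` evolving as leaky integrators with time constant
``tau`` and stochastic units ``z`` with a learned Gaussian prior conditioned
on ``d_{t-1}``.  The approximate posterior at every (sequence, step, layer)
is parameterised by free *adaptive vectors* ``A`` rather than an amortised
encoder; after training, these are the only quantities any optimizer touches.

The module exposes both the small algebraic primitives (``prior_params``,
``sample_latent``, ``step_dynamics``, ``gaussian_kl``, ...) and a fused
forward/backward engine over a time window (:func:`forward_posterior`,
:func:`backward_window`) used by training and by online inference.  All
array functions are batched over a leading axis.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SIGMA_CLIP",
    "LayerConfig",
    "ModelSpec",
    "ModelWeights",
    "SequenceBatch",
    "prior_params",
    "posterior_params",
    "sample_latent",
    "step_dynamics",
    "project_outputs",
    "gaussian_kl",
    "WindowStates",
    "forward_posterior",
    "rollout_prior",
    "backward_window",
    "kl_weight_schedule",
]

# Pre-exponential clamp for all log-sigma quantities (numerical safety).
SIGMA_CLIP = (-10.0, 6.0)


@dataclass(frozen=True)
class LayerConfig:
    """Static configuration of one PV-RNN layer.

    Parameters
    ----------
    num_d : number of deterministic units.
    num_z : number of stochastic units.
    tau : leaky-integrator time constant (>= 1; tau = 1 means no carry-over).
    meta_prior_w : weight on this layer's KL term in the free energy
        (the *meta-prior*); the initial time step always uses weight 1.0.
    """

    num_d: int
    num_z: int
    tau: float
    meta_prior_w: float

    def __post_init__(self) -> None:
        if self.num_d < 1 or self.num_z < 1:
            raise ValueError("num_d and num_z must be >= 1")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.meta_prior_w <= 0:
            raise ValueError("meta_prior_w must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Model topology: layer stack (index 0 = lowest, projects to outputs)
    plus the observation/goal split of the output vector.

    ``proprio_dim`` is the leading block of the observation that the agent
    can directly control (discrete position one-hot, or (x, y) pose).
    """

    layers: tuple[LayerConfig, ...]
    obs_dim: int
    goal_dim: int
    proprio_dim: int

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        if not (0 < self.proprio_dim <= self.obs_dim):
            raise ValueError("proprio_dim must lie in (0, obs_dim]")

    @property
    def out_dim(self) -> int:
        return self.obs_dim + self.goal_dim

    @property
    def num_layers(self) -> int:
        return len(self.layers)


@dataclass
class SequenceBatch:
    """Training targets for a batch of sequences: ``obs`` (B, T, Dx) and
    ``goal`` (B, T, Dg), with an optional per-step validity mask (B, T)."""

    obs: np.ndarray
    goal: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.obs.ndim != 3 or self.goal.ndim != 3:
            raise ValueError("obs and goal must be (B, T, D) arrays")
        if self.obs.shape[:2] != self.goal.shape[:2]:
            raise ValueError("obs and goal must share (B, T)")

    @property
    def targets(self) -> np.ndarray:
        return np.concatenate([self.obs, self.goal], axis=-1)


class ModelWeights:
    """All trainable connectivity of the network.

    Per layer ``l``: recurrent map ``w_hd[l]`` (Rd, Rd), latent map
    ``w_hz[l]`` (Rd, Rz), top-down map ``w_td[l]`` (Rd_l, Rd_{l+1}) for all
    but the top layer, prior maps ``w_mu``/``w_sig`` (Rz, Rd) and biases;
    plus the affine output projection from the lowest layer's ``d``.
    Weights can be frozen after training; a checksum guards against
    accidental updates.
    """

    #: ordered roles; w_td is absent for the top layer
    _LAYER_ROLES = ("w_hd", "w_hz", "w_td", "b_h", "w_mu", "b_mu", "w_sig", "b_sig")

    def __init__(self, spec: ModelSpec, seed: int | None = 0):
        self.spec = spec
        self._frozen_checksum: str | None = None
        rng = np.random.default_rng(seed)
        L = spec.num_layers
        self.w_hd, self.w_hz, self.w_td, self.b_h = [], [], [], []
        self.w_mu, self.b_mu, self.w_sig, self.b_sig = [], [], [], []
        for l, cfg in enumerate(spec.layers):
            self.w_hd.append(_init(rng, (cfg.num_d, cfg.num_d)))
            self.w_hz.append(_init(rng, (cfg.num_d, cfg.num_z)))
            if l < L - 1:
                self.w_td.append(_init(rng, (cfg.num_d, spec.layers[l + 1].num_d)))
            else:
                self.w_td.append(None)
            self.b_h.append(np.zeros(cfg.num_d))
            self.w_mu.append(_init(rng, (cfg.num_z, cfg.num_d)))
            self.b_mu.append(np.zeros(cfg.num_z))
            self.w_sig.append(_init(rng, (cfg.num_z, cfg.num_d)))
            self.b_sig.append(np.zeros(cfg.num_z))
        self.w_out = _init(rng, (spec.out_dim, spec.layers[0].num_d))
        self.b_out = np.zeros(spec.out_dim)

    # -- parameter plumbing ------------------------------------------------
    def param_list(self) -> list[np.ndarray]:
        """Flat, ordered list of all weight arrays (views, not copies)."""
        out: list[np.ndarray] = []
        for l in range(self.spec.num_layers):
            for role in self._LAYER_ROLES:
                arr = getattr(self, role)[l]
                if arr is not None:
                    out.append(arr)
        out.extend([self.w_out, self.b_out])
        return out

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        if self._frozen_checksum is not None:
            raise RuntimeError("weights are frozen")
        params = self.param_list()
        if len(params) != len(values):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(params, values):
            if dst.shape != src.shape:
                raise ValueError("parameter shape mismatch")
            dst[...] = src

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in self.param_list():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def freeze(self) -> None:
        self._frozen_checksum = self.checksum()

    @property
    def frozen(self) -> bool:
        return self._frozen_checksum is not None

    def assert_frozen_intact(self) -> None:
        if self._frozen_checksum is None:
            raise RuntimeError("weights were never frozen")
        if self.checksum() != self._frozen_checksum:
            raise RuntimeError("frozen weights were modified")

    def copy(self) -> "ModelWeights":
        other = ModelWeights(self.spec, seed=None)
        for dst, src in zip(other.param_list(), self.param_list()):
            dst[...] = src
        other._frozen_checksum = self._frozen_checksum
        return other

    # -- serialisation -----------------------------------------------------
    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for l in range(self.spec.num_layers):
            for role in self._LAYER_ROLES:
                arr = getattr(self, role)[l]
                if arr is not None:
                    out[f"layer{l}/{role}"] = arr
        out["out/w_out"] = self.w_out
        out["out/b_out"] = self.b_out
        return out

    @classmethod
    def from_arrays(cls, spec: ModelSpec, arrays: dict[str, np.ndarray],
                    frozen: bool = False) -> "ModelWeights":
        w = cls(spec, seed=None)
        for key, ref in w.to_arrays().items():
            if key not in arrays:
                raise ValueError(f"checkpoint missing array {key!r}")
            if arrays[key].shape != ref.shape:
                raise ValueError(
                    f"checkpoint array {key!r} has shape {arrays[key].shape}, "
                    f"config implies {ref.shape}")
            ref[...] = arrays[key]
        if frozen:
            w.freeze()
        return w


def _init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Small scaled-uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    a = 1.0 / np.sqrt(shape[-1])
    return rng.uniform(-a, a, size=shape)


# ---------------------------------------------------------------------------
# algebraic primitives
# ---------------------------------------------------------------------------

def prior_params(d_prev: np.ndarray | None, weights: ModelWeights, layer: int,
                 num_z: int | None = None):
    """Gaussian prior stats for layer ``layer`` conditioned on ``d_{t-1}``.

    ``mu_p = tanh(W_mu d + b)``, ``sigma_p = exp(W_sig d + b)``.  At the very
    first time step (``d_prev is None``) the prior is the unit Gaussian.
    """
    cfg = weights.spec.layers[layer]
    if d_prev is None:
        rz = cfg.num_z if num_z is None else num_z
        return np.zeros(rz), np.ones(rz)
    d_prev = np.asarray(d_prev, dtype=float)
    if d_prev.shape[-1] != cfg.num_d:
        raise ValueError(
            f"d_prev last dim {d_prev.shape[-1]} != num_d {cfg.num_d}")
    mu = np.tanh(d_prev @ weights.w_mu[layer].T + weights.b_mu[layer])
    pre = np.clip(d_prev @ weights.w_sig[layer].T + weights.b_sig[layer], *SIGMA_CLIP)
    return mu, np.exp(pre)


def posterior_params(a_mu: np.ndarray, a_sig: np.ndarray):
    """Posterior stats from an adaptive-vector entry:
    ``mu_q = tanh(A_mu)``, ``sigma_q = exp(A_sig)`` (clamped pre-exponential)."""
    a_mu = np.asarray(a_mu, dtype=float)
    a_sig = np.asarray(a_sig, dtype=float)
    if not (np.all(np.isfinite(a_mu)) and np.all(np.isfinite(a_sig))):
        raise ValueError("adaptive vector contains non-finite entries")
    return np.tanh(a_mu), np.exp(np.clip(a_sig, *SIGMA_CLIP))


def sample_latent(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Reparameterised draw ``z = mu + sigma * eps``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return np.asarray(mu, dtype=float) + sigma * np.asarray(eps, dtype=float)


def step_dynamics(h_prev, d_prev, z, top_down_d, weights: ModelWeights, layer: int):
    """One leaky-integrator update of layer ``layer``:

    ``h = (1 - 1/tau) h_prev + (1/tau)(W_hd d_prev + W_hz z + W_td d_td + b)``
    and ``d = tanh(h)``.  ``top_down_d`` is the *higher* layer's previous-step
    activation; pass ``None`` for the top layer.
    """
    cfg = weights.spec.layers[layer]
    tau = cfg.tau
    u = (np.asarray(d_prev, dtype=float) @ weights.w_hd[layer].T
         + np.asarray(z, dtype=float) @ weights.w_hz[layer].T
         + weights.b_h[layer])
    if top_down_d is not None:
        if weights.w_td[layer] is None:
            raise ValueError("top layer takes no top-down input")
        u = u + np.asarray(top_down_d, dtype=float) @ weights.w_td[layer].T
    h = (1.0 - 1.0 / tau) * np.asarray(h_prev, dtype=float) + u / tau
    return h, np.tanh(h)


def project_outputs(d_lowest: np.ndarray, weights: ModelWeights):
    """Affine readout of the lowest layer's activation into the concatenated
    (observation, goal) space; no output nonlinearity."""
    y = np.asarray(d_lowest, dtype=float) @ weights.w_out.T + weights.b_out
    dx = weights.spec.obs_dim
    return y[..., :dx], y[..., dx:]


def gaussian_kl(post_mu, post_sigma, prior_mu, prior_sigma) -> np.ndarray:
    """KL(N(mu_q, sig_q^2) || N(mu_p, sig_p^2)) for diagonal Gaussians,
    summed over the last axis.  Nonnegative; zero iff the stats coincide."""
    mq, sq = np.asarray(post_mu, float), np.asarray(post_sigma, float)
    mp, sp = np.asarray(prior_mu, float), np.asarray(prior_sigma, float)
    if np.any(sq <= 0) or np.any(sp <= 0):
        raise ValueError("sigmas must be strictly positive")
    term = np.log(sp / sq) + (sq ** 2 + (mq - mp) ** 2) / (2.0 * sp ** 2) - 0.5
    return term.sum(axis=-1)


def kl_weight_schedule(spec: ModelSpec, T: int, t0_abs: int) -> np.ndarray:
    """(T, L) array of per-step, per-layer KL weights: the layer meta-prior
    everywhere except the sequence's very first step, whose KL (taken
    against the unit-Gaussian initial prior) is weighted 1.0 so the initial
    latent stays calibrated to the sampling distribution."""
    kw = np.empty((T, spec.num_layers))
    for l, cfg in enumerate(spec.layers):
        kw[:, l] = cfg.meta_prior_w
    if t0_abs == 0 and T > 0:
        kw[0, :] = 1.0
    return kw


# ---------------------------------------------------------------------------
# fused window engine
# ---------------------------------------------------------------------------

class WindowStates:
    """Per-layer, per-step state of a forward pass over a window.

    Lists indexed ``[layer][t]`` of (B, R) arrays; ``y`` is (B, T, Dy).
    ``h0``/``d0`` hold the state entering the window.
    """

    def __init__(self, spec: ModelSpec, T: int, t0_abs: int):
        self.spec = spec
        self.T = T
        self.t0_abs = t0_abs
        L = spec.num_layers
        self.h = [[None] * T for _ in range(L)]
        self.d = [[None] * T for _ in range(L)]
        self.z = [[None] * T for _ in range(L)]
        self.mu_q = [[None] * T for _ in range(L)]
        self.sig_q = [[None] * T for _ in range(L)]
        self.mu_p = [[None] * T for _ in range(L)]
        self.sig_p = [[None] * T for _ in range(L)]
        self.sig_p_open = [[None] * T for _ in range(L)]  # clip-gradient mask
        self.eps = [[None] * T for _ in range(L)]
        self.h0: list[np.ndarray] = []
        self.d0: list[np.ndarray] = []
        self.y: np.ndarray | None = None

    def kl_matrix(self) -> np.ndarray:
        """Unweighted KL terms, shape (B, T, L)."""
        B = self.y.shape[0]
        out = np.empty((B, self.T, self.spec.num_layers))
        for l in range(self.spec.num_layers):
            for t in range(self.T):
                out[:, t, l] = gaussian_kl(self.mu_q[l][t], self.sig_q[l][t],
                                           self.mu_p[l][t], self.sig_p[l][t])
        return out


def _zero_state(spec: ModelSpec, B: int):
    h0 = [np.zeros((B, cfg.num_d)) for cfg in spec.layers]
    return h0, [np.zeros((B, cfg.num_d)) for cfg in spec.layers]


def forward_posterior(weights: ModelWeights, A_mu: list[np.ndarray],
                      A_sig: list[np.ndarray], *, h0=None, d0=None,
                      t0_abs: int = 0, eps: list[np.ndarray] | None = None
                      ) -> WindowStates:
    """Posterior-driven forward pass over a window of T steps.

    ``A_mu[l]``/``A_sig[l]`` are (B, T, Rz_l) adaptive vectors.  ``eps[l]``
    (same shape) supplies reparameterisation noise; ``None`` propagates the
    posterior mean (``z = mu_q``), which makes the pass deterministic.
    Prior stats along the realised trajectory are recorded for KL terms.
    """
    spec = weights.spec
    L = spec.num_layers
    B, T = A_mu[0].shape[:2]
    if h0 is None:
        h0, d0 = _zero_state(spec, B)
    st = WindowStates(spec, T, t0_abs)
    st.h0, st.d0 = h0, d0
    h_prev, d_prev = list(h0), list(d0)
    ys = np.empty((B, T, spec.out_dim))
    for t in range(T):
        h_new, d_new = [], []
        for l in range(L):
            cfg = spec.layers[l]
            if t0_abs + t == 0:
                mu_p = np.zeros((B, cfg.num_z))
                sig_p = np.ones((B, cfg.num_z))
                st.sig_p_open[l][t] = np.ones((B, cfg.num_z), dtype=bool)
            else:
                mu_p = np.tanh(d_prev[l] @ weights.w_mu[l].T + weights.b_mu[l])
                pre = d_prev[l] @ weights.w_sig[l].T + weights.b_sig[l]
                st.sig_p_open[l][t] = (pre > SIGMA_CLIP[0]) & (pre < SIGMA_CLIP[1])
                sig_p = np.exp(np.clip(pre, *SIGMA_CLIP))
            mu_q = np.tanh(A_mu[l][:, t])
            sig_q = np.exp(np.clip(A_sig[l][:, t], *SIGMA_CLIP))
            if eps is None:
                e = None
                z = mu_q
            else:
                e = eps[l][:, t]
                z = mu_q + sig_q * e
            u = d_prev[l] @ weights.w_hd[l].T + z @ weights.w_hz[l].T + weights.b_h[l]
            if l < L - 1:
                u = u + d_prev[l + 1] @ weights.w_td[l].T
            tau = 1.0 if t0_abs + t == 0 else cfg.tau  # leak-free first step
            h = (1.0 - 1.0 / tau) * h_prev[l] + u / tau
            d = np.tanh(h)
            st.mu_p[l][t], st.sig_p[l][t] = mu_p, sig_p
            st.mu_q[l][t], st.sig_q[l][t] = mu_q, sig_q
            st.z[l][t], st.eps[l][t] = z, e
            st.h[l][t], st.d[l][t] = h, d
            h_new.append(h)
            d_new.append(d)
        h_prev, d_prev = h_new, d_new
        ys[:, t] = d_new[0] @ weights.w_out.T + weights.b_out
    st.y = ys
    return st


def rollout_prior(weights: ModelWeights, *, h0=None, d0=None, steps: int,
                  t0_abs: int = 0, eps: list[np.ndarray] | None = None,
                  B: int | None = None) -> WindowStates:
    """Prior-driven rollout: each step samples ``z`` from the learned prior
    (``z = mu_p + sig_p * eps``; mean rollout if ``eps`` is ``None``) and
    propagates the dynamics.  Posterior stats are set equal to the prior so
    the returned window has zero KL by construction.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    spec = weights.spec
    L = spec.num_layers
    if h0 is None:
        if B is None:
            B = 1 if eps is None else eps[0].shape[0]
        h0, d0 = _zero_state(spec, B)
    else:
        B = h0[0].shape[0]
    st = WindowStates(spec, steps, t0_abs)
    st.h0, st.d0 = list(h0), list(d0)
    h_prev, d_prev = list(h0), list(d0)
    ys = np.empty((B, steps, spec.out_dim))
    for t in range(steps):
        h_new, d_new = [], []
        for l in range(L):
            cfg = spec.layers[l]
            if t0_abs + t == 0:
                mu_p = np.zeros((B, cfg.num_z))
                sig_p = np.ones((B, cfg.num_z))
            else:
                mu_p = np.tanh(d_prev[l] @ weights.w_mu[l].T + weights.b_mu[l])
                pre = np.clip(d_prev[l] @ weights.w_sig[l].T + weights.b_sig[l],
                              *SIGMA_CLIP)
                sig_p = np.exp(pre)
            e = None if eps is None else eps[l][:, t]
            z = mu_p if e is None else mu_p + sig_p * e
            u = d_prev[l] @ weights.w_hd[l].T + z @ weights.w_hz[l].T + weights.b_h[l]
            if l < L - 1:
                u = u + d_prev[l + 1] @ weights.w_td[l].T
            tau = 1.0 if t0_abs + t == 0 else cfg.tau  # leak-free first step
            h = (1.0 - 1.0 / tau) * h_prev[l] + u / tau
            d = np.tanh(h)
            st.mu_p[l][t], st.sig_p[l][t] = mu_p, sig_p
            st.mu_q[l][t], st.sig_q[l][t] = mu_p, sig_p
            st.z[l][t], st.eps[l][t] = z, e
            st.h[l][t], st.d[l][t] = h, d
            h_new.append(h)
            d_new.append(d)
        h_prev, d_prev = h_new, d_new
        ys[:, t] = d_new[0] @ weights.w_out.T + weights.b_out
    st.y = ys
    return st


def backward_window(weights: ModelWeights, st: WindowStates, *,
                    grad_y: np.ndarray | None,
                    kl_weights: np.ndarray | None,
                    A_sig: list[np.ndarray],
                    need_weight_grads: bool = False,
                    batch_scale: float = 1.0):
    """Reverse-mode gradients of

    ``batch_scale * sum_b [ sum_{t,l} kw[t,l] KL_{b,t,l} + recon_b ]``

    through a posterior-driven window, where the reconstruction seed
    ``grad_y`` is d(recon)/d(y) (e.g. ``mask * (y - target)`` for the
    half-squared-error likelihood).  Returns ``(gA_mu, gA_sig[, gW])``:
    adaptive-vector gradients per layer (B, T, Rz), and — when
    ``need_weight_grads`` — weight gradients ordered like ``param_list()``.
    """
    spec = weights.spec
    L = spec.num_layers
    T = st.T
    B = st.y.shape[0]
    s = batch_scale

    gA_mu = [np.zeros_like(a) for a in A_sig]  # same shapes as A arrays
    gA_sig = [np.zeros_like(a) for a in A_sig]
    if need_weight_grads:
        gW = {k: np.zeros_like(v) for k, v in weights.to_arrays().items()}

    gd_next = [np.zeros((B, cfg.num_d)) for cfg in spec.layers]
    gh_next = [np.zeros((B, cfg.num_d)) for cfg in spec.layers]

    for t in range(T - 1, -1, -1):
        gd_cur = gd_next
        gh_cur = gh_next
        gd_next = [np.zeros((B, cfg.num_d)) for cfg in spec.layers]
        gh_next = [np.zeros((B, cfg.num_d)) for cfg in spec.layers]
        if grad_y is not None:
            gy = s * grad_y[:, t]
            gd_cur[0] = gd_cur[0] + gy @ weights.w_out
            if need_weight_grads:
                gW["out/w_out"] += gy.T @ st.d[0][t]
                gW["out/b_out"] += gy.sum(axis=0)
        for l in range(L):
            cfg = spec.layers[l]
            d_prev = st.d0[l] if t == 0 else st.d[l][t - 1]
            tau = 1.0 if st.t0_abs + t == 0 else cfg.tau
            gh = gh_cur[l] + gd_cur[l] * (1.0 - st.d[l][t] ** 2)
            gh_next[l] += gh * (1.0 - 1.0 / tau)
            gu = gh / tau
            # recurrent / latent / top-down inputs
            gd_prev_l = gu @ weights.w_hd[l]
            gz = gu @ weights.w_hz[l]
            if need_weight_grads:
                gW[f"layer{l}/w_hd"] += gu.T @ d_prev
                gW[f"layer{l}/w_hz"] += gu.T @ st.z[l][t]
                gW[f"layer{l}/b_h"] += gu.sum(axis=0)
            if l < L - 1:
                d_prev_td = st.d0[l + 1] if t == 0 else st.d[l + 1][t - 1]
                gd_next[l + 1] += gu @ weights.w_td[l]
                if need_weight_grads:
                    gW[f"layer{l}/w_td"] += gu.T @ d_prev_td
            # z = mu_q + sig_q * eps
            g_mu_q = gz.copy()
            g_sig_q = np.zeros_like(gz) if st.eps[l][t] is None else gz * st.eps[l][t]
            # KL(q||p) contributions
            mu_q, sig_q = st.mu_q[l][t], st.sig_q[l][t]
            mu_p, sig_p = st.mu_p[l][t], st.sig_p[l][t]
            if kl_weights is not None and kl_weights[t, l] != 0.0:
                kw = s * kl_weights[t, l]
                diff = mu_q - mu_p
                g_mu_q += kw * diff / sig_p ** 2
                g_sig_q += kw * (sig_q / sig_p ** 2 - 1.0 / sig_q)
                if st.t0_abs + t > 0:
                    g_mu_p = -kw * diff / sig_p ** 2
                    g_sig_p = kw * (1.0 / sig_p
                                    - (sig_q ** 2 + diff ** 2) / sig_p ** 3)
                    ga_mu_p = g_mu_p * (1.0 - mu_p ** 2)
                    ga_sig_p = g_sig_p * sig_p * st.sig_p_open[l][t]
                    gd_prev_l = (gd_prev_l + ga_mu_p @ weights.w_mu[l]
                                 + ga_sig_p @ weights.w_sig[l])
                    if need_weight_grads:
                        gW[f"layer{l}/w_mu"] += ga_mu_p.T @ d_prev
                        gW[f"layer{l}/b_mu"] += ga_mu_p.sum(axis=0)
                        gW[f"layer{l}/w_sig"] += ga_sig_p.T @ d_prev
                        gW[f"layer{l}/b_sig"] += ga_sig_p.sum(axis=0)
            # chain into adaptive vectors
            a_sig = A_sig[l][:, t]
            open_mask = (a_sig > SIGMA_CLIP[0]) & (a_sig < SIGMA_CLIP[1])
            gA_mu[l][:, t] = g_mu_q * (1.0 - mu_q ** 2)
            gA_sig[l][:, t] = g_sig_q * sig_q * open_mask
            gd_next[l] += gd_prev_l
        # gradients flowing into h0/d0 (gh_next/gd_next at t == 0) are
        # discarded: windows are truncation boundaries.

    if need_weight_grads:
        order = [k for k in weights.to_arrays().keys()]
        return gA_mu, gA_sig, [gW[k] for k in order]
    return gA_mu, gA_sig
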