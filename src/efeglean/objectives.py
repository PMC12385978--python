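"""Free-energy functionals.

Two windows, two functionals.  Over *observed* (past or training) steps the
agent minimises the evidence free energy

    Fe = sum_t [ sum_l w_l KL(q_tl || p_tl) + 1/2 ||y_t - target_t||^2 ],

a weighted KL regulariser (the per-layer *meta-prior* ``w``, fixed to 1.0 at
the sequence's first step) plus a Gaussian reconstruction term with unit
likelihood variance.  Over *future* steps the planner scores a candidate
trajectory by the expected free energy

    G = sum_t [ -KL(q_tl || p_tl) + ||gbar_t - ghat||^2 / (2 m) ],

whose KL term enters with the opposite sign — in the future the agent seeks
divergence between the posterior (conditioned on its own predicted
outcomes) and the prior, i.e. expected information gain — and whose goal
error is precision-weighted by an adaptive preference variance ``m``: the
median absolute deviation of all candidates' predicted observations.  Small
``m`` (candidates agree; little left to learn) sharpens the preference and
tips the agent from exploration into goal exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import SequenceBatch, WindowStates, gaussian_kl

__all__ = [
    "FreeEnergyBreakdown",
    "PreferenceSpec",
    "ScoreBreakdown",
    "evidence_free_energy",
    "free_energy_from_window",
    "preference_variance",
    "expected_free_energy",
]

DEFAULT_VARIANCE_FLOOR = 1e-3


@dataclass
class FreeEnergyBreakdown:
    """Evidence free energy of a (batch of) window(s), with per-step terms.

    ``kl_per_step_layer``: (B, T, L) meta-prior-weighted KL terms;
    ``recon_per_step``: (B, T) half-squared reconstruction errors;
    ``total``: (B,) sums of both.
    """

    kl_per_step_layer: np.ndarray
    recon_per_step: np.ndarray
    total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.kl_per_step_layer.sum(axis=(1, 2))
                      + self.recon_per_step.sum(axis=1))

    @property
    def kl_sum(self) -> np.ndarray:
        return self.kl_per_step_layer.sum(axis=(1, 2))

    @property
    def recon_sum(self) -> np.ndarray:
        return self.recon_per_step.sum(axis=1)


@dataclass(frozen=True)
class PreferenceSpec:
    """Prior preference over the goal block: a Gaussian centred on the
    preferred goal ``ghat`` whose variance is either fixed at 1 or set
    adaptively to the candidate ensemble's MAD (floored)."""

    preferred_goal: np.ndarray
    variance_mode: str = "adaptive"  # "adaptive" | "fixed"
    variance_floor: float = DEFAULT_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if self.variance_mode not in ("adaptive", "fixed"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class ScoreBreakdown:
    """Expected free energy of one candidate plan: ``G = -epistemic + extrinsic``."""

    epistemic_sum: float
    extrinsic_sum: float

    @property
    def G(self) -> float:
        return self.extrinsic_sum - self.epistemic_sum


def evidence_free_energy(post_mu, post_sigma, prior_mu, prior_sigma,
                         outputs: np.ndarray, targets: SequenceBatch,
                         kl_weights: np.ndarray,
                         recon_mask: np.ndarray | None = None
                         ) -> FreeEnergyBreakdown:
    """Evidence free energy assembled from raw per-step stats.

    ``post_mu[l]`` etc. are lists over layers of per-step lists of (B, Rz)
    stats (the layout produced by the forward engine); ``outputs`` is
    (B, T, Dy).  ``kl_weights`` is the (T, L) schedule.  ``recon_mask``
    optionally restricts the reconstruction term to a subset of output
    dimensions and/or steps (broadcastable against ``outputs``).
    """
    tgt = targets.targets
    if outputs.shape != tgt.shape:
        raise ValueError("outputs and targets are misaligned")
    B, T, _ = outputs.shape
    L = len(post_mu)
    kl = np.empty((B, T, L))
    for l in range(L):
        for t in range(T):
            kl[:, t, l] = kl_weights[t, l] * gaussian_kl(
                post_mu[l][t], post_sigma[l][t], prior_mu[l][t], prior_sigma[l][t])
    err = outputs - tgt
    if recon_mask is not None:
        err = err * recon_mask
    if targets.mask is not None:
        err = err * targets.mask[..., None]
    recon = 0.5 * (err ** 2).sum(axis=-1)
    return FreeEnergyBreakdown(kl, recon)


def free_energy_from_window(st: WindowStates, targets: SequenceBatch,
                            kl_weights: np.ndarray,
                            recon_mask: np.ndarray | None = None
                            ) -> FreeEnergyBreakdown:
    """Convenience wrapper taking a forward-engine window."""
    return evidence_free_energy(st.mu_q, st.sig_q, st.mu_p, st.sig_p,
                                st.y, targets, kl_weights, recon_mask)


def preference_variance(predicted_obs: np.ndarray,
                        floor: float = DEFAULT_VARIANCE_FLOOR) -> float:
    """Adaptive preference variance ``m``: the median absolute deviation of
    the candidate ensemble's predicted observations.

    ``predicted_obs`` is (N, T_future, Dx); deviations are taken against the
    across-sample mean at each (step, dimension) and the median is over all
    (sample, step, dimension) entries.  Returns ``max(m, floor)``.
    """
    x = np.asarray(predicted_obs, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need an (N >= 2, T, D) prediction ensemble")
    dev = np.abs(x - x.mean(axis=0, keepdims=True))
    return max(float(np.median(dev)), floor)


def expected_free_energy(kl_per_step_layer: np.ndarray,
                         predicted_goals: np.ndarray,
                         pref: PreferenceSpec, m: float,
                         kl_weights: np.ndarray) -> ScoreBreakdown:
    """Expected free energy of one candidate over its future window.

    ``kl_per_step_layer``: (T_f, L) *unweighted* KL terms between the
    candidate's inferred future posterior and its prior; ``predicted_goals``:
    (T_f, Dg) likelihood-mean goal predictions; ``m``: shared preference
    variance.  The KL enters negatively (information gain is sought), the
    goal error positively, scaled by 1/(2 sigma^2) with sigma^2 = m in
    adaptive mode and 1 in fixed mode.
    """
    if m <= 0:
        raise ValueError("preference variance must be positive")
    var = m if pref.variance_mode == "adaptive" else 1.0
    epi = float((kl_weights * kl_per_step_layer).sum())
    err = predicted_goals - pref.preferred_goal
    ext = float((err ** 2).sum() / (2.0 * var))
    return ScoreBreakdown(epistemic_sum=epi, extrinsic_sum=ext)
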