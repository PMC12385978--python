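"""Receding-horizon active-inference planning on a frozen PV-RNN.

Each control step runs five stages (replanning at every step, emitting
exactly one action):

1. *Error regression*: gradient descent on the sliding past window's
   adaptive vectors, minimising evidence free energy against the observed
   sensory sequence (and the given goal).
2. *Plan refinement*: goal-conditioned free-energy descent on the future
   window's plan posterior — the goal-directed plan-generation core that
   the epistemic machinery extends.
3. *Candidate generation*: N latent samples seeded at the last observed
   step's posterior, each rolled forward through the learned prior to the
   horizon; predicted observations/goals are likelihood means.
4. *Future-posterior inference*: per candidate, the future window's
   adaptive vectors (warm-started at the candidate's own prior) are fitted
   to the candidate's predictions, yielding the posterior that the expected
   information gain is measured against.
5. *Scoring and selection*: expected free energy G = -(epistemic) +
   (extrinsic) per candidate with a shared adaptive preference variance;
   argmin-G wins (ties to the lowest index), its next-step proprioceptive
   prediction becomes the action, and the plan posterior is updated to the
   exp(-G)-weighted average of all candidate plans.

All internal arrays are batched over trials (leading axis B) and candidates
(flattened B*N), so an ensemble of independent trials advances in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model_core as mc
from .objectives import PreferenceSpec, preference_variance
from .training import Adam, TrainedModel

__all__ = ["PlannerConfig", "PlannerState", "CandidateSet", "StepLog",
           "Planner", "error_regression", "refine_plan",
           "generate_candidates", "infer_future_posterior", "select_plan",
           "average_posteriors"]


@dataclass(frozen=True)
class PlannerConfig:
    """Planning hyperparameters.

    ``past_window``: tau_p, max steps of observed history re-inferred online;
    ``num_samples``: N candidate futures per replanning event;
    ``infer_iters``/``infer_rate``: Adam budget for both past and future
    inference (fresh optimizer state every event);
    ``preference``: the prior-preference spec (goal + variance mode);
    ``goal_in_past_targets``: whether the preferred goal is imposed as the
    goal-block reconstruction target over the past window.
    """

    past_window: int
    num_samples: int
    preference: PreferenceSpec
    infer_iters: int = 100
    infer_rate: float = 0.1
    goal_in_past_targets: bool = True
    goal_in_future_targets: bool = False
    efe_kl_weight: float = 1.0  # epistemic-term weight on the future KL sum
    plan_sampling: bool = False  # sample candidates from the merged plan

    def __post_init__(self) -> None:
        if self.past_window < 1:
            raise ValueError("past_window must be >= 1")
        if self.num_samples < 2:
            raise ValueError("need at least 2 candidate samples "
                             "(preference variance is undefined for fewer)")
        if self.infer_iters < 1:
            raise ValueError("infer_iters must be >= 1")


@dataclass
class PlannerState:
    """Mutable per-ensemble planning state.

    ``A_mu``/``A_sig`` span the full episode horizon; entries before ``tc``
    hold the past posteriors (frozen once they leave the sliding window),
    entries from ``tc`` on hold the merged warm start for the future.
    """

    weights: mc.ModelWeights
    horizon: int
    B: int
    tc: int = 0
    obs_hist: np.ndarray = None
    A_mu: list = None
    A_sig: list = None
    faults: int = 0
    plan_ready: bool = False  # future A holds a merged plan posterior

    def __post_init__(self) -> None:
        spec = self.weights.spec
        self.obs_hist = np.zeros((self.B, self.horizon, spec.obs_dim))
        self.A_mu = [np.zeros((self.B, self.horizon, c.num_z))
                     for c in spec.layers]
        self.A_sig = [np.zeros((self.B, self.horizon, c.num_z))
                      for c in spec.layers]

    def prefix_state(self, upto: int):
        """(h, d) entering step ``upto``, by posterior-mean propagation of
        steps [0, upto) under the stored adaptive vectors."""
        spec = self.weights.spec
        if upto == 0:
            return ([np.zeros((self.B, c.num_d)) for c in spec.layers],
                    [np.zeros((self.B, c.num_d)) for c in spec.layers])
        st = mc.forward_posterior(
            self.weights,
            [a[:, :upto] for a in self.A_mu],
            [a[:, :upto] for a in self.A_sig])
        L = spec.num_layers
        return ([st.h[l][upto - 1] for l in range(L)],
                [st.d[l][upto - 1] for l in range(L)])


@dataclass
class CandidateSet:
    """N sampled future trajectories per trial (flattened to B*N rows)."""

    tc: int
    tau_f: int
    B: int
    N: int
    x_pred: np.ndarray          # (B*N, tau_f, Dx) likelihood-mean observations
    g_pred: np.ndarray          # (B*N, tau_f, Dg) likelihood-mean goals
    A_mu_f: list                # per layer (B*N, tau_f, Rz), warm start -> posterior
    A_sig_f: list
    h0: list                    # prefix state tiled to B*N
    d0: list
    kl: np.ndarray | None = None          # (B*N, tau_f, L) unweighted
    x_inf: np.ndarray | None = None       # posterior-inferred observations
    epistemic: np.ndarray | None = None   # (B, N)
    extrinsic: np.ndarray | None = None
    G: np.ndarray | None = None


@dataclass
class StepLog:
    """Per-replanning-event record: all candidate scores, the shared
    preference variance, the selection, and the winning trajectory."""

    tc: int
    m: np.ndarray
    G: np.ndarray
    epistemic: np.ndarray
    extrinsic: np.ndarray
    selected: np.ndarray
    action: np.ndarray
    x_pred_sel: np.ndarray
    fe_first: np.ndarray | None = None
    fe_last: np.ndarray | None = None
    policies: np.ndarray | None = None  # decoded candidate state seqs (discrete)

    def to_dict(self) -> dict:
        out = {"tc": self.tc}
        for k in ("m", "G", "epistemic", "extrinsic", "selected", "action",
                  "fe_first", "fe_last"):
            v = getattr(self, k)
            if v is not None:
                out[k] = np.asarray(v).tolist()
        return out


def _tile(arrs: list[np.ndarray], N: int) -> list[np.ndarray]:
    return [np.repeat(a, N, axis=0) for a in arrs]


# ---------------------------------------------------------------------------
# the four planning stages
# ---------------------------------------------------------------------------

def error_regression(state: PlannerState, new_obs: np.ndarray,
                     cfg: PlannerConfig):
    """Append an observation and re-infer the sliding past window.

    Runs ``infer_iters`` Adam steps on the window's adaptive vectors,
    minimising evidence free energy with the observed sensory track (and,
    by default, the preferred goal) as targets.  Returns (Fe_first, Fe_last)
    per trial.
    """
    state.weights.assert_frozen_intact()
    spec = state.weights.spec
    state.obs_hist[:, state.tc] = new_obs
    state.tc += 1
    tc = state.tc
    t0 = max(0, tc - cfg.past_window)
    Tw = tc - t0
    h0, d0 = state.prefix_state(t0)
    A_mu_w = [a[:, t0:tc] for a in state.A_mu]   # views: optimised in place
    A_sig_w = [a[:, t0:tc] for a in state.A_sig]
    goal_tgt = np.tile(cfg.preference.preferred_goal,
                       (state.B, Tw, 1))
    tgt = np.concatenate([state.obs_hist[:, t0:tc], goal_tgt], axis=-1)
    recon_mask = np.ones(spec.out_dim)
    if not cfg.goal_in_past_targets:
        recon_mask[spec.obs_dim:] = 0.0
    kl_w = mc.kl_weight_schedule(spec, Tw, t0)
    params = A_mu_w + A_sig_w
    opt = Adam(params, cfg.infer_rate)
    fe_first = fe_last = None
    for it in range(cfg.infer_iters):
        st = mc.forward_posterior(state.weights, A_mu_w, A_sig_w,
                                  h0=h0, d0=d0, t0_abs=t0)
        err = (st.y - tgt) * recon_mask
        fe = (kl_w[None] * st.kl_matrix()).sum(axis=(1, 2)) \
            + 0.5 * (err ** 2).sum(axis=(1, 2))
        if not np.all(np.isfinite(fe)):
            for a in A_mu_w + A_sig_w:
                a[...] = 0.0
            import warnings
            warnings.warn("non-finite Fe during error regression; "
                          "window posteriors reset")
            opt = Adam(params, cfg.infer_rate)
            continue
        if fe_first is None:
            fe_first = fe
        fe_last = fe
        gA_mu, gA_sig = mc.backward_window(
            state.weights, st, grad_y=err, kl_weights=kl_w, A_sig=A_sig_w)
        opt.step(params, gA_mu + gA_sig)
    return fe_first, fe_last


def refine_plan(state: PlannerState, cfg: PlannerConfig) -> None:
    """Goal-conditioned plan inference over the future window.

    Gradient descent on the plan posterior's adaptive vectors minimising
    the evidence free energy with the *preferred goal* as the only
    reconstruction target (future observations are unobserved): the KL
    term keeps the plan on the habitual manifold, the goal term bends it
    toward outcomes that reach the goal.  This is the goal-directed plan
    *generation* step; candidate sampling and EFE selection then explore
    around the refined plan.
    """
    spec = state.weights.spec
    tc, T = state.tc, state.horizon
    tau_f = T - tc
    if tau_f < 1:
        return
    h0, d0 = state.prefix_state(tc)
    A_mu_w = [a[:, tc:] for a in state.A_mu]   # views, optimised in place
    A_sig_w = [a[:, tc:] for a in state.A_sig]
    tgt = np.zeros((state.B, tau_f, spec.out_dim))
    tgt[:, :, spec.obs_dim:] = cfg.preference.preferred_goal
    mask = np.zeros(spec.out_dim)
    mask[spec.obs_dim:] = 1.0
    kl_w = mc.kl_weight_schedule(spec, tau_f, tc)
    params = A_mu_w + A_sig_w
    opt = Adam(params, cfg.infer_rate)
    for _ in range(cfg.infer_iters):
        st = mc.forward_posterior(state.weights, A_mu_w, A_sig_w,
                                  h0=h0, d0=d0, t0_abs=tc)
        gy = (st.y - tgt) * mask
        gA_mu, gA_sig = mc.backward_window(
            state.weights, st, grad_y=gy, kl_weights=kl_w, A_sig=A_sig_w)
        opt.step(params, gA_mu + gA_sig)
    state.plan_ready = True


def generate_candidates(state: PlannerState, cfg: PlannerConfig,
                        rngs: list[np.random.Generator]) -> CandidateSet:
    """Sample N future trajectories per trial.

    Each candidate re-simulates the last *observed* step with a latent
    sample drawn from its inferred posterior (the agent's state-estimate
    uncertainty), then rolls the learned prior forward to the horizon,
    sampling ``z`` from the prior at every step; predicted observations and
    goals are likelihood means.  Before any observation the rollout starts
    from the resting state and the unit-Gaussian initial prior.
    Deterministic given the trial generators.
    """
    spec = state.weights.spec
    tc, T, B, N = state.tc, state.horizon, state.B, cfg.num_samples
    L = spec.num_layers
    tau_f = T - tc
    if tau_f < 1:
        raise ValueError("no future steps left to plan over")

    def draws(steps):
        return [np.stack([rng.standard_normal((N, steps, c.num_z))
                          for rng in rngs]).reshape(B * N, steps, c.num_z)
                for c in spec.layers]

    if tc == 0:
        h0c, d0c = mc._zero_state(spec, B * N)
    else:
        h0, d0 = state.prefix_state(tc - 1)
        A_mu_s = [np.repeat(a[:, tc - 1:tc], N, axis=0) for a in state.A_mu]
        A_sig_s = [np.repeat(a[:, tc - 1:tc], N, axis=0) for a in state.A_sig]
        st_seed = mc.forward_posterior(
            state.weights, A_mu_s, A_sig_s, h0=_tile(h0, N), d0=_tile(d0, N),
            t0_abs=tc - 1, eps=draws(1))
        h0c = [st_seed.h[l][0] for l in range(L)]
        d0c = [st_seed.d[l][0] for l in range(L)]
    if state.plan_ready and cfg.plan_sampling:
        # sample future latents from the current (merged) plan posterior:
        # candidates are perturbations of the running plan, which is what
        # keeps the agent committed to a trajectory across replanning events
        st = mc.forward_posterior(
            state.weights,
            [np.repeat(a[:, tc:], N, axis=0) for a in state.A_mu],
            [np.repeat(a[:, tc:], N, axis=0) for a in state.A_sig],
            h0=h0c, d0=d0c, t0_abs=tc, eps=draws(tau_f))
    else:
        # no plan yet: free generation from the learned prior
        st = mc.rollout_prior(state.weights, h0=h0c, d0=d0c, steps=tau_f,
                              t0_abs=tc, eps=draws(tau_f))
    dx = spec.obs_dim
    # warm start: invert the candidate's own rolled-out prior stats so the
    # future posterior starts at zero KL and diverges only where the
    # candidate's predictions demand it
    A_mu_f, A_sig_f = [], []
    for l in range(L):
        am = np.empty((B * N, tau_f, spec.layers[l].num_z))
        asg = np.empty_like(am)
        for t in range(tau_f):
            am[:, t] = np.arctanh(np.clip(st.mu_p[l][t], -0.999999, 0.999999))
            asg[:, t] = np.log(st.sig_p[l][t])
        A_mu_f.append(am)
        A_sig_f.append(asg)
    return CandidateSet(tc=tc, tau_f=tau_f, B=B, N=N,
                        x_pred=st.y[:, :, :dx].copy(),
                        g_pred=st.y[:, :, dx:].copy(),
                        A_mu_f=A_mu_f, A_sig_f=A_sig_f, h0=h0c, d0=d0c)


def infer_future_posterior(cands: CandidateSet, state: PlannerState,
                           cfg: PlannerConfig, iters: int | None = None
                           ) -> CandidateSet:
    """Fit each candidate's future posterior to the candidate's predicted
    observations — and, by default, the *preferred* goal in the goal
    channel (the future posterior is conditioned on both the imagined
    outcomes and the given goal) — by minimising evidence free energy over
    the future window; then record the per-step KL between that posterior
    and the prior."""
    spec = state.weights.spec
    kl_w = mc.kl_weight_schedule(spec, cands.tau_f, cands.tc)
    if cfg.goal_in_future_targets:
        g_tgt = np.tile(cfg.preference.preferred_goal,
                        (cands.x_pred.shape[0], cands.tau_f, 1))
    else:
        g_tgt = cands.g_pred
    tgt = np.concatenate([cands.x_pred, g_tgt], axis=-1)
    params = cands.A_mu_f + cands.A_sig_f
    opt = Adam(params, cfg.infer_rate)
    n_iters = cfg.infer_iters if iters is None else iters
    for _ in range(n_iters):
        st = mc.forward_posterior(state.weights, cands.A_mu_f, cands.A_sig_f,
                                  h0=cands.h0, d0=cands.d0, t0_abs=cands.tc)
        gy = st.y - tgt
        gA_mu, gA_sig = mc.backward_window(
            state.weights, st, grad_y=gy, kl_weights=kl_w,
            A_sig=cands.A_sig_f)
        opt.step(params, gA_mu + gA_sig)
    st = mc.forward_posterior(state.weights, cands.A_mu_f, cands.A_sig_f,
                              h0=cands.h0, d0=cands.d0, t0_abs=cands.tc)
    cands.kl = st.kl_matrix()
    cands.x_inf = st.y[:, :, :spec.obs_dim].copy()
    return cands


def score_candidates(cands: CandidateSet, cfg: PlannerConfig,
                     state: PlannerState, include_epistemic: bool = True
                     ) -> tuple[CandidateSet, np.ndarray]:
    """Expected free energy per candidate with a per-trial shared preference
    variance m (MAD of all candidates' predicted observations)."""
    B, N, tau_f = cands.B, cands.N, cands.tau_f
    if include_epistemic:
        # information gain: unweighted KL sum over the future window (the
        # meta-prior is a learning regularizer; the planning-time trade-off
        # against the precision-weighted goal error uses the KL itself)
        epi = cfg.efe_kl_weight * cands.kl.sum(axis=(1, 2)).reshape(B, N)
    else:
        epi = np.zeros((B, N))
    xp = cands.x_pred.reshape(B, N, tau_f, -1)
    m = np.array([preference_variance(xp[b], cfg.preference.variance_floor)
                  for b in range(B)])
    gerr = ((cands.g_pred - cfg.preference.preferred_goal) ** 2
            ).sum(axis=(1, 2)).reshape(B, N)
    var = m[:, None] if cfg.preference.variance_mode == "adaptive" else 1.0
    ext = gerr / (2.0 * var)
    cands.epistemic, cands.extrinsic = epi, ext
    cands.G = ext - epi
    return cands, m


def select_plan(cands: CandidateSet, proprio_dim: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Argmin-G per trial (ties to the lowest candidate index); the action
    is the winner's proprioceptive prediction at the next step, read from
    its inferred (posterior-mean, de-noised) trajectory when available."""
    if cands.G is None or cands.G.size == 0:
        raise ValueError("no scored candidates to select from")
    idx = np.argmin(cands.G, axis=1)
    src = cands.x_inf if cands.x_inf is not None else cands.x_pred
    xp = src.reshape(cands.B, cands.N, cands.tau_f, -1)
    action = xp[np.arange(cands.B), idx, 0, :proprio_dim]
    return idx, action


def average_posteriors(cands: CandidateSet, state: PlannerState) -> None:
    """Update the plan posterior to the average of the candidate plans.

    Candidates are averaged as *distributions* (moment-matched Gaussian
    mixture), weighted by the policy posterior ``q(pi) ∝ exp(-G)`` when the
    candidates are scored (uniformly otherwise), so the merged plan both
    retains the candidates' disagreement as breadth and concentrates on the
    low-expected-free-energy plans.  The result becomes the distribution the
    next replanning event samples its candidates from.
    """
    tc, tau_f = cands.tc, cands.tau_f
    if cands.G is not None:
        g = cands.G - cands.G.min(axis=1, keepdims=True)
        w = np.exp(-g)
        w /= w.sum(axis=1, keepdims=True)          # (B, N)
    else:
        w = np.full((cands.B, cands.N), 1.0 / cands.N)
    wbn = w[:, :, None, None]
    for l in range(len(state.A_mu)):
        am = cands.A_mu_f[l].reshape(cands.B, cands.N, tau_f, -1)
        asg = cands.A_sig_f[l].reshape(cands.B, cands.N, tau_f, -1)
        if am.shape[-1] != state.A_mu[l].shape[-1]:
            raise ValueError("candidate/posterior shape mismatch")
        mu = np.tanh(am)
        var = np.exp(np.clip(asg, *mc.SIGMA_CLIP)) ** 2
        mu_m = (wbn * mu).sum(axis=1)
        var_m = ((wbn * var).sum(axis=1)
                 + (wbn * (mu - mu_m[:, None]) ** 2).sum(axis=1))
        state.A_mu[l][:, tc:tc + tau_f] = np.arctanh(
            np.clip(mu_m, -0.999999, 0.999999))
        state.A_sig[l][:, tc:tc + tau_f] = np.clip(
            0.5 * np.log(var_m), *mc.SIGMA_CLIP)
    state.plan_ready = True


# ---------------------------------------------------------------------------
# agent frontends
# ---------------------------------------------------------------------------

class Planner:
    """Stateful agent ensemble over B lockstep trials.

    ``mode``: "efe" (full expected-free-energy agent), "extrinsic_only"
    (goal-error scoring with fixed unit preference variance — no epistemic
    drive), or "habituation" (past-window inference plus a one-step
    prior-mean prediction; no sampling, no scoring).
    """

    MODES = ("efe", "extrinsic_only", "habituation")

    def __init__(self, model: TrainedModel, horizon: int, B: int,
                 cfg: PlannerConfig, rngs: list[np.random.Generator],
                 mode: str = "efe"):
        if mode not in self.MODES:
            raise ValueError(f"unknown agent mode {mode!r}")
        model.weights.assert_frozen_intact()
        self.model = model
        self.cfg = cfg
        self.mode = mode
        self.rngs = rngs
        self.state = PlannerState(model.weights, horizon, B)
        self.logs: list[StepLog] = []
        self._last_candidates: CandidateSet | None = None

    def step(self, new_obs: np.ndarray | None) -> np.ndarray:
        """One receding-horizon control step: absorb an observation (None
        only before the very first action), replan, emit one action per
        trial."""
        state, cfg = self.state, self.cfg
        fe_first = fe_last = None
        if new_obs is not None:
            fe_first, fe_last = error_regression(state, new_obs, cfg)
        if self.mode == "habituation":
            return self._habituation_action(fe_first, fe_last)
        refine_plan(state, cfg)
        cands = generate_candidates(state, cfg, self.rngs)
        cands = infer_future_posterior(cands, state, cfg)
        if self.mode == "extrinsic_only":
            fixed = PreferenceSpec(cfg.preference.preferred_goal,
                                   variance_mode="fixed",
                                   variance_floor=cfg.preference.variance_floor)
            cands, m = score_candidates(
                cands, _with_pref(cfg, fixed), state,
                include_epistemic=False)
        else:
            cands, m = score_candidates(cands, cfg, state)
        idx, action = select_plan(cands, self.model.weights.spec.proprio_dim)
        average_posteriors(cands, state)
        self._last_candidates = cands
        xp = cands.x_pred.reshape(cands.B, cands.N, cands.tau_f, -1)
        self.logs.append(StepLog(
            tc=cands.tc, m=m, G=cands.G, epistemic=cands.epistemic,
            extrinsic=cands.extrinsic, selected=idx, action=action,
            x_pred_sel=xp[np.arange(cands.B), idx],
            fe_first=fe_first, fe_last=fe_last))
        return action

    def _habituation_action(self, fe_first, fe_last) -> np.ndarray:
        state = self.state
        spec = state.weights.spec
        h0, d0 = state.prefix_state(state.tc)
        st = mc.rollout_prior(state.weights, h0=h0, d0=d0, steps=1,
                              t0_abs=state.tc)
        action = st.y[:, 0, :spec.proprio_dim]
        self.logs.append(StepLog(
            tc=state.tc, m=np.full(state.B, np.nan),
            G=np.zeros((state.B, 0)), epistemic=np.zeros((state.B, 0)),
            extrinsic=np.zeros((state.B, 0)),
            selected=np.zeros(state.B, dtype=int), action=action,
            x_pred_sel=st.y[:, :, :spec.obs_dim],
            fe_first=fe_first, fe_last=fe_last))
        return action


def _with_pref(cfg: PlannerConfig, pref: PreferenceSpec) -> PlannerConfig:
    import dataclasses
    return dataclasses.replace(cfg, preference=pref)
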