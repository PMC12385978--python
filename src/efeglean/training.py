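"""Evidence-free-energy learning.

Weights and per-training-sequence adaptive vectors are optimised jointly by
full-batch gradient descent (Adam) on the summed evidence free energy, with
gradients propagated backward through time over the whole sequence.  After
training, the weights are frozen — at test time only adaptive vectors move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model_core as mc
from .objectives import FreeEnergyBreakdown, free_energy_from_window

__all__ = ["Adam", "TrainConfig", "TrainTrace", "TrainedModel",
           "train_model", "reconstruct_sequence"]


class Adam:
    """Elementwise adaptive-moment optimizer (conventional betas, no weight
    decay).  Operates in place on a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int
    learn_rate: float = 1e-3
    seed: int = 0
    dataset_id: str = ""
    log_interval: int = 100
    clip_norm: float = 10.0  # applied only if the loss goes non-finite

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")


@dataclass
class TrainTrace:
    """Per-logged-epoch training diagnostics (batch-mean values)."""

    epochs: list[int] = field(default_factory=list)
    fe: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    recon: list[float] = field(default_factory=list)

    def append(self, epoch: int, fe: float, kl: float, recon: float) -> None:
        self.epochs.append(epoch)
        self.fe.append(fe)
        self.kl.append(kl)
        self.recon.append(recon)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.epochs, self.fe, self.kl, self.recon])
        np.savetxt(path, arr, delimiter=",", header="epoch,fe,kl,recon",
                   comments="")


@dataclass
class TrainedModel:
    """Frozen weights plus the training-set posteriors and loss trace."""

    weights: mc.ModelWeights
    A_mu: list[np.ndarray]  # per layer (B, T, Rz)
    A_sig: list[np.ndarray]
    trace: TrainTrace


def _new_adaptive(spec: mc.ModelSpec, B: int, T: int) -> tuple[list, list]:
    A_mu = [np.zeros((B, T, cfg.num_z)) for cfg in spec.layers]
    A_sig = [np.zeros((B, T, cfg.num_z)) for cfg in spec.layers]
    return A_mu, A_sig


def train_model(batch: mc.SequenceBatch, spec: mc.ModelSpec,
                cfg: TrainConfig, progress: bool = False) -> TrainedModel:
    """Fit the PV-RNN to a batch of sequences by minimising the batch-mean
    evidence free energy.  Reparameterisation noise is redrawn every epoch
    from a generator keyed by ``cfg.seed``; identical seeds give bit-identical
    results.  Raises if the loss diverges despite emergency gradient clipping.
    """
    B, T, _ = batch.obs.shape
    if batch.targets.shape[-1] != spec.out_dim:
        raise ValueError("dataset dimensionality does not match model spec")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    weights = mc.ModelWeights(spec, seed=int(rng.integers(2 ** 31)))
    A_mu, A_sig = _new_adaptive(spec, B, T)
    kl_w = mc.kl_weight_schedule(spec, T, 0)
    targets = batch.targets
    tmask = None if batch.mask is None else batch.mask[..., None]

    params = weights.param_list() + A_mu + A_sig
    opt = Adam(params, cfg.learn_rate)
    trace = TrainTrace()
    scale = 1.0 / B
    it = range(cfg.epochs)
    if progress:
        from tqdm import tqdm
        it = tqdm(it, desc="train", unit="epoch")
    for epoch in it:
        eps = [rng.standard_normal(a.shape) for a in A_mu]
        st = mc.forward_posterior(weights, A_mu, A_sig, eps=eps)
        gy = st.y - targets
        if tmask is not None:
            gy = gy * tmask
        fe = free_energy_from_window(
            st, batch, kl_w, recon_mask=tmask)
        loss = float(fe.total.mean())
        gA_mu, gA_sig, gW = mc.backward_window(
            weights, st, grad_y=gy, kl_weights=kl_w, A_sig=A_sig,
            need_weight_grads=True, batch_scale=scale)
        grads = gW + gA_mu + gA_sig
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: Fe = {loss}")
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
        if not np.isfinite(gnorm):
            raise FloatingPointError(
                f"non-finite gradient at epoch {epoch}")
        if gnorm > 1e6:  # emergency clip far outside normal operation
            for g in grads:
                g *= cfg.clip_norm / gnorm
        opt.step(params, grads)
        if epoch % cfg.log_interval == 0 or epoch == cfg.epochs - 1:
            trace.append(epoch, loss, float(fe.kl_sum.mean()),
                         float(fe.recon_sum.mean()))
    weights.freeze()
    return TrainedModel(weights, A_mu, A_sig, trace)


def reconstruct_sequence(model: TrainedModel, batch: mc.SequenceBatch,
                         index: int) -> tuple[np.ndarray, np.ndarray,
                                              FreeEnergyBreakdown]:
    """Regenerate training sequence ``index`` by propagating its learned
    posterior means through the frozen network; returns the predicted
    observation and goal tracks with the evidence free energy of the pass."""
    B, T, _ = batch.obs.shape
    if not (0 <= index < B):
        raise IndexError(f"sequence index {index} outside training set")
    spec = model.weights.spec
    A_mu = [a[index:index + 1] for a in model.A_mu]
    A_sig = [a[index:index + 1] for a in model.A_sig]
    st = mc.forward_posterior(model.weights, A_mu, A_sig)
    sub = mc.SequenceBatch(batch.obs[index:index + 1],
                           batch.goal[index:index + 1])
    fe = free_energy_from_window(st, sub, mc.kl_weight_schedule(spec, T, 0))
    dx = spec.obs_dim
    return st.y[0, :, :dx], st.y[0, :, dx:], fe
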