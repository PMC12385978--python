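# Methods

## Overview

`efeglean` implements a goal-directed, information-seeking agent built on a
predictive-coding-inspired variational recurrent neural network (PV-RNN)
world model.  The agent plans in the model's low-dimensional latent space:
at every control step it re-infers its recent past, imagines a population of
candidate futures, scores each by expected free energy (EFE) — an epistemic
information-gain term minus nothing, plus a precision-weighted goal error —
and executes the first step of the best plan.  The testbed is a T-maze whose
bottom arm carries a *conditioning stimulus* (CS): a colored floor patch
whose color deterministically reveals which top arm holds the red goal.
Reliable goal-reaching therefore requires visiting the CS first, an
epistemic detour that a purely goal-driven agent never takes.

## Generative model

Each layer `l` holds deterministic units `d = tanh(h)` evolving as leaky
integrators with time constant `tau_l`,

    h_t = (1 - 1/tau) h_{t-1} + (1/tau) (W_hd d_{t-1} + W_hz z_t
                                          + W_td d^{l+1}_{t-1} + b),

and stochastic units `z` with a learned Gaussian prior conditioned on the
previous deterministic state,

    mu^p_t = tanh(W_mu d_{t-1} + b_mu),   sigma^p_t = exp(W_sig d_{t-1} + b_sig),

with the unit Gaussian as the prior at the first step.  The approximate
posterior at every (sequence, step, layer) is parameterised by free
*adaptive vectors* `A`,

    mu^q_t = tanh(A^mu_t),   sigma^q_t = exp(A^sigma_t),

rather than by an amortised encoder; inference means gradient descent on
`A`.  A single affine projection maps the lowest layer's `d` to the
concatenated (observation, goal) vector; there is no output nonlinearity.

Design choices where the architecture was open:

* **Top-down timing.** The higher layer's `d_{t-1}` (previous step) enters
  the lower layer's update, so all layers advance in parallel from the
  step-`t-1` state.
* **First step.** `h_0 = d_0 = 0`; the effective time constant at the very
  first step is 1 (a leak-free first update, standard in
  multiple-timescale RNNs), and the KL weight at that step is fixed to 1.0
  so the initial latent stays calibrated to its unit-Gaussian sampling
  distribution.
* **Numerics.** Every pre-exponential log-sigma quantity is clamped to
  [-10, 6].  Biases are included in all affine maps.
* **Gradients.** Forward and reverse passes are hand-written in NumPy
  (reverse-mode through the reparameterised sampler, the leaky dynamics,
  the prior maps and the KL terms); they are verified against central
  finite differences to 1e-4 relative error in the test suite.

## Learning

Weights and per-training-sequence adaptive vectors are optimised jointly by
full-batch Adam (lr 1e-3) on the evidence free energy

    Fe = sum_t [ sum_l w_l KL(q || p) + 1/2 || y_t - target_t ||^2 ],

where `w_l` is the per-layer *meta-prior* controlling regularization
(0.1 for the discrete maze; 0.005 / 0.01 for the two continuous-maze
layers).  Reparameterisation noise is redrawn every epoch.  After training
the weights are frozen (guarded by a checksum); only adaptive vectors move
at test time.

## Planning loop

Each control step runs five stages:

1. **Error regression.** The sliding past window (length `tau_p`) of
   adaptive vectors is optimised for 100 Adam iterations at lr 0.1 against
   the observed sensory track, with the *preferred* goal imposed on the
   goal channel (goal-conditioned inference, the GLean mechanism; a config
   flag disables it).  Inference propagates the posterior mean (`z = mu^q`),
   which makes whole trials deterministic under a seed.
2. **Plan refinement.** The future window's plan posterior (which persists
   across replanning events and is merged from the previous event's
   candidates) is refined by goal-conditioned free-energy descent: the
   preferred goal is the only reconstruction target over the future —
   future observations are unobserved — while the KL term keeps the plan
   on the habitual manifold.  This is the goal-directed plan *generation*
   step; it matters mechanically because when a newly observed step enters
   the past window, error regression starts from the refined, goal-bent
   value.  A useful consequence of goal conditioning in this maze: the two
   direct routes (left and right) cancel each other at the junction while
   both CS routes agree (down), so the goal-conditioned expectation of the
   next move points toward the CS.
3. **Candidate generation.** N futures per trial: the last observed step
   is re-simulated with a latent sample from its inferred posterior, then
   the learned prior is sampled forward to the horizon.  Predicted
   observations and goals are likelihood means.
4. **Future-posterior inference.** Per candidate, the future window's
   adaptive vectors are warm-started by inverting the candidate's own
   rolled-out prior (zero KL at the window head) and fitted to the
   candidate's predictions for 100 iterations.  The resulting per-step KL
   against the prior measures how much latent information the imagined
   trajectory commits — trajectories that pass informative places (the CS)
   and keep moving commit more.
5. **Scoring, selection, plan update.** Each candidate's EFE is

       G = - sum_t KL_t  +  sum_t || gbar_t - ghat ||^2 / (2 m),

   with `m` the median absolute deviation of all candidates' predicted
   observations (shared per replanning event, floored at 1e-3): when the
   candidate population disagrees about the future, uncertainty is high,
   the goal error is de-weighted and information gain dominates; as the
   plan converges, `m` collapses and the agent turns exploitative.  The KL
   enters G *unweighted*: the meta-prior is a learning-time regulariser,
   and with the continuous model's meta-priors of 0.005-0.01 a weighted
   epistemic term would be numerically invisible next to the goal error.
   The argmin-G candidate (ties to the lowest index) supplies the action —
   its next-step proprioceptive prediction, read from its de-noised
   (posterior-inferred) trajectory.  Finally the plan posterior is updated
   to the average of all candidate plans, averaged as distributions
   (moment-matched Gaussian mixture) under the canonical policy posterior
   weights `q(pi) ∝ exp(-G)`; a config option can additionally make
   candidate generation sample around this merged plan instead of the
   free prior.

Baselines: *habituation* runs error regression and a single prior-mean
one-step prediction (no sampling, no scoring); *extrinsic-only* runs the
full loop but scores with the goal error alone at fixed unit preference
variance (no epistemic term), the behaviour of a goal-directed planner
without intrinsic motivation.

## Environments and synthetic data

The data generator defines the study conditions; nothing is read from disk.

* **Discrete maze** (experiment 1): four states — center (1), CS (2), left
  (3), right (4); center and CS reach every state, arms absorb.  Episodes
  are the ten length-3 state sequences from the center; the two that check
  the CS and then enter an arm — (1,2,3), (1,2,4) — are the preferred
  policies.  Observations: position one-hot(4) + color one-hot(4) + a
  2-dim goal block.  The training goal block is teleological: whether the
  episode ends on red, constant across the sequence (the same outcome
  encoding the continuous experiments use).  Training set: all ten
  policies under both CS contexts (20 x 3 x 10).
* **Continuous maze** (experiment 2): T-shaped corridors of width 1 (stem
  x in [1,2], y in [0,2]; top bar y in [2,3], x in [0,3]), colored zones at
  the three corridor ends, start pose (1.5, 1.5).  A proportional
  controller (gain 1, max speed 0.4 units/s, dt 0.5) tracks predicted
  positions; Gaussian pose noise sigma 0.01 moving / 0.005 stationary.
  Observations: (x, y) + color one-hot(4); goal channel: 4-dim one-hot of
  the *final* sensation (red or white).  Training set: 4 behaviours
  (direct/CS-route x found/not-found) x 2 goal sides x 10 noisy
  repetitions (80 x 25 x 10).
* **Obstacle maze** (experiment 3): as above with RGB floor color, four
  45-degree range sensors clipped at 0.7, dt 0.2, 60 steps, and an
  obstacle (0.5 x 0.5, hanging from the top wall) placed uniformly outside
  the goal areas.  The agent body keeps a 0.15 margin from the obstacle,
  so the half-corridor block genuinely forces a detour under it.  Data
  collection uses max speed 0.55 units/s with a 0.7 slow-down factor
  within 0.45 of the obstacle — calibrated once so every CS-route with a
  worst-case obstacle still terminates inside its goal zone within 60
  steps.  Training set: 8 patterns x (4 with obstacle + 4 without)
  (64 x 60 x 12).

What the generator does *not* emulate: continuous collision dynamics,
sensor-specific noise models, or any embodiment beyond a kinematic point
with a margin; passing tests show the planning machinery works under the
idealised world rules, not that it transfers to a physical robot.

## Scaled evaluation protocol

Full-scale runs (500k/200k training epochs, 100 trials x N=100) exceed a
desk budget; the packaged protocol scales down while keeping every
mechanism live:

* experiment 1: 50k epochs, 20 trials, N=50 in the test suite; the
  acceptance script uses 100k epochs and N=100, a budget at which training
  has converged into the selection mechanism's operating regime (the
  selection rate strengthens with both epochs and candidate count, while
  the sample fraction stays at the training frequency at every scale; the
  attained selection rate also varies across training seeds — different
  trained models express the CS preference with different strength).
* experiment 2: 20k epochs, 20 trials, N=50, all three agents.
* experiment 3: 4k epochs, 10 trials per past-window condition
  (tau_p = 60, 30, 1), N=16.

## Known limitations

* The discrete maze's preferred-vs-direct selection margin rests on the
  extra latent information committed by longer, CS-visiting trajectories;
  at heavily reduced training budgets that margin is noisy and the
  selection rate sits below the converged value.
* Under the symmetric training distribution (every policy under both
  contexts), a single sampled future that goes directly to an arm and
  happens to imagine the correct color is, information-theoretically, as
  coherent as a CS-checking one; the CS preference is an emergent property
  of the trained network's representations, not a theorem about the
  objective.
* The extrinsic-only baseline reproduces the qualitative behaviour of a
  goal-only planner (never detours to the CS) but is a sampling-based
  stand-in for the original gradient-search planner it models.
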