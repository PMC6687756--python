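# Methods

## Model

`neuroloop` simulates a closed loop between a small network of noisy
rate neurons and a benchmark reinforcement-learning environment.  Every
neuron obeys the stochastic rate equation

    tau dz_i/dt = -z_i + mu_i + f(h_i + ext_i - theta_i) + xi_i(t),

with recurrent input field `h_i = sum_j w_ij z_j(t - delay_ij)`,
external drive `ext_i`, activation `f` either the identity or the
threshold-linear function `f(x) = Theta(x) x` (strict Heaviside,
`Theta(0) = 0`), and Gaussian white noise of amplitude `sigma_xi`.
Time is in milliseconds and activities are dimensionless.

Integration uses the stochastic exponential-Euler scheme on a fixed
grid (default `dt = 1 ms`): the leak is integrated exactly with the
input held constant over the step, and the noise increment is drawn
with standard deviation `sigma_xi * sqrt((1 - exp(-2 dt/tau)) / 2)`.
This convention makes the stationary distribution of a free noisy
neuron an Ornstein-Uhlenbeck stationary law with standard deviation
`sigma_xi / sqrt(2)` independent of `dt` (verified by test).  Delays
are realized through a ring buffer of past activities sized at build
time from the largest configured delay; requesting a longer lag is an
error, not a resize.

## Actor-critic architecture

A layer of place cells encodes the observation: Gaussian tuning curves
on a grid for continuous observations, one-hot (non-overlapping) cells
for discrete state spaces.  The place cells project through plastic
weights to a single linear critic unit and to one linear actor unit
per action.  Actor units are recurrently coupled as a winner-take-all
(WTA) circuit: `+exc` between a unit and itself or its nearest
neighbors, `-inh` otherwise, with the distance metric reflecting
action similarity (a line for the three ordered MountainCar
accelerations, a ring for the four compass directions of FrozenLake).
The selected action is the index of the most active actor unit,
decoded every network step but forwarded to the environment only at
environment-step boundaries.

The critic activity v(t) should approximate the continuous-time value
function `V(t) = int_t^inf r(t') exp(-(t'-t)/tau_r) dt'`.  A dedicated
reward-prediction-error (RPE) unit computes the two-point
temporal-difference error

    delta(t) = (1/d - 1/tau_r) v(t) - (1/d) v(t - d) + r(t)

through two critic connections (one instantaneous, one delayed by
`d`), plus the reward as external input.  Both plastic projections are
updated every network step by the three-factor rule

    w <- max(w_min, w + eta * delta(t) * x_pre * Theta(z_post - theta_post)),

where for discrete environments the pre- and postsynaptic factors are
read `delta_t` (one environment step) in the past, so that plasticity
credits the state-action pair that caused the current transition even
though the one-hot tuning curves do not overlap.

## Design choices in detail

Several choices were genuinely open; the reasoning behind each:

* **Linear actor and critic units.**  The critic must represent
  graded values, and the actor units follow the same dynamics as the
  critic.  With the prescribed WTA connectivity (+exc to ring/line
  neighbors) a threshold-linear actor cannot silence the neighbors of
  the winner once feedforward drives exceed the unit threshold, so
  linear units with contrast amplification by the recurrence are used;
  selectivity is enforced by the plasticity gate `theta_post` rather
  than by rectification.
* **Exclusively excitatory plastic weights.**  Both plastic
  projections carry a minimal weight `w_min > 0`.  Besides preventing
  action deadlock, this bounds the critic below, so the constant step
  punishment is never fully "predicted away": the active action keeps
  being weakly depressed, which is the mechanism that sustains
  exploration.  (An earlier variant with a negative critic floor let
  delta converge to zero in punishing regions and froze exploration.)
  The goal bonus exists for the same reason: with non-negative
  weights, a task with purely negative reinforcement has no
  learnable value gradient.
* **Reward as a rate.**  The environment reward enters the RPE unit
  scaled by `reward_gain = 1 / env_step_interval` and held constant
  over the interval.  The value of a state one step before a unit
  reward is then ~1 regardless of the interval length, keeping all
  activities, weights and the fixed gate `theta_post` on one scale.
* **Plasticity pause after resets.**  When an episode ends, the
  terminal observation and reward are delivered for one environment
  interval (so the terminal reward actually reaches the RPE unit),
  the network then evolves freely for `episode_break` ms with zero
  drive, and the environment resets.  For `(d + 3 tau_critic)` ms
  after the reset, plasticity is paused: during that window the
  two-point RPE straddles the value discontinuity of the teleport
  back to the start, which carries no reward information; without the
  pause the start state slowly pumps its own value through the
  eligibility lag and the start-state policy destabilizes cyclically.
* **Per-projection gate thresholds.**  The actor projection uses the
  configured `theta_post` so that only the winning unit's weights are
  updated; the critic projection's gate is effectively open (a large
  negative threshold), because the critic is a single noise-free unit
  whose learning must not stop at low activity.

## Study configurations

Parameters that the underlying experimental protocol fixes:
FrozenLake uses the standard non-slippery 4x4 map (SFFF/FHFH/FFFH/HFFG)
with 16 one-hot place cells, 4 actions, reward +1 at the goal, a small
step punishment (-0.01), a hole punishment (-0.2, holes teleport back
to the start without ending the episode), and an eligibility delay of
one environment step.  MountainCar uses the canonical kinematics
(force 0.001, gravity 0.0025, goal at x = 0.5), 25 place cells on a
5 x 5 grid over position x velocity, 3 actions, per-step punishment
-0.01 plus a goal bonus +1, and no eligibility delay.  Learning curves
are averaged over 5 (FrozenLake) and 10 (MountainCar) seeds.

Constants that are not printed in the source material are package
defaults, chosen once by tuning on the generator defaults and then
frozen (units ms unless noted):

| parameter | FrozenLake | MountainCar | role |
|---|---|---|---|
| network dt | 1 | 1 | integration step |
| env step interval | 10 | 10 | coarse grid |
| episode break | 50 | 100 | free evolution after reset |
| tau input/critic | 1 / 1 | 1 / 1 | fast encoding and value read-out |
| tau actor | 2 | 50 | action persistence |
| tau RPE | 0.5 | 0.5 | delta read-out |
| tau_r | 100 | 400 | discount horizon |
| d | 10 | 10 | two-point RPE delay |
| delta_t | 10 | 0 | eligibility delay |
| eta | 0.2 | 0.3 | learning rate (both projections) |
| theta_post | 0.1 | 0.1 | actor plasticity gate |
| WTA exc / inh | 0.05 / 0.45 (ring) | 0.05 / 0.3 (line) | action selection |
| actor input noise | 0.04 | 0.8 | exploration drive |
| w_init / w_min (actor) | 0.2 / 0.05 | 0.2 / 0.05 | initial drive, floor |
| w_init / w_min (critic) | 0.05 / 0.01 | 0.05 / 0.01 | initial value, floor |
| place-cell width scale | (one-hot) | 0.5 x spacing | tuning overlap |

The two tasks sit in different exploration regimes.  FrozenLake uses a
fast actor with tiny noise: unlearned states have floor-tied drives,
so even tiny noise randomizes the argmax, while learned drive gaps
(~0.3-0.6) dominate the noise and the policy executes
deterministically.  MountainCar uses a slow actor with large noise:
a single action persists for many steps, the constant punishment
gradually depresses the active unit's weights until another takes
over, and these coherent action blocks pump the car out of the
valley; the narrow place fields (0.5 x spacing) keep the punishment
accumulated in the valley from erasing the goal credit of near-goal
cells.

## What the simulations show — and what they do not

With these defaults the architecture learns both tasks from scratch:
FrozenLake runs reach perfect six-step looping (forward 500-step
average reward per step equal to the shaped optimum 0.94/6 ~ 0.157)
and the MountainCar 10-seed mean per-episode reward improves from
~1,400-step to ~800-step episodes within 20 episodes while the value
map develops the expected momentum-dependent gradient toward the
goal.  Two caveats are measured
rather than hidden.  First, convergence times are seed-dependent:
individual FrozenLake seeds lock onto the optimal policy anywhere
between ~1,600 steps and beyond the 4,000-step budget, so the 5-seed
mean of the strict reach-and-hold criterion can exceed 2,000 steps.
Second, locked policies are metastable on long horizons: the
within-interval fine structure of delta, harvested selectively by
ring-neighbor actor units whose activity crosses the gate late in the
interval, lets a suppressed action's weight creep upward over
thousands of steps until the policy transiently collapses and
relearns.  Both phenomena are discussed in the test suite and bounded
by the experiment budgets.

The environments are exact re-implementations of the standard tasks,
not approximations; what the synthetic set-up does *not* model is
sensor noise, continuous action spaces, non-stationary dynamics, or
any real-time constraint — the loop advances in logical time, and
wall-clock pacing in the bridge is optional.

## Numerical and procedural details

* Seeding: every run derives independent child streams (network noise,
  actor noise, weight jitter, tie breaking) from one master seed via
  `numpy.random.SeedSequence`; identical (configuration, seed) pairs
  are bit-reproducible, including through the lockstep socket bridge.
* Ties in `argmax_decode` break to the lowest index by default
  (configurable to seeded-random).
* The value-function oracle `discounted_value` integrates the reward
  trace backward with the exponential kernel treating rewards as
  piecewise constant; it is used only as a test oracle.
* Degenerate inputs raise: empty activity vectors, delays that are not
  multiples of dt, lags beyond the history depth, observations of the
  wrong dimension, malformed bridge messages (dropped and counted,
  never fatal).
* The Q-learning baseline trains an MLP (2-64-3 by default) with ADAM
  on the semi-gradient TD loss with uniform replay and a linearly
  decaying epsilon; no target network, per the plain description of
  the comparison algorithm.

## Problem sizes

Test and acceptance runs use 4,000 environment steps per FrozenLake
seed (5 seeds) and 20 episodes capped at 3,000 steps per MountainCar
seed (10 seeds); at 10 network steps per environment step these are
~0.4 M and ~2 M network updates respectively, which keeps a full
suite run in the minutes range on one CPU.
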