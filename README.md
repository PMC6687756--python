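# neuroloop

Closed-loop reinforcement learning with networks of rate neurons.

`neuroloop` is a self-contained simulator of a biologically motivated
actor-critic agent: a place-cell input layer projects through plastic
synapses to a critic unit (state value) and to a winner-take-all
circuit of actor units (action selection), and a reward-prediction-error
unit gates the plasticity of both projections.  The agent is trained in
a closed loop against built-in re-implementations of two classic
benchmark tasks — MountainCar (continuous states) and non-slippery 4x4
FrozenLake (discrete states) — and can also be coupled to any
environment over a publish-subscribe socket bridge exchanging JSON
messages.  A Q-learning baseline (MLP function approximation,
epsilon-greedy, replay memory, ADAM) is included for comparison.

## The model

Each unit follows the stochastic rate equation

    tau dz_i/dt = -z_i + mu_i + f(h_i - theta_i) + xi_i(t),
    h_i = sum_j w_ij z_j(t - d_ij),

integrated with a stochastic exponential-Euler scheme on a 1 ms grid.
The critic activity v(t) learns the continuous-time value function
V(t) = ∫ r(t') e^-(t'-t)/tau_r dt' by gradient descent on
E = (V - v)^2 / 2, which yields the three-factor Hebbian rule

    dw_j = eta * delta(t) * x_j(t) * Theta(z(t) - theta_post),

with the reward-prediction error approximated by a two-point
difference realized as two critic connections (one instantaneous, one
delayed by d):

    delta(t) = (1/d - 1/tau_r) v(t) - (1/d) v(t - d) + r(t).

For discrete environments, whose one-hot place cells do not overlap,
the pre- and postsynaptic factors are evaluated one environment step
in the past (an eligibility delay), so plasticity credits the
state-action pair that produced the current transition.  See
`docs/methods.md` for the full account, all defaults, and known
limitations.

## Worked example

Train the actor-critic on FrozenLake for one seed and inspect what it
learned:

```python
from neuroloop import Observation, extract_policy_value
from neuroloop.experiments import train_frozenlake, frozenlake_convergence

agent, env, log = train_frozenlake(seed=3, max_env_steps=4000)
opt = env.theoretical_optimum_per_step()
step, curve = frozenlake_convergence(log, opt)
print(f"goals reached: {len(log.episode_returns)}")
print(f"optimum per step: {opt:.4f}, final 500-step average: {curve[-1]:.4f}")
pv = extract_policy_value(agent, [Observation(discrete_index=i) for i in range(16)])
print("policy:", pv.actions.reshape(4, 4))
```

A representative run prints:

```
goals reached: 416
optimum per step: 0.1567, final 500-step average: 0.1560
policy: [[3 0 0 0]
         [2 3 1 2]
         [2 3 0 0]
         [1 2 2 0]]
```

416 completed episodes in 4,000 steps means the agent ends up looping
start-to-goal in about six moves; the 500-step average reward per step
(0.156) sits at the theoretical optimum under the configured shaping
((1 - 6*0.01)/6 ~ 0.157), and the policy arrows (0=W, 1=N, 2=E, 3=S)
follow the shortest path 0 -> 4 -> 8 -> 9 -> 13 -> 14 -> goal while
pointing away from the holes (states 5, 7, 11, 12).

The same experiments are available from the shell:

```bash
neuroloop run --experiment frozenlake --seed 1 --n-seeds 5 --out results/fl
neuroloop show-defaults
neuroloop serve --env frozenlake --ports 7555 7556 7557   # socket bridge
```

`run` writes per-seed curves (CSV), a summary (JSON), the learned
policy/value map and a learning-curve figure.

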