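"""Controller-gain selection by reinforcement learning.

The tuning problem is cast as an episodic MDP: an *action* is a
candidate gain triple (k1, k2, k3) inside a box, one *episode* is a
short closed-loop simulation run with those gains, the *observation*
is a fixed-length summary of the input and tumour trajectories
(u1, u2, y), and the per-step *reward* scores the deviation of the
applied input from a nominal reference input:

    r_t = +sigma1 * |u(t) - u_ref(t)|   if |u(t) - u_ref(t)| < epsilon
          -sigma2 * |u(t) - u_ref(t)|   otherwise

(verbatim mode).  Inside the deadband this rewards *larger* deviations,
which contradicts the stated intent of penalising distance from the
reference; a ``corrected`` mode returning sigma1 * (epsilon - |dev|)
inside the band is provided, but verbatim is the default.  The
condition is read on the absolute deviation: a signed reading would
reward arbitrarily negative deviations.

Two optimizers are provided: a soft actor-critic (entropy-regularised
off-policy learning with twin critics, replay buffer and a
reparameterised tanh-Gaussian policy) and a seeded cross-entropy method
as a derivative-free fallback.  Both respect the action box and are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from ._mlp import MLP, Adam
from .closed_loop import ScenarioConfig, scenario_preset, simulate
from .controller import ControlGains
from .integrators import DivergenceError, IntegratorConfig

__all__ = [
    "RewardConfig",
    "reward",
    "TuningEnvironment",
    "TuningResult",
    "env_step",
    "tune_gains",
]


@dataclass(frozen=True)
class RewardConfig:
    sigma1: float = 1.0          # in-band weight
    sigma2: float = 10.0         # out-of-band penalty weight
    epsilon: float = 5.0         # deadband half-width, input units
    mode: str = "verbatim"       # or "corrected"

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0 or self.epsilon < 0:
            raise ValueError("sigma1, sigma2 and epsilon must be nonnegative")
        if self.mode not in ("verbatim", "corrected"):
            raise ValueError(f"unknown reward mode {self.mode!r}")


def reward(u: float, u_ref: float, cfg: RewardConfig = RewardConfig()) -> float:
    """Per-step reward for one input channel (piecewise, strict '<')."""
    dev = abs(u - u_ref)
    if dev < cfg.epsilon:
        if cfg.mode == "corrected":
            return cfg.sigma1 * (cfg.epsilon - dev)
        return cfg.sigma1 * dev
    return -cfg.sigma2 * dev


class EpisodicEnv(Protocol):
    """Anything the optimizers can tune: a box of actions, a fixed-length
    observation, and a deterministic episode evaluator."""

    action_low: np.ndarray
    action_high: np.ndarray
    obs_dim: int

    def episode(self, action: np.ndarray) -> tuple[np.ndarray, float, bool]:
        ...


@dataclass
class TuningEnvironment:
    """Closed-loop gain-tuning environment.

    Episodes run a shortened version of ``base`` (``episode_horizon``
    days on a coarser grid) so that hundreds of episodes stay cheap; the
    reference input trajectory is produced once by running the same
    episode with the base scenario's own gains ("nominal system input").
    """

    base: ScenarioConfig = field(default_factory=lambda: scenario_preset("nominal"))
    reward_cfg: RewardConfig = field(default_factory=RewardConfig)
    bounds: tuple[tuple[float, float], ...] = ((0.01, 1.0),) * 3  # k1,k2,k3
    episode_horizon: float = 5.0       # days
    episode_step: float = 0.1          # days -> 50 steps per episode
    discount: float = 0.99
    n_obs_samples: int = 10            # per channel (u1, u2, y)
    divergence_floor: float = -1e9

    def __post_init__(self) -> None:
        low = np.array([b[0] for b in self.bounds], dtype=float)
        high = np.array([b[1] for b in self.bounds], dtype=float)
        if np.any(low <= 0) or np.any(high <= low):
            raise ValueError("action bounds must be positive with high > low")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError("discount must lie in [0, 1]")
        self.action_low = low
        self.action_high = high
        self.obs_dim = 3 * self.n_obs_samples
        self._episode_scenario = replace(
            self.base, horizon=self.episode_horizon,
            integrator=IntegratorConfig(method="rk4_fixed",
                                        step=self.episode_step),
            order=None, measurement_interval=None)
        ref = simulate(self._episode_scenario)
        self._u_ref = ref.trajectory.inputs.copy()

    def _gains(self, action: np.ndarray) -> ControlGains:
        base = self.base.gains
        return ControlGains(alpha=base.alpha, k1=float(action[0]),
                            k2=float(action[1]), k3=float(action[2]))

    def episode(self, action: np.ndarray) -> tuple[np.ndarray, float, bool]:
        action = np.asarray(action, dtype=float)
        if np.any(action < self.action_low - 1e-12) or \
           np.any(action > self.action_high + 1e-12):
            raise ValueError(f"action {action} outside bounds")
        scenario = replace(self._episode_scenario, gains=self._gains(action))
        try:
            result = simulate(scenario)
        except (DivergenceError, OverflowError, FloatingPointError):
            return np.zeros(self.obs_dim), self.divergence_floor, True
        traj = result.trajectory
        u = traj.inputs
        disc = self.discount ** np.arange(len(traj))
        r_steps = np.array(
            [reward(u[i, 0], self._u_ref[i, 0], self.reward_cfg)
             + reward(u[i, 1], self._u_ref[i, 1], self.reward_cfg)
             for i in range(len(traj))])
        total = float(np.sum(disc * r_steps))
        if not np.isfinite(total):
            return np.zeros(self.obs_dim), self.divergence_floor, True
        idx = np.linspace(0, len(traj) - 1, self.n_obs_samples).astype(int)
        # scale-compressed summary keeps the observation O(1)
        obs = np.concatenate([
            np.sign(u[idx, 0]) * np.log1p(np.abs(u[idx, 0])),
            np.sign(u[idx, 1]) * np.log1p(np.abs(u[idx, 1])),
            np.log1p(np.abs(traj.channel("y")[idx])),
        ])
        return obs, total, True


def env_step(env: EpisodicEnv, action: np.ndarray
             ) -> tuple[np.ndarray, float, bool]:
    """Run one episode with a candidate action (gain triple)."""
    return env.episode(action)


@dataclass
class TuningResult:
    best_gains: np.ndarray
    best_reward: float
    reward_history: list[float]
    optimizer: str
    seed: int


# ---------------------------------------------------------------------------
# Cross-entropy method

def _tune_cross_entropy(env: EpisodicEnv, budget: int, seed: int,
                        population: int = 16, elite_frac: float = 0.25
                        ) -> TuningResult:
    rng = np.random.default_rng(seed)
    low, high = env.action_low, env.action_high
    mu = 0.5 * (low + high)
    sigma = 0.5 * (high - low)
    n_elite = max(1, int(round(elite_frac * population)))
    history: list[float] = []
    best_a, best_r = mu.copy(), -np.inf
    evaluated = 0
    while evaluated < budget:
        pop = min(population, budget - evaluated)
        actions = np.clip(mu + sigma * rng.standard_normal((pop, len(low))),
                          low, high)
        rewards = np.empty(pop)
        for i, a in enumerate(actions):
            _, rewards[i], _ = env.episode(a)
        history.extend(rewards.tolist())
        evaluated += pop
        order = np.argsort(rewards)[::-1]
        if rewards[order[0]] > best_r:
            best_r = float(rewards[order[0]])
            best_a = actions[order[0]].copy()
        elite = actions[order[:min(n_elite, pop)]]
        mu = elite.mean(axis=0)
        sigma = elite.std(axis=0) + 0.05 * (high - low) * 0.01
    return TuningResult(best_a, best_r, history, "cross_entropy", seed)


# ---------------------------------------------------------------------------
# Soft actor-critic (episodic / one-step form)

def _tune_sac(env: EpisodicEnv, budget: int, seed: int,
              hidden: int = 64, batch: int = 64, lr: float = 3e-3,
              temperature: float = 0.1, buffer_size: int = 10_000,
              warmup: int = 16, updates_per_episode: int = 4
              ) -> TuningResult:
    """Soft actor-critic over the episodic gain MDP.

    Twin critics Q1/Q2 with MSE regression to the (entropy-free,
    terminal) episode return; a reparameterised tanh-Gaussian policy
    maximises min(Q1, Q2) - temperature * log pi.  Episodes terminate
    after one action, so no bootstrapped target network is needed: the
    target value of a terminal transition is the reward itself.
    Rewards are normalised online to keep critic regression scaled.
    """
    rng = np.random.default_rng(seed)
    low, high = env.action_low, env.action_high
    da, ds = len(low), env.obs_dim
    mid, half = 0.5 * (low + high), 0.5 * (high - low)

    policy = MLP([ds, hidden, hidden, 2 * da], rng, out_scale=0.1)
    critics = [MLP([ds + da, hidden, hidden, 1], rng) for _ in range(2)]
    opt_pi = Adam(policy.params, lr=lr)
    opt_q = [Adam(c.params, lr=lr) for c in critics]

    buf_s = np.zeros((buffer_size, ds))
    buf_a = np.zeros((buffer_size, da))
    buf_r = np.zeros(buffer_size)
    n_buf = 0

    LOG_STD_MIN, LOG_STD_MAX = -4.0, 1.0

    def policy_sample(s: np.ndarray, xi: np.ndarray):
        out = policy.forward(s)
        mu_p, log_std = out[:, :da], np.clip(out[:, da:], LOG_STD_MIN, LOG_STD_MAX)
        std = np.exp(log_std)
        pre = mu_p + std * xi
        t = np.tanh(pre)
        a = mid + half * t
        log_pi = (-0.5 * (xi**2 + np.log(2 * np.pi)) - log_std
                  - np.log(half * (1.0 - t**2) + 1e-8)).sum(axis=1)
        return a, log_pi, (out, mu_p, log_std, std, pre, t, xi)

    history: list[float] = []
    best_a, best_r = mid.copy(), -np.inf
    obs = np.zeros(ds)
    r_scale = 1.0

    for ep in range(budget):
        if ep < warmup:
            act = rng.uniform(low, high)
        else:
            xi = rng.standard_normal((1, da))
            act, _, _ = policy_sample(obs[None, :], xi)
            act = np.clip(act[0], low, high)
        next_obs, r, _ = env.episode(act)
        history.append(r)
        if r > best_r:
            best_r, best_a = float(r), np.asarray(act, dtype=float).copy()
        i = n_buf % buffer_size
        buf_s[i], buf_a[i], buf_r[i] = obs, act, r
        n_buf += 1
        obs = next_obs
        if n_buf < warmup:
            continue
        r_scale = max(1.0, float(np.abs(buf_r[:min(n_buf, buffer_size)]).max()))
        for _ in range(updates_per_episode):
            m = min(n_buf, buffer_size)
            idx = rng.integers(0, m, size=min(batch, m))
            s, a, rr = buf_s[idx], buf_a[idx], buf_r[idx] / r_scale
            sa = np.concatenate([s, a], axis=1)
            # critic regression to the terminal return
            for c, opt in zip(critics, opt_q):
                q = c.forward(sa)[:, 0]
                grads, _ = c.backward((2.0 * (q - rr) / len(rr))[:, None])
                opt.step(grads)
            # policy: maximise min-Q of the reparameterised action minus
            # the entropy penalty
            xi = rng.standard_normal((len(idx), da))
            a_pi, log_pi, cache = policy_sample(s, xi)
            out, mu_p, log_std, std, pre, t, xi = cache
            sa_pi = np.concatenate([s, a_pi], axis=1)
            qs = [c.forward(sa_pi)[:, 0] for c in critics]
            which = np.argmin(np.stack(qs), axis=0)
            g_a = np.zeros((len(idx), da))
            for ci, c in enumerate(critics):
                rows = which == ci
                if not np.any(rows):
                    continue
                c.forward(sa_pi[rows])
                _, g_in = c.backward(np.ones((rows.sum(), 1)))
                g_a[rows] = g_in[:, ds:]
            n = float(len(idx))
            dt2 = 1.0 - t**2
            # d(-Q)/d pre  +  temperature * d log_pi / d pre
            g_pre = (-g_a * half * dt2
                     + temperature * 2.0 * t * half * dt2 / (half * dt2 + 1e-8)) / n
            g_mu = g_pre
            g_logstd = g_pre * std * xi - (temperature / n) * np.ones_like(log_std)
            g_logstd[(log_std <= LOG_STD_MIN) | (log_std >= LOG_STD_MAX)] = 0.0
            grads, _ = policy.backward(np.concatenate([g_mu, g_logstd], axis=1))
            opt_pi.step(grads)
    return TuningResult(best_a, best_r, history, "sac", seed)


def tune_gains(env: EpisodicEnv, optimizer: str = "cross_entropy",
               budget: int = 200, seed: int = 0, **kwargs) -> TuningResult:
    """Search the gain box for high-reward gains.

    ``optimizer`` is ``"sac"`` (soft actor-critic) or ``"cross_entropy"``
    (derivative-free fallback).  Deterministic given ``seed``; the
    returned best gains always lie inside the action box.
    """
    if budget < 1:
        raise ValueError("budget must be at least one episode")
    if optimizer == "cross_entropy":
        result = _tune_cross_entropy(env, budget, seed, **kwargs)
    elif optimizer == "sac":
        result = _tune_sac(env, budget, seed, **kwargs)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    result.best_gains = np.clip(result.best_gains, env.action_low,
                                env.action_high)
    return result
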