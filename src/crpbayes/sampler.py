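"""Hamiltonian Monte Carlo with warmup adaptation.

A static-path HMC sampler in the style of Stan's adaptive variant: leapfrog
integration with a randomly jittered number of steps, dual-averaging step
size adaptation toward a target acceptance rate, and a windowed diagonal
mass-matrix estimate.  The protocol mirrors the analysis it supports: four
chains of 2000 iterations, the first 1000 discarded as combined burn-in and
adaptation.  Everything is deterministic given the master seed; per-chain
streams are derived by seed-sequence spawning on (seed, chain index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

_DIVERGENCE_THRESHOLD = 1000.0  # energy error treated as a divergence


@dataclass
class SamplerConfig:
    n_chains: int = 4
    n_iterations: int = 2000
    n_warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 32
    init_radius: float = 2.0
    init_buffer: int = 75     # step-size-only adaptation at warmup start
    term_buffer: int = 50     # step-size-only adaptation at warmup end
    base_window: int = 25     # first mass-matrix window, then doubling

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.n_warmup < self.n_iterations:
            raise ValueError("need 0 < n_warmup < n_iterations")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.max_leapfrog < 1:
            raise ValueError("max_leapfrog must be at least 1")


@dataclass
class ChainSet:
    """Post-warmup posterior draws plus sampler health statistics.

    ``draws`` has shape (chains, kept iterations, parameters) on the
    constrained scale; ``names`` labels the last axis.
    """

    draws: np.ndarray
    names: list[str]
    accept_rate: np.ndarray       # mean acceptance probability per chain
    divergences: np.ndarray       # post-warmup divergence count per chain
    step_sizes: np.ndarray        # frozen step size per chain
    seeds: list[list[int]]        # per-chain seed-sequence keys
    config: SamplerConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def parameter(self, name: str) -> np.ndarray:
        """Draws of one parameter as a (chains, iterations) array."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def to_csv(self, out_dir, prefix: str = "chain") -> None:
        """One CSV per chain plus a JSON manifest."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            pd.DataFrame(self.draws[c], columns=self.names).to_csv(
                out / f"{prefix}_{c}.csv", index=False)
        manifest = {
            "config": asdict(self.config),
            "seeds": self.seeds,
            "accept_rate": self.accept_rate.tolist(),
            "divergences": self.divergences.tolist(),
            "step_sizes": self.step_sizes.tolist(),
            "warnings": self.warnings,
        }
        with open(out / f"{prefix}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def initialize(logp, dim: int, rng: np.random.Generator,
               radius: float = 2.0, max_tries: int = 100) -> np.ndarray:
    """Jittered starting point with a finite target value."""
    for _ in range(max_tries):
        q = rng.uniform(-radius, radius, size=dim)
        if np.isfinite(logp(q)):
            return q
    raise RuntimeError("could not find a finite initialization")


def _find_reasonable_step(logp, grad, q, inv_mass, rng) -> float:
    """Double/halve the step size until one leapfrog step accepts near 0.5."""
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp(q) - 0.5 * float(p * inv_mass @ p)

    def h_after(eps):
        qn, pn = _leapfrog(logp, grad, q, p, eps, 1, inv_mass)
        lp = logp(qn)
        if not np.isfinite(lp) or not np.all(np.isfinite(pn)):
            return -np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            return lp - 0.5 * float(pn * inv_mass @ pn)

    delta = h_after(eps) - h0
    direction = 1.0 if delta > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        delta = h_after(eps) - h0
        if (direction == 1.0 and delta <= np.log(0.5)) or \
           (direction == -1.0 and delta >= np.log(0.5)):
            break
        if eps > 1e7 or eps < 1e-10:
            break
    return eps


def _leapfrog(logp, grad, q, p, eps, n_steps, inv_mass):
    q = q.copy()
    p = p + 0.5 * eps * grad(q)
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        g = grad(q)
        if not np.all(np.isfinite(g)):
            return q, np.full_like(p, np.nan)
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * g
    return q, p


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman scheme)."""

    def __init__(self, eps0: float, target: float,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        frac = 1.0 / (m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _mass_windows(warmup: int, init_buffer: int, term_buffer: int,
                  base_window: int) -> list[int]:
    """End iterations of the mass-matrix estimation windows (Stan-style)."""
    if warmup < init_buffer + term_buffer + base_window:
        return []
    ends = []
    start = init_buffer
    size = base_window
    while True:
        end = start + size
        if end + 2 * size > warmup - term_buffer:
            ends.append(warmup - term_buffer)
            break
        ends.append(end)
        start, size = end, 2 * size
    return ends


def _run_single_chain(logp, grad, dim, config: SamplerConfig,
                      seed_key: list[int]):
    rng = np.random.default_rng(seed_key)
    q = initialize(logp, dim, rng, radius=config.init_radius)
    inv_mass = np.ones(dim)
    eps = _find_reasonable_step(logp, grad, q, inv_mass, rng)
    da = _DualAveraging(eps, config.target_accept)
    windows = _mass_windows(config.n_warmup, config.init_buffer,
                            config.term_buffer, config.base_window)
    window_draws: list[np.ndarray] = []

    kept = np.empty((config.n_iterations - config.n_warmup, dim))
    accept_sum = 0.0
    divergences = 0
    log_q = logp(q)

    for it in range(config.n_iterations):
        warm = it < config.n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(1, config.max_leapfrog + 1))
        h0 = log_q - 0.5 * float(p0 * inv_mass @ p0)
        qn, pn = _leapfrog(logp, grad, q, p0, eps, n_steps, inv_mass)
        if np.all(np.isfinite(pn)):
            log_qn = logp(qn)
            with np.errstate(over="ignore", invalid="ignore"):
                h1 = log_qn - 0.5 * float(pn * inv_mass @ pn)
            delta = h1 - h0
        else:
            log_qn, delta = -np.inf, -np.inf
        divergent = (not np.isfinite(delta)) or (delta < -_DIVERGENCE_THRESHOLD)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta, 0.0))))
        if not divergent and np.log(rng.uniform()) < delta:
            q, log_q = qn, log_qn

        if warm:
            eps = da.update(accept_prob)
            window_draws.append(q.copy())
            if it + 1 in windows:
                block = np.asarray(window_draws)
                w = block.shape[0]
                var = block.var(axis=0, ddof=1) if w > 1 else np.ones(dim)
                # regularize toward a small diagonal, as Stan does
                inv_mass = (w / (w + 5.0)) * var + 1e-3 * (5.0 / (w + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-10)
                window_draws = []
                eps = _find_reasonable_step(logp, grad, q, inv_mass, rng)
                da = _DualAveraging(eps, config.target_accept)
            if it + 1 == config.n_warmup:
                eps = da.adapted
        else:
            accept_sum += accept_prob
            divergences += int(divergent)
            kept[it - config.n_warmup] = q

    n_kept = config.n_iterations - config.n_warmup
    return kept, accept_sum / n_kept, divergences, eps


def run_chains(logp, grad, config: SamplerConfig, dim: int,
               constrain=None, names: list[str] | None = None) -> ChainSet:
    """Run all chains and return constrained post-warmup draws.

    ``constrain`` maps an unconstrained vector to the reported constrained
    vector (identity if omitted); ``names`` labels the constrained axis.
    """
    chains = []
    accept = np.empty(config.n_chains)
    div = np.zeros(config.n_chains, dtype=int)
    steps = np.empty(config.n_chains)
    seed_keys = [[int(config.seed), c] for c in range(config.n_chains)]
    for c, key in enumerate(seed_keys):
        kept, acc, d, eps = _run_single_chain(logp, grad, dim, config, key)
        accept[c], div[c], steps[c] = acc, d, eps
        if constrain is not None:
            kept = np.apply_along_axis(constrain, 1, kept)
        chains.append(kept)
    draws = np.asarray(chains)
    if names is None:
        names = [f"q{i}" for i in range(draws.shape[2])]
    warnings = []
    n_kept = config.n_iterations - config.n_warmup
    frac_div = div.sum() / (config.n_chains * n_kept)
    if frac_div > 0.10:
        warnings.append(f"{100 * frac_div:.1f}% divergent transitions "
                        "after warmup; results are unreliable")
    if np.any(~np.isfinite(draws)):
        raise RuntimeError("non-finite draws returned by the sampler")
    return ChainSet(draws=draws, names=list(names), accept_rate=accept,
                    divergences=div, step_sizes=steps, seeds=seed_keys,
                    config=config, warnings=warnings)
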