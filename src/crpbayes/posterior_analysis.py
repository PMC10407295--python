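"""Convergence diagnostics and posterior reporting.

Split-chain R-hat and autocorrelation-based effective sample size assess
convergence; summaries report the posterior mean, SD and 2.5/50/97.5%
quantiles per parameter; contrasts express hierarchical group deviations
relative to a reference category; and regression-line draws and 65% density
intervals provide plot-ready output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import ChainSet

#: quantile estimator for all reported quantiles (median-unbiased)
_Q_METHOD = "median_unbiased"


def _chain_matrix(chainset, parameter) -> np.ndarray:
    """Accept a ChainSet + name or a bare (chains, draws) array."""
    if isinstance(chainset, ChainSet):
        return chainset.parameter(parameter)
    x = np.asarray(chainset, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    return x


def rhat(chainset, parameter=None) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half, doubling the chain count, so that trends
    within a chain also inflate the statistic.  Returns NaN when the draws
    carry no variance (undefined).
    """
    x = _chain_matrix(chainset, parameter)
    m, n = x.shape
    if m < 1 or n < 4:
        raise ValueError("need at least one chain with >= 4 draws")
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return float("nan")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def autocorrelation(chainset, parameter=None, max_lag: int = 100) -> np.ndarray:
    """Per-lag autocorrelation, averaged over chains (FFT-based)."""
    x = _chain_matrix(chainset, parameter)
    m, n = x.shape
    max_lag = min(max_lag, n - 1)
    acf = np.zeros(max_lag + 1)
    for c in range(m):
        xc = x[c] - x[c].mean()
        size = 2 ** int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(xc, size)
        acov = np.fft.irfft(f * np.conj(f), size)[: max_lag + 1].real / n
        if acov[0] <= 0:
            return np.full(max_lag + 1, np.nan)
        acf += acov / acov[0]
    return acf / m


def ess(chainset, parameter=None) -> float:
    """Effective sample size via Geyer's initial monotone positive sequence.

    Combines within-chain autocovariances with the between-chain variance
    so that non-overlapping chains shrink the estimate.
    """
    x = _chain_matrix(chainset, parameter)
    m, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w <= 0:
        return float("nan")
    var_plus = w * (n - 1) / n
    if m > 1:
        var_plus += chain_means.var(ddof=1)

    # mean autocovariance over chains per lag
    max_lag = n - 1
    acov = np.zeros(max_lag + 1)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    for c in range(m):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(xc, size)
        acov += np.fft.irfft(f * np.conj(f), size)[: max_lag + 1].real / n
    acov /= m

    rho = 1.0 - (w - acov) / var_plus
    # Geyer: sum consecutive-lag pairs while positive, enforce monotonicity
    tau = 1.0  # rho_0 contributes 1 (2*0.5)
    prev_pair = np.inf
    t = 1
    while t + 1 <= max_lag:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


def summarize(chainset: ChainSet, names: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter posterior mean, SD and 2.5/50/97.5% quantiles.

    Chains are pooled; rows keep the model's reporting order.
    """
    if chainset.draws.size == 0:
        raise ValueError("empty chain set")
    use = names if names is not None else chainset.names
    rows = []
    for name in use:
        d = chainset.pooled(name)
        q = np.quantile(d, [0.025, 0.5, 0.975], method=_Q_METHOD)
        rows.append({"parameter": name, "mean": float(d.mean()),
                     "sd": float(d.std(ddof=1)),
                     "q2.5": float(q[0]), "q50": float(q[1]),
                     "q97.5": float(q[2])})
    return pd.DataFrame(rows)


def diagnostics_table(chainset: ChainSet) -> pd.DataFrame:
    """R-hat and ESS for every reported parameter."""
    rows = [{"parameter": name,
             "rhat": rhat(chainset, name),
             "ess": ess(chainset, name)} for name in chainset.names]
    return pd.DataFrame(rows)


def contrasts(chainset: ChainSet, factor: str, reference: str,
              side: str = "mu") -> dict[str, np.ndarray]:
    """Per-draw deviation contrasts against a reference category.

    For each category of ``factor`` (education or occupation), returns the
    pooled per-draw difference ``deviation[category] - deviation[reference]``.
    ``side="sigma"`` addresses the scale-side deviations of Model 2.
    """
    if factor not in ("education", "occupation"):
        raise ValueError("factor must be 'education' or 'occupation'")
    prefix = {"mu": "", "sigma": "sigma_"}[side]
    stem = {"education": "edu_dev", "occupation": "occ_dev"}[factor]
    pattern = f"{prefix}{stem}["
    levels = [n[len(pattern):-1] for n in chainset.names
              if n.startswith(pattern)]
    if not levels:
        raise ValueError(f"no {side}-side {factor} deviations in the draws")
    if reference not in levels:
        raise ValueError(f"unknown reference category {reference!r}")
    ref = chainset.pooled(f"{pattern}{reference}]")
    return {lvl: chainset.pooled(f"{pattern}{lvl}]") - ref for lvl in levels}


def density_interval(draws: np.ndarray, mass: float = 0.65,
                     method: str = "central") -> tuple[float, float]:
    """Interval containing ``mass`` of the posterior draws.

    ``central`` takes equal-tail quantiles; ``hpd`` the shortest interval.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    if draws.size < 1:
        raise ValueError("no draws")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    if mass == 1.0:
        return float(draws[0]), float(draws[-1])
    if method == "central":
        lo, hi = np.quantile(draws, [(1 - mass) / 2, 1 - (1 - mass) / 2],
                             method=_Q_METHOD)
        return float(lo), float(hi)
    if method == "hpd":
        n = draws.size
        k = max(1, int(np.ceil(mass * n)))
        widths = draws[k - 1:] - draws[: n - k + 1]
        i = int(np.argmin(widths))
        return float(draws[i]), float(draws[i + k - 1])
    raise ValueError(f"unknown method {method!r}")


def sample_regression_lines(chainset: ChainSet, predictor: str = "z_income",
                            k: int = 20, seed: int = 0,
                            side: str = "mu") -> np.ndarray:
    """k (intercept, slope) pairs sampled without replacement from the draws.

    Each pair comes from a single posterior draw, so the lines jointly
    visualise posterior uncertainty about the predictor's effect.  For the
    scale side of Model 2 the sigma-model intercept and coefficient are
    used instead.
    """
    prefix = {"mu": "", "sigma": "sigma_"}[side]
    intercept = chainset.pooled(f"{prefix}intercept")
    slope = chainset.pooled(f"{prefix}{predictor}")
    n = intercept.size
    if k > n:
        raise ValueError(f"requested {k} lines from only {n} draws")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return np.column_stack([intercept[idx], slope[idx]])


def trace_export(chainset: ChainSet, parameters: list[str] | None = None,
                 max_lag: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready trace and autocorrelation tables (long format)."""
    params = parameters if parameters is not None else chainset.names
    trace_rows, acf_rows = [], []
    for name in params:
        x = chainset.parameter(name)
        for c in range(x.shape[0]):
            trace_rows.append(pd.DataFrame({
                "parameter": name, "chain": c,
                "iteration": np.arange(x.shape[1]), "value": x[c]}))
        acf = autocorrelation(chainset, name, max_lag=max_lag)
        acf_rows.append(pd.DataFrame({
            "parameter": name, "lag": np.arange(acf.size), "acf": acf}))
    return pd.concat(trace_rows, ignore_index=True), \
        pd.concat(acf_rows, ignore_index=True)
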