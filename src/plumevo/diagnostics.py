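"""Convergence and autocorrelation checks for the RJMCMC chains.

Cross-chain agreement is judged on the log harmonic mean (lnHM) of sampled
likelihoods: chains are called converged when all pairwise differences are
below 1 lnHM.  The harmonic mean is used here purely as a convergence
heuristic, not as a marginal-likelihood estimate.  Residual autocorrelation
of the retained log-likelihood trace is tested with the Ljung-Box portmanteau
statistic; if autocorrelation is detected the trace can be thinned further
until it passes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .rjmcmc import PosteriorSample

__all__ = [
    "log_harmonic_mean",
    "ljung_box",
    "converged",
    "ChainDiagnostics",
    "diagnose_chains",
    "autocorrelation_thin",
]


def log_harmonic_mean(logL: Sequence[float]) -> float:
    """log of the harmonic mean of likelihoods, computed entirely in log
    space: -(logsumexp(-logL) - log n)."""
    logL = np.asarray(logL, dtype=float)
    if logL.size == 0:
        raise ValueError("empty log-likelihood sequence")
    return float(-(logsumexp(-logL) - math.log(logL.size)))


def ljung_box(series: Sequence[float], lags: int) -> tuple[float, float]:
    """Ljung-Box portmanteau test for autocorrelation up to ``lags``.

    Q = n (n + 2) sum_{h=1..lags} r_h^2 / (n - h), compared against a
    chi-square with ``lags`` degrees of freedom.  Returns (Q, p-value).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if n <= lags:
        raise ValueError(f"series length {n} must exceed lags {lags}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("constant series: autocorrelation undefined")
    q = 0.0
    for h in range(1, lags + 1):
        r_h = float(np.dot(xc[h:], xc[:-h])) / denom
        q += r_h * r_h / (n - h)
    q *= n * (n + 2)
    p = float(chi2.sf(q, df=lags))
    return q, p


@dataclass
class ChainDiagnostics:
    chain_id: int
    n_samples: int
    log_harmonic_mean: float
    acceptance: dict = field(default_factory=dict)
    ljung_box_stat: float = float("nan")
    ljung_box_p: float = float("nan")
    ljung_box_lags: int = 0


def converged(diags: Sequence[ChainDiagnostics], threshold: float = 1.0) -> tuple[bool, dict]:
    """Cross-chain convergence rule: every pairwise |delta lnHM| < threshold.

    Returns (flag, report) with the maximum pairwise spread."""
    if len(diags) < 2:
        raise ValueError("convergence check requires at least 2 chains")
    hms = [d.log_harmonic_mean for d in diags]
    spread = max(hms) - min(hms)
    report = {
        "lnHM_per_chain": {d.chain_id: d.log_harmonic_mean for d in diags},
        "max_pairwise_spread": spread,
        "threshold": threshold,
    }
    return spread < threshold, report


def diagnose_chains(
    samples: Sequence[PosteriorSample], lags: int | None = None
) -> list[ChainDiagnostics]:
    """Per-chain lnHM, acceptance rates, and a Ljung-Box test on the retained
    log-likelihood trace (lags default min(10, n // 5))."""
    out = []
    for s in samples:
        logL = s.logliks
        lb_lags = lags if lags is not None else max(1, min(10, len(logL) // 5))
        try:
            stat, p = ljung_box(logL, lb_lags)
        except ValueError:
            stat, p = float("nan"), float("nan")
        out.append(
            ChainDiagnostics(
                chain_id=s.chain_id,
                n_samples=len(s),
                log_harmonic_mean=log_harmonic_mean(logL) if len(s) else float("nan"),
                acceptance=dict(s.acceptance),
                ljung_box_stat=stat,
                ljung_box_p=p,
                ljung_box_lags=lb_lags,
            )
        )
    return out


def autocorrelation_thin(
    series: Sequence[float],
    p_threshold: float = 0.05,
    min_size: int = 100,
    max_rounds: int = 6,
) -> tuple[int, float]:
    """Find a thinning factor (powers of 2) at which the Ljung-Box test no
    longer rejects, stopping at a floor sample size.  Returns (thin, p)."""
    x = np.asarray(series, dtype=float)
    thin = 1
    for _ in range(max_rounds + 1):
        sub = x[::thin]
        if len(sub) < max(min_size, 11):
            break
        lags = max(1, min(10, len(sub) // 5))
        try:
            _, p = ljung_box(sub, lags)
        except ValueError:
            return thin, float("nan")
        if p > p_threshold:
            return thin, p
        thin *= 2
    lags = max(1, min(10, len(x[::thin]) // 5))
    try:
        _, p = ljung_box(x[::thin], lags)
    except ValueError:
        p = float("nan")
    return thin, p


def diagnostics_report(diags: Sequence[ChainDiagnostics], path=None) -> str:
    payload = {
        "chains": [
            {
                "chain": d.chain_id,
                "n_samples": d.n_samples,
                "lnHM": d.log_harmonic_mean,
                "acceptance": d.acceptance,
                "ljung_box": {"stat": d.ljung_box_stat, "p": d.ljung_box_p,
                              "lags": d.ljung_box_lags},
            }
            for d in diags
        ]
    }
    if len(diags) >= 2:
        flag, report = converged(diags)
        payload["converged"] = flag
        payload["convergence"] = report
    text = json.dumps(payload, indent=1, default=float)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
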