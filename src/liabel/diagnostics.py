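"""MCMC convergence diagnostics: Geweke, Heidelberger-Welch, HPD.

The spectral density at zero is estimated throughout by non-overlapping
batch means, the simplest consistent estimator for the Monte-Carlo
standard error of a correlated chain. Numeric thresholds (|z| < 1.96,
Cramer-von Mises at 5%) are advisory: they flag chains for inspection
rather than certify convergence.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "geweke_z",
    "heidelberger_welch",
    "HeidelbergerWelchResult",
    "hpd",
    "batch_means_se",
    "DiagnosticReport",
    "diagnose_chain",
]

# asymptotic critical values of the Cramer-von Mises statistic
_CVM_CRITICAL = {0.10: 0.3473, 0.05: 0.4614, 0.025: 0.5806, 0.01: 0.7435}


def batch_means_se(draws, n_batches: int = 20) -> float:
    """Monte-Carlo SE of the chain mean via non-overlapping batch means."""
    x = np.asarray(draws, dtype=float)
    nb = min(n_batches, len(x))
    if nb < 2:
        return float("nan")
    usable = (len(x) // nb) * nb
    means = x[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(nb))


def _spectral0(x, n_batches: int = 20) -> float:
    """Estimate of S(0), the spectral density at frequency zero."""
    se = batch_means_se(x, n_batches)
    return se * se * len(x)


def geweke_z(
    draws,
    frac_first: float = 0.1,
    frac_last: float = 0.5,
    n_batches: int = 20,
) -> float:
    """Geweke's comparison of early and late segment means.

    z = (mean_first - mean_last) / sqrt(SE_first^2 + SE_last^2) with
    batch-means standard errors. A constant chain returns 0 with a
    "degenerate chain" warning. Invariant to affine transformation.
    """
    x = np.asarray(draws, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need at least 100 draws, got {len(x)}")
    if np.ptp(x) == 0.0:
        warnings.warn("degenerate chain: constant draws, Geweke z set to 0")
        return 0.0
    first = x[: int(frac_first * len(x))]
    last = x[len(x) - int(frac_last * len(x)):]
    se1 = batch_means_se(first, n_batches)
    se2 = batch_means_se(last, n_batches)
    denom = math.sqrt(se1 * se1 + se2 * se2)
    if denom == 0.0:
        warnings.warn("degenerate chain segments: zero variance, Geweke z set to 0")
        return 0.0
    return float((first.mean() - last.mean()) / denom)


@dataclass
class HeidelbergerWelchResult:
    stationary: bool
    halfwidth_ratio: float | None  # None when the mean is ~0 (not applicable)
    halfwidth_passed: bool
    start_frac: float  # fraction of the chain discarded before stationarity held
    cvm_statistic: float

    @property
    def passed(self) -> bool:
        return self.stationary and self.halfwidth_passed


def _cvm_statistic(x) -> float:
    """Cramer-von Mises statistic of the Brownian-bridge of partial sums."""
    n = len(x)
    s0 = _spectral0(x)
    if s0 <= 0.0:
        return 0.0
    csum = np.cumsum(x)
    k = np.arange(1, n + 1)
    bridge = csum - k * (csum[-1] / n)
    return float(np.sum(bridge**2) / (n**2 * s0))


def heidelberger_welch(
    draws, eps: float = 0.1, alpha: float = 0.05
) -> HeidelbergerWelchResult:
    """Heidelberger & Welch stationarity and halfwidth tests.

    The stationarity test applies the Cramer-von Mises statistic to the
    chain, discarding initial 10% increments (up to 50%) until the test
    passes. The halfwidth test requires the 95% Monte-Carlo halfwidth of
    the retained mean to be at most ``eps`` times |mean|; when the mean
    is numerically zero the ratio is reported as not applicable rather
    than blowing up.
    """
    x = np.asarray(draws, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need at least 100 draws, got {len(x)}")
    crit = _CVM_CRITICAL.get(round(alpha, 3))
    if crit is None:
        raise ValueError(f"alpha must be one of {sorted(_CVM_CRITICAL)}, got {alpha}")
    if np.ptp(x) == 0.0:
        return HeidelbergerWelchResult(True, 0.0, True, 0.0, 0.0)
    stationary = False
    start_frac = 0.0
    stat = float("inf")
    kept = x
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        kept = x[int(frac * len(x)):]
        stat = _cvm_statistic(kept)
        if stat <= crit:
            stationary = True
            start_frac = frac
            break
    mean = kept.mean()
    hw = 1.96 * batch_means_se(kept)
    scale = max(abs(x.mean()), x.std())
    if abs(mean) < 1e-12 * max(scale, 1.0):
        ratio = None
        hw_passed = hw <= eps * max(scale, 1e-12)  # fall back to the chain scale
    else:
        ratio = float(hw / abs(mean))
        hw_passed = ratio <= eps
    return HeidelbergerWelchResult(stationary, ratio, bool(hw_passed), start_frac, stat)


def hpd(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted draws."""
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws for an interval")
    m = int(math.ceil(mass * n))
    m = min(m, n)
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


@dataclass
class DiagnosticReport:
    """Per-parameter convergence summary for a fitted chain."""

    geweke: dict = field(default_factory=dict)
    geweke_degenerate: dict = field(default_factory=dict)
    heidelberger: dict = field(default_factory=dict)
    n_kept: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "n_kept": self.n_kept,
            "geweke_z": self.geweke,
            "geweke_degenerate": self.geweke_degenerate,
            "heidelberger_welch": {
                k: {
                    "stationary": v.stationary,
                    "halfwidth_ratio": v.halfwidth_ratio,
                    "halfwidth_passed": v.halfwidth_passed,
                    "start_frac": v.start_frac,
                    "cvm_statistic": v.cvm_statistic,
                }
                for k, v in self.heidelberger.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def trace_plot(chain, path, parameters: dict | None = None) -> None:
    """Export trace plots of the variance and h2 streams to ``path``.

    Replaces by-eye inspection of convergence; requires matplotlib and
    is never part of any pass/fail criterion.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    streams = {"sigma2_a": chain.sigma2_a, "h2": chain.h2()}
    if chain.model_type == "linear":
        streams["sigma2_e"] = chain.sigma2_e
    if parameters:
        streams.update(parameters)
    fig, axes = plt.subplots(len(streams), 1, figsize=(8, 2.2 * len(streams)),
                             sharex=True, squeeze=False)
    for ax, (name, x) in zip(axes[:, 0], streams.items()):
        ax.plot(np.asarray(x), lw=0.6)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("retained draw")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def diagnose_chain(chain, parameters: dict | None = None) -> DiagnosticReport:
    """Run Geweke and Heidelberger-Welch on the variance and h2 streams.

    ``chain`` is an :class:`liabel.mcmc.MCMCChain`; extra named draw
    streams can be supplied through ``parameters``.
    """
    streams = {"sigma2_a": chain.sigma2_a, "h2": chain.h2()}
    if chain.model_type == "linear":
        streams["sigma2_e"] = chain.sigma2_e
    if parameters:
        streams.update(parameters)
    rep = DiagnosticReport(n_kept=chain.n_kept)
    for name, x in streams.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rep.geweke[name] = geweke_z(x)
            rep.geweke_degenerate[name] = any(
                "degenerate" in str(w.message) for w in caught
            )
        rep.heidelberger[name] = heidelberger_welch(x)
    return rep
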