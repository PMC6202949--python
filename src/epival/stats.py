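"""Agreement statistics for the monitoring-vs-imaging comparison.

Nonparametric Bland-Altman limits of agreement (empirical quantiles with
linear interpolation between order statistics), a Lilliefors-style
Kolmogorov-Smirnov normality test with a seeded Monte-Carlo null,
ordinary-least-squares R-squared, and the Kruskal-Wallis rank ANOVA used
to compare per-fraction confidence/error across image-quality groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import ndtr

__all__ = [
    "AgreementTable",
    "TestResult",
    "nonparametric_loa",
    "ks_normality",
    "linreg_r2",
    "kruskal_wallis",
    "summarize_errors",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class AgreementTable:
    """Median and nested nonparametric limits of agreement.

    For signed errors each level holds an equal-tailed (lower, upper)
    interval; for non-negative magnitudes the one-sided upper limit is
    stored with ``None`` as the lower bound.
    """

    median: float
    loa: dict[int, tuple[float | None, float]]
    n: int
    two_sided: bool

    def __post_init__(self) -> None:
        levels = sorted(self.loa)
        for a, b in zip(levels, levels[1:]):
            lo_a, hi_a = self.loa[a]
            lo_b, hi_b = self.loa[b]
            if hi_a > hi_b + 1e-12 or (
                lo_a is not None and lo_b is not None and lo_a < lo_b - 1e-12
            ):
                raise ValueError("limits of agreement must be nested across levels")
        for lo, hi in self.loa.values():
            if lo is not None and not lo - 1e-12 <= self.median <= hi + 1e-12:
                raise ValueError("median must lie inside every two-sided interval")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def nonparametric_loa(
    errors: Sequence[float] | np.ndarray,
    levels: Sequence[int] = (25, 50, 75, 95),
    kind: str = "auto",
) -> AgreementTable:
    """Nonparametric limits of agreement from empirical quantiles.

    Signed errors get equal-tailed intervals: the level-p interval spans
    the (1-p/100)/2 and 1-(1-p/100)/2 quantiles (linear interpolation
    between order statistics).  Non-negative magnitudes get the one-sided
    p-quantile.  ``kind`` is "signed", "magnitude" or "auto" (magnitude
    when no value is negative).
    """
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise ValueError("empty error sample")
    if kind not in ("auto", "signed", "magnitude"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "auto":
        kind = "magnitude" if np.all(x >= 0) else "signed"
    if x.size < 20 and any(lv >= 95 for lv in levels):
        warnings.warn("fewer than 20 samples: the 95% limit is poorly determined")
    loa: dict[int, tuple[float | None, float]] = {}
    for lv in levels:
        p = lv / 100.0
        if kind == "signed":
            alpha = (1.0 - p) / 2.0
            loa[int(lv)] = (float(np.quantile(x, alpha)), float(np.quantile(x, 1.0 - alpha)))
        else:
            loa[int(lv)] = (None, float(np.quantile(x, p)))
    return AgreementTable(median=float(np.median(x)), loa=loa, n=int(x.size),
                          two_sided=kind == "signed")


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality with estimated parameters (Lilliefors)


def _ks_statistic(sorted_std: np.ndarray) -> np.ndarray:
    """Vectorized KS distance of standardized sorted rows against N(0, 1)."""
    n = sorted_std.shape[-1]
    cdf = ndtr(sorted_std)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the KS statistic with fitted moments."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    draws = rng.standard_normal((n_reps, n))
    std = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
    std.sort(axis=1)
    return np.sort(_ks_statistic(std))


def ks_normality(
    sample: Sequence[float] | np.ndarray,
    n_null: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """One-sample KS normality test with sample-estimated mean and SD.

    Because the parameters are fitted, the plain KS null is wrong; the
    p-value comes from a seeded Monte-Carlo (Lilliefors) null of
    ``n_null`` replicates, cached per sample size.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("at least 8 observations required")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test is degenerate")
    std = np.sort((x - x.mean()) / sd)
    d = float(_ks_statistic(std[None, :])[0])
    null = _lilliefors_null(int(x.size), int(n_null), int(seed))
    p = (1.0 + float(np.sum(null >= d))) / (len(null) + 1.0)
    return TestResult(statistic=d, p_value=min(p, 1.0), test_name="ks_normality",
                      group_sizes=(int(x.size),))


def linreg_r2(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Coefficient of determination of the ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank ANOVA (tie-corrected H, chi-squared p-value)."""
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        # all observations tied: no evidence of any difference
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(a.size for a in arrays))
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal_wallis", tuple(a.size for a in arrays))


# ---------------------------------------------------------------------------
# study-level summaries


def summarize_errors(
    e_u: np.ndarray, e_v: np.ndarray, levels: Sequence[int] = (25, 50, 75, 95)
) -> dict:
    """Agreement-table summary for both imager axes and the 2D magnitude.

    Mirrors the headline table of the validation: per-axis equal-tailed
    limits, one-sided magnitude limits, signed medians, and median
    absolute errors.
    """
    e_u = np.asarray(e_u, dtype=float)
    e_v = np.asarray(e_v, dtype=float)
    mag = np.hypot(e_u, e_v)
    out = {"n": int(e_u.size), "levels": [int(v) for v in levels], "axes": {}}
    for name, vals, kind in (("u", e_u, "signed"), ("v", e_v, "signed"),
                             ("magnitude", mag, "magnitude")):
        table = nonparametric_loa(vals, levels, kind=kind)
        out["axes"][name] = {
            "median": table.median,
            "median_abs": float(np.median(np.abs(vals))),
            "loa": {str(lv): list(pair) for lv, pair in table.loa.items()},
        }
    return out


def bland_altman_plot(errors: np.ndarray, means: np.ndarray, path, level: int = 95,
                      label: str = "E (mm)") -> None:
    """Save a Bland-Altman scatter with median and nonparametric limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    errors = np.asarray(errors, dtype=float)
    table = nonparametric_loa(errors, (level,))
    lo, hi = table.loa[level]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.asarray(means, dtype=float), errors, s=12, alpha=0.6)
    ax.axhline(table.median, color="k", lw=1.2)
    ax.axhline(hi, color="k", ls="--", lw=1.0)
    if lo is not None:
        ax.axhline(lo, color="k", ls="--", lw=1.0)
    ax.set_xlabel("mean position (mm)")
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
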