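"""Inferential toolkit: pooled-shift bootstrap, Welch ANOVA, t-tests.

The workhorse is a two-sample bootstrap test of equal means for small
samples (Efron & Tibshirani's shifted-resampling scheme): both samples are
translated so each has the pooled mean — enforcing the null — then
resampled with replacement arm-by-arm, and the Welch t statistic of each
resample pair is compared with the observed one.  The p-value is the
fraction of resamples at least as extreme, at resolution 1/B, with no
continuity correction.

Welch's one-way ANOVA (the heteroscedasticity-robust W ratio, analogous to
F) and the pooled-variance Student t-test support the same comparisons at
the whole-trend and single-pair level.  ``significance_onset`` applies the
bootstrap per timepoint between two replicate series and reports the first
time the groups separate at level alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scistats

from .errors import DegenerateVarianceError

logger = logging.getLogger(__name__)

DEFAULT_B = 100_000
DEFAULT_ALPHA = 0.05
ALTERNATIVES = ("two-sided", "ge")
# cap on elements per resampling chunk, to bound memory at large B
_CHUNK_ELEMS = 10_000_000


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of the pooled-shift bootstrap test."""

    t_obs: float
    p: float
    B: int
    seed: int
    alternative: str
    n_degenerate: int = 0


@dataclass(frozen=True)
class AnovaResult:
    """Welch one-way ANOVA: W ratio with (df1, df2) and upper-tail p."""

    W: float
    df1: int
    df2: float
    p: float


@dataclass(frozen=True)
class OnsetResult:
    """Per-timepoint bootstrap p-values and the earliest significant time."""

    times_h: tuple[float, ...]
    p_values: tuple[float, ...]
    alpha: float
    onset_time_h: float | None


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"sample {name} needs >= 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def welch_t_statistic(x, y) -> float:
    """Welch t: (x̄ − ȳ) / sqrt(s²x/n + s²y/m), variances with n − 1.

    Each sample's own size appears in its variance term.  Raises
    :class:`DegenerateVarianceError` when both samples are constant.
    """
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise DegenerateVarianceError("both samples constant; t undefined")
    return float((xa.mean() - ya.mean()) / math.sqrt(vx / xa.size + vy / ya.size))


def bootstrap_p(
    x,
    y,
    B: int = DEFAULT_B,
    seed: int = 0,
    alternative: str = "two-sided",
) -> BootstrapResult:
    """Pooled-shift bootstrap test of equal means.

    Both samples are shifted to the pooled mean (x′i = xi − x̄ + z̄,
    y′i = yi − ȳ + z̄); each bootstrap replicate draws n values with
    replacement from x′ and m from y′ and computes the Welch t statistic.
    ``alternative`` is ``"two-sided"`` (default; counts |t*| >= |t_obs|) or
    ``"ge"`` (counts t* >= t_obs, the one-sided form).  Resamples in which
    both arms are constant leave t* undefined; they are excluded from the
    denominator and their count is logged and returned.

    Deterministic for a fixed seed: one generator per call, each
    replicate's x indices drawn before its y indices.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if B < 1:
        raise ValueError("B must be >= 1")
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    t_obs = welch_t_statistic(xa, ya)  # raises on degenerate observed data
    n, m = xa.size, ya.size
    zbar = np.concatenate([xa, ya]).mean()
    xs = xa - xa.mean() + zbar
    ys = ya - ya.mean() + zbar

    rng = np.random.default_rng(seed)
    hits = 0
    degenerate = 0
    chunk = max(1, _CHUNK_ELEMS // (n + m))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        bx = xs[rng.integers(0, n, size=(b, n))]
        by = ys[rng.integers(0, m, size=(b, m))]
        vx = bx.var(axis=1, ddof=1)
        vy = by.var(axis=1, ddof=1)
        valid = (vx > 0.0) | (vy > 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = (bx.mean(axis=1) - by.mean(axis=1)) / np.sqrt(vx / n + vy / m)
        if alternative == "two-sided":
            cond = np.abs(t_star) >= abs(t_obs)
        else:
            cond = t_star >= t_obs
        hits += int(np.count_nonzero(cond & valid))
        degenerate += int(b - np.count_nonzero(valid))
        done += b
    if degenerate:
        logger.info("excluded %d degenerate resamples of %d", degenerate, B)
    denom = B - degenerate
    if denom == 0:
        raise DegenerateVarianceError("every resample was degenerate")
    return BootstrapResult(
        t_obs=t_obs,
        p=hits / denom,
        B=B,
        seed=seed,
        alternative=alternative,
        n_degenerate=degenerate,
    )


def welch_anova(groups) -> AnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA (the W ratio).

    With group weights w_i = n_i / s_i² and weighted grand mean m_w:

        W = [Σ w_i (m_i − m_w)² / (k − 1)] /
            [1 + 2(k − 2)/(k² − 1) · Σ (1 − w_i/Σw)²/(n_i − 1)]

    df1 = k − 1; df2 = (k² − 1) / (3 Σ (1 − w_i/Σw)²/(n_i − 1)); the
    p-value is the F(df1, df2) upper tail.  For two groups W equals the
    Welch t statistic squared.  Any zero-variance group makes the weights
    undefined and raises :class:`DegenerateVarianceError`.
    """
    arrs = [_as_sample(g, f"group{i}") for i, g in enumerate(groups)]
    k = len(arrs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([a.size for a in arrs], dtype=float)
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    if np.any(variances == 0.0):
        raise DegenerateVarianceError(
            "zero within-group variance; Welch weights undefined"
        )
    w = ns / variances
    sw = w.sum()
    mw = float((w * means).sum() / sw)
    num = float((w * (means - mw) ** 2).sum() / (k - 1))
    lam = float((((1.0 - w / sw) ** 2) / (ns - 1.0)).sum())
    W = num / (1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam)
    df1 = k - 1
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(_scistats.f.sf(W, df1, df2))
    return AnovaResult(W=float(W), df1=df1, df2=float(df2), p=p)


def unpaired_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance Student t-test; returns (t, df, p), df = n + m − 2."""
    xa, ya = _as_sample(x, "x"), _as_sample(y, "y")
    if xa.var(ddof=1) == 0.0 and ya.var(ddof=1) == 0.0:
        raise DegenerateVarianceError("zero pooled variance; t undefined")
    res = _scistats.ttest_ind(xa, ya, equal_var=True)
    return float(res.statistic), int(xa.size + ya.size - 2), float(res.pvalue)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·sd/mean, as a percent to one decimal."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return round(100.0 * sd / mean, 1)


def significance_onset(
    times_h,
    replicates_a,
    replicates_b,
    alpha: float = DEFAULT_ALPHA,
    B: int = DEFAULT_B,
    seed: int = 0,
    alternative: str = "two-sided",
) -> OnsetResult:
    """First time two replicate series separate at level ``alpha``.

    ``replicates_a`` and ``replicates_b`` are (T, n_rep) arrays of
    per-timepoint replicate measurements on a shared time grid.  A
    bootstrap test runs per timepoint (seeds spawned deterministically from
    ``seed``); the onset is the earliest time with p < alpha, or None.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.atleast_2d(np.asarray(replicates_a, dtype=float))
    b = np.atleast_2d(np.asarray(replicates_b, dtype=float))
    if a.shape[0] != t.size or b.shape[0] != t.size:
        raise ValueError("replicate arrays must have one row per timepoint")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per timepoint")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    child_seeds = np.random.SeedSequence(seed).spawn(t.size)
    ps: list[float] = []
    onset: float | None = None
    for i in range(t.size):
        sub_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        try:
            res = bootstrap_p(a[i], b[i], B=B, seed=sub_seed, alternative=alternative)
            p = res.p
        except DegenerateVarianceError:
            # identical constant replicates: no evidence of separation
            p = 1.0
        ps.append(p)
        if onset is None and p < alpha:
            onset = float(t[i])
    return OnsetResult(
        times_h=tuple(float(v) for v in t),
        p_values=tuple(ps),
        alpha=alpha,
        onset_time_h=onset,
    )
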