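"""Distribution and scaling fits.

Three fits drive the scale-free part of the analysis:

* a **discrete power law** for the degree-distribution tail,
  p(k) = k^-gamma / zeta(gamma, xmin), fitted by maximum likelihood with
  the Hurwitz-zeta normalisation; the tail threshold xmin is chosen by
  minimising the Kolmogorov-Smirnov distance between the empirical and
  fitted tail CDFs, goodness of fit comes from a semiparametric
  bootstrap (the body is resampled empirically, the tail redrawn from
  the fitted model, and every replicate refitted in full), and the
  exponent CI from a nonparametric percentile bootstrap;
* **strength-degree scaling** s ~ k^beta by ordinary least squares of
  log s on log k, with the mean edge weight reported so the
  uncorrelated baseline s = w_bar * k can be drawn;
* a **betweenness-degree quadratic** b ~ c0 + c1 k + c2 k^2, with nodes
  beyond +/- ``flag_threshold`` internally studentised residuals flagged
  as structurally over- (high) or under-important (low).

All random streams are seeded; identical seeds give identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import DegenerateDataError, InsufficientDataError, InvalidParameterError

_GAMMA_LO = 1.000001
_GAMMA_HI = 25.0


@dataclass
class PowerLawFit:
    gamma: float
    xmin: int
    ks: float
    p_value: float | None
    ci_low: float | None
    ci_high: float | None
    n_tail: int
    b_gof: int
    b_ci: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScalingFit:
    beta: float
    intercept: float  # log-scale intercept (natural log)
    mean_weight: float
    r_squared: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OutlierReport:
    fit_coefficients: tuple[float, float, float]  # (c0, c1, c2)
    residual_sd: float
    flagged: list[tuple[str, float, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fit_coefficients": list(self.fit_coefficients),
            "residual_sd": self.residual_sd,
            "flagged": [
                {"node": n, "residual": r, "direction": d} for n, r, d in self.flagged
            ],
        }


# ---------------------------------------------------------------------------
# discrete power law


def _neg_loglik(gamma: float, xmin: int, n_tail: int, sum_log: float) -> float:
    return n_tail * np.log(zeta(gamma, xmin)) + gamma * sum_log


def _mle_gamma(xmin: int, n_tail: int, sum_log: float) -> float:
    res = minimize_scalar(
        _neg_loglik,
        bounds=(_GAMMA_LO, _GAMMA_HI),
        args=(xmin, n_tail, sum_log),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _ks_distance(tail_vals: np.ndarray, tail_counts: np.ndarray, xmin: int, gamma: float) -> float:
    """Sup distance between empirical and fitted tail CDFs at the observed
    support points (evaluated from both sides of each empirical step)."""
    n = tail_counts.sum()
    ecdf_hi = np.cumsum(tail_counts) / n  # P(X <= x)
    ecdf_lo = ecdf_hi - tail_counts / n  # P(X < x)
    z0 = zeta(gamma, xmin)
    model = 1.0 - zeta(gamma, tail_vals + 1) / z0
    model_lo = 1.0 - zeta(gamma, tail_vals) / z0
    return float(
        max(np.abs(ecdf_hi - model).max(), np.abs(ecdf_lo - model_lo).max())
    )


def _fit_once(
    samples: np.ndarray, xmin: int | str, min_tail: int
) -> tuple[float, int, float, int]:
    """One full fit (xmin scan + MLE). Returns (gamma, xmin, ks, n_tail)."""
    vals, counts = np.unique(samples, return_counts=True)
    n_ge = np.cumsum(counts[::-1])[::-1]  # n_ge[i] = #samples >= vals[i]
    logs = np.log(vals.astype(float))
    slog_ge = np.cumsum((counts * logs)[::-1])[::-1]

    if xmin == "auto":
        q90 = np.quantile(samples, 0.9)
        cand_idx = [
            i
            for i, v in enumerate(vals)
            if v <= q90 and n_ge[i] >= min_tail and vals[-1] > v
        ]
        if not cand_idx:
            raise InsufficientDataError(
                f"no xmin candidate leaves a tail of >= {min_tail} samples"
            )
    else:
        x0 = int(xmin)
        if x0 < 1:
            raise InvalidParameterError("xmin must be >= 1")
        idx = int(np.searchsorted(vals, x0))
        if idx >= len(vals) or n_ge[idx] < 2:
            raise InsufficientDataError("fewer than 2 samples at or above xmin")
        if idx == len(vals) - 1:
            raise DegenerateDataError("tail has zero variance (all values equal)")
        cand_idx = [idx]

    best = None
    for i in cand_idx:
        x0 = int(max(vals[i], 1)) if xmin == "auto" else int(xmin)
        tail_mask = vals >= x0
        tv = vals[tail_mask].astype(float)
        tc = counts[tail_mask]
        g = _mle_gamma(x0, int(tc.sum()), float((tc * np.log(tv)).sum()))
        ks = _ks_distance(tv, tc, x0, g)
        if best is None or ks < best[2]:
            best = (g, x0, ks, int(tc.sum()))
    return best


def sample_discrete_powerlaw(
    n: int, gamma: float, xmin: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw integers from the discrete power law by exact inverse-CDF.

    For each uniform u, returns the smallest x >= xmin with
    F(x) = 1 - zeta(gamma, x+1)/zeta(gamma, xmin) >= u, located by
    doubling then bisection on the exact CDF.
    """
    if n == 0:
        return np.empty(0, dtype=np.int64)
    u = rng.random(n)
    z0 = zeta(gamma, xmin)

    def cdf(x: np.ndarray) -> np.ndarray:
        return 1.0 - zeta(gamma, x.astype(float) + 1.0) / z0

    hi = np.full(n, xmin, dtype=np.int64)
    pending = cdf(hi) < u
    while pending.any():
        hi[pending] = np.minimum(hi[pending] * 2, 2**40)
        pending = cdf(hi) < u
        if (hi >= 2**40).all():
            break
    lo = np.full(n, xmin, dtype=np.int64)
    while (hi - lo).max() > 0:
        mid = (lo + hi) // 2
        ge = cdf(mid) >= u
        hi[ge] = mid[ge]
        lo[~ge] = mid[~ge] + 1
    return hi


def fit_discrete_powerlaw(
    samples,
    xmin: int | str = "auto",
    b_gof: int = 1000,
    b_ci: int = 1000,
    seed: int = 0,
    min_tail: int = 10,
) -> PowerLawFit:
    """Fit the tail of a positive-integer sample to a discrete power law.

    ``xmin='auto'`` scans every distinct sample value up to the 90th
    percentile (keeping at least ``min_tail`` tail observations) and
    picks the KS-minimising threshold.  ``b_gof``/``b_ci`` set the
    bootstrap replicate counts for the goodness-of-fit p-value and the
    95% percentile CI of gamma; either can be 0 to skip that stage.
    """
    samples = np.asarray(samples, dtype=np.int64)
    if samples.size < 2:
        raise InsufficientDataError("need at least 2 samples")
    if (samples < 1).any():
        raise InvalidParameterError("samples must be positive integers")
    if np.ptp(samples) == 0:
        raise DegenerateDataError("all samples identical; tail has zero variance")

    gamma, x0, ks, n_tail = _fit_once(samples, xmin, min_tail)
    root = np.random.SeedSequence(seed)

    p_value = None
    if b_gof > 0:
        below = samples[samples < x0]
        p_below = below.size / samples.size
        exceed = 0
        for b, ss in enumerate(root.spawn(b_gof)):
            rng = np.random.default_rng(ss)
            n_below = rng.binomial(samples.size, p_below)
            parts = []
            if n_below > 0:
                parts.append(rng.choice(below, size=n_below, replace=True))
            parts.append(
                sample_discrete_powerlaw(samples.size - n_below, gamma, x0, rng)
            )
            rep = np.concatenate(parts)
            try:
                _, _, ks_b, _ = _fit_once(rep, xmin, min_tail)
            except (DegenerateDataError, InsufficientDataError):
                continue
            if ks_b >= ks:
                exceed += 1
        p_value = exceed / b_gof

    ci_low = ci_high = None
    if b_ci > 0:
        ci_root = np.random.SeedSequence(seed, spawn_key=(1,))
        gammas = []
        for ss in ci_root.spawn(b_ci):
            rng = np.random.default_rng(ss)
            rep = rng.choice(samples, size=samples.size, replace=True)
            try:
                g_b, _, _, _ = _fit_once(rep, xmin, min_tail)
            except (DegenerateDataError, InsufficientDataError):
                continue
            gammas.append(g_b)
        if gammas:
            ci_low, ci_high = (
                float(np.percentile(gammas, 2.5)),
                float(np.percentile(gammas, 97.5)),
            )

    return PowerLawFit(
        gamma=gamma,
        xmin=x0,
        ks=ks,
        p_value=p_value,
        ci_low=ci_low,
        ci_high=ci_high,
        n_tail=n_tail,
        b_gof=b_gof,
        b_ci=b_ci,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# strength-degree scaling


def fit_strength_scaling(metrics: pd.DataFrame) -> ScalingFit:
    """OLS of log s on log k over nodes with k >= 1 and s >= 1.

    The uncorrelated baseline is s = w_bar * k with w_bar the mean
    undirected edge weight; from the node table, w_bar = sum(s)/sum(k)
    exactly (both sums count each undirected edge twice).
    """
    ok = metrics[(metrics["k"] >= 1) & (metrics["s"] >= 1)]
    if ok["k"].nunique() < 3:
        raise InsufficientDataError("need >= 3 distinct degree values")
    x = np.log(ok["k"].to_numpy(dtype=float))
    y = np.log(ok["s"].to_numpy(dtype=float))
    beta, intercept = np.polyfit(x, y, 1)
    resid = y - (beta * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return ScalingFit(
        beta=float(beta),
        intercept=float(intercept),
        mean_weight=float(ok["s"].sum() / ok["k"].sum()),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# betweenness-degree quadratic


def fit_betweenness_quadratic(
    metrics: pd.DataFrame, flag_threshold: float = 2.0
) -> OutlierReport:
    """Least-squares b ~ c0 + c1 k + c2 k^2 over nodes with b > 0.

    Nodes whose internally studentised residual exceeds the threshold in
    magnitude are flagged ``high`` (more central than their connectivity
    predicts) or ``low``.  An exact fit produces no flags.
    """
    if flag_threshold <= 0:
        raise InvalidParameterError("flag_threshold must be positive")
    ok = metrics[metrics["b"] > 0]
    if len(ok) < 4:
        raise InsufficientDataError("need >= 4 nodes with positive betweenness")
    b = ok["b"].to_numpy(dtype=float)
    if np.ptp(b) == 0:
        raise DegenerateDataError("betweenness has no variation")
    k = ok["k"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(k), k, k**2])
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    resid = b - X @ coef
    dof = len(b) - 3
    sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0

    flagged: list[tuple[str, float, str]] = []
    if sd > 1e-12:
        # leverage via the hat matrix of the quadratic design
        XtX_inv = np.linalg.pinv(X.T @ X)
        leverage = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        denom = sd * np.sqrt(np.clip(1.0 - leverage, 1e-12, None))
        student = resid / denom
        for node, t in zip(ok.index, student):
            if abs(t) > flag_threshold:
                flagged.append((str(node), float(t), "high" if t > 0 else "low"))
    return OutlierReport(
        fit_coefficients=(float(coef[0]), float(coef[1]), float(coef[2])),
        residual_sd=sd,
        flagged=flagged,
    )
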