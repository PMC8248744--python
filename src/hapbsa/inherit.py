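"""Mode-of-inheritance analysis from dose-response bioassays.

Mortality against log10 concentration is fitted by maximum-likelihood
binomial regression with a probit link; the LC50 is the concentration at
which predicted mortality is 0.5, with a delta-method 95% confidence
interval.  The degree of dominance of resistance is Stone's

    D = (2 log LC50_F1 - log LC50_R - log LC50_S) / (log LC50_R - log LC50_S)

ranging from -1 (fully recessive) to +1 (fully dominant).  Under a
one-locus recessive model, backcross progeny are an equal mixture of
F1-like and resistant-parent-like genotypes, so their expected mortality at
a dose is c = 0.5 W(F1) + 0.5 W(R); a chi-square goodness-of-fit against
the observed backcross kill tests the monogenic hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

__all__ = [
    "ProbitFit",
    "DominanceResult",
    "MonogenicExpectation",
    "probit_fit",
    "degree_of_dominance",
    "monogenic_test",
    "classify_inheritance",
]


@dataclass
class ProbitFit:
    """Probit regression of mortality on log10 dose."""

    intercept: float
    slope: float
    lc50: float
    lc50_ci: tuple[float, float]
    cov: np.ndarray  # covariance of (intercept, slope)
    n_doses: int

    def predict(self, dose: float | np.ndarray) -> np.ndarray:
        return norm.cdf(self.intercept + self.slope * np.log10(dose))


def probit_fit(data: pd.DataFrame, abbott_correction: bool = False) -> ProbitFit:
    """Fit a probit dose-response curve.

    ``data`` needs columns ``dose`` (mg/L, > 0), ``n`` and ``dead``.
    Control (dose 0) rows are used only for the optional Abbott correction
    of control mortality (off by default) and excluded from the fit.
    ``pre``: at least 3 positive-dose points, at least one with partial
    kill; all-0% or all-100% mortality is complete separation and is
    rejected.
    """
    d = data.copy()
    control = d[d["dose"] == 0]
    d = d[d["dose"] > 0]
    if (d["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if len(d) < 3:
        raise ValueError("need at least 3 positive doses")
    if ((d["dead"] < 0) | (d["dead"] > d["n"])).any():
        raise ValueError("require 0 <= dead <= n")
    dead = d["dead"].to_numpy(dtype=float)
    n = d["n"].to_numpy(dtype=float)
    if abbott_correction and len(control):
        c = control["dead"].sum() / control["n"].sum()
        dead = np.clip((dead / n - c) / (1 - c), 0.0, 1.0) * n
    if np.all(dead == 0) or np.all(dead == n):
        raise ValueError("no partial kill: mortality is 0% or 100% at every dose")

    x = sm.add_constant(np.log10(d["dose"].to_numpy(dtype=float)))
    y = np.column_stack([dead, n - dead])
    model = sm.GLM(y, x, family=sm.families.Binomial(link=sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-kill endpoints trigger benign warnings
        res = model.fit()
    alpha, beta = res.params
    if beta <= 0:
        raise ValueError("fitted slope is non-positive; mortality must increase with dose")
    cov = np.asarray(res.cov_params())
    # delta method on log10 LC50 = -alpha / beta
    log_lc50 = -alpha / beta
    grad = np.array([-1.0 / beta, alpha / beta**2])
    se = float(np.sqrt(grad @ cov @ grad))
    ci = (10 ** (log_lc50 - 1.959964 * se), 10 ** (log_lc50 + 1.959964 * se))
    return ProbitFit(
        intercept=float(alpha),
        slope=float(beta),
        lc50=float(10**log_lc50),
        lc50_ci=ci,
        cov=cov,
        n_doses=len(d),
    )


@dataclass
class DominanceResult:
    """Stone's degree of dominance, clipped to [-1, 1] with a flag."""

    d: float
    clipped: bool

    @property
    def label(self) -> str:
        if self.d <= -0.999:
            return "fully recessive"
        if self.d < 0:
            return "incompletely recessive"
        if self.d == 0:
            return "semi-dominant"
        if self.d < 0.999:
            return "incompletely dominant"
        return "fully dominant"


def degree_of_dominance(lc50_r: float, lc50_s: float, lc50_f1: float) -> DominanceResult:
    """Stone's D from the three LC50s (base-10 logs).

    D = +1 when the F1 responds like the resistant parent, -1 like the
    susceptible parent, 0 at the geometric mean.  Invariant to a common
    rescaling of all three concentrations.
    """
    if min(lc50_r, lc50_s, lc50_f1) <= 0:
        raise ValueError("LC50s must be positive")
    if lc50_r == lc50_s:
        raise ValueError("parental LC50s are equal; dominance is undefined")
    lr, ls, lf = np.log10(lc50_r), np.log10(lc50_s), np.log10(lc50_f1)
    d = (2 * lf - lr - ls) / (lr - ls)
    clipped = not (-1.0 <= d <= 1.0)
    return DominanceResult(d=float(np.clip(d, -1.0, 1.0)), clipped=clipped)


@dataclass
class MonogenicExpectation:
    """Expected backcross response under one-locus recessive resistance and
    the goodness-of-fit of the observed kill."""

    expected: pd.DataFrame  # dose, c (expected mortality), n, dead
    chi2: float
    df: int
    p_value: float


def monogenic_test(
    w_f1: dict[float, float], w_r: dict[float, float], backcross: pd.DataFrame
) -> MonogenicExpectation:
    """Test the monogenic-recessive hypothesis on backcross mortality.

    ``w_f1`` and ``w_r`` map dose -> observed parental mortality; the
    expected backcross mortality is c = 0.5 W(F1) + 0.5 W(R) per dose.
    The chi-square statistic sums (obs - exp)^2 / exp over the dead and
    alive cells of every dose, with df = number of doses (no parameter is
    estimated from the backcross data); doses with degenerate expectation
    (c of exactly 0 or 1) are excluded with a warning.
    """
    rows = []
    stat = 0.0
    used = 0
    for _, row in backcross.iterrows():
        dose = float(row["dose"])
        if dose not in w_f1 or dose not in w_r:
            raise ValueError(f"dose {dose} missing from a parental response table")
        c = 0.5 * w_f1[dose] + 0.5 * w_r[dose]
        n, dead = float(row["n"]), float(row["dead"])
        rows.append((dose, c, n, dead))
        if c in (0.0, 1.0):
            warnings.warn(
                f"dose {dose}: expected mortality is exactly {c}; cell excluded from chi-square",
                stacklevel=2,
            )
            continue
        stat += (dead - n * c) ** 2 / (n * c) + ((n - dead) - n * (1 - c)) ** 2 / (n * (1 - c))
        used += 1
    if used == 0:
        raise ValueError("no dose with a non-degenerate expectation")
    return MonogenicExpectation(
        expected=pd.DataFrame(rows, columns=["dose", "c", "n", "dead"]),
        chi2=float(stat),
        df=used,
        p_value=float(chi2.sf(stat, used)),
    )


def classify_inheritance(
    fit_r: ProbitFit,
    fit_s: ProbitFit,
    fit_f1_rm: ProbitFit,
    fit_f1_sm: ProbitFit,
) -> dict:
    """Summarize mode of inheritance from parental and reciprocal-F1 fits.

    A maternal effect is flagged when the 95% LC50 confidence intervals of
    the reciprocal F1s (resistant-mother vs susceptible-mother) are
    disjoint.  The degree of dominance is computed from the pooled F1 LC50
    (geometric mean of the reciprocals).
    """
    lo_a, hi_a = fit_f1_rm.lc50_ci
    lo_b, hi_b = fit_f1_sm.lc50_ci
    maternal = hi_a < lo_b or hi_b < lo_a
    pooled_f1 = float(np.sqrt(fit_f1_rm.lc50 * fit_f1_sm.lc50))
    dom = degree_of_dominance(fit_r.lc50, fit_s.lc50, pooled_f1)
    return {
        "maternal_effect": bool(maternal),
        "lc50_r": fit_r.lc50,
        "lc50_s": fit_s.lc50,
        "lc50_f1_pooled": pooled_f1,
        "dominance": dom.d,
        "dominance_label": dom.label,
    }
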