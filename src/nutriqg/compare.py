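"""Comparing nutritional response surfaces between groups.

Two complementary tools:

* a sequential model-building procedure that tests, tier by tier, whether the
  linear, quadratic and correlational nutritional gradients differ between two
  groups (partial F-tests on nested dummy-coded models), and
* the angle theta between two linear nutritional-gradient vectors,

    theta = arccos( a . b / (|a| |b|) ),

  with a Bayesian 95% highest-posterior-density interval obtained by pairing
  posterior draws of the two gradient vectors from conjugate Gibbs chains.

The sequential procedure pools the two groups (each already z-standardized
within group) and fits nested models with a group main effect always present:
tier 1 adds group-specific linear slopes (df1 = 2), tier 2 — given
group-specific linear terms — group-specific quadratic terms (df1 = 2), and
tier 3 group-specific correlational P x C terms (df1 = 1).  Each tier's
partial F is ((SS_R - SS_C)/df1) / (SS_C/df2) with df2 the complete-model
residual df, and significant tiers are followed up per nutrient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import StandardizedTable
from .mcmc import McmcSettings, hpd_interval

TIERS = ("linear", "quadratic", "correlational")


def partial_f(ss_r: float, ss_c: float, df1: int, df2: int) -> tuple[float, float]:
    """Partial F comparing a reduced model (residual SS ``ss_r``) to a
    complete model (``ss_c``), with the upper-tail p from F(df1, df2)."""
    if not (ss_r >= ss_c >= 0):
        raise ValueError(f"need ss_r >= ss_c >= 0, got {ss_r}, {ss_c}")
    if df1 < 1 or df2 < 1:
        raise ValueError("df1 and df2 must be >= 1")
    if ss_c == 0:
        if ss_r == 0:
            return 0.0, 1.0
        warnings.warn("complete model has zero residual SS; F is infinite")
        return float("inf"), 0.0
    f = ((ss_r - ss_c) / df1) / (ss_c / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def vector_angle(a, b) -> float:
    """Angle in degrees between two 2-vectors of linear gradients.

    0 deg means the two traits' optima lie in the same direction of nutrient
    space; 180 deg is maximal divergence.  Symmetric and invariant to positive
    rescaling of either vector.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero gradient vector")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# sequential model building


@dataclass
class SequentialComparison:
    """Per-tier partial-F table for a two-group surface comparison."""

    group_a: str
    group_b: str
    trait: str
    n: int
    tiers: dict[str, dict]  # tier -> {ss_r, ss_c, df1, df2, F, p, followups}

    def table(self) -> pd.DataFrame:
        rows = []
        for tier in TIERS:
            t = self.tiers[tier]
            rows.append({"trait": self.trait, "tier": tier,
                         "ss_r": t["ss_r"], "ss_c": t["ss_c"],
                         "df1": t["df1"], "df2": t["df2"],
                         "F": t["F"], "p": t["p"]})
        return pd.DataFrame(rows)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def sequential_f_tests(
    data_a: pd.DataFrame | StandardizedTable,
    data_b: pd.DataFrame | StandardizedTable,
    trait: str,
    labels: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> SequentialComparison:
    """Sequential partial-F comparison of two nutritional response surfaces.

    Both inputs must already be on the z-scale (standardized within group);
    they are pooled with a group indicator, and nested models are compared
    tier by tier.  When a tier is significant at ``alpha``, single-df
    follow-up tests per nutrient are attached under ``followups``.
    """
    da = data_a.data if isinstance(data_a, StandardizedTable) else data_a
    db = data_b.data if isinstance(data_b, StandardizedTable) else data_b
    cols = ["p_intake", "c_intake", trait]
    da = da[cols].dropna()
    db = db[cols].dropna()
    if len(da) < 7 or len(db) < 7:
        raise ValueError("each group needs at least 7 complete rows")
    if len(da) == len(db) and np.allclose(da.to_numpy(), db.to_numpy()):
        raise ValueError("the two groups have identical membership")

    P = np.concatenate([da["p_intake"], db["p_intake"]])
    C = np.concatenate([da["c_intake"], db["c_intake"]])
    y = np.concatenate([da[trait], db[trait]])
    g = np.concatenate([np.zeros(len(da)), np.ones(len(db))])
    n = len(y)
    one = np.ones(n)

    # named column blocks, in nesting order
    cols_by_name = {
        "1": one, "g": g, "P": P, "C": C,
        "gP": g * P, "gC": g * C,
        "PP": P * P, "CC": C * C,
        "gPP": g * P * P, "gCC": g * C * C,
        "PC": P * C, "gPC": g * P * C,
    }

    def rss(names):
        return _rss(np.column_stack([cols_by_name[nm] for nm in names]), y)

    tiers: dict[str, dict] = {}

    base = ["1", "g", "P", "C"]
    specs = [
        ("linear", base, ["gP", "gC"], {"P": "gP", "C": "gC"}),
        ("quadratic", base + ["gP", "gC", "PP", "CC"], ["gPP", "gCC"],
         {"PxP": "gPP", "CxC": "gCC"}),
        ("correlational",
         base + ["gP", "gC", "PP", "CC", "gPP", "gCC", "PC"], ["gPC"],
         {"PxC": "gPC"}),
    ]
    for tier, reduced_names, added, follow_terms in specs:
        complete_names = reduced_names + added
        ss_r = rss(reduced_names)
        ss_c = min(rss(complete_names), ss_r)  # guard float noise in lstsq
        df1 = len(added)
        df2 = n - len(complete_names)
        F, p = partial_f(ss_r, ss_c, df1, df2)
        entry = {"ss_r": ss_r, "ss_c": ss_c, "df1": df1, "df2": df2,
                 "F": F, "p": p, "followups": {}}
        if p < alpha and df1 > 1:
            for term, drop_name in follow_terms.items():
                ss_rr = max(rss([nm for nm in complete_names if nm != drop_name]),
                            ss_c)
                Ft, pt = partial_f(ss_rr, ss_c, 1, df2)
                entry["followups"][term] = {"F": Ft, "p": pt}
        tiers[tier] = entry

    return SequentialComparison(group_a=labels[0], group_b=labels[1],
                                trait=trait, n=n, tiers=tiers)


# ---------------------------------------------------------------------------
# Bayesian angle posterior


class BayesianGradientSampler(BaseEstimator):
    """Conjugate Gibbs sampler for the linear nutritional-gradient model
    ``trait = beta_P * P + beta_C * C + eps`` on z-standardized data.

    The coefficient prior is flat; the residual variance carries a scaled
    inverse-chi-square prior parameterized by ``settings.prior_v`` and
    ``settings.prior_nu``.  Updates alternate

        beta   | sigma2 ~ N(beta_hat, sigma2 * (X'X)^-1)
        sigma2 | beta   ~ Inv-Gamma((nu + n)/2, (nu V + RSS(beta))/2)

    Attributes
    ----------
    coef_draws_ : (n_draws, 2) retained posterior draws of (beta_P, beta_C)
    sigma2_draws_ : (n_draws,) retained residual-variance draws
    coef_hat_ : least-squares point estimate
    """

    def __init__(self, settings: McmcSettings = McmcSettings()):
        self.settings = settings

    def fit(self, X, y):
        s = self.settings
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta_hat = xtx_inv @ X.T @ y
        rss_min = float(np.sum((y - X @ beta_hat) ** 2))
        L = np.linalg.cholesky(xtx_inv)

        rng = np.random.default_rng(s.seed)
        niter = s.iterations
        z = rng.standard_normal((niter, k))
        znorm2 = np.einsum("ij,ij->i", z, z)
        shape = (s.prior_nu + n) / 2.0
        gam = rng.gamma(shape, 1.0, size=niter)
        nu_v = s.prior_nu * s.prior_v

        # sigma2 recursion: beta_t = beta_hat + sigma_{t-1} L z_t, and
        # (beta_t - beta_hat)' X'X (beta_t - beta_hat) = sigma2_{t-1} |z_t|^2
        sigma2 = np.empty(niter)
        s2 = rss_min / max(n - k, 1)  # start at the REML-ish point
        s2_prev = np.empty(niter)
        for t in range(niter):
            s2_prev[t] = s2
            quad = s2 * znorm2[t]
            scale = (nu_v + rss_min + quad) / 2.0
            s2 = scale / gam[t]
            sigma2[t] = s2

        keep = s.retained_indices()
        if len(keep) < 100:
            raise ValueError(
                f"only {len(keep)} retained draws; need at least 100 for a "
                "stable HPD interval"
            )
        sig_prev = np.sqrt(s2_prev[keep])
        self.coef_draws_ = beta_hat + sig_prev[:, None] * (z[keep] @ L.T)
        self.sigma2_draws_ = sigma2[keep]
        self.coef_hat_ = beta_hat
        self.n_ = n
        return self


@dataclass
class AngleEstimate:
    """Plug-in and posterior summaries of the gradient-vector angle."""

    theta_plugin: float
    theta_posterior_mean: float
    hpd95: tuple[float, float]
    n_draws: int
    theta_draws: np.ndarray = field(repr=False, default=None)


def angle_posterior(
    data_a: pd.DataFrame | StandardizedTable,
    data_b: pd.DataFrame | StandardizedTable,
    trait: str | tuple[str, str],
    settings: McmcSettings = McmcSettings(),
) -> AngleEstimate:
    """Posterior of the angle between two groups' linear gradient vectors.

    Each group's ``trait = beta_P P + beta_C C + eps`` model is sampled by an
    independent conjugate Gibbs chain (seeds derived from ``settings.seed``);
    theta is computed per paired draw and summarized by its posterior mean
    and the 95% shortest (HPD) interval.  Pass a pair of trait names to
    compare two traits within the same table instead of one trait across two
    tables.
    """
    trait_a, trait_b = (trait, trait) if isinstance(trait, str) else trait
    da = data_a.data if isinstance(data_a, StandardizedTable) else data_a
    db = data_b.data if isinstance(data_b, StandardizedTable) else data_b
    da = da[["p_intake", "c_intake", trait_a]].dropna()
    db = db[["p_intake", "c_intake", trait_b]].dropna()

    sampler_a = BayesianGradientSampler(
        settings=McmcSettings(**{**settings.__dict__, "seed": settings.seed * 2 + 1})
    ).fit(da[["p_intake", "c_intake"]].to_numpy(), da[trait_a].to_numpy())
    sampler_b = BayesianGradientSampler(
        settings=McmcSettings(**{**settings.__dict__, "seed": settings.seed * 2 + 2})
    ).fit(db[["p_intake", "c_intake"]].to_numpy(), db[trait_b].to_numpy())

    A = sampler_a.coef_draws_
    B = sampler_b.coef_draws_
    dots = np.einsum("ij,ij->i", A, B)
    cosang = np.clip(
        dots / (np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)), -1, 1
    )
    theta = np.degrees(np.arccos(cosang))
    lo, hi = hpd_interval(theta, 0.95)
    return AngleEstimate(
        theta_plugin=vector_angle(sampler_a.coef_hat_, sampler_b.coef_hat_),
        theta_posterior_mean=float(theta.mean()),
        hpd95=(lo, hi),
        n_draws=len(theta),
        theta_draws=theta,
    )
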