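"""Multivariate sex-limited pedigree animal model for nutrient regulation.

The regulated intake of protein and carbohydrate is treated as four traits —
(Pm, Cm, Pf, Cf) — of which each individual expresses only its own sex's two.
Breeding values for all four traits are propagated through the pedigree via
the numerator relationship matrix A, so the between-sex additive covariance
block B is identified from cross-sex relatives (e.g. brothers vs sisters)
even though no individual expresses both sexes' traits.

Model, for individual i of sex s with phenotype vector y_i (2 traits):

    y_i = mu_s + Z_s a_i + e_i,   a ~ N(0, A (x) G),   e_i ~ N(0, R_s)

with G the 4x4 additive covariance, R_m and R_f 2x2 sex-specific residual
blocks (cross-sex residual covariances are structurally zero: they are
inestimable when the sexes never share an individual), and Z_s picking the
sex's two traits.  Estimation is by Gibbs sampling: single-site blocked
updates of each individual's 4-trait breeding value (using the sparse A
inverse), conjugate normal updates of the trait means, and inverse-Wishart
updates of G and the residual blocks.  The prior on G is inverse-Wishart
with scale ``prior_nu * prior_v * I`` and ``prior_nu`` degrees of freedom;
the residual prior mirrors it on each 2x2 block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy import stats

from .data_model import PedigreeEntry, StandardizedTable, check_pedigree
from .mcmc import McmcSettings, hpd_interval, summarize_draws

TRAIT_ORDER = ("Pm", "Cm", "Pf", "Cf")


# ---------------------------------------------------------------------------
# numerator relationship matrix


@dataclass
class AMatrixFactors:
    """Pedigree-ordered individuals plus the sparse inverse of the numerator
    relationship matrix A (Henderson's rules, non-inbred founders)."""

    ids: list[str]
    index: dict[str, int]
    a_inverse: sparse.csr_matrix

    @property
    def n(self) -> int:
        return len(self.ids)

    def a_dense(self) -> np.ndarray:
        """Dense A by inverting A^-1 (small pedigrees only; for checks)."""
        return np.linalg.inv(self.a_inverse.toarray())


def _canonical_order(entries: Sequence[PedigreeEntry]) -> list[PedigreeEntry]:
    """Founders-first order that is invariant to input row permutation:
    sort by (pedigree depth, individual id)."""
    ordered = check_pedigree(entries)
    by_id = {e.individual_id: e for e in ordered}
    depth: dict[str, int] = {}
    for e in ordered:  # topological, so parents are already assigned
        d = 0
        for p in (e.sire_id, e.dam_id):
            if p is not None:
                d = max(d, depth[p] + 1)
        depth[e.individual_id] = d
    return sorted(ordered, key=lambda e: (depth[e.individual_id], e.individual_id))


def build_a_inverse(pedigree: Sequence[PedigreeEntry]) -> AMatrixFactors:
    """Sparse A^-1 by Henderson's rules, assuming non-inbred known parents.

    Per individual with both parents known the Mendelian-sampling variance
    is 1/2, with one parent 3/4, with none 1.  Raises on pedigree cycles or
    parent ids that do not resolve.
    """
    ordered = _canonical_order(pedigree)
    index = {e.individual_id: k for k, e in enumerate(ordered)}
    n = len(ordered)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for e in ordered:
        i = index[e.individual_id]
        s = index[e.sire_id] if e.sire_id is not None else None
        d = index[e.dam_id] if e.dam_id is not None else None
        n_known = (s is not None) + (d is not None)
        alpha = {0: 1.0, 1: 4.0 / 3.0, 2: 2.0}[n_known]
        add(i, i, alpha)
        for p in (s, d):
            if p is not None:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, d):
            for q in (s, d):
                if p is not None and q is not None:
                    add(p, q, alpha / 4.0)

    a_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    a_inv.sum_duplicates()
    return AMatrixFactors(ids=[e.individual_id for e in ordered],
                          index=index, a_inverse=a_inv)


# ---------------------------------------------------------------------------
# Gibbs kernel


@njit(cache=True)
def _update_breeding_values(indptr, indices, ainv_data, a, y, sexcode,
                            has_pheno, mu, g_inv, rinv_m, rinv_f, noise):
    """One sweep of single-site blocked updates of 4-trait breeding values.

    ``noise`` is an (n, 4) array of standard normals drawn outside the
    kernel so all randomness flows from one seeded generator.
    """
    n = a.shape[0]
    for i in range(n):
        dii = 0.0
        ssum = np.zeros(4)
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            v = ainv_data[ptr]
            if j == i:
                dii = v
            else:
                for t in range(4):
                    ssum[t] += v * a[j, t]
        prec = dii * g_inv
        b = -g_inv @ ssum
        if has_pheno[i]:
            if sexcode[i] == 0:
                r0, rinv = 0, rinv_m
            else:
                r0, rinv = 2, rinv_f
            e0 = y[i, 0] - mu[r0]
            e1 = y[i, 1] - mu[r0 + 1]
            for t1 in range(2):
                for t2 in range(2):
                    prec[r0 + t1, r0 + t2] += rinv[t1, t2]
                b[r0 + t1] += rinv[t1, 0] * e0 + rinv[t1, 1] * e1
        chol = np.linalg.cholesky(prec)
        w = np.linalg.solve(chol, b)
        mean = np.linalg.solve(chol.T, w)
        dev = np.linalg.solve(chol.T, noise[i])
        for t in range(4):
            a[i, t] = mean[t] + dev[t]


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    tau = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class GMatrixPosterior:
    """Posterior draws of the partitioned 4x4 G matrix and residual blocks.

    ``g_draws`` has shape (n_draws, 4, 4) in trait order (Pm, Cm, Pf, Cf);
    ``r_m_draws`` / ``r_f_draws`` are the sex-specific 2x2 residual draws.
    """

    g_draws: np.ndarray
    r_m_draws: np.ndarray
    r_f_draws: np.ndarray
    trait_order: tuple = TRAIT_ORDER
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.g_draws.shape[0]

    @property
    def gm_draws(self) -> np.ndarray:
        return self.g_draws[:, :2, :2]

    @property
    def gf_draws(self) -> np.ndarray:
        return self.g_draws[:, 2:, 2:]

    @property
    def b_draws(self) -> np.ndarray:
        """Between-sex covariance block; rows male traits, columns female."""
        return self.g_draws[:, :2, 2:]

    def h2_draws(self) -> np.ndarray:
        """Per-draw heritabilities Va/(Va+Ve) per trait (n_draws, 4)."""
        va = np.diagonal(self.g_draws, axis1=1, axis2=2)
        ve = np.concatenate(
            [np.diagonal(self.r_m_draws, axis1=1, axis2=2),
             np.diagonal(self.r_f_draws, axis1=1, axis2=2)], axis=1)
        return va / (va + ve)

    def posterior_mean_g(self) -> np.ndarray:
        return self.g_draws.mean(axis=0)

    def posterior_sd_g(self) -> np.ndarray:
        return self.g_draws.std(axis=0, ddof=1)

    def summary(self) -> pd.DataFrame:
        """Posterior mean and 95% HPD per unique G entry."""
        rows = []
        for i in range(4):
            for j in range(i, 4):
                d = self.g_draws[:, i, j]
                lo, hi = hpd_interval(d)
                rows.append({"entry": f"{TRAIT_ORDER[i]}:{TRAIT_ORDER[j]}",
                             "mean": d.mean(), "hpd_lo": lo, "hpd_hi": hi})
        return pd.DataFrame(rows)


def genetic_correlations(posterior: GMatrixPosterior) -> dict:
    """Per-draw and summarized genetic correlations from a G posterior.

    Returns r_M and r_F (within-sex P-C correlations) and r_MF for each
    nutrient (between-sex correlation of the same trait).  Draws with a zero
    variance are excluded; the exclusion count is reported.
    """
    if posterior.n_draws == 0:
        raise ValueError("empty posterior")
    g = posterior.g_draws
    pairs = {"r_M": (0, 1), "r_F": (2, 3), "r_MF_P": (0, 2), "r_MF_C": (1, 3)}
    out: dict = {"n_excluded": 0}
    var = np.diagonal(g, axis1=1, axis2=2)
    ok = np.all(var > 0, axis=1)
    out["n_excluded"] = int((~ok).sum())
    gok = g[ok]
    vok = var[ok]
    for name, (i, j) in pairs.items():
        r = gok[:, i, j] / np.sqrt(vok[:, i] * vok[:, j])
        out[name] = {"draws": r, **summarize_draws(r)}
    return out


# ---------------------------------------------------------------------------
# the sampler


class AnimalModelGibbs:
    """Gibbs sampler for the 4-trait sex-limited pedigree animal model.

    Parameters
    ----------
    settings:
        Chain length, thinning and the inverse-Wishart prior (``prior_v``
        scales the identity prior scale for both G and the residual blocks;
        ``prior_nu`` is the prior df).  Defaults are a test-scale chain;
        publication-scale settings are available via
        :data:`nutriqg.mcmc.ANIMAL_PUBLISHED_SETTINGS`.
    fit_diet_pair:
        If True, include diet pair (the ``design_cell`` column) as a fixed
        effect.  Off by default so the genetic parameters describe regulated
        intake across diet pairs.

    Attributes
    ----------
    posterior_ : :class:`GMatrixPosterior` with retained draws
    mu_draws_ : (n_draws, 4) fixed-effect (trait mean) draws
    ess_ : effective sample sizes of the four genetic variances
    """

    def __init__(self, settings: McmcSettings = McmcSettings(),
                 fit_diet_pair: bool = False):
        self.settings = settings
        self.fit_diet_pair = fit_diet_pair

    def get_params(self, deep: bool = True) -> dict:
        return {"settings": self.settings, "fit_diet_pair": self.fit_diet_pair}

    def set_params(self, **params) -> "AnimalModelGibbs":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame | StandardizedTable,
            pedigree: Sequence[PedigreeEntry]) -> "AnimalModelGibbs":
        s = self.settings
        df = data.data if isinstance(data, StandardizedTable) else data
        factors = build_a_inverse(pedigree)
        n = factors.n

        missing = set(df["individual_id"].astype(str)) - set(factors.ids)
        if missing:
            raise ValueError(
                f"phenotyped individuals absent from the pedigree: "
                f"{sorted(missing)[:5]}"
            )
        sex_by_id = {e.individual_id: e.sex for e in pedigree}

        y = np.full((n, 2), np.nan)
        sexcode = np.zeros(n, dtype=np.int64)
        has_pheno = np.zeros(n, dtype=np.bool_)
        # deterministic row order: sort phenotypes by individual id
        df = df.sort_values("individual_id", kind="mergesort")
        for _, row in df.iterrows():
            iid = str(row["individual_id"])
            i = factors.index[iid]
            if row["sex"] != sex_by_id[iid]:
                raise ValueError(f"sex mismatch for individual {iid!r}")
            y[i, 0] = row["p_intake"]
            y[i, 1] = row["c_intake"]
            has_pheno[i] = True
        for e in pedigree:
            sexcode[factors.index[e.individual_id]] = 0 if e.sex == "male" else 1
        if np.isnan(y[has_pheno]).any():
            raise ValueError("phenotyped individuals must have both intakes")

        idx_m = np.where(has_pheno & (sexcode == 0))[0]
        idx_f = np.where(has_pheno & (sexcode == 1))[0]
        n_m, n_f = len(idx_m), len(idx_f)
        if n_m == 0 or n_f == 0:
            raise ValueError("both sexes must contribute phenotyped records")

        ainv = factors.a_inverse
        indptr = ainv.indptr.astype(np.int64)
        indices = ainv.indices.astype(np.int64)
        ainv_data = ainv.data.astype(np.float64)

        rng = np.random.default_rng(s.seed)
        nu, v0 = s.prior_nu, s.prior_v

        # initial state
        G = np.eye(4) * 0.3
        R_m = np.eye(2) * 0.7
        R_f = np.eye(2) * 0.7
        mu = np.zeros(4)
        mu[0:2] = np.nanmean(y[idx_m], axis=0)
        mu[2:4] = np.nanmean(y[idx_f], axis=0)
        a = np.zeros((n, 4))

        keep = set(s.retained_indices().tolist())
        g_draws = np.empty((s.n_draws, 4, 4))
        rm_draws = np.empty((s.n_draws, 2, 2))
        rf_draws = np.empty((s.n_draws, 2, 2))
        mu_draws = np.empty((s.n_draws, 4))
        k = 0

        for it in range(s.iterations):
            g_inv = np.linalg.inv(G)
            rinv_m = np.linalg.inv(R_m)
            rinv_f = np.linalg.inv(R_f)

            noise = rng.standard_normal((n, 4))
            _update_breeding_values(indptr, indices, ainv_data, a, y, sexcode,
                                    has_pheno, mu, g_inv, rinv_m, rinv_f, noise)

            # trait means (flat prior, conjugate normal per sex)
            for r0, idx, R in ((0, idx_m, R_m), (2, idx_f, R_f)):
                resid = y[idx] - a[idx][:, r0:r0 + 2]
                mbar = resid.mean(axis=0)
                chol = np.linalg.cholesky(R / len(idx))
                mu[r0:r0 + 2] = mbar + chol @ rng.standard_normal(2)

            # additive covariance: IW(nu*V + a' A^-1 a, nu + n)
            S = a.T @ (ainv @ a)
            scale_g = nu * v0 * np.eye(4) + S
            G = stats.invwishart.rvs(df=nu + n, scale=scale_g, random_state=rng)

            # residual blocks per sex
            for r0, idx in ((0, idx_m), (2, idx_f)):
                e = y[idx] - mu[r0:r0 + 2] - a[idx][:, r0:r0 + 2]
                scale_r = nu * v0 * np.eye(2) + e.T @ e
                R = stats.invwishart.rvs(df=nu + len(idx), scale=scale_r,
                                         random_state=rng)
                if r0 == 0:
                    R_m = R
                else:
                    R_f = R

            if it in keep:
                g_draws[k] = G
                rm_draws[k] = R_m
                rf_draws[k] = R_f
                mu_draws[k] = mu
                k += 1

        posterior = GMatrixPosterior(g_draws=g_draws[:k], r_m_draws=rm_draws[:k],
                                     r_f_draws=rf_draws[:k])
        self.ess_ = np.array([_ess(g_draws[:k, t, t]) for t in range(4)])
        if np.any(self.ess_ < 50):
            msg = ("low effective sample size on a genetic variance "
                   f"(ESS = {np.round(self.ess_, 1).tolist()}); "
                   "lengthen the chain")
            posterior.warnings_.append(msg)
            warnings.warn(msg)
        self.posterior_ = posterior
        self.mu_draws_ = mu_draws[:k]
        self.factors_ = factors
        return self


def fit_animal_model(
    data: pd.DataFrame | StandardizedTable,
    pedigree: Sequence[PedigreeEntry],
    settings: McmcSettings = McmcSettings(),
) -> GMatrixPosterior:
    """Fit the sex-limited animal model and return the G-matrix posterior."""
    return AnimalModelGibbs(settings=settings).fit(data, pedigree).posterior_
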