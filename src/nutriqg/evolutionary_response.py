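"""Predicted evolutionary response of nutrient regulation and the genetic
constraint imposed (or not) by the between-sex covariance block B.

Under equal autosomal inheritance the multivariate breeder's equation for a
trait expressed in both sexes is

    dz = 1/2 G beta

with G the 4x4 additive covariance in trait order (Pm, Cm, Pf, Cf) and beta
the stacked (male, female) linear nutritional gradients.  Setting the
between-sex block B of G to zero gives the counterfactual response dz_B0 of
sexes evolving independently; the constraint ratio

    R = dz / dz_B0   (elementwise)

reads > 1 as B accelerating the response, < 1 as constraining it, and 1 as
neutral.  Posterior uncertainty is propagated per draw: one G draw and one
beta draw enter the equation together, and the per-draw ratios are then
summarized — the posterior mean of a ratio is *not* the ratio of posterior
means, and the per-draw route is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal_model import GMatrixPosterior, TRAIT_ORDER
from .mcmc import hpd_interval

#: below this magnitude a counterfactual response is treated as zero and the
#: draw's ratio for that entry is excluded rather than winsorized
ZERO_RESPONSE_TOL = 1e-8


@dataclass(frozen=True)
class SelectionVector:
    """Linear nutritional gradients for one trait in each sex.

    Stacking follows the G matrix's trait order (Pm, Cm, Pf, Cf); labels,
    not positions, are authoritative, so construction is by named sex.
    """

    beta_m: tuple[float, float]
    beta_f: tuple[float, float]
    trait: str = ""

    def stacked(self, order: tuple = TRAIT_ORDER) -> np.ndarray:
        lookup = {"Pm": self.beta_m[0], "Cm": self.beta_m[1],
                  "Pf": self.beta_f[0], "Cf": self.beta_f[1]}
        try:
            return np.array([lookup[t] for t in order], dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"trait label {exc} not recognised; expected labels from "
                f"{sorted(lookup)}"
            ) from exc


def predict_response(G: np.ndarray, beta: SelectionVector | np.ndarray,
                     order: tuple = TRAIT_ORDER) -> np.ndarray:
    """One-generation predicted response dz = 1/2 G beta (SD units)."""
    G = np.asarray(G, dtype=float)
    if G.shape != (len(order), len(order)):
        raise ValueError(f"G must be {len(order)}x{len(order)}")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    b = beta.stacked(order) if isinstance(beta, SelectionVector) \
        else np.asarray(beta, dtype=float)
    if b.shape != (len(order),):
        raise ValueError("beta order mismatch with G's trait order")
    return 0.5 * (G @ b)


def zero_b(G: np.ndarray) -> np.ndarray:
    """Copy of G with the between-sex 2x2 blocks zeroed (within-sex intact)."""
    G = np.asarray(G, dtype=float)
    if G.shape != (4, 4):
        raise ValueError("G must be 4x4 in trait order (Pm, Cm, Pf, Cf)")
    out = G.copy()
    out[:2, 2:] = 0.0
    out[2:, :2] = 0.0
    return out


@dataclass
class ResponsePrediction:
    """Posterior (or plug-in) summaries of dz, dz_B0 and R per trait entry."""

    trait: str
    entries: tuple
    dz_mean: np.ndarray
    dz_hpd: np.ndarray        # (4, 2)
    dz_b0_mean: np.ndarray
    dz_b0_hpd: np.ndarray
    r_mean: np.ndarray
    r_hpd: np.ndarray
    n_draws: int
    n_excluded: np.ndarray    # per-entry count of excluded ratio draws
    mode: str

    def table(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.entries):
            rows.append({
                "trait": self.trait, "entry": e,
                "dz": self.dz_mean[i],
                "dz_lo": self.dz_hpd[i, 0], "dz_hi": self.dz_hpd[i, 1],
                "dz_b0": self.dz_b0_mean[i],
                "dz_b0_lo": self.dz_b0_hpd[i, 0],
                "dz_b0_hi": self.dz_b0_hpd[i, 1],
                "R": self.r_mean[i],
                "R_lo": self.r_hpd[i, 0], "R_hi": self.r_hpd[i, 1],
                "n_excluded": int(self.n_excluded[i]),
            })
        return pd.DataFrame(rows)


def constraint_R(
    posterior: GMatrixPosterior,
    beta: SelectionVector | np.ndarray,
    mode: str = "per_draw",
    trait: str = "",
) -> ResponsePrediction:
    """Constraint metric R = dz / dz_B0 with posterior uncertainty.

    ``beta`` is either a fixed :class:`SelectionVector` (used for every G
    draw) or an (n_draws, 4) array of per-draw gradient vectors in G's trait
    order.  ``mode="per_draw"`` (default) computes dz, dz_B0 and their ratio
    per paired draw and summarizes afterwards; ``mode="plug_in"`` applies the
    posterior-mean G (and mean beta) once, as a cross-check.

    Ratio draws whose counterfactual response is within ``ZERO_RESPONSE_TOL``
    of zero are excluded for that entry; exclusion counts are reported.
    """
    if posterior.n_draws == 0:
        raise ValueError("empty posterior")
    g_draws = posterior.g_draws
    n = g_draws.shape[0]
    if isinstance(beta, SelectionVector):
        b_draws = np.broadcast_to(beta.stacked(), (n, 4))
    else:
        b_draws = np.asarray(beta, dtype=float)
        if b_draws.ndim == 1:
            b_draws = np.broadcast_to(b_draws, (n, 4))
        elif b_draws.shape[0] < n:
            raise ValueError(
                "per_draw mode consumes one beta draw per G draw; got "
                f"{b_draws.shape[0]} beta draws for {n} G draws"
            )
        else:
            b_draws = b_draws[:n]

    if mode == "plug_in":
        Gbar = g_draws.mean(axis=0)
        bbar = b_draws.mean(axis=0)
        dz = predict_response(Gbar, bbar)
        dz0 = predict_response(zero_b(Gbar), bbar)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(np.abs(dz0) > ZERO_RESPONSE_TOL, dz / dz0, np.nan)
        zeros = np.zeros((4, 2))
        return ResponsePrediction(
            trait=trait, entries=TRAIT_ORDER,
            dz_mean=dz, dz_hpd=np.column_stack([dz, dz]),
            dz_b0_mean=dz0, dz_b0_hpd=np.column_stack([dz0, dz0]),
            r_mean=r, r_hpd=np.column_stack([r, r]),
            n_draws=1, n_excluded=np.isnan(r).astype(int), mode=mode)
    if mode != "per_draw":
        raise ValueError("mode must be 'per_draw' or 'plug_in'")

    dz = 0.5 * np.einsum("nij,nj->ni", g_draws, b_draws)
    g0 = g_draws.copy()
    g0[:, :2, 2:] = 0.0
    g0[:, 2:, :2] = 0.0
    dz0 = 0.5 * np.einsum("nij,nj->ni", g0, b_draws)
    valid = np.abs(dz0) > ZERO_RESPONSE_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, dz / dz0, np.nan)

    def _summ(x):
        mean = np.nanmean(x, axis=0)
        hpd = np.empty((4, 2))
        for i in range(4):
            col = x[:, i]
            col = col[np.isfinite(col)]
            hpd[i] = hpd_interval(col) if len(col) else (np.nan, np.nan)
        return mean, hpd

    dz_mean, dz_hpd = _summ(dz)
    dz0_mean, dz0_hpd = _summ(dz0)
    r_mean, r_hpd = _summ(ratio)
    return ResponsePrediction(
        trait=trait, entries=TRAIT_ORDER,
        dz_mean=dz_mean, dz_hpd=dz_hpd,
        dz_b0_mean=dz0_mean, dz_b0_hpd=dz0_hpd,
        r_mean=r_mean, r_hpd=r_hpd,
        n_draws=n, n_excluded=(~valid).sum(axis=0), mode=mode)


def interpret_R(prediction: ResponsePrediction) -> dict[str, str]:
    """Classify each entry's R: HPD entirely above 1 -> "accelerated",
    entirely below 1 -> "constrained", spanning 1 -> "neutral"."""
    out = {}
    for i, e in enumerate(prediction.entries):
        lo, hi = prediction.r_hpd[i]
        if np.isnan(lo) or np.isnan(hi):
            out[e] = "undefined"
        elif lo > 1.0:
            out[e] = "accelerated"
        elif hi < 1.0:
            out[e] = "constrained"
        else:
            out[e] = "neutral"
    return out
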