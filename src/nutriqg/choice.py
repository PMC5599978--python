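"""Dietary-choice analysis: diet preference, sex and diet-pair effects on
nutrient intake, regulated intake points (RIPs), and the RIP sex-difference
test.

The RIP is the (P, C) intake an animal defends when offered complementary
diets; it is estimated as the mean intake across diet pairs in each sex.
Sex and diet-pair effects on the bivariate (P, C) intake are tested with a
two-factor MANOVA (Pillai's trace with its standard approximate-F
transformation), followed up by univariate ANOVAs per nutrient and Fisher's
LSD orderings of the diet pairs.  Whether the sexes regulate along different
lines in nutrient space is tested by an ANCOVA of C intake on sex, P intake
and their interaction: a significant interaction means the sexes' regulation
lines have different slopes, i.e. different RIP ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .response_surface import LandscapeGrid


# ---------------------------------------------------------------------------
# diet preference


def diet_preference(records: pd.DataFrame, by_sex: bool = True) -> pd.DataFrame:
    """Paired t-tests of high-C versus high-P diet consumption per diet pair.

    ``records`` must carry ``consumed_high_p`` and ``consumed_high_c``
    columns (dry mass of each diet in the pair eaten by the individual).
    A positive mean difference means the high-C diet was preferred.  Exact
    ties (zero-variance differences) are flagged rather than erroring.
    """
    for col in ("consumed_high_p", "consumed_high_c"):
        if col not in records.columns:
            raise ValueError(f"records lack the per-diet column {col!r}")
    group_cols = ["sex", "design_cell"] if by_sex else ["design_cell"]
    rows = []
    for keys, sub in records.groupby(group_cols, sort=True):
        if len(sub) < 2:
            raise ValueError(f"group {keys}: need >= 2 paired observations")
        diff = (sub["consumed_high_c"] - sub["consumed_high_p"]).to_numpy()
        entry = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        entry["n"] = len(diff)
        entry["mean_diff"] = float(diff.mean())
        entry["df"] = len(diff) - 1
        if np.allclose(diff, diff[0]):
            entry["tie"] = True
            if np.allclose(diff, 0):
                entry["t"], entry["p"] = 0.0, 1.0
            else:  # constant nonzero difference: direction certain
                entry["t"] = float(np.inf if diff[0] > 0 else -np.inf)
                entry["p"] = 0.0
        else:
            t, p = stats.ttest_rel(sub["consumed_high_c"], sub["consumed_high_p"])
            entry["t"], entry["p"], entry["tie"] = float(t), float(p), False
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-factor MANOVA (Pillai's trace)


def _pillai_f(V: float, p: int, q: int, v: int) -> tuple[float, int, int, float]:
    """Standard approximate F for Pillai's trace.

    p = number of responses, q = hypothesis df, v = error df.
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n2 = (v - p - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * n2 + s + 1))
    denom = s - V
    if denom <= 0:
        return float("inf"), df1, df2, 0.0
    F = (df2 / df1) * (V / denom)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def _sum_coded(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(labels.unique())
    k = len(levels)
    X = np.zeros((len(labels), k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = (labels == lev).astype(float) - (labels == levels[-1]).astype(float)
    return X, levels


@dataclass
class ManovaResult:
    """Pillai's-trace tests per term plus univariate follow-ups and LSD
    orderings of the diet pairs per nutrient per sex."""

    terms: dict[str, dict]                  # term -> pillai, F, df1, df2, p
    univariate: pd.DataFrame                # term x nutrient ANOVA table
    lsd: dict[tuple[str, str], str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [{"term": t, **v} for t, v in self.terms.items()]
        return pd.DataFrame(rows)


def manova_intake(records: pd.DataFrame, alpha: float = 0.05,
                  responses: tuple[str, ...] = ("p_intake", "c_intake"),
                  follow_up: bool = True) -> ManovaResult:
    """Two-factor MANOVA of (P, C) intake on sex and diet pair.

    Pillai's trace per term (sex, diet pair, interaction) uses partial
    (type-III-style) hypothesis SSCP matrices under sum-to-zero coding, so
    in balanced designs the conventions coincide.  Univariate ANOVAs per
    nutrient and Fisher's-LSD pair orderings (within sex) are attached
    unless ``follow_up`` is off; LSD is only computed when the univariate
    omnibus pair effect is significant.  A single entry in ``responses``
    reduces the procedure to the univariate ANOVA (Pillai's approximate F
    then equals the ordinary F exactly).
    """
    counts = records.groupby(["sex", "design_cell"]).size()
    sexes = records["sex"].unique()
    pairs = records["design_cell"].unique()
    for s in sexes:
        for pr in pairs:
            if (s, pr) not in counts.index or counts[(s, pr)] < 2:
                raise ValueError(f"design cell (sex={s}, pair={pr}) is empty "
                                 "or has fewer than 2 replicates")

    Y = records[list(responses)].to_numpy(dtype=float)
    n, p = Y.shape
    Xa, _ = _sum_coded(records["sex"])
    Xb, _ = _sum_coded(records["design_cell"])
    inter = np.column_stack([Xa[:, i:i + 1] * Xb for i in range(Xa.shape[1])])
    one = np.ones((n, 1))
    blocks = {"sex": Xa, "diet_pair": Xb, "sex:diet_pair": inter}

    def resid_sscp(X):
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ coef
        return R.T @ R

    X_full = np.column_stack([one, Xa, Xb, inter])
    E = resid_sscp(X_full)
    v = n - X_full.shape[1]

    terms: dict[str, dict] = {}
    for term, block in blocks.items():
        X_red = np.column_stack([one] + [b for t, b in blocks.items() if t != term])
        H = resid_sscp(X_red) - E
        q = block.shape[1]
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        F, df1, df2, pval = _pillai_f(V, p, q, v)
        terms[term] = {"pillai": V, "F": F, "df1": df1, "df2": df2, "p": pval}

    if not follow_up:
        return ManovaResult(terms=terms, univariate=pd.DataFrame())

    # univariate follow-ups (type III, sum coding)
    uni_rows = []
    pair_sig = {}
    for nutrient in responses:
        df = records.rename(columns={nutrient: "y"})
        model = smf.ols(
            "y ~ C(sex, Sum) * C(design_cell, Sum)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=3)
        for term, row_name in (("sex", "C(sex, Sum)"),
                               ("diet_pair", "C(design_cell, Sum)"),
                               ("sex:diet_pair",
                                "C(sex, Sum):C(design_cell, Sum)")):
            uni_rows.append({
                "nutrient": nutrient, "term": term,
                "F": float(tab.loc[row_name, "F"]),
                "df1": int(tab.loc[row_name, "df"]),
                "df2": int(tab.loc["Residual", "df"]),
                "p": float(tab.loc[row_name, "PR(>F)"]),
            })
            if term == "diet_pair":
                pair_sig[nutrient] = tab.loc[row_name, "PR(>F)"] < alpha
    univariate = pd.DataFrame(uni_rows)

    lsd = {}
    for nutrient in responses:
        if not pair_sig.get(nutrient, False):
            continue
        for sex, sub in records.groupby("sex"):
            lsd[(sex, nutrient)] = _lsd_ordering(sub, nutrient, alpha)
    return ManovaResult(terms=terms, univariate=univariate, lsd=lsd)


def _lsd_ordering(sub: pd.DataFrame, nutrient: str, alpha: float) -> str:
    """Fisher's-LSD ordering string over diet pairs, e.g. "pair2 < pair1 = pair4"."""
    groups = {pr: g[nutrient].to_numpy() for pr, g in sub.groupby("design_cell")}
    labels = sorted(groups, key=lambda pr: groups[pr].mean())
    nobs = {pr: len(groups[pr]) for pr in labels}
    mse = np.sum([(len(g) - 1) * np.var(g, ddof=1) for g in groups.values()])
    dfe = sum(nobs.values()) - len(labels)
    mse /= dfe
    pieces = [labels[0]]
    for a, b in zip(labels, labels[1:]):
        se = np.sqrt(mse * (1 / nobs[a] + 1 / nobs[b]))
        t = (groups[b].mean() - groups[a].mean()) / se
        sig = 2 * stats.t.sf(abs(t), dfe) < alpha
        pieces.append(("< " if sig else "= ") + b)
    return " ".join(pieces)


# ---------------------------------------------------------------------------
# regulated intake points


@dataclass
class RegulatedIntakePoint:
    """Mean regulated intake of P and C (mg) with SEs for one sex."""

    sex: str
    mean_p: float
    se_p: float
    mean_c: float
    se_c: float
    n: int

    @property
    def pc_ratio(self) -> float:
        """C consumed per unit P."""
        return self.mean_c / self.mean_p

    @property
    def ratio_string(self) -> str:
        return f"1P:{self.pc_ratio:.2f}C"


def compute_rip(records: pd.DataFrame, sex: str) -> RegulatedIntakePoint:
    """RIP for one sex: the mean of per-diet-pair mean intakes.

    Averaging pair means (rather than pooling individuals) keeps unbalanced
    pair attrition from biasing the RIP; with balanced data the two coincide.
    Missing pairs produce a warning-style note via the available-pair mean.
    """
    sub = records[records["sex"] == sex]
    if len(sub) == 0:
        raise ValueError(f"no records for sex {sex!r}")
    pair_means = sub.groupby("design_cell")[["p_intake", "c_intake"]].mean()
    n = len(sub)
    return RegulatedIntakePoint(
        sex=sex,
        mean_p=float(pair_means["p_intake"].mean()),
        se_p=float(sub["p_intake"].std(ddof=1) / np.sqrt(n)),
        mean_c=float(pair_means["c_intake"].mean()),
        se_c=float(sub["c_intake"].std(ddof=1) / np.sqrt(n)),
        n=n,
    )


def rip_sex_test(records: pd.DataFrame) -> pd.DataFrame:
    """ANCOVA for a sex difference in the regulated intake line.

    Fits C intake ~ sex + P intake + sex x P intake (type-III tests,
    sum-to-zero coding).  A significant interaction means the sexes regulate
    along lines of different slope — different RIP ratios.
    """
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex]
        if len(sub) < 3:
            raise ValueError(f"need >= 3 individuals of sex {sex!r}")
        if sub["p_intake"].std(ddof=1) == 0:
            raise ValueError(f"P intake has zero variance within sex {sex!r}")
    model = smf.ols("c_intake ~ C(sex, Sum) * p_intake", data=records).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    out_rows = []
    for term, row_name in (("sex", "C(sex, Sum)"), ("p_intake", "p_intake"),
                           ("sex:p_intake", "C(sex, Sum):p_intake")):
        out_rows.append({
            "term": term,
            "F": float(tab.loc[row_name, "F"]),
            "df1": int(tab.loc[row_name, "df"]),
            "df2": int(tab.loc["Residual", "df"]),
            "p": float(tab.loc[row_name, "PR(>F)"]),
        })
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# RIP-on-landscape overlay


def overlay_rip(rip: RegulatedIntakePoint, landscape: LandscapeGrid) -> dict:
    """Where the RIP sits on a trait's nutritional landscape.

    Returns the landscape value at the RIP, the location and value of the
    (hull-restricted) landscape maximum, and the Euclidean distance from the
    RIP to that maximum in intake units.  A RIP outside the data hull is
    reported as extrapolation rather than silently evaluated.
    """
    p, c = rip.mean_p, rip.mean_c
    extrapolated = not landscape.contains(p, c)
    peak_p, peak_c, peak_val = landscape.peak(within_hull=True)
    out = {
        "sex": rip.sex,
        "rip_p": p, "rip_c": c,
        "peak_p": peak_p, "peak_c": peak_c, "peak_value": peak_val,
        "distance_to_peak": float(np.hypot(p - peak_p, c - peak_c)),
        "extrapolated": extrapolated,
    }
    out["value_at_rip"] = np.nan if extrapolated else landscape.value_at(p, c)
    return out
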