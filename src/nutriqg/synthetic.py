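"""Synthetic datasets with the statistical structure of the three study
designs: a 24-diet no-choice array, a half-sib dietary-choice breeding design,
and an outbred dietary-choice experiment.

Every generator has known ground truth (response surfaces, the 4x4 G matrix,
regulated intake points), so each downstream estimator can be tested for
parameter recovery without external data.  Defaults follow the published
study conditions: 6 nutritional rails x 4 dilutions spanning 5P:1C to 1P:8C,
10 individuals per sex per diet; 30 sires x 3 dams x 12 offspring per sex
split over 4 diet pairs (n = 2160); 30 individuals per sex per diet pair in
the outbred choice design.  Ground-truth surface gradients and G default to
the published cricket point estimates (:mod:`nutriqg.reference`), so
recovery tests run at the study's own effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .data_model import DietComposition, PedigreeEntry

#: phenotypic SD of intake (mg) per trait (Pm, Cm, Pf, Cf) used to place the
#: unit-variance generative scale onto a realistic mg scale
DEFAULT_TRAIT_SD = (55.0, 137.0, 80.3, 126.4)

#: phenotypic mean intake (mg) per trait (Pm, Cm, Pf, Cf)
DEFAULT_TRAIT_MEAN = (179.22, 578.57, 262.69, 577.10)


@dataclass(frozen=True)
class SurfaceSpec:
    """Ground-truth response surface for one sex x trait on the z-scale."""

    beta: tuple[float, float]
    gamma: np.ndarray  # symmetric 2x2
    noise_sd: float = 0.9

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.shape != (2, 2) or not np.allclose(g, g.T):
            raise ValueError("gamma must be a symmetric 2x2 matrix")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def evaluate(self, zp: np.ndarray, zc: np.ndarray) -> np.ndarray:
        """Surface value on the z-scale; the off-diagonal of gamma is the raw
        P x C regression coefficient (no doubling convention)."""
        g = np.asarray(self.gamma, dtype=float)
        return (self.beta[0] * zp + self.beta[1] * zc
                + g[0, 0] * zp**2 + g[1, 1] * zc**2 + g[0, 1] * zp * zc)


def surface_spec(beta, quadratic, correlational, noise_sd=0.9) -> SurfaceSpec:
    """Build a SurfaceSpec from (beta_P, beta_C), (g_PP, g_CC) and g_PC."""
    g = np.array([[quadratic[0], correlational], [correlational, quadratic[1]]])
    return SurfaceSpec(beta=tuple(beta), gamma=g, noise_sd=noise_sd)


def default_surface_specs(noise_sd: float = 0.9) -> dict:
    """Published gradients per (sex, trait) as ground-truth surfaces."""
    specs = {}
    for key, beta in reference.LINEAR_GRADIENTS.items():
        g11, g22, g12 = reference.NONLINEAR_GRADIENTS[key]
        specs[key] = surface_spec(beta, (g11, g22), g12, noise_sd)
    return specs


# ---------------------------------------------------------------------------
# diets


def make_diet_grid(
    n_ratios: int = 6,
    n_dilutions: int = 4,
    rail_lo: float = 5.0,
    rail_hi: float = 1.0 / 8.0,
    max_total: float = 0.9,
) -> list[DietComposition]:
    """Geometric array of diets: P:C ratios log-spaced between the outer
    rails, crossed with evenly spaced total-nutrient dilutions.

    ``rail_lo`` and ``rail_hi`` are P:C ratios (P per unit C); the defaults
    span 5P:1C to 1P:8C, giving the classic 6 x 4 = 24-diet array.
    """
    if n_ratios < 2 and rail_lo != rail_hi:
        raise ValueError("n_ratios must be >= 2 to span two distinct rails")
    if n_dilutions < 1:
        raise ValueError("n_dilutions must be >= 1")
    if rail_lo <= 0 or rail_hi <= 0:
        raise ValueError("rails must be positive P:C ratios")
    if rail_lo == rail_hi and n_ratios > 1:
        raise ValueError("degenerate rails: rail_lo == rail_hi with n_ratios > 1")
    ratios = np.exp(np.linspace(np.log(rail_lo), np.log(rail_hi), n_ratios))
    totals = np.linspace(max_total / n_dilutions, max_total, n_dilutions)
    diets = []
    k = 1
    for ratio in ratios:
        for total in totals:
            c = total / (1.0 + ratio)
            p = total - c
            diets.append(DietComposition(diet_id=f"d{k:02d}", p_frac=p, c_frac=c))
            k += 1
    return diets


#: four complementary diet pairs (one P-biased, one C-biased diet each) at
#: two dilutions, mirroring the published choice design's coverage
def default_diet_pairs() -> list[tuple[DietComposition, DietComposition]]:
    def diet(tag, ratio, total):
        c = total / (1 + ratio)
        return DietComposition(diet_id=tag, p_frac=total - c, c_frac=c)

    hp_lo = diet("p5c1_lo", 5.0, 0.45)
    hp_hi = diet("p5c1_hi", 5.0, 0.90)
    hc_lo = diet("p1c8_lo", 1 / 8, 0.45)
    hc_hi = diet("p1c8_hi", 1 / 8, 0.90)
    return [(hp_lo, hc_lo), (hp_lo, hc_hi), (hp_hi, hc_lo), (hp_hi, hc_hi)]


# ---------------------------------------------------------------------------
# no-choice design


def simulate_nochoice(
    specs: Mapping[tuple[str, str], SurfaceSpec] | None = None,
    diets: Sequence[DietComposition] | None = None,
    n_per_diet_per_sex: int = 10,
    seed: int = 0,
    total_mg_mean: float = 600.0,
    total_mg_cv: float = 0.35,
) -> pd.DataFrame:
    """Simulate the no-choice design: each individual is confined to one
    diet's nutritional rail and its traits follow known response surfaces.

    Total dry-mass consumption is log-normal (mean ``total_mg_mean`` mg,
    coefficient of variation ``total_mg_cv``); intakes are the consumed mass
    times the diet's nutrient fractions, so each individual sits on its
    diet's rail.  Traits are generated on the z-scale of intake (standardized
    within sex with the sample moments) as beta . z + z' gamma z + noise, and
    are returned on that generator scale.
    """
    if specs is None:
        specs = default_surface_specs()
    if diets is None:
        diets = make_diet_grid()
    if len(diets) == 0:
        raise ValueError("empty diet list")
    sexes = sorted({s for s, _ in specs})
    traits = sorted({t for _, t in specs})
    for sex in sexes:
        for t in traits:
            if (sex, t) not in specs:
                raise ValueError(f"missing surface spec for ({sex}, {t})")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + total_mg_cv**2))
    mu_log = np.log(total_mg_mean) - sigma**2 / 2

    frames = []
    for sex in sexes:
        rows = {"individual_id": [], "sex": [], "design_cell": [],
                "p_intake": [], "c_intake": []}
        for diet in diets:
            mass = rng.lognormal(mu_log, sigma, size=n_per_diet_per_sex)
            for m in mass:
                rows["individual_id"].append(f"{sex[0]}{len(rows['sex']):04d}")
                rows["sex"].append(sex)
                rows["design_cell"].append(diet.diet_id)
                rows["p_intake"].append(m * diet.p_frac)
                rows["c_intake"].append(m * diet.c_frac)
        df = pd.DataFrame(rows)
        zp = (df["p_intake"] - df["p_intake"].mean()) / df["p_intake"].std(ddof=1)
        zc = (df["c_intake"] - df["c_intake"].mean()) / df["c_intake"].std(ddof=1)
        for t in traits:
            sp = specs[(sex, t)]
            surface = sp.evaluate(zp.to_numpy(), zc.to_numpy())
            df[t] = surface + rng.normal(0, sp.noise_sd, size=len(df))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# half-sib choice design


def _check_psd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g})")


def _default_e_true() -> np.ndarray:
    """Residual covariance completing G to unit phenotypic variances with
    moderate within-sex residual correlations; cross-sex blocks are
    structurally zero (no individual expresses both sexes' traits)."""
    e = np.zeros((4, 4))
    e[:2, :2] = np.array([[0.66, 0.22], [0.22, 0.80]])
    e[2:, 2:] = np.array([[0.69, 0.27], [0.27, 0.85]])
    return e


@dataclass
class GenParams:
    """Ground truth and design counts for the half-sib choice simulation."""

    g_true: np.ndarray = field(default_factory=lambda: reference.G_POINT.copy())
    e_true: np.ndarray = field(default_factory=_default_e_true)
    mu: tuple = DEFAULT_TRAIT_MEAN
    trait_sd: tuple = DEFAULT_TRAIT_SD
    n_sires: int = 30
    n_dams_per_sire: int = 3
    n_offspring_per_dam_per_sex: int = 12
    diet_pairs: Sequence = field(default_factory=default_diet_pairs)

    def validate(self) -> None:
        _check_psd(self.g_true, "G_true")
        _check_psd(self.e_true, "E_true")
        e = np.asarray(self.e_true)
        if not np.allclose(e[:2, 2:], 0):
            raise ValueError("cross-sex residual covariances must be exactly 0")
        if min(self.n_sires, self.n_dams_per_sire,
               self.n_offspring_per_dam_per_sex) < 1:
            raise ValueError("design counts must be >= 1")


def simulate_halfsib_choice(
    params: GenParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, list[PedigreeEntry]]:
    """Simulate the half-sib dietary-choice design.

    Founder breeding values are MVN(0, G_true); offspring breeding values are
    the mid-parent value plus a Mendelian deviation MVN(0, G_true/2)
    (non-inbred parents).  Each individual expresses only its own sex's two
    traits: intake = mu + trait_sd * (a + e) on the mg scale, with residuals
    drawn from the sex's 2x2 block of E_true.  Offspring of each dam are
    split evenly across the diet pairs, sexes balanced.

    Returns the intake table (``design_cell`` is the diet-pair label) and the
    pedigree including the unphenotyped founders.
    """
    if params is None:
        params = GenParams()
    params.validate()
    rng = np.random.default_rng(seed)
    G = np.asarray(params.g_true, dtype=float)
    E = np.asarray(params.e_true, dtype=float)
    mu = np.asarray(params.mu, dtype=float)
    sd = np.asarray(params.trait_sd, dtype=float)
    n_pairs = len(params.diet_pairs)
    per_pair = params.n_offspring_per_dam_per_sex / n_pairs

    chol_g = np.linalg.cholesky(G + 1e-10 * np.eye(4))
    chol_m = np.linalg.cholesky(G / 2 + 1e-10 * np.eye(4))

    pedigree: list[PedigreeEntry] = []
    rows = []
    for si in range(params.n_sires):
        sire_id = f"s{si + 1:03d}"
        a_sire = chol_g @ rng.standard_normal(4)
        pedigree.append(PedigreeEntry(sire_id, None, None, "male"))
        for di in range(params.n_dams_per_sire):
            dam_id = f"{sire_id}.d{di + 1}"
            a_dam = chol_g @ rng.standard_normal(4)
            pedigree.append(PedigreeEntry(dam_id, None, None, "female"))
            mid = 0.5 * (a_sire + a_dam)
            for sex_i, sex in enumerate(("male", "female")):
                for k in range(params.n_offspring_per_dam_per_sex):
                    off_id = f"{dam_id}.{sex[0]}{k + 1:02d}"
                    a = mid + chol_m @ rng.standard_normal(4)
                    pedigree.append(PedigreeEntry(off_id, sire_id, dam_id, sex))
                    t0 = 0 if sex == "male" else 2
                    eblk = np.linalg.cholesky(E[t0:t0 + 2, t0:t0 + 2])
                    e = eblk @ rng.standard_normal(2)
                    pheno = mu[t0:t0 + 2] + sd[t0:t0 + 2] * (a[t0:t0 + 2] + e)
                    pair_idx = int(k // per_pair) % n_pairs
                    rows.append({
                        "individual_id": off_id, "sex": sex,
                        "design_cell": f"pair{pair_idx + 1}",
                        "p_intake": pheno[0], "c_intake": pheno[1],
                    })
    return pd.DataFrame(rows), pedigree


# ---------------------------------------------------------------------------
# outbred choice design


def rip_dispersion(rip: tuple[float, float], frac_along: float = 0.25,
                   frac_perp: float = 0.03) -> np.ndarray:
    """Intake covariance around a regulated intake point.

    Individuals defend a nutrient *ratio* much more tightly than their total
    consumption, so the dispersion's long axis lies along the sex's
    regulation line (the ray through the RIP) and the short axis
    perpendicular to it.  Fractions are of the RIP's norm; the defaults put
    the P and C standard errors at study-like magnitudes for n = 120 per sex
    while keeping within-sex intake tightly on the regulation line.
    """
    rip = np.asarray(rip, dtype=float)
    norm = np.linalg.norm(rip)
    u = rip / norm
    v = np.array([-u[1], u[0]])
    return ((frac_along * norm) ** 2 * np.outer(u, u)
            + (frac_perp * norm) ** 2 * np.outer(v, v))


def simulate_outbred_choice(
    rip_by_sex: Mapping[str, tuple[float, float]] | None = None,
    dispersion: Mapping[str, np.ndarray] | np.ndarray | None = None,
    diet_pairs: Sequence | None = None,
    n_per_pair_per_sex: int = 30,
    seed: int = 0,
    pair_offsets: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate the outbred dietary-choice design.

    Each individual's (P, C) intake is drawn around its sex's regulated
    intake point (mg), by default independently of diet pair — perfect
    regulation.  ``pair_offsets`` maps a diet-pair label to an additive
    (P, C) shift for imperfect regulation.  Per-diet consumed dry masses are
    back-computed from the intake and the pair's diet compositions, giving
    the paired-preference columns ``consumed_high_p`` / ``consumed_high_c``.
    """
    if n_per_pair_per_sex < 2:
        raise ValueError("need n_per_pair_per_sex >= 2 for downstream tests")
    if rip_by_sex is None:
        rip_by_sex = reference.RIP_MEAN
    if diet_pairs is None:
        diet_pairs = default_diet_pairs()
    if dispersion is None:
        disp = {sex: rip_dispersion(rip) for sex, rip in rip_by_sex.items()}
    elif isinstance(dispersion, Mapping):
        disp = dict(dispersion)
    else:
        disp = {sex: np.asarray(dispersion, dtype=float) for sex in rip_by_sex}
    for sex, mat in disp.items():
        _check_psd(mat, f"dispersion[{sex}]")

    rng = np.random.default_rng(seed)
    rows = []
    for sex in sorted(rip_by_sex):
        rip = np.asarray(rip_by_sex[sex], dtype=float)
        chol = np.linalg.cholesky(np.asarray(disp[sex]) + 1e-12 * np.eye(2))
        for pi, (diet_a, diet_b) in enumerate(diet_pairs, start=1):
            label = f"pair{pi}"
            target = rip.copy()
            if pair_offsets and label in pair_offsets:
                target = target + np.asarray(pair_offsets[label], dtype=float)
            # order the pair as (high-P, high-P:C ratio first)
            if diet_a.pc_ratio < diet_b.pc_ratio:
                diet_a, diet_b = diet_b, diet_a
            comp = np.array([[diet_a.p_frac, diet_b.p_frac],
                             [diet_a.c_frac, diet_b.c_frac]])
            for k in range(n_per_pair_per_sex):
                intake = target + chol @ rng.standard_normal(2)
                intake = np.maximum(intake, 1e-6)
                masses = np.linalg.solve(comp, intake)
                masses = np.maximum(masses, 0.0)
                rows.append({
                    "individual_id": f"{sex[0]}{label}_{k + 1:03d}",
                    "sex": sex, "design_cell": label,
                    "p_intake": intake[0], "c_intake": intake[1],
                    "consumed_high_p": masses[0], "consumed_high_c": masses[1],
                })
    return pd.DataFrame(rows)


def write_manifest(path, seed: int, description: str, params: dict) -> None:
    """JSON run manifest recording the seed and generator parameters."""
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    with open(path, "w") as fh:
        json.dump({"seed": seed, "description": description,
                   "params": {k: _clean(v) for k, v in params.items()}},
                  fh, indent=2)
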