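"""Run configuration and end-to-end pipeline orchestration.

The pipeline chains the full analysis: (optionally) simulate the three study
designs, fit per-sex response surfaces, compare them between sexes
(sequential F-tests plus the gradient-vector angle with its Bayesian HPD
interval), fit the pedigree animal model, propagate the G posterior into
predicted responses and the R constraint metric, and run the choice analysis
(preference, MANOVA, RIPs, RIP sex test).  Every artifact carries the seed
and a hash of the configuration; all randomness flows from explicit seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import choice, compare, synthetic
from .animal_model import fit_animal_model, genetic_correlations
from .data_model import read_intake_table, read_pedigree, validate_intake_table, z_standardize
from .evolutionary_response import SelectionVector, constraint_R, interpret_R
from .mcmc import McmcSettings
from .response_surface import fit_gradients, fit_landscape

log = logging.getLogger("nutriqg")

TRAITS = ("lifespan", "dre", "lre")


@dataclass
class RunConfig:
    """Human-editable run configuration; every field mirrors a CLI flag."""

    seed: int = 1
    out_dir: str = "nutriqg_out"
    # input paths; when None the corresponding design is simulated
    nochoice_path: str | None = None
    halfsib_path: str | None = None
    pedigree_path: str | None = None
    choice_path: str | None = None
    standardize_by: str = "sex"          # "sex" or "pooled"
    response_mode: str = "per_draw"      # or "plug_in"
    angle_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(
        iterations=20_000, burn_in=2_000, thin=10))
    animal_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(
        iterations=20_000, burn_in=2_000, thin=10, prior_nu=1.002))
    # scaled-down simulated designs keep the default end-to-end run quick
    n_sires: int = 30
    n_dams_per_sire: int = 3
    n_offspring_per_dam_per_sex: int = 12

    def validate(self) -> None:
        for p in (self.nochoice_path, self.halfsib_path, self.pedigree_path,
                  self.choice_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input path missing: {p}")
        if (self.halfsib_path is None) != (self.pedigree_path is None):
            raise ValueError("halfsib_path and pedigree_path must be given together")
        if self.standardize_by not in ("sex", "pooled"):
            raise ValueError("standardize_by must be 'sex' or 'pooled'")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("angle_mcmc", "animal_mcmc"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = McmcSettings(**raw[key])
        return cls(**raw)


def validate_inputs(paths: dict[str, str]) -> dict[str, list[str]]:
    """Schema and integrity checks for the configured input files."""
    report: dict[str, list[str]] = {}
    for name, path in paths.items():
        if path is None:
            continue
        findings: list[str] = []
        try:
            if name == "pedigree":
                read_pedigree(path)
            else:
                findings = validate_intake_table(pd.read_csv(path).rename(
                    columns={"p_intake_mg": "p_intake",
                             "c_intake_mg": "c_intake",
                             "diet": "design_cell",
                             "diet_pair": "design_cell",
                             "lifespan_d": "lifespan"}))
        except Exception as exc:  # structural problem: hard failure
            raise ValueError(f"{name} ({path}): {exc}") from exc
        report[name] = findings
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the artifact bundle as a dict and
    writes delimited/JSON reports under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stamp = {"seed": seed, "config_hash": config.config_hash()}
    bundle: dict = {"meta": stamp}
    t0 = time.time()

    # ---- stage 1: data
    if config.nochoice_path:
        nochoice = read_intake_table(config.nochoice_path)
    else:
        nochoice = synthetic.simulate_nochoice(seed=seed)
    if config.halfsib_path:
        halfsib = read_intake_table(config.halfsib_path)
        pedigree = read_pedigree(config.pedigree_path)
    else:
        params = synthetic.GenParams(
            n_sires=config.n_sires,
            n_dams_per_sire=config.n_dams_per_sire,
            n_offspring_per_dam_per_sex=config.n_offspring_per_dam_per_sex)
        halfsib, pedigree = synthetic.simulate_halfsib_choice(params, seed=seed + 1)
    if config.choice_path:
        choice_tab = read_intake_table(config.choice_path)
    else:
        choice_tab = synthetic.simulate_outbred_choice(seed=seed + 2)
    log.info("stage data: %d no-choice, %d half-sib, %d choice rows",
             len(nochoice), len(halfsib), len(choice_tab))

    # ---- stage 2: response surfaces per sex per trait
    group_by = None if config.standardize_by == "pooled" else "sex"
    std = z_standardize(nochoice, group_by=group_by)
    traits = [t for t in TRAITS if t in nochoice.columns]
    gradient_tables = []
    landscapes = {}
    for sex in ("female", "male"):
        for trait in traits:
            gs = fit_gradients(std, trait, sex)
            gradient_tables.append(gs.table())
            landscapes[(sex, trait)] = fit_landscape(
                nochoice, trait, group=sex, smoothing="gcv")
    gradients = pd.concat(gradient_tables, ignore_index=True)
    gradients.to_csv(out / "gradients.csv", index=False)
    bundle["gradients"] = gradients
    log.info("stage surfaces: %d gradient sets", len(gradient_tables))

    # ---- stage 3: between-sex comparisons + angles
    per_sex = {s: z_standardize(nochoice[nochoice["sex"] == s],
                                group_by=None).data
               for s in ("female", "male")}
    comp_rows, angle_rows = [], []
    sel_vectors = {}
    for trait in traits:
        seq = compare.sequential_f_tests(per_sex["female"], per_sex["male"],
                                         trait, labels=("female", "male"))
        comp_rows.append(seq.table())
        ang = compare.angle_posterior(per_sex["female"], per_sex["male"], trait,
                                      settings=McmcSettings(
                                          **{**config.angle_mcmc.__dict__,
                                             "seed": seed + 10}))
        angle_rows.append({"trait": trait, "theta_plugin": ang.theta_plugin,
                           "theta_mean": ang.theta_posterior_mean,
                           "hpd_lo": ang.hpd95[0], "hpd_hi": ang.hpd95[1],
                           "n_draws": ang.n_draws})
        gs_f = fit_gradients(std, trait, "female")
        gs_m = fit_gradients(std, trait, "male")
        sel_vectors[trait] = SelectionVector(
            beta_m=tuple(gs_m.linear), beta_f=tuple(gs_f.linear), trait=trait)
    comparisons = pd.concat(comp_rows, ignore_index=True)
    comparisons.to_csv(out / "surface_comparisons.csv", index=False)
    angles = pd.DataFrame(angle_rows)
    angles.to_csv(out / "angles.csv", index=False)
    bundle["comparisons"] = comparisons
    bundle["angles"] = angles
    log.info("stage compare: %d traits", len(traits))

    # ---- stage 4: animal model
    std_halfsib = z_standardize(halfsib, columns=["p_intake", "c_intake"],
                                group_by="sex")
    posterior = fit_animal_model(
        std_halfsib, pedigree,
        settings=McmcSettings(**{**config.animal_mcmc.__dict__,
                                 "seed": seed + 20}))
    posterior.summary().to_csv(out / "g_matrix.csv", index=False)
    corr = genetic_correlations(posterior)
    bundle["g_posterior"] = posterior
    bundle["genetic_correlations"] = corr
    log.info("stage animal model: %d draws, %d zero-variance draws excluded",
             posterior.n_draws, corr["n_excluded"])

    # ---- stage 5: predicted response and R
    resp_rows = []
    for trait in traits:
        pred = constraint_R(posterior, sel_vectors[trait],
                            mode=config.response_mode, trait=trait)
        tab = pred.table()
        tab["classification"] = tab["entry"].map(interpret_R(pred))
        resp_rows.append(tab)
    responses = pd.concat(resp_rows, ignore_index=True)
    responses.to_csv(out / "predicted_responses.csv", index=False)
    bundle["responses"] = responses
    log.info("stage response: %d rows", len(responses))

    # ---- stage 6: choice analysis
    pref = choice.diet_preference(choice_tab)
    pref.to_csv(out / "diet_preference.csv", index=False)
    manova = choice.manova_intake(choice_tab)
    manova.table().to_csv(out / "manova.csv", index=False)
    rips = {s: choice.compute_rip(choice_tab, s) for s in ("female", "male")}
    rip_df = pd.DataFrame([{
        "sex": r.sex, "mean_p": r.mean_p, "se_p": r.se_p,
        "mean_c": r.mean_c, "se_c": r.se_c, "ratio": r.ratio_string}
        for r in rips.values()])
    rip_df.to_csv(out / "rip.csv", index=False)
    ancova = choice.rip_sex_test(choice_tab)
    ancova.to_csv(out / "rip_sex_test.csv", index=False)
    overlays = []
    for sex, rip in rips.items():
        for trait in traits:
            overlays.append(choice.overlay_rip(rip, landscapes[(sex, trait)])
                            | {"trait": trait})
    pd.DataFrame(overlays).to_csv(out / "rip_overlay.csv", index=False)
    bundle.update({"preference": pref, "manova": manova, "rip": rip_df,
                   "rip_sex_test": ancova,
                   "rip_overlay": pd.DataFrame(overlays)})
    log.info("pipeline complete in %.1f s", time.time() - t0)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(stamp | {"traits": list(traits),
                           "elapsed_s": time.time() - t0}, fh, indent=2)
    return bundle
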