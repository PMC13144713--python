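"""Synthetic study generator: birth cohort, hardship waves, DDM task data.

The generator emulates the structure of a longitudinal adversity-cognition
study: a large birth cohort (default 3,714) with material-hardship waves at
ages 1, 3, 5 and 9 produced by a latent linear growth process; a task
subsample (default 187) that completes a 100-trial two-choice task
simulated from per-subject DDM parameters; covariates; and a
multi-indicator attentional-problems battery loading on one factor.

Calibrated effects (all standardized):

* cumulative hardship -> drift rate, default -0.17;
* drift rate -> attention factor, default -0.15 (no direct hardship ->
  attention path, so the marginal indirect effect is the product).

DDM population means and SDs default to published cohort descriptives
(v 2.89/0.91, a 1.38/0.33, z 0.49/0.05, t0 0.36/0.08).  The within-subject
drift variability mean (1.45) is set so the model-implied cohort mean
accuracy matches the published 0.90; covariates are correlated with
hardship but conditionally independent of drift, so marginal calibrated
effects equal covariate-adjusted ones in expectation.

The truth table (latents, true parameters) is written alongside the
observable CSVs but must never be consumed by analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ddm_core import DDMParams, simulate_trials
from .longitudinal import LOADINGS, WAVE_AGES

__all__ = ["GeneratorConfig", "PathCoefficients", "CohortBundle",
           "calibrate_effects", "generate_cohort", "generate_trials"]


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic study, with study-calibrated defaults."""

    n_cohort: int = 3714
    n_subsample: int = 187

    # latent hardship growth (per-wave expected item sum, loadings 0/2/4/6)
    growth_mean_i: float = 1.0
    growth_mean_s: float = 0.15
    growth_sd_i: float = 0.8
    growth_sd_s: float = 0.1
    growth_corr: float = 0.3
    # logistic link from wave propensity to per-item endorsement probability,
    # anchored so the expected 8-item sum tracks the propensity at sums 1-2
    item_link_intercept: float = -2.7932
    item_link_slope: float = 0.8473
    wave_missing_rate: float = 0.08

    # DDM population (means/SDs); v's mean/SD are the published descriptives
    ddm_mean: dict = Field(default_factory=lambda: dict(
        v=2.89, a=1.38, z=0.49, t0=0.36, sv=1.45, sz=0.15, st0=0.12))
    ddm_sd: dict = Field(default_factory=lambda: dict(
        v=0.91, a=0.33, z=0.05, t0=0.08, sv=0.5, sz=0.06, st0=0.05))

    # standardized path coefficients
    effect_hardship_drift: float = -0.17
    effect_drift_attention: float = -0.15

    attention_loadings: tuple = (0.8, 0.75, 0.7, 0.65, 0.6)

    # covariates
    p_male: float = 0.5
    pubertal_mean: float = 2.8
    pubertal_sd: float = 0.6
    race_probs: dict = Field(default_factory=lambda: dict(
        black=0.77, white=0.09, hispanic=0.08, other=0.06))
    p_two_parent: float = 0.35
    adversity_corr: float = 0.3  # violence/deprivation correlation with hardship

    # task
    n_trials: int = 100
    deadline: float = 1.75
    sim_dt: float = 1e-4

    @model_validator(mode="after")
    def _check(self):
        for e in (self.effect_hardship_drift, self.effect_drift_attention):
            if not -1.0 < e < 1.0:
                raise ValueError(f"effect sizes must lie in (-1, 1), got {e}")
        if not 0 < self.n_subsample <= self.n_cohort:
            raise ValueError("subsample must be a nonempty subset of the cohort")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race probabilities must sum to 1")
        for lam in self.attention_loadings:
            if not 0 < lam < 1:
                raise ValueError("attention loadings must lie in (0, 1)")
        return self


@dataclass(frozen=True)
class PathCoefficients:
    """Raw-scale coefficients implied by the standardized targets."""

    drift_per_sd_hardship: float   # coefficient on z-scored cumulative hardship
    drift_resid_sd: float
    attention_per_sd_drift: float  # coefficient on z-scored drift
    attention_resid_sd: float
    implied_indirect_std: float    # product of the standardized paths


def calibrate_effects(config: GeneratorConfig) -> PathCoefficients:
    """Closed-form coefficients giving the target standardized effects.

    With drift = mean + r * sd_v * Z_h + sd_v * sqrt(1 - r^2) * eps the
    correlation of drift with hardship is exactly r in expectation, and
    likewise for the attention path.  Targets with |r| >= 1 would imply a
    negative residual variance and raise before any sampling.
    """
    r = config.effect_hardship_drift
    beta = config.effect_drift_attention
    sd_v = config.ddm_sd["v"]
    for val, nm in ((r, "hardship->drift"), (beta, "drift->attention")):
        if 1.0 - val ** 2 <= 0.0:
            raise ValueError(f"target {nm} effect {val} implies negative residual variance")
    return PathCoefficients(
        drift_per_sd_hardship=r * sd_v,
        drift_resid_sd=sd_v * np.sqrt(1.0 - r ** 2),
        attention_per_sd_drift=beta,
        attention_resid_sd=float(np.sqrt(1.0 - beta ** 2)),
        implied_indirect_std=float(r * beta),
    )


@dataclass
class CohortBundle:
    """The synthetic study: observable tables plus the guarded truth table."""

    hardship: pd.DataFrame       # long: subject_id, wave_age, item1..item8
    covariates: pd.DataFrame
    attention: pd.DataFrame      # indicator columns att1..attK
    truth: pd.DataFrame          # latents + true parameters; never analysed
    trials: Optional[pd.DataFrame]
    config: GeneratorConfig
    seed: int

    def write(self, out_dir) -> dict:
        """Write the five CSVs plus a manifest; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("hardship", self.hardship), ("covariates", self.covariates),
                         ("attention", self.attention), ("truth", self.truth),
                         ("trials", self.trials)]:
            if df is None:
                continue
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        manifest = {
            "seed": self.seed,
            "config": json.loads(self.config.model_dump_json()),
            "files": {k: Path(v).name for k, v in paths.items()},
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(mp)
        return paths


def _draw_ddm_population(rng, config, n, z_hardship, coef):
    """Per-subject true DDM parameter draws honouring the invariants."""
    mean, sd = config.ddm_mean, config.ddm_sd
    v = mean["v"] + coef.drift_per_sd_hardship * z_hardship \
        + coef.drift_resid_sd * rng.standard_normal(n)
    cols = {}
    for key in ("a", "z", "t0", "sv", "sz", "st0"):
        cols[key] = mean[key] + sd[key] * rng.standard_normal(n)
    out = pd.DataFrame({"v": v, **cols})
    for _ in range(200):
        bad = ((out.a <= 0.05)
               | (out.sv < 0) | (out.sz < 0) | (out.st0 < 0)
               | (out.z - out.sz / 2 <= 0.01) | (out.z + out.sz / 2 >= 0.99)
               | (out.t0 - out.st0 / 2 <= 0.0) | (out.t0 <= 0.05))
        if not bad.any():
            break
        nb = int(bad.sum())
        for key in ("a", "z", "t0", "sv", "sz", "st0"):
            out.loc[bad, key] = mean[key] + sd[key] * rng.standard_normal(nb)
    else:
        raise RuntimeError("could not draw parameter sets inside the invariant region")
    return out


def generate_cohort(config: Optional[GeneratorConfig] = None, seed: int = 0) -> CohortBundle:
    """Generate the full synthetic study (without trial data).

    Per-subject quantities are drawn from a single seeded generator; the
    task subsample is a seeded random subset of the cohort.  Call
    :func:`generate_trials` afterwards for the subsample's task data.
    """
    config = config or GeneratorConfig()
    coef = calibrate_effects(config)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_cohort

    # latent growth of hardship
    cov = np.array([
        [config.growth_sd_i ** 2,
         config.growth_corr * config.growth_sd_i * config.growth_sd_s],
        [config.growth_corr * config.growth_sd_i * config.growth_sd_s,
         config.growth_sd_s ** 2]])
    lat = rng.multivariate_normal([config.growth_mean_i, config.growth_mean_s], cov, size=n)
    i_lat, s_lat = lat[:, 0], lat[:, 1]
    lam = np.asarray(LOADINGS)
    eta = i_lat[:, None] + s_lat[:, None] * lam[None, :]          # wave propensities
    p_item = 1.0 / (1.0 + np.exp(-(config.item_link_intercept
                                   + config.item_link_slope * eta)))
    p_item = np.clip(p_item, 1e-4, 1 - 1e-4)
    items = rng.random((n, len(lam), 8)) < p_item[:, :, None]     # (subject, wave, item)
    wave_sums = items.sum(axis=2)
    cum_true = wave_sums.sum(axis=1).astype(float)

    # observed hardship table with missing-at-random waves
    observed = rng.random((n, len(lam))) >= config.wave_missing_rate
    rows = []
    sids = np.arange(1, n + 1)
    for w, age in enumerate(WAVE_AGES):
        mask = observed[:, w]
        block = pd.DataFrame(items[mask, w, :].astype(int),
                             columns=[f"item{k}" for k in range(1, 9)])
        block.insert(0, "wave_age", age)
        block.insert(0, "subject_id", sids[mask])
        rows.append(block)
    hardship = pd.concat(rows, ignore_index=True).sort_values(
        ["subject_id", "wave_age"]).reset_index(drop=True)

    # true drift linked to (true) cumulative hardship at the calibrated effect
    z_h = (cum_true - cum_true.mean()) / cum_true.std(ddof=0)
    ddm = _draw_ddm_population(rng, config, n, z_h, coef)

    # attention factor from z-scored drift; indicators load on the factor
    z_v = (ddm.v - ddm.v.mean()) / ddm.v.std(ddof=0)
    attention_factor = coef.attention_per_sd_drift * z_v.to_numpy() \
        + coef.attention_resid_sd * rng.standard_normal(n)
    lams = np.asarray(config.attention_loadings)
    ind = lams[None, :] * attention_factor[:, None] \
        + np.sqrt(1 - lams ** 2)[None, :] * rng.standard_normal((n, len(lams)))
    attention = pd.DataFrame(ind, columns=[f"att{k+1}" for k in range(len(lams))])
    attention.insert(0, "subject_id", sids)

    # covariates: correlated with hardship, conditionally independent of drift
    rho = config.adversity_corr
    violence = rho * z_h + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    deprivation = rho * z_h + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    race = rng.choice(list(config.race_probs), size=n,
                      p=list(config.race_probs.values()))
    covariates = pd.DataFrame({
        "subject_id": sids,
        "sex_male": (rng.random(n) < config.p_male).astype(int),
        "pubertal_stage": np.clip(
            config.pubertal_mean + config.pubertal_sd * rng.standard_normal(n), 1.0, 4.0),
        "race": race,
        "two_parent": (rng.random(n) < config.p_two_parent).astype(int),
        "violence_exposure": violence,
        "social_deprivation": deprivation,
    })

    in_sub = np.zeros(n, dtype=bool)
    in_sub[rng.choice(n, size=config.n_subsample, replace=False)] = True

    truth = pd.DataFrame({
        "subject_id": sids,
        "latent_i": i_lat, "latent_s": s_lat,
        "cum_hardship_true": cum_true,
        "attention_factor": attention_factor,
        "in_subsample": in_sub.astype(int),
    })
    truth = pd.concat([truth, ddm.add_prefix("true_")], axis=1)

    return CohortBundle(hardship=hardship, covariates=covariates,
                        attention=attention, truth=truth, trials=None,
                        config=config, seed=seed)


def generate_trials(bundle: CohortBundle, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate the task for every subsample subject from their true DDM
    parameters; attaches and returns the trial table.

    Each subject gets exactly ``n_trials`` pseudo-randomized trials, 20 per
    emotion, half male/half female faces; responses landing after the
    deadline are recorded as omissions.  Per-subject simulator seeds are
    split off one seed sequence (documented rule: ``SeedSequence(seed)
    .generate_state(n)``).
    """
    config = bundle.config
    if seed is None:
        seed = bundle.seed + 1
    ss = np.random.SeedSequence(seed)
    n_sub = int(bundle.truth.in_subsample.sum())
    trial_seeds = ss.generate_state(n_sub) % (2 ** 31)
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    emotions = np.repeat(["fearful", "happy", "angry", "sad", "neutral"],
                         config.n_trials // 5)
    genders = np.array(["male", "female"] * (config.n_trials // 2))

    rows = []
    subs = bundle.truth[bundle.truth.in_subsample == 1]
    for k, (_, subj) in enumerate(subs.iterrows()):
        params = DDMParams(v=subj.true_v, a=subj.true_a, z=subj.true_z,
                           t0=subj.true_t0, sv=subj.true_sv, sz=subj.true_sz,
                           st0=subj.true_st0)
        sim = simulate_trials(params, config.n_trials, deadline=config.deadline,
                              seed=int(trial_seeds[k]), dt=config.sim_dt)
        emo = order_rng.permutation(emotions)
        gen = order_rng.permutation(genders)
        resp = np.where(sim.omitted == 1, "none",
                        np.where(sim.correct == 1, gen,
                                 np.where(gen == "male", "female", "male")))
        df = pd.DataFrame({
            "subject_id": int(subj.subject_id),
            "trial_index": np.arange(1, config.n_trials + 1),
            "emotion": emo,
            "stimulus_gender": gen,
            "response": resp,
            "rt_s": np.where(sim.omitted == 1, np.nan, np.round(sim.rt, 4)),
        })
        rows.append(df)
    trials = pd.concat(rows, ignore_index=True)
    bundle.trials = trials
    return trials
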