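"""Monte-Carlo parameter-recovery experiments.

Replicates redraw the study year — weather anomalies, covariates and
posts — over one fixed world and reference climatology, then push each
draw through the pipeline's own index construction, sentiment
aggregation, instrument synthesis and estimators.  Truth is therefore
conditional on the fixed climatology, and recovery checks compare the
replicate mean of each estimate with the generating coefficient on the
Monte-Carlo standard-error scale.

Fits here use the raw (unstandardized) indices so estimates are on the
same °C scale as the generating coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climatology, instruments, sentiment, simulate
from .heterogeneity import SplitRule, run_battery
from .panel import PanelSpec, build_panel, fit_2sls, fit_fe_ols


@dataclass
class RecoverySetup:
    """Fixed across replicates: world, thresholds, covariate stream seed."""

    scenario: simulate.SimScenario
    world: simulate.World
    thresholds: pd.DataFrame
    q_upper: float = 0.95
    q_lower: float = 0.05


def prepare(scenario: simulate.SimScenario, seed: int,
            q_upper: float = 0.95, q_lower: float = 0.05) -> RecoverySetup:
    """Generate the world and reference-period climatology once."""
    ss = np.random.SeedSequence([seed, 0])
    r_world, r_ref = [np.random.default_rng(s) for s in ss.spawn(2)]
    world = simulate.generate_world(scenario, r_world)
    ref_days, _ = simulate.generate_climate(
        scenario, world, r_ref,
        start_year=min(scenario.ref_years), end_year=max(scenario.ref_years))
    ref = climatology.aggregate_stations(ref_days)
    thresholds = climatology.compute_thresholds(ref, q_upper, q_lower)
    return RecoverySetup(scenario=scenario, world=world, thresholds=thresholds,
                         q_upper=q_upper, q_lower=q_lower)


def one_replicate(setup: RecoverySetup, rep_seed, *, iv: bool = False,
                  het_rule: SplitRule | None = None) -> dict:
    """Draw one study year and estimate.

    Returns the OLS estimates/SEs/CIs for EHT and ELT, plus — when
    requested — 2SLS estimates and first-stage diagnostics, or per-group
    estimates under a split rule.
    """
    sc, world = setup.scenario, setup.world
    ss = (rep_seed if isinstance(rep_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rep_seed))
    r_climate, r_cov, r_posts = [np.random.default_rng(s) for s in ss.spawn(3)]

    station_days, truth_climate = simulate.generate_climate(
        sc, world, r_climate, start_year=sc.study_year, end_year=sc.study_year)
    weather = climatology.aggregate_stations(station_days)
    covariates = simulate.generate_covariates(sc, world, r_cov, sc.study_year)
    indices = climatology.compute_indices(weather, setup.thresholds)

    gen_panel = (indices.merge(weather, on=["city_id", "date"])
                 .merge(covariates, on=["city_id", "date"])
                 .merge(truth_climate, on=["city_id", "date"])
                 .dropna(subset=["EHT", "ELT"])
                 .sort_values(["city_id", "date"]).reset_index(drop=True))
    posts, truth = simulate.generate_posts(sc, world, gen_panel, r_posts,
                                           with_text=False)
    sent = sentiment.city_day_sentiment(posts)

    weather_cov = weather.merge(covariates, on=["city_id", "date"], how="left")
    spec = PanelSpec(standardize=[])  # estimates on the generating °C scale
    inst = None
    if iv:
        inst = instruments.synthesize_instruments(indices, world.meta,
                                                  world.adjacency)
    panel = build_panel(weather_cov, indices, sent, inst, world.meta,
                        PanelSpec(standardize=[],
                                  instruments=["NEHT", "NELT"] if iv else []))

    out: dict = {"truth": truth}
    res = fit_fe_ols(panel, spec)
    for term in ("EHT", "ELT"):
        out[f"ols_{term}"] = res.coef(term)
        out[f"ols_{term}_se"] = res.stderr(term)
        out[f"ols_{term}_ci"] = res.conf_int(term)
    if iv:
        spec_iv = PanelSpec(standardize=[], endogenous=["EHT", "ELT"],
                            instruments=["NEHT", "NELT"])
        ivres = fit_2sls(panel, spec_iv)
        for term in ("EHT", "ELT"):
            out[f"iv_{term}"] = ivres.second_stage.coef(term)
            out[f"iv_{term}_se"] = ivres.second_stage.stderr(term)
        out["first_stage_F"] = ivres.diagnostics["first_stage_F"]
        out["cragg_donald"] = ivres.diagnostics["cragg_donald"]
    if het_rule is not None:
        report = run_battery(panel, spec, [het_rule])
        for _, r in report.iterrows():
            out[f"het_{r['group']}_{r['term']}"] = r["estimate"]
    return out


def run_replicates(setup: RecoverySetup, seed: int, n_reps: int, *,
                   iv: bool = False, het_rule: SplitRule | None = None
                   ) -> pd.DataFrame:
    """Run ``n_reps`` independent study-year replicates."""
    children = np.random.SeedSequence([seed, 1]).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        r = one_replicate(setup, child, iv=iv, het_rule=het_rule)
        r.pop("truth")
        flat = {}
        for k, v in r.items():
            if isinstance(v, tuple):
                flat[f"{k}_lo"], flat[f"{k}_hi"] = v
            elif isinstance(v, dict):
                for kk, vv in v.items():
                    flat[f"{k}_{kk}"] = vv
            else:
                flat[k] = v
        flat["rep"] = rep
        rows.append(flat)
    return pd.DataFrame(rows)


def summarize_recovery(reps: pd.DataFrame, truth: dict[str, float]) -> pd.DataFrame:
    """Replicate mean, Monte-Carlo SE of the mean, bias in MC-SE units,
    and (when CI columns exist) 95% CI coverage, per estimate column."""
    rows = []
    for col, true_val in truth.items():
        est = reps[col].to_numpy()
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        row = {
            "estimate": col, "truth": true_val, "mean": est.mean(),
            "mc_se": mc_se, "bias": est.mean() - true_val,
            "bias_in_mc_se": (est.mean() - true_val) / mc_se,
        }
        lo, hi = f"{col}_ci_lo", f"{col}_ci_hi"
        if lo in reps.columns:
            row["coverage"] = float(((reps[lo] <= true_val)
                                     & (true_val <= reps[hi])).mean())
        rows.append(row)
    return pd.DataFrame(rows)
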