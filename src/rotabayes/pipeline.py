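"""End-to-end orchestration of models 1–5 plus recovery suites.

``run_model`` takes validated records through design construction,
Gibbs fitting and posterior summarization, and optionally writes the
report bundle (contrast CSV, R-hat table, drop report, config echo and
a simple plot). ``run_recovery`` is the calibration engine: it
generates replicate synthetic datasets, refits the models at reduced
MCMC settings and scores HPDI coverage, bias and convergence against
the known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import yaml

from . import metareg, posterior, synthetic
from .hblm import McmcConfig, PosteriorSamples, PriorSpec, gibbs_fit
from .posterior import ContrastSummary
from .preprocess import JUNE, JuneWindow, build_design
from .records import FieldYearRecord, read_records, validate

RHAT_WARN = 1.1


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible run: priors, MCMC protocol, June window, the
    consecutive-cotton zero-run switch and the percent-change baseline
    override (default: mean observed yield among the rows the model
    fitted)."""

    prior: PriorSpec = PriorSpec()
    mcmc: McmcConfig = McmcConfig()
    window: JuneWindow = JUNE
    include_zero: bool = False
    percent_baseline: Optional[float] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        prior = PriorSpec(**raw.get("prior", {}))
        mcmc = McmcConfig(**raw.get("mcmc", {}))
        window = JuneWindow(**raw.get("window", {}))
        return cls(
            prior=prior,
            mcmc=mcmc,
            window=window,
            include_zero=raw.get("include_zero", False),
            percent_baseline=raw.get("percent_baseline"),
        )

    def to_dict(self) -> dict:
        return {
            "prior": dataclasses.asdict(self.prior),
            "mcmc": dataclasses.asdict(self.mcmc),
            "window": dataclasses.asdict(self.window),
            "include_zero": self.include_zero,
            "percent_baseline": self.percent_baseline,
        }


@dataclass
class ModelReport:
    """Everything one model stage produced."""

    model_id: int
    summaries: list
    rhat: dict
    drop_report: dict
    n_obs: int
    samples: Optional[PosteriorSamples] = None
    extras: dict = dc_field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if v is not None and not math.isnan(v)]
        return max(vals) if vals else float("nan")

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_WARN


def _fit_mixed(records, model_id, cfg: PipelineConfig):
    design = build_design(
        records, model_id, window=cfg.window, include_zero=cfg.include_zero
    )
    samples = gibbs_fit(design, cfg.prior, cfg.mcmc)
    return design, samples


def run_model(
    model_id: int,
    records,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir=None,
    upstream: Optional[dict] = None,
    plot: bool = False,
) -> ModelReport:
    """Run one model stage end to end on a record set.

    Model 3 needs the model-1 and model-2 reports; pass them via
    ``upstream={1: report1, 2: report2}`` or they are computed on the
    fly. When ``out_dir`` is given the report bundle is written there.
    """
    if model_id == 3:
        upstream = dict(upstream or {})
        missing = [m for m in (1, 2) if m not in upstream]
        for m in missing:
            upstream[m] = run_model(m, records, cfg)
        pairs = metareg.effect_pairs(upstream[1].summaries, upstream[2].summaries)
        if len(pairs) < 3:
            raise ValueError(
                f"model 3 needs >= 3 crops represented in both models 1 and 2, got {len(pairs)}"
            )
        res = metareg.fit_effect_regression(pairs, cfg.prior, cfg.mcmc)
        rhat = res.samples.rhat_table()
        report = ModelReport(
            model_id=3,
            summaries=[res.intercept, res.slope],
            rhat=rhat,
            drop_report={},
            n_obs=len(pairs),
            samples=res.samples,
            extras={"pairs": res.pairs},
        )
    elif model_id in (1, 2, 4, 5):
        design, samples = _fit_mixed(records, model_id, cfg)
        rhat = samples.rhat_table()
        if model_id in (1, 2):
            summaries = posterior.crop_contrasts(samples, design)
            extras = {}
        else:
            slope = posterior.summarize(
                "per consecutive cotton year", samples.pooled("consec_cotton")
            )
            species = posterior.summarize(
                "species upland-pima", samples.pooled("species_upland")
            )
            summaries = [slope, species]
            extras = {}
            if model_id == 4:
                baseline = (
                    cfg.percent_baseline
                    if cfg.percent_baseline is not None
                    else float(design.response.mean())
                )
                _, pct = posterior.percent_change(
                    samples.pooled("consec_cotton"), baseline
                )
                extras = {"percent_change": pct, "percent_baseline": baseline}
        report = ModelReport(
            model_id=model_id,
            summaries=summaries,
            rhat=rhat,
            drop_report=design.drop_report,
            n_obs=design.n_obs,
            samples=samples,
            extras=extras,
        )
    else:
        raise ValueError(f"model_id must be in 1..5, got {model_id}")

    if out_dir is not None:
        _write_report(report, cfg, out_dir, plot=plot)
    return report


def _write_report(report: ModelReport, cfg: PipelineConfig, out_dir, plot=False):
    os.makedirs(out_dir, exist_ok=True)
    posterior.contrast_table(report.summaries).to_csv(
        os.path.join(out_dir, f"model{report.model_id}_contrasts.csv"), index=False
    )
    with open(os.path.join(out_dir, f"model{report.model_id}_rhat.json"), "w") as fh:
        json.dump(
            {k: (None if v is None or math.isnan(v) else v) for k, v in report.rhat.items()},
            fh,
            indent=2,
        )
    with open(os.path.join(out_dir, f"model{report.model_id}_drop_report.json"), "w") as fh:
        json.dump({"n_obs": report.n_obs, **report.drop_report}, fh, indent=2)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
    if report.model_id == 3:
        rows = [
            {"crop": p.crop, "yield_effect": p.yield_effect, "lygus_effect": p.lygus_effect}
            for p in report.extras["pairs"]
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "effect_pairs.csv"), index=False)
    if report.model_id == 4 and "percent_change" in report.extras:
        pct = report.extras["percent_change"]
        with open(os.path.join(out_dir, "model4_percent_change.json"), "w") as fh:
            json.dump(
                {
                    "baseline_kg_ha": report.extras["percent_baseline"],
                    "post_mean_pct_per_year": pct.post_mean,
                    "hpdi_low": pct.hpdi_low,
                    "hpdi_high": pct.hpdi_high,
                },
                fh,
                indent=2,
            )
    if plot:
        _plot_report(report, out_dir)


def _plot_report(report: ModelReport, out_dir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    if report.model_id == 3:
        pairs = report.extras["pairs"]
        x = np.array([p.lygus_effect for p in pairs])
        y = np.array([p.yield_effect for p in pairs])
        ax.scatter(x, y, facecolors="none", edgecolors="k")
        icpt, slope = report.summaries[0].post_mean, report.summaries[1].post_mean
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, icpt + slope * xs, "k-")
        ax.set_xlabel("effect on June L. hesperus (insects/sweep)")
        ax.set_ylabel("effect on yield (kg/ha)")
    else:
        avail = [s for s in report.summaries if s.available]
        ys = np.arange(len(avail))
        ax.errorbar(
            [s.post_mean for s in avail],
            ys,
            xerr=[
                [s.post_mean - s.hpdi_low for s in avail],
                [s.hpdi_high - s.post_mean for s in avail],
            ],
            fmt="o",
            color="k",
            capsize=2,
        )
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_yticks(ys)
        ax.set_yticklabels([s.label for s in avail])
        ax.set_xlabel("posterior mean and 95% HPDI")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, f"model{report.model_id}.png"), dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class RecoveryConfig:
    """A parameter-recovery suite: replicate datasets from ``sim``
    (reseeded per replicate), each fitted with ``mcmc`` and scored
    against ground truth."""

    n_replicates: int = 50
    sim: synthetic.SimConfig = synthetic.SimConfig(
        n_fields=200, year_start=2000, year_end=2005, n_records=700
    )
    prior: PriorSpec = PriorSpec()
    mcmc: McmcConfig = McmcConfig(n_chains=3, n_iter=2000, n_burn=1000)
    models: tuple = (1, 4)
    master_seed: int = 0
    matched_regimes: bool = True


def run_recovery(suite: RecoveryConfig, out_path=None) -> dict:
    """Run the suite and score coverage, bias and convergence.

    Per replicate and model: 95% HPDI coverage of every true contrast,
    the posterior-mean error of the consecutive-cotton slope (model 4),
    and whether all reported R-hats are below 1.1. The report carries
    per-replicate rows plus the aggregates the calibration claims rest
    on.

    With ``matched_regimes`` (the default) each model is scored on data
    generated under that model's own assumptions: the first-year-crop
    models (1/2) on replicates with the consecutive-planting effects
    switched off, the consecutive-planting models (4/5) on the full
    regime (whose crop effects never touch their cotton-run rows). A
    calibration check is only meaningful when the fitted model matches
    the generative one; on mixed-regime data the crop-contrast estimand
    is shifted by the run effect on the cotton baseline, which measures
    prior-data conflict rather than the correctness of the machinery.
    """
    ss = np.random.SeedSequence(suite.master_seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * suite.n_replicates)]
    rows = []
    cover_events: list[bool] = []
    crop_cover: list[bool] = []
    consec_cover: list[bool] = []
    consec_err: list[float] = []
    rhat_ok: list[bool] = []

    firstyear_sim = (
        dataclasses.replace(suite.sim, consec_cotton_effect=0.0, lygus_consec_effect=0.0)
        if suite.matched_regimes
        else suite.sim
    )

    for r in range(suite.n_replicates):
        sim_cfg = dataclasses.replace(suite.sim, master_seed=rep_seeds[2 * r])
        records, truth = synthetic.generate(sim_cfg)
        if suite.matched_regimes and any(m in (1, 2) for m in suite.models):
            fy_cfg = dataclasses.replace(firstyear_sim, master_seed=rep_seeds[2 * r])
            fy_records, fy_truth = synthetic.generate(fy_cfg)
        else:
            fy_records, fy_truth = records, truth
        mcmc = dataclasses.replace(suite.mcmc, master_seed=rep_seeds[2 * r + 1])
        cfg = PipelineConfig(prior=suite.prior, mcmc=mcmc)
        row: dict = {"replicate": r}
        for model_id in suite.models:
            if model_id in (1, 2):
                records_m, truth_m = fy_records, fy_truth
            else:
                records_m, truth_m = records, truth
            report = run_model(model_id, records_m, cfg)
            rhat_ok_model = report.converged
            rhat_ok.append(rhat_ok_model)
            if model_id in (1, 2):
                response = "yield" if model_id == 1 else "lygus"
                mask = _fitted_mask(records_m, truth_m, model_id, cfg)
                truths = truth_m.contrast_truth(response, record_mask=mask)
                n_cov = 0
                n_eff = 0
                for s in report.summaries:
                    if not s.available or s.label not in truths:
                        continue
                    tv = truths[s.label]
                    hit = s.hpdi_low <= tv <= s.hpdi_high
                    cover_events.append(hit)
                    if s.label.endswith(" vs cotton"):
                        crop_cover.append(hit)
                    n_cov += hit
                    n_eff += 1
                row[f"model{model_id}_covered"] = n_cov
                row[f"model{model_id}_n_effects"] = n_eff
            elif model_id in (4, 5):
                tv = (
                    truth_m.consec_cotton_effect
                    if model_id == 4
                    else truth_m.lygus_consec_effect
                )
                slope = report.summaries[0]
                hit = slope.hpdi_low <= tv <= slope.hpdi_high
                consec_cover.append(hit)
                cover_events.append(hit)
                if model_id == 4:
                    crop_cover.append(hit)  # the scored slope joins the calibration pool
                consec_err.append(slope.post_mean - tv)
                row[f"model{model_id}_slope_mean"] = slope.post_mean
                row[f"model{model_id}_slope_true"] = tv
            row[f"model{model_id}_max_rhat"] = report.max_rhat
        rows.append(row)

    result = {
        "n_replicates": suite.n_replicates,
        "models": list(suite.models),
        "coverage_all_effects": float(np.mean(cover_events)) if cover_events else None,
        "n_coverage_events": len(cover_events),
        "coverage_crop_and_consec": float(np.mean(crop_cover)) if crop_cover else None,
        "n_crop_and_consec_events": len(crop_cover),
        "consec_slope_coverage": float(np.mean(consec_cover)) if consec_cover else None,
        "consec_slope_mean_bias": float(np.mean(consec_err)) if consec_err else None,
        "consec_slope_true": suite.sim.consec_cotton_effect,
        "rhat_ok_fraction": float(np.mean(rhat_ok)) if rhat_ok else None,
        "replicates": rows,
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(result, fh, indent=2)
    return result


def _fitted_mask(records, truth, model_id, cfg: PipelineConfig):
    """Boolean mask over truth.record_meta rows for the records the
    model actually fitted (mirrors the design's drop rules)."""
    meta = truth.record_meta
    keyed = {(r.field_id, r.year): r for r in records}
    mask = []
    for _, row in meta.iterrows():
        rec: FieldYearRecord = keyed[(row["field_id"], row["year"])]
        ok = rec.surrounding_counts is not None
        if model_id in (1, 4):
            ok = ok and rec.yield_kg_ha is not None
        if model_id in (2, 5):
            from .preprocess import mean_density

            ok = ok and mean_density(rec.lygus_samples, cfg.window) is not None
        if model_id in (1, 2):
            ok = ok and bool(rec.rotation_history) and rec.rotation_history[0] is not None
        mask.append(ok)
    return np.array(mask)


def load_and_check(records_path, lygus_path=None):
    """Read a record set and fail loudly on invariant violations."""
    records = read_records(records_path, lygus_path)
    violations = validate(records)
    if violations:
        head = "; ".join(v.message for v in violations[:5])
        raise ValueError(f"{len(violations)} record validation failures: {head} ...")
    return records
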