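"""Synthetic field-year record sets with known ground truth.

The commercial grower/consultant database behind this analysis is
proprietary, so the pipeline ships its own generative counterpart: a
simulator producing record sets with the same statistical structure the
models assume — clustering by field and year, 15-crop rotation
histories with realistic persistence, adjacent-landscape composition,
two cotton species, weekly June–July sweep-net samples around a latent
seasonal density, and the observed pattern of yield and adjacency
missingness. Every effect the models estimate has a known true value,
so parameter-recovery and calibration tests can score the whole
pipeline end to end.

Generative model (per record, field *j*, year *t*)::

    yield  = base + species*upland + crop_effect[prior] + consec_effect*run
             + sum_c adj_coef[c]*adj_count[c] + u_j + v_t + N(0, sigma_resid)
    june   = base_L + species_L*upland + crop_effect_L[prior]
             + consec_effect_L*run + uL_j + vL_t + N(0, sigma_resid_L)

with cotton the reference crop (effect 0) and ``run`` the consecutive
prior cotton plantings (capped at 4). Sweep samples are emitted weekly
around ``june * shape(day)`` where the seasonal shape averages to 1 over
June, so the window-averaging step is unbiased for the latent June mean.
Crop yield effects are tied to crop pest effects through a linear
relation with configurable slope, which is what makes the second-stage
effect regression testable with a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import CROPS, FieldYearRecord

NON_COTTON = tuple(c for c in CROPS if c != "cotton")

#: San Joaquin Valley-flavoured landscape frequencies: cotton dominates,
#: the rest of the vocabulary shares the remainder unevenly.
DEFAULT_CROP_FREQ = {
    "cotton": 0.40,
    "alfalfa": 0.07,
    "tomatoes": 0.08,
    "wheat": 0.09,
    "corn": 0.05,
    "safflower": 0.04,
    "garlic": 0.03,
    "onions": 0.03,
    "lettuce": 0.03,
    "melons": 0.03,
    "carrots": 0.03,
    "barley": 0.03,
    "garbanzo": 0.03,
    "potatoes": 0.03,
    "sugarbeets": 0.03,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic record set.

    Size defaults mirror the real database's marginals: 1498 field-year
    records from 566 fields over 1997–2008, yield observed for
    1240/1498 and adjacency for 1026/1498. Yield-scale defaults put
    Pima lint yield near 1450 kg/ha with field, year and residual
    standard deviations of a few hundred kg/ha; pest-scale defaults put
    mean June densities under one insect per sweep.

    ``crop_lygus_effects``/``crop_yield_effects`` may be given
    explicitly (14 non-cotton crops each); when ``None`` the pest
    effects are drawn from Normal(``lygus_effect_mean``,
    ``lygus_effect_sd``²) and the yield effects derived through
    ``effect_intercept + effect_slope * pest_effect`` plus
    Normal(0, ``effect_noise_sd``²) noise — the hook that gives the
    effect regression a known slope.
    """

    # size and span
    n_fields: int = 566
    year_start: int = 1997
    year_end: int = 2008
    n_records: int = 1498
    # species mix and yield scale (kg/ha)
    p_upland: float = 0.6
    base_yield: float = 1450.0
    species_effect: float = 160.0
    sigma_field: float = 250.0
    sigma_year: float = 150.0
    sigma_resid: float = 250.0
    # crop effects
    crop_yield_effects: Optional[dict] = None
    crop_lygus_effects: Optional[dict] = None
    effect_intercept: float = 30.0
    effect_slope: float = -300.0
    effect_noise_sd: float = 40.0
    lygus_effect_mean: float = 0.12
    lygus_effect_sd: float = 0.28
    consec_cotton_effect: float = -40.0
    # adjacency nuisance (kg/ha per neighbouring field of a crop)
    adj_effect_sd: float = 3.0
    # pest scale (insects/sweep)
    lygus_base: float = 0.8
    lygus_species_effect: float = -0.33
    lygus_consec_effect: float = 0.04
    lygus_sigma_field: float = 0.25
    lygus_sigma_year: float = 0.12
    lygus_sigma_resid: float = 0.18
    # rotation process
    crop_freq: Optional[dict] = None
    rotation_transition: float = 0.5
    history_len_p: float = 0.2
    adj_prior_bias: float = 0.0
    # sweep sampling
    sample_start_day: int = 150
    sample_end_day: int = 212
    sample_interval: int = 7
    seasonal_shape: str = "ramp"
    seasonal_ramp: float = 0.01
    sampling_noise_sd: float = 0.15
    noise_model: str = "truncnorm"
    # missingness (defaults are the observed marginal rates)
    p_yield_missing: float = 258 / 1498
    p_adj_missing: float = 472 / 1498
    master_seed: int = 0

    def __post_init__(self):
        sds = (
            self.sigma_field, self.sigma_year, self.sigma_resid,
            self.lygus_sigma_field, self.lygus_sigma_year, self.lygus_sigma_resid,
            self.effect_noise_sd, self.lygus_effect_sd, self.adj_effect_sd,
            self.sampling_noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")
        probs = (
            self.p_upland, self.p_yield_missing, self.p_adj_missing,
            self.rotation_transition, self.adj_prior_bias,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.history_len_p <= 1:
            raise ValueError("history_len_p must lie in (0, 1]")
        if self.n_records < 1 or self.n_fields < 1:
            raise ValueError("n_records and n_fields must be >= 1")
        n_years = self.year_end - self.year_start + 1
        if n_years < 1:
            raise ValueError("year span must contain at least one year")
        if self.n_records > self.n_fields * n_years:
            raise ValueError("n_records exceeds the number of distinct field-years")
        for d, label in ((self.crop_yield_effects, "crop_yield_effects"),
                         (self.crop_lygus_effects, "crop_lygus_effects")):
            if d is not None and set(d) != set(NON_COTTON):
                raise ValueError(f"{label} must have exactly the 14 non-cotton crops as keys")
        if self.seasonal_shape not in ("ramp", "constant"):
            raise ValueError("seasonal_shape must be 'ramp' or 'constant'")
        if self.noise_model not in ("truncnorm", "poisson"):
            raise ValueError("noise_model must be 'truncnorm' or 'poisson'")
        if self.crop_freq is not None:
            if set(self.crop_freq) != set(CROPS) or any(v < 0 for v in self.crop_freq.values()):
                raise ValueError("crop_freq must give a non-negative weight to all 15 crops")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass
class GroundTruth:
    """Realized generative state, keyed for comparison against fits.

    ``record_meta`` is a per-record frame (field_id, year, species,
    prior crop, true consecutive-cotton run, latent June mean, noiseless
    yield component) used to compute the exact estimand of each model on
    any subset of the records.
    """

    config: SimConfig
    crop_yield_effects: dict
    crop_lygus_effects: dict
    species_effect: float
    lygus_species_effect: float
    consec_cotton_effect: float
    lygus_consec_effect: float
    adj_yield_coefs: dict
    field_effects: dict
    year_effects: dict
    lygus_field_effects: dict
    lygus_year_effects: dict
    record_meta: pd.DataFrame = dc_field(repr=False, default=None)

    def contrast_truth(
        self, response: str = "yield", record_mask=None
    ) -> dict:
        """Exact estimand of each cotton-baseline contrast on a subset.

        The first-year-contrast models compare rows whose previous crop
        was X against rows whose previous crop was cotton; among the
        latter, longer consecutive-cotton runs shift the response by the
        run effect. The estimand of "X vs cotton" is therefore
        ``crop_effect[X] - run_effect * mean(run | prior cotton)`` on
        the rows actually fitted, which this method computes from the
        realized records (``record_mask`` selects the fitted subset).
        """
        meta = self.record_meta
        if record_mask is not None:
            meta = meta.loc[record_mask]
        cotton_rows = meta[meta["prior_crop"] == "cotton"]
        mean_run = float(cotton_rows["consec_cotton"].mean()) if len(cotton_rows) else 0.0
        if response == "yield":
            effects, run_eff = self.crop_yield_effects, self.consec_cotton_effect
        elif response == "lygus":
            effects, run_eff = self.crop_lygus_effects, self.lygus_consec_effect
        else:
            raise ValueError("response must be 'yield' or 'lygus'")
        out = {f"{c} vs cotton": effects[c] - run_eff * mean_run for c in NON_COTTON}
        out["species upland-pima"] = (
            self.species_effect if response == "yield" else self.lygus_species_effect
        )
        return out


def truth_table(truth: GroundTruth, response: str = "yield", record_mask=None) -> pd.DataFrame:
    """Tabulate true effect values under the labels the fitted-model
    summaries use, for recovery scoring."""
    d = truth.contrast_truth(response, record_mask)
    rows = [{"label": k, "true_value": v} for k, v in d.items()]
    rows.append(
        {
            "label": "per consecutive cotton year",
            "true_value": truth.consec_cotton_effect
            if response == "yield"
            else truth.lygus_consec_effect,
        }
    )
    return pd.DataFrame(rows)


def _allocate_record_counts(rng, cfg: SimConfig) -> np.ndarray:
    """Per-field record counts: geometric (most fields appear 1–3 times),
    clipped to the year span, then adjusted to sum exactly to n_records."""
    mean_per_field = cfg.n_records / cfg.n_fields
    p = min(1.0, 1.0 / max(mean_per_field, 1.0))
    counts = np.clip(rng.geometric(p, size=cfg.n_fields), 1, cfg.n_years)
    diff = cfg.n_records - int(counts.sum())
    order = rng.permutation(cfg.n_fields)
    k = 0
    while diff != 0:
        i = order[k % cfg.n_fields]
        if diff > 0 and counts[i] < cfg.n_years:
            counts[i] += 1
            diff -= 1
        elif diff < 0 and counts[i] > 1:
            counts[i] -= 1
            diff += 1
        k += 1
    return counts


def _draw_crop(rng, freq_crops, freq_probs):
    return freq_crops[rng.choice(len(freq_crops), p=freq_probs)]


def generate(config: SimConfig):
    """Generate one record set; returns ``(records, GroundTruth)``.

    Deterministic given ``master_seed``: identical configs give
    byte-identical records. Generated records always pass
    :func:`rotabayes.records.validate`.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed))
    years = list(range(cfg.year_start, cfg.year_end + 1))

    freq = dict(cfg.crop_freq) if cfg.crop_freq is not None else dict(DEFAULT_CROP_FREQ)
    total = sum(freq.values())
    freq_crops = list(CROPS)
    freq_probs = np.array([freq[c] / total for c in freq_crops])

    # crop effects (drawn unless pinned by config)
    if cfg.crop_lygus_effects is not None:
        lyg_eff = dict(cfg.crop_lygus_effects)
    else:
        lyg_eff = {
            c: float(rng.normal(cfg.lygus_effect_mean, cfg.lygus_effect_sd))
            for c in NON_COTTON
        }
    if cfg.crop_yield_effects is not None:
        yld_eff = dict(cfg.crop_yield_effects)
    else:
        yld_eff = {
            c: float(
                cfg.effect_intercept
                + cfg.effect_slope * lyg_eff[c]
                + rng.normal(0, cfg.effect_noise_sd)
            )
            for c in NON_COTTON
        }
    adj_coefs = {c: float(rng.normal(0, cfg.adj_effect_sd)) for c in CROPS}

    field_ids = [f"F{i:04d}" for i in range(cfg.n_fields)]
    species = {
        f: ("upland" if rng.random() < cfg.p_upland else "pima") for f in field_ids
    }
    u = {f: float(rng.normal(0, cfg.sigma_field)) for f in field_ids}
    uL = {f: float(rng.normal(0, cfg.lygus_sigma_field)) for f in field_ids}
    v = {t: float(rng.normal(0, cfg.sigma_year)) for t in years}
    vL = {t: float(rng.normal(0, cfg.lygus_sigma_year)) for t in years}

    counts = _allocate_record_counts(rng, cfg)

    records: list[FieldYearRecord] = []
    meta_rows = []
    for fi, f in enumerate(field_ids):
        record_years = sorted(
            int(y) for y in rng.choice(years, size=int(counts[fi]), replace=False)
        )
        record_set = set(record_years)
        # crop trajectory over the field's full past, cotton forced in
        # record years (the database only contains cotton crops)
        traj: dict[int, str] = {}
        prev = None
        for t in range(cfg.year_start - 10, cfg.year_end + 1):
            if t in record_set:
                crop = "cotton"
            elif prev is not None and rng.random() < cfg.rotation_transition:
                crop = prev
            else:
                crop = _draw_crop(rng, freq_crops, freq_probs)
            traj[t] = crop
            prev = crop

        for t in record_years:
            full_hist = [traj[t - k] for k in range(1, 11)]
            hist_len = int(min(10, rng.geometric(cfg.history_len_p)))
            history = tuple(full_hist[:hist_len])

            run = 0
            for crop in full_hist[:4]:
                if crop != "cotton":
                    break
                run += 1
            prior = full_hist[0]

            # adjacent landscape: 8 neighbours from the frequency vector,
            # optionally biased toward the focal field's prior crop
            neighbors = []
            for _ in range(8):
                if cfg.adj_prior_bias > 0 and rng.random() < cfg.adj_prior_bias:
                    neighbors.append(prior)
                else:
                    neighbors.append(_draw_crop(rng, freq_crops, freq_probs))
            adj = {c: 0 for c in CROPS}
            for c in neighbors:
                adj[c] += 1

            upland = 1.0 if species[f] == "upland" else 0.0
            crop_term = yld_eff.get(prior, 0.0)  # cotton -> 0 (reference)
            adj_term = sum(adj_coefs[c] * adj[c] for c in CROPS)
            mean_yield = (
                cfg.base_yield
                + cfg.species_effect * upland
                + crop_term
                + cfg.consec_cotton_effect * run
                + adj_term
                + u[f]
                + v[t]
            )
            yield_val = mean_yield + float(rng.normal(0, cfg.sigma_resid))
            yield_val = max(yield_val, 1.0)  # lint yield must stay positive

            june = (
                cfg.lygus_base
                + cfg.lygus_species_effect * upland
                + lyg_eff.get(prior, 0.0)
                + cfg.lygus_consec_effect * run
                + uL[f]
                + vL[t]
                + float(rng.normal(0, cfg.lygus_sigma_resid))
            )
            june = max(june, 0.02)  # densities cannot be negative

            offset = int(rng.integers(0, cfg.sample_interval))
            days = list(
                range(cfg.sample_start_day + offset, cfg.sample_end_day + 1, cfg.sample_interval)
            )
            samples = []
            for d in days:
                if cfg.seasonal_shape == "constant":
                    latent = june
                else:
                    # linear ramp whose trapezoid average over June is
                    # exactly 1, so the June window mean recovers `june`
                    latent = june * (1.0 + cfg.seasonal_ramp * (d - 166.5))
                latent = max(latent, 0.0)
                if cfg.noise_model == "poisson":
                    obs = rng.poisson(latent * 50) / 50.0
                else:
                    obs = max(0.0, latent + float(rng.normal(0, cfg.sampling_noise_sd)))
                samples.append((d, float(obs)))

            yield_missing = rng.random() < cfg.p_yield_missing
            adj_missing = rng.random() < cfg.p_adj_missing

            records.append(
                FieldYearRecord(
                    field_id=f,
                    year=t,
                    species=species[f],
                    yield_kg_ha=None if yield_missing else float(yield_val),
                    rotation_history=history,
                    surrounding_counts=None if adj_missing else adj,
                    lygus_samples=tuple(samples),
                )
            )
            meta_rows.append(
                {
                    "field_id": f,
                    "year": t,
                    "species": species[f],
                    "prior_crop": prior,
                    "consec_cotton": run,
                    "latent_june_mean": june,
                    "mean_yield": mean_yield,
                    "yield_observed": not yield_missing,
                    "adj_observed": not adj_missing,
                }
            )

    truth = GroundTruth(
        config=cfg,
        crop_yield_effects=yld_eff,
        crop_lygus_effects=lyg_eff,
        species_effect=cfg.species_effect,
        lygus_species_effect=cfg.lygus_species_effect,
        consec_cotton_effect=cfg.consec_cotton_effect,
        lygus_consec_effect=cfg.lygus_consec_effect,
        adj_yield_coefs=adj_coefs,
        field_effects=u,
        year_effects=v,
        lygus_field_effects=uL,
        lygus_year_effects=vL,
        record_meta=pd.DataFrame(meta_rows),
    )
    return records, truth


def small_fixture_config(master_seed: int = 20240204) -> SimConfig:
    """A fast, fully-representative test configuration (~200 records).

    Every non-cotton crop gets a uniform share of the non-cotton
    landscape so that all 14 contrasts are exercised even at this size.
    """
    freq = {c: (0.35 if c == "cotton" else 0.65 / 14) for c in CROPS}
    return SimConfig(
        n_fields=50,
        year_start=2001,
        year_end=2006,
        n_records=200,
        crop_freq=freq,
        history_len_p=0.15,
        p_yield_missing=0.1,
        p_adj_missing=0.1,
        master_seed=master_seed,
    )
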