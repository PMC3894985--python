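"""Second-stage regression of yield effects on pest effects.

For each of the 14 crops other than cotton, stage one produces two
posterior-mean contrasts vs. the cotton baseline: the effect of growing
that crop the year before on lint yield, and on mean June *L. hesperus*
density. Stage two regresses the yield effects on the pest effects with
a Bayesian simple linear model — the degenerate mixed model with no
random-effect groups, so the sampler is reused unchanged. A negative
slope supports the hypothesis that rotation crops favouring the pest
depress the following cotton crop's yield.

Regressing point estimates discards their posterior uncertainty; a
draw-pairing sensitivity mode refits the regression across random joint
draws from the stage-one posteriors to show how much that matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hblm import McmcConfig, PosteriorSamples, PriorSpec, gibbs_fit
from .preprocess import ModelDesign
from .posterior import ContrastSummary, summarize


@dataclass(frozen=True)
class EffectPair:
    """Posterior-mean yield and pest contrasts for one non-cotton crop."""

    crop: str
    yield_effect: float
    lygus_effect: float

    def __post_init__(self):
        if self.crop == "cotton":
            raise ValueError("the cotton baseline has no contrast with itself")
        if not (np.isfinite(self.yield_effect) and np.isfinite(self.lygus_effect)):
            raise ValueError(f"effects for {self.crop!r} must be finite")


@dataclass
class EffectRegressionResult:
    samples: PosteriorSamples
    slope: ContrastSummary
    intercept: ContrastSummary
    pairs: list


def effect_pairs(yield_summaries, lygus_summaries) -> list:
    """Join the two stage-one contrast lists on crop label.

    Only crops available in both models form a pair; the species rows
    are ignored.
    """
    def crops_of(summaries):
        out = {}
        for s in summaries:
            if s.label.endswith(" vs cotton") and s.available:
                crop = s.label[: -len(" vs cotton")]
                if crop != "cotton":
                    out[crop] = s.post_mean
        return out

    ymap = crops_of(yield_summaries)
    lmap = crops_of(lygus_summaries)
    return [
        EffectPair(crop, ymap[crop], lmap[crop])
        for crop in sorted(set(ymap) & set(lmap))
    ]


def _regression_design(x: np.ndarray, y: np.ndarray) -> ModelDesign:
    X = np.column_stack([np.ones_like(x), x])
    return ModelDesign(
        model_id=3,
        response=y,
        response_name="yield_effect_kg_ha",
        fixed_names=["intercept", "slope"],
        fixed_matrix=X,
        field_index=None,
        year_index=None,
    )


def fit_effect_regression(
    pairs,
    prior: PriorSpec = PriorSpec(),
    config: McmcConfig = McmcConfig(),
) -> EffectRegressionResult:
    """Gibbs-sample the conjugate Normal linear model on the effect pairs.

    Intercept and slope get Normal(0, ``beta_sd``²) priors and the
    residual variance the usual InvGamma(0.001, 0.001). Returns the
    slope and intercept summaries (posterior mean, 95% HPDI, sign
    probability) alongside the raw draws.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 effect pairs, got {len(pairs)}")
    x = np.array([p.lygus_effect for p in pairs], dtype=float)
    y = np.array([p.yield_effect for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all pest effects are identical; the slope is unidentifiable")
    design = _regression_design(x, y)
    samples = gibbs_fit(design, prior, config)
    return EffectRegressionResult(
        samples=samples,
        slope=summarize("slope", samples.pooled("slope")),
        intercept=summarize("intercept", samples.pooled("intercept")),
        pairs=pairs,
    )


def fit_effect_regression_draws(
    yield_samples: PosteriorSamples,
    lygus_samples: PosteriorSamples,
    crops,
    prior: PriorSpec = PriorSpec(),
    config: McmcConfig = McmcConfig(),
    n_pairings: int = 50,
    seed: int = 0,
) -> list:
    """Uncertainty-propagating sensitivity mode.

    Instead of regressing posterior means, draw ``n_pairings`` random
    joint stage-one draws and refit the regression on each; returns the
    list of slope posterior means across pairings. Their spread shows
    how much the point-estimate shortcut understates uncertainty.
    """
    rng = np.random.default_rng(seed)
    ny = yield_samples.pooled(f"prior_{crops[0]}").size
    nl = lygus_samples.pooled(f"prior_{crops[0]}").size
    slopes = []
    for k in range(n_pairings):
        iy, il = rng.integers(ny), rng.integers(nl)
        pairs = [
            EffectPair(
                c,
                float(yield_samples.pooled(f"prior_{c}")[iy]),
                float(lygus_samples.pooled(f"prior_{c}")[il]),
            )
            for c in crops
        ]
        sub = McmcConfig(
            n_chains=config.n_chains,
            n_iter=config.n_iter,
            n_burn=config.n_burn,
            master_seed=int(rng.integers(2**31 - 1)),
        )
        slopes.append(fit_effect_regression(pairs, prior, sub).slope.post_mean)
    return slopes
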