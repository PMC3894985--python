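"""Posterior summaries: HPDIs, baseline contrasts, sign probabilities.

Every effect is reported the same way: posterior mean on the response
scale, 95% highest-posterior-density interval, and the posterior
probability that the effect is negative. With cotton-reference coding in
the designs, each prior-crop coefficient already *is* the contrast
"that crop grown the year before vs. cotton grown the year before", so
no recombination of draws is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hblm import PosteriorSamples
from .preprocess import ModelDesign
from .records import CROPS


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior mean, 95% HPDI and sign probability for one effect.

    ``available`` is False when the underlying design column was dropped
    (no records with that prior crop); the numeric fields are then NaN.
    """

    label: str
    post_mean: float
    hpdi_low: float
    hpdi_high: float
    prob_negative: float
    available: bool = True

    @property
    def excludes_zero(self) -> bool:
        return self.available and (self.hpdi_low > 0 or self.hpdi_high < 0)


def hpdi(draws, mass: float = 0.95):
    """Highest-posterior-density interval of a draw vector.

    The narrowest contiguous window of the sorted draws containing
    ``ceil(mass * n)`` of them; ties go to the leftmost window.
    ``mass = 1`` returns ``(min, max)`` exactly.
    """
    if not 0 < mass <= 1:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    m = min(n, math.ceil(mass * n))
    if m < 2:
        raise ValueError(f"need at least 2 draws inside the interval, got {m}")
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: leftmost rule
    return float(x[i]), float(x[i + m - 1])


def sign_probability(draws) -> float:
    """Fraction of draws strictly below zero (draws at exactly 0 count
    as non-negative)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("sign_probability needs at least one draw")
    return float(np.mean(x < 0))


def summarize(label: str, draws, mass: float = 0.95) -> ContrastSummary:
    """Build a :class:`ContrastSummary` from pooled draws."""
    x = np.asarray(draws, dtype=float)
    lo, hi = hpdi(x, mass)
    return ContrastSummary(
        label=label,
        post_mean=float(np.mean(x)),
        hpdi_low=lo,
        hpdi_high=hi,
        prob_negative=sign_probability(x),
    )


def _unavailable(label: str) -> ContrastSummary:
    nan = float("nan")
    return ContrastSummary(label, nan, nan, nan, nan, available=False)


def crop_contrasts(
    samples: PosteriorSamples,
    design: ModelDesign,
    mass: float = 0.95,
    include_reference: bool = False,
) -> list:
    """Per-crop contrasts vs. the cotton baseline, plus the species effect.

    One summary per non-cotton prior-crop coefficient (draws pooled
    across chains) and one for the upland-minus-pima species effect.
    Crops dropped from the design are returned marked unavailable. With
    ``include_reference`` the degenerate cotton-vs-cotton contrast
    (exactly 0, zero-width interval) is prepended.
    """
    out: list[ContrastSummary] = []
    if include_reference:
        out.append(ContrastSummary("cotton vs cotton", 0.0, 0.0, 0.0, 0.0))
    for crop in CROPS:
        if crop == "cotton":
            continue
        name = f"prior_{crop}"
        label = f"{crop} vs cotton"
        if name in samples.beta_names:
            out.append(summarize(label, samples.pooled(name), mass))
        elif name in design.dropped_columns:
            out.append(_unavailable(label))
    if "species_upland" in samples.beta_names:
        out.append(summarize("species upland-pima", samples.pooled("species_upland"), mass))
    return out


def percent_change(slope_draws, baseline: float, mass: float = 0.95):
    """Convert slope draws (kg/ha per year) to percent-per-year.

    Divides each draw by ``baseline`` (kg/ha, must be > 0) and scales by
    100; returns the transformed draws and their summary.
    """
    if not baseline > 0:
        raise ValueError(f"baseline yield must be > 0, got {baseline}")
    pct = np.asarray(slope_draws, dtype=float) * 100.0 / baseline
    return pct, summarize("percent change per year", pct, mass)


def contrast_table(summaries) -> pd.DataFrame:
    """Tabulate summaries (one row per effect) for CSV output; ``flagged``
    marks HPDIs that exclude zero."""
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "post_mean": s.post_mean,
                "hpdi_low": s.hpdi_low,
                "hpdi_high": s.hpdi_high,
                "prob_negative": s.prob_negative,
                "available": s.available,
                "flagged": s.excludes_zero,
            }
            for s in summaries
        ]
    )
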