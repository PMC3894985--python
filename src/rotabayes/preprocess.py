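"""Turn raw field-year records into model-ready responses and designs.

Responses
---------
* Lint yield (kg/ha), used directly.
* Mean June *L. hesperus* density (insects/sweep): because consultants
  sampled on irregular dates, successive sweep samples are reduced to a
  window average by integrating the piecewise-linear density-versus-time
  curve over the window and dividing by the days covered.

Designs
-------
Four linear-mixed-model designs share the crossed field/year grouping:

=====  ==========================  ======================================
model  response                    fixed effects
=====  ==========================  ======================================
1      yield                       intercept, prior-crop indicators
                                   (cotton = reference), species,
                                   15 surrounding-crop counts
2      mean June Lygus density     as model 1
4      yield                       intercept, consecutive prior cotton
                                   plantings (1–4), species, surrounding
                                   cotton count
5      mean June Lygus density     as model 4
=====  ==========================  ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import CROPS, N_NEIGHBORS, FieldYearRecord


@dataclass(frozen=True)
class JuneWindow:
    """Inclusive day-of-year window over which pest density is averaged."""

    start_day: int = 152
    end_day: int = 181

    def __post_init__(self):
        if not self.start_day < self.end_day:
            raise ValueError("window start_day must be < end_day")


#: Calendar June of a non-leap year.
JUNE = JuneWindow(152, 181)


@dataclass
class ModelDesign:
    """Response, fixed-effect matrix and grouping indices for one model.

    ``field_index``/``year_index`` are dense integer codes into
    ``field_levels``/``year_levels``; ``None`` means the corresponding
    random effect is absent (used by the effect meta-regression).
    """

    model_id: int
    response: np.ndarray
    response_name: str
    fixed_names: list
    fixed_matrix: np.ndarray
    field_index: Optional[np.ndarray]
    year_index: Optional[np.ndarray]
    field_levels: list = field(default_factory=list)
    year_levels: list = field(default_factory=list)
    drop_report: dict = field(default_factory=dict)
    dropped_columns: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.response)

    @property
    def n_fixed(self) -> int:
        return self.fixed_matrix.shape[1]


def mean_density(samples, window: JuneWindow = JUNE) -> Optional[float]:
    """Window-average pest density from dated sweep samples.

    Integrates the piecewise-linear interpolant of density versus
    day-of-year over the intersection of the sampled span with *window*
    (trapezoid rule) and divides by the days covered. Samples outside the
    window contribute only through interpolated boundary values. A single
    covered day returns the (interpolated) density on that day. Returns
    ``None`` when the samples do not reach the window — the record is
    then excluded from density models.
    """
    if len(samples) == 0:
        return None
    pts = sorted((float(d), float(v)) for d, v in samples)
    days = np.array([p[0] for p in pts])
    dens = np.array([p[1] for p in pts])
    lo = max(float(window.start_day), days[0])
    hi = min(float(window.end_day), days[-1])
    if lo > hi:
        return None
    if lo == hi:
        return float(np.interp(lo, days, dens))
    inside = (days > lo) & (days < hi)
    grid = np.concatenate(([lo], days[inside], [hi]))
    vals = np.interp(grid, days, dens)
    area = np.trapezoid(vals, grid)
    return float(area / (hi - lo))


def consecutive_cotton(history: Sequence[Optional[str]]) -> Optional[int]:
    """Consecutive prior cotton plantings from a rotation history.

    Requires a complete record of the 4 preceding years (positions 1–4
    all known); otherwise returns ``None`` and the record is ineligible
    for the consecutive-planting models. Returns the length of the
    maximal run of cotton starting the year immediately before the focal
    crop, capped at 4 (0 when that year was not cotton).
    """
    if len(history) < 4 or any(h is None for h in history[:4]):
        return None
    run = 0
    for crop in history[:4]:
        if crop != "cotton":
            break
        run += 1
    return run


def _june_response(rec: FieldYearRecord, window: JuneWindow) -> Optional[float]:
    return mean_density(rec.lygus_samples, window)


def build_design(
    records: Sequence[FieldYearRecord],
    model_id: int,
    window: JuneWindow = JUNE,
    include_zero: bool = False,
) -> ModelDesign:
    """Assemble the design for one of models 1, 2, 4, 5.

    Records are sorted by (field_id, year) first so that fits are
    reproducible under input permutation. Rows lacking a response, a
    known prior crop (models 1/2), adjacency data, or an eligible 4-year
    history (models 4/5) are dropped; ``drop_report`` counts each reason
    and always reconciles: kept rows + dropped rows = input rows.
    ``include_zero`` admits eligible histories whose previous crop was
    not cotton (predictor value 0) into models 4/5; by default only runs
    of 1–4 enter, mirroring the restriction to fields coming out of
    cotton.

    A prior-crop category with no remaining rows is dropped from the
    design and listed in ``dropped_columns``. Zero eligible rows is an
    error.
    """
    if model_id not in (1, 2, 4, 5):
        raise ValueError(f"model_id must be 1, 2, 4 or 5, got {model_id}")
    recs = sorted(records, key=lambda r: (r.field_id, r.year))
    yield_response = model_id in (1, 4)
    response_name = "yield_kg_ha" if yield_response else "june_lygus_per_sweep"

    drop_report = {"missing_response": 0, "missing_adjacency": 0}
    if model_id in (1, 2):
        drop_report["missing_prior_crop"] = 0
    else:
        drop_report["ineligible_history"] = 0
        if not include_zero:
            drop_report["zero_consecutive_cotton"] = 0

    kept: list[tuple[FieldYearRecord, float, object]] = []
    for rec in recs:
        y = rec.yield_kg_ha if yield_response else _june_response(rec, window)
        if y is None:
            drop_report["missing_response"] += 1
            continue
        if model_id in (1, 2):
            prior = rec.rotation_history[0] if rec.rotation_history else None
            if prior is None:
                drop_report["missing_prior_crop"] += 1
                continue
            extra: object = prior
        else:
            consec = consecutive_cotton(rec.rotation_history)
            if consec is None:
                drop_report["ineligible_history"] += 1
                continue
            if consec == 0 and not include_zero:
                drop_report["zero_consecutive_cotton"] += 1
                continue
            extra = consec
        if rec.surrounding_counts is None:
            drop_report["missing_adjacency"] += 1
            continue
        kept.append((rec, float(y), extra))

    if not kept:
        raise ValueError(
            f"model {model_id}: zero eligible rows after filtering "
            f"(drop report: {drop_report})"
        )

    field_levels = sorted({r.field_id for r, _, _ in kept})
    year_levels = sorted({r.year for r, _, _ in kept})
    fmap = {f: i for i, f in enumerate(field_levels)}
    ymap = {yv: i for i, yv in enumerate(year_levels)}
    n = len(kept)
    response = np.array([y for _, y, _ in kept])
    field_index = np.array([fmap[r.field_id] for r, _, _ in kept])
    year_index = np.array([ymap[r.year] for r, _, _ in kept])

    dropped_columns: list[str] = []
    if model_id in (1, 2):
        present = {extra for _, _, extra in kept}
        crop_cols = []
        for crop in CROPS:
            if crop == "cotton":
                continue  # reference category: each coefficient is the contrast vs cotton
            if crop in present:
                crop_cols.append(crop)
            else:
                dropped_columns.append(f"prior_{crop}")
        names = (
            ["intercept"]
            + [f"prior_{c}" for c in crop_cols]
            + ["species_upland"]
            + [f"adj_{c}" for c in CROPS]
        )
        X = np.zeros((n, len(names)))
        X[:, 0] = 1.0
        col = {nm: j for j, nm in enumerate(names)}
        for i, (rec, _, prior) in enumerate(kept):
            if prior != "cotton":
                X[i, col[f"prior_{prior}"]] = 1.0
            X[i, col["species_upland"]] = 1.0 if rec.species == "upland" else 0.0
            for c in CROPS:
                X[i, col[f"adj_{c}"]] = rec.surrounding_counts.get(c, 0)
    else:
        names = ["intercept", "consec_cotton", "species_upland", "adj_cotton"]
        X = np.zeros((n, len(names)))
        X[:, 0] = 1.0
        for i, (rec, _, consec) in enumerate(kept):
            X[i, 1] = float(consec)
            X[i, 2] = 1.0 if rec.species == "upland" else 0.0
            X[i, 3] = rec.surrounding_counts.get("cotton", 0)

    return ModelDesign(
        model_id=model_id,
        response=response,
        response_name=response_name,
        fixed_names=names,
        fixed_matrix=X,
        field_index=field_index,
        year_index=year_index,
        field_levels=field_levels,
        year_levels=year_levels,
        drop_report=drop_report,
        dropped_columns=dropped_columns,
    )
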