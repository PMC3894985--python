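"""Field-year crop records: data model, CSV interchange and validation.

A *field-year record* is one commercial cotton crop: the lint yield it
produced, the identity of the crops grown in the same field in up to ten
prior seasons, the crops planted in the eight immediately adjoining fields,
and the sweep-net *Lygus hesperus* samples taken in it during the season.

Two plain CSV files carry a record set:

* the **records table** — one row per field-year, columns
  ``field_id, year, species, yield_kg_ha, prior_crop_1 .. prior_crop_10,
  adj_<crop> × 15`` (empty cell = missing);
* the **lygus table** — one row per sweep sample, columns
  ``field_id, year, day_of_year, density_per_sweep``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

#: The closed vocabulary of crops appearing in rotational histories.
CROPS: tuple[str, ...] = (
    "alfalfa", "barley", "carrots", "corn", "cotton",
    "garbanzo", "garlic", "lettuce", "melons", "onions",
    "potatoes", "safflower", "sugarbeets", "tomatoes", "wheat",
)

#: Cotton species present in the records (Gossypium barbadense / hirsutum).
SPECIES: tuple[str, str] = ("pima", "upland")

#: Maximum depth of a recorded rotation history, in years.
MAX_HISTORY = 10

#: Number of adjoining fields (N, NE, E, SE, S, SW, W, NW).
N_NEIGHBORS = 8

# Lint-yield unit conversion. Yields are recorded commercially in
# bales/acre; the package works natively in kg/ha.
KG_PER_BALE = 217.72
HA_PER_ACRE = 0.404686


def bales_per_acre_to_kg_per_ha(x: float) -> float:
    """Convert a lint yield from bales/acre to kg/ha (1 bale = 217.72 kg,
    1 acre = 0.404686 ha)."""
    return x * KG_PER_BALE / HA_PER_ACRE


@dataclass(frozen=True)
class FieldYearRecord:
    """One crop season of one field.

    Parameters
    ----------
    field_id
        Opaque identifier of the physical field.
    year
        Calendar year of the focal cotton crop.
    species
        ``"pima"`` or ``"upland"``.
    yield_kg_ha
        Lint yield in kg/ha, or ``None`` when not recorded.
    rotation_history
        Crops grown in prior years, position 0 = the year immediately
        before the focal crop; entries are crop names or ``None``;
        length 0–10.
    surrounding_counts
        Mapping crop name -> number of the 8 adjacent fields planted with
        that crop, or ``None`` when adjacency was not recorded.
    lygus_samples
        ``(day_of_year, insects_per_sweep)`` pairs, days strictly
        increasing.
    """

    field_id: str
    year: int
    species: str
    yield_kg_ha: Optional[float] = None
    rotation_history: tuple = ()
    surrounding_counts: Optional[dict] = None
    lygus_samples: tuple = ()


@dataclass(frozen=True)
class Violation:
    """A single invariant breach found by :func:`validate`."""

    record_index: int
    field_id: str
    year: int
    message: str


RECORD_COLUMNS = (
    ["field_id", "year", "species", "yield_kg_ha"]
    + [f"prior_crop_{i}" for i in range(1, MAX_HISTORY + 1)]
    + [f"adj_{c}" for c in CROPS]
)

LYGUS_COLUMNS = ["field_id", "year", "day_of_year", "density_per_sweep"]


def _parse_row(i: int, row: pd.Series) -> FieldYearRecord:
    def bad(col: str, why: str) -> ValueError:
        return ValueError(f"row {i}, column {col!r}: {why}")

    field_id = str(row["field_id"])
    try:
        year = int(row["year"])
    except (TypeError, ValueError):
        raise bad("year", f"not an integer: {row['year']!r}") from None

    species = str(row["species"]).strip()
    if species not in SPECIES:
        raise bad("species", f"{species!r} is not one of {SPECIES}")

    y = row["yield_kg_ha"]
    if pd.isna(y):
        yield_kg_ha = None
    else:
        try:
            yield_kg_ha = float(y)
        except (TypeError, ValueError):
            raise bad("yield_kg_ha", f"not a number: {y!r}") from None

    history: list[Optional[str]] = []
    for k in range(1, MAX_HISTORY + 1):
        cell = row[f"prior_crop_{k}"]
        if pd.isna(cell):
            history.append(None)
        else:
            crop = str(cell).strip()
            if crop not in CROPS:
                raise bad(
                    f"prior_crop_{k}",
                    f"unknown crop {crop!r}; the vocabulary is {', '.join(CROPS)}",
                )
            history.append(crop)
    while history and history[-1] is None:  # trailing unrecorded years
        history.pop()

    adj_cells = {c: row[f"adj_{c}"] for c in CROPS}
    n_missing = sum(pd.isna(v) for v in adj_cells.values())
    if n_missing == len(CROPS):
        surrounding: Optional[dict] = None
    elif n_missing == 0:
        surrounding = {}
        for c, v in adj_cells.items():
            try:
                surrounding[c] = int(v)
            except (TypeError, ValueError):
                raise bad(f"adj_{c}", f"not an integer count: {v!r}") from None
    else:
        missing = [c for c, v in adj_cells.items() if pd.isna(v)]
        raise bad(
            f"adj_{missing[0]}",
            "surrounding-crop counts must be given for all 15 crops or none",
        )

    return FieldYearRecord(
        field_id=field_id,
        year=year,
        species=species,
        yield_kg_ha=yield_kg_ha,
        rotation_history=tuple(history),
        surrounding_counts=surrounding,
    )


def read_records(path, lygus_path=None) -> list[FieldYearRecord]:
    """Read a record set from the records CSV (plus optional lygus CSV).

    Missing cells become explicit ``None`` markers; row order is
    preserved. Malformed rows raise :class:`ValueError` naming the row
    and column; unknown crop names raise an error listing the 15-crop
    vocabulary.
    """
    df = pd.read_csv(path, dtype={"field_id": str}, float_precision="round_trip")
    missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records file {path}: missing columns {missing_cols}")

    samples: dict[tuple[str, int], list[tuple[int, float]]] = {}
    if lygus_path is not None:
        ldf = pd.read_csv(lygus_path, dtype={"field_id": str}, float_precision="round_trip")
        missing_cols = [c for c in LYGUS_COLUMNS if c not in ldf.columns]
        if missing_cols:
            raise ValueError(f"lygus file {lygus_path}: missing columns {missing_cols}")
        for j, lrow in ldf.iterrows():
            key = (str(lrow["field_id"]), int(lrow["year"]))
            samples.setdefault(key, []).append(
                (int(lrow["day_of_year"]), float(lrow["density_per_sweep"]))
            )

    out = []
    for i, row in df.iterrows():
        rec = _parse_row(i, row)
        key = (rec.field_id, rec.year)
        if key in samples:
            rec = dataclasses.replace(rec, lygus_samples=tuple(samples.pop(key)))
        out.append(rec)
    if samples:
        key = next(iter(samples))
        raise ValueError(
            f"lygus file {lygus_path}: samples for unknown field-year {key}"
        )
    return out


def write_records(records: Sequence[FieldYearRecord], path, lygus_path=None) -> None:
    """Write a record set to CSV; :func:`read_records` inverts it."""
    rows = []
    lrows = []
    for rec in records:
        row: dict = {
            "field_id": rec.field_id,
            "year": rec.year,
            "species": rec.species,
            "yield_kg_ha": rec.yield_kg_ha,
        }
        for k in range(1, MAX_HISTORY + 1):
            hist = rec.rotation_history
            row[f"prior_crop_{k}"] = hist[k - 1] if k <= len(hist) else None
        for c in CROPS:
            if rec.surrounding_counts is None:
                row[f"adj_{c}"] = None
            else:
                row[f"adj_{c}"] = rec.surrounding_counts.get(c, 0)
        rows.append(row)
        for day, dens in rec.lygus_samples:
            lrows.append(
                {
                    "field_id": rec.field_id,
                    "year": rec.year,
                    "day_of_year": day,
                    "density_per_sweep": dens,
                }
            )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    # pandas writes pd.NA/None as empty cells, the documented missing marker
    df.to_csv(path, index=False)
    if lygus_path is not None:
        pd.DataFrame(lrows, columns=LYGUS_COLUMNS).to_csv(lygus_path, index=False)


def validate(records: Iterable[FieldYearRecord]) -> list[Violation]:
    """Check every record against the data-model invariants.

    Never raises on well-typed input; returns one :class:`Violation` per
    breach, an empty list iff all records are valid.
    """
    report: list[Violation] = []

    def flag(i: int, rec: FieldYearRecord, msg: str) -> None:
        report.append(Violation(i, rec.field_id, rec.year, msg))

    for i, rec in enumerate(records):
        if rec.species not in SPECIES:
            flag(i, rec, f"species {rec.species!r} not in {SPECIES}")
        if rec.yield_kg_ha is not None:
            if not math.isfinite(rec.yield_kg_ha) or rec.yield_kg_ha <= 0:
                flag(i, rec, f"yield {rec.yield_kg_ha} is not finite and > 0")
        if len(rec.rotation_history) > MAX_HISTORY:
            flag(i, rec, f"rotation history longer than {MAX_HISTORY} years")
        for k, crop in enumerate(rec.rotation_history, start=1):
            if crop is not None and crop not in CROPS:
                flag(i, rec, f"prior_crop_{k} {crop!r} not in the crop vocabulary")
        if rec.surrounding_counts is not None:
            bad_counts = [
                (c, n)
                for c, n in rec.surrounding_counts.items()
                if not isinstance(n, (int,)) or n < 0
            ]
            for c, n in bad_counts:
                flag(i, rec, f"surrounding count for {c!r} is not a non-negative integer: {n!r}")
            unknown = [c for c in rec.surrounding_counts if c not in CROPS]
            for c in unknown:
                flag(i, rec, f"surrounding crop {c!r} not in the crop vocabulary")
            if not bad_counts:
                total = sum(rec.surrounding_counts.values())
                if total > N_NEIGHBORS:
                    flag(i, rec, f"surrounding counts sum to {total} > {N_NEIGHBORS}")
        last_day = None
        for day, dens in rec.lygus_samples:
            if last_day is not None and day <= last_day:
                flag(i, rec, f"sample days not strictly increasing at day {day}")
            last_day = day
            if not math.isfinite(dens) or dens < 0:
                flag(i, rec, f"sample density {dens} on day {day} is not finite and >= 0")
    return report
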