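"""Food-frequency-questionnaire (FFQ) processing.

A semi-quantitative FFQ records, for every food item, how often it is
consumed (a closed set of frequency categories) and the portion eaten per
occasion, in grams (volumes in mL are treated as grams, i.e. density 1).
This module converts item-level responses into daily gram intakes and
aggregates items into food groups using a user-supplied item-to-group map.

The per-category daily multipliers are conventions, not universal
constants: published FFQ pipelines differ on the midpoint used for the
open-ended top category.  The defaults below use midpoints (2/month for
"1-3/month", 3/week for "2-4/week", 5.5/week for ">=4/week") with a month
of 365.25/12 days; they can be overridden via the ``factors`` argument.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "FREQUENCY_CATEGORIES",
    "DEFAULT_FREQUENCY_FACTORS",
    "FFQError",
    "frequency_to_daily_factor",
    "item_daily_grams",
    "aggregate_food_groups",
    "load_group_map",
    "read_responses",
    "write_intakes",
]

DAYS_PER_MONTH = 365.25 / 12.0

#: Closed set of frequency-of-consumption categories.
FREQUENCY_CATEGORIES = (
    "never/rare",
    "1-3/month",
    "1/week",
    "2-4/week",
    ">=4/week",
)

#: Default occasions-per-day multiplier for each category.
DEFAULT_FREQUENCY_FACTORS: dict[str, float] = {
    "never/rare": 0.0,
    "1-3/month": 2.0 / DAYS_PER_MONTH,
    "1/week": 1.0 / 7.0,
    "2-4/week": 3.0 / 7.0,
    ">=4/week": 5.5 / 7.0,
}

RESPONSE_COLUMNS = ("subject_id", "item_id", "frequency", "portion_g")


class FFQError(ValueError):
    """Invalid FFQ response, category, or item-to-group mapping."""


def frequency_to_daily_factor(
    category: str, factors: Mapping[str, float] | None = None
) -> float:
    """Return the occasions-per-day multiplier for a frequency category.

    Parameters
    ----------
    category : str
        One of :data:`FREQUENCY_CATEGORIES` (or a key of ``factors``).
    factors : mapping, optional
        Override of the default category-to-multiplier table.
    """
    table = DEFAULT_FREQUENCY_FACTORS if factors is None else factors
    try:
        return float(table[category])
    except KeyError:
        raise FFQError(
            f"unknown frequency category {category!r}; "
            f"expected one of {sorted(table)}"
        ) from None


def item_daily_grams(
    portion_g: float, category: str, factors: Mapping[str, float] | None = None
) -> float:
    """Daily grams contributed by one item: portion x daily frequency factor."""
    if portion_g < 0:
        raise FFQError(f"negative portion: {portion_g!r}")
    return float(portion_g) * frequency_to_daily_factor(category, factors)


def aggregate_food_groups(
    responses: pd.DataFrame,
    group_map: Mapping[str, str],
    factors: Mapping[str, float] | None = None,
    subjects: list | None = None,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate item-level responses into a subject x food-group gram matrix.

    Parameters
    ----------
    responses : DataFrame
        Columns ``subject_id``, ``item_id``, ``frequency``, ``portion_g``;
        one row per (subject, item) response.
    group_map : mapping
        Total map from item id to food-group label.
    factors : mapping, optional
        Frequency-multiplier override passed to :func:`item_daily_grams`.
    subjects, groups : lists, optional
        Row / column universes.  Subjects (groups) with no responses are
        included as all-zero rows (columns).  Defaults to the ids present
        in ``responses`` / the groups present in ``group_map``.

    Returns
    -------
    DataFrame
        Index = subject id, columns = group labels, values = grams/day.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing:
        raise FFQError(f"responses table missing columns: {missing}")
    unmapped = sorted(set(responses["item_id"]) - set(group_map))
    if unmapped:
        raise FFQError(f"unmapped item ids: {unmapped}")

    if groups is None:
        groups = list(dict.fromkeys(group_map.values()))
    if subjects is None:
        subjects = list(dict.fromkeys(responses["subject_id"]))

    daily = [
        item_daily_grams(p, c, factors)
        for p, c in zip(responses["portion_g"], responses["frequency"])
    ]
    work = pd.DataFrame(
        {
            "subject_id": responses["subject_id"].to_numpy(),
            "group": responses["item_id"].map(group_map).to_numpy(),
            "grams": daily,
        }
    )
    table = (
        work.pivot_table(
            index="subject_id", columns="group", values="grams", aggfunc="sum"
        )
        .reindex(index=subjects, columns=groups)
        .fillna(0.0)
    )
    table.index.name = "subject_id"
    table.columns.name = "food_group"
    return table


def load_group_map(path: str | Path) -> dict[str, str]:
    """Read an item-to-group map from YAML or delimited text.

    Two YAML layouts are accepted: ``item: group`` pairs, or
    ``group: [item, ...]`` lists.  Delimited text (``.tsv``/``.csv``) must
    have columns ``item_id`` and ``group``.  Every item must map to
    exactly one group and every group must have at least one item.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise FFQError(f"group map {path} is not a mapping")
        mapping: dict[str, str] = {}
        for key, value in raw.items():
            if isinstance(value, list):
                for item in value:
                    if item in mapping:
                        raise FFQError(f"item {item!r} mapped more than once")
                    mapping[str(item)] = str(key)
            else:
                if key in mapping:
                    raise FFQError(f"item {key!r} mapped more than once")
                mapping[str(key)] = str(value)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep)
        if not {"item_id", "group"} <= set(frame.columns):
            raise FFQError(f"group map {path} needs columns item_id, group")
        if frame["item_id"].duplicated().any():
            dup = frame.loc[frame["item_id"].duplicated(), "item_id"].tolist()
            raise FFQError(f"items mapped more than once: {dup}")
        mapping = dict(zip(frame["item_id"].astype(str), frame["group"].astype(str)))
    if not mapping:
        raise FFQError(f"group map {path} is empty")
    return mapping


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read an FFQ response table (TSV with the documented header)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise FFQError(f"response table {path} missing columns: {missing}")
    bad = sorted(set(frame["frequency"]) - set(FREQUENCY_CATEGORIES))
    if bad:
        raise FFQError(f"unknown frequency categories in {path}: {bad}")
    return frame


def write_intakes(intakes: pd.DataFrame, path: str | Path) -> None:
    """Write a subject x group gram matrix as TSV with a group-name header."""
    intakes.to_csv(path, sep="\t", index=True)
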