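"""Mapping of anxiolytic/hypnotic drugs to analysis groups.

The analysis covers ATC groups N05B (anxiolytics) and N05C
(hypnotics/sedatives) and reports results for therapeutic groups that
cut across ATC fourth levels, because benzodiazepine half-life classes
do: midazolam is coded as a hypnotic (N05CD) but is a short-acting
benzodiazepine, grouped with the short-acting anxiolytics oxazepam and
alprazolam.

Groups
------
anxiolytics_total          all studied N05B substances
hypnotics_total            all studied N05C substances
short_acting_benzodiazepine   half-life < 24 h: oxazepam, alprazolam, midazolam
long_acting_benzodiazepine    half-life > 24 h: diazepam, nitrazepam, flunitrazepam
z_hypnotic                 benzodiazepine-like hypnotics: zopiclone, zolpidem
benzo_hypnotic             N05CD benzodiazepine hypnotics
melatonin                  melatonin receptor agonists
other_anxiolytic           hydroxyzine
any_benzo_or_like          short + long + z-hypnotics, exactly

A substance belongs to every group that applies (totals, half-life
class, combination group).  Hydroxyzine and melatonin count toward
their totals but carry no half-life class and are outside the
combination group.  A fixed exclusion list removes substances whose
main indication is neither anxiety nor sleep disturbance, or whose use
is very rare; excluded substances classify to the empty set.

Classification is keyed on the substance name, with the ATC prefix as a
fallback for substances not in the packaged table.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GROUP_IDS",
    "EXCLUDED_SUBSTANCES",
    "classify",
    "assign_groups",
    "group_table",
    "load_group_table",
]

GROUP_IDS = frozenset(
    {
        "anxiolytics_total",
        "hypnotics_total",
        "short_acting_benzodiazepine",
        "long_acting_benzodiazepine",
        "z_hypnotic",
        "benzo_hypnotic",
        "melatonin",
        "other_anxiolytic",
        "any_benzo_or_like",
    }
)

_BENZO = "any_benzo_or_like"

# (substance, ATC prefix, groups)
_TABLE = [
    ("diazepam", "N05BA", ("anxiolytics_total", "long_acting_benzodiazepine", _BENZO)),
    ("oxazepam", "N05BA", ("anxiolytics_total", "short_acting_benzodiazepine", _BENZO)),
    ("alprazolam", "N05BA", ("anxiolytics_total", "short_acting_benzodiazepine", _BENZO)),
    ("hydroxyzine", "N05BB", ("anxiolytics_total", "other_anxiolytic")),
    ("nitrazepam", "N05CD", ("hypnotics_total", "benzo_hypnotic", "long_acting_benzodiazepine", _BENZO)),
    ("flunitrazepam", "N05CD", ("hypnotics_total", "benzo_hypnotic", "long_acting_benzodiazepine", _BENZO)),
    ("midazolam", "N05CD", ("hypnotics_total", "benzo_hypnotic", "short_acting_benzodiazepine", _BENZO)),
    ("zopiclone", "N05CF", ("hypnotics_total", "z_hypnotic", _BENZO)),
    ("zolpidem", "N05CF", ("hypnotics_total", "z_hypnotic", _BENZO)),
    ("melatonin", "N05CH", ("hypnotics_total", "melatonin")),
]

# Excluded for indications other than anxiety/sleep disturbance, or very
# rare use.  Common alternate spellings are accepted as aliases.
EXCLUDED_SUBSTANCES = frozenset(
    {
        "clomethiazole",
        "chlordiazepoxide",
        "lorazepam",
        "bromazepam",
        "clobazam",
        "meprobamate",
        "meoprobamate",
        "buspirone",
        "busperione",
        "barbital",
        "flurazepam",
        "triazolam",
        "zaleplon",
        "scopolamine",
        "scopalamine",
    }
)

_BY_SUBSTANCE = {s: frozenset(g) for s, _, g in _TABLE}

# ATC-prefix fallback for substances absent from the table: an unknown
# member of a studied fourth level gets that level's generic groups; an
# unknown N05B/N05C substance gets its total only.
_BY_ATC_PREFIX = {
    "N05BA": frozenset({"anxiolytics_total"}),
    "N05BB": frozenset({"anxiolytics_total", "other_anxiolytic"}),
    "N05CD": frozenset({"hypnotics_total", "benzo_hypnotic"}),
    "N05CF": frozenset({"hypnotics_total", "z_hypnotic", _BENZO}),
    "N05CH": frozenset({"hypnotics_total", "melatonin"}),
    "N05B": frozenset({"anxiolytics_total"}),
    "N05C": frozenset({"hypnotics_total"}),
}

_EMPTY = frozenset()


def classify(atc_code: str, substance: str, table: dict | None = None) -> frozenset:
    """Return the set of analysis groups for one dispensing.

    Excluded substances and ATC codes outside N05B/N05C return the
    empty set.  ``table`` may override the packaged substance map (a
    mapping of lowercase substance name to an iterable of group ids).
    """
    if not atc_code:
        raise ValueError("atc_code must be non-empty")
    substance = (substance or "").strip().lower()
    atc_code = atc_code.strip().upper()
    if substance in EXCLUDED_SUBSTANCES:
        return _EMPTY
    lookup = _BY_SUBSTANCE if table is None else table
    if substance in lookup:
        return frozenset(lookup[substance])
    if not (atc_code.startswith("N05B") or atc_code.startswith("N05C")):
        return _EMPTY
    for prefix in (atc_code[:5], atc_code[:4]):
        if prefix in _BY_ATC_PREFIX:
            return _BY_ATC_PREFIX[prefix]
    return _EMPTY


def assign_groups(dispensings: pd.DataFrame, table: dict | None = None) -> pd.DataFrame:
    """Explode a dispensings frame to one row per (dispensing, group).

    Dispensings that classify to the empty set (excluded or out of
    scope) contribute no rows.
    """
    pairs = dispensings[["atc_code", "substance"]].drop_duplicates()
    mapping = {
        (a, s): sorted(classify(a, s, table=table))
        for a, s in pairs.itertuples(index=False)
    }
    keys = list(zip(dispensings["atc_code"], dispensings["substance"]))
    out = dispensings.copy()
    out["group"] = [mapping[k] for k in keys]
    out = out.explode("group", ignore_index=True)
    return out[out["group"].notna()].reset_index(drop=True)


def group_table() -> pd.DataFrame:
    """The packaged classification as a tidy frame (substance, atc_prefix, group)."""
    rows = [
        {"substance": s, "atc_prefix": p, "group": g}
        for s, p, groups in _TABLE
        for g in groups
    ]
    return pd.DataFrame(rows)


def load_group_table(path) -> dict:
    """Read a user override table (columns substance, group) into a classify() mapping."""
    df = pd.read_csv(path)
    if not {"substance", "group"} <= set(df.columns):
        raise ValueError("override table needs 'substance' and 'group' columns")
    bad = set(df["group"]) - GROUP_IDS
    if bad:
        raise ValueError(f"unknown group ids in override table: {sorted(bad)}")
    out: dict[str, set] = {}
    for s, g in zip(df["substance"].str.lower(), df["group"]):
        out.setdefault(s, set()).add(g)
    return {s: frozenset(g) for s, g in out.items()}
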