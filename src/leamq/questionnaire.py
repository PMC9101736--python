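"""Key-driven scoring of questionnaire responses.

Section scores are sums of reverse-adjusted ordinal item codes over the
items that were actually answered; a section whose items are all missing
scores *missing*, never zero.  No imputation or proration is applied — the
completeness fraction per section is reported alongside so downstream
analysis can apply its own missing-data rule.

Besides the per-section sums, three derived quantities are produced:

``ehmc_score``
    Sum of the nine sex-drive + wellbeing items of the exercise
    hypogonadal male condition composite; missing if any constituent is.
``low_sex_drive_flag``
    True iff general sex drive >= 2, or morning-erection frequency >= 2
    together with a >= 1 adverse change in number of morning erections.
``weight_flux_kg``
    Self-reported highest minus lowest body weight at current height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .keys import SEX_DRIVE_RULE_ITEMS, ScoringKey, SECTIONS, default_key

#: columns of a response table that are not item codes
META_COLUMNS = ("athlete_id", "version", "highest_weight_kg", "lowest_weight_kg")


@dataclass
class SectionScores:
    """Scores for one athlete.  ``nan`` encodes missing throughout."""

    athlete_id: str
    version: str
    sections: dict[str, float] = field(default_factory=dict)
    subscales: dict[str, float] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)
    total: float = math.nan
    ehmc_score: float = math.nan
    low_sex_drive_score: float = math.nan
    low_sex_drive_flag: Optional[bool] = None
    weight_flux_kg: float = math.nan

    def as_row(self) -> dict:
        row = {"athlete_id": self.athlete_id, "version": self.version}
        row.update({f"{s}_score": v for s, v in self.sections.items()})
        row.update({f"{s}_subscore": v for s, v in self.subscales.items()})
        row.update({f"{s}_completeness": v for s, v in self.completeness.items()})
        row["total_score"] = self.total
        row["ehmc_score"] = self.ehmc_score
        row["low_sex_drive_score"] = self.low_sex_drive_score
        row["low_sex_drive_flag"] = (
            float(self.low_sex_drive_flag) if self.low_sex_drive_flag is not None else math.nan
        )
        row["weight_flux_kg"] = self.weight_flux_kg
        return row


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(v))
    except TypeError:
        return False


def compute_weight_flux(highest_kg, lowest_kg) -> float:
    """Highest minus lowest self-reported body weight (kg).

    Missing if either endpoint is missing; a highest weight below the
    lowest one is rejected as a likely data-entry swap.
    """
    if _is_missing(highest_kg) or _is_missing(lowest_kg):
        return math.nan
    highest_kg, lowest_kg = float(highest_kg), float(lowest_kg)
    if highest_kg < lowest_kg:
        raise ValidationError(
            f"highest weight {highest_kg} kg below lowest {lowest_kg} kg (entry swap?)"
        )
    return highest_kg - lowest_kg


def categorize_low_sex_drive(answers: Mapping[str, float], version: str = "v2") -> Optional[bool]:
    """Apply the low-sex-drive categorisation rule.

    True iff 6A >= 2, or (6C >= 2 and 6D >= 1).  Returns ``None`` (missing)
    if any of the three constituent items is unanswered, including the
    structural case of a version-1 response.
    """
    if version == "v1":
        warnings.warn("sex-drive items are version-2 only; flag is missing for v1 responses")
        return None
    vals = []
    for item in SEX_DRIVE_RULE_ITEMS:
        v = answers.get(item)
        if _is_missing(v):
            return None
        vals.append(float(v))
    a6, c6, d6 = vals
    return bool(a6 >= 2 or (c6 >= 2 and d6 >= 1))


def compute_ehmc_score(answers: Mapping[str, float], key: ScoringKey) -> float:
    """EHMC composite: sum of the key's nine constituent items after
    reverse adjustment.  Missing if any constituent is unanswered."""
    total = 0.0
    for item_id in key.ehmc_items:
        v = answers.get(item_id)
        if _is_missing(v):
            return math.nan
        total += key[item_id].adjust(int(v))
    return total


def score_response(
    answers: Mapping[str, float],
    version: str,
    key: Optional[ScoringKey] = None,
    athlete_id: str = "",
    highest_weight_kg=None,
    lowest_weight_kg=None,
) -> SectionScores:
    """Score a single response against the key.

    Unknown item ids raise :class:`SchemaError`; codes outside an item's
    allowed set raise :class:`ValidationError` naming the item.
    """
    key = key or default_key()
    if version not in ("v1", "v2"):
        raise SchemaError(f"unknown questionnaire version {version!r}")

    unknown = [i for i in answers if i not in key]
    if unknown:
        raise SchemaError([f"unknown item id {i!r}" for i in sorted(unknown)])

    adjusted: dict[str, float] = {}
    for item_id, code in answers.items():
        it = key[item_id]
        if not it.available_in(version):
            raise SchemaError(f"item {item_id!r} is not part of version {version}")
        if _is_missing(code):
            continue
        code = float(code)
        if code != int(code) or int(code) not in it.allowed_codes:
            raise ValidationError(
                f"item {item_id!r}: code {code!r} outside allowed codes {it.allowed_codes}"
            )
        adjusted[item_id] = it.adjust(int(code))

    res = SectionScores(athlete_id=athlete_id, version=version)
    for section in SECTIONS:
        items = key.items_for(version, section)
        if not items:  # section absent from this version (e.g. v1 sex drive)
            res.sections[section] = math.nan
            res.completeness[section] = 0.0
            continue
        answered = [it.item_id for it in items if it.item_id in adjusted]
        res.completeness[section] = len(answered) / len(items)
        res.sections[section] = (
            float(sum(adjusted[i] for i in answered)) if answered else math.nan
        )

    # wellbeing sub-scales (fatigue, poor_recovery, low_energy, ...)
    subs: dict[str, list] = {}
    for it in key.items_for(version, "wellbeing"):
        if it.subscale:
            subs.setdefault(it.subscale, []).append(it.item_id)
    for name, ids in subs.items():
        answered = [i for i in ids if i in adjusted]
        res.subscales[name] = float(sum(adjusted[i] for i in answered)) if answered else math.nan

    present = [v for v in res.sections.values() if not math.isnan(v)]
    res.total = float(sum(present)) if present else math.nan

    res.low_sex_drive_score = res.sections.get("sex_drive", math.nan)
    res.low_sex_drive_flag = categorize_low_sex_drive(answers, version)
    res.ehmc_score = compute_ehmc_score(answers, key) if version == "v2" else math.nan
    res.weight_flux_kg = compute_weight_flux(highest_weight_kg, lowest_weight_kg)
    return res


def score_table(
    responses: pd.DataFrame,
    key: Optional[ScoringKey] = None,
    drop_items: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Vectorised scoring of a response table (one row per athlete).

    Expects columns ``athlete_id``, ``version``, optional
    ``highest_weight_kg``/``lowest_weight_kg`` and one column per item id.
    Items in ``drop_items`` (e.g. removed after test-retest) are ignored.
    """
    key = (key or default_key()).drop(drop_items)
    df = responses.copy()
    out = pd.DataFrame({"athlete_id": df["athlete_id"], "version": df["version"]})
    n = len(df)
    if n == 0:
        cols = (
            [f"{s}_score" for s in SECTIONS]
            + ["total_score", "ehmc_score", "low_sex_drive_score",
               "low_sex_drive_flag", "weight_flux_kg"]
        )
        for c in cols:
            out[c] = pd.Series(dtype=float)
        return out

    dropped = set(drop_items)
    unknown = [
        c for c in df.columns
        if c not in META_COLUMNS and c not in key and c not in dropped
        and c not in ("centre", "sport")
    ]
    if unknown:
        raise SchemaError([f"unknown item id {c!r}" for c in unknown])

    # adjusted item matrix; structurally missing items stay NaN
    adj = {}
    v2 = (df["version"] == "v2").to_numpy()
    for it in key:
        if it.item_id in df.columns:
            col = pd.to_numeric(df[it.item_id], errors="coerce").astype(float).to_numpy()
        else:
            col = np.full(n, np.nan)
        bad = col[~np.isnan(col)]
        if bad.size and (np.any(bad != np.round(bad)) or np.any(~np.isin(bad.astype(int), it.allowed_codes))):
            raise ValidationError(f"item {it.item_id!r}: codes outside {it.allowed_codes}")
        if it.version == "v2":
            col = np.where(v2, col, np.nan)
        adj[it.item_id] = (it.max_code - col) if it.reverse_coded else col
    adj = pd.DataFrame(adj, index=df.index)

    for section in SECTIONS:
        ids_any = [it.item_id for it in key if it.section == section]
        sec = adj[ids_any]
        out[f"{section}_score"] = sec.sum(axis=1, min_count=1)
        n_avail = np.where(v2, len(ids_any),
                           sum(key[i].version != "v2" for i in ids_any))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{section}_completeness"] = sec.notna().sum(axis=1) / n_avail

    for sub in sorted({it.subscale for it in key if it.subscale}):
        ids = [it.item_id for it in key if it.subscale == sub]
        out[f"{sub}_subscore"] = adj[ids].sum(axis=1, min_count=1)

    out["total_score"] = out[[f"{s}_score" for s in SECTIONS]].sum(axis=1, min_count=1)
    out["low_sex_drive_score"] = out["sex_drive_score"]

    a6, c6, d6 = (adj[i] for i in SEX_DRIVE_RULE_ITEMS)
    flag = (a6 >= 2) | ((c6 >= 2) & (d6 >= 1))
    out["low_sex_drive_flag"] = flag.astype(float).where(
        a6.notna() & c6.notna() & d6.notna(), np.nan
    )

    ehmc = adj[list(key.ehmc_items)]
    out["ehmc_score"] = ehmc.sum(axis=1).where(ehmc.notna().all(axis=1), np.nan)

    if {"highest_weight_kg", "lowest_weight_kg"} <= set(df.columns):
        hi = pd.to_numeric(df["highest_weight_kg"], errors="coerce")
        lo = pd.to_numeric(df["lowest_weight_kg"], errors="coerce")
        swapped = (hi < lo) & hi.notna() & lo.notna()
        if swapped.any():
            ids = df.loc[swapped, "athlete_id"].tolist()
            raise ValidationError(f"highest weight below lowest for athletes {ids}")
        out["weight_flux_kg"] = hi - lo
    else:
        out["weight_flux_kg"] = np.nan
    return out
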