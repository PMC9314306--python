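"""Domain types and derived quantities for item-level symptom-diary data.

The central container is :class:`ItemDataset`: long-format ordinal item
responses (one record per subject x study day x item) together with
per-subject covariates and the instrument definition.  Study days are
integers; days -14..-1 are the baseline run-in, treatment starts at day 1
and runs for 24 weeks (day 168).  Diary completion is all-or-nothing within
a day: a subject-day with fewer than the full item set is invalid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "arm", "smoking", "region", "study_day", "item_id", "score")

#: Baseline window (inclusive) used for the per-subject baseline score.
BASELINE_WINDOW = (-14, -1)

#: Number of 28-day post-baseline intervals in the 24-week treatment period.
N_INTERVALS = 6
TREATMENT_DAYS = 168

INTERVAL_LABELS = ("1-4", "5-8", "9-12", "13-16", "17-20", "21-24")


class FormatError(ValueError):
    """Input file does not have the expected layout."""


class ValidationError(ValueError):
    """Input rows violate an instrument or completeness constraint."""


@dataclass(frozen=True)
class ItemDef:
    item_id: int
    label: str
    max_score: int
    construct: str = ""

    @property
    def n_categories(self) -> int:
        return self.max_score + 1


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordinal multi-item instrument; scores on item *j* run 0..max_score_j."""

    name: str
    items: tuple[ItemDef, ...]

    def __post_init__(self):
        if not self.items:
            raise ValueError("instrument needs at least one item")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids")
        if any(it.max_score < 1 for it in self.items):
            raise ValueError("items need at least two categories")

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return sum(it.max_score for it in self.items)

    def max_scores(self) -> dict[int, int]:
        return {it.item_id: it.max_score for it in self.items}


def ers_copd_instrument() -> InstrumentSpec:
    """The packaged 11-item E-RS:COPD definition (RS-Total range 0-40).

    Seven items have five response categories (0-4) and four items
    (mucus quantity, breathless with activity, and the two shortness-of-
    breath activity items) have four (0-3).
    """
    raw = json.loads(resources.files("promirt._assets").joinpath("instrument_ers.json").read_text())
    items = tuple(
        ItemDef(item_id=d["item_id"], label=d["label"], max_score=d["max_score"], construct=d["construct"])
        for d in raw["items"]
    )
    spec = InstrumentSpec(name=raw["name"], items=items)
    assert spec.n_items == 11 and spec.max_total == 40
    return spec


@dataclass
class ItemDataset:
    """Validated long-format item responses plus per-subject covariates."""

    responses: pd.DataFrame  # subject_id, arm, study_day, item_id, score
    covariates: pd.DataFrame  # subject_id, arm, smoking, region
    instrument: InstrumentSpec

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def arms(self) -> list[str]:
        return sorted(self.covariates["arm"].unique())

    def write_csv(self, path) -> None:
        """Write back to the single-file long format accepted by ``read_item_data``."""
        df = self.responses.merge(self.covariates[["subject_id", "smoking", "region"]], on="subject_id")
        df = df[list(REQUIRED_COLUMNS)].sort_values(["subject_id", "study_day", "item_id"], kind="stable")
        df.to_csv(path, index=False)


def validate_item_data(df: pd.DataFrame, instrument: InstrumentSpec) -> None:
    """Raise :class:`ValidationError` on out-of-range scores or partial diary days."""
    known = df["item_id"].isin(instrument.item_ids)
    if not known.all():
        bad = df.loc[~known, "item_id"].unique()
        raise ValidationError(f"unknown item ids {sorted(bad)!r}")
    max_by_item = df["item_id"].map(instrument.max_scores())
    bad = (df["score"] < 0) | (df["score"] > max_by_item) | (df["score"] != df["score"].round())
    if bad.any():
        rows = df.loc[bad, ["subject_id", "study_day", "item_id", "score"]]
        raise ValidationError(
            f"{bad.sum()} score(s) outside item range; first offenders:\n{rows.head(10).to_string(index=False)}"
        )
    counts = df.groupby(["subject_id", "study_day"])["item_id"].agg(["count", "nunique"])
    partial = counts[(counts["count"] != instrument.n_items) | (counts["nunique"] != instrument.n_items)]
    if len(partial):
        raise ValidationError(
            "diary days with a partial or duplicated item set (the instrument does not "
            f"allow skipping individual items):\n{partial.head(10).to_string()}"
        )
    nreg = df.groupby("subject_id")["region"].nunique()
    if (nreg != 1).any() or df.groupby("subject_id")["smoking"].nunique().gt(1).any():
        raise ValidationError("covariates must be constant within subject")
    if df.groupby("subject_id")["arm"].nunique().gt(1).any():
        raise ValidationError("treatment arm must be constant within subject")


def from_frame(df: pd.DataFrame, instrument: InstrumentSpec) -> ItemDataset:
    """Build a validated :class:`ItemDataset` from a long-format frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    df = df.copy()
    df["score"] = pd.to_numeric(df["score"])
    df["study_day"] = df["study_day"].astype(int)
    validate_item_data(df, instrument)
    df["score"] = df["score"].astype(np.int64)
    covs = (
        df[["subject_id", "arm", "smoking", "region"]]
        .drop_duplicates("subject_id")
        .reset_index(drop=True)
    )
    resp = df[["subject_id", "arm", "study_day", "item_id", "score"]].sort_values(
        ["subject_id", "study_day", "item_id"], kind="stable"
    ).reset_index(drop=True)
    return ItemDataset(responses=resp, covariates=covs, instrument=instrument)


def read_item_data(path, instrument: InstrumentSpec | None = None) -> ItemDataset:
    """Read and validate a comma-delimited long-format item-response file."""
    instrument = instrument or ers_copd_instrument()
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    return from_frame(df, instrument)


def compute_total_scores(dataset: ItemDataset) -> pd.DataFrame:
    """Per complete subject-day total score (sum over items)."""
    g = dataset.responses.groupby(["subject_id", "arm", "study_day"], sort=True)["score"].sum()
    out = g.rename("rs_total").reset_index()
    return out


def derive_baselines(total_scores: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-subject baseline: mean daily total over the day -14..-1 window.

    Returns (frame with subject_id/arm/baseline, list of excluded subject ids
    that have no complete day in the window).  Excluded subjects are logged;
    they cannot contribute change-from-baseline endpoints.
    """
    lo, hi = BASELINE_WINDOW
    base = total_scores[(total_scores["study_day"] >= lo) & (total_scores["study_day"] <= hi)]
    out = base.groupby(["subject_id", "arm"], sort=True)["rs_total"].mean().rename("baseline").reset_index()
    excluded = sorted(set(total_scores["subject_id"]) - set(out["subject_id"]))
    if excluded:
        logger.warning("%d subject(s) without baseline diary days excluded from CFB endpoints: %s",
                       len(excluded), excluded[:10])
    return out, excluded


def assign_interval(study_day) -> np.ndarray:
    """Map treatment days 1..168 to 4-week interval indices 1..6.

    Interval i covers days 28*(i-1)+1 .. 28*i.  Days outside the treatment
    window are rejected.
    """
    day = np.asarray(study_day)
    if (day < 1).any() or (day > TREATMENT_DAYS).any():
        raise ValueError(f"study days must lie in 1..{TREATMENT_DAYS}")
    return ((day - 1) // 28 + 1).astype(int)
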