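"""Independent-occasion view of an item dataset.

For item-parameter estimation every complete subject-day is treated as its
own pseudo-subject ("independent occasion" approach): baseline-window days
form one occasion class with the latent variable fixed at N(0, 1) — this
anchors the scale — and post-baseline days form classes whose latent mean
and variance are estimated.  The meta table retains the original ids so the
per-occasion latent estimates can later be reconciled into subject
time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ItemDataset, assign_interval


@dataclass
class OccasionData:
    """Score matrix (one row per complete subject-day) plus the id mapping."""

    scores: np.ndarray          # (n_occasions, n_items) ints, instrument item order
    meta: pd.DataFrame          # pseudo_id, subject_id, arm, study_day, smoking, region, is_baseline, interval
    item_ids: tuple
    max_scores: tuple = ()      # per-item top category from the instrument

    @property
    def n_occasions(self) -> int:
        return self.scores.shape[0]

    @property
    def is_baseline(self) -> np.ndarray:
        return self.meta["is_baseline"].to_numpy()


def build_independent_occasions(dataset: ItemDataset) -> OccasionData:
    item_ids = dataset.instrument.item_ids
    wide = dataset.responses.pivot(index=["subject_id", "study_day"], columns="item_id", values="score")
    wide = wide[item_ids]  # enforce instrument order; validation guarantees completeness
    idx = wide.index.to_frame(index=False)
    meta = idx.merge(dataset.covariates, on="subject_id", how="left")
    meta = meta.sort_values(["subject_id", "study_day"], kind="stable").reset_index(drop=True)
    order = wide.index.get_indexer(pd.MultiIndex.from_frame(meta[["subject_id", "study_day"]]))
    scores = wide.to_numpy(dtype=np.int64)[order]
    meta.insert(0, "pseudo_id", np.arange(len(meta)))
    meta["is_baseline"] = meta["study_day"] < 1
    interval = np.zeros(len(meta), dtype=int)
    post = ~meta["is_baseline"].to_numpy()
    interval[post] = assign_interval(meta.loc[post, "study_day"].to_numpy())
    meta["interval"] = interval
    return OccasionData(scores=scores, meta=meta, item_ids=tuple(item_ids),
                        max_scores=tuple(it.max_score for it in dataset.instrument.items))
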