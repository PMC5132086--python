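"""Forced-choice rating statistics for synthetic-map quality assessment.

Expert raters compare each measured map with its synthetic counterpart and
pick the one with less motion artefact.  Per participant and map type, the
number of raters preferring the synthetic map is tested against chance
(probability 0.5) with an exact one-sided binomial test in the observed
direction.  The one-sided tail is used deliberately: with five raters a
unanimous 5/5 verdict has one-sided p = 0.5^5 = 0.03125 (< 0.05) but
two-sided p = 0.0625, and unanimous verdicts are exactly the outcomes such a
study flags as significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForcedChoiceResult",
    "RatingSummary",
    "RatingTable",
    "forced_choice_test",
    "load_rating_table",
    "summarize_rating_study",
]

_FIXTURE = "motion_rating_study.csv"


@dataclass(frozen=True)
class ForcedChoiceResult:
    p_value: float
    significant: bool
    direction: str    # "synthetic" | "original" | "none"
    k: int
    n: int


def forced_choice_test(k_selected: int, n_raters: int,
                       alpha: float = 0.05) -> ForcedChoiceResult:
    """Exact one-sided binomial test of a forced-choice verdict against chance.

    ``k_selected`` raters out of ``n_raters`` chose the synthetic map.  The
    tail is taken in the observed direction: P(X >= k) when the synthetic map
    is preferred (k > n/2), P(X <= k) when the original is (k < n/2); a split
    verdict has p = 1 and no direction.
    """
    if not 0 <= k_selected <= n_raters:
        raise ValueError("k must lie in [0, n]")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    if k_selected > n_raters / 2:
        direction = "synthetic"
        p = stats.binomtest(k_selected, n_raters, 0.5, alternative="greater").pvalue
    elif k_selected < n_raters / 2:
        direction = "original"
        p = stats.binomtest(k_selected, n_raters, 0.5, alternative="less").pvalue
    else:
        direction, p = "none", 1.0
    return ForcedChoiceResult(p_value=float(p), significant=bool(p < alpha),
                              direction=direction, k=int(k_selected),
                              n=int(n_raters))


@dataclass
class RatingTable:
    """Per-participant forced-choice percentages for the two synthetic maps.

    ``data`` columns: participant, pct_r1, pct_mt — the percentage of the
    ``n_raters`` raters who selected the synthetic R1 / MT map.  Percentages
    must correspond to integer rater counts.
    """

    data: pd.DataFrame
    n_raters: int = 5

    def __post_init__(self):
        required = {"participant", "pct_r1", "pct_mt"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"rating table missing columns: {sorted(missing)}")
        for col in ("pct_r1", "pct_mt"):
            pct = self.data[col].to_numpy(dtype=float)
            if np.any((pct < 0) | (pct > 100)):
                raise ValueError(f"{col}: percentages must lie in [0, 100]")
            counts = pct * self.n_raters / 100.0
            if not np.allclose(counts, np.round(counts), atol=1e-9):
                raise ValueError(
                    f"{col}: percentages inconsistent with {self.n_raters} raters")

    def counts(self, col: str) -> np.ndarray:
        return np.round(self.data[col].to_numpy(dtype=float)
                        * self.n_raters / 100.0).astype(int)


def load_rating_table(path=None, n_raters: int = 5) -> RatingTable:
    """Load a rating table CSV (participant, pct_r1, pct_mt).

    Without ``path``, loads the packaged fixture: the forced-choice study of
    12 motion-affected datasets evaluated by five expert raters.
    """
    if path is None:
        with resources.files("synthmpm.data").joinpath(_FIXTURE).open() as fh:
            data = pd.read_csv(fh, comment="#")
    else:
        data = pd.read_csv(path, comment="#")
    return RatingTable(data=data, n_raters=n_raters)


@dataclass
class RatingSummary:
    per_participant: pd.DataFrame
    improved_r1: list
    improved_mt: list
    improved_any: list
    improved_both: list
    proportion_improved: float
    alpha: float


def summarize_rating_study(table: RatingTable, alpha: float = 0.05) -> RatingSummary:
    """Per-participant significance calls and study-level improvement counts.

    A participant counts as improved for a map type when the synthetic map is
    significantly preferred.  ``improved_both`` should be empty (an
    acquisition corrupted badly enough to improve one map leaves the inputs
    of the other intact); it is reported, not enforced.
    """
    rows = []
    for _, row in table.data.iterrows():
        res_r1 = forced_choice_test(int(round(row.pct_r1 * table.n_raters / 100)),
                                    table.n_raters, alpha)
        res_mt = forced_choice_test(int(round(row.pct_mt * table.n_raters / 100)),
                                    table.n_raters, alpha)
        rows.append({
            "participant": row.participant,
            "pct_r1": row.pct_r1, "p_r1": res_r1.p_value,
            "r1_improved": res_r1.significant and res_r1.direction == "synthetic",
            "pct_mt": row.pct_mt, "p_mt": res_mt.p_value,
            "mt_improved": res_mt.significant and res_mt.direction == "synthetic",
        })
    per = pd.DataFrame(rows)
    improved_r1 = per.loc[per.r1_improved, "participant"].tolist()
    improved_mt = per.loc[per.mt_improved, "participant"].tolist()
    improved_any = per.loc[per.r1_improved | per.mt_improved, "participant"].tolist()
    improved_both = per.loc[per.r1_improved & per.mt_improved, "participant"].tolist()
    return RatingSummary(
        per_participant=per,
        improved_r1=improved_r1, improved_mt=improved_mt,
        improved_any=improved_any, improved_both=improved_both,
        proportion_improved=len(improved_any) / len(per) if len(per) else 0.0,
        alpha=alpha)
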