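"""Human-validation statistics: inter-judge reliability and the
agreement between judge ratings and cluster-derived quality tiers.

Quality levels are coded high=1, average=2, low=3. Reliability is
unweighted Cohen kappa per judge pair (a linearly weighted variant is
available since the levels are ordinal); validity is the Pearson
correlation between consensus ratings and cluster tiers on the 1/2/3
codes, with r > 0.5 conventionally read as strong agreement and
kappa > 0.70 as substantial reliability.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JudgeRatings",
    "cohen_kappa",
    "panel_kappa",
    "rating_cluster_correlation",
    "consensus_by_majority",
]

logger = logging.getLogger(__name__)

VALID_LEVELS = (1, 2, 3)


class JudgeRatings:
    """Per-question, per-judge quality levels.

    Wraps a (record x judge) table whose cells are levels 1/2/3 or
    missing (NaN). Built from a long-format frame with columns
    record_id, judge_id, rating.
    """

    def __init__(self, table: pd.DataFrame):
        values = table.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, VALID_LEVELS)
        if not ok.all():
            bad = sorted(set(values[~ok].tolist()))
            raise ValueError(f"ratings must be in {VALID_LEVELS} or missing; got {bad}")
        if table.shape[1] < 2:
            raise ValueError("need at least 2 judges")
        self.table = table

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "JudgeRatings":
        required = {"record_id", "judge_id", "rating"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"ratings frame is missing columns {sorted(missing)}")
        wide = frame.pivot(index="record_id", columns="judge_id", values="rating")
        return cls(wide)

    @property
    def judges(self) -> list:
        return list(self.table.columns)

    def pair(self, a, b) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case rating vectors for judges ``a`` and ``b``."""
        sub = self.table[[a, b]].dropna()
        return sub[a].to_numpy(dtype=int), sub[b].to_numpy(dtype=int)


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Unweighted Cohen kappa between two paired rating vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the raters' marginal distributions. The degenerate case
    p_e = 1 (both raters constant on the same level, hence p_o = 1) is
    defined as 1 with a warning rather than 0/0.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired ratings")
    n = len(a)
    p_o = float(np.mean(a == b))
    levels = np.union1d(a, b)
    p_e = float(
        sum((np.mean(a == lv)) * (np.mean(b == lv)) for lv in levels)
    )
    if math.isclose(p_e, 1.0):
        warnings.warn(
            "both raters are constant on one level; kappa defined as 1",
            stacklevel=2,
        )
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def weighted_kappa(ratings_a, ratings_b) -> float:
    """Linearly weighted kappa for the ordinal 1/2/3 levels."""
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if len(a) < 2:
        raise ValueError("need at least 2 paired ratings")
    levels = np.array(VALID_LEVELS)
    w = np.abs(levels[:, None] - levels[None, :]) / (len(levels) - 1)
    obs = np.zeros((3, 3))
    for x, y in zip(a, b):
        obs[x - 1, y - 1] += 1
    obs /= len(a)
    pa = obs.sum(axis=1)
    pb = obs.sum(axis=0)
    exp = np.outer(pa, pb)
    denom = (w * exp).sum()
    if math.isclose(denom, 0.0):
        warnings.warn("degenerate marginals; weighted kappa defined as 1", stacklevel=2)
        return 1.0
    return 1.0 - (w * obs).sum() / denom


def panel_kappa(ratings: JudgeRatings, weighted: bool = False) -> dict:
    """All pairwise kappas plus their unweighted mean.

    A pair that fails (for example, fewer than 2 complete cases) is
    reported with its error message and excluded from the mean; the
    other pairs still compute.
    """
    fn = weighted_kappa if weighted else cohen_kappa
    pairs: dict[tuple, float] = {}
    errors: dict[tuple, str] = {}
    for a, b in itertools.combinations(ratings.judges, 2):
        va, vb = ratings.pair(a, b)
        try:
            pairs[(a, b)] = fn(va, vb)
        except ValueError as exc:
            errors[(a, b)] = str(exc)
            logger.warning("kappa(%s, %s) failed: %s", a, b, exc)
    mean = float(np.mean(list(pairs.values()))) if pairs else math.nan
    return {"pairs": pairs, "mean": mean, "errors": errors}


def rating_cluster_correlation(consensus, assignment) -> float:
    """Pearson r between consensus ratings and cluster quality levels,
    both on the 1/2/3 coding. Zero variance on either side is an error
    (a correlation is then undefined, not zero)."""
    x = np.asarray(consensus, dtype=float)
    y = np.asarray(assignment, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("consensus and assignment must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def consensus_by_majority(
    ratings: JudgeRatings, on_tie: str = "error"
) -> pd.Series:
    """Strict-majority consensus per record.

    Ties cannot be resolved by any statistic — they require
    adjudication by discussion — so ``on_tie="error"`` (default)
    raises, while ``on_tie="drop"`` excludes tied records with a
    logged count.
    """
    if on_tie not in ("error", "drop"):
        raise ValueError("on_tie must be 'error' or 'drop'")
    out = {}
    dropped = []
    for rec, row in ratings.table.iterrows():
        votes = row.dropna().astype(int)
        counts = votes.value_counts()
        if len(counts) and counts.iloc[0] > len(votes) / 2:
            out[rec] = int(counts.index[0])
        elif on_tie == "drop":
            dropped.append(rec)
        else:
            raise ValueError(
                f"record {rec!r}: no majority among {votes.tolist()}; "
                "adjudication required"
            )
    if dropped:
        logger.warning(
            "%d record(s) without a majority rating dropped from consensus",
            len(dropped),
        )
    return pd.Series(out, name="rating")
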