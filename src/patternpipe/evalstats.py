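"""Matching-task construction and rank-based evaluation.

The evaluation protocol mirrors photographic mark–recapture practice: two
suitable crops per individual taken on *different days* (one query, one
database entry), optional augmentation with horizontally mirrored
left-flank crops treated as extra identities (left and right flanks carry
independent patterns, so this adds identities without bias), ranking each
query against the full database, and summarizing with the cumulative match
characteristic (CMC): the proportion of queries whose true match appears
within the top-k candidates.  The headline statistic is the CMC at k = 10,
the number of candidates an operator is assumed willing to inspect.

Group comparisons (between populations or preprocessing variants) are
reported as a 2x2 odds ratio of matched-within-10 vs not, with a Wald CI
on the log odds ratio (Haldane 0.5 correction when a cell is empty) and
per-group Wilson CIs.  Per-query results can be exported as a tidy table
so any external model (e.g. a mixed-effects logistic regression) can be
fit downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .matchcore import DescriptorSet, RankingResult, extract_features, mirror, rank
from .preprocess import Crop
from .viewclass import accuracy_ci

__all__ = [
    "MatchTask",
    "CMCCurve",
    "OddsRatioResult",
    "build_match_task",
    "run_match_task",
    "cmc",
    "compare_accuracy",
    "assign_quality_scores",
    "per_query_table",
]


@dataclass
class MatchTask:
    queries: list[str]
    database: list[str]
    truth: dict[str, str]          # query crop id -> true database crop id
    group_labels: dict[str, str] = field(default_factory=dict)
    crops: dict[str, Crop] = field(default_factory=dict)
    excluded_individuals: list[str] = field(default_factory=list)


@dataclass
class CMCCurve:
    k: np.ndarray
    prop_matched: np.ndarray
    n_queries: int

    def at(self, k: int) -> float:
        i = int(np.searchsorted(self.k, k))
        if i >= len(self.k) or self.k[i] != k:
            raise KeyError(f"k={k} not on curve")
        return float(self.prop_matched[i])


@dataclass
class OddsRatioResult:
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    table: tuple[tuple[int, int], tuple[int, int]]
    group_cis: dict[str, tuple[float, float, float]]
    degenerate: bool = False


def _flank_key(ind_id: str, side: str) -> str:
    return ind_id if side == "right" else f"{ind_id}/L"


def build_match_task(
    crops: Sequence[Crop],
    side: Literal["right", "left"] = "right",
    mirror_left: bool = False,
    seed: int = 0,
    group: str | None = None,
    require_suitable: bool = True,
) -> MatchTask:
    """Select two different-day crops per identity and split them into a
    query and a database entry.

    ``side`` picks the primary flank; with ``mirror_left`` every identity
    that has two suitable left-flank crops on distinct days is added as an
    extra mirrored identity.  Individuals lacking two distinct-day crops
    for a flank are excluded with a warning.  Selection is seeded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 3]))
    sides = [side] + (["left"] if (mirror_left and side == "right") else [])
    by_flank: dict[str, list[Crop]] = {}
    for c in crops:
        attrs = c.attributes or {}
        ind = attrs.get("individual_id")
        cside = attrs.get("side")
        if ind is None or cside not in sides:
            continue
        if require_suitable:
            suitable = (
                attrs.get("flank_visible_frac", 1.0) >= 0.8
                and attrs.get("rotation_deg", 0.0) < 30.0
                and attrs.get("pose", "standing") == "standing"
            )
            if not suitable:
                continue
        by_flank.setdefault(_flank_key(ind, cside), []).append(c)

    queries: list[str] = []
    database: list[str] = []
    truth: dict[str, str] = {}
    group_labels: dict[str, str] = {}
    crop_index: dict[str, Crop] = {}
    excluded: list[str] = []
    for key in sorted(by_flank):
        pool = sorted(by_flank[key], key=lambda c: c.crop_id)
        days = sorted({c.day for c in pool})
        if len(days) < 2:
            excluded.append(key)
            continue
        day_a, day_b = rng.choice(days, size=2, replace=False)

        def pick(day: int) -> Crop:
            cands = [c for c in pool if c.day == day]
            return cands[int(rng.integers(len(cands)))]

        pick_a, pick_b = pick(day_a), pick(day_b)
        if key.endswith("/L"):
            pick_a, pick_b = mirror(pick_a), mirror(pick_b)
        queries.append(pick_a.crop_id)
        database.append(pick_b.crop_id)
        truth[pick_a.crop_id] = pick_b.crop_id
        if group is not None:
            group_labels[pick_a.crop_id] = group
        crop_index[pick_a.crop_id] = pick_a
        crop_index[pick_b.crop_id] = pick_b
    if excluded:
        warnings.warn(
            f"{len(excluded)} identities lacked two suitable distinct-day "
            f"crops and were excluded: {excluded[:5]}..."
        )
    return MatchTask(
        queries=queries,
        database=database,
        truth=truth,
        group_labels=group_labels,
        crops=crop_index,
        excluded_individuals=excluded,
    )


def run_match_task(
    task: MatchTask,
    method: Literal["lnbnn", "pairwise"] = "lnbnn",
    k: int = 5,
    seed: int = 0,
    feature_kwargs: dict | None = None,
) -> list[RankingResult]:
    """Extract features for every crop in the task and rank each query
    against the database."""
    fk = feature_kwargs or {}
    features: dict[str, DescriptorSet] = {
        cid: extract_features(task.crops[cid], **fk)
        for cid in set(task.queries) | set(task.database)
    }
    db_sets = [features[cid] for cid in task.database]
    results = []
    for qid in task.queries:
        results.append(
            rank(
                features[qid],
                db_sets,
                method=method,
                k=k,
                true_id=task.truth[qid],
                seed=seed,
            )
        )
    return results


def cmc(rankings: Sequence[RankingResult], k_max: int = 20) -> CMCCurve:
    """Cumulative match characteristic over ``k = 1..k_max``.

    ``prop_matched(k)`` counts queries whose true match sits within the
    top-k; unranked true matches never count, so the curve is monotone
    nondecreasing in k and bounded by 1.
    """
    if not rankings:
        raise ValueError("no rankings")
    ranks = np.array(
        [r.true_match_rank if r.true_match_rank is not None else np.inf
         for r in rankings]
    )
    ks = np.arange(1, k_max + 1)
    prop = np.array([(ranks <= kk).mean() for kk in ks])
    return CMCCurve(k=ks, prop_matched=prop, n_queries=len(rankings))


def top_k_accuracy(rankings: Sequence[RankingResult], k: int = 10) -> float:
    return cmc(rankings, k_max=k).at(k)


def compare_accuracy(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    labels: tuple[str, str] = ("a", "b"),
) -> OddsRatioResult:
    """Odds ratio of matching success between two groups.

    ``group_a`` and ``group_b`` are ``(n_matched, n_total)``.  OR > 1 means
    group_a's queries are more matchable.  The 95% CI is Wald on log-OR
    with a Haldane 0.5 correction when any cell is zero; a table with no
    variation at all (both groups all-matched or all-unmatched) is flagged
    degenerate with no OR.
    """
    a, n_a = group_a
    b, n_b = group_b
    if not (0 <= a <= n_a and 0 <= b <= n_b and n_a >= 1 and n_b >= 1):
        raise ValueError("need 0 <= matched <= n and n >= 1 per group")
    cells = [a, n_a - a, b, n_b - b]
    group_cis = {
        labels[0]: accuracy_ci(a, n_a),
        labels[1]: accuracy_ci(b, n_b),
    }
    table = ((a, n_a - a), (b, n_b - b))
    if (a == 0 and b == 0) or (a == n_a and b == n_b):
        return OddsRatioResult(None, None, table, group_cis, degenerate=True)
    if 0 in cells:
        cells = [c + 0.5 for c in cells]
    or_ = (cells[0] / cells[1]) / (cells[2] / cells[3])
    se = float(np.sqrt(sum(1.0 / c for c in cells)))
    log_or = float(np.log(or_))
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return OddsRatioResult(float(or_), ci, table, group_cis)


def _sharpness(crop: Crop) -> float:
    gray = crop.pixels.astype(float).mean(axis=2)
    return float(np.var(ndi.laplace(gray)))


def assign_quality_scores(crops: Sequence[Crop]) -> list[int]:
    """Quality score 1-3 per crop: ground truth when recorded, otherwise a
    variance-of-Laplacian sharpness proxy cut at terciles of the batch
    (blur / motion / poor lighting all depress the Laplacian response)."""
    scores: list[int | None] = []
    missing: list[int] = []
    for i, c in enumerate(crops):
        q = (c.attributes or {}).get("quality_score")
        if q in (1, 2, 3):
            scores.append(int(q))
        else:
            scores.append(None)
            missing.append(i)
    if missing:
        sharp = np.array([_sharpness(crops[i]) for i in missing])
        t1, t2 = np.quantile(sharp, [1 / 3, 2 / 3])
        for pos, s in zip(missing, sharp):
            scores[pos] = 1 if s <= t1 else (2 if s <= t2 else 3)
    return [int(s) for s in scores]


def per_query_table(
    task: MatchTask,
    rankings: Sequence[RankingResult],
    method: str = "lnbnn",
    top_k: int = 10,
) -> pd.DataFrame:
    """Tidy per-query results for downstream modeling."""
    rows = []
    by_q = {r.query_id: r for r in rankings}
    for qid in task.queries:
        r = by_q[qid]
        c = task.crops[qid]
        rows.append(
            {
                "query_id": qid,
                "group": task.group_labels.get(qid, ""),
                "method": method,
                "true_match_rank": r.true_match_rank,
                f"matched_top{top_k}": bool(
                    r.true_match_rank is not None and r.true_match_rank <= top_k
                ),
                "quality_score": (c.attributes or {}).get("quality_score"),
                "crop_pixels": int(c.pixels.shape[0] * c.pixels.shape[1]),
            }
        )
    return pd.DataFrame(rows)
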