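"""Leave-one-out cross-validation of the decay models as date predictors.

Each resampled (t, s) set is one LOOCV round: every node is held out once,
the model is refitted to the rest under least squared error of predicted
t, and the held-out node's age is predicted from its substitutions s.
Rounds are scored by out-of-sample mean squared error (MSE_OOS, Myr
scale); models are compared over rounds-as-blocks with Friedman's test
(tie-corrected) and complete pairwise Wilcoxon signed-rank tests under a
Bonferroni correction (factor 6 for four models).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import RateSampleSet
from .fitting import FitError, fit_time_model, _to_x
from .models import RateModelKind, ex_max_substitutions, invert_time

__all__ = [
    "LoocvResult",
    "loocv_round",
    "mse_oos",
    "friedman_mean_ranks",
    "pairwise_wilcoxon_bonferroni",
    "run_loocv",
]

ALL_KINDS = (RateModelKind.VEX, RateModelKind.EX, RateModelKind.VPL, RateModelKind.PL)

#: rounds this small get the exact signed-rank null, larger ones the
#: normal approximation with continuity correction
WILCOXON_EXACT_MAX = 25


@dataclass
class LoocvResult:
    predictions: pd.DataFrame  # round_index, node_id, kind, predicted_t_myr, reference_t_myr
    mse: pd.DataFrame  # round_index x kind
    mse_summary: pd.DataFrame  # per kind: median, q2.5, q97.5
    mean_ranks: Dict[str, float]
    friedman_statistic: float
    friedman_p: float
    pairwise_p_adjusted: Dict[Tuple[str, str], float]
    n_rounds_used: int
    n_rounds_dropped: int


def mse_oos(predicted, reference) -> float:
    """Mean squared error of predicted vs reference node ages (Myr scale)."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predicted and reference must be equal-length, nonempty")
    return float(np.mean((p - r) ** 2))


def loocv_round(
    points: RateSampleSet,
    kinds: Sequence[Union[str, RateModelKind]] = ALL_KINDS,
    seed=0,
    n_starts: int = 4,
) -> pd.DataFrame:
    """One LOOCV round: hold out each node once, refit, predict its age.

    Fold fits warm-start from the full-round optimum of the same kind plus
    ``n_starts`` fresh Latin-hypercube starts.  Folds whose fit fails, or
    where the held-out s is beyond an EX fit's saturation bound, yield NaN
    predictions (flagged downstream).
    """
    kinds = [RateModelKind(k if isinstance(k, RateModelKind) else str(k).upper()) for k in kinds]
    n = len(points)
    need = max(k.n_free_params for k in kinds) + 2
    if n < need:
        raise ValueError(f"LOOCV with these kinds needs >= {need} points, got {n}")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(kinds) * (n + 1)))
    rows = []
    for kind in kinds:
        try:
            full = fit_time_model(points, kind, n_starts=n_starts * 2, seed=int(next(seeds)))
            warm = [_to_x(kind, full.params)]
        except FitError:
            warm = []
        for i in range(n):
            train = points.drop(i)
            pred = np.nan
            try:
                # warm-started fold fits skip the Nelder-Mead polish; the
                # polished full-round optimum is among their starts
                fit = fit_time_model(
                    train, kind, n_starts=n_starts, seed=int(next(seeds)),
                    warm_starts=warm, polish=False,
                )
                s_test = points.s[i]
                if s_test < ex_max_substitutions(fit.params):
                    pred = float(invert_time(fit.params, s_test))
            except FitError:
                pass  # fold flagged missing (NaN prediction)
            rows.append(
                {
                    "node_id": points.node_ids[i],
                    "kind": kind.value,
                    "predicted_t_myr": pred,
                    "reference_t_myr": float(points.t_myr[i]),
                }
            )
    return pd.DataFrame(rows)


def friedman_mean_ranks(score_matrix) -> Tuple[Dict[int, float], float, float]:
    """Within-round mean ranks (1 = smallest error) and the tie-corrected
    Friedman chi-square test over rounds-as-blocks.

    A fully tied matrix yields statistic 0, p = 1.
    """
    m = np.asarray(score_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("score matrix must be (>=2 rounds) x (>=2 kinds)")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    mean_ranks = {j: float(ranks[:, j].mean()) for j in range(m.shape[1])}
    if np.all(m == m[:, [0]]):
        return mean_ranks, 0.0, 1.0
    n, k = m.shape
    if k >= 3:
        res = stats.friedmanchisquare(*(m[:, j] for j in range(k)))
        return mean_ranks, float(res.statistic), float(res.pvalue)
    # two treatments: same tie-corrected rank statistic, chi-square df = 1
    correction = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        correction += float(np.sum(counts**3 - counts))
    rj = ranks.sum(axis=0)
    stat = (12.0 * np.sum(rj**2) / (n * k * (k + 1)) - 3.0 * n * (k + 1)) / (
        1.0 - correction / (n * k * (k**2 - 1))
    )
    return mean_ranks, float(stat), float(stats.chi2.sf(stat, k - 1))


def pairwise_wilcoxon_bonferroni(
    score_matrix, labels: Optional[Sequence[str]] = None
) -> Dict[Tuple[str, str], float]:
    """Two-sided Wilcoxon signed-rank per unordered pair of columns, with
    p multiplied by the number of pairs (6 for four models), capped at 1."""
    m = np.asarray(score_matrix, dtype=float)
    n_rounds, n_kinds = m.shape
    if labels is None:
        labels = [str(j) for j in range(n_kinds)]
    n_pairs = n_kinds * (n_kinds - 1) // 2
    out: Dict[Tuple[str, str], float] = {}
    for i, j in combinations(range(n_kinds), 2):
        diffs = m[:, i] - m[:, j]
        if np.all(diffs == 0):
            p = 1.0
        else:
            method = "exact" if n_rounds <= WILCOXON_EXACT_MAX else "approx"
            p = float(
                stats.wilcoxon(
                    m[:, i], m[:, j], alternative="two-sided",
                    method=method, correction=(method == "approx"),
                ).pvalue
            )
        out[(labels[i], labels[j])] = min(1.0, p * n_pairs)
    return out


def run_loocv(
    sets: Sequence[RateSampleSet],
    kinds: Sequence[Union[str, RateModelKind]] = ALL_KINDS,
    seed=0,
    n_starts: int = 4,
) -> LoocvResult:
    """LOOCV over many resampled rounds with model-comparison tests.

    Rounds missing any prediction for any kind are dropped from the rank
    tests and counted in ``n_rounds_dropped``.
    """
    if len(sets) == 0:
        raise ValueError("need at least one rate set")
    kinds = [RateModelKind(k if isinstance(k, RateModelKind) else str(k).upper()) for k in kinds]
    labels = [k.value for k in kinds]
    # one shared per-round seed: identical input sets yield identical scores
    round_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    frames = []
    for idx, pts in enumerate(sets):
        df = loocv_round(pts, kinds, seed=round_seed, n_starts=n_starts)
        df.insert(0, "round_index", idx)
        frames.append(df)
    predictions = pd.concat(frames, ignore_index=True)

    sq = predictions.assign(
        sqerr=(predictions.predicted_t_myr - predictions.reference_t_myr) ** 2
    )
    mse = (
        sq.groupby(["round_index", "kind"], sort=False)["sqerr"]
        .apply(lambda v: float(np.mean(v)))  # NaN if any fold missing
        .unstack()[labels]
    )
    complete = mse.dropna()
    n_dropped = len(mse) - len(complete)

    summary = pd.DataFrame(
        {
            "median": complete.median(),
            "q2.5": complete.quantile(0.025),
            "q97.5": complete.quantile(0.975),
        }
    )
    if len(complete) >= 2 and len(labels) >= 2:
        ranks_by_col, stat, p = friedman_mean_ranks(complete.to_numpy())
        mean_ranks = {labels[j]: r for j, r in ranks_by_col.items()}
        pairwise = pairwise_wilcoxon_bonferroni(complete.to_numpy(), labels)
    else:
        mean_ranks = {lab: float("nan") for lab in labels}
        stat, p = float("nan"), float("nan")
        pairwise = {}
    return LoocvResult(
        predictions=predictions,
        mse=mse,
        mse_summary=summary,
        mean_ranks=mean_ranks,
        friedman_statistic=stat,
        friedman_p=p,
        pairwise_p_adjusted=pairwise,
        n_rounds_used=len(complete),
        n_rounds_dropped=n_dropped,
    )
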