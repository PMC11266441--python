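"""Cross-validation schemes and evaluation metrics.

Three schemes, all 5-fold with 10 repetitions by default:

* **CV2** (sparse testing): hold out 20% of the environment x hybrid
  combinations of the last two years; hybrid and environment both remain
  represented in training, only the combination is new.
* **CV1** (new hybrids): hold out all final-year records of 20% of the
  final-year hybrids and remove every record of those hybrids from the
  last-two-years training frame.
* **CV0** (new year): predict final-year records of 20% of the final-year
  hybrids from their earlier-year records plus an additional 60% sample of
  the remaining earlier-year hybrids; no final-year record enters training.

Metrics: Pearson accuracy, the Coincidence Index CI = (B - R)/(T - R) on the
top 20%, the Jaccard tester-set overlap between training and validation
populations, and the Meng-Rosenthal-Rubin z-test for comparing two dependent
overlapping correlations (Bonferroni-corrected across the model-pair family).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import KeyMismatchError, SplitError, UndefinedMetricError
from .utils import env_year

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    scheme: str  # "CV2" | "CV1" | "CV0"
    folds: int
    repetitions: int
    seed: int
    records: pd.DataFrame  # the records the plan indexes (Env, Hybrid, y, Year)
    assignments: dict  # (rep, fold) -> (train_idx, valid_idx) positional arrays

    def split(self, rep: int, fold: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        tr, va = self.assignments[(rep, fold)]
        return self.records.iloc[tr], self.records.iloc[va]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "folds": self.folds,
            "repetitions": self.repetitions,
            "seed": self.seed,
            "assignments": {
                f"{rep}:{fold}": {"train": tr.tolist(), "valid": va.tolist()}
                for (rep, fold), (tr, va) in self.assignments.items()
            },
        }


def _with_year(blues: pd.DataFrame) -> pd.DataFrame:
    out = blues.reset_index(drop=True).copy()
    out["Year"] = out["Env"].map(env_year)
    return out


def _last_years(records: pd.DataFrame, n: int = 2) -> pd.DataFrame:
    years = sorted(records["Year"].unique())
    return records[records["Year"].isin(years[-n:])].reset_index(drop=True)


def split_cv2(
    blues: pd.DataFrame, seed: int, folds: int = 5, repetitions: int = 10
) -> CVPlan:
    """Sparse-testing plan over the last two years' env x hybrid combinations."""
    records = _last_years(_with_year(blues))
    n = len(records)
    if n < folds:
        raise SplitError(f"need >= {folds} combinations, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    assignments = {}
    idx_all = np.arange(n)
    for rep in range(1, repetitions + 1):
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        for fold, valid in enumerate(parts, start=1):
            valid = np.sort(valid)
            train = np.setdiff1d(idx_all, valid)
            assignments[(rep, fold)] = (train, valid)
    return CVPlan("CV2", folds, repetitions, seed, records, assignments)


def split_cv1(
    blues: pd.DataFrame, seed: int, folds: int = 5, repetitions: int = 10
) -> CVPlan:
    """New-hybrid plan: final-year records of held-out hybrids, with every
    record of those hybrids removed from the last-two-years training frame."""
    records = _last_years(_with_year(blues))
    final_year = int(records["Year"].max())
    hybrids = np.array(sorted(records.loc[records["Year"] == final_year, "Hybrid"].unique()))
    if len(hybrids) < folds:
        raise SplitError(f"need >= {folds} final-year hybrids")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    assignments = {}
    idx_all = np.arange(len(records))
    hyb_col = records["Hybrid"].to_numpy()
    year_col = records["Year"].to_numpy()
    for rep in range(1, repetitions + 1):
        groups = np.array_split(rng.permutation(hybrids), folds)
        for fold, held in enumerate(groups, start=1):
            held = set(held)
            in_held = np.array([h in held for h in hyb_col])
            valid = idx_all[in_held & (year_col == final_year)]
            train = idx_all[~in_held]
            assignments[(rep, fold)] = (train, valid)
    return CVPlan("CV1", folds, repetitions, seed, records, assignments)


def split_cv0(
    blues: pd.DataFrame,
    seed: int,
    folds: int = 5,
    repetitions: int = 10,
    extra_frac: float = 0.6,
) -> CVPlan:
    """New-year plan: per fold, validation is the final-year records of 20% of
    the final-year hybrids (those with earlier records — "known" hybrids);
    training is those hybrids' earlier-year records plus the earlier-year
    records of an additional ``extra_frac`` sample of the remaining
    earlier-year hybrids.  The 60% default reproduces an ~80:20
    train:validation record proportion on a study shaped like the default
    synthetic design."""
    records = _with_year(blues)
    years = sorted(records["Year"].unique())
    if len(years) < 3:
        raise SplitError("CV0 needs three years of records")
    final_year = years[-1]
    earlier = records["Year"] < final_year
    earlier_hybrids = set(records.loc[earlier, "Hybrid"])
    final_hybrids = sorted(
        set(records.loc[records["Year"] == final_year, "Hybrid"]) & earlier_hybrids
    )
    if len(final_hybrids) < folds:
        raise SplitError("too few known final-year hybrids for CV0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    idx_all = np.arange(len(records))
    hyb_col = records["Hybrid"].to_numpy()
    year_col = records["Year"].to_numpy()
    assignments = {}
    hybrids_arr = np.array(final_hybrids)
    for rep in range(1, repetitions + 1):
        groups = np.array_split(rng.permutation(hybrids_arr), folds)
        for fold, held in enumerate(groups, start=1):
            held_set = set(held)
            pool = sorted(earlier_hybrids - held_set)
            n_extra = int(round(extra_frac * len(pool)))
            extra = set(rng.choice(pool, size=n_extra, replace=False)) if n_extra else set()
            train_hybrids = held_set | extra
            in_train_h = np.array([h in train_hybrids for h in hyb_col])
            in_held = np.array([h in held_set for h in hyb_col])
            valid = idx_all[in_held & (year_col == final_year)]
            train = idx_all[in_train_h & (year_col < final_year)]
            frac = len(train) / max(len(train) + len(valid), 1)
            if frac < 0.5:
                logger.warning(
                    "CV0 rep %d fold %d: achieved training fraction %.1f%%",
                    rep, fold, 100 * frac,
                )
            assignments[(rep, fold)] = (train, valid)
    return CVPlan("CV0", folds, repetitions, seed, records, assignments)


SPLITTERS = {"CV2": split_cv2, "CV1": split_cv1, "CV0": split_cv0}


def pearson_accuracy(pred) -> float:
    """Pearson correlation between observed and predicted yield."""
    df = pred.records if hasattr(pred, "records") else pred
    obs = np.asarray(df["y_observed"], dtype=float)
    est = np.asarray(df["y_predicted"], dtype=float)
    if len(obs) < 3:
        raise UndefinedMetricError("need >= 3 records for a correlation")
    if np.std(obs) == 0 or np.std(est) == 0:
        raise UndefinedMetricError("zero variance in observed or predicted values")
    return float(stats.pearsonr(obs, est)[0])


def coincidence_index(
    observed, predicted, top_frac: float = 0.20, ids=None
) -> float:
    """Coincidence Index (B - R) / (T - R) on the top ``top_frac`` selection.

    T individuals are selected from each ranking (T = ceil(top_frac * N),
    ties broken by stable sort on id), B is the overlap, and R = top_frac * T
    is the overlap expected by chance when both rankings select the same
    fraction.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("paired vectors must have equal length")
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must lie in (0, 1)")
    N = len(observed)
    T = int(math.ceil(top_frac * N))
    R = top_frac * T
    if T - R == 0:
        raise UndefinedMetricError("degenerate selection: T equals R")
    ids = np.asarray(ids if ids is not None else np.arange(N))
    order = np.lexsort((ids, -observed))
    top_obs = set(ids[order[:T]])
    order = np.lexsort((ids, -predicted))
    top_pred = set(ids[order[:T]])
    B = len(top_obs & top_pred)
    return (B - R) / (T - R)


def tester_overlap(plan: CVPlan, tester_of: dict) -> float:
    """Mean Jaccard overlap of training vs validation tester sets over all
    (repetition, fold) cells of a cross-validation plan."""
    unmapped = sorted(set(plan.records["Hybrid"]) - set(tester_of))
    if unmapped:
        raise KeyMismatchError("hybrids without a tester mapping", unmapped)
    testers = plan.records["Hybrid"].map(tester_of).to_numpy()
    vals = []
    for (rep, fold), (tr, va) in plan.assignments.items():
        W = set(testers[tr])
        Z = set(testers[va])
        union = W | Z
        vals.append(len(W & Z) / len(union) if union else float("nan"))
    return float(np.mean(vals))


def meng_test(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z-test for two dependent overlapping correlations.

    ``r1`` and ``r2`` each correlate the shared variable (the observed BLUEs)
    with one of two prediction vectors whose intercorrelation is ``r12``;
    ``n`` is the common sample size.  Returns (z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise UndefinedMetricError("|r| = 1 overflows the Fisher transform")
    if n < 4:
        raise UndefinedMetricError("need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    r_sq = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - r_sq)), 1.0)
    h = (1.0 - f * r_sq) / (1.0 - r_sq)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni correction over the comparison family."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)


def fold_metrics(predictions: list) -> pd.DataFrame:
    """Per-(model, rep, fold) Pearson accuracy and Coincidence Index."""
    rows = []
    for ps in predictions:
        df = ps.records
        try:
            r = pearson_accuracy(ps)
        except UndefinedMetricError:
            r = float("nan")
        try:
            ci = coincidence_index(
                df["y_observed"], df["y_predicted"], ids=df["Hybrid"].to_numpy()
            )
        except UndefinedMetricError:
            ci = float("nan")
        rows.append(
            {
                "model": ps.model_kind,
                "repetition": ps.repetition,
                "fold": ps.fold,
                "n": len(df),
                "pearson_r": r,
                "coincidence_index": ci,
            }
        )
    return pd.DataFrame(rows)


def model_comparisons(predictions: list) -> pd.DataFrame:
    """Pairwise Meng tests between models on their pooled predictions.

    Predictions of each model are pooled over (rep, fold); each pair's
    r12 is the correlation of the two models' prediction vectors aligned on
    (Env, Hybrid, rep, fold).  Bonferroni corrects across all pairs.
    """
    pooled = {}
    for ps in predictions:
        df = ps.records.copy()
        df["repetition"] = ps.repetition
        df["fold"] = ps.fold
        pooled.setdefault(ps.model_kind, []).append(df)
    frames = {
        m: pd.concat(parts, ignore_index=True).set_index(
            ["Env", "Hybrid", "repetition", "fold"]
        ).sort_index()
        for m, parts in pooled.items()
    }
    models = sorted(frames)
    rows = []
    for i, m1 in enumerate(models):
        for m2 in models[i + 1 :]:
            a, b = frames[m1].align(frames[m2], join="inner", axis=0)
            obs = a["y_observed"].to_numpy()
            p1, p2 = a["y_predicted"].to_numpy(), b["y_predicted"].to_numpy()
            r1 = float(np.corrcoef(obs, p1)[0, 1])
            r2 = float(np.corrcoef(obs, p2)[0, 1])
            r12 = float(np.corrcoef(p1, p2)[0, 1])
            z, p = meng_test(r1, r2, r12, len(obs))
            rows.append(
                {
                    "model_1": m1,
                    "model_2": m2,
                    "r_1": r1,
                    "r_2": r2,
                    "r_12": r12,
                    "n": len(obs),
                    "meng_z": z,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_raw"])
    return out
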