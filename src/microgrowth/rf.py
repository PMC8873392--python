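"""Permutation-calibrated random-forest inference.

Exploratory layer: random-forest regressions of zBMI on genus CLR
abundances, one cross-sectional and one future-outcome model per stool
time point.  Because RF accuracy estimates have no analytic null, inference
is by outcome permutation: the whole fitting procedure (including
hyperparameter tuning, to keep the null honest about optimisation bias) is
re-run B times on permuted outcomes, and

    p_pearson = (1 + #{null >= observed}) / (B + 1)
    p_oob     = (1 + #{null <= observed}) / (B + 1)   (lower error is better)

The accuracy statistic is the median over repeats of repeated k-fold CV,
with the Pearson correlation computed on pooled out-of-fold predictions
per repeat; OOB mean squared error from a full-data fit is reported
alongside.  Per-feature inference uses permutation importances with
null-importance p-values (refit on permuted outcomes), and the family of
models is FDR-corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .compositions import TaxonTable, clr, relative_abundance
from .forest import RandomForest
from .screen import bh_adjust

__all__ = [
    "RFHyperparams",
    "AccuracyResult",
    "PermutationTestResult",
    "ImportanceResult",
    "tune_rf",
    "repeated_cv",
    "permutation_null_test",
    "bh_over_models",
    "altmann_importance",
    "run_model_family",
]


@dataclass(frozen=True)
class RFHyperparams:
    mtry: int
    sample_fraction: float
    n_trees: int = 500

    def __post_init__(self):
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.n_trees < 50:
            raise ValueError("n_trees must be >= 50 for stable OOB estimates")


@dataclass
class AccuracyResult:
    oob_mse: float
    cv_pearson_median: float
    per_repeat_pearson: np.ndarray
    per_repeat_oob: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class PermutationTestResult:
    observed: AccuracyResult
    null_pearson: np.ndarray
    null_oob: np.ndarray
    p: dict[str, float]
    params: RFHyperparams


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # feature, importance, p


def _forest(params: RFHyperparams, seed) -> RandomForest:
    return RandomForest(
        n_trees=params.n_trees,
        mtry=params.mtry,
        sample_fraction=params.sample_fraction,
        seed=int(seed),
    )


def tune_rf(
    X,
    y,
    n_candidates: int = 20,
    n_trees: int = 500,
    seed: int = 0,
) -> RFHyperparams:
    """Randomised search over (mtry, sample_fraction) minimising OOB-MSE."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if np.std(y) == 0:
        raise ValueError("outcome has zero variance; nothing to tune")
    rng = np.random.default_rng(seed)
    seen = set()
    candidates = []
    for _ in range(n_candidates * 4):
        cand = (
            int(rng.integers(1, p + 1)),
            float(np.round(rng.uniform(0.3, 1.0), 3)),
        )
        if cand not in seen:
            seen.add(cand)
            candidates.append(cand)
        if len(candidates) == n_candidates:
            break
    best, best_mse = None, np.inf
    for mtry, frac in candidates:
        params = RFHyperparams(mtry, frac, n_trees)
        est = _forest(params, rng.integers(2**31)).fit(X, y, compute_oob=True)
        if est.oob_mse_ < best_mse:
            best, best_mse = params, est.oob_mse_
    return best


def repeated_cv(
    X,
    y,
    params: RFHyperparams,
    folds: int = 4,
    repeats: int = 10,
    seed: int = 0,
    compute_oob: bool = True,
) -> AccuracyResult:
    """Repeated k-fold CV accuracy: median over repeats of pooled-prediction
    Pearson r, plus full-data OOB-MSE."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(y) < 2 * folds:
        raise ValueError("need at least 2*folds samples")
    rng = np.random.default_rng(seed)
    pearsons = []
    for _ in range(repeats):
        preds = np.empty_like(y)
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for tr, te in kf.split(X):
            est = _forest(params, rng.integers(2**31)).fit(X[tr], y[tr])
            preds[te] = est.predict(X[te])
        if np.std(preds) == 0 or np.std(y) == 0:
            warnings.warn("constant predictions/outcome in a repeat; repeat dropped")
            continue
        pearsons.append(stats.pearsonr(preds, y).statistic)
    pearsons = np.asarray(pearsons)
    oob = np.nan
    if compute_oob:
        oob = float(
            _forest(params, rng.integers(2**31)).fit(X, y, compute_oob=True).oob_mse_
        )
    return AccuracyResult(
        oob_mse=oob,
        cv_pearson_median=float(np.median(pearsons)) if len(pearsons) else np.nan,
        per_repeat_pearson=pearsons,
    )


def permutation_null_test(
    X,
    y,
    B: int = 199,
    repeats: int = 10,
    folds: int = 4,
    seed: int = 0,
    retune: bool = True,
    params: RFHyperparams | None = None,
    tune_candidates: int = 20,
    n_trees: int = 500,
    compute_oob: bool = True,
) -> PermutationTestResult:
    """Outcome-permutation test of RF accuracy.

    Observed metrics come from (tuned) repeated CV; B permutations of y,
    each re-tuned when ``retune`` so the null includes the optimisation
    step, give the null distributions.
    """
    if B < 19:
        raise ValueError("B must be >= 19 for usable p-value resolution")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    if params is None:
        params = tune_rf(X, y, n_candidates=tune_candidates, n_trees=n_trees,
                         seed=int(rng.integers(2**31)))
    observed = repeated_cv(X, y, params, folds=folds, repeats=repeats,
                           seed=int(rng.integers(2**31)), compute_oob=compute_oob)
    null_pearson = np.empty(B)
    null_oob = np.empty(B)
    for b in range(B):
        yb = rng.permutation(y)
        pb = params
        if retune:
            pb = tune_rf(X, yb, n_candidates=tune_candidates, n_trees=n_trees,
                         seed=int(rng.integers(2**31)))
        res = repeated_cv(X, yb, pb, folds=folds, repeats=repeats,
                          seed=int(rng.integers(2**31)), compute_oob=compute_oob)
        null_pearson[b] = res.cv_pearson_median
        null_oob[b] = res.oob_mse
    p = {
        "pearson": float(
            (1 + np.sum(null_pearson >= observed.cv_pearson_median)) / (B + 1)
        )
    }
    if compute_oob:
        p["oob"] = float((1 + np.sum(null_oob <= observed.oob_mse)) / (B + 1))
    return PermutationTestResult(observed, null_pearson, null_oob, p, params)


def bh_over_models(p_values) -> np.ndarray:
    """BH q-values across a family of model p-values."""
    return bh_adjust(p_values)


def altmann_importance(
    X,
    y,
    params: RFHyperparams,
    B: int = 199,
    seed: int = 0,
    n_repeats: int = 3,
    feature_names=None,
) -> ImportanceResult:
    """Null-importance p-values for permutation variable importances.

    Observed importances (mean accuracy decrease, i.e. mean MSE increase
    when the feature is permuted) come from the fit on the real outcome;
    the null importances from B refits on permuted outcomes.  Constant
    features get importance 0 and p = 1 by convention.
    """
    if B < 19:
        raise ValueError("B must be >= 19")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    def importances(yv):
        est = _forest(params, rng.integers(2**31)).fit(X, yv)
        base = float(np.mean((est.predict(X) - yv) ** 2))
        out = np.zeros(X.shape[1])
        Xp = X.copy()
        for j in range(X.shape[1]):
            col = Xp[:, j].copy()
            acc = 0.0
            for _ in range(n_repeats):
                Xp[:, j] = rng.permutation(col)
                acc += float(np.mean((est.predict(Xp) - yv) ** 2))
            Xp[:, j] = col
            out[j] = acc / n_repeats - base  # mean accuracy (MSE) decrease
        return out

    obs = importances(y)
    null = np.vstack([importances(rng.permutation(y)) for _ in range(B)])
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (B + 1)
    constant = X.std(axis=0) == 0
    obs = np.where(constant, 0.0, obs)
    p = np.where(constant, 1.0, p)
    return ImportanceResult(
        pd.DataFrame({"feature": feature_names, "importance": obs, "p": p})
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# the model family (one cross-sectional + one future model per stool tp)

def _features_for(table: TaxonTable, mode: str, pseudocount: float) -> pd.DataFrame:
    if mode == "clr":
        return pd.DataFrame(
            clr(table.counts.to_numpy(float), pseudocount),
            index=table.counts.index,
            columns=table.counts.columns,
        )
    if mode == "relative":
        return relative_abundance(table, level="genus")
    raise ValueError(f"unknown feature mode {mode!r}")


def run_model_family(
    taxon_tables: dict[str, TaxonTable],
    cohort: pd.DataFrame,
    anthro_order,
    feature_mode: str = "clr",
    pseudocount: float = 0.5,
    B: int = 199,
    repeats: int = 10,
    folds: int = 4,
    tune_candidates: int = 20,
    n_trees: int = 500,
    retune: bool = True,
    importance_p_threshold: float = 0.05,
    importance_B: int | None = None,
    compute_oob: bool = True,
    min_samples: int = 20,
    seed: int = 0,
):
    """Run the full RF family and assemble a Table-4-shaped report.

    For each stool time point, fit a cross-sectional model (microbiota and
    zBMI at the same time point) and, when a later anthropometry time
    point exists, a future model (microbiota at t, zBMI at the next time
    point).  Permutation p-values per metric, BH q-values over the whole
    family, and importances with null-importance p-values for every model
    whose smallest metric p-value passes the threshold.

    Returns (report DataFrame, {model label: ImportanceResult},
    {model label: PermutationTestResult}).
    """
    anthro_order = list(anthro_order)
    zwide = cohort.pivot(index="subject", columns="time_point", values="zbmi")
    master = np.random.SeedSequence(seed)

    models = []  # (label, tp_micro, tp_z)
    for tp in taxon_tables:
        models.append((f"{tp}->{tp}", tp, tp))
        if tp in anthro_order:
            i = anthro_order.index(tp)
            if i + 1 < len(anthro_order):
                models.append((f"{tp}->{anthro_order[i + 1]}", tp, anthro_order[i + 1]))

    results: dict[str, PermutationTestResult] = {}
    feats: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for (label, tpm, tpz), ss in zip(models, master.spawn(len(models))):
        table = taxon_tables[tpm]
        F = _features_for(table, feature_mode, pseudocount)
        subj = pd.Index([sid.rsplit("_", 1)[0] for sid in F.index])
        unmatched = [s for s in subj if s not in zwide.index]
        if unmatched:
            raise ValueError(f"sample ids with no cohort subject: {unmatched[:5]}")
        if tpz not in zwide.columns:
            continue
        yv = zwide.loc[subj, tpz].to_numpy(float)
        ok = ~np.isnan(yv)
        if ok.sum() < min_samples:
            continue
        Xv = F.to_numpy(float)[ok]
        results[label] = permutation_null_test(
            Xv, yv[ok], B=B, repeats=repeats, folds=folds,
            seed=int(ss.generate_state(1)[0] % 2**31), retune=retune,
            tune_candidates=tune_candidates, n_trees=n_trees,
            compute_oob=compute_oob,
        )
        feats[label] = (Xv, yv[ok], list(F.columns))

    rows = []
    for label, res in results.items():
        tpm, tpz = label.split("->")
        rows.append({"time_microbiota": tpm, "time_zbmi": tpz, "metric": "pearson",
                     "median": res.observed.cv_pearson_median, "p": res.p["pearson"]})
        if compute_oob:
            rows.append({"time_microbiota": tpm, "time_zbmi": tpz, "metric": "oob",
                         "median": res.observed.oob_mse, "p": res.p["oob"]})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = bh_over_models(report["p"].to_numpy())

    importances: dict[str, ImportanceResult] = {}
    imp_seeds = master.spawn(len(results))
    for (label, res), ss in zip(results.items(), imp_seeds):
        if min(res.p.values()) < importance_p_threshold:
            Xv, yv, names = feats[label]
            importances[label] = altmann_importance(
                Xv, yv, res.params, B=importance_B or B,
                seed=int(ss.generate_state(1)[0] % 2**31), feature_names=names,
            )
    return report, importances, results
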