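"""Cross-validation, prediction accuracy and selection response.

Prediction accuracy is the Pearson correlation between GEBVs and observed
phenotypes in the validation fold — the estimand used when assessing genomic
selection on real populations, where true breeding values are unknown.  A
k-fold plan partitions individuals into balanced folds (1,218 individuals in
5 folds gives training/validation splits of 975/243); each fold serves once
for validation, so every individual is predicted exactly once.  Selection
response is the mean of the selected top fraction minus the population mean,
the realized gain from one round of truncation selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .wgr import BayesianWGR, RRBLUP, WGRConfig

__all__ = [
    "CVPlan",
    "CVResult",
    "SelectionReport",
    "make_cv_plan",
    "accuracy",
    "run_cv",
    "selection_response",
    "accuracy_heritability_summary",
]


@dataclass
class CVPlan:
    """Balanced fold assignment (labels 1..n_folds) under a seed."""

    n_folds: int
    assignments: np.ndarray
    seed: int

    def folds(self):
        """Yield (fold_label, train_index, validation_index)."""
        for k in range(1, self.n_folds + 1):
            val = np.flatnonzero(self.assignments == k)
            train = np.flatnonzero(self.assignments != k)
            yield k, train, val


@dataclass
class CVResult:
    trait: str
    method: str
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    gebv_table: pd.DataFrame  # per-individual observed/predicted (validation fold)


@dataclass
class SelectionReport:
    trait: str
    top_fraction: float
    response: float
    selected_ids: list


def make_cv_plan(n_individuals: int, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Random balanced partition; fold sizes differ by at most one."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n_individuals:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_individuals, n_folds)
    sizes = [base + 1 if k < extra else base for k in range(n_folds)]
    labels = np.repeat(np.arange(1, n_folds + 1), sizes)
    assignments = labels[rng.permutation(n_individuals)]
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def accuracy(observed, predicted) -> float:
    """Pearson correlation between observed values and GEBVs."""
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if len(observed) != len(predicted):
        raise ValueError("vectors must have equal length")
    if len(observed) < 3:
        raise ValueError("need at least 3 pairs")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("accuracy undefined for constant input")
    return float(np.corrcoef(observed, predicted)[0, 1])


def _fit_one(method: str, y_train, G_train, config: WGRConfig | None, fold_seed: int):
    if method == "RRBLUP":
        return RRBLUP(y_train, G_train).fit()
    cfg_base = config if config is not None else WGRConfig()
    cfg = WGRConfig(**{**cfg_base.__dict__, "method": method, "seed": fold_seed})
    return BayesianWGR(y_train, G_train, config=cfg).fit()


def run_cv(
    G: GenotypeMatrix,
    y,
    methods,
    plan: CVPlan,
    config: WGRConfig | None = None,
    trait: str = "trait",
) -> dict:
    """Cross-validated accuracy per method on a shared fold plan.

    For each fold the model is fitted on training individuals only and GEBVs
    are computed for the validation fold; per-method results aggregate the
    per-fold accuracies (mean and sd over folds).  Bayesian fits derive a
    distinct sampler seed per fold from the config seed.
    """
    if not methods:
        raise ValueError("methods list is empty")
    y = np.asarray(y, dtype=np.float64)
    base_seed = (config.seed if config is not None else 0) or 0
    results = {}
    for method in methods:
        fold_acc = []
        rows = []
        for k, train, val in plan.folds():
            method_tag = sum(ord(c) for c in method)  # deterministic across runs
            fold_seed = (base_seed * 1009 + 31 * k + method_tag) % (2**31 - 1)
            fit = _fit_one(method, y[train], G.subset_individuals(train), config, fold_seed)
            pred = fit.predict(G.subset_individuals(val))
            try:
                fold_acc.append(accuracy(y[val], pred))
            except ValueError:
                warnings.warn(f"fold {k}: accuracy undefined; recorded as NaN")
                fold_acc.append(np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "id": G.individual_ids[val],
                        "fold": k,
                        "observed": y[val],
                        "predicted": pred,
                    }
                )
            )
        fold_acc = np.asarray(fold_acc)
        results[method] = CVResult(
            trait=trait,
            method=method,
            per_fold_accuracy=fold_acc,
            mean_accuracy=float(np.nanmean(fold_acc)),
            sd_accuracy=float(np.nanstd(fold_acc, ddof=1)) if len(fold_acc) > 1 else 0.0,
            gebv_table=pd.concat(rows, ignore_index=True),
        )
    return results


def selection_response(
    y, top_fraction: float = 0.25, individual_ids=None, maximize: bool = True,
    trait: str = "trait",
) -> SelectionReport:
    """Mean of the top fraction minus the overall mean.

    With ``maximize=False`` the lowest values are selected (traits bred
    downward) and the signed difference is negative when selection gains
    ground in the desired direction.
    """
    y = np.asarray(y, dtype=np.float64)
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(y)
    k = int(round(top_fraction * n))
    if k == 0:
        raise ValueError("selection fraction selects zero individuals")
    order = np.argsort(y)
    chosen = order[-k:] if maximize else order[:k]
    response = float(y[chosen].mean() - y.mean())
    if individual_ids is None:
        individual_ids = np.arange(n)
    ids = [individual_ids[i] for i in chosen]
    return SelectionReport(trait=trait, top_fraction=top_fraction,
                           response=response, selected_ids=ids)


def accuracy_heritability_summary(mean_accuracy_by_trait: dict,
                                  h2_by_trait: dict) -> tuple:
    """Correlation of per-trait mean CV accuracy against genomic h2.

    Both mappings must cover the same >= 3 traits; accuracy values are the
    per-trait means over methods, heritabilities the subset-based estimates.
    Returns ``(r, table)``.
    """
    traits = sorted(mean_accuracy_by_trait)
    if set(traits) != set(h2_by_trait):
        raise ValueError("trait sets of accuracies and heritabilities differ")
    if len(traits) < 3:
        raise ValueError("need at least 3 traits for the correlation")
    acc = np.array([mean_accuracy_by_trait[t] for t in traits])
    h2 = np.array([h2_by_trait[t] for t in traits])
    if acc.std() == 0 or h2.std() == 0:
        r = 1.0 if np.allclose(acc - acc.mean(), h2 - h2.mean()) else np.nan
    else:
        r = float(np.corrcoef(acc, h2)[0, 1])
    table = pd.DataFrame({"trait": traits, "mean_accuracy": acc, "h2_subset": h2})
    return r, table
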