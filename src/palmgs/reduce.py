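"""Marker-density reduction: association-ranked subsets and LD pruning.

RR-BLUP B ranks markers by a training-only association scan, refits RR-BLUP
on growing top-k subsets (stepwise, default +10 markers up to 20,000) and
records the cross-validated accuracy per marker count.  The optimal density
rule scans the accuracy at 100-marker windows and stops where the next
increment falls below 0.05.  LD pruning walks the ranked list greedily and
keeps a marker only if its squared dosage correlation (r^2) with every
already-kept marker stays below a cutoff (default 0.6), so each LD group
contributes a single representative.

Validation data never enters the ranking or the fits: every fold ranks with
its own training scan, and accuracies are measured on the held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .assoc import gwas_scan
from .containers import GenotypeMatrix
from .evaluate import CVPlan, accuracy
from .wgr import RRBLUP

__all__ = [
    "AccuracyCurve",
    "LDPruneResult",
    "ld_r2",
    "ld_prune_ranked",
    "rrblup_b_curve",
    "optimal_density",
    "ld_filtered_curve",
]


@dataclass
class AccuracyCurve:
    """Cross-validated accuracy as a function of marker count."""

    marker_counts: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    trait: str = "trait"
    strategy: str = "ranked"  # or "ranked+ld"
    fold_rankings: list = field(default_factory=list)  # per-fold marker order used

    def __post_init__(self):
        self.marker_counts = np.asarray(self.marker_counts, dtype=np.int64)
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=np.float64)
        self.sd_accuracy = np.asarray(self.sd_accuracy, dtype=np.float64)
        if np.any(np.diff(self.marker_counts) <= 0):
            raise ValueError("marker counts must be strictly increasing")
        if not (len(self.marker_counts) == len(self.mean_accuracy) == len(self.sd_accuracy)):
            raise ValueError("curve arrays must have equal length")

    def at(self, count: int) -> float:
        idx = np.flatnonzero(self.marker_counts == count)
        if len(idx) == 0:
            raise KeyError(f"curve not evaluated at {count} markers")
        return float(self.mean_accuracy[idx[0]])


@dataclass
class LDPruneResult:
    kept: np.ndarray  # ordered marker indices (rank order preserved)
    dropped: np.ndarray
    dropped_against: dict  # dropped marker -> kept marker it was pruned against
    r2_cutoff: float


def ld_r2(g_a, g_b) -> float:
    """Squared Pearson correlation of two dosage vectors (symmetric).

    Constant vectors are an error: monomorphic markers must be filtered by
    the caller.  Invariant to flipping the counted allele (g -> 2 - g).
    """
    g_a = np.asarray(g_a, dtype=np.float64)
    g_b = np.asarray(g_b, dtype=np.float64)
    if len(g_a) != len(g_b):
        raise ValueError("vectors must have equal length")
    if g_a.std() == 0 or g_b.std() == 0:
        raise ValueError("LD undefined for a monomorphic marker")
    r = np.corrcoef(g_a, g_b)[0, 1]
    return float(min(r * r, 1.0))


def ld_prune_ranked(
    G: GenotypeMatrix,
    ranked_markers,
    r2_cutoff: float = 0.6,
    individuals=None,
) -> LDPruneResult:
    """Greedy LD pruning in rank order (best marker first).

    A marker is kept iff its r^2 with every already-kept marker is below the
    cutoff; the best-ranked member of each LD group therefore survives.  A
    cutoff >= 1.0 disables the filter (everything kept).  Markers that are
    monomorphic among the chosen individuals cannot be in LD and are kept.
    """
    ranked_markers = np.asarray(ranked_markers, dtype=np.int64)
    if len(ranked_markers) == 0:
        return LDPruneResult(
            kept=np.array([], dtype=np.int64),
            dropped=np.array([], dtype=np.int64),
            dropped_against={},
            r2_cutoff=r2_cutoff,
        )
    if r2_cutoff >= 1.0:
        return LDPruneResult(
            kept=ranked_markers.copy(),
            dropped=np.array([], dtype=np.int64),
            dropped_against={},
            r2_cutoff=r2_cutoff,
        )
    D = G.dosages[:, ranked_markers].astype(np.float64)
    if individuals is not None:
        D = D[np.asarray(individuals)]
    D = D - D.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", D, D))
    poly = norms > 0
    Z = np.where(poly, 1.0, np.nan) * D / np.where(poly, norms, 1.0)

    kept_pos: list = []
    dropped_pos: list = []
    dropped_against: dict = {}
    for pos in range(len(ranked_markers)):
        if not poly[pos]:
            kept_pos.append(pos)
            continue
        if kept_pos:
            kept_poly = [p for p in kept_pos if poly[p]]
            if kept_poly:
                r2 = (Z[:, kept_poly].T @ Z[:, pos]) ** 2
                hit = np.flatnonzero(r2 >= r2_cutoff)
                if len(hit) > 0:
                    dropped_pos.append(pos)
                    dropped_against[int(ranked_markers[pos])] = int(
                        ranked_markers[kept_poly[hit[0]]]
                    )
                    continue
        kept_pos.append(pos)
    return LDPruneResult(
        kept=ranked_markers[kept_pos],
        dropped=ranked_markers[dropped_pos],
        dropped_against=dropped_against,
        r2_cutoff=r2_cutoff,
    )


def _count_grid(step: int, max_markers: int, counts=None) -> np.ndarray:
    if counts is not None:
        grid = np.asarray(sorted(set(int(c) for c in counts)), dtype=np.int64)
    else:
        grid = np.arange(step, max_markers + 1, step, dtype=np.int64)
        if len(grid) == 0 or grid[-1] != max_markers:
            grid = np.append(grid, max_markers)
    return grid[grid >= 1]


def _fold_curve(G, y, train, val, order, grid):
    """Validation accuracy of top-k RR-BLUP fits for one fold."""
    acc = np.empty(len(grid))
    y_train, y_val = y[train], y[val]
    D_train = G.dosages[train].astype(np.float64)
    D_val = G.dosages[val].astype(np.float64)
    for i, k in enumerate(grid):
        top = order[:k]
        fit = RRBLUP(y_train, D_train[:, top]).fit()
        pred = fit.intercept + D_val[:, top] @ fit.marker_effects
        acc[i] = accuracy(y_val, pred)
    return acc


def rrblup_b_curve(
    G: GenotypeMatrix,
    y,
    cv_plan: CVPlan,
    step: int = 10,
    max_markers: int = 20000,
    counts=None,
    trait: str = "trait",
) -> AccuracyCurve:
    """Association-ranked stepwise marker addition (RR-BLUP B).

    Per fold: a training-only association scan ranks all markers; RR-BLUP is
    refitted on the top-k subset for each count k on the grid (multiples of
    ``step`` up to ``max_markers``, or an explicit ``counts`` grid) and the
    validation accuracy recorded.  The curve reports the per-count mean and
    sd over folds.  Each fold uses its own ranking.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    y = np.asarray(y, dtype=np.float64)
    m = G.n_markers
    if max_markers > m:
        warnings.warn(f"max_markers {max_markers} exceeds {m} markers; truncated")
        max_markers = m
    grid = _count_grid(step, max_markers, counts)
    grid = grid[grid <= m]

    fold_acc = []
    fold_rankings = []
    for k, train, val in cv_plan.folds():
        if len(train) < 10:
            raise ValueError(f"fold {k} has fewer than 10 training individuals")
        res = gwas_scan(G.subset_individuals(train), y[train])
        order = res.ranking
        fold_rankings.append(order)
        fold_acc.append(_fold_curve(G, y, train, val, order, grid))
    A = np.vstack(fold_acc)
    return AccuracyCurve(
        marker_counts=grid,
        mean_accuracy=A.mean(axis=0),
        sd_accuracy=A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1]),
        trait=trait,
        strategy="ranked",
        fold_rankings=fold_rankings,
    )


def optimal_density(curve: AccuracyCurve, window: int = 100, threshold: float = 0.05) -> int:
    """Smallest marker count whose next window increment is below threshold.

    Accuracy is read at multiples of ``window``; scanning upward, the first
    count whose following +window step improves accuracy by less than
    ``threshold`` is returned — the last count before gains become
    negligible.  If every increment meets the threshold the maximum count is
    returned with a warning.
    """
    counts = curve.marker_counts
    at_window = counts[counts % window == 0]
    if len(at_window) < 2:
        raise ValueError("curve must be evaluated at >= 2 window multiples")
    acc = np.array([curve.at(int(c)) for c in at_window])
    for i in range(len(at_window) - 1):
        if acc[i + 1] - acc[i] < threshold:
            return int(at_window[i])
    warnings.warn("no window increment falls below the threshold; returning max count")
    return int(at_window[-1])


def ld_filtered_curve(
    G: GenotypeMatrix,
    y,
    cv_plan: CVPlan,
    top_n: int = 300,
    r2_cutoff: float = 0.6,
    plot_n: int = 600,
    step: int = 10,
    trait: str = "trait",
) -> tuple:
    """Accuracy curves with and without LD filtering of the ranked list.

    Per fold the top ``top_n`` training-ranked markers are LD-pruned (r^2
    cutoff, one marker per LD group, rank priority); both the pruned and the
    raw ranked list then produce accuracy curves on a common count grid so
    the two strategies can be compared side by side (up to ``plot_n`` for
    the unfiltered curve, up to the shortest pruned list for the filtered
    one).  Returns ``(filtered_curve, unfiltered_curve)``.
    """
    y = np.asarray(y, dtype=np.float64)
    m = G.n_markers
    if top_n > m:
        raise ValueError("top_n exceeds the number of markers")
    plot_n = min(plot_n, m)

    fold_orders = []
    fold_kept = []
    for k, train, val in cv_plan.folds():
        res = gwas_scan(G.subset_individuals(train), y[train])
        order = res.ranking
        pruned = ld_prune_ranked(G, order[:top_n], r2_cutoff=r2_cutoff, individuals=train)
        fold_orders.append(order)
        fold_kept.append(pruned.kept)

    min_kept = min(len(kept) for kept in fold_kept)
    grid_filtered = _count_grid(step, min(min_kept, plot_n))
    grid_plain = _count_grid(step, plot_n)

    acc_f, acc_p = [], []
    for (k, train, val), order, kept in zip(cv_plan.folds(), fold_orders, fold_kept):
        acc_f.append(_fold_curve(G, y, train, val, kept, grid_filtered))
        acc_p.append(_fold_curve(G, y, train, val, order, grid_plain))
    Af, Ap = np.vstack(acc_f), np.vstack(acc_p)

    def build(grid, A, strategy, rankings):
        return AccuracyCurve(
            marker_counts=grid,
            mean_accuracy=A.mean(axis=0),
            sd_accuracy=A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1]),
            trait=trait,
            strategy=strategy,
            fold_rankings=rankings,
        )

    return (
        build(grid_filtered, Af, "ranked+ld", fold_kept),
        build(grid_plain, Ap, "ranked", fold_orders),
    )
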