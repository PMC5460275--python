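"""Single-marker association scan (-log10 p scores) for marker ranking.

Each marker is tested one at a time in an ordinary least-squares model
``y ~ intercept + dosage (+ covariates)``; the two-sided t-test p-value of
the dosage slope is reported as a score ``-log10(p)``.  Scores feed two
consumers: heritability estimation on the markers passing a score cutoff
(1.3, i.e. p <= 0.05), and the association-ranked stepwise marker addition
of RR-BLUP B, where the scan is always run on training individuals only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = ["AssociationResult", "gwas_scan", "select_by_score"]

_P_FLOOR = 1e-300


@dataclass
class AssociationResult:
    """Per-marker association scores, effects and deterministic ranks."""

    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    score: np.ndarray  # -log10(p), >= 0
    effect: np.ndarray  # OLS slope, trait units per dosage unit
    rank: np.ndarray  # 1-based, by descending score then genome order
    monomorphic: np.ndarray  # flagged markers (score and effect forced to 0)

    @property
    def ranking(self) -> np.ndarray:
        """Marker indices ordered best-first (rank 1 first)."""
        return np.argsort(self.rank, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chrom": self.chrom,
                "pos": self.pos_cm,
                "effect": self.effect,
                "score": self.score,
                "rank": self.rank,
                "monomorphic": self.monomorphic,
            }
        )


def gwas_scan(G: GenotypeMatrix, y, covariates=None) -> AssociationResult:
    """Scan every marker with a single-marker linear model.

    Ties in score are broken by genome order, making the ranking fully
    deterministic.  Monomorphic markers get score 0 and effect 0 and are
    flagged.  Scores are invariant to affine transformations of ``y``.
    """
    y = np.asarray(y, dtype=np.float64)
    n = G.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length does not match genotypes")
    if n < 10:
        raise ValueError("association scan requires at least 10 individuals")
    if np.var(y) == 0.0:
        raise ValueError("phenotype has zero variance")

    X = G.dosages.astype(np.float64)
    df = n - 2
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        Q = np.column_stack([np.ones(n), C])
        # Frisch-Waugh: residualize y and every marker on the covariates
        beta_y, *_ = np.linalg.lstsq(Q, y, rcond=None)
        yc = y - Q @ beta_y
        beta_x, *_ = np.linalg.lstsq(Q, X, rcond=None)
        Xc = X - Q @ beta_x
        df = n - 2 - C.shape[1]
    else:
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)

    sxx = np.einsum("ij,ij->j", Xc, Xc)
    mono = sxx <= 1e-12
    sxy = Xc.T @ yc
    syy = float(yc @ yc)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        sse = np.maximum(syy - slope**2 * sxx, 0.0)
        sigma2 = sse / df
        se = np.sqrt(np.where(mono, np.inf, sigma2 / np.where(mono, 1.0, sxx)))
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(mono, 1.0, np.clip(p, _P_FLOOR, 1.0))
    score = -np.log10(p)
    score[mono] = 0.0
    slope[mono] = 0.0

    order = np.lexsort((np.arange(G.n_markers), -score))
    rank = np.empty(G.n_markers, dtype=np.int64)
    rank[order] = np.arange(1, G.n_markers + 1)

    return AssociationResult(
        marker_ids=G.marker_ids,
        chrom=G.chrom,
        pos_cm=G.pos_cm,
        score=score,
        effect=slope,
        rank=rank,
        monomorphic=mono,
    )


def select_by_score(res: AssociationResult, cutoff: float = 1.3) -> np.ndarray:
    """Markers with score >= cutoff, in genome order.

    The comparison is inclusive: a printed cutoff of 1.3 is the rounded
    -log10(0.05) convention.  An empty selection is returned with a warning
    (the caller decides how to proceed).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    selected = np.flatnonzero(res.score >= cutoff)
    if len(selected) == 0:
        warnings.warn(f"no markers reach score cutoff {cutoff}")
    return selected
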