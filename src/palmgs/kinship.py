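"""Pairwise relatedness with the Lynch & Li allele-sharing moment estimator.

For a biallelic locus the similarity between two genotypes is scored 1 when
the genotypes are identical, 0.75 when a homozygote meets a heterozygote
(one shared allele), and 0 for opposite homozygotes.  Averaged over loci this
similarity S_xy is corrected by its expectation S_0 under unrelatedness,
computed from allele frequencies as S_0 = 2*a2 - a3 with a_k = p^k + q^k, and
rescaled:

    r_xy = (S_xy - S_0) / (1 - S_0)

The estimate lives on the relatedness (r) scale: ~0 for unrelated pairs,
~0.25 for half sibs, ~0.5 for full sibs or parent-offspring, ~1 for
duplicated samples.  Protocol defaults follow common practice for large SNP
panels: a random subsample of 15,000 SNPs and 100 bootstrap replicates over
loci for per-pair standard errors, with no inbreeding adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = ["KinshipResult", "lynch_li_pair", "kinship_matrix"]


@dataclass
class KinshipResult:
    """Pairwise relatedness estimates for a sample of individuals."""

    pairwise: np.ndarray  # symmetric (n, n); diagonal set to 1.0 by convention
    bootstrap_sd: np.ndarray | None
    snps_used: np.ndarray
    summary: tuple  # (mean, min, max) over off-diagonal entries
    individual_ids: np.ndarray


def _locus_s0(freqs: np.ndarray) -> np.ndarray:
    p = np.asarray(freqs, dtype=np.float64)
    q = 1.0 - p
    a2 = p**2 + q**2
    a3 = p**3 + q**3
    return 2.0 * a2 - a3


def lynch_li_pair(g_i, g_j, freqs) -> float:
    """Lynch & Li relatedness for one pair of dosage vectors.

    Monomorphic loci (frequency 0 or 1) are excluded with a warning; an
    empty usable-locus set is an error.  Symmetric in (g_i, g_j) and
    invariant to swapping the counted allele.
    """
    g_i = np.asarray(g_i, dtype=np.float64)
    g_j = np.asarray(g_j, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    if not (len(g_i) == len(g_j) == len(freqs)):
        raise ValueError("genotype and frequency vectors must have equal length")
    usable = (freqs > 0.0) & (freqs < 1.0)
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} monomorphic loci from the estimate"
        )
    if not usable.any():
        raise ValueError("no polymorphic loci available for the estimator")
    gi, gj, p = g_i[usable], g_j[usable], freqs[usable]
    diff = np.abs(gi - gj)
    s = np.where(diff == 0, 1.0, np.where(diff == 1, 0.75, 0.0))
    s_bar = s.mean()
    s0_bar = _locus_s0(p).mean()
    return float((s_bar - s0_bar) / (1.0 - s0_bar))


def _similarity_matrix(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean allele-sharing similarity for all pairs at once."""
    a0 = (dosages == 0).astype(np.float32)
    a1 = (dosages == 1).astype(np.float32)
    a2 = (dosages == 2).astype(np.float32)
    w = weights.astype(np.float32)
    eq = (a0 * w) @ a0.T + (a1 * w) @ a1.T + (a2 * w) @ a2.T
    adj = (a0 * w) @ a1.T + (a1 * w) @ a0.T + (a1 * w) @ a2.T + (a2 * w) @ a1.T
    return (eq + 0.75 * adj) / w.sum()


def kinship_matrix(
    G: GenotypeMatrix,
    n_snps: int = 15000,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> KinshipResult:
    """All pairwise Lynch & Li estimates on a random marker subsample.

    Markers are subsampled without replacement (all markers with a warning
    if fewer than ``n_snps`` are available); the bootstrap resamples loci
    with replacement to give a per-pair standard deviation.  Allele
    frequencies for the null expectation come from the full analyzed sample.
    No inbreeding adjustment is applied.
    """
    if G.n_individuals < 2:
        raise ValueError("kinship requires at least 2 individuals")
    rng = np.random.default_rng(seed)
    poly = np.flatnonzero(G.polymorphic)
    if len(poly) == 0:
        raise ValueError("no polymorphic markers available")
    if n_snps > len(poly):
        warnings.warn(
            f"requested {n_snps} SNPs but only {len(poly)} polymorphic; using all"
        )
        chosen = poly
    else:
        chosen = np.sort(rng.choice(poly, size=n_snps, replace=False))

    D = np.ascontiguousarray(G.dosages[:, chosen])
    freqs = D.mean(axis=0) / 2.0
    s0 = _locus_s0(freqs)
    m_used = len(chosen)

    def estimate(w: np.ndarray) -> np.ndarray:
        s = _similarity_matrix(D, w)
        s0_bar = float(np.dot(s0, w) / w.sum())
        return (s - s0_bar) / (1.0 - s0_bar)

    ones = np.ones(m_used)
    r = estimate(ones)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0

    boot_sd = None
    if n_bootstrap and n_bootstrap > 0:
        acc = np.zeros_like(r)
        acc2 = np.zeros_like(r)
        for _ in range(n_bootstrap):
            w = rng.multinomial(m_used, np.full(m_used, 1.0 / m_used)).astype(np.float64)
            rb = estimate(w)
            acc += rb
            acc2 += rb**2
        mean = acc / n_bootstrap
        var = np.maximum(acc2 / n_bootstrap - mean**2, 0.0)
        boot_sd = np.sqrt(var)
        np.fill_diagonal(boot_sd, 0.0)

    off = r[~np.eye(len(r), dtype=bool)]
    summary = (float(off.mean()), float(off.min()), float(off.max()))
    return KinshipResult(
        pairwise=r.astype(np.float64),
        bootstrap_sd=None if boot_sd is None else boot_sd.astype(np.float64),
        snps_used=chosen,
        summary=summary,
        individual_ids=G.individual_ids,
    )
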