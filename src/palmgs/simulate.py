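"""Synthetic breeding populations with half-sib family structure.

The generator emulates a commercial cross between a small set of pollen
parents (sires) and many seed parents (dams): founders are drawn in linkage
equilibrium, one generation of crossing produces full-sib families that share
sires (half sibs across families), and recombination against a per-chromosome
genetic map generates block LD among the progeny.  Quantitative traits are
built from marker-QTL effects plus homoscedastic Gaussian noise scaled to a
target narrow-sense heritability.

The defaults reflect a desk-scale version of a large half-sib oil-palm
population: 40 families of 30 progeny (1,200 palms), 16 chromosomes of
~1 Morgan carrying 5,008 SNPs in total, with oligogenic (few large QTL) and
polygenic (many small QTL) trait presets at heritabilities 0.7 and 0.45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .containers import GenotypeMatrix, SimTruth, TraitTable

__all__ = ["SimConfig", "simulate_population", "simulate_trait", "architecture_presets"]


@dataclass
class SimConfig:
    """Parameters of a simulated half-sib breeding population.

    Attributes
    ----------
    n_founders : int
        Total founders; the last ``n_sires`` act as shared pollen parents,
        the first ``n_families`` as seed parents (requires
        ``n_founders >= n_families + n_sires`` unless dams double as sires).
    n_sires : int
        Number of sires shared round-robin across families.  Few sires give
        a population dominated by half-sib relationships.
    chromosome_length_morgans : float
        Genetic map length per chromosome; crossover counts are Poisson with
        this expectation.
    founder_maf_range : tuple
        Founder allele frequencies are drawn uniformly from this interval.
    qtl_effect_distribution : str
        ``"gaussian"`` (many small effects) or ``"geometric-series"``
        (effects decaying as 0.8**k with random signs; few large QTL).
    target_h2 : float
        Noise is scaled so the realized heritability matches this target in
        expectation.
    """

    n_founders: int = 42
    n_families: int = 40
    progeny_per_family: int = 30
    n_chromosomes: int = 16
    markers_per_chromosome: int = 313
    chromosome_length_morgans: float = 1.0
    founder_maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 600
    qtl_effect_distribution: str = "gaussian"
    target_h2: float = 0.45
    seed: int = 0
    n_sires: int = 2
    trait_name: str = "trait"

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def n_progeny(self) -> int:
        return self.n_families * self.progeny_per_family

    def validate(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ValueError(
                f"n_qtl ({self.n_qtl}) exceeds total markers ({self.n_markers})"
            )
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.chromosome_length_morgans <= 0:
            raise ValueError("chromosome_length_morgans must be positive")
        if self.n_sires < 1 or self.n_families < 1 or self.progeny_per_family < 1:
            raise ValueError("population counts must be positive")
        if self.n_founders < self.n_families + self.n_sires:
            raise ValueError(
                "n_founders must cover n_families dams plus n_sires sires"
            )
        if self.qtl_effect_distribution not in ("gaussian", "geometric-series"):
            raise ValueError(
                f"unknown qtl_effect_distribution {self.qtl_effect_distribution!r}"
            )


def architecture_presets() -> dict:
    """Trait-architecture presets as deltas over :class:`SimConfig`.

    ``"oligogenic"`` mirrors high-heritability traits controlled by a few
    large QTL; ``"polygenic"`` mirrors medium-heritability traits controlled
    by many small QTL.
    """
    return {
        "oligogenic": {
            "n_qtl": 8,
            "qtl_effect_distribution": "geometric-series",
            "target_h2": 0.7,
        },
        "polygenic": {
            "n_qtl": 600,
            "qtl_effect_distribution": "gaussian",
            "target_h2": 0.45,
        },
    }


def _gamete(haplos: np.ndarray, chrom_slices, chrom_pos, length_m, rng) -> np.ndarray:
    """One recombinant gamete from a parent's (2, m) haplotype pair."""
    m = haplos.shape[1]
    gam = np.empty(m, dtype=np.int8)
    for sl, pos in zip(chrom_slices, chrom_pos):
        n_x = rng.poisson(length_m)
        start = rng.integers(0, 2)
        if n_x == 0:
            gam[sl] = haplos[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, length_m * 100.0, size=n_x))
        # haplotype index alternates at each crossover
        segment = (start + np.searchsorted(xpos, pos, side="right")) % 2
        block = haplos[:, sl]
        gam[sl] = block[segment, np.arange(sl.stop - sl.start)]
    return gam


def simulate_trait(
    G: GenotypeMatrix,
    n_qtl: int,
    target_h2: float,
    qtl_effect_distribution: str = "gaussian",
    seed: int = 0,
) -> tuple:
    """Simulate one trait on existing genotypes.

    Returns ``(phenotype, SimTruth)``.  QTL are chosen among genotyped
    markers (perfect tagging); noise is Gaussian and homoscedastic, scaled
    so var(TBV)/var(phenotype) matches ``target_h2`` in expectation.  A
    target of exactly 0 produces a pure-noise phenotype (all effects zero).
    """
    if n_qtl > G.n_markers:
        raise ValueError("n_qtl exceeds number of markers")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    if n_qtl == 0 or target_h2 == 0.0:
        qtl_idx = np.sort(rng.choice(G.n_markers, size=n_qtl, replace=False))
        effects = np.zeros(n_qtl)
        tbv = np.zeros(n)
        y = rng.standard_normal(n)
        return y, SimTruth(qtl_idx, effects, tbv, 0.0)

    poly = np.flatnonzero(G.polymorphic)
    if len(poly) < n_qtl:
        raise ValueError("not enough polymorphic markers for requested n_qtl")
    qtl_idx = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    if qtl_effect_distribution == "gaussian":
        effects = rng.standard_normal(n_qtl)
    elif qtl_effect_distribution == "geometric-series":
        mags = 0.8 ** np.arange(n_qtl)
        signs = rng.choice([-1.0, 1.0], size=n_qtl)
        effects = rng.permutation(mags) * signs
    else:
        raise ValueError(f"unknown qtl_effect_distribution {qtl_effect_distribution!r}")

    tbv = G.dosages[:, qtl_idx].astype(np.float64) @ effects
    var_g = tbv.var()
    if var_g == 0.0:
        warnings.warn("QTL set is monomorphic; trait has no genetic variance")
        y = rng.standard_normal(n)
        return y, SimTruth(qtl_idx, effects, tbv - tbv.mean(), 0.0)
    if target_h2 >= 1.0:
        noise = np.zeros(n)
    else:
        sigma_e = np.sqrt(var_g * (1.0 - target_h2) / target_h2)
        noise = rng.normal(0.0, sigma_e, size=n)
    y = tbv + noise
    realized = float(tbv.var() / y.var()) if y.var() > 0 else 0.0
    return y, SimTruth(qtl_idx, effects, tbv, realized)


def simulate_population(config: SimConfig) -> tuple:
    """Simulate genotypes, one trait, and the ground truth.

    Returns ``(GenotypeMatrix, TraitTable, SimTruth)``.  Founders are drawn
    with independent loci at frequencies inside ``founder_maf_range``
    (columns monomorphic among founders are redrawn); families are single
    crosses dam x sire with sires shared round-robin across families, so
    progeny of different families with a common sire are half sibs.
    Reproducible bit-for-bit under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    n_chr = config.n_chromosomes
    mpc = config.markers_per_chromosome
    length_m = config.chromosome_length_morgans

    chrom = np.repeat(np.arange(1, n_chr + 1), mpc)
    pos_cm = np.concatenate(
        [np.sort(rng.uniform(0.0, length_m * 100.0, size=mpc)) for _ in range(n_chr)]
    )
    marker_ids = np.array(
        [f"chr{c}_snp{i % mpc + 1}" for i, c in enumerate(chrom)], dtype=object
    )
    chrom_slices = [slice(c * mpc, (c + 1) * mpc) for c in range(n_chr)]
    chrom_pos = [pos_cm[sl] for sl in chrom_slices]

    lo, hi = config.founder_maf_range
    freqs = rng.uniform(lo, hi, size=m)
    n_f = config.n_founders
    haplos = (rng.random((n_f, 2, m)) < freqs).astype(np.int8)
    # redraw loci fixed among founders so every marker can segregate
    for _ in range(100):
        tot = haplos.sum(axis=(0, 1))
        bad = np.flatnonzero((tot == 0) | (tot == 2 * n_f))
        if len(bad) == 0:
            break
        haplos[:, :, bad] = (rng.random((n_f, 2, len(bad))) < freqs[bad]).astype(np.int8)

    dam_ids = [f"DAM{i + 1}" for i in range(config.n_families)]
    sire_ids = [f"SIRE{i + 1}" for i in range(config.n_sires)]
    n_prog = config.n_progeny
    dosages = np.empty((n_prog, m), dtype=np.int8)
    ids = np.empty(n_prog, dtype=object)
    pedigree = []
    row = 0
    for fam in range(config.n_families):
        dam = haplos[fam]
        sire_no = fam % config.n_sires
        sire = haplos[n_f - config.n_sires + sire_no]
        for j in range(config.progeny_per_family):
            g_d = _gamete(dam, chrom_slices, chrom_pos, length_m, rng)
            g_s = _gamete(sire, chrom_slices, chrom_pos, length_m, rng)
            dosages[row] = g_d + g_s
            ids[row] = f"F{fam + 1}_P{j + 1}"
            pedigree.append((sire_ids[sire_no], dam_ids[fam]))
            row += 1

    G = GenotypeMatrix(dosages, marker_ids, chrom, pos_cm, ids)
    fixed = int((~G.polymorphic).sum())
    if fixed:
        warnings.warn(f"{fixed} markers are monomorphic in the progeny sample")

    y, truth = simulate_trait(
        G,
        n_qtl=config.n_qtl,
        target_h2=config.target_h2,
        qtl_effect_distribution=config.qtl_effect_distribution,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth.pedigree = pedigree
    traits = TraitTable.from_arrays(ids, **{config.trait_name: y})
    return G, traits, truth


def preset_config(name: str, base: SimConfig | None = None, **overrides) -> SimConfig:
    """Build a SimConfig from an architecture preset plus overrides."""
    presets = architecture_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    base = base if base is not None else SimConfig()
    return replace(base, **{**presets[name], **overrides})
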