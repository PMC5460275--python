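"""Core in-memory containers shared across the package.

A :class:`GenotypeMatrix` stores additive dosages (counts of one allele per
biallelic marker, 0/1/2) together with the marker map; a :class:`TraitTable`
stores per-individual phenotype values for one or more named traits; a
:class:`SimTruth` records the ground truth of a simulated population (QTL
positions/effects, true breeding values, realized heritability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "TraitTable", "SimTruth"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive-dosage matrix with marker map.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_markers)
        Counts of the counted allele per individual and marker.  Simulated
        data is strictly integer in {0, 1, 2}; after mean-imputation of
        missing real-data genotypes entries may be fractional in [0, 2].
    marker_ids : ndarray of str
    chrom : ndarray of int
        Chromosome index per marker.
    pos_cm : ndarray of float
        Genetic position in centimorgans.  Markers must be sorted by
        (chrom, pos_cm).
    individual_ids : ndarray of str
    """

    dosages: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.dosages.shape
        if len(self.marker_ids) != m or len(self.chrom) != m or len(self.pos_cm) != m:
            raise ValueError("marker annotation length does not match dosage columns")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if not np.all(np.isfinite(self.dosages)):
            raise ValueError("dosages contain non-finite values")
        if self.dosages.min(initial=0) < 0 or self.dosages.max(initial=0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if m > 1:
            key = np.lexsort((self.pos_cm, self.chrom))
            if not np.array_equal(key, np.arange(m)):
                raise ValueError("markers must be sorted by (chrom, pos_cm)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele, recomputed as column mean / 2."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def polymorphic(self) -> np.ndarray:
        """Boolean mask of markers segregating in this sample."""
        p = self.allele_freq
        return (p > 0.0) & (p < 1.0)

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.sort(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            marker_ids=self.marker_ids[index],
            chrom=self.chrom[index],
            pos_cm=self.pos_cm[index],
            individual_ids=self.individual_ids,
        )

    def subset_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            marker_ids=self.marker_ids,
            chrom=self.chrom,
            pos_cm=self.pos_cm,
            individual_ids=self.individual_ids[index],
        )


class TraitTable:
    """Per-individual phenotype values, one column per named trait."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        self._frame = frame.copy()
        self._frame.index = self._frame.index.astype(str)

    @classmethod
    def from_arrays(cls, individual_ids, **traits) -> "TraitTable":
        idx = pd.Index([str(i) for i in individual_ids], name="id")
        return cls(pd.DataFrame(traits, index=idx))

    @property
    def individual_ids(self) -> np.ndarray:
        return self._frame.index.to_numpy(dtype=object)

    @property
    def trait_names(self) -> list:
        return list(self._frame.columns)

    def values(self, trait: str, individual_ids=None) -> np.ndarray:
        """Trait values, optionally aligned to a given individual order."""
        if trait not in self._frame.columns:
            raise KeyError(f"unknown trait {trait!r}")
        col = self._frame[trait]
        if individual_ids is not None:
            wanted = [str(i) for i in individual_ids]
            missing = [i for i in wanted if i not in self._frame.index]
            if missing:
                raise KeyError(f"individuals missing from trait table: {missing[:5]}")
            col = col.loc[wanted]
        vals = col.to_numpy(dtype=np.float64)
        if np.isnan(vals).all():
            raise ValueError(f"trait {trait!r} has no values")
        return vals

    def add_trait(self, name: str, values) -> None:
        self._frame[name] = np.asarray(values, dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)


@dataclass
class SimTruth:
    """Ground truth of a simulated population (recovery target for tests)."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float
    pedigree: list = field(default_factory=list)  # per-individual (sire_id, dam_id)

    def to_dict(self) -> dict:
        return {
            "qtl_indices": [int(i) for i in self.qtl_indices],
            "qtl_effects": [float(x) for x in self.qtl_effects],
            "true_breeding_values": [float(x) for x in self.true_breeding_values],
            "realized_h2": float(self.realized_h2),
            "pedigree": [list(p) for p in self.pedigree],
        }
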