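"""Readers and writers for the formats the pipeline touches.

Genotypes: PLINK .bed/.bim/.fam (2-bit SNP-major codec), additive-dosage TSV
(markers as rows, individuals as columns), VCF (read-only, via cyvcf2).
Dosages count the A1 (minor/alternate) allele per the format's convention.
Phenotypes: TSV with a header, id column first.  Results: TSV/JSON plus a
manifest listing every artifact with a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SimTruth, TraitTable

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_truth",
    "write_results",
]

log = logging.getLogger("palmgs")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes, counted allele = A1: 00 hom A1 (dosage 2), 10 het (1),
# 11 hom A2 (0), 01 missing
_CODE_TO_DOSAGE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}
MISSING_RATE_MAX = 0.10


def write_genotypes(G: GenotypeMatrix, prefix, fmt: str = "plink-bed") -> list:
    """Write genotypes; returns the list of files written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "plink-bed":
        return _write_plink(G, prefix)
    if fmt == "dosage-tsv":
        path = prefix.with_suffix(".dosage.tsv")
        df = pd.DataFrame(
            G.dosages.T,
            columns=[str(i) for i in G.individual_ids],
        )
        df.insert(0, "pos_cm", G.pos_cm)
        df.insert(0, "chrom", G.chrom)
        df.insert(0, "marker", G.marker_ids)
        df.to_csv(path, sep="\t", index=False)
        return [path]
    raise ValueError(f"unknown genotype format {fmt!r}")


def _write_plink(G: GenotypeMatrix, prefix: Path) -> list:
    n, m = G.n_individuals, G.n_markers
    bed = prefix.with_suffix(".bed")
    dos = np.asarray(np.rint(G.dosages), dtype=np.int8)
    code = np.empty((m, n), dtype=np.uint8)
    code[dos.T == 2] = 0b00
    code[dos.T == 1] = 0b10
    code[dos.T == 0] = 0b11
    nbytes = (n + 3) // 4
    packed = np.zeros((m, nbytes), dtype=np.uint8)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        packed[:, (cols - offset) // 4 + 0] |= code[:, cols] << (2 * offset)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = prefix.with_suffix(".bim")
    with open(bim, "w") as fh:
        for j in range(m):
            bp = int(round(G.pos_cm[j] * 1e4)) + 1
            fh.write(
                f"{G.chrom[j]}\t{G.marker_ids[j]}\t{G.pos_cm[j]:.6f}\t{bp}\tA\tB\n"
            )
    fam = prefix.with_suffix(".fam")
    with open(fam, "w") as fh:
        for iid in G.individual_ids:
            fh.write(f"0\t{iid}\t0\t0\t0\t-9\n")
    return [bed, bim, fam]


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bed = prefix.with_suffix(".bed")
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "marker", "cm", "bp", "a1", "a2"],
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{bed}: malformed .bed magic bytes at offset 0")
    nbytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * nbytes:
        raise ValueError(f"{bed}: unexpected length at offset {3 + len(body)}")
    packed = body.reshape(m, nbytes)
    dosage = np.empty((m, n), dtype=np.float64)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        codes = (packed[:, (cols - offset) // 4] >> (2 * offset)) & 0b11
        lut = np.array([2.0, np.nan, 1.0, 0.0])
        dosage[:, cols] = lut[codes]
    dosage = dosage.T
    dosage = _impute(dosage, bim_df["marker"].to_numpy())
    kept = ~np.isnan(dosage).any(axis=0)
    return _assemble(
        dosage[:, kept],
        bim_df.loc[kept, "marker"].to_numpy(dtype=object),
        bim_df.loc[kept, "chrom"].to_numpy(),
        bim_df.loc[kept, "cm"].to_numpy(dtype=np.float64),
        fam_df["iid"].astype(str).to_numpy(dtype=object),
    )


def _impute(dosage: np.ndarray, marker_ids) -> np.ndarray:
    """Drop markers above the missing-rate threshold, mean-impute the rest."""
    miss = np.isnan(dosage)
    rate = miss.mean(axis=0)
    drop = rate > MISSING_RATE_MAX
    if drop.any():
        log.info("dropping %d markers with missing rate > %.0f%%",
                 int(drop.sum()), MISSING_RATE_MAX * 100)
        dosage = dosage.copy()
        dosage[:, drop] = np.nan
    fill = np.where(miss.any(axis=0) & ~drop)[0]
    if len(fill):
        log.info("mean-imputing missing dosages at %d markers", len(fill))
        dosage = dosage.copy()
        for j in fill:
            col = dosage[:, j]
            col[np.isnan(col)] = np.nanmean(col)
    return dosage


def _assemble(dosage, marker_ids, chrom, pos_cm, individual_ids) -> GenotypeMatrix:
    order = np.lexsort((pos_cm, chrom))
    return GenotypeMatrix(
        dosages=dosage[:, order],
        marker_ids=np.asarray(marker_ids)[order],
        chrom=np.asarray(chrom)[order],
        pos_cm=np.asarray(pos_cm)[order],
        individual_ids=individual_ids,
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["marker", "chrom", "pos_cm"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: dosage TSV must start with columns {required}")
    ind = df.columns[3:].to_numpy(dtype=object)
    dosage = df.iloc[:, 3:].to_numpy(dtype=np.float64).T
    dosage = _impute(dosage, df["marker"].to_numpy())
    kept = ~np.isnan(dosage).any(axis=0)
    return _assemble(
        dosage[:, kept],
        df.loc[kept, "marker"].to_numpy(dtype=object),
        df.loc[kept, "chrom"].to_numpy(),
        df.loc[kept, "pos_cm"].to_numpy(dtype=np.float64),
        ind,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, ids, chroms, pos = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=np.float64)
        d = np.full(len(gt), np.nan)
        d[gt == 0] = 0.0
        d[gt == 1] = 1.0
        d[gt == 3] = 2.0
        rows.append(d)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(_chrom_to_int(var.CHROM))
        pos.append(var.POS / 1e4)  # bp -> approximate cM (1 cM per 10 kb)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-biallelic records")
    if not rows:
        raise ValueError(f"{path}: no biallelic records found")
    dosage = np.vstack(rows).T
    dosage = _impute(dosage, np.asarray(ids))
    kept = ~np.isnan(dosage).any(axis=0)
    return _assemble(
        dosage[:, kept],
        np.asarray(ids, dtype=object)[kept],
        np.asarray(chroms)[kept],
        np.asarray(pos, dtype=np.float64)[kept],
        samples,
    )


def _chrom_to_int(name: str) -> int:
    s = str(name).lower().removeprefix("chr")
    try:
        return int(s)
    except ValueError:
        return sum(ord(c) for c in s) % 1000 + 100  # stable fallback


def read_genotypes(path_or_prefix, fmt: str | None = None) -> GenotypeMatrix:
    """Load genotypes from PLINK bed, dosage TSV or VCF (auto-detected)."""
    p = Path(path_or_prefix)
    if fmt is None:
        if p.suffix == ".vcf" or str(p).endswith(".vcf.gz"):
            fmt = "vcf"
        elif str(p).endswith(".dosage.tsv") or p.suffix == ".tsv":
            fmt = "dosage-tsv"
        else:
            fmt = "plink-bed"
    if fmt == "plink-bed":
        prefix = p.with_suffix("") if p.suffix == ".bed" else p
        return _read_plink(prefix)
    if fmt == "dosage-tsv":
        path = p if p.suffix == ".tsv" else p.with_suffix(".dosage.tsv")
        return _read_dosage_tsv(path)
    if fmt == "vcf":
        return _read_vcf(p)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path) -> TraitTable:
    """TSV with header, id column first; one column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus trait columns")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"{path}: duplicate ids {dupes[:5]}")
    df = df.set_index(id_col)
    for col in df.columns:
        if df[col].isna().all():
            raise ValueError(f"{path}: trait {col!r} is empty")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value in trait {col!r} at id {row!r}"
            )
        df[col] = coerced
    return TraitTable(df)


def write_phenotypes(traits: TraitTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = traits.to_frame()
    frame.index.name = "id"
    frame.to_csv(path, sep="\t")
    return path


def write_truth(truth: SimTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def read_truth(path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        qtl_indices=np.asarray(d["qtl_indices"], dtype=np.int64),
        qtl_effects=np.asarray(d["qtl_effects"], dtype=np.float64),
        true_breeding_values=np.asarray(d["true_breeding_values"], dtype=np.float64),
        realized_h2=float(d["realized_h2"]),
        pedigree=[tuple(p) for p in d.get("pedigree", [])],
    )


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(tables: dict, outdir, config: dict | None = None) -> Path:
    """Write result tables (DataFrame -> TSV, mapping -> JSON) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False)
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=1, default=_jsonable))
        written.append(path.name)
    manifest = {
        "files": sorted(written),
        "config": config or {},
        "config_hash": config_hash(config or {}),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=_jsonable))
    return mpath


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
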