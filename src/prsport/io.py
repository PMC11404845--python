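"""Readers/writers for the on-disk formats the pipeline touches.

Formats: VCF v4.2 (read via cyvcf2, written as plain text), PLINK1
bed/bim/fam (SNP-major bed, magic 0x6c 0x1b 0x01), tab-separated GWAS
summary statistics, and self-describing JSON model files.

Coordinates are 1-based in every on-disk format; only in-memory interval
logic (see :mod:`prsport.ld`) uses 0-based half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ParseError",
    "SchemaError",
    "MissingVariantError",
    "read_genotypes",
    "write_vcf",
    "write_plink1",
    "read_summary_stats",
    "write_summary_stats",
    "save_model",
    "load_model",
]

SUMSTAT_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "STAT", "P", "N", "MAF"]

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A genotype file failed structural validation."""


class SchemaError(ValueError):
    """A tabular file is missing required columns."""


class MissingVariantError(KeyError):
    """A cohort lacks variants a trained model requires."""


@dataclass
class GenotypeMatrix:
    """Samples x variants additive alternate-allele dosages.

    ``dosages`` is float with values {0, 1, 2} and NaN for missing calls;
    ``variants`` carries chrom, pos (1-based), id, ref, alt and optional
    info_score per variant, aligned with the dosage columns.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample count mismatch")
        if len(self.variants) != m:
            raise ValueError("variant count mismatch")
        if len(set(self.samples)) != n:
            raise ParseError("duplicated sample IDs")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant; missing calls are excluded
        from the denominator."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.samples),
            self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[idx], [self.samples[i] for i in idx], self.variants,
        )


# ---------------------------------------------------------------------------
# VCF

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write unphased diploid genotypes as minimal VCF v4.2 text."""
    path = Path(path)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        v = gm.variants
        for j in range(gm.m):
            gts = [
                "./." if np.isnan(d) else gt_map[float(d)]
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom[j]}\t{int(v.pos[j])}\t{v.id[j]}\t{v.ref[j]}\t"
                f"{v.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ParseError("duplicated sample IDs in VCF header")
    rows, meta = [], []
    for rec in vcf:
        gts = rec.genotypes  # [allele1, allele2, phased]
        dos = np.empty(len(samples))
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise ParseError(
                    f"ploidy != 2 at {rec.CHROM}:{rec.POS} sample {samples[i]}"
                )
            a, b = g[0], g[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        alt = rec.ALT[0] if rec.ALT else "."
        meta.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                     rec.REF, alt))
        rows.append(dos)
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, variants)


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam (SNP-major). A1 is stored as the alternate allele so
# that the 2-bit codes map to alt-allele dosage: 00 -> 2, 10 -> 1, 11 -> 0,
# 01 -> missing.

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def write_plink1(gm: GenotypeMatrix, prefix) -> None:
    prefix = str(prefix)
    v = gm.variants
    with open(prefix + ".bim", "w") as fh:
        for j in range(gm.m):
            fh.write(f"{v.chrom[j]}\t{v.id[j]}\t0\t{int(v.pos[j])}\t"
                     f"{v.alt[j]}\t{v.ref[j]}\n")
    with open(prefix + ".fam", "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n = gm.n
    code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(gm.m):
            col = gm.dosages[:, j]
            buf = bytearray(-(-n // 4))
            for i in range(n):
                d = col[i]
                c = 0b01 if np.isnan(d) else code[float(d)]
                buf[i >> 2] |= c << ((i & 3) * 2)
            fh.write(bytes(buf))


def _read_plink1(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    if len(set(samples)) != len(samples):
        raise ParseError("duplicated sample IDs in .fam")
    n, m = len(samples), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(".bed magic bytes missing or not SNP-major")
    body = raw[3:]
    bpv = -(-n // 4)
    if body.size != bpv * m:
        raise ParseError(".bed size inconsistent with .bim/.fam")
    body = body.reshape(m, bpv)
    # unpack 2-bit codes, sample-minor within byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpv * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "id": bim["id"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    return GenotypeMatrix(dosages, samples, variants)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype file as alternate-allele dosages.

    ``format`` is "vcf" or "plink1"; when omitted it is inferred from the
    path (".vcf"/".vcf.gz" vs a bed/bim/fam prefix).
    """
    p = str(path)
    if format is None:
        format = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "plink1"
    if format == "vcf":
        return _read_vcf(Path(p))
    if format == "plink1":
        if p.endswith(".bed"):
            p = p[:-4]
        return _read_plink1(p)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# GWAS summary statistics

def write_summary_stats(stats: pd.DataFrame, path) -> None:
    """Write per-variant association results with the fixed column schema
    CHR POS ID A1 A2 BETA SE STAT P N MAF (A1 = effect/alt allele)."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise SchemaError(f"summary stats missing columns: {missing}")
    stats.loc[:, SUMSTAT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_summary_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise SchemaError(f"summary stats missing columns: {missing}")
    return stats


# ---------------------------------------------------------------------------
# Model files

def save_model(model, path) -> None:
    """Serialize a trained prediction model as self-describing JSON."""
    doc = model.to_dict()
    doc["format_version"] = MODEL_FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path):
    from .models import TrainedModel  # local import avoids a cycle

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"truncated or invalid model file: {exc}") from exc
    version = doc.pop("format_version", None)
    if version != MODEL_FORMAT_VERSION:
        raise ParseError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel.from_dict(doc)
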