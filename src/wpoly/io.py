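"""Readers, writers and in-memory containers for the standard formats.

The central container is :class:`SiteTable`, a ploidy-aware biallelic SNP
matrix.  Each sample owns two allele slots; haploid calls (W and Z in
females, W absent in males) occupy the first slot only, with the second
slot marked :data:`ABSENT`.  Coordinates follow the usual conventions:
VCF positions are 1-based, BED intervals 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: allele-slot sentinel: genotype expected but not called
MISSING = -1
#: allele-slot sentinel: slot does not exist (haploid second slot, no W in males)
ABSENT = -2

CHROM_CLASSES = ("autosome", "Z", "W", "mt")

MORPHS = ("gray", "rufous")
SEXES = ("M", "F")


@dataclass
class SiteTable:
    """Biallelic SNP matrix with per-site QC annotations.

    Parameters
    ----------
    chrom, pos, ref, alt
        Per-site arrays; ``pos`` is 1-based and strictly increasing within
        each chromosome.
    alleles
        int8 array of shape ``(n_sites, n_samples, 2)`` holding allele codes
        0 (ref), 1 (alt), :data:`MISSING` or :data:`ABSENT`.
    samples
        Sample identifiers, in column order.
    chrom_class
        One of ``autosome | Z | W | mt``; drives ploidy expectations.
    qual, site_dp, mq, rpbz
        Optional per-site float annotations (NaN = not recorded).
    allele_depths
        Optional int32 array ``(n_sites, n_samples, 2)`` of ref/alt read
        depths; -1 = not recorded.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray
    samples: list[str]
    chrom_class: str = "autosome"
    qual: np.ndarray | None = None
    site_dp: np.ndarray | None = None
    mq: np.ndarray | None = None
    rpbz: np.ndarray | None = None
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"unknown chromosome class {self.chrom_class!r}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} not in table") from None

    # -- subsetting -----------------------------------------------------
    def take_sites(self, mask_or_index) -> "SiteTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        else:
            idx = idx.astype(np.int64)

        def _sub(a):
            return None if a is None else a[idx]

        return SiteTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            alleles=self.alleles[idx],
            samples=list(self.samples),
            chrom_class=self.chrom_class,
            qual=_sub(self.qual),
            site_dp=_sub(self.site_dp),
            mq=_sub(self.mq),
            rpbz=_sub(self.rpbz),
            allele_depths=_sub(self.allele_depths),
        )

    def select_samples(self, ids: Sequence[str]) -> "SiteTable":
        idx = self.sample_indices(ids)
        return replace(
            self,
            alleles=self.alleles[:, idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, idx],
            samples=[self.samples[i] for i in idx],
        )

    # -- genotype views -------------------------------------------------
    def haplotypes(self, ids: Sequence[str] | None = None):
        """Per-sequence allele matrix for the given samples.

        Returns ``(matrix, names)`` where ``matrix`` has one column per
        existing allele slot (two for diploid samples, one for haploid)
        with entries 0/1/:data:`MISSING`, and ``names`` are
        ``"<sample>/<0|1>"`` labels.
        """
        idx = np.arange(self.n_samples) if ids is None else self.sample_indices(ids)
        cols, names = [], []
        for i in idx:
            for slot in (0, 1):
                col = self.alleles[:, i, slot]
                if np.all(col == ABSENT):
                    continue
                cols.append(np.where(col == ABSENT, MISSING, col))
                names.append(f"{self.samples[i]}/{slot}")
        if not cols:
            return np.empty((self.n_sites, 0), dtype=np.int8), []
        return np.stack(cols, axis=1), names

    def allele_counts(self, ids: Sequence[str] | None = None):
        """Per-site ``(alt_count, called_total)`` over the given samples."""
        idx = np.arange(self.n_samples) if ids is None else self.sample_indices(ids)
        sub = self.alleles[:, idx]
        alt = (sub == 1).sum(axis=(1, 2))
        called = ((sub == 0) | (sub == 1)).sum(axis=(1, 2))
        return alt.astype(np.int64), called.astype(np.int64)

    def maf(self, ids: Sequence[str] | None = None) -> np.ndarray:
        alt, called = self.allele_counts(ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of expected (non-absent) slots that are missing."""
        miss = (self.alleles == MISSING).sum(axis=(1, 2))
        expected = (self.alleles != ABSENT).sum(axis=(1, 2))
        return miss / np.maximum(expected, 1)


def concat_site_tables(tables: Sequence[SiteTable]) -> SiteTable:
    if not tables:
        raise ValueError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.samples != first.samples or t.chrom_class != first.chrom_class:
            raise ValueError("tables differ in samples or chromosome class")

    def _cat(attr):
        vals = [getattr(t, attr) for t in tables]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals)

    return SiteTable(
        chrom=_cat("chrom"),
        pos=_cat("pos"),
        ref=_cat("ref"),
        alt=_cat("alt"),
        alleles=np.concatenate([t.alleles for t in tables]),
        samples=list(first.samples),
        chrom_class=first.chrom_class,
        qual=_cat("qual"),
        site_dp=_cat("site_dp"),
        mq=_cat("mq"),
        rpbz=_cat("rpbz"),
        allele_depths=_cat("allele_depths"),
    )


# ---------------------------------------------------------------------------
# sample metadata (popmap)
# ---------------------------------------------------------------------------

POPMAP_COLUMNS = ["sample", "species", "morph", "sex", "population"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a popmap table (sample, species, morph, sex, population)."""
    missing = [c for c in POPMAP_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"popmap missing columns: {missing}")
    meta = meta[POPMAP_COLUMNS].copy()
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in popmap: {dups}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    morph = meta["morph"].fillna("").astype(str)
    meta["morph"] = morph.where(morph.str.len() > 0, "unknown")
    return meta


def read_popmap(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_metadata(meta)


def write_popmap(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


def samples_by_group(meta: pd.DataFrame, by: str | Sequence[str]) -> dict:
    """Group sample ids by one or more metadata columns."""
    if isinstance(by, str):
        by = [by]
    out = {}
    for key, sub in meta.groupby(list(by), sort=True):
        if len(by) == 1:
            key = key[0] if isinstance(key, tuple) else key
        out[key] = list(sub["sample"])
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    region: str | None = None,
    chrom_class: str = "autosome",
    meta: pd.DataFrame | None = None,
) -> tuple[SiteTable, dict]:
    """Read biallelic SNPs from a VCF into a :class:`SiteTable`.

    Multiallelic records, indels and non-SNPs are skipped and counted.
    Haploid GT calls are accepted; the second allele slot is marked
    :data:`ABSENT`.  On the W, a "." call is ambiguous between a missing
    genotype and a chromosome the sample does not carry; passing sample
    ``meta`` resolves male W slots to :data:`ABSENT`.  Returns
    ``(table, skip_counts)``.
    """
    skips = {"multiallelic": 0, "not_snp": 0}
    chroms, poss, refs, alts = [], [], [], []
    quals, dps, mqs, rpbzs = [], [], [], []
    gts, ads = [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        records = vf.fetch(region=region) if region else vf
        for rec in records:
            if rec.alts is None or len(rec.alts) != 1:
                skips["multiallelic"] += len(rec.alts or ()) > 1
                skips["not_snp"] += rec.alts is None
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1 or rec.alts[0] == "*":
                skips["not_snp"] += 1
                continue
            row = np.full((len(samples), 2), ABSENT, dtype=np.int8)
            ad_row = np.full((len(samples), 2), -1, dtype=np.int32)
            has_ad = False
            for j, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT", (None,))
                if gt is None:
                    gt = (None,)
                for slot, a in enumerate(gt[:2]):
                    row[j, slot] = MISSING if a is None else a
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    ad_row[j, : len(ad)] = ad[:2]
                    has_ad = True
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            quals.append(np.nan if rec.qual is None else float(rec.qual))
            info = rec.info
            dps.append(float(info["DP"]) if "DP" in info else np.nan)
            mqs.append(float(info["MQ"]) if "MQ" in info else np.nan)
            rpbzs.append(float(info["RPBZ"]) if "RPBZ" in info else np.nan)
            gts.append(row)
            ads.append(ad_row if has_ad else None)
    n = len(poss)
    any_ad = any(a is not None for a in ads)
    table = SiteTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        alleles=(
            np.stack(gts) if n else np.empty((0, len(samples), 2), dtype=np.int8)
        ),
        samples=samples,
        chrom_class=chrom_class,
        qual=np.array(quals),
        site_dp=np.array(dps),
        mq=np.array(mqs),
        rpbz=np.array(rpbzs),
        allele_depths=(
            np.stack([a if a is not None else np.full((len(samples), 2), -1, np.int32) for a in ads])
            if any_ad
            else None
        ),
    )
    if meta is not None and chrom_class == "W" and table.n_sites:
        males = set(meta.loc[meta["sex"] == "M", "sample"])
        for j, s in enumerate(samples):
            if s in males:
                table.alleles[:, j, :] = ABSENT
    if skips["multiallelic"] or skips["not_snp"]:
        logger.info("read_vcf skipped records: %s", skips)
    return table, skips


def write_vcf(table: SiteTable, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a :class:`SiteTable` as VCF 4.2 (GT and, when present, AD)."""
    header = pysam.VariantHeader()
    contigs = list(dict.fromkeys(table.chrom.tolist()))
    for c in contigs:
        length = None if contig_lengths is None else contig_lengths.get(c)
        if length is None:
            on_c = table.pos[table.chrom == c]
            length = int(on_c.max()) + 1 if len(on_c) else 1
        header.contigs.add(c, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    if table.allele_depths is not None:
        header.formats.add("AD", "R", "Integer", "Allele read depths")
    header.info.add("DP", 1, "Integer", "Site depth")
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add("RPBZ", 1, "Float", "Read position bias Z-score")
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            rec = out.new_record(
                contig=str(table.chrom[i]),
                start=int(table.pos[i]) - 1,
                stop=int(table.pos[i]),
                alleles=(str(table.ref[i]), str(table.alt[i])),
            )
            if table.qual is not None and np.isfinite(table.qual[i]):
                rec.qual = float(table.qual[i])
            if table.site_dp is not None and np.isfinite(table.site_dp[i]):
                rec.info["DP"] = int(table.site_dp[i])
            if table.mq is not None and np.isfinite(table.mq[i]):
                rec.info["MQ"] = float(table.mq[i])
            if table.rpbz is not None and np.isfinite(table.rpbz[i]):
                rec.info["RPBZ"] = float(table.rpbz[i])
            for j, s in enumerate(table.samples):
                a0, a1 = table.alleles[i, j]
                if a0 == ABSENT and a1 == ABSENT:
                    gt = (None,)
                elif a1 == ABSENT:
                    gt = (None,) if a0 == MISSING else (int(a0),)
                else:
                    gt = tuple(None if a == MISSING else int(a) for a in (a0, a1))
                rec.samples[s]["GT"] = gt
                if table.allele_depths is not None:
                    ad = table.allele_depths[i, j]
                    if ad[0] >= 0:
                        rec.samples[s]["AD"] = (int(ad[0]), int(ad[1]))
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / windows / generic tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicWindow:
    """0-based half-open genomic interval with a callable-site count."""

    chrom: str
    start: int
    end: int
    n_called_sites: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


def make_windows(chrom: str, length: int, size: int) -> pd.DataFrame:
    """Tile ``[0, length)`` with non-overlapping windows of ``size`` bp."""
    starts = np.arange(0, length, size)
    ends = np.minimum(starts + size, length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df.astype({"start": np.int64, "end": np.int64})


def write_bed(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end"]].sort_values(["chrom", "start"])
    out.to_csv(path, sep="\t", header=False, index=False)


def vcf_pos_to_bed(pos: int) -> tuple[int, int]:
    """Convert a 1-based VCF position to a 0-based half-open BED interval."""
    return pos - 1, pos


def write_table(df: pd.DataFrame, path, kind: str = "stats") -> None:
    """Serialize records of a declared kind (TSV with header, or BED)."""
    if kind == "bed":
        write_bed(df, path)
    else:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
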