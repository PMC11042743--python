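"""Genotype/site filters, sex-linked heterozygote resolution and coverage masks.

Site-level filters remove SNPs on quality (QUAL), site depth (too high:
repeats; too low: unreliable), mapping quality and read-position bias.
Genotype-level filters blank low-depth calls (diploid < 4x, haploid < 2x)
and resolve weak heterozygotes on haploid-expected chromosomes (W, Z in
females, mtDNA) to the major allele when an exact binomial test rejects
a balanced allele-depth ratio.  Coverage masks flag W windows with male
reads or repeat-inflated female depth, Z windows that behave like W or
repeat sequence, and mtDNA windows with NUMT-like depth anomalies.

Rules are applied in a fixed order (site-level, then genotype-level,
then missingness, then linked-SNP pruning) so that per-rule removal
counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ABSENT, MISSING, SiteTable, write_bed

__all__ = [
    "FilterConfig",
    "CoverageTable",
    "MaskSet",
    "filter_sites",
    "resolve_sex_linked_het",
    "haploidize_sex_linked",
    "prune_linked_snps",
    "merge_intervals",
    "build_sex_mask",
    "sex_coverage_log2",
]


@dataclass
class FilterConfig:
    """Thresholds for site- and genotype-level filtering."""

    min_qual: float = 20.0
    max_dp_factor: float = 2.0      # site DP > factor x chromosomal mean -> drop
    min_site_dp: int | None = None  # default: number of samples
    min_mq: float = 30.0
    rpbz_bounds: tuple[float, float] = (-3.0, 3.0)
    min_diploid_depth: int = 4
    min_haploid_depth: int = 2
    max_missing_frac: float = 0.20
    prune_span_bp: int = 5
    het_binom_alpha: float = 1e-5

    def __post_init__(self):
        lo, hi = self.rpbz_bounds
        if not lo < hi:
            raise ValueError("rpbz_bounds must be ordered")


class CoverageTable:
    """Long-format per-sample, per-window sequencing depth.

    Wraps a DataFrame with columns (chrom, start, end, sample,
    mean_depth) and derives per-sample reference depths: the autosomal
    reference is each sample's median depth over autosomal windows, the
    mtDNA reference its mean over mtDNA windows.
    """

    def __init__(self, df: pd.DataFrame, class_map=None):
        required = {"chrom", "start", "end", "sample", "mean_depth"}
        if not required.issubset(df.columns):
            raise ValueError(f"coverage table needs columns {sorted(required)}")
        if (df["mean_depth"] < 0).any():
            raise ValueError("negative depths in coverage table")
        if df.duplicated(["chrom", "start", "sample"]).any():
            raise ValueError("duplicate (sample, window) rows in coverage table")
        self.df = df.reset_index(drop=True)
        self._class_map = class_map or self._infer_classes()

    def _infer_classes(self) -> dict:
        out = {}
        for c in self.df["chrom"].unique():
            lc = str(c).lower()
            if lc.endswith("w"):
                out[c] = "W"
            elif lc.endswith("z"):
                out[c] = "Z"
            elif lc.endswith(("m", "mt")):
                out[c] = "mt"
            else:
                out[c] = "autosome"
        return out

    def chrom_class(self, chrom) -> str:
        return self._class_map[chrom]

    def subset(self, chrom_class: str) -> pd.DataFrame:
        keep = [c for c, k in self._class_map.items() if k == chrom_class]
        return self.df[self.df["chrom"].isin(keep)]

    def autosomal_reference(self) -> pd.Series:
        """Per-sample autosomal depth reference (median genome-wide)."""
        auto = self.subset("autosome")
        if auto.empty:
            raise ValueError("no autosomal coverage to derive reference depths")
        return auto.groupby("sample")["mean_depth"].median()

    def mt_reference(self) -> pd.Series:
        mt = self.subset("mt")
        if mt.empty:
            raise ValueError("no mtDNA coverage rows")
        return mt.groupby("sample")["mean_depth"].mean()


@dataclass
class MaskSet:
    """Masked intervals for one chromosome class (BED semantics)."""

    chrom_class: str
    intervals: pd.DataFrame  # chrom, start, end (sorted, non-overlapping)

    @property
    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def to_bed(self, path) -> None:
        write_bed(self.intervals, path)


# ---------------------------------------------------------------------------
# site and genotype filters
# ---------------------------------------------------------------------------

def filter_sites(
    sites: SiteTable, cfg: FilterConfig, chrom_mean_dp: float | None
) -> tuple[SiteTable, dict]:
    """Apply site-level, genotype-level and missingness filters in order.

    Returns the filtered table and an ordered dict of removal counts
    (sites per site-level rule, genotypes blanked by the depth rule,
    sites dropped for missingness).  Annotations that are absent (NaN)
    never trigger a rule: "not recorded" is distinct from "failing".
    """
    counts: dict[str, int] = {}
    t = sites

    def drop(name: str, bad: np.ndarray) -> None:
        nonlocal t
        counts[name] = int(bad.sum())
        if counts[name]:
            t = t.take_sites(~bad)

    qual = t.qual if t.qual is not None else np.full(t.n_sites, np.nan)
    drop("qual", np.nan_to_num(qual, nan=np.inf) < cfg.min_qual)

    dp = t.site_dp if t.site_dp is not None else np.full(t.n_sites, np.nan)
    if chrom_mean_dp is None:
        if np.isfinite(dp).any():
            raise ValueError("chrom_mean_dp required when site DP is present")
        chrom_mean_dp = np.nan
    drop("dp_high", np.nan_to_num(dp, nan=-np.inf) > cfg.max_dp_factor * chrom_mean_dp)
    dp = t.site_dp if t.site_dp is not None else np.full(t.n_sites, np.nan)
    min_dp = cfg.min_site_dp if cfg.min_site_dp is not None else t.n_samples
    drop("dp_low", np.nan_to_num(dp, nan=np.inf) < min_dp)

    mq = t.mq if t.mq is not None else np.full(t.n_sites, np.nan)
    drop("mq", np.nan_to_num(mq, nan=np.inf) < cfg.min_mq)

    rpbz = t.rpbz if t.rpbz is not None else np.full(t.n_sites, np.nan)
    lo, hi = cfg.rpbz_bounds
    drop("rpbz", (np.nan_to_num(rpbz, nan=0.0) < lo) | (np.nan_to_num(rpbz, nan=0.0) > hi))

    # genotype-level depth: blank calls below the ploidy-specific minimum
    blanked = 0
    if t.allele_depths is not None and t.n_sites:
        depth = t.allele_depths.clip(min=0).sum(axis=2)
        has_ad = t.allele_depths[:, :, 0] >= 0
        haploid = t.alleles[:, :, 1] == ABSENT
        need = np.where(haploid, cfg.min_haploid_depth, cfg.min_diploid_depth)
        called = (t.alleles[:, :, 0] >= 0)
        bad = called & has_ad & (depth < need)
        blanked = int(bad.sum())
        if blanked:
            alleles = t.alleles.copy()
            alleles[:, :, 0][bad] = MISSING
            alleles[:, :, 1][bad & ~haploid] = MISSING
            t = SiteTable(
                chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt, alleles=alleles,
                samples=t.samples, chrom_class=t.chrom_class, qual=t.qual,
                site_dp=t.site_dp, mq=t.mq, rpbz=t.rpbz, allele_depths=t.allele_depths,
            )
    counts["low_depth_genotypes"] = blanked

    drop("missingness", t.missing_fraction() > cfg.max_missing_frac)
    return t, counts


def resolve_sex_linked_het(
    gt: tuple[int, int], allele_depths: tuple[int, int] | None, alpha: float = 1e-5
):
    """Resolve one heterozygous call on a haploid-expected chromosome.

    A two-sided exact binomial test asks whether the minor-allele depth
    is compatible with a true 50:50 heterozygote.  Strong imbalance
    (P < ``alpha``) returns the major allele as a haploid call; anything
    else returns None (missing).  Homozygous calls pass through as their
    haploid allele.
    """
    a, b = gt
    if a == b:
        return a
    if allele_depths is None or allele_depths[0] < 0:
        return None
    ref_d, alt_d = allele_depths
    n = ref_d + alt_d
    if n == 0:
        return None
    p = stats.binomtest(min(ref_d, alt_d), n, 0.5).pvalue
    if p < alpha:
        return 0 if ref_d >= alt_d else 1
    return None


def haploidize_sex_linked(
    sites: SiteTable, haploid_samples: Sequence[str], alpha: float = 1e-5
) -> SiteTable:
    """Convert diploid calls of haploid-expected samples to haploid.

    Homozygotes become single-allele calls; heterozygotes are resolved
    with :func:`resolve_sex_linked_het`.  Samples not listed are left
    untouched (e.g. males on the Z).
    """
    idx = sites.sample_indices(haploid_samples)
    alleles = sites.alleles.copy()
    for j in idx:
        for i in range(sites.n_sites):
            a0, a1 = alleles[i, j]
            if a1 == ABSENT:
                continue
            if a0 == MISSING or a1 == MISSING:
                alleles[i, j] = (MISSING, ABSENT)
                continue
            if a0 == a1:
                alleles[i, j] = (a0, ABSENT)
                continue
            ad = None
            if sites.allele_depths is not None:
                ad = tuple(int(x) for x in sites.allele_depths[i, j])
            call = resolve_sex_linked_het((int(a0), int(a1)), ad, alpha)
            alleles[i, j] = (MISSING if call is None else call, ABSENT)
    return SiteTable(
        chrom=sites.chrom, pos=sites.pos, ref=sites.ref, alt=sites.alt,
        alleles=alleles, samples=sites.samples, chrom_class=sites.chrom_class,
        qual=sites.qual, site_dp=sites.site_dp, mq=sites.mq, rpbz=sites.rpbz,
        allele_depths=sites.allele_depths,
    )


def prune_linked_snps(sites: SiteTable, span_bp: int = 5) -> SiteTable:
    """Keep one SNP per chain of tightly linked SNPs.

    SNPs on the same chromosome whose consecutive distance is below
    ``span_bp`` form a chain; only the chain's highest-MAF SNP survives
    (ties broken toward the lower coordinate).
    """
    if sites.n_sites == 0:
        return sites
    maf = sites.maf()
    keep = np.zeros(sites.n_sites, dtype=bool)
    i = 0
    while i < sites.n_sites:
        j = i
        while (
            j + 1 < sites.n_sites
            and sites.chrom[j + 1] == sites.chrom[j]
            and sites.pos[j + 1] - sites.pos[j] < span_bp
        ):
            j += 1
        chain = np.arange(i, j + 1)
        best = chain[np.argmax(np.nan_to_num(maf[chain], nan=-1.0))]
        keep[best] = True
        i = j + 1
    return sites.take_sites(keep)


# ---------------------------------------------------------------------------
# interval utilities and coverage masks
# ---------------------------------------------------------------------------

def merge_intervals(hits: Sequence[tuple[int, int]], gap_bp: int = 0) -> list[tuple[int, int]]:
    """Sort intervals and merge transitively any pair closer than ``gap_bp``.

    Overlapping and book-ended intervals always merge; with ``gap_bp`` >
    0 intervals separated by a gap strictly smaller than ``gap_bp`` merge
    too (the rule used when consolidating NUMT blast hits).
    """
    ivals = sorted(tuple(map(int, h)) for h in hits)
    for s, e in ivals:
        if s < 0:
            raise ValueError("negative interval coordinate")
        if e < s:
            raise ValueError(f"inverted interval ({s}, {e})")
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s - merged[-1][1] < max(gap_bp, 1):
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _window_matrix(cov: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """(window x sample) depth matrix for one chromosome class subset."""
    pivot = cov.pivot_table(
        index=["chrom", "start", "end"], columns="sample", values="mean_depth"
    )
    return pivot[[s for s in samples if s in pivot.columns]]


def build_sex_mask(
    cov: CoverageTable,
    meta: pd.DataFrame,
    chrom_class: str,
    male_depth_max: float = 1.0,
    sample_frac: float = 0.25,
) -> MaskSet:
    """Coverage-based masks for W, Z or mtDNA windows.

    W: masked when any male shows depth > ``male_depth_max`` (no W in
    males, so male reads mean shared/repeat sequence) or when more than
    ``sample_frac`` of females exceed their autosomal reference depth
    (repeat-collapsed sequence).
    Z: masked when > ``sample_frac`` of males exceed twice their
    autosomal reference (repeats) or > ``sample_frac`` of females exceed
    their autosomal reference (W-like sequence misassembled into Z).
    mt: masked when any sample's depth is more than double, or under a
    third of, that sample's mtDNA average (NUMT-like anomalies).
    """
    if chrom_class not in ("W", "Z", "mt"):
        raise ValueError(f"no coverage-mask rule for class {chrom_class!r}")
    sub = cov.subset(chrom_class)
    if sub.empty:
        raise ValueError(f"no coverage rows for class {chrom_class!r}")
    females = meta.loc[meta["sex"] == "F", "sample"].tolist()
    males = meta.loc[meta["sex"] == "M", "sample"].tolist()
    masked = []
    if chrom_class == "mt":
        ref = cov.mt_reference()
        mat = _window_matrix(sub, list(meta["sample"]))
        rel = mat / ref.reindex(mat.columns)
        bad = ((rel > 2.0) | (rel < 1.0 / 3.0)).any(axis=1)
    else:
        ref = cov.autosomal_reference()
        fmat = _window_matrix(sub, females)
        mmat = _window_matrix(sub, males)
        if fmat.empty or mmat.empty:
            raise ValueError("need coverage for both sexes to build W/Z masks")
        f_over = (fmat > ref.reindex(fmat.columns)).mean(axis=1)
        if chrom_class == "W":
            male_hit = (mmat > male_depth_max).any(axis=1)
            bad = male_hit | (f_over > sample_frac)
        else:
            m_over = (mmat > 2.0 * ref.reindex(mmat.columns)).mean(axis=1)
            bad = (m_over > sample_frac) | (f_over > sample_frac)
    for (chrom, start, end), flag in bad.items():
        if flag:
            masked.append((chrom, int(start), int(end)))
    if masked:
        df = pd.DataFrame(masked, columns=["chrom", "start", "end"])
        parts = []
        for chrom, grp in df.groupby("chrom", sort=True):
            for s, e in merge_intervals(list(zip(grp["start"], grp["end"]))):
                parts.append((chrom, s, e))
        intervals = pd.DataFrame(parts, columns=["chrom", "start", "end"])
    else:
        intervals = pd.DataFrame(columns=["chrom", "start", "end"])
    return MaskSet(chrom_class=chrom_class, intervals=intervals)


def sex_coverage_log2(
    cov: pd.DataFrame,
    meta: pd.DataFrame,
    pseudocount: float = 0.01,
    scale_to_smallest: bool = True,
) -> pd.DataFrame:
    """Per-window log2 fold change between mean female and male depth.

    Depths are first normalized across samples by scaling each sample to
    the library with the smallest total depth, then a small constant
    avoids division by zero: ``log2((mean_F + c) / (mean_M + c))``.
    Windows of female-specific (W-like) sequence score strongly positive,
    shared sequence near zero.
    """
    sex = meta.set_index("sample")["sex"]
    females = set(sex.index[sex == "F"])
    males = set(sex.index[sex == "M"])
    if not females or not males:
        raise ValueError("need samples of both sexes")
    df = cov.copy()
    if scale_to_smallest:
        totals = df.groupby("sample")["mean_depth"].sum()
        df["mean_depth"] = df["mean_depth"] * (
            totals.min() / totals.reindex(df["sample"]).to_numpy()
        )
    grp = df.groupby(["chrom", "start", "end"])
    out = []
    for key, sub in grp:
        mf = sub.loc[sub["sample"].isin(females), "mean_depth"].mean()
        mm = sub.loc[sub["sample"].isin(males), "mean_depth"].mean()
        out.append((*key, np.log2((mf + pseudocount) / (mm + pseudocount))))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "log2_fm"])
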