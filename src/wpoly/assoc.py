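"""Case/control allele-frequency association between colour morphs.

Each biallelic SNP is tested with a likelihood ratio comparing a model
with separate case and control allele frequencies against a pooled
frequency, on called allele counts (haploid W/Z calls in females count
one allele, diploid calls two).  Twice the log-likelihood ratio is
referred to a chi-square distribution with 1 df; genome-wide
significance uses a Bonferroni threshold, and phenotype-permutation
scans (group sizes preserved) provide an empirical null for the whole
scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SiteTable

__all__ = [
    "allele_lrt",
    "bonferroni_threshold",
    "gwas_scan",
    "permute_phenotypes",
    "MorphAssociation",
]


def _binom_ll(k, n, p):
    """Binomial log-likelihood kernel (without the combinatorial term)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(k > 0, k * np.log(p, where=p > 0, out=np.zeros_like(p, dtype=float)), 0.0) + \
               np.where(n - k > 0, (n - k) * np.log(1 - p, where=p < 1, out=np.zeros_like(p, dtype=float)), 0.0)


def allele_lrt(case_alt, case_total, ctrl_alt, ctrl_total):
    """Likelihood-ratio test of equal allele frequency in cases/controls.

    Accepts scalars or arrays; returns ``(lrt, p)`` with the LRT clipped
    at zero (numerical noise) and p from the upper tail of chi2(1 df).
    Sites with an empty group return NaN.
    """
    ca, cn = np.asarray(case_alt, float), np.asarray(case_total, float)
    fa, fn = np.asarray(ctrl_alt, float), np.asarray(ctrl_total, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ca / cn
        p2 = fa / fn
        p0 = (ca + fa) / (cn + fn)
    ll_alt = _binom_ll(ca, cn, p1) + _binom_ll(fa, fn, p2)
    ll_null = _binom_ll(ca, cn, p0) + _binom_ll(fa, fn, p0)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    bad = (cn == 0) | (fn == 0)
    lrt = np.where(bad, np.nan, lrt)
    p = np.where(bad, np.nan, p)
    if np.ndim(case_alt) == 0:
        return float(lrt), float(p)
    return lrt, p


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Per-test p threshold ``alpha/n`` and the matching chi2(1) critical value."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_thresh = alpha / n_tests
    return p_thresh, float(stats.chi2.isf(p_thresh, df=1))


def _case_control_counts(sites: SiteTable, meta: pd.DataFrame,
                         case: str, control: str):
    morph = meta.set_index("sample")["morph"]
    case_ids = [s for s in sites.samples if morph.get(s) == case]
    ctrl_ids = [s for s in sites.samples if morph.get(s) == control]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >=2 samples per class, got {len(case_ids)} {case!r} "
            f"and {len(ctrl_ids)} {control!r}"
        )
    return case_ids, ctrl_ids


def gwas_scan(
    sites: SiteTable,
    meta: pd.DataFrame,
    case: str = "rufous",
    control: str = "gray",
    maf_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP allele LRT between two morph classes, ploidy-aware.

    Missing genotypes are excluded per site; ``maf_floor`` optionally
    drops rare variants before testing (no floor by default).  Output is
    ordered by (chrom, pos).
    """
    case_ids, ctrl_ids = _case_control_counts(sites, meta, case, control)
    ca, cn = sites.allele_counts(case_ids)
    fa, fn = sites.allele_counts(ctrl_ids)
    keep = (cn > 0) & (fn > 0)
    if maf_floor > 0:
        alt, tot = ca + fa, cn + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / np.maximum(tot, 1)
        keep &= np.minimum(p, 1 - p) >= maf_floor
    lrt, p = allele_lrt(ca, cn, fa, fn)
    df = pd.DataFrame(
        {
            "chrom": sites.chrom,
            "pos": sites.pos,
            "case_alt": ca,
            "case_n": cn,
            "ctrl_alt": fa,
            "ctrl_n": fn,
            "maf": sites.maf(case_ids + ctrl_ids),
            "lrt": lrt,
            "p": p,
        }
    )[keep]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def permute_phenotypes(
    sites: SiteTable,
    meta: pd.DataFrame,
    iters: int = 10,
    seed: int = 0,
    case: str = "rufous",
    control: str = "gray",
    maf_floor: float = 0.0,
) -> dict:
    """Phenotype-shuffled association scans (group sizes preserved).

    Returns per-iteration genome-wide maximum LRT values and, per site,
    the count of iterations whose shuffled LRT met or exceeded the
    observed one.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    observed = gwas_scan(sites, meta, case, control, maf_floor)
    morph = meta.set_index("sample")["morph"]
    pool = [s for s in sites.samples if morph.get(s) in (case, control)]
    n_case = sum(morph[s] == case for s in pool)
    max_lrt = []
    exceed = np.zeros(len(observed), dtype=int)
    for _ in range(iters):
        perm = list(rng.permutation(pool))
        shuffled = meta.copy()
        lab = {s: (case if i < n_case else control) for i, s in enumerate(perm)}
        shuffled["morph"] = shuffled.apply(
            lambda r: lab.get(r["sample"], r["morph"]), axis=1
        )
        null = gwas_scan(sites, shuffled, case, control, maf_floor)
        merged = observed.merge(null, on=["chrom", "pos"], how="left",
                                suffixes=("", "_null"))
        max_lrt.append(float(np.nanmax(merged["lrt_null"])) if len(merged) else np.nan)
        exceed += (merged["lrt_null"].to_numpy() >= merged["lrt"].to_numpy()).astype(int)
    return {"observed": observed, "max_lrt": np.array(max_lrt), "exceedance": exceed}


class MorphAssociation:
    """Genome-wide case/control morph association model.

    ``fit`` runs the LRT scan and returns a results object that knows its
    Bonferroni threshold and can generate permutation nulls and a
    Manhattan plot.
    """

    def __init__(self, sites: SiteTable, meta: pd.DataFrame,
                 case: str = "rufous", control: str = "gray",
                 maf_floor: float = 0.0):
        self.sites = sites
        self.meta = meta
        self.case = case
        self.control = control
        self.maf_floor = maf_floor

    def fit(self) -> "MorphAssociationResults":
        table = gwas_scan(self.sites, self.meta, self.case, self.control, self.maf_floor)
        return MorphAssociationResults(self, table)


@dataclass
class MorphAssociationResults:
    model: MorphAssociation
    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def n_tests(self) -> int:
        return len(self.table)

    def threshold(self, alpha: float | None = None, n_tests: int | None = None):
        return bonferroni_threshold(alpha or self.alpha, n_tests or self.n_tests)

    def significant(self, alpha: float | None = None, n_tests: int | None = None) -> pd.DataFrame:
        p_thresh, _ = self.threshold(alpha, n_tests)
        return self.table[self.table["p"] < p_thresh]

    def permutation_null(self, iters: int = 10, seed: int = 0) -> dict:
        return permute_phenotypes(
            self.model.sites, self.model.meta, iters=iters, seed=seed,
            case=self.model.case, control=self.model.control,
            maf_floor=self.model.maf_floor,
        )

    def summary(self) -> str:
        p_thresh, chi2_crit = self.threshold()
        hits = self.significant()
        lines = [
            f"Morph association scan ({self.model.case} vs {self.model.control})",
            f"  sites tested        : {self.n_tests}",
            f"  Bonferroni P thresh : {p_thresh:.3g} (chi2(1) critical {chi2_crit:.2f})",
            f"  significant sites   : {len(hits)}",
        ]
        if len(hits):
            per_chrom = hits.groupby("chrom").size()
            for c, k in per_chrom.items():
                lines.append(f"    {c}: {k}")
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """-log10(p) per site, coloured by chromosome, with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        offset = 0
        for chrom, sub in self.table.groupby("chrom", sort=True):
            ax.scatter(sub["pos"] + offset, -np.log10(sub["p"]), s=4, label=str(chrom))
            offset += sub["pos"].max()
        p_thresh, _ = self.threshold()
        ax.axhline(-np.log10(p_thresh), color="red", ls="--", lw=0.8)
        ax.set_xlabel("genome position")
        ax.set_ylabel(r"$-\log_{10} P$")
        ax.legend(fontsize=7)
        return ax
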