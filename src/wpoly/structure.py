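"""Sample-structure checks: genotype PCA and rank-sum tests on components.

The PCA operates on mean-centred genotype dosages (alt-allele counts per
sample), singletons excluded, missing dosages mean-imputed per site.
Component scores are min-max scaled to [0, 1] after a fixed orientation
rule (the sample with the largest absolute score is made positive), so
identical inputs always yield identical scaled scores.  Species and
morph effects per component are tested with two-sided Wilcoxon rank-sum
tests (exact for small samples) under a configurable Bonferroni
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, SiteTable

__all__ = ["pca_genotypes", "pc_group_tests", "GenotypePCA", "PCAResults"]


def _dosage_matrix(sites: SiteTable, exclude_singletons: bool) -> np.ndarray:
    """(n_samples, n_sites) alt dosage with per-site mean imputation."""
    alleles = sites.alleles
    called = (alleles == 0) | (alleles == 1)
    dosage = np.where(called, (alleles == 1), 0).sum(axis=2).T.astype(float)
    n_called = called.sum(axis=2).T
    # scale haploid/partial calls onto a per-sample dosage; leave fully
    # missing entries for imputation
    with np.errstate(invalid="ignore", divide="ignore"):
        dosage = np.where(n_called > 0, dosage, np.nan)
    if exclude_singletons:
        alt = np.nansum(dosage, axis=0)
        tot = n_called.sum(axis=0).astype(float)
        minor = np.minimum(alt, tot - alt)
        keep = minor > 1
        dosage = dosage[:, keep]
    site_mean = np.nanmean(dosage, axis=0)
    idx = np.where(np.isnan(dosage))
    dosage[idx] = site_mean[idx[1]]
    poly = np.nanstd(dosage, axis=0) > 0
    return dosage[:, poly]


def pca_genotypes(
    sites: SiteTable, exclude_singletons: bool = True, n_components: int = 6
) -> "PCAResults":
    """PCA of the genotype-dosage matrix with 0-1 scaled scores."""
    if sites.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = _dosage_matrix(sites, exclude_singletons)
    if X.shape[1] < 1:
        raise ValueError("no polymorphic sites after filtering")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate genotype matrix (all samples identical)")
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, (s > 1e-12).sum())
    scores = u[:, :k] * s[:k]
    # fixed orientation: the largest-|score| sample is positive
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var = s**2 / (s**2).sum()
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    scaled = (scores - lo) / np.where(hi > lo, hi - lo, 1.0)
    df = pd.DataFrame(
        scaled, index=sites.samples,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return PCAResults(scores=df, raw_scores=scores,
                      variance_explained=var[:k], n_sites=X.shape[1])


def pc_group_tests(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    factors: Sequence[str] = ("species", "morph"),
    components: int = 6,
    bonferroni_n: int = 24,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests per component and factor.

    Each factor must be two-level on the scored samples; p-values are
    multiplied by ``bonferroni_n`` (capped at 1).  The exact null
    distribution is used for small groups, the normal approximation
    otherwise (scipy's default switching rule).
    """
    m = meta.set_index("sample").loc[scores.index]
    rows = []
    for factor in factors:
        levels = [lv for lv in m[factor].unique() if lv != "unknown"]
        if len(levels) != 2:
            raise ValueError(f"factor {factor!r} needs exactly two levels, got {levels}")
        a_idx = m[factor] == levels[0]
        b_idx = m[factor] == levels[1]
        for pc in scores.columns[:components]:
            res = stats.mannwhitneyu(
                scores.loc[a_idx.values, pc], scores.loc[b_idx.values, pc],
                alternative="two-sided",
            )
            rows.append(
                dict(component=pc, factor=factor,
                     p_raw=float(res.pvalue),
                     p_adj=float(min(res.pvalue * bonferroni_n, 1.0)))
            )
    return pd.DataFrame(rows)


class GenotypePCA:
    """PCA-based structure check as an estimator object."""

    def __init__(self, sites: SiteTable, meta: pd.DataFrame,
                 exclude_singletons: bool = True, n_components: int = 6,
                 bonferroni_n: int = 24):
        self.sites = sites
        self.meta = meta
        self.exclude_singletons = exclude_singletons
        self.n_components = n_components
        self.bonferroni_n = bonferroni_n

    def fit(self) -> "PCAResults":
        res = pca_genotypes(self.sites, self.exclude_singletons, self.n_components)
        res.model = self
        return res


@dataclass
class PCAResults:
    scores: pd.DataFrame              # min-max scaled to [0, 1]
    raw_scores: np.ndarray
    variance_explained: np.ndarray
    n_sites: int
    model: GenotypePCA | None = None

    def group_tests(self, meta: pd.DataFrame | None = None,
                    factors: Sequence[str] = ("species", "morph"),
                    bonferroni_n: int | None = None) -> pd.DataFrame:
        if meta is None:
            if self.model is None:
                raise ValueError("no metadata attached; pass meta explicitly")
            meta = self.model.meta
        n = bonferroni_n or (self.model.bonferroni_n if self.model else 24)
        return pc_group_tests(self.scores, meta,
                              factors=factors,
                              components=len(self.scores.columns),
                              bonferroni_n=n)

    def summary(self) -> str:
        lines = [f"Genotype PCA on {self.n_sites} sites, "
                 f"{len(self.scores)} samples:"]
        for j, v in enumerate(self.variance_explained):
            lines.append(f"  PC{j + 1}: {v:.1%} variance")
        return "\n".join(lines)

    def plot(self, meta: pd.DataFrame | None = None, x: str = "PC1", y: str = "PC2", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if meta is None and self.model is not None:
            meta = self.model.meta
        if meta is not None:
            m = meta.set_index("sample").loc[self.scores.index]
            for (sp, morph), sub in self.scores.groupby([m["species"], m["morph"]]):
                ax.scatter(sub[x], sub[y], label=f"{sp}/{morph}", s=18)
            ax.legend(fontsize=7)
        else:
            ax.scatter(self.scores[x], self.scores[y], s=18)
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        return ax
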