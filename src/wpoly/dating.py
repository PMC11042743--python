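"""Net-divergence (D_a) dating and the plumage/species divergence ratio.

Net divergence strips within-population diversity from absolute
divergence, estimating the mutations accumulated since the split of the
most recent common ancestor:

    D_a = D_XY - (pi_X + pi_Y) / 2
    tau = D_a / (2 mu)           [generations]
    age = tau * g                [years; g = generation time]

It assumes the ancestral population held as much variation as the
contemporary ones.  The W chromosome uses half the autosomal mutation
rate (its maternal restriction shields it from the mutation-richer male
germ line); Z and autosomes share one rate.  The relative age of the
colour polymorphism is the bootstrap ratio of mean W net divergence
between morphs to mean net divergence between species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RateConfig",
    "net_divergence",
    "divergence_generations",
    "generations_to_ka",
    "da_ratio_ci",
    "window_da",
    "DivergenceDating",
    "DatingResults",
]

AVIAN_MU = 1.01e-8          # mutations / site / generation, avian trio mean
CUCKOO_GENERATION_YEARS = 2.76


@dataclass
class RateConfig:
    """Mutation rates (per site per generation) and generation time."""

    mu_auto: float = AVIAN_MU
    mu_w: float | None = None       # default: half the autosomal rate
    mu_z: float | None = None       # default: equal to the autosomal rate
    generation_time_years: float = CUCKOO_GENERATION_YEARS

    def __post_init__(self):
        if self.mu_w is None:
            self.mu_w = self.mu_auto / 2.0
        if self.mu_z is None:
            self.mu_z = self.mu_auto
        for v in (self.mu_auto, self.mu_w, self.mu_z, self.generation_time_years):
            if v <= 0:
                raise ValueError("rates and generation time must be positive")

    def mu(self, chrom_class: str) -> float:
        return {"autosome": self.mu_auto, "Z": self.mu_z, "W": self.mu_w}[chrom_class]


def net_divergence(pi_x, pi_y, dxy):
    """D_a = D_XY - (pi_X + pi_Y)/2, unclamped (may be negative)."""
    return np.asarray(dxy, float) - (np.asarray(pi_x, float) + np.asarray(pi_y, float)) / 2.0


def divergence_generations(d_a, mu: float):
    """tau = D_a / (2 mu) in generations."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(d_a, float) / (2.0 * mu)


def generations_to_ka(tau, generation_time_years: float, round_to_int: bool = True):
    """Convert generations to thousands of years (rounded for reporting)."""
    ka = np.asarray(tau, float) * generation_time_years / 1000.0
    if round_to_int:
        out = np.round(ka).astype(int)
        return int(out) if out.ndim == 0 else out
    return float(ka) if ka.ndim == 0 else ka


def window_da(windows: pd.DataFrame, group_x: str, group_y: str) -> np.ndarray:
    """Per-window D_a between two groups from a windowed-diversity table."""
    key = f"dxy_{group_x}_{group_y}"
    if key not in windows:
        key = f"dxy_{group_y}_{group_x}"
    return np.asarray(net_divergence(
        windows[f"pi_{group_x}"], windows[f"pi_{group_y}"], windows[key]
    ), float)


@dataclass
class DaRatio:
    mean: float
    ci_low: float
    ci_high: float
    n_skipped: int
    replicates: np.ndarray

    def summary(self) -> str:
        return (
            f"Da ratio (plumage/species) = {self.mean:.3f} "
            f"[95% CI {self.ci_low:.3f}, {self.ci_high:.3f}]"
            + (f"; {self.n_skipped} degenerate replicates skipped" if self.n_skipped else "")
        )


def da_ratio_ci(
    da_plumage: Sequence[float],
    da_species: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    paired: bool | None = None,
) -> DaRatio:
    """Bootstrap the ratio of mean plumage D_a to mean species D_a.

    Each replicate resamples windows with replacement and takes the
    ratio of replicate means (never per-window ratios, which explode for
    near-zero window D_a).  When the two window sets are the same length
    they are resampled as pairs by default.  Replicates with
    non-positive species mean are skipped and counted.
    """
    x = np.asarray(da_plumage, float)
    y = np.asarray(da_species, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty window sets")
    if paired is None:
        paired = len(x) == len(y)
    if paired and len(x) != len(y):
        raise ValueError("paired resampling needs equally many windows")
    rng = np.random.default_rng(seed)
    reps, skipped = [], 0
    for _ in range(B):
        if paired:
            idx = rng.integers(0, len(x), size=len(x))
            mx, my = x[idx].mean(), y[idx].mean()
        else:
            mx = x[rng.integers(0, len(x), size=len(x))].mean()
            my = y[rng.integers(0, len(y), size=len(y))].mean()
        if my <= 0:
            skipped += 1
            continue
        reps.append(mx / my)
    if not reps:
        raise ValueError("all bootstrap replicates had non-positive species Da")
    reps = np.asarray(reps)
    return DaRatio(
        mean=float(reps.mean()),
        ci_low=float(np.percentile(reps, 2.5)),
        ci_high=float(np.percentile(reps, 97.5)),
        n_skipped=skipped,
        replicates=reps,
    )


class DivergenceDating:
    """Split-time estimator from a windowed-diversity table.

    Parameters
    ----------
    windows
        Output of the windowed diversity scan containing ``pi_<x>``,
        ``pi_<y>`` and ``dxy_<x>_<y>`` columns for the two groups.
    group_x, group_y
        The diverged groups to date.
    chrom_class
        Picks the mutation rate from ``rates``.
    """

    def __init__(self, windows: pd.DataFrame, group_x: str, group_y: str,
                 chrom_class: str = "autosome", rates: RateConfig | None = None):
        self.windows = windows
        self.group_x = group_x
        self.group_y = group_y
        self.chrom_class = chrom_class
        self.rates = rates or RateConfig()

    def _da(self) -> np.ndarray:
        key = f"dxy_{self.group_x}_{self.group_y}"
        if key not in self.windows:
            key = f"dxy_{self.group_y}_{self.group_x}"
        da = net_divergence(
            self.windows[f"pi_{self.group_x}"],
            self.windows[f"pi_{self.group_y}"],
            self.windows[key],
        )
        return np.asarray(da, float)

    def fit(self, B: int = 1000, seed: int = 0) -> "DatingResults":
        da = self._da()
        da = da[np.isfinite(da)]
        if len(da) == 0:
            raise ValueError("no finite windows to date")
        mu = self.rates.mu(self.chrom_class)
        g = self.rates.generation_time_years
        rng = np.random.default_rng(seed)
        boot = np.array([
            da[rng.integers(0, len(da), size=len(da))].mean() for b in range(B)
        ])
        tau = float(divergence_generations(da.mean(), mu))
        tau_ci = divergence_generations(np.percentile(boot, [2.5, 97.5]), mu)
        return DatingResults(
            model=self,
            da_mean=float(da.mean()),
            tau=tau,
            tau_ci=(float(tau_ci[0]), float(tau_ci[1])),
            n_windows=len(da),
        )


@dataclass
class DatingResults:
    model: DivergenceDating
    da_mean: float
    tau: float
    tau_ci: tuple[float, float]
    n_windows: int

    @property
    def years(self) -> float:
        return self.tau * self.model.rates.generation_time_years

    @property
    def ka(self) -> int:
        return generations_to_ka(self.tau, self.model.rates.generation_time_years)

    def summary(self) -> str:
        g = self.model.rates.generation_time_years
        lo = generations_to_ka(self.tau_ci[0], g)
        hi = generations_to_ka(self.tau_ci[1], g)
        return (
            f"Net divergence {self.model.group_x} vs {self.model.group_y} "
            f"({self.model.chrom_class}, {self.n_windows} windows):\n"
            f"  Da   = {self.da_mean:.3e} per site\n"
            f"  tau  = {self.tau:,.0f} generations "
            f"[{self.tau_ci[0]:,.0f}, {self.tau_ci[1]:,.0f}]\n"
            f"  age  = {self.ka} ka [{lo}, {hi}] at {g} years/generation"
        )
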