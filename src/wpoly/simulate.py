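"""Synthetic ZW cohorts with a trans-species W polymorphism.

The generator emulates the sampling design the analysis chain assumes:
two sister species with a recent split of their autosomal (and Z) gene
pools, and a non-recombining W chromosome split into two deep allelic
classes ("haplogroups") that deterministically set the female colour
morph.  Because the haplogroup split predates the species split, the W
carries a trans-species balanced polymorphism while autosomes sort by
species.

Genealogies are drawn per window with a Hudson-style structured
coalescent (discrete lineages, exponential waiting times, population
merges at fixed epoch times, no recombination within a window; windows
are independent).  Mutations follow an infinite-sites model inside each
window, coded ancestral=0 / derived=1, so downstream statistics that
need polarized alleles (ABBA-BABA) have exact truth.

Sex-specific ploidy is enforced at emission: autosomes are diploid in
everyone, the Z is diploid in males and haploid in females, and the W is
haploid in females and entirely absent in males.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    ABSENT,
    MISSING,
    SiteTable,
    validate_metadata,
    write_bed,
    write_popmap,
    write_table,
    write_vcf,
)

SPECIES = ("canorus", "optatus")
MORPHS = ("gray", "rufous")

CHROM_NAMES = {"autosome": "chrA", "Z": "chrZ", "W": "chrW"}


@dataclass
class SimulationConfig:
    """Demographic and mutational parameters of the synthetic cohort.

    Defaults follow the study conditions the analysis is designed for: an
    avian-wide germline rate of 1.01e-8 mutations/site/generation on
    autosomes and half that on the W (its maternal restriction shields it
    from the male germ line), a species split 5e4 generations ago and a W
    haplogroup split ten times deeper, surveyed in 50-kb windows.

    ``ne_auto`` is the diploid effective size per species; ``ne_w`` the
    effective number of W-carrying females per species, split evenly
    between the two haplogroup classes while the polymorphism is
    balanced.
    """

    n_per_group: int = 5
    n_males_per_species: int = 2
    ne_auto: float = 5.0e4
    ne_w: float = 2.5e4
    t_species: float = 5.0e4
    t_plumage: float = 5.0e5
    mu_auto: float = 1.01e-8
    mu_w: float | None = None
    gene_flow_p2p3: float = 0.0
    n_windows: int = 100
    window_len_bp: int = 50_000
    seed: int = 0
    chromosomes: tuple[str, ...] = ("autosome", "Z", "W")
    # optional step change in population size (all demes), for
    # expansion/bottleneck scenarios: sizes are multiplied by
    # ``resize_factor`` for times older than ``t_resize``.
    t_resize: float | None = None
    resize_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_w is None:
            self.mu_w = self.mu_auto / 2.0
        for name in ("n_per_group", "n_males_per_species", "n_windows", "window_len_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.t_plumage >= self.t_species >= 0):
            raise ValueError("need t_plumage >= t_species >= 0")
        if not (0.0 <= self.gene_flow_p2p3 < 1.0):
            raise ValueError("gene_flow_p2p3 must be in [0, 1)")
        unknown = set(self.chromosomes) - set(CHROM_NAMES)
        if unknown:
            raise ValueError(f"unknown chromosome classes: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = list(self.chromosomes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "chromosomes" in d:
            d["chromosomes"] = tuple(d["chromosomes"])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """Simulated genotype tables plus the metadata that generated them."""

    site_tables: dict[str, SiteTable]
    metadata: pd.DataFrame
    config: SimulationConfig
    windows: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coalescent engine
# ---------------------------------------------------------------------------

def _simulate_genealogy(rng, tip_pops, pop_sizes, events):
    """Hudson-style structured coalescent for one non-recombining window.

    tip_pops: population id per tip (tips are numbered 0..n-1).
    pop_sizes: {pop: size in sequence copies}.
    events: time-sorted list of ("merge", t, src, dst, new_dst_size|None)
            and ("resize", t, pop, size) tuples.
    Returns (parent, node_time) arrays over 2n-1 nodes; root parent = -1.
    """
    n = len(tip_pops)
    active: dict[object, list[int]] = defaultdict(list)
    for i, p in enumerate(tip_pops):
        active[p].append(i)
    sizes = dict(pop_sizes)
    node_time = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    nxt = n
    t = 0.0
    ei = 0
    events = sorted(events, key=lambda e: e[1])

    def n_active():
        return sum(len(v) for v in active.values())

    while n_active() > 1 or ei < len(events):
        rates = {p: len(v) * (len(v) - 1) / (2.0 * sizes[p])
                 for p, v in active.items() if len(v) >= 2}
        total = sum(rates.values())
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = np.inf
        if ei < len(events) and t + wait >= events[ei][1]:
            ev = events[ei]
            ei += 1
            t = ev[1]
            if ev[0] == "merge":
                _, _, src, dst, new_size = ev
                if src in active:
                    active[dst].extend(active.pop(src))
                if new_size is not None:
                    sizes[dst] = new_size
            else:  # resize
                _, _, pop, size = ev
                sizes[pop] = size
            continue
        if not np.isfinite(wait):
            raise RuntimeError("lineages stranded in non-coalescing demes")
        t += wait
        pops, weights = zip(*rates.items())
        pop = pops[int(rng.choice(len(pops), p=np.asarray(weights) / total))]
        lin = active[pop]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[int(i)], lin[int(j)]
        node_time[nxt] = t
        parent[a] = parent[b] = nxt
        lin.remove(a)
        lin.remove(b)
        lin.append(nxt)
        nxt += 1
    return parent, node_time


def _leaf_sets(parent, n_tips):
    """Boolean (n_nodes, n_tips) matrix of tip descendancy."""
    n_nodes = len(parent)
    below = np.zeros((n_nodes, n_tips), dtype=bool)
    below[np.arange(n_tips), np.arange(n_tips)] = True
    # children have smaller index than parents by construction
    for node in range(n_nodes - 1):
        p = parent[node]
        if p >= 0:
            below[p] |= below[node]
    return below

def _drop_mutations(rng, parent, node_time, n_tips, mu, window_len, max_redraws=100):
    """Poisson infinite-sites mutations; returns (positions, derived matrix).

    positions are 1-based within the window.  If a draw yields more
    segregating sites than the window has base pairs, the draw is
    rejected and repeated.
    """
    branch = np.where(parent >= 0, node_time[parent] - node_time, 0.0)
    lam = mu * window_len * branch
    for _ in range(max_redraws):
        nmut = rng.poisson(lam)
        total = int(nmut.sum())
        if total <= window_len:
            break
    else:
        raise RuntimeError(
            "segregating sites persistently exceed window length; "
            "check mutation rate / population sizes"
        )
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, n_tips), dtype=np.int8)
    below = _leaf_sets(parent, n_tips)
    carriers = np.repeat(np.arange(len(parent)), nmut)
    derived = below[carriers].astype(np.int8)
    positions = np.sort(rng.choice(window_len, size=total, replace=False)) + 1
    # drop mutations on the root edge or fixed in the sample (non-segregating)
    seg = (derived.sum(axis=1) > 0) & (derived.sum(axis=1) < n_tips)
    return positions[seg], derived[seg]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _build_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for morph in MORPHS:
            for k in range(cfg.n_per_group):
                rows.append((f"{sp[:3]}_{morph}_F{k:02d}", sp, morph, "F", sp))
        for k in range(cfg.n_males_per_species):
            rows.append((f"{sp[:3]}_M{k:02d}", sp, "unknown", "M", sp))
    meta = pd.DataFrame(rows, columns=["sample", "species", "morph", "sex", "population"])
    return validate_metadata(meta)


def _tip_layout(meta: pd.DataFrame, chrom_class: str):
    """Sequence tips for one chromosome class.

    Returns (tip_pops, tip_owner, tip_slot): population label, sample row
    index and allele slot per tip.
    """
    tip_pops, owner, slot = [], [], []
    for i, row in meta.reset_index(drop=True).iterrows():
        sp, morph, sex = row["species"], row["morph"], row["sex"]
        if chrom_class == "autosome":
            copies = 2
            pop = sp
        elif chrom_class == "Z":
            copies = 2 if sex == "M" else 1
            pop = sp
        elif chrom_class == "W":
            if sex == "M":
                continue
            copies = 1
            pop = (sp, morph)
        else:  # pragma: no cover
            raise ValueError(chrom_class)
        for c in range(copies):
            tip_pops.append(pop)
            owner.append(i)
            slot.append(c)
    return tip_pops, owner, slot


def _demography(cfg: SimulationConfig, chrom_class: str):
    """Population sizes (sequence copies) and epoch events per class."""
    sp1, sp2 = SPECIES
    if chrom_class in ("autosome", "Z"):
        per_species = 2.0 * cfg.ne_auto if chrom_class == "autosome" else 1.5 * cfg.ne_auto
        sizes = {sp1: per_species, sp2: per_species}
        events = [("merge", cfg.t_species, sp2, sp1, per_species)]
        resizable = [sp1, sp2]
    else:  # W: four haplogroup classes, merged within haplogroup at the
        # species split and across haplogroups at the plumage split
        half = cfg.ne_w / 2.0
        sizes = {(sp, m): half for sp in SPECIES for m in MORPHS}
        events = [
            ("merge", cfg.t_species, (sp2, "gray"), (sp1, "gray"), half),
            ("merge", cfg.t_species, (sp2, "rufous"), (sp1, "rufous"), half),
            ("merge", cfg.t_plumage, (sp1, "rufous"), (sp1, "gray"), float(cfg.ne_w)),
        ]
        resizable = list(sizes)
    if cfg.t_resize is not None and cfg.resize_factor != 1.0:
        for pop in resizable:
            events.append(("resize", cfg.t_resize, pop, sizes[pop] * cfg.resize_factor))
    return sizes, events


def _expected_tree_length(cfg: SimulationConfig, chrom_class: str, n_tips: int) -> float:
    """Coarse upper estimate of E[total branch length], generations."""
    sizes, _ = _demography(cfg, chrom_class)
    n_max = max(sizes.values())
    harmonic = np.sum(1.0 / np.arange(1, max(n_tips, 2)))
    deep = cfg.t_plumage if chrom_class == "W" else cfg.t_species
    return 2.0 * n_max * harmonic + 2.0 * len(sizes) * deep


def _window_rng(seed: int, chrom_class: str, window: int):
    code = {"autosome": 0, "Z": 1, "W": 2}[chrom_class]
    return np.random.default_rng([seed, code, window])


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort under ``config``.

    Per chromosome class and window, a genealogy is sampled from the
    structured coalescent described in the module docstring, mutations are
    dropped on branches, and genotypes are emitted with sex-specific
    ploidy.  Windows are laid out contiguously (window ``i`` covers
    positions ``[i*L+1, (i+1)*L]``), so 50-kb scan windows align with
    simulation windows.
    """
    cfg = config
    meta = _build_metadata(cfg)
    tables: dict[str, SiteTable] = {}
    windows: dict[str, pd.DataFrame] = {}
    L = cfg.window_len_bp
    for chrom_class in cfg.chromosomes:
        chrom = CHROM_NAMES[chrom_class]
        tip_pops, owner, slot = _tip_layout(meta, chrom_class)
        n_tips = len(tip_pops)
        mu = cfg.mu_w if chrom_class == "W" else cfg.mu_auto
        exp_s = mu * L * _expected_tree_length(cfg, chrom_class, n_tips)
        if exp_s > 1.5 * L:
            raise ValueError(
                f"expected segregating sites ({exp_s:.0f}) exceed window "
                f"length by >50% on {chrom_class}; parameters look wrong"
            )
        sizes, events = _demography(cfg, chrom_class)
        all_pos, all_gt = [], []
        for w in range(cfg.n_windows):
            rng = _window_rng(cfg.seed, chrom_class, w)
            tips = list(tip_pops)
            if (
                chrom_class == "autosome"
                and cfg.gene_flow_p2p3 > 0.0
            ):
                # recent admixture pulse: optatus-rufous haplotypes carry
                # canorus ancestry with probability gene_flow_p2p3
                for k, pop in enumerate(tips):
                    if (
                        meta.iloc[owner[k]]["species"] == SPECIES[1]
                        and meta.iloc[owner[k]]["morph"] == "rufous"
                        and rng.random() < cfg.gene_flow_p2p3
                    ):
                        tips[k] = SPECIES[0]
            parent, node_time = _simulate_genealogy(rng, tips, sizes, events)
            pos, derived = _drop_mutations(rng, parent, node_time, n_tips, mu, L)
            if len(pos) == 0:
                continue
            gt = np.full((len(pos), len(meta), 2), ABSENT, dtype=np.int8)
            for k in range(n_tips):
                gt[:, owner[k], slot[k]] = derived[:, k]
            all_pos.append(pos + w * L)
            all_gt.append(gt)
        if all_pos:
            pos = np.concatenate(all_pos)
            gt = np.concatenate(all_gt)
        else:
            pos = np.empty(0, dtype=np.int64)
            gt = np.empty((0, len(meta), 2), dtype=np.int8)
        # males have no W at all: mark every slot absent (males were never
        # assigned tips, so this is already true by construction)
        tables[chrom_class] = SiteTable(
            chrom=np.full(len(pos), chrom, dtype=object),
            pos=pos,
            ref=np.full(len(pos), "A", dtype=object),
            alt=np.full(len(pos), "T", dtype=object),
            alleles=gt,
            samples=list(meta["sample"]),
            chrom_class=chrom_class,
        )
        windows[chrom_class] = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(cfg.n_windows) * L,
                "end": (np.arange(cfg.n_windows) + 1) * L,
            }
        )
    return SimulatedCohort(site_tables=tables, metadata=meta, config=cfg, windows=windows)


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def _overlaps(start, end, intervals) -> bool:
    return any(s < end and start < e for s, e in intervals)


def simulate_coverage(
    cohort: SimulatedCohort,
    repetitive_w: Sequence[tuple[int, int]] = (),
    misassembled_z: Sequence[tuple[int, int]] = (),
    mean_depth: float = 10.0,
    depth_sd_frac: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample per-window depths mirroring ZW coverage structure.

    Baseline: autosomes ~ ``mean_depth`` in everyone; W ~ half depth in
    females and zero in males; Z ~ full depth in males, half in females.
    ``repetitive_w`` intervals collapse repeats onto single W windows:
    depth is elevated in both sexes.  ``misassembled_z`` intervals behave
    like W sequence stranded on the Z: female depth exceeds male depth.

    Returns a long-format coverage table (chrom, start, end, sample,
    mean_depth) consumable by the masking module.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 7_777 if seed is None else seed)
    meta = cohort.metadata
    rows = []

    def depth(base):
        if base <= 0:
            return 0.0
        return float(max(0.0, rng.normal(base, depth_sd_frac * mean_depth)))

    for chrom_class, wins in cohort.windows.items():
        chrom = CHROM_NAMES[chrom_class]
        for _, win in wins.iterrows():
            s, e = int(win["start"]), int(win["end"])
            rep = chrom_class == "W" and _overlaps(s, e, repetitive_w)
            mis = chrom_class == "Z" and _overlaps(s, e, misassembled_z)
            for _, m in meta.iterrows():
                female = m["sex"] == "F"
                if chrom_class == "autosome":
                    base = mean_depth
                elif chrom_class == "W":
                    if rep:
                        base = 2.0 * mean_depth if female else mean_depth
                    else:
                        base = 0.5 * mean_depth if female else 0.0
                else:  # Z
                    if mis:
                        base = 1.5 * mean_depth if female else 0.5 * mean_depth
                    else:
                        base = 0.5 * mean_depth if female else mean_depth
                rows.append((chrom, s, e, m["sample"], depth(base)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "mean_depth"])


def simulate_mt_coverage(
    samples: Sequence[str],
    n_windows: int = 40,
    window_bp: int = 25,
    mean_depth: float = 200.0,
    outlier_windows: Mapping[int, float] | dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mitochondrial coverage fixture: flat depth with injected outliers.

    ``outlier_windows`` maps window index -> depth multiplier (e.g. 0.2
    for a NUMT-depleted window, 3.0 for a repeat-inflated one).
    """
    rng = np.random.default_rng(seed)
    outlier_windows = dict(outlier_windows or {})
    rows = []
    for w in range(n_windows):
        mult = outlier_windows.get(w, 1.0)
        for s in samples:
            d = max(0.0, rng.normal(mean_depth * mult, 0.02 * mean_depth))
            rows.append(("chrM", w * window_bp, (w + 1) * window_bp, s, d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "mean_depth"])


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, directory, coverage: pd.DataFrame | None = None) -> dict:
    """Write VCFs, popmap, window BEDs, optional coverage TSV and config.

    Output is byte-deterministic for a given cohort.  Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    paths = {}
    contig_len = cfg.n_windows * cfg.window_len_bp
    for chrom_class, table in cohort.site_tables.items():
        p = directory / f"{chrom_class}.vcf"
        write_vcf(table, p, contig_lengths={CHROM_NAMES[chrom_class]: contig_len})
        paths[f"vcf_{chrom_class}"] = p
        b = directory / f"windows_{chrom_class}.bed"
        write_bed(cohort.windows[chrom_class], b)
        paths[f"windows_{chrom_class}"] = b
    paths["popmap"] = directory / "popmap.tsv"
    write_popmap(cohort.metadata, paths["popmap"])
    if coverage is not None:
        paths["coverage"] = directory / "coverage.tsv"
        write_table(coverage, paths["coverage"])
    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths
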