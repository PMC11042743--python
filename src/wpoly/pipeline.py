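"""End-to-end orchestration of the analysis stages on one cohort.

The pipeline runs simulate -> filter/mask -> association -> windowed
diversity -> ABBA-BABA -> topology weighting -> dating -> PCA, writing
per-stage tables and a JSON summary report.  Every stochastic stage
derives its stream from the single run seed, so a rerun with the same
config reproduces the report exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import MorphAssociation
from .dating import DivergenceDating, RateConfig, da_ratio_ci, window_da
from .diversity import WindowedDiversity, tajimas_d
from .filtering import CoverageTable, FilterConfig, build_sex_mask, filter_sites
from .introgression import PattersonD
from .io import samples_by_group, write_table
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort, simulate_coverage, write_cohort
from .structure import GenotypePCA
from .topology import TopologyWeighting, enumerate_topologies, topology_from_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    outdir: str = "wpoly_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    window_bp: int = 50_000
    min_called_frac: float = 0.2
    assoc_alpha: float = 0.05
    n_blocks: int = 50
    window_snps: int = 100
    min_scored: int = 10
    bootstrap: int = 1000
    rates: dict = field(default_factory=dict)
    stages: tuple[str, ...] = (
        "simulate", "filter", "mask", "assoc", "windows",
        "dstat", "topoweight", "date", "pca",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    cohort: SimulatedCohort | None = None

    def stage(name):
        return name in config.stages

    try:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        if stage("simulate"):
            cohort = simulate_cohort(sim_cfg)
            coverage = simulate_coverage(cohort, seed=config.seed + 1)
            write_cohort(cohort, out / "cohort", coverage)
            report["stages"]["simulate"] = {
                cls: int(t.n_sites) for cls, t in cohort.site_tables.items()
            }
        if cohort is None:
            raise FileNotFoundError(
                "pipeline currently runs from a simulated cohort; enable the "
                "'simulate' stage or load tables through the library API"
            )
        meta = cohort.metadata
        tables = dict(cohort.site_tables)

        if stage("filter"):
            fcfg = FilterConfig(**config.filters)
            counts = {}
            for cls, t in tables.items():
                mean_dp = (
                    float(np.nanmean(t.site_dp))
                    if t.site_dp is not None and np.isfinite(t.site_dp).any()
                    else None
                )
                tables[cls], counts[cls] = filter_sites(t, fcfg, mean_dp)
            report["stages"]["filter"] = counts

        if stage("mask"):
            cov = CoverageTable(pd.read_csv(out / "cohort" / "coverage.tsv", sep="\t"))
            masks = {}
            for cls in ("W", "Z"):
                m = build_sex_mask(cov, meta, cls)
                m.to_bed(out / f"mask_{cls}.bed")
                masks[cls] = m.total_bp
            report["stages"]["mask"] = masks

        groups_sm = {
            f"{sp[:3]}_{morph}": ids
            for (sp, morph), ids in samples_by_group(
                meta[meta["sex"] == "F"], ["species", "morph"]
            ).items()
        }
        hun = meta[(meta["species"] == "canorus") & (meta["sex"] == "F")]
        morph_groups = samples_by_group(hun, "morph")

        if stage("assoc"):
            res = MorphAssociation(tables["W"], meta).fit()
            auto_res = MorphAssociation(tables["autosome"], meta).fit()
            combined = pd.concat([auto_res.table, res.table], ignore_index=True)
            write_table(combined, out / "assoc.tsv")
            n_tests = len(combined)
            p_thr, chi2_crit = res.threshold(config.assoc_alpha, n_tests)
            hits = combined[combined["p"] < p_thr]
            report["stages"]["assoc"] = {
                "n_tests": n_tests,
                "p_threshold": p_thr,
                "chi2_critical": chi2_crit,
                "hits": int(len(hits)),
                "hits_on_W": int((hits["chrom"] == "chrW").sum()),
            }

        win = {}
        if stage("windows"):
            for cls in ("autosome", "W"):
                g = groups_sm if cls == "autosome" else groups_sm
                res = WindowedDiversity(
                    tables[cls], g, config.window_bp, config.min_called_frac
                ).fit()
                win[cls] = res.windows
                write_table(res.windows, out / f"windows_{cls}.tsv")
            td = tajimas_d(tables["W"], list(hun["sample"]), config.window_bp)
            write_table(td, out / "tajimas_d_W.tsv")
            report["stages"]["windows"] = {
                cls: int(len(df)) for cls, df in win.items()
            }

        if stage("dstat"):
            dres = PattersonD(
                tables["autosome"],
                p1=groups_sm["opt_gray"],
                p2=groups_sm["opt_rufous"],
                targets={"can_gray": groups_sm["can_gray"],
                         "can_rufous": groups_sm["can_rufous"]},
                outgroup_samples=None,
                n_blocks=config.n_blocks,
            ).fit()
            write_table(dres, out / "dstat.tsv")
            report["stages"]["dstat"] = dres.set_index("P3")["D"].to_dict()

        if stage("topoweight"):
            sp_topo = "((can_gray,can_rufous),(opt_gray,opt_rufous));"
            pl_topo = "((can_gray,opt_gray),(can_rufous,opt_rufous));"
            cats = {}
            for cls in ("autosome", "W"):
                tw = TopologyWeighting(
                    tables[cls], meta, groups_sm, sp_topo, pl_topo,
                    window_snps=config.window_snps, min_scored=config.min_scored,
                    seed=config.seed,
                ).fit()
                write_table(tw.table, out / f"topoweight_{cls}.tsv")
                cats[cls] = tw.table["category"].value_counts().to_dict()
            report["stages"]["topoweight"] = cats

        if stage("date") and win:
            rates = RateConfig(**config.rates)
            species = DivergenceDating(
                win["autosome"], "can_gray", "opt_gray", "autosome", rates
            ).fit(B=config.bootstrap, seed=config.seed)
            da_pl = window_da(win["W"], "can_gray", "can_rufous")
            da_sp = window_da(win["W"], "can_gray", "opt_gray")
            ratio = da_ratio_ci(da_pl, da_sp, B=config.bootstrap, seed=config.seed)
            report["stages"]["date"] = {
                "tau_species_autosomal": species.tau,
                "tau_ci": list(species.tau_ci),
                "ka": species.ka,
                "w_da_ratio": ratio.mean,
                "w_da_ratio_ci": [ratio.ci_low, ratio.ci_high],
            }

        if stage("pca"):
            pca_w = GenotypePCA(
                tables["W"].select_samples(
                    list(meta.loc[meta["sex"] == "F", "sample"])
                ),
                meta,
            ).fit()
            pca_w.scores.to_csv(out / "pca_W_scores.tsv", sep="\t")
            tests = pca_w.group_tests(meta)
            write_table(tests, out / "pca_W_tests.tsv")
            report["stages"]["pca"] = {
                "variance_explained": [float(v) for v in pca_w.variance_explained[:3]],
                "morph_pc1_p_adj": float(
                    tests.query("component == 'PC1' and factor == 'morph'")["p_adj"].iloc[0]
                ),
            }
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    config.to_yaml(out / "effective_config.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
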