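"""End-to-end orchestration: simulate -> normalize -> translatome -> compare
-> regulation -> enrich, driven by a single config.

``run_all`` executes the stages in order on a synthetic experiment, collects
the gene-count funnel (expressed -> peak-called -> single-fraction ->
non-aberrant -> both-conditions), the regulation-class counts, cluster sizes
and enrichment hits into a :class:`RunReport`, and — because the synthetic
truth is known — also reports recovery metrics (occupancy error, peak-call
accuracy, class accuracy). Identical config and seeds give identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import compare as compare_mod
from . import enrich as enrich_mod
from . import normalize as normalize_mod
from . import simulate as simulate_mod
from .regulation import RegulationModel
from .translatome import TranslatomeModel, fraction_engaged_from_trace

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all"]

_STAGES = ("simulate", "normalize", "translatome", "compare", "regulation", "enrich")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full synthetic run.

    Defaults reproduce the emulated study design: 1948 genes spotted in
    duplicate, five replicate series, five stress fractions / seven optimal
    fractions, 95% bootstrap confidence, per-gene alpha 0.05, six Ward
    clusters. ``n_iter`` defaults to 1000 bootstrap iterations (the fast
    profile); set 10000 for the full-depth bootstrap.
    """

    n_genes: int = 1948
    n_series: int = 5
    seed: int = 0
    archetype_probs: dict[str, float] = field(
        default_factory=lambda: dict(simulate_mod.DEFAULT_ARCHETYPE_PROBS)
    )
    frac_silent: float = 0.12
    noise_sigma: float = 0.2
    background_mean: float = 2.0
    background_sd: float = 0.5
    empty_spot_mean: float = 2.0
    empty_spot_sd: float = 0.5
    n_iter: int = 1000
    conf: float = 0.95
    alpha: float = 0.05
    pooled_ttest: bool = False
    k_clusters: int = 6
    min_series: int = 3
    equalize_arrays: bool = False
    engaged_target_stress: float = 0.59
    engaged_target_optimal: float = 0.61

    def stage_seeds(self) -> dict[str, int]:
        return {
            stage: (self.seed * 1000003 + i + 1) % (2**31)
            for i, stage in enumerate(_STAGES)
        }

    def noise_model(self) -> simulate_mod.NoiseModel:
        return simulate_mod.NoiseModel(
            lognormal_sigma=self.noise_sigma,
            background_mean=self.background_mean,
            background_sd=self.background_sd,
            empty_spot_mean=self.empty_spot_mean,
            empty_spot_sd=self.empty_spot_sd,
            seed=self.stage_seeds()["simulate"],
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict[str, Any]
    seeds: dict[str, int]
    funnel: dict[str, int]
    class_counts: dict[str, int]
    occupancy_calls: dict[str, int]
    density_calls: dict[str, int]
    cluster_sizes: dict[int, int]
    median_occupancy: dict[str, float]
    median_density: dict[str, float]
    engaged_pct: dict[str, float]
    mrna_share_ratio: float
    mu_ratio: float
    kdeg_ratio_of_mean_half_lives: float
    enrichment_significant: dict[str, list[str]]
    codon_test: dict[str, float]
    recovery: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["polytome run report", "==================="]
        lines.append("gene funnel:")
        for k, v in self.funnel.items():
            lines.append(f"  {k:>18}: {v}")
        lines.append(
            "regulation classes: "
            + ", ".join(f"{k} {v}" for k, v in sorted(self.class_counts.items()))
        )
        lines.append(
            "cluster sizes: "
            + ", ".join(f"{k}:{v}" for k, v in sorted(self.cluster_sizes.items()))
        )
        for cond in self.median_occupancy:
            lines.append(
                f"{cond}: median occupancy {self.median_occupancy[cond]:.3f}, "
                f"median density {self.median_density[cond]:.3f}, "
                f"engaged {self.engaged_pct[cond]:.1f}%"
            )
        lines.append(f"mu ratio (stress/optimal): {self.mu_ratio:.4f}")
        lines.append(
            "k_deg ratio of mean half-lives: "
            f"{self.kdeg_ratio_of_mean_half_lives:.4f}"
        )
        lines.append(f"mRNA share ratio: {self.mrna_share_ratio:.3f}")
        if self.recovery:
            lines.append("recovery vs planted truth:")
            for k, v in sorted(self.recovery.items()):
                lines.append(f"  {k}: {v:.4f}")
        return "\n".join(lines)


def _stage(name: str):
    """Decorator-free stage guard: re-raise stage failures tagged."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the whole synthetic pipeline; optionally write all tables."""
    seeds = config.stage_seeds()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yml")

    with _stage("simulate"):
        catalog = simulate_mod.generate_catalog(
            config.n_genes, seed=seeds["simulate"]
        )
        optimal = simulate_mod.optimal_condition()
        stress = simulate_mod.stress_condition()
        truth = simulate_mod.generate_truth(
            catalog,
            optimal,
            stress,
            archetype_probs=config.archetype_probs,
            seed=seeds["simulate"] + 1,
            frac_silent=config.frac_silent,
        )
        tables = simulate_mod.simulate_arrays(
            truth, config.noise_model(), config.n_series
        )
        traces = {
            "stress": simulate_mod.simulate_trace(
                truth, stress, config.engaged_target_stress
            ),
            "optimal": simulate_mod.simulate_trace(
                truth, optimal, config.engaged_target_optimal
            ),
        }
        if out is not None:
            truth.write(out / "truth")
            simulate_mod.write_tables(tables, out / "arrays")
            for name, tr in traces.items():
                tr.to_csv(out / f"trace_{name}.tsv", sep="\t", index=False)

    with _stage("normalize"):
        norm = normalize_mod.normalize_experiment(
            tables, equalize_arrays=config.equalize_arrays
        )
        share = normalize_mod.mrna_share(
            norm.s0_spot_sum(tables, "stress"),
            stress.total_rna,
            norm.s0_spot_sum(tables, "optimal"),
            optimal.total_rna,
        )
        if out is not None:
            norm.write(out / "proportions.tsv")

    with _stage("translatome"):
        results = {}
        for cond in (stress, optimal):
            model = TranslatomeModel.from_experiment(
                norm, cond, catalog, min_series=config.min_series
            )
            results[cond.name] = model.fit(
                n_iter=config.n_iter,
                conf=config.conf,
                seed=seeds["translatome"],
            )
            if out is not None:
                results[cond.name].write(out / f"translatome_{cond.name}.tsv")
        engaged = {
            name: fraction_engaged_from_trace(tr) for name, tr in traces.items()
        }

    with _stage("compare"):
        comparison = compare_mod.compare_conditions(
            results["stress"],
            results["optimal"],
            alpha=config.alpha,
            pooled=config.pooled_ttest,
        )
        if out is not None:
            comparison.write(out / "comparison.tsv")

    with _stage("regulation"):
        rate_cols = ["gene_id", "half_life_min", "mrna_level"]
        rates = {
            name: truth.condition_table(name)
            .reset_index()[rate_cols]
            .query("mrna_level > 0")
            for name in ("stress", "optimal")
        }
        reg_model = RegulationModel(
            rates["stress"],
            rates["optimal"],
            stress.growth_rate,
            optimal.growth_rate,
            results["stress"],
            results["optimal"],
        )
        regulation = reg_model.fit(k=config.k_clusters)
        if out is not None:
            regulation.write(out / "regulation.tsv")

    with _stage("enrich"):
        categories = catalog.categories.to_dict()
        background = list(comparison.table.index)
        enrichment_sig: dict[str, list[str]] = {}
        enrich_tables = {}
        for cls in ("up", "down", "antagonistic"):
            subset = list(comparison.genes_in_class(cls))
            if subset:
                res = enrich_mod.category_enrichment(
                    subset, background, categories, alpha=config.alpha
                )
                enrich_tables[cls] = res
                enrichment_sig[cls] = res.loc[
                    res["significant"], "category"
                ].tolist()
            else:
                enrichment_sig[cls] = []
        sequences = catalog.sequences()
        dens_up = [
            g
            for g in comparison.table.index[
                comparison.table["dens_call"] == compare_mod.HIGHER
            ]
            if g in sequences
        ]
        rest = [
            g for g in background if g not in set(dens_up) and g in sequences
        ]
        if dens_up and rest:
            stat, p = enrich_mod.compare_codon_content(dens_up, rest, sequences)
            codon_test = {"statistic": stat, "p_value": p}
        else:
            codon_test = {}
        if out is not None:
            for cls, res in enrich_tables.items():
                res.to_csv(out / f"enrichment_{cls}.tsv", sep="\t", index=False)

    # ---- report assembly -------------------------------------------------
    stress_res = results["stress"]
    optimal_res = results["optimal"]
    expressed_stress = norm.condition_profiles("stress")["gene_id"].nunique()
    funnel = {
        "genes_on_array": config.n_genes,
        "expressed": int(expressed_stress),
        **stress_res.funnel(),
        "both_conditions": int(len(comparison.table)),
    }

    truth_stress = truth.condition_table("stress")
    truth_optimal = truth.condition_table("optimal")
    recovery: dict[str, float] = {}
    errs = []
    peak_hits, peak_total = 0, 0
    for res, tt in (
        (stress_res, truth_stress),
        (optimal_res, truth_optimal),
    ):
        joined = res.table.join(tt[["occupancy_true", "peak_fraction"]], rsuffix="_true")
        errs.append((joined["occupancy"] - joined["occupancy_true"]).abs())
        single = joined[~joined["widened"]]
        peak_hits += int(
            (single["peak_fraction"] == single["peak_fraction_true"]).sum()
        )
        peak_total += len(single)
    all_errs = pd.concat(errs)
    recovery["mean_abs_occupancy_error"] = float(all_errs.mean())
    recovery["peak_call_accuracy"] = (
        peak_hits / peak_total if peak_total else float("nan")
    )
    truth_class = truth.genes.set_index("gene_id")["archetype"]
    pred = comparison.table["reg_class"]
    matched = (pred == truth_class.loc[pred.index]).mean() if len(pred) else float("nan")
    recovery["class_accuracy"] = float(matched)

    report = RunReport(
        config=dataclasses.asdict(config),
        seeds=seeds,
        funnel=funnel,
        class_counts={str(k): int(v) for k, v in comparison.class_counts().items()},
        occupancy_calls={
            str(k): int(v) for k, v in comparison.occupancy_call_counts().items()
        },
        density_calls={
            str(k): int(v) for k, v in comparison.density_call_counts().items()
        },
        cluster_sizes={
            int(k): int(v) for k, v in regulation.clusters.sizes().items()
        },
        median_occupancy={
            name: float(res.table["occupancy"].median())
            for name, res in results.items()
        },
        median_density={
            name: float(res.retained()["density"].median())
            for name, res in results.items()
        },
        engaged_pct={k: float(v) for k, v in engaged.items()},
        mrna_share_ratio=float(share),
        mu_ratio=float(stress.growth_rate / optimal.growth_rate),
        kdeg_ratio_of_mean_half_lives=float(
            truth_optimal.loc[truth_optimal["mrna_level"] > 0, "half_life_min"].mean()
            / truth_stress.loc[truth_stress["mrna_level"] > 0, "half_life_min"].mean()
        ),
        enrichment_significant=enrichment_sig,
        codon_test=codon_test,
        recovery=recovery,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text())
    return report
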