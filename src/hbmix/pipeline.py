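"""End-to-end pipeline: generate/load -> preprocess -> network -> weight.

The run writes every intermediate artifact (panel CSVs, exclusion
report, standardized matrix, instability curve, GraphML network, edge
list, community table, HQ/HI matrices) plus a JSON run report, and is
fully reproducible under a fixed seed.

The two analysis branches share inputs but not transforms: the
network runs on log-transformed, imputed, winsorized, standardized,
covariate-adjusted values, while hazard quotients use raw-scale
concentrations (censored cells at their imputed value by default, or
at LOQ/2 under the alternative policy).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .guidance import load_database, load_molecular_weights
from .hazard import community_hi, compute_hq_matrix, driver_analysis, exceedance_stats
from .network import estimate_network, export_network, walktrap_communities
from .panel import ExposurePanel, validate_covariates
from .preprocess import (
    adjust_covariates,
    correct_outliers,
    filter_loq,
    impute_censored,
    impute_missing,
    log_transform,
    standardize,
)
from .synthetic import GeneratorConfig, generate_panel, write_dataset

__all__ = ["RunConfig", "run_pipeline", "render_report"]


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of a pipeline run."""

    out_dir: str
    seed: int = 0
    # inputs: either a generator config or a directory of CSVs
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    guidance_db: str | None = None  # packaged default when None
    # preprocessing
    max_censored_fraction: float = 0.40
    outlier_z: float = 4.0
    # network
    n_subsamples: int = 20
    subsample_size: int | None = None
    stars_threshold: float = 0.1
    walktrap_steps: int = 4
    min_community_size: int = 3
    weighted_graph: bool = False
    # hazard
    censored_value_policy: str = "imputed"  # or "loq_half"

    def __post_init__(self) -> None:
        if self.generator is None and self.input_dir is None:
            raise ValueError("config needs either a generator section or input_dir")
        if self.censored_value_policy not in ("imputed", "loq_half"):
            raise ValueError("censored_value_policy must be 'imputed' or 'loq_half'")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        if self.guidance_db is not None and not Path(self.guidance_db).exists():
            raise ValueError(f"guidance database not found: {self.guidance_db}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = raw.pop("generator", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(generator=GeneratorConfig(**gen) if gen else None, **raw)
        return cfg


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report.setdefault("stage_seconds", {})[name] = round(
                time.perf_counter() - self.t0, 3
            )
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": _config_dict(config)}

    with _stage(report, "inputs"):
        if config.generator is not None:
            panel, covariates, truth = generate_panel(config.generator, seed=config.seed)
            write_dataset(panel, covariates, truth, out / "input")
        else:
            src = Path(config.input_dir)
            panel = ExposurePanel.from_dir(src)
            covariates = pd.read_csv(src / "covariates.csv", index_col="sample")
        validate_covariates(covariates, panel.n_samples)
        db = load_database(config.guidance_db)
        report["n_samples"] = panel.n_samples
        report["n_biomarkers"] = panel.n_biomarkers

    with _stage(report, "preprocess"):
        kept, exclusions = filter_loq(panel, config.max_censored_fraction)
        exclusions.to_csv(out / "exclusion_report.csv")
        logged = log_transform(kept)
        imputed = impute_missing(impute_censored(logged))
        corrected, n_winsorized = correct_outliers(imputed, z_cut=config.outlier_z)
        adjusted = adjust_covariates(standardize(corrected), covariates)
        network_input = standardize(adjusted)
        network_input.values.to_csv(out / "standardized_panel.csv", index_label="sample")
        report["excluded_biomarkers"] = exclusions.index[exclusions["excluded"]].tolist()
        report["n_winsorized_cells"] = int(n_winsorized.sum())

    with _stage(report, "network"):
        model = estimate_network(
            network_input.values,
            n_subsamples=config.n_subsamples,
            subsample_size=config.subsample_size,
            threshold=config.stars_threshold,
            seed=config.seed,
        )
        communities = walktrap_communities(
            model.adjacency,
            steps=config.walktrap_steps,
            min_size=config.min_community_size,
            weights=model.partial_correlation if config.weighted_graph else None,
        )
        pd.DataFrame({
            "lambda": model.lambdas,
            "instability": model.instability,
            "monotonized": model.monotonized,
        }).to_csv(out / "instability_curve.csv", index=False)
        export_network(model, communities, out / "network.graphml", out / "edges.csv")
        communities.to_frame().to_csv(out / "communities.csv")
        report["selected_lambda"] = model.selected_lambda
        report["n_edges"] = model.n_edges
        report["no_stable_graph"] = model.no_stable_graph
        report["communities"] = {k: v for k, v in sorted(communities.communities.items())}
        report["n_singletons"] = len(communities.singletons)
        report["modularity"] = communities.modularity

    with _stage(report, "hazard"):
        # raw-scale concentrations with censored/missing filled
        raw = np.exp(imputed.values)
        if config.censored_value_policy == "loq_half":
            cens = kept.censored
            half = pd.DataFrame(
                np.broadcast_to((kept.loq / 2.0).to_numpy(), raw.shape),
                index=raw.index, columns=raw.columns,
            )
            raw = raw.mask(cens, half)
        raw.to_csv(out / "hazard_input_concentrations.csv", index_label="sample")
        hq, info, members_of = compute_hq_matrix(
            raw, covariates["creatinine"], covariates["age"],
            db=db, mw=load_molecular_weights(),
        )
        result = community_hi(hq, communities, members_of, info)
        hq.to_csv(out / "hazard_quotients.csv", index_label="sample")
        result.community_hi.to_csv(out / "community_hazard_index.csv", index_label="sample")
        result.overall_hi.to_csv(out / "overall_hazard_index.csv", index_label="sample")
        result.coverage.to_csv(out / "coverage.csv")
        drivers = driver_analysis(hq)
        drivers.to_csv(out / "drivers.csv")

        summary = {
            "overall_hi": exceedance_stats(result.overall_hi),
            "community_hi": {
                lab: exceedance_stats(result.community_hi[lab])
                for lab in result.community_hi.columns
            },
            "component_hq": {c: exceedance_stats(hq[c]) for c in hq.columns},
            "drivers": drivers.reset_index().to_dict(orient="records"),
            "coverage": result.coverage.reset_index().to_dict(orient="records"),
            "component_community": result.component_community,
            "occupational_fallbacks": info.index[info["occupational_fallback"]].tolist(),
        }
        (out / "hazard_summary.json").write_text(json.dumps(summary, indent=1))
        report["hazard_summary"] = summary

    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("generator") is not None:
        gen = d["generator"]
        for k, v in list(gen.items()):
            if isinstance(v, tuple):
                gen[k] = list(v)
            elif isinstance(v, np.ndarray):
                gen[k] = v.tolist()
    return d


def render_report(report: dict) -> str:
    """Human-readable markdown summary of a run report."""
    lines = [
        "# Biomonitoring hazard index run",
        "",
        f"- samples: {report['n_samples']}, biomarkers: {report['n_biomarkers']}",
        f"- excluded (> censoring cutoff): {len(report['excluded_biomarkers'])} "
        f"{report['excluded_biomarkers']}",
        f"- selected lambda: {report['selected_lambda']:.4g}; "
        f"edges: {report['n_edges']}",
    ]
    comms = report.get("communities", {})
    if not comms:
        lines.append("- no communities of size >= min_size")
    else:
        lines.append(f"- communities ({len(comms)}):")
        for lab, members in comms.items():
            lines.append(f"    - {lab}: {', '.join(members)}")
    hz = report.get("hazard_summary", {})
    if hz:
        lines += ["", "## Hazard indices (fraction of individuals with HI > 1)", ""]
        lines.append("| scope | exceedance | geometric mean | P50 | P95 |")
        lines.append("|---|---|---|---|---|")
        ov = hz["overall_hi"]
        lines.append(
            f"| overall | {ov['exceedance_fraction']:.1%} | "
            f"{ov['geometric_mean']:.3g} | {ov['p50']:.3g} | {ov['p95']:.3g} |"
        )
        for lab, st in sorted(hz["community_hi"].items()):
            lines.append(
                f"| community {lab} | {st['exceedance_fraction']:.1%} | "
                f"{st['geometric_mean']:.3g} | {st['p50']:.3g} | {st['p95']:.3g} |"
            )
        lines += ["", "## Component hazard quotients", ""]
        lines.append("| component | exceedance | geometric mean | P95 |")
        lines.append("|---|---|---|---|")
        for c, st in sorted(hz["component_hq"].items()):
            lines.append(
                f"| {c} | {st['exceedance_fraction']:.1%} | "
                f"{st['geometric_mean']:.3g} | {st['p95']:.3g} |"
            )
        drivers = hz.get("drivers", [])
        if drivers:
            lines += ["", "## Drivers (leave-one-out)", ""]
            lines.append("| component | mean share of HI | removal ratio |")
            lines.append("|---|---|---|")
            for row in sorted(drivers, key=lambda r: -r["mean_share"]):
                lines.append(
                    f"| {row['component']} | {row['mean_share']:.1%} | "
                    f"{row['removal_ratio']:.2f} |"
                )
    return "\n".join(lines) + "\n"
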