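"""End-to-end orchestration: load -> trait space -> moments -> drivers ->
decomposition, from one configuration, with a CSV results bundle.

The bundle is a directory of plain CSV tables plus one YAML manifest, so
every intermediate is inspectable without the tool.  All numeric outputs
are deterministic under a fixed seed; the run log is the only file with a
timestamp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .decomposition import build_cwm_series, decompose
from .drivers import all_subsets_selection, oneway_anova_tukey
from .errors import ConfigError, RegionalTraitError, TraitMomentsError
from .io import Dataset, load_dataset, select_dominant_species, write_dataset
from .moments import plot_moments, summarize_moments
from .synthetic import SyntheticScenario, generate
from .trait_space import build_trait_space

logger = logging.getLogger("traitmoments")

MOMENTS_ANALYZED = ("CWM", "CWS", "CWK")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``(trait_path, composition_path, environment_path)`` or
    ``scenario`` must be given.  ``axes`` restricts which retained axes are
    analysed (default: all retained).  ``axis_names`` maps axis rank to a
    syndrome label; ``pin_positive`` orients named axes so a chosen trait
    loads positively.
    """

    outdir: str | Path = "results"
    trait_path: str | Path | None = None
    composition_path: str | Path | None = None
    environment_path: str | Path | None = None
    scenario: SyntheticScenario | dict | None = None
    trait_columns: list[str] | None = None
    abiotic_columns: list[str] | None = None
    dominance_threshold: float = 0.90
    axes: list[str] | None = None
    axis_names: dict[int, str] = field(
        default_factory=lambda: {1: "LES", 2: "RES", 3: "HyArq"}
    )
    pin_positive: dict[str, str] | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        paths = (self.trait_path, self.composition_path, self.environment_path)
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.scenario is not None and some_paths:
            raise ConfigError("give either input paths or a synthetic scenario, not both")
        if self.scenario is None and not have_paths:
            raise ConfigError("give the three input paths, or a synthetic scenario")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if isinstance(self.scenario, dict):
            self.scenario = SyntheticScenario(**{**self.scenario, "seed": self.scenario.get("seed", self.seed)})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "axis_names" in raw:
            raw["axis_names"] = {int(k): v for k, v in raw["axis_names"].items()}
        return cls(**raw)


def _stage(outdir: Path, name: str):
    """Context recording stage failure with a FAILED marker file."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
                logger.error("stage %s: FAILED (%s)", name, exc)
            else:
                logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the results bundle.

    Returns a dict of in-memory results keyed by stage (``dataset``,
    ``scores``, ``moments``, ``summaries``, ``anova``, ``selection``,
    ``decomposition``) alongside the files written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()

    results: dict = {}
    ground_truth = None

    with _stage(outdir, "load"):
        if config.scenario is not None:
            dataset, ground_truth = generate(config.scenario)
            write_dataset(dataset, outdir / "dataset")
            with open(outdir / "dataset" / "ground_truth.yaml", "w") as fh:
                yaml.safe_dump(ground_truth, fh, sort_keys=True)
        else:
            dataset = load_dataset(
                config.trait_path,
                config.composition_path,
                config.environment_path,
                trait_columns=config.trait_columns,
                abiotic_columns=config.abiotic_columns,
            )
    results["dataset"] = dataset
    results["ground_truth"] = ground_truth

    with _stage(outdir, "dominance"):
        dom_rows = [
            {
                "community_id": comm,
                "rank": i + 1,
                "species_id": sp,
            }
            for comm in sorted(dataset.composition.communities)
            for i, sp in enumerate(
                select_dominant_species(
                    dataset.composition, comm, config.dominance_threshold
                )
            )
        ]
        pd.DataFrame(dom_rows).to_csv(outdir / "dominant_species.csv", index=False)

    with _stage(outdir, "trait_space"):
        scores, fill_report = build_trait_space(
            dataset.traits,
            axis_names=config.axis_names,
            pin_positive=config.pin_positive,
        )
        scores.loadings.rename_axis("trait").to_csv(outdir / "loadings.csv")
        eig = pd.DataFrame(
            {
                "eigenvalue": scores.eigenvalues,
                "explained_fraction": scores.explained,
                "retained": [a in scores.retained for a in scores.axes],
            }
        )
        eig.rename_axis("axis").to_csv(outdir / "eigenvalues.csv")
        pd.concat([scores.meta, scores.scores], axis=1).rename_axis(
            "individual_id"
        ).to_csv(outdir / "scores.csv")
        fill_report.to_csv(outdir / "fill_report.csv", index=False)
    results["scores"] = scores

    axes = config.axes or scores.retained
    unknown = [a for a in axes if a not in scores.axes]
    if unknown:
        raise ConfigError(f"requested axes not present: {unknown}")

    with _stage(outdir, "moments"):
        moments = plot_moments(scores, dataset.composition, axes=axes)
        moments.to_csv(outdir / "plot_moments.csv", index=False)
        summaries = summarize_moments(moments, alpha=config.alpha)
        summaries.to_csv(outdir / "community_summary.csv", index=False)
    results["moments"] = moments
    results["summaries"] = summaries

    with _stage(outdir, "anova"):
        anova_rows = []
        for axis in axes:
            sub = moments[moments["axis"] == axis]
            for name in MOMENTS_ANALYZED:
                res = oneway_anova_tukey(
                    sub[name], sub["community_id"], alpha=config.alpha
                )
                for comm in res.group_means.index:
                    anova_rows.append(
                        {
                            "axis": axis,
                            "moment": name,
                            "community_id": comm,
                            "mean": res.group_means[comm],
                            "F": res.f_statistic,
                            "p_value": res.p_value,
                            "letters": res.letters[comm],
                        }
                    )
        anova_df = pd.DataFrame(anova_rows)
        anova_df.to_csv(outdir / "anova_tukey.csv", index=False)
    results["anova"] = anova_df

    with _stage(outdir, "drivers"):
        env = dataset.environment.data.set_index("plot_id")
        abiotic = list(dataset.environment.abiotic)
        selection: dict[tuple[str, str], object] = {}
        table_rows = []
        supported_rows = []
        for axis in axes:
            sub = moments[moments["axis"] == axis].set_index("plot_id")
            predictors = env.loc[sub.index, abiotic].copy()
            predictors["community"] = sub["community_id"]
            for name in MOMENTS_ANALYZED:
                sel = all_subsets_selection(
                    sub[name].to_numpy(),
                    predictors,
                    terms=abiotic + ["community"],
                    factor="community",
                    response=f"{axis}:{name}",
                )
                selection[(axis, name)] = sel
                row = {"axis": axis, "moment": name}
                for _, srow in sel.shares.iterrows():
                    if srow["term"] == "Residuals":
                        continue
                    row[srow["term"]] = f"{srow['sign']} ({srow['pct_of_total']:.1f})"
                row["adj_r2"] = round(sel.best.adj_r2, 3)
                table_rows.append(row)
                sup = sel.supported.copy()
                sup.insert(0, "moment", name)
                sup.insert(0, "axis", axis)
                supported_rows.append(sup)
        cols = ["axis", "moment", *abiotic, "community", "adj_r2"]
        driver_table = pd.DataFrame(table_rows).reindex(columns=cols)
        driver_table.to_csv(outdir / "driver_models.csv", index=False)
        pd.concat(supported_rows, ignore_index=True).to_csv(
            outdir / "supported_models.csv", index=False
        )
    results["selection"] = selection
    results["driver_table"] = driver_table

    with _stage(outdir, "decomposition"):
        decomp_tables = []
        decomp_results = {}
        for axis in axes[:2]:
            try:
                series = build_cwm_series(scores, dataset.composition, axis)
            except RegionalTraitError as err:
                logger.warning("decomposition skipped for %s: %s", axis, err)
                continue
            res_comm = decompose(series, predictor_set="community")
            decomp_results[(axis, "community")] = res_comm
            decomp_tables.append(res_comm.table())

            sel = selection.get((axis, "CWM"))
            abiotic_terms = sorted(
                t for t in (sel.best_terms if sel else []) if t != "community"
            )
            if abiotic_terms:
                env_pred = env.loc[series.data.index, abiotic_terms]
                res_env = decompose(
                    series,
                    predictors=env_pred,
                    terms=abiotic_terms,
                    predictor_set="abiotic:" + "+".join(abiotic_terms),
                )
                decomp_results[(axis, "abiotic")] = res_env
                decomp_tables.append(res_env.table())
            else:
                logger.info("no abiotic terms selected for %s CWM; abiotic partition skipped", axis)
        if decomp_tables:
            pd.concat(decomp_tables, ignore_index=True).to_csv(
                outdir / "decomposition.csv", index=False
            )
    results["decomposition"] = decomp_results

    with _stage(outdir, "manifest"):
        manifest = {
            "package": "traitmoments",
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "dominance_threshold": config.dominance_threshold,
            "axes_analyzed": list(axes),
            "settings": {
                "pca": "correlation-matrix PCA, Kaiser retention (eigenvalue > 1)",
                "moment_estimators": "population form, excess-kurtosis convention",
                "individual_weights": "species relative abundance / n scored individuals",
                "aicc": "Gaussian likelihood, k includes residual variance",
                "variance_shares": "Type-II SS as % of total SS",
                "decomposition": "specific/fixed CWM construction, signed covariation",
            },
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return results


def run_from_yaml(config_path: str | Path, **overrides) -> dict:
    config = RunConfig.from_yaml(config_path)
    for key, value in overrides.items():
        if value is not None:
            setattr(config, key, value)
    return run_pipeline(config)
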