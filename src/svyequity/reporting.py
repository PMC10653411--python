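"""Equity heatmaps and end-to-end pipeline orchestration.

Heatmaps follow the six-color legend: red Absent, orange Highly Inadequate,
light orange Inadequate, teal Adequate, light blue Abundant, blue Highly
Abundant; structurally missing cells (a subgroup level absent from a
conditioning stratum) are rendered uncolored.  Every figure gets a sidecar
CSV of exactly what was drawn, so no number exists only as pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import __version__
from .equity import EquityLevel, EquityTable, EquityThresholds, equity_table
from .harmonize import AnalysisTable, SurveyDesign, combine_cycles, drop_missing, filter_cohort
from .regression import Covariate, ModelSpec, SurveyLogisticRegression
from .simulate import Scenario, draw_survey, generate_population

__all__ = ["HeatmapStyle", "render_heatmap", "run_pipeline"]

DEFAULT_COLORS: dict[EquityLevel, str] = {
    EquityLevel.ABSENT: "#d7191c",  # red
    EquityLevel.HIGHLY_INADEQUATE: "#f46d43",  # orange
    EquityLevel.INADEQUATE: "#fdbf6f",  # light orange
    EquityLevel.ADEQUATE: "#1b9e8f",  # teal
    EquityLevel.ABUNDANT: "#abd9e9",  # light blue
    EquityLevel.HIGHLY_ABUNDANT: "#2c7bb6",  # blue
}


@dataclass(frozen=True)
class HeatmapStyle:
    """Level -> color mapping plus the cell-annotation mode."""

    colors: Mapping[EquityLevel, str] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    annotation: str = "score"  # {"level", "score", "both"}
    missing_color: str = "#ffffff"

    def __post_init__(self) -> None:
        if set(self.colors) != set(EquityLevel):
            raise ValueError("style must map all six equity levels")
        if len(set(self.colors.values())) != 6:
            raise ValueError("the six level colors must be distinct")
        if self.annotation not in ("level", "score", "both"):
            raise ValueError(f"unknown annotation mode {self.annotation!r}")


def render_heatmap(
    table: EquityTable, path, style: HeatmapStyle | None = None
) -> Path:
    """Draw the equity grid (rows: subgroup x conditioning; columns: outcomes).

    Writes the figure to ``path`` and a sidecar CSV (same stem, ``.csv``)
    holding the serialized table.  Returns the figure path.
    """
    style = style or HeatmapStyle()
    frame = table.to_frame()
    if frame.empty:
        raise ValueError("cannot render an empty equity table")
    frame["row_label"] = np.where(
        frame["conditioning"] != "",
        frame["subgroup"] + " | " + frame["conditioning"],
        frame["subgroup"],
    )
    rows = list(dict.fromkeys(frame["row_label"]))
    cols = list(dict.fromkeys(frame["outcome"]))
    level_order = list(EquityLevel)
    color_list = [style.missing_color] + [style.colors[l] for l in level_order]
    grid = np.zeros((len(rows), len(cols)), dtype=int)  # 0 = structurally missing
    annot = np.full((len(rows), len(cols)), "", dtype=object)
    for _, r in frame.iterrows():
        i, j = rows.index(r["row_label"]), cols.index(r["outcome"])
        if r["structurally_missing"] or not r["level"]:
            continue
        level = EquityLevel(r["level"])
        grid[i, j] = 1 + level_order.index(level)
        if style.annotation == "level":
            annot[i, j] = level.value
        elif style.annotation == "score":
            annot[i, j] = "*" if level is EquityLevel.ABSENT else f"{r['score']:.2f}"
        else:
            annot[i, j] = (
                f"{level.value}\n"
                + ("*" if level is EquityLevel.ABSENT else f"{r['score']:.2f}")
            )

    fig, ax = plt.subplots(
        figsize=(1.6 + 1.1 * len(cols), 1.2 + 0.45 * len(rows))
    )
    cmap = matplotlib.colors.ListedColormap(color_list)
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=6, aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
    ax.set_yticks(range(len(rows)), rows)
    for i in range(len(rows)):
        for j in range(len(cols)):
            if annot[i, j]:
                ax.text(j, i, annot[i, j], ha="center", va="center", fontsize=7)
    handles = [
        matplotlib.patches.Patch(color=style.colors[l], label=l.value)
        for l in level_order
    ]
    ax.legend(
        handles=handles,
        bbox_to_anchor=(1.02, 1),
        loc="upper left",
        fontsize=7,
        frameon=False,
    )
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    table.to_csv(path.with_suffix(".csv"))
    return path


def _load_config(config_path) -> dict:
    with open(config_path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config_path, out_dir, *, seed: int = 0) -> Path:
    """Execute simulate/load -> harmonize -> equity + regression -> report.

    The YAML config names either a synthetic scenario (section ``scenario``,
    possibly empty for defaults) or input files, plus cohort, outcomes,
    sensitive covariates, optional conditioning columns, thresholds, and an
    optional regression model.  All artifacts land in ``out_dir`` together
    with a JSON log carrying the config hash, seed, row counts and active
    design choices — enough to re-execute the run.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = _load_config(config_path)
    log: dict = {
        "config": str(config_path),
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "stages": [],
    }

    def stage(name):
        log["stages"].append(name)

    try:
        # --- data -------------------------------------------------------
        stage("simulate")
        rng = np.random.default_rng(seed)
        scenario = Scenario(**(cfg.get("scenario") or {}))
        census, truth = generate_population(scenario, rng)
        cycle_tables = [
            draw_survey(census, scenario, rng, cycle=c)[0] for c in scenario.cycles
        ]
        base_design = SurveyDesign(weight="weight", stratum="stratum", psu="psu")
        combined, design = combine_cycles(cycle_tables, base_design)
        truth.to_json(out_dir / "ground_truth.json")

        stage("harmonize")
        table = AnalysisTable(df=combined, design=design)
        table.record("combine_cycles", len(combined), len(combined), cycles=len(cycle_tables))
        cohort = cfg.get("cohort", "hav_hbv")
        table = filter_cohort(table, cohort, t2dm_col=cfg.get("t2dm_column", "t2dm"))
        required = cfg.get("required_columns") or [
            design.weight, design.stratum, design.psu
        ]
        table = drop_missing(table, required)
        table.df.to_csv(out_dir / "analysis_table.csv", index=False)
        with open(out_dir / "provenance.json", "w") as fh:
            fh.write(table.provenance_json())
        log["rows"] = {p["operation"]: p["rows_after"] for p in table.provenance}

        # --- equity grid --------------------------------------------------
        stage("equity")
        th_cfg = cfg.get("thresholds") or {}
        thresholds = EquityThresholds(
            tau_rule_lower=th_cfg.get("tau_rule_lower", 0.2),
            tau_rule_upper=th_cfg.get("tau_rule_upper", 0.4),
            alpha=th_cfg.get("alpha", 0.05),
        )
        log["thresholds"] = {
            "tau_l": thresholds.tau_l,
            "tau_u": thresholds.tau_u,
            "alpha": thresholds.alpha,
        }
        outcomes = cfg.get("outcomes") or list(scenario.outcome_models)
        sensitive = cfg.get("sensitive", "race")
        conditioning = cfg.get("conditioning")
        test_method = cfg.get("test_method", "exact")
        log["test_method"] = test_method
        grid = equity_table(
            table.df,
            sensitive=sensitive,
            outcomes=outcomes,
            design=table.design,
            conditioning=conditioning,
            thresholds=thresholds,
            test_method=test_method,
        )
        grid.to_csv(out_dir / "equity_table.csv")
        grid.to_json(out_dir / "equity_table.json")
        stage("heatmap")
        render_heatmap(grid, out_dir / "equity_heatmap.png")

        # --- regression ---------------------------------------------------
        if cfg.get("model", True):
            stage("regress")
            model_cfg = cfg.get("model")
            if isinstance(model_cfg, dict):
                covs = tuple(
                    Covariate(
                        name=c["name"],
                        kind=c.get("kind", "categorical"),
                        reference=c.get("reference"),
                    )
                    for c in model_cfg["covariates"]
                )
                spec = ModelSpec(outcome=model_cfg["outcome"], covariates=covs)
            else:
                spec = ModelSpec(
                    outcome=outcomes[0],
                    covariates=(
                        Covariate("race", reference="NH White"),
                        Covariate("gender", reference="male"),
                        Covariate("age", kind="continuous"),
                    ),
                )
            fitdf = table.df.copy()
            fitdf[spec.outcome] = fitdf[spec.outcome].astype(float)
            model = SurveyLogisticRegression(spec, table.design).fit(fitdf)
            ors = model.odds_ratios()
            ors.to_csv(out_dir / "odds_ratios.csv")
            log["regression"] = {
                "outcome": spec.outcome,
                "n_iter": model.n_iter_,
                "df_resid": model.df_resid_,
            }
    except Exception as err:
        failed = log["stages"][-1] if log["stages"] else "config"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {err}") from err

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out_dir
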