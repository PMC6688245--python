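"""End-to-end analysis: estimation → decomposition → detailed → inference.

``run_analysis`` reproduces the study design: one pooled analysis across all
survey years plus one per survey year, each running every requested weighting
scheme, the detailed decomposition of the explained component, and (when
``bootstrap_B > 0``) stratified-bootstrap inference.  Terms constant within
an analysis window (e.g. the survey-year effect inside a single survey) are
dropped automatically and logged.  Identical config + seed reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import SCHEMES, DecompositionResult, DetailedContributions, detailed_explained
from .descriptives import descriptives
from .design import OUTCOME_TERMS, build_design
from .estimation import ModelFit, SelectionFit, heckman_augment
from .inference import ComponentInference, bootstrap_components, decompose_table
from .io import read_survey_csv, write_survey_csv
from .popspec import PopulationSpec
from .simulate import default_ghana_spec, generate_population, generate_survey

__all__ = ["AnalysisConfig", "AnalysisReport", "PipelineError", "run_analysis", "window_exclusions"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one end-to-end analysis."""

    input_csv: str | None = None
    spec: PopulationSpec | str | None = None  # PopulationSpec, "ghana", or YAML path
    n: int = 13802
    seed: int = 0
    link: str = "logit"
    schemes: tuple[str, ...] = SCHEMES
    heckman: bool = False
    variables: tuple[str, ...] | None = None
    bootstrap_B: int = 0
    detailed_omega: float = 0.5
    omega_override: float | None = None
    per_year: bool = True
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        if d.get("variables") is not None:
            d["variables"] = tuple(d["variables"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.spec, PopulationSpec):
            d["spec"] = self.spec.to_dict()
        d["schemes"] = list(self.schemes)
        d["variables"] = list(self.variables) if self.variables else None
        return d

    def config_hash(self) -> str:
        # the output location does not affect results, so it is not hashed
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class WindowResult:
    window: str
    n_rows: int
    excluded_terms: tuple[str, ...]
    results: dict[str, DecompositionResult]
    inference: dict[str, ComponentInference]
    detailed: DetailedContributions
    fits: dict[str, ModelFit]


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    descriptives: pd.DataFrame
    windows: dict[str, WindowResult]
    selection_fit: SelectionFit | None
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "descriptives": {
                " | ".join(map(str, k)) if isinstance(k, tuple) else str(k): {
                    str(col): (None if pd.isna(v) else round(float(v), 6))
                    for col, v in row.items()
                }
                for k, row in self.descriptives.iterrows()
            },
            "windows": {},
        }
        for name, win in self.windows.items():
            w = {
                "n_rows": win.n_rows,
                "excluded_terms": list(win.excluded_terms),
                "schemes": {},
                "detailed": {
                    "explained": win.detailed.explained,
                    "omega": win.detailed.omega,
                    "contributions": dict(win.detailed.contributions),
                    "shares": dict(win.detailed.shares),
                    "residual": win.detailed.residual,
                },
                "fits": {g: f.to_json_dict() for g, f in win.fits.items()},
            }
            for scheme, res in win.results.items():
                block = {
                    "omega": res.omega,
                    "total": res.total,
                    "components": res.components(),
                    "percent_of_total": res.percent_of_total,
                }
                if scheme in win.inference:
                    inf = win.inference[scheme]
                    block["inference"] = {
                        "se": inf.se,
                        "ci_low": inf.ci_low,
                        "ci_high": inf.ci_high,
                        "significant_at_5pct": inf.significant_at_5pct,
                        "B": inf.n_replicates,
                        "n_failed": inf.n_failed,
                    }
                w["schemes"][scheme] = block
            out["windows"][name] = w
        if self.selection_fit is not None:
            out["selection"] = {
                "gamma": dict(self.selection_fit.gamma),
                "n_total": self.selection_fit.n_total,
                "n_selected": self.selection_fit.n_selected,
            }
        return out

    def overall_table(self) -> pd.DataFrame:
        """Long-format overall-decomposition table (one row per window ×
        scheme × component), coefficients to 3 decimals and percentages to 1."""
        rows = []
        for name, win in self.windows.items():
            for scheme, res in win.results.items():
                comps = dict(res.components())
                comps["total"] = res.total
                pct = dict(res.percent_of_total)
                pct["total"] = 100.0 if res.total != 0 else 0.0
                for comp, val in comps.items():
                    row = {
                        "window": name,
                        "scheme": scheme,
                        "weight": round(res.omega, 2),
                        "component": comp,
                        "coefficient": round(val, 3),
                        "percent": round(pct[comp], 1),
                    }
                    if scheme in win.inference:
                        inf = win.inference[scheme]
                        row.update(
                            se=round(inf.se[comp], 4),
                            ci_low=round(inf.ci_low[comp], 4),
                            ci_high=round(inf.ci_high[comp], 4),
                            sig=inf.significant_at_5pct[comp],
                        )
                    rows.append(row)
        return pd.DataFrame(rows)

    def detailed_table(self) -> pd.DataFrame:
        """Long-format detailed-decomposition table (window × variable group)."""
        rows = []
        for name, win in self.windows.items():
            det = win.detailed
            for group, contrib in det.contributions.items():
                rows.append(
                    {
                        "window": name,
                        "variable_group": group,
                        "contribution": round(contrib, 3),
                        "share_of_explained_pct": round(100.0 * det.shares.get(group, 0.0), 1),
                    }
                )
            rows.append(
                {
                    "window": name,
                    "variable_group": "explained_component",
                    "contribution": round(det.explained, 3),
                    "share_of_explained_pct": 100.0,
                }
            )
        return pd.DataFrame(rows)


def _load_table(config: AnalysisConfig):
    if config.input_csv is not None:
        table = read_survey_csv(config.input_csv)
        return table, None
    spec = config.spec
    if spec is None or (isinstance(spec, str) and spec == "ghana"):
        spec = default_ghana_spec(link=config.link)
    elif isinstance(spec, str):
        spec = PopulationSpec.from_yaml(spec)
    if config.heckman:
        return generate_population(spec, config.n, config.seed), spec
    return generate_survey(spec, config.n, config.seed), spec


#: Minimum occupied cell size for a dummy column within a group; sparser
#: cells are dropped from the window's design to avoid quasi-separation.
MIN_DUMMY_CELL = 5


def window_exclusions(win: pd.DataFrame, variables: list[str]) -> tuple[str, ...]:
    """Design columns unusable within the window.

    A column is excluded when, within either residence group, it is constant
    (e.g. the survey-year effect inside a single survey), or it is a dummy
    whose occupied cell has fewer than :data:`MIN_DUMMY_CELL` rows or a
    single-class outcome (which would quasi-separate the likelihood).
    Exclusions apply to both groups so the fits keep a common term namespace.
    """
    excluded: list[str] = []
    for group in ("urban", "rural"):
        sub = win.loc[win["residence"] == group]
        if len(sub) == 0:
            continue
        X, _ = build_design(sub, variables)
        y = sub["outcome"].to_numpy(dtype=float)
        for col in X.columns:
            if col == "intercept" or col in excluded:
                continue
            vals = X[col].to_numpy()
            if X[col].nunique() <= 1:
                excluded.append(col)
                continue
            if set(np.unique(vals)) <= {0.0, 1.0}:
                on = y[vals == 1.0]
                if len(on) < MIN_DUMMY_CELL or on.min() == on.max():
                    excluded.append(col)
    if excluded:
        logger.info("window exclusions (constant/sparse terms): %s", excluded)
    return tuple(excluded)


def _analyze_window(name: str, win: pd.DataFrame, config: AnalysisConfig, include_mills: bool) -> WindowResult:
    variables = list(config.variables if config.variables is not None else OUTCOME_TERMS)
    if include_mills and "mills_ratio" not in variables:
        variables.append("mills_ratio")
    excluded = window_exclusions(win, variables)
    results: dict[str, DecompositionResult] = {}
    inference: dict[str, ComponentInference] = {}
    fits: dict[str, ModelFit] = {}
    designs = None
    for scheme in config.schemes:
        res, fits, designs = decompose_table(
            win,
            scheme,
            link=config.link,
            variables=variables,
            exclude_terms=excluded,
            omega=config.omega_override,
        )
        results[scheme] = res
        if config.bootstrap_B > 0:
            inference[scheme] = bootstrap_components(
                win,
                scheme,
                link=config.link,
                variables=variables,
                exclude_terms=excluded,
                omega=config.omega_override,
                B=config.bootstrap_B,
                seed=config.seed,
            )
    detailed = detailed_explained(
        fits["urban"],
        fits["rural"],
        designs["urban"],
        designs["rural"],
        omega=config.detailed_omega,
    )
    return WindowResult(
        window=name,
        n_rows=len(win),
        excluded_terms=excluded,
        results=results,
        inference=inference,
        detailed=detailed,
        fits=fits,
    )


def run_analysis(config: AnalysisConfig | dict) -> AnalysisReport:
    """Execute the full pipeline for the pooled window and each survey year.

    With ``output_dir`` set, writes ``report.json``, ``overall.csv`` (scheme ×
    component), ``detailed.csv`` (variable-group contributions), the analyzed
    table (``survey.csv``) and a ``run.log``; on a stage failure the partial
    outputs are removed and a :class:`PipelineError` naming the stage is
    raised.
    """
    if isinstance(config, dict):
        config = AnalysisConfig.from_dict(config)
    written: list[str] = []
    try:
        stage = "load"
        table, spec = _load_table(config)
        selection_fit = None
        if config.heckman:
            stage = "selection"
            if "selected" not in table.columns:
                raise ValueError("Heckman correction requires a 'selected' column")
            aug = heckman_augment(table)
            analysis = aug.table.copy()
            analysis["outcome"] = analysis["outcome"].astype(int)
            selection_fit = aug.selection_fit
        else:
            analysis = table.loc[table["outcome"].notna()].copy()
            analysis["outcome"] = analysis["outcome"].astype(int)
        include_mills = config.heckman
        stage = "descriptives"
        desc = descriptives(analysis, by_year=config.per_year)
        stage = "windows"
        windows: dict[str, WindowResult] = {}
        windows["pooled"] = _analyze_window("pooled", analysis, config, include_mills)
        if config.per_year:
            for year in sorted(analysis["survey_year"].unique()):
                win = analysis.loc[analysis["survey_year"] == year]
                name = str(int(year))
                stage = f"window {name}"
                windows[name] = _analyze_window(name, win, config, include_mills)
        report = AnalysisReport(
            config=config,
            descriptives=desc,
            windows=windows,
            selection_fit=selection_fit,
            provenance={
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_rows": len(analysis),
                "n_urban": int((analysis["residence"] == "urban").sum()),
                "n_rural": int((analysis["residence"] == "rural").sum()),
                "n_dropped_rows": int(
                    sum(f.n_dropped_rows for w in windows.values() for f in w.fits.values())
                ),
            },
        )
        if config.output_dir:
            stage = "write"
            os.makedirs(config.output_dir, exist_ok=True)

            def _path(name: str) -> str:
                p = os.path.join(config.output_dir, name)
                written.append(p)
                return p

            with open(_path("report.json"), "w") as fh:
                json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
            report.overall_table().to_csv(_path("overall.csv"), index=False)
            report.detailed_table().to_csv(_path("detailed.csv"), index=False)
            write_survey_csv(analysis, _path("survey.csv"))
            with open(_path("run.log"), "w") as fh:
                fh.write(
                    "\n".join(
                        [
                            f"config_hash: {config.config_hash()}",
                            f"seed: {config.seed}",
                            f"rows: {len(analysis)}",
                            *(
                                f"window {w.window}: n={w.n_rows} excluded={list(w.excluded_terms)}"
                                for w in windows.values()
                            ),
                        ]
                    )
                    + "\n"
                )
        return report
    except Exception as exc:
        for p in written:
            try:
                os.remove(p)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
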