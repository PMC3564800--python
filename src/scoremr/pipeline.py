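"""End-to-end orchestration: simulate -> associate -> meta -> MR -> power.

Every number written to a report table is produced by calling the stage
operations (`scoremr.associate`, `scoremr.meta`, `scoremr.mr`) with the same
inputs; the pipeline adds only sequencing, file IO, seeding and logging.
A machine-readable results index (JSON with a content hash per table) makes
reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import (
    AssocEstimate,
    adjusted_percent_association,
    joint_percent_association,
    variance_explained,
)
from .errors import (
    InsufficientStudiesError,
    PipelineStageError,
    ScoremrError,
    ScoreUndefinedError,
)
from .meta import MetaEstimate, meta_regression, multivariate_pool, pool
from .model import CohortSpec, TrueModel
from .mr import (
    ci_to_se,
    instrument_f,
    iv_power,
    iv_ratio,
    percent_change_per_10pct,
    summary_score,
)
from .panel import make_snp_panel, read_panel, write_panel
from .scenario import dcardia21_specs, default_truth, small_specs
from .scores import allele_score, default_scores
from .simulate import read_cohort_table, simulate_collaboration, write_cohort_table

BASE_COVARIATES = ("age", "sex")
STAGES = (
    "simulate",
    "associate",
    "meta",
    "metareg",
    "bivariate",
    "mr",
    "summary",
    "power",
)

#: (exposure, outcome) pairs estimated per cohort; 25(OH)D outcomes are
#: additionally month-adjusted.
ASSOCIATION_GROUPS = (
    ("bmi_score", "bmi"),
    ("bmi_score", "vitd"),
    ("synthesis_score", "vitd"),
    ("metabolism_score", "vitd"),
    ("synthesis_score", "bmi"),
    ("metabolism_score", "bmi"),
)


def default_power_grid() -> list[dict]:
    """Power grid over the three instruments at the full and halved effect."""
    grid = []
    for effect in (0.02, 0.01):
        grid.append(dict(label="bmi_score", effect=effect, n=31120,
                         instrument_r2=0.0097, resid_sd=0.35))
        grid.append(dict(label="synthesis_score", effect=effect, n=36553,
                         instrument_r2=0.0064, resid_sd=0.16))
        grid.append(dict(label="metabolism_score", effect=effect, n=40367,
                         instrument_r2=0.0126, resid_sd=0.16))
    return grid


@dataclass
class RunConfig:
    """Configuration of a pipeline run (loadable from YAML)."""

    scenario: str | None = "dcardia21"
    cohort_files: list[str] | None = None
    panel_file: str | None = None
    seed: int = 20130205
    outdir: str = "scoremr_out"
    het_alpha: float = 0.05
    tau2_estimator: str = "dl"
    metareg_factors: dict = field(
        default_factory=lambda: {
            "continent": "europe",
            "assay_label": "ria",
            "age_group": "young",
            "mean_bmi_group": "lean",
        }
    )
    power_grid: list | None = None
    power_reps: int = 1000
    summary_stats_file: str | None = None
    n_cohorts: int = 5        # used by the "small" scenario only
    n_per_cohort: int = 4000  # used by the "small" scenario only

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ScoremrError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def attach_scores(table: pd.DataFrame, scores) -> tuple[pd.DataFrame, dict]:
    """Add one column per allele score; report which scores could be formed."""
    table = table.copy()
    available = {}
    for name, sdef in scores.items():
        try:
            table[name] = allele_score(table, sdef)
            available[name] = True
        except ScoreUndefinedError:
            available[name] = False
    return table, available


def _covariates_for(table: pd.DataFrame, outcome: str) -> tuple[str, ...]:
    covs = list(BASE_COVARIATES) + [
        c for c in table.columns if c.startswith("pc")
    ]
    if outcome in ("vitd", "ln_vitd"):
        covs.append("month")
    return tuple(covs)


def score_trait_associations(tables, panel, scores=None):
    """Per-cohort score-trait associations for every analysis group.

    Returns ``(groups, r2_rows)`` where ``groups`` maps
    (exposure, outcome) -> list of AssocEstimate and ``r2_rows`` holds the
    per-cohort marginal variance explained by each score in its own phenotype.
    """
    scores = scores if scores is not None else default_scores(panel)
    groups = {g: [] for g in ASSOCIATION_GROUPS}
    r2_rows = []
    own_trait = {
        "bmi_score": "bmi",
        "synthesis_score": "vitd",
        "metabolism_score": "vitd",
    }
    for table in tables:
        cohort = str(table["iid"].iloc[0]).rsplit("_", 1)[0]
        table, available = attach_scores(table, scores)
        for exposure, outcome in ASSOCIATION_GROUPS:
            if not available.get(exposure, False):
                continue
            est = adjusted_percent_association(
                table,
                outcome=outcome,
                exposure=exposure,
                covariates=_covariates_for(table, outcome),
                cohort=cohort,
            )
            groups[(exposure, outcome)].append(est)
        for name in scores:
            if available.get(name, False) and own_trait[name]:
                r2_rows.append(
                    dict(
                        cohort=cohort,
                        score=name,
                        phenotype=own_trait[name],
                        r2=variance_explained(table, table[name], own_trait[name]),
                        n=len(table),
                    )
                )
    return groups, r2_rows


def pooled_r2(r2_rows, score: str) -> tuple[float, int]:
    """Sample-size-weighted mean R^2 for one score with the total n behind it."""
    rows = [r for r in r2_rows if r["score"] == score]
    if not rows:
        raise ScoremrError(f"no R^2 rows for score {score!r}")
    n_total = sum(r["n"] for r in rows)
    r2 = sum(r["r2"] * r["n"] for r in rows) / n_total
    return float(r2), int(n_total)


def collaboration_mr(tables, panel, het_alpha: float = 0.05):
    """Both MR directions from a set of cohort tables.

    Returns a dict with pooled meta-estimates, IV ratios keyed by direction,
    and instrument F statistics.
    """
    groups, r2_rows = score_trait_associations(tables, panel)
    pooled = {
        key: pool(ests, alpha_het=het_alpha)
        for key, ests in groups.items()
        if len(ests) >= 2
    }
    results = {"pooled": pooled, "groups": groups, "r2_rows": r2_rows, "iv": {}}
    directions = {
        "bmi_to_vitd": (("bmi_score", "vitd"), ("bmi_score", "bmi")),
        "vitd_to_bmi_synthesis": (("synthesis_score", "bmi"),
                                  ("synthesis_score", "vitd")),
        "vitd_to_bmi_metabolism": (("metabolism_score", "bmi"),
                                   ("metabolism_score", "vitd")),
    }
    for direction, (num_key, den_key) in directions.items():
        if num_key in pooled and den_key in pooled:
            results["iv"][direction] = iv_ratio(pooled[num_key], pooled[den_key])
    results["f_stats"] = {}
    for score in ("bmi_score", "synthesis_score", "metabolism_score"):
        try:
            r2, n_total = pooled_r2(r2_rows, score)
        except ScoremrError:
            continue
        results["f_stats"][score] = dict(
            r2=r2, n=n_total, f=instrument_f(r2, n_total)
        )
    return results


def load_summary_table(path=None) -> pd.DataFrame:
    """Read a per-SNP summary-statistics TSV; CIs are converted to SEs.

    Columns: rsid, beta, then either se or (ci_low, ci_high), plus n, weight,
    and optionally score/gene.  The bundled default carries the published
    per-allele vitamin D SNP associations with BMI from a large adult-BMI
    GWAS consortium (per-allele change in kg/m^2).
    """
    if path is None:
        src = resources.files("scoremr").joinpath("data/giant_vitd_bmi.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if "se" not in df.columns:
        df["se"] = [ci_to_se(lo, hi) for lo, hi in zip(df["ci_low"], df["ci_high"])]
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return df


class Pipeline:
    """Stateful runner executing the stage DAG with file IO and logging."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.state: dict = {}
        self.io_events: list[tuple[str, str, str]] = []
        self.log_lines: list[str] = []
        self._stage = "init"
        self._seed_root = np.random.SeedSequence(config.seed)
        children = self._seed_root.spawn(3)
        self._panel_seed, self._cohort_seed, self._power_seed = children

    # -- IO bookkeeping ----------------------------------------------------
    def _log(self, message: str) -> None:
        self.log_lines.append(f"[{self._stage}] {message}")

    def _write_table(self, df: pd.DataFrame, relpath: str) -> Path:
        path = self.outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, na_rep="")
        self.io_events.append(("write", relpath, self._stage))
        return path

    def _read_table(self, relpath: str) -> pd.DataFrame:
        self.io_events.append(("read", relpath, self._stage))
        return pd.read_csv(self.outdir / relpath, sep="\t")

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        truth = default_truth()
        if cfg.scenario is not None:
            if cfg.scenario == "dcardia21":
                specs = dcardia21_specs(truth)
            elif cfg.scenario == "small":
                specs = small_specs(cfg.n_cohorts, cfg.n_per_cohort, truth)
            else:
                raise ScoremrError(f"unknown scenario {cfg.scenario!r}")
            panel = make_snp_panel(self._panel_seed)
            tables = simulate_collaboration(specs, panel, truth, self._cohort_seed)
            self._log(
                f"simulated {len(tables)} cohorts, "
                f"{sum(len(t) for t in tables)} subjects, seed={cfg.seed}"
            )
            write_panel(panel, self.outdir / "panel.tsv")
            self.io_events.append(("write", "panel.tsv", self._stage))
            with open(self.outdir / "truth.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(asdict(truth), fh, sort_keys=True)
            self.io_events.append(("write", "truth.yaml", self._stage))
            for spec, table in zip(specs, tables):
                rel = f"cohorts/{spec.name}.tsv"
                path = self.outdir / rel
                path.parent.mkdir(parents=True, exist_ok=True)
                write_cohort_table(table, path)
                self.io_events.append(("write", rel, self._stage))
            self.state.update(tables=tables, panel=panel, specs=specs, truth=truth)
        else:
            if not cfg.cohort_files or not cfg.panel_file:
                raise ScoremrError(
                    "without a scenario, cohort_files and panel_file are required"
                )
            panel = read_panel(cfg.panel_file)
            tables = [read_cohort_table(f) for f in cfg.cohort_files]
            self._log(f"loaded {len(tables)} cohort tables from files")
            self.state.update(tables=tables, panel=panel, specs=None, truth=None)

    def _require_tables(self):
        if "tables" not in self.state:
            panel = read_panel(self.outdir / "panel.tsv")
            self.io_events.append(("read", "panel.tsv", self._stage))
            tables = []
            for path in sorted((self.outdir / "cohorts").glob("*.tsv")):
                tables.append(self._read_table(f"cohorts/{path.name}"))
            if not tables:
                raise ScoremrError("no cohort tables in memory or on disk")
            self.state.update(tables=tables, panel=panel)

    def stage_associate(self) -> None:
        self._require_tables()
        tables, panel = self.state["tables"], self.state["panel"]
        obs = []
        for table in tables:
            cohort = str(table["iid"].iloc[0]).rsplit("_", 1)[0]
            obs.append(
                adjusted_percent_association(
                    table,
                    outcome="vitd",
                    exposure="bmi",
                    covariates=_covariates_for(table, "vitd"),
                    cohort=cohort,
                )
            )
        groups, r2_rows = score_trait_associations(tables, panel)
        for (exposure, outcome), ests in groups.items():
            skipped = len(tables) - len(ests)
            if skipped:
                self._log(
                    f"{exposure}->{outcome}: score unavailable in "
                    f"{skipped} cohort(s); skipped, not imputed"
                )
        self.state.update(observational=obs, groups=groups, r2_rows=r2_rows)
        rows = [
            dict(cohort=e.cohort, outcome=e.outcome, exposure=e.exposure,
                 beta=e.beta, se=e.se, n=e.n, covariates=";".join(e.covariates))
            for e in obs
        ] + [
            dict(cohort=e.cohort, outcome=e.outcome, exposure=e.exposure,
                 beta=e.beta, se=e.se, n=e.n, covariates=";".join(e.covariates))
            for ests in groups.values()
            for e in ests
        ]
        self._write_table(pd.DataFrame(rows), "associations.tsv")
        self._write_table(pd.DataFrame(r2_rows), "variance_explained.tsv")

    def _require_groups(self):
        if "groups" not in self.state:
            df = self._read_table("associations.tsv")
            obs, groups = [], {g: [] for g in ASSOCIATION_GROUPS}
            for row in df.itertuples():
                est = AssocEstimate(
                    beta=float(row.beta), se=float(row.se), n=int(row.n),
                    outcome=row.outcome, exposure=row.exposure,
                    covariates=tuple(str(row.covariates).split(";")),
                    cohort=row.cohort,
                )
                if row.exposure == "bmi":
                    obs.append(est)
                else:
                    groups[(row.exposure, row.outcome)].append(est)
            r2df = self._read_table("variance_explained.tsv")
            self.state.update(
                observational=obs,
                groups=groups,
                r2_rows=r2df.to_dict("records"),
            )

    def stage_meta(self) -> None:
        self._require_groups()
        alpha = self.config.het_alpha
        pooled: dict = {}
        rows = []

        def _add(label, ests):
            try:
                m = pool(ests, alpha_het=alpha,
                         tau2_estimator=self.config.tau2_estimator)
            except InsufficientStudiesError:
                raise PipelineStageError(
                    "meta", message=f"{label}: fewer than 2 studies to pool"
                )
            pooled[label] = m
            self._log(
                f"{label}: model={m.model} (Q={m.Q:.3f}, p_Q={m.p_Q:.4f}, "
                f"tau2={m.tau2:.5f})"
            )
            rows.append(dict(analysis=label, **asdict(m)))
            forest = pd.DataFrame(
                [
                    dict(study=e.cohort, beta=e.beta, se=e.se,
                         ci_low=e.ci_low, ci_high=e.ci_high, n=e.n)
                    for e in ests
                ]
                + [
                    dict(study="POOLED", beta=m.beta, se=m.se,
                         ci_low=m.ci_low, ci_high=m.ci_high,
                         n=sum(e.n for e in ests))
                ]
            )
            self._write_table(forest, f"forest/{label}.tsv")

        _add("observational_bmi_vitd", self.state["observational"])
        for (exposure, outcome), ests in self.state["groups"].items():
            _add(f"{exposure}__{outcome}", ests)
        self.state["pooled"] = pooled
        self._write_table(pd.DataFrame(rows), "meta.tsv")

    def _study_factor(self, ests, factor: str):
        """Per-study covariate values for meta-regression."""
        tables = {  # cohort name -> table, for data-derived factors
            str(t["iid"].iloc[0]).rsplit("_", 1)[0]: t
            for t in self.state.get("tables", [])
        }
        specs = {s.name: s for s in (self.state.get("specs") or [])}
        values = []
        for est in ests:
            spec = specs.get(est.cohort)
            table = tables.get(est.cohort)
            if factor in ("continent", "assay_label"):
                if spec is None:
                    return None
                values.append(getattr(spec, factor))
            elif factor == "age_group":
                if table is None:
                    return None
                mean_age = float(table["age"].mean())
                values.append(
                    "young" if mean_age <= 40
                    else ("middle" if mean_age <= 60 else "older")
                )
            elif factor == "mean_bmi_group":
                if table is None:
                    return None
                values.append(
                    "lean" if float(table["bmi"].mean()) <= 25 else "overweight"
                )
            elif factor == "prop_female":
                if table is None:
                    return None
                values.append(float((table["sex"] == "F").mean()))
            else:
                return None
        return values

    def stage_metareg(self) -> None:
        self._require_groups()
        rows = []
        for (exposure, outcome), ests in self.state["groups"].items():
            if len(ests) < 4:
                continue
            for factor, reference in self.config.metareg_factors.items():
                values = self._study_factor(ests, factor)
                if values is None:
                    self._log(
                        f"{exposure}->{outcome} by {factor}: factor values "
                        "unavailable; skipped"
                    )
                    continue
                try:
                    res = meta_regression(ests, values, reference=reference)
                except ScoremrError as exc:
                    self._log(f"{exposure}->{outcome} by {factor}: {exc}")
                    continue
                for term in res.terms:
                    rows.append(
                        dict(analysis=f"{exposure}__{outcome}", factor=factor,
                             contrast=term.name, slope=term.slope,
                             se=term.se, p=term.p, tau2=res.tau2, k=res.k)
                    )
        self._write_table(pd.DataFrame(rows), "meta_regression.tsv")
        self.state["metareg_rows"] = rows

    def stage_bivariate(self) -> None:
        self._require_tables()
        tables, panel = self.state["tables"], self.state["panel"]
        scores = default_scores(panel)
        bivs = []
        for table in tables:
            cohort = str(table["iid"].iloc[0]).rsplit("_", 1)[0]
            table, available = attach_scores(table, scores)
            if not (available["synthesis_score"] and available["metabolism_score"]):
                self._log(f"{cohort}: joint vitamin D model skipped "
                          "(score unavailable)")
                continue
            bivs.append(
                joint_percent_association(
                    table,
                    outcome="bmi",
                    exposures=("synthesis_score", "metabolism_score"),
                    covariates=_covariates_for(table, "bmi"),
                    cohort=cohort,
                )
            )
        (comp_syn, comp_met), joint_p = multivariate_pool(bivs)
        self._log(f"joint synthesis+metabolism on BMI: p={joint_p:.4f}")
        rows = [
            dict(component="synthesis_score", beta=comp_syn.beta,
                 se=comp_syn.se, ci_low=comp_syn.ci_low,
                 ci_high=comp_syn.ci_high, p=comp_syn.p, k=comp_syn.k,
                 joint_p=joint_p),
            dict(component="metabolism_score", beta=comp_met.beta,
                 se=comp_met.se, ci_low=comp_met.ci_low,
                 ci_high=comp_met.ci_high, p=comp_met.p, k=comp_met.k,
                 joint_p=joint_p),
        ]
        self._write_table(pd.DataFrame(rows), "bivariate.tsv")
        self.state["bivariate"] = (comp_syn, comp_met, joint_p)

    def stage_mr(self) -> None:
        self._require_groups()
        if "pooled" not in self.state:
            self.stage_meta()
        pooled = self.state["pooled"]
        r2_rows = self.state["r2_rows"]
        rows = []
        directions = {
            "bmi_to_vitd": ("bmi_score__vitd", "bmi_score__bmi", "bmi_score"),
            "vitd_to_bmi_synthesis": (
                "synthesis_score__bmi", "synthesis_score__vitd",
                "synthesis_score"),
            "vitd_to_bmi_metabolism": (
                "metabolism_score__bmi", "metabolism_score__vitd",
                "metabolism_score"),
        }
        iv_results = {}
        for direction, (num_key, den_key, score) in directions.items():
            num, den = pooled[num_key], pooled[den_key]
            iv = iv_ratio(num, den)
            iv_results[direction] = iv
            r2, n_total = pooled_r2(r2_rows, score)
            f_stat = instrument_f(r2, n_total)
            self._log(
                f"{direction}: ratio={iv.ratio:.4f} "
                f"({iv.ci_low:.4f}, {iv.ci_high:.4f}), F={f_stat:.1f}"
            )
            rows.append(
                dict(direction=direction, instrument=score, ratio=iv.ratio,
                     se=iv.se, ci_low=iv.ci_low, ci_high=iv.ci_high, p=iv.p,
                     f_stat=f_stat, r2=r2, n=n_total,
                     model=pooled[num_key].model)
            )
        scaled = percent_change_per_10pct(iv_results["bmi_to_vitd"])
        rows.append(
            dict(direction="bmi_to_vitd_per_10pct", instrument="bmi_score",
                 ratio=scaled.ratio, se=scaled.se, ci_low=scaled.ci_low,
                 ci_high=scaled.ci_high, p=scaled.p, f_stat=np.nan,
                 r2=np.nan, n=np.nan, model="")
        )
        self._write_table(pd.DataFrame(rows), "iv_results.tsv")
        self.state["iv"] = iv_results

    def stage_summary(self) -> None:
        df = load_summary_table(self.config.summary_stats_file)
        if self.config.summary_stats_file is not None:
            self.io_events.append(
                ("read", str(self.config.summary_stats_file), self._stage)
            )
        rows = []
        score_col = df["score"] if "score" in df.columns else ["score"] * len(df)
        for score_name in pd.unique(score_col):
            sub = df[np.asarray(score_col) == score_name]
            ests = [
                AssocEstimate(beta=float(r.beta), se=float(r.se), n=int(r.n),
                              outcome="bmi", exposure=r.rsid)
                for r in sub.itertuples()
            ]
            combined = summary_score(ests, weights=sub["weight"].tolist())
            rows.append(
                dict(score=score_name, beta=combined.beta, se=combined.se,
                     ci_low=combined.ci_low, ci_high=combined.ci_high,
                     n=combined.n, k_snps=len(ests))
            )
            self._log(
                f"summary score {score_name}: {combined.beta:.4f} "
                f"({combined.ci_low:.4f}, {combined.ci_high:.4f})"
            )
        self._write_table(pd.DataFrame(rows), "summary_scores.tsv")
        self.state["summary_scores"] = rows

    def stage_power(self) -> None:
        grid = (
            self.config.power_grid
            if self.config.power_grid is not None
            else default_power_grid()
        )
        rows = []
        seeds = self._power_seed.spawn(max(len(grid), 1))
        for point, seed in zip(grid, seeds):
            res = iv_power(
                effect=point["effect"],
                n=int(point["n"]),
                instrument_r2=point["instrument_r2"],
                resid_sd=point.get("resid_sd", 0.35),
                alpha=point.get("alpha", 0.05),
                reps=point.get("reps", self.config.power_reps),
                seed=seed,
            )
            rows.append(
                dict(label=point.get("label", ""), effect=res.effect, n=res.n,
                     instrument_r2=res.instrument_r2, alpha=res.alpha,
                     reps=res.reps, power=res.power, mc_se=res.mc_se)
            )
        self._write_table(pd.DataFrame(rows), "power.tsv")
        self.state["power"] = rows

    # -- driver ------------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(STAGES) if stages is None else list(stages)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ScoremrError(f"unknown stages: {sorted(unknown)}")
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in STAGES:
            if stage not in stages:
                continue
            self._stage = stage
            try:
                getattr(self, f"stage_{stage}")()
            except PipelineStageError:
                self._flush_log()
                raise
            except ScoremrError as exc:
                self._flush_log()
                raise PipelineStageError(stage, message=str(exc)) from exc
        self._stage = "index"
        index_path = self._write_index()
        self._flush_log()
        return {
            "index": index_path,
            "state": self.state,
            "io_events": self.io_events,
        }

    def _flush_log(self) -> None:
        with open(self.outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"scoremr {__version__}, master seed {self.config.seed}\n")
            for line in self.log_lines:
                fh.write(line + "\n")
            fh.write("# io events\n")
            for op, rel, stage in self.io_events:
                fh.write(f"{op}\t{rel}\t{stage}\n")

    def _write_index(self) -> Path:
        tables = {}
        written = [rel for op, rel, _ in self.io_events if op == "write"]
        for rel in sorted(set(written)):
            path = self.outdir / rel
            if not path.exists():
                continue
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            tables[rel] = {"path": rel, "sha256": digest}
        index = {
            "package": "scoremr",
            "version": __version__,
            "seed": self.config.seed,
            "tables": tables,
        }
        path = self.outdir / "results_index.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(index, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the configured stages; see :class:`Pipeline`."""
    return Pipeline(config).run(stages=stages)
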