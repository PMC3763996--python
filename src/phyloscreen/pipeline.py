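"""CSV formats, pipeline configuration and end-to-end orchestration.

The exchange format is a tidy long table, one row per sample x assay,
with columns ``sample_id, phylum, genus, bioregion, category, assay_id``
and either a pre-normalized ``response`` (percent of control) or raw
``raw``/``control`` readings that are normalized on read.  All outputs
are UTF-8 CSVs with a header row; a run directory collects thresholds,
calls, cell summaries, per-category model outputs, a manifest and a
machine-readable run report.  Identical configuration and seed
reproduce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import CellMeansModel, HierarchicalActivityModel
from .errors import SchemaError, StageError
from .lineage import default_scheme, load_scheme, rekey_records
from .sampler import MCMCConfig
from .scoring import call_activity, compute_thresholds, summarize_cells
from .synthetic import NegBinCellCounts, SimConfig, generate_screen

__all__ = [
    "REQUIRED_COLUMNS",
    "read_records",
    "write_records",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
]

logger = logging.getLogger("phyloscreen")

REQUIRED_COLUMNS = ["sample_id", "phylum", "bioregion", "category", "assay_id"]


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a screening record CSV, normalizing raw/control rows if present.

    Rows carrying both ``response`` and ``raw``/``control`` keep the
    pre-normalized ``response`` (with a warning).  Duplicate
    (sample_id, assay_id) rows and non-numeric responses are rejected
    with the offending line numbers.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "phylum": str, "genus": str,
                                  "bioregion": str, "category": str,
                                  "assay_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    has_response = "response" in df.columns
    has_raw = "raw" in df.columns and "control" in df.columns
    if not has_response and not has_raw:
        raise SchemaError(
            f"{path}: need a 'response' column or both 'raw' and 'control'"
        )
    if has_response:
        resp = pd.to_numeric(df["response"], errors="coerce")
        if has_raw:
            warnings.warn(
                f"{path}: both 'response' and raw/control present; "
                "'response' takes precedence",
                stacklevel=2,
            )
    if has_raw and not has_response:
        from .scoring import normalize_to_control

        raw = pd.to_numeric(df["raw"], errors="coerce")
        ctl = pd.to_numeric(df["control"], errors="coerce")
        bad = raw.isna() | ctl.isna()
        if bad.any():
            lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()[:10]
            raise SchemaError(f"{path}: non-numeric raw/control at line(s) {lines}")
        resp = pd.Series(normalize_to_control(raw.to_numpy(), ctl.to_numpy()))
    bad = resp.isna()
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()[:10]
        raise SchemaError(f"{path}: non-numeric response at line(s) {lines}")
    dup = df.duplicated(subset=["sample_id", "assay_id"], keep=False)
    if dup.any():
        lines = (np.nonzero(dup.to_numpy())[0] + 2).tolist()[:10]
        raise SchemaError(
            f"{path}: duplicate (sample_id, assay_id) rows at line(s) {lines}"
        )
    out = df[REQUIRED_COLUMNS[:2]].copy()
    out["genus"] = df["genus"] if "genus" in df.columns else pd.NA
    for c in ("bioregion", "category", "assay_id"):
        out[c] = df[c]
    out["response"] = resp.astype(float).to_numpy()
    return out[["sample_id", "phylum", "genus", "bioregion", "category",
                "assay_id", "response"]]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def _mcmc_from_dict(d: dict, seed: int) -> MCMCConfig:
    return MCMCConfig(
        n_chains=int(d.get("n_chains", 3)),
        n_iter=int(d.get("n_iter", 20_000)),
        burn_in=int(d.get("burn_in", 5_000)),
        thin=int(d.get("thin", 1)),
        seed=seed,
        target_accept=float(d.get("target_accept", 0.44)),
    )


def _sim_from_dict(d: dict, seed: int) -> SimConfig:
    kw = dict(d)
    kw.setdefault("seed", seed)
    if "cell_n" in kw and isinstance(kw["cell_n"], dict):
        spec = kw["cell_n"]
        kw["cell_n"] = NegBinCellCounts(
            mean=float(spec.get("mean", 16.0)), shape=float(spec.get("shape", 2.0))
        )
    for key in ("phyla", "bioregions"):
        if key in kw:
            kw[key] = tuple(str(v) for v in kw[key])
    if "categories" in kw:
        kw["categories"] = {k: tuple(v) for k, v in kw["categories"].items()}
    return SimConfig(**kw)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, loadable from YAML."""

    outdir: Path
    seed: int = 0
    records_csv: str | None = None
    simulate: SimConfig | None = None
    pooling: str = "pooled"
    rule: str = "any"
    levels: tuple[str, ...] = ("phylum",)
    lineage_scheme_path: str | None = None
    tiers: tuple[str, ...] = ("hierarchical", "main_effects")
    factors: tuple[str, ...] = ("taxon", "bioregion")
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    save_draws: bool = True
    draws_export_thin: int = 1
    allow_unconverged: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.records_csv is None and self.simulate is None:
            raise SchemaError("config needs an input: records_csv or simulate")
        if self.records_csv is not None and not Path(self.records_csv).exists():
            raise SchemaError(f"records_csv does not exist: {self.records_csv}")
        if self.lineage_scheme_path is not None and not Path(
            self.lineage_scheme_path
        ).exists():
            raise SchemaError(
                f"lineage scheme does not exist: {self.lineage_scheme_path}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(overrides.get("seed", raw.get("seed", 0)))
        inp = raw.get("input", {})
        sim = inp.get("simulate")
        kw: dict = {
            "outdir": overrides.get("outdir", raw.get("outdir", "phyloscreen_run")),
            "seed": seed,
            "records_csv": inp.get("records_csv"),
            "simulate": _sim_from_dict(sim, seed) if sim is not None else None,
        }
        scoring = raw.get("scoring", {})
        kw["pooling"] = scoring.get("pooling", "pooled")
        kw["rule"] = scoring.get("rule", "any")
        agg = raw.get("aggregation", {})
        kw["levels"] = tuple(agg.get("levels", ["phylum"]))
        kw["lineage_scheme_path"] = agg.get("lineage_scheme")
        models = raw.get("models", {})
        kw["tiers"] = tuple(models.get("tiers", ["hierarchical", "main_effects"]))
        kw["factors"] = tuple(models.get("factors", ["taxon", "bioregion"]))
        kw["mcmc"] = _mcmc_from_dict(raw.get("mcmc", {}), seed)
        out = raw.get("output", {})
        kw["save_draws"] = bool(out.get("save_draws", True))
        kw["draws_export_thin"] = int(out.get("draws_export_thin", 1))
        kw["allow_unconverged"] = bool(out.get("allow_unconverged", True))
        return cls(**kw)

    def echo(self) -> dict:
        d: dict = {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "records_csv": self.records_csv,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "pooling": self.pooling,
            "rule": self.rule,
            "levels": list(self.levels),
            "lineage_scheme_path": self.lineage_scheme_path,
            "tiers": list(self.tiers),
            "factors": list(self.factors),
            "mcmc": dataclasses.asdict(self.mcmc),
            "save_draws": self.save_draws,
            "draws_export_thin": self.draws_export_thin,
            "allow_unconverged": self.allow_unconverged,
        }
        return d


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    config: dict
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def add_warning(self, stage: str, message: str, count: int) -> None:
        self.warnings.append({"stage": stage, "message": message, "count": count})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _write_csv(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    report.outputs.append(str(path))


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:  # tag errors with the failing stage
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("input")
def _acquire_records(config: PipelineConfig, report: RunReport):
    if config.records_csv is not None:
        records = read_records(config.records_csv)
        truth = None
    else:
        records, truth = generate_screen(config.simulate)
        _write_csv(records, config.outdir / "records.csv", report)
        _write_csv(
            truth.cell_probability, config.outdir / "ground_truth_cells.csv", report
        )
        _write_csv(
            truth.per_sample_latent,
            config.outdir / "ground_truth_samples.csv",
            report,
        )
    report.row_counts["records"] = len(records)
    return records, truth


@_stage("scoring")
def _score(config: PipelineConfig, records: pd.DataFrame, report: RunReport):
    thresholds = compute_thresholds(records, config.pooling)
    zero_var = int((thresholds["sd"] == 0).sum())
    if zero_var:
        report.add_warning("scoring", "zero-variance thresholds", zero_var)
    calls = call_activity(records, thresholds, config.rule)
    n_partial = calls.attrs.get("n_partial_samples", 0)
    if n_partial:
        report.add_warning("scoring", "partially-measured samples", n_partial)
    _write_csv(thresholds, config.outdir / "thresholds.csv", report)
    _write_csv(calls, config.outdir / "calls.csv", report)
    report.row_counts["thresholds"] = len(thresholds)
    report.row_counts["calls"] = len(calls)
    cells_by_level = {}
    for level in config.levels:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # counted below
            keyed, rk = rekey_records(calls, level)
        if rk["n_dropped_missing_genus"]:
            report.add_warning(
                "aggregation", "records dropped for missing genus",
                rk["n_dropped_missing_genus"],
            )
        cells = summarize_cells(keyed, level)
        cells_by_level[level] = (keyed, cells)
        _write_csv(cells, config.outdir / f"cells_{level}.csv", report)
        report.row_counts[f"cells_{level}"] = len(cells)
    return calls, cells_by_level


def _fit_outputs(config, est, outdir: Path, report: RunReport,
                 factors: tuple[str, ...], scheme, phylum_of=None) -> None:
    diag = est.diagnostics_
    _write_csv(diag.to_frame(), outdir / "diagnostics.csv", report)
    report.diagnostics[str(outdir.relative_to(config.outdir))] = {
        "passed": diag.passed,
        "reasons": diag.reasons,
        "max_lag1_autocorr": diag.max_lag1,
        "max_rhat": diag.max_rhat,
        "min_ess": diag.min_ess,
        "thin_applied": diag.thin_applied,
    }
    for factor in factors:
        mm = est.marginal_means(
            factor, allow_unconverged=config.allow_unconverged
        )
        _write_csv(mm, outdir / f"marginal_means_{factor}.csv", report)
    if isinstance(est, HierarchicalActivityModel):
        lm = est.lineage_means(scheme=scheme, phylum_of=phylum_of)
        _write_csv(lm, outdir / "lineage_means.csv", report)
    if config.save_draws:
        export = est.draws_.thin_by(max(1, config.draws_export_thin)) \
            if config.draws_export_thin > 1 else est.draws_
        _write_csv(export.to_frame(), outdir / "draws.csv", report)


@_stage("models")
def _fit_models(config: PipelineConfig, calls, cells_by_level, report: RunReport):
    scheme = (
        load_scheme(config.lineage_scheme_path)
        if config.lineage_scheme_path
        else default_scheme()
    )
    categories = sorted(calls["category"].unique())
    for category in categories:
        for level in config.levels:
            keyed, cells = cells_by_level[level]
            cat_calls = keyed.loc[keyed["category"] == category]
            cat_cells = cells.loc[cells["category"] == category]
            base = config.outdir / category / level
            phylum_of = None
            if level == "genus":
                phylum_of = dict(
                    cat_calls.drop_duplicates("taxon")[["taxon", "phylum"]]
                    .itertuples(index=False)
                )
            if "hierarchical" in config.tiers:
                est = HierarchicalActivityModel(
                    n_chains=config.mcmc.n_chains,
                    n_iter=config.mcmc.n_iter,
                    burn_in=config.mcmc.burn_in,
                    thin=config.mcmc.thin,
                    target_accept=config.mcmc.target_accept,
                    random_state=config.mcmc.seed,
                ).fit(cat_calls)
                _fit_outputs(
                    config, est, base / "hierarchical", report,
                    ("taxon", "bioregion"), scheme, phylum_of,
                )
            if "main_effects" in config.tiers:
                for factor in config.factors:
                    est = CellMeansModel(
                        factor=factor,
                        n_chains=config.mcmc.n_chains,
                        n_iter=config.mcmc.n_iter,
                        burn_in=config.mcmc.burn_in,
                        thin=config.mcmc.thin,
                        target_accept=config.mcmc.target_accept,
                        random_state=config.mcmc.seed,
                    ).fit(cat_cells)
                    _fit_outputs(
                        config, est, base / f"main_effects_{factor}", report,
                        (factor,), scheme,
                    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run scoring and modelling end to end, writing a run directory.

    Each bioassay category is compiled and analysed separately; every
    stage error aborts the run with a stage-tagged message.
    """
    report = RunReport(config=config.echo())
    report.started = datetime.now(timezone.utc).isoformat()
    config.outdir.mkdir(parents=True, exist_ok=True)
    records, _truth = _acquire_records(config, report)
    logger.info("input stage: %d records", len(records))
    calls, cells_by_level = _score(config, records, report)
    logger.info("scoring stage: %d calls", len(calls))
    if config.tiers:
        _fit_models(config, calls, cells_by_level, report)
        logger.info("model stage: %d fits", len(report.diagnostics))
    report.finished = datetime.now(timezone.utc).isoformat()
    with open(config.outdir / "run_config.json", "w") as fh:
        json.dump(config.echo(), fh, indent=2, default=str)
    report.outputs.append(str(config.outdir / "run_config.json"))
    manifest = sorted(report.outputs)
    with open(config.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report.to_json(config.outdir / "run_report.json")
    return report
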