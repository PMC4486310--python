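"""End-to-end run: preprocess -> DE -> (prediction || correlation) -> merge -> network.

``RunConfig`` carries every stage threshold with the protocol defaults
(gene significance |logFC| >= 0.585 at adjusted p <= 0.05; miR significance
|logFC| >= 0.485 at raw p <= 0.01; correlation |r| >= 0.7 at p <= 0.05 with
no multiplicity correction; prediction union over >= 1 database).  Every
intermediate is persisted as TSV in the output directory so each stage can
be re-run or inspected independently, and the final counts are written both
as a machine-readable table and a human-readable text summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import correlate as corr_mod
from . import de as de_mod
from . import integrate as int_mod
from . import io as io_mod
from . import network as net_mod
from . import predict as pred_mod
from .errors import ConfigError
from .io import DAYS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of a full pipeline run (defaults = protocol values)."""

    gene_matrix: str = ""
    mir_matrix: str = ""
    design: str = ""
    probe_map: str | None = None
    prediction_tables: dict[str, str] = field(default_factory=dict)  # name -> path
    outdir: str = "mirmint_out"

    gene_raw_threshold: float = 100.0
    gene_low_frac: float = 0.75
    apply_iqr: bool = True
    mir_raw_threshold: float = 100.0
    mir_apply_iqr: bool = False

    gene_lfc: float = 0.585
    gene_p: float = 0.05
    gene_use_adjusted: bool = True
    mir_lfc: float = 0.485
    mir_p: float = 0.01
    mir_use_adjusted: bool = False

    min_databases: int = 1
    r_min: float = 0.7
    p_max: float = 0.05
    sample_scope: str = "per_day"
    p_method: str = "t"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for label, p in (
            ("gene_matrix", self.gene_matrix),
            ("mir_matrix", self.mir_matrix),
            ("design", self.design),
        ):
            if not p or not Path(p).exists():
                raise ConfigError(f"{label} path not resolvable: {p!r}")
        for name, p in self.prediction_tables.items():
            if not Path(p).exists():
                raise ConfigError(f"prediction table {name!r} not resolvable: {p!r}")
        if self.probe_map and not Path(self.probe_map).exists():
            raise ConfigError(f"probe_map path not resolvable: {self.probe_map!r}")


@dataclass
class RunResult:
    outdir: Path
    summary: int_mod.PipelineSummary
    couples: pd.DataFrame  # collapsed, gene level, long (per day)
    couples_wide: pd.DataFrame
    paths: dict[str, Path]


@dataclass
class StageOutputs:
    """In-memory results of every stage (what ``run_pipeline`` persists)."""

    genes_filtered: io_mod.ExpressionMatrix
    mirs_filtered: io_mod.ExpressionMatrix
    gene_results: pd.DataFrame
    gene_significant: pd.DataFrame
    mir_results: pd.DataFrame
    mir_significant: pd.DataFrame
    prediction_union: pred_mod.PredictionSet
    preds_by_day: dict[int, pred_mod.PredictionSet]
    corr_records: pd.DataFrame
    corr_significant: pd.DataFrame
    couples_probe_level: pd.DataFrame
    couples: pd.DataFrame
    couples_wide: pd.DataFrame
    summary: int_mod.PipelineSummary

    def couples_by_day(self) -> dict[int, list[tuple[str, str]]]:
        return {
            d: [
                (row.mir, row.gene)
                for row in self.couples.loc[self.couples["day"] == d].itertuples()
            ]
            for d in DAYS
        }


def run_stages(
    genes: io_mod.ExpressionMatrix,
    mirs: io_mod.ExpressionMatrix,
    design: io_mod.SampleDesign,
    prediction_sets: list[pred_mod.PredictionSet],
    config: RunConfig | None = None,
) -> StageOutputs:
    """Run preprocessing, DE, prediction, correlation and integration in memory."""
    cfg = config or RunConfig()

    genes_f = io_mod.filter_low_expression(genes, cfg.gene_raw_threshold, cfg.gene_low_frac)
    if cfg.apply_iqr:
        genes_f = io_mod.filter_low_iqr(genes_f)
    mirs_f = io_mod.filter_low_expression(mirs, cfg.mir_raw_threshold, cfg.gene_low_frac)
    if cfg.mir_apply_iqr:
        mirs_f = io_mod.filter_low_iqr(mirs_f)

    gene_res = de_mod.fit_moderated_t(genes_f, design)
    mir_res = de_mod.fit_moderated_t(mirs_f, design)
    gene_sig = de_mod.call_significant(gene_res, cfg.gene_lfc, cfg.gene_p, cfg.gene_use_adjusted)
    mir_sig = de_mod.call_significant(mir_res, cfg.mir_lfc, cfg.mir_p, cfg.mir_use_adjusted)

    de_probes = {d: set(gene_sig.loc[gene_sig["day"] == d, "feature"]) for d in DAYS}
    de_gene_syms = {d: {genes_f.gene_of(p) for p in de_probes[d]} for d in DAYS}
    de_mir_ids = {d: set(mir_sig.loc[mir_sig["day"] == d, "feature"]) for d in DAYS}

    if prediction_sets:
        union = pred_mod.union_predictions(prediction_sets, cfg.min_databases)
    else:
        union = pred_mod.PredictionSet()
    preds_by_day = pred_mod.restrict_to_de(union, de_gene_syms, de_mir_ids)

    rec_frames = [
        corr_mod.correlate_day(
            mirs_f, genes_f, design, d, sorted(de_mir_ids[d]), sorted(de_probes[d]),
            sample_scope=cfg.sample_scope, p_method=cfg.p_method,
        )
        for d in DAYS
    ]
    non_empty = [f for f in rec_frames if not f.empty]
    corr_records = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=corr_mod.RECORD_COLUMNS)
    )
    corr_sig = corr_mod.filter_correlations(corr_records, cfg.r_min, cfg.p_max)

    intersected = int_mod.intersect_couples(corr_sig, preds_by_day)
    collapsed = int_mod.collapse_probes(intersected)
    wide = int_mod.couples_wide(collapsed)
    summary = int_mod.summarize_pipeline(
        gene_sig, mir_sig, corr_records, corr_sig, preds_by_day, collapsed,
        probe_to_gene=genes.probe_to_gene,
    )
    return StageOutputs(
        genes_filtered=genes_f,
        mirs_filtered=mirs_f,
        gene_results=gene_res,
        gene_significant=gene_sig,
        mir_results=mir_res,
        mir_significant=mir_sig,
        prediction_union=union,
        preds_by_day=preds_by_day,
        corr_records=corr_records,
        corr_significant=corr_sig,
        couples_probe_level=intersected,
        couples=collapsed,
        couples_wide=wide,
        summary=summary,
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order and persist every intermediate."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    design = io_mod.read_design(config.design)
    probe_to_gene = read_probe_map(config.probe_map) if config.probe_map else None
    genes = io_mod.read_matrix(config.gene_matrix, design, "gene", probe_to_gene)
    mirs = io_mod.read_matrix(config.mir_matrix, design, "mir")
    logger.info("loaded %d probes, %d miRs, %d samples", len(genes.data), len(mirs.data), len(design.samples))

    sets = [
        pred_mod.load_prediction_table(p, name)
        for name, p in sorted(config.prediction_tables.items())
    ]
    out = run_stages(genes, mirs, design, sets, config)
    logger.info(
        "filters kept %d/%d probes, %d/%d miRs; DE probes per day %s; DE miRs per day %s",
        len(out.genes_filtered.data), len(genes.data),
        len(out.mirs_filtered.data), len(mirs.data),
        out.summary.de_probes, out.summary.de_mirs,
    )

    paths["filtered_genes"] = outdir / "filtered_genes.tsv"
    io_mod.write_matrix(out.genes_filtered, paths["filtered_genes"])
    paths["filtered_mirs"] = outdir / "filtered_mirs.tsv"
    io_mod.write_matrix(out.mirs_filtered, paths["filtered_mirs"])
    for res, sig, name in (
        (out.gene_results, out.gene_significant, "de_genes"),
        (out.mir_results, out.mir_significant, "de_mirs"),
    ):
        res = res.copy()
        res["significant"] = res.index.isin(sig.index)
        paths[name] = _write(res, outdir / f"{name}.tsv")

    paths["predictions_union"] = outdir / "predictions_union.tsv"
    pred_mod.write_prediction_set(out.prediction_union, paths["predictions_union"])
    for d in DAYS:
        paths[f"predictions_day{d}"] = outdir / f"predictions_day{d}.tsv"
        pred_mod.write_prediction_set(out.preds_by_day[d], paths[f"predictions_day{d}"])
    de_mirs_all = set(out.mir_significant["feature"])
    no_coverage = pred_mod.uncovered_mirs(out.prediction_union, de_mirs_all)
    if no_coverage:
        logger.info("DE miRs with no prediction coverage: %s", no_coverage)

    annotated = out.corr_records.copy()
    annotated["significant"] = annotated.index.isin(out.corr_significant.index)
    paths["correlations"] = _write(annotated, outdir / "correlations.tsv")
    paths["correlations_significant"] = _write(
        out.corr_significant, outdir / "correlations_significant.tsv"
    )
    paths["couples_probe_level"] = _write(
        out.couples_probe_level, outdir / "couples_probe_level.tsv"
    )
    paths["couples"] = _write(out.couples, outdir / "couples.tsv")
    paths["couples_wide"] = _write(out.couples_wide, outdir / "couples_wide.tsv")

    for d in DAYS:
        net = net_mod.build_network(out.couples, day=d)
        paths[f"network_day{d}_sif"] = net_mod.export_network(net, outdir / f"network_day{d}.sif", "sif")
        paths[f"network_day{d}_graphml"] = net_mod.export_network(net, outdir / f"network_day{d}.graphml", "graphml")

    paths["summary"] = _write(out.summary.to_frame(), outdir / "summary.tsv")
    paths["summary_txt"] = outdir / "summary.txt"
    paths["summary_txt"].write_text(out.summary.describe() + "\n")
    logger.info("integrated couples (union over days): %d", out.summary.couples_total)

    used = dataclasses.replace(config, outdir=str(outdir))
    used.to_yaml(outdir / "config_used.yaml")

    return RunResult(
        outdir=outdir,
        summary=out.summary,
        couples=out.couples,
        couples_wide=out.couples_wide,
        paths=paths,
    )


def report_from_rundir(outdir: str | Path) -> int_mod.PipelineSummary:
    """Recompute the summary from a run directory's persisted intermediates."""
    outdir = Path(outdir)
    needed = ["de_genes.tsv", "de_mirs.tsv", "correlations.tsv", "couples.tsv"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise ConfigError(f"run directory {outdir} lacks: {missing}")
    gene_res = pd.read_csv(outdir / "de_genes.tsv", sep="\t")
    mir_res = pd.read_csv(outdir / "de_mirs.tsv", sep="\t")
    corr = pd.read_csv(outdir / "correlations.tsv", sep="\t")
    collapsed = pd.read_csv(outdir / "couples.tsv", sep="\t")
    preds_by_day = {}
    for d in DAYS:
        p = outdir / f"predictions_day{d}.tsv"
        pset = pred_mod.PredictionSet()
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            for _, row in df.iterrows():
                for db in str(row.get("databases", "db")).split(";"):
                    pset.add(row["mir"], row["gene"], db)
        preds_by_day[d] = pset
    probe_map = None
    cfg = outdir / "config_used.yaml"
    if cfg.exists():
        pm = RunConfig.from_yaml(cfg).probe_map
        if pm and Path(pm).exists():
            probe_map = read_probe_map(pm)
    return int_mod.summarize_pipeline(
        gene_res.loc[gene_res["significant"]] if "significant" in gene_res else gene_res,
        mir_res.loc[mir_res["significant"]] if "significant" in mir_res else mir_res,
        corr,
        corr.loc[corr["significant"]] if "significant" in corr else corr,
        preds_by_day,
        collapsed,
        probe_to_gene=probe_map,
    )
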