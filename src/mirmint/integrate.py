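"""Intersection of correlation and prediction evidence, and the run summary.

A couple (miR, gene) is *integrated* when, on at least one day, one of the
gene's probes is significantly correlated with the miR AND the couple is
listed by the prediction union.  Probe-level records are collapsed to gene
level per (miR, gene, day) by keeping the most correlated probe (largest
|r|; ties broken by the lexicographically smallest probe ID).  The per-day
view is pivoted into a wide couples table with one column of r per day
(missing = not significant that day), which is also the schema of the
bundled reference couples table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IncompleteSummaryError
from .io import DAYS
from .predict import PredictionSet, normalize_couple

logger = logging.getLogger(__name__)

R_COLUMNS = {0: "r_day0", 7: "r_day7", 14: "r_day14"}


def intersect_couples(
    corr_sig: pd.DataFrame, preds_by_day: Mapping[int, PredictionSet]
) -> pd.DataFrame:
    """Significant probe-level correlations whose (miR, gene) is predicted.

    ``corr_sig`` may span several days; each row is matched against the
    prediction set restricted to its own day.  Support columns
    ``n_databases`` / ``databases`` are attached to the surviving rows.
    """
    if corr_sig.empty:
        out = corr_sig.copy()
        out["n_databases"] = pd.Series(dtype=int)
        out["databases"] = pd.Series(dtype=str)
        return out
    keep, ndb, dbs = [], [], []
    for _, row in corr_sig.iterrows():
        preds = preds_by_day.get(int(row["day"]))
        if preds is None:
            keep.append(False)
            continue
        key = normalize_couple(row["mir"], row["gene"])
        if key in preds.couples:
            keep.append(True)
            sources = preds.sources[key]
            ndb.append(len(sources))
            dbs.append(";".join(sorted(sources)))
        else:
            keep.append(False)
    out = corr_sig.loc[keep].copy()
    out["n_databases"] = ndb
    out["databases"] = dbs
    return out


def collapse_probes(couples: pd.DataFrame) -> pd.DataFrame:
    """Per (miR, gene, day) keep the most correlated probe.

    Largest |r| wins; exact |r| ties keep the lexicographically smallest
    probe ID (logged).  Output keeps one row per (miR, gene, day).
    """
    if couples.empty:
        return couples.copy()
    rows = []
    for (mir, gene, day), grp in couples.groupby(["mir", "gene", "day"], sort=True):
        best_abs = grp["r"].abs().max()
        at_best = grp.loc[(grp["r"].abs() - best_abs).abs() < 1e-15]
        if len(at_best) > 1:
            logger.info(
                "|r| tie for (%s, %s, day %s): keeping probe %s of %s",
                mir,
                gene,
                day,
                sorted(at_best["probe"])[0],
                sorted(at_best["probe"]),
            )
        chosen = at_best.loc[at_best["probe"] == sorted(at_best["probe"])[0]].iloc[0]
        rows.append(chosen)
    return pd.DataFrame(rows).reset_index(drop=True)


def couples_wide(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Wide couples table: one row per (miR, gene), one r column per day."""
    cols = ["mir", "gene", *R_COLUMNS.values()]
    if collapsed.empty:
        return pd.DataFrame(columns=cols)
    wide = collapsed.pivot_table(
        index=["mir", "gene"], columns="day", values="r", aggfunc="first"
    ).reset_index()
    for day, name in R_COLUMNS.items():
        wide[name] = wide[day] if day in wide.columns else np.nan
    return wide[cols].sort_values(["mir", "gene"]).reset_index(drop=True)


@dataclass
class CoupleStats:
    """Summary of a wide couples table (rows are couples, as printed tables do)."""

    n_couples: int
    n_mirs: int
    single_target_mirs: list[str]
    per_mir_counts: dict[str, int]
    per_mir_signs: dict[str, tuple[int, int]]  # miR -> (n_negative, n_positive)


def _row_sign(row: pd.Series) -> int:
    """Sign of a couple: sign of the per-day r with the largest magnitude."""
    vals = [row[c] for c in R_COLUMNS.values() if pd.notna(row[c])]
    if not vals:
        return 0
    best = max(vals, key=abs)
    return 1 if best >= 0 else -1


def couple_stats(wide: pd.DataFrame) -> CoupleStats:
    counts = wide.groupby("mir").size().to_dict()
    signs: dict[str, tuple[int, int]] = {}
    for mir, grp in wide.groupby("mir"):
        s = grp.apply(_row_sign, axis=1)
        signs[mir] = (int((s < 0).sum()), int((s > 0).sum()))
    return CoupleStats(
        n_couples=len(wide),
        n_mirs=wide["mir"].nunique(),
        single_target_mirs=sorted(m for m, c in counts.items() if c == 1),
        per_mir_counts=counts,
        per_mir_signs=signs,
    )


def overall_significant_pct(
    computed: Mapping[int, int], significant: Mapping[int, int]
) -> float:
    """Percentage of significant correlations pooled over days: 100 * sum/sum."""
    total = sum(computed.values())
    if total == 0:
        return 0.0
    return 100.0 * sum(significant.values()) / total


@dataclass
class PipelineSummary:
    """Per-day counts of every stage, with derived percentages.

    Percentages are always computed from the stored counts, never stored.
    """

    de_probes: dict[int, int] = field(default_factory=dict)
    de_probes_up: dict[int, int] = field(default_factory=dict)
    de_probes_down: dict[int, int] = field(default_factory=dict)
    de_genes: dict[int, int] = field(default_factory=dict)
    de_mirs: dict[int, int] = field(default_factory=dict)
    de_mirs_up: dict[int, int] = field(default_factory=dict)
    de_mirs_down: dict[int, int] = field(default_factory=dict)
    correlations_computed: dict[int, int] = field(default_factory=dict)
    correlations_significant: dict[int, int] = field(default_factory=dict)
    correlations_positive: dict[int, int] = field(default_factory=dict)
    correlations_negative: dict[int, int] = field(default_factory=dict)
    predictions_probe_level: dict[int, int] = field(default_factory=dict)
    predictions_gene_level: dict[int, int] = field(default_factory=dict)
    couples: dict[int, int] = field(default_factory=dict)
    couples_total: int = 0
    mirs_with_couples: int = 0
    single_target_mirs: int = 0
    per_mir_couples: dict[str, int] = field(default_factory=dict)

    def overall_significant_pct(self) -> float:
        return overall_significant_pct(
            self.correlations_computed, self.correlations_significant
        )

    def positive_pct(self, day: int) -> float:
        sig = self.correlations_significant.get(day, 0)
        if sig == 0:
            return 0.0
        return 100.0 * self.correlations_positive.get(day, 0) / sig

    def to_frame(self) -> pd.DataFrame:
        """Per-day count table (one row per statistic, one column per day + total)."""
        stats = {
            "de_probes": self.de_probes,
            "de_probes_up": self.de_probes_up,
            "de_probes_down": self.de_probes_down,
            "de_genes": self.de_genes,
            "de_mirs": self.de_mirs,
            "de_mirs_up": self.de_mirs_up,
            "de_mirs_down": self.de_mirs_down,
            "correlations_computed": self.correlations_computed,
            "correlations_significant": self.correlations_significant,
            "correlations_positive": self.correlations_positive,
            "correlations_negative": self.correlations_negative,
            "predictions_probe_level": self.predictions_probe_level,
            "predictions_gene_level": self.predictions_gene_level,
            "couples": self.couples,
        }
        rows = []
        for name, by_day in stats.items():
            row = {"statistic": name}
            row.update({f"day{d}": by_day.get(d, 0) for d in DAYS})
            row["total"] = sum(by_day.get(d, 0) for d in DAYS)
            rows.append(row)
        rows.append(
            {
                "statistic": "couples_union",
                **{f"day{d}": self.couples.get(d, 0) for d in DAYS},
                "total": self.couples_total,
            }
        )
        return pd.DataFrame(rows)

    def describe(self) -> str:
        lines = [self.to_frame().to_string(index=False)]
        lines.append(f"overall significant correlations: {self.overall_significant_pct():.1f}%")
        lines.append(f"miRs with >=1 integrated couple: {self.mirs_with_couples}")
        lines.append(f"single-target miRs: {self.single_target_mirs}")
        return "\n".join(lines)


def _updown(sig: pd.DataFrame, day: int) -> tuple[int, int]:
    sub = sig.loc[sig["day"] == day]
    return int((sub["logFC"] > 0).sum()), int((sub["logFC"] < 0).sum())


def summarize_pipeline(
    gene_sig: pd.DataFrame | None,
    mir_sig: pd.DataFrame | None,
    corr_records: pd.DataFrame | None,
    corr_sig: pd.DataFrame | None,
    preds_by_day: Mapping[int, PredictionSet] | None,
    collapsed: pd.DataFrame | None,
    probe_to_gene: Mapping[str, str] | None = None,
) -> PipelineSummary:
    """Assemble the end-of-run count summary from the stage outputs."""
    stages = {
        "differential expression (genes)": gene_sig,
        "differential expression (miRs)": mir_sig,
        "correlation records": corr_records,
        "significant correlations": corr_sig,
        "prediction sets": preds_by_day,
        "integrated couples": collapsed,
    }
    missing = [name for name, value in stages.items() if value is None]
    if missing:
        raise IncompleteSummaryError(missing)

    s = PipelineSummary()
    p2g = probe_to_gene or {}
    for day in DAYS:
        gsub = gene_sig.loc[gene_sig["day"] == day]
        s.de_probes[day] = len(gsub)
        s.de_probes_up[day], s.de_probes_down[day] = _updown(gene_sig, day)
        s.de_genes[day] = gsub["feature"].map(lambda p: p2g.get(p, p)).nunique()
        msub = mir_sig.loc[mir_sig["day"] == day]
        s.de_mirs[day] = len(msub)
        s.de_mirs_up[day], s.de_mirs_down[day] = _updown(mir_sig, day)
        s.correlations_computed[day] = int((corr_records["day"] == day).sum())
        csub = corr_sig.loc[corr_sig["day"] == day]
        s.correlations_significant[day] = len(csub)
        s.correlations_positive[day] = int((csub["r"] > 0).sum())
        s.correlations_negative[day] = int((csub["r"] < 0).sum())
        preds = preds_by_day.get(day)
        if preds is None:
            s.predictions_gene_level[day] = 0
            s.predictions_probe_level[day] = 0
        else:
            s.predictions_gene_level[day] = len(preds.couples)
            if p2g:
                gene_probes: dict[str, int] = {}
                for probe, gene in p2g.items():
                    key = gene.upper()
                    gene_probes[key] = gene_probes.get(key, 0) + 1
                s.predictions_probe_level[day] = sum(
                    gene_probes.get(gene.upper(), 1) for _, gene in preds.couples
                )
            else:
                s.predictions_probe_level[day] = len(preds.couples)
        s.couples[day] = int((collapsed["day"] == day).sum()) if not collapsed.empty else 0

    wide = couples_wide(collapsed)
    stats = couple_stats(wide)
    s.couples_total = stats.n_couples
    s.mirs_with_couples = stats.n_mirs
    s.single_target_mirs = len(stats.single_target_mirs)
    s.per_mir_couples = stats.per_mir_counts
    return s
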