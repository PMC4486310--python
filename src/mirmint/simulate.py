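"""Synthetic paired gene/miRNA expression data with planted regulation.

The generator emulates the structure of a two-condition (transfected vs
parental), three-time-point (days 0/7/14), two-replicate microarray study:
12 arrays per platform, born normalized on the log2 scale.  A small set of
miRs receives a per-day condition effect (magnitude >= 0.6 log2 units,
mostly up-regulated), each such miR regulates a disjoint block of target
genes, and every probe of a target gene tracks the miR's deviation from
its baseline scaled by an effect size ``beta`` — with a negative sign for
repressive couples and a positive sign otherwise.  The fraction of planted
DE genes that are down-regulated is controlled by ``frac_down`` (default
0.80, the strong down-modulation typical of differentiation-inducing
transfection).  Planted low-intensity and near-flat probes exercise the
two preprocessing filters.

Four synthetic prediction databases are drawn from the true couples at a
per-database sensitivity plus uniformly random false couples, so the
prediction-union stage is testable end to end.  A ``TruthLedger`` records
what was planted; it is written separately and never read by the pipeline.

All randomness flows through one ``numpy`` Generator seeded from
``SimulationConfig.seed``, consumed in a fixed documented order
(miR structure -> miR expression -> gene expression -> databases), so a
given seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, NamespaceError
from .io import CONDITIONS, DAYS, ExpressionMatrix, SampleDesign, write_matrix
from .predict import PredictionSet, normalize_couple, normalize_gene, normalize_mir

DB_NAMES = ("targetscan_sim", "miranda_sim", "pictar_sim", "microt_sim")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the simulated study conditions."""

    n_probes: int = 2000
    n_genes: int = 1500
    n_mirs: int = 150
    n_de_mirs: int = 12
    targets_per_mir: tuple[int, int] = (5, 50)
    frac_down: float = 0.80
    beta: float = 1.0
    sigma: float = 0.25
    db_sensitivity: float = 0.7
    db_fpr: float = 0.001
    seed: int = 0
    # structural nuisance fractions exercising the preprocessing filters
    frac_low_intensity: float = 0.05
    frac_flat: float = 0.05
    frac_low_mirs: float = 0.10
    mir_up_prob: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_genes", "n_mirs", "n_de_mirs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.targets_per_mir
        if not (0 < lo <= hi):
            raise ConfigError(f"targets_per_mir range invalid: {self.targets_per_mir}")
        if hi > self.n_genes:
            raise ConfigError(
                f"targets_per_mir upper bound {hi} exceeds n_genes={self.n_genes}"
            )
        if self.n_probes < self.n_genes:
            raise ConfigError("n_probes must be >= n_genes (every gene carries a probe)")
        if self.n_probes > 3 * self.n_genes:
            raise ConfigError("at most 3 probes per gene are generated")
        if self.n_de_mirs > self.n_mirs:
            raise ConfigError("n_de_mirs cannot exceed n_mirs")
        for name in ("frac_down", "db_sensitivity", "mir_up_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.db_fpr <= 1:
            raise ConfigError("db_fpr must be in [0, 1]")
        if self.sigma < 0 or self.beta < 0:
            raise ConfigError("sigma and beta must be non-negative")


@dataclass
class TruthLedger:
    """Ground truth of the planted structure, kept apart from the data files."""

    de_genes_by_day: dict[int, set[tuple[str, str]]]
    de_mirs_by_day: dict[int, set[tuple[str, str]]]
    true_couples: set[tuple[str, str, str]]  # (mir, gene, 'negative'|'positive')
    mir_names: frozenset[str] = field(default_factory=frozenset)
    gene_names: frozenset[str] = field(default_factory=frozenset)

    def de_mir_ids(self, day: int) -> set[str]:
        return {m for m, _ in self.de_mirs_by_day.get(day, ())}

    def de_gene_ids(self, day: int) -> set[str]:
        return {g for g, _ in self.de_genes_by_day.get(day, ())}

    def couple_keys(self) -> set[tuple[str, str]]:
        return {normalize_couple(m, g) for m, g, _ in self.true_couples}


@dataclass
class SimulatedDataset:
    genes: ExpressionMatrix
    mirs: ExpressionMatrix
    design: SampleDesign
    predictions: list[PredictionSet]
    truth: TruthLedger


def make_design() -> SampleDesign:
    rows = []
    for day in DAYS:
        for cond in CONDITIONS:
            for rep in (1, 2):
                tag = "tr" if cond == "transfected" else "pa"
                rows.append(
                    {
                        "sample": f"{tag}_d{day:02d}_r{rep}",
                        "condition": cond,
                        "day": day,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the paired matrices, prediction tables and truth ledger."""
    rng = np.random.default_rng(config.seed)
    design = make_design()
    n_samples = len(design.samples)
    day_index = np.array([DAYS.index(int(d)) for d in design.table["day"]])
    is_transfected = (design.table["condition"] == "transfected").to_numpy()

    gene_names = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    mir_names = [f"miR-{i + 1:04d}" for i in range(config.n_mirs)]

    # --- probe layout: one probe per gene, extras spread over genes (<=3 each)
    probe_gene_idx = np.arange(config.n_genes)
    extra = config.n_probes - config.n_genes
    if extra > 0:
        pool = rng.permutation(np.repeat(np.arange(config.n_genes), 2))[:extra]
        probe_gene_idx = np.concatenate([probe_gene_idx, pool])
    probe_names = [f"P{i + 1:05d}" for i in range(config.n_probes)]
    probe_to_gene = {p: gene_names[g] for p, g in zip(probe_names, probe_gene_idx)}

    # --- miR structure
    de_mir_idx = np.sort(rng.choice(config.n_mirs, config.n_de_mirs, replace=False))
    mir_dir = np.where(rng.random(config.n_de_mirs) < config.mir_up_prob, 1.0, -1.0)
    mir_mag = rng.uniform(0.6, 1.5, size=(config.n_de_mirs, len(DAYS)))

    # --- planted couples: disjoint target blocks per DE miR
    lo, hi = config.targets_per_mir
    n_targets = rng.integers(lo, hi + 1, size=config.n_de_mirs)
    if int(n_targets.sum()) > config.n_genes:
        raise ConfigError(
            f"targets_per_mir draws {int(n_targets.sum())} targets for "
            f"{config.n_genes} genes; shrink the range or n_de_mirs"
        )
    shuffled_genes = rng.permutation(config.n_genes)
    gene_regulator = np.full(config.n_genes, -1)  # index into de_mir_idx, -1 = none
    gene_sign = np.zeros(config.n_genes)  # coupling sign for regulated genes
    pos = 0
    for k in range(config.n_de_mirs):
        block = shuffled_genes[pos : pos + int(n_targets[k])]
        pos += int(n_targets[k])
        gene_regulator[block] = k
        gene_down = np.where(rng.random(block.size) < config.frac_down, -1.0, 1.0)
        # coupling sign chosen so the gene moves in its drawn direction:
        # gene effect = sign * beta * (miR condition effect), so
        # sign = gene_direction * mir_direction
        gene_sign[block] = gene_down * mir_dir[k]

    target_mask = gene_regulator >= 0

    # --- nuisance probes (never on regulated genes)
    eligible = np.flatnonzero(~target_mask[probe_gene_idx])
    n_low = int(round(config.frac_low_intensity * config.n_probes))
    n_flat = int(round(config.frac_flat * config.n_probes))
    picked = rng.choice(eligible, size=min(n_low + n_flat, eligible.size), replace=False)
    low_probes = picked[:n_low]
    flat_probes = picked[n_low : n_low + n_flat]

    # --- miR expression
    mir_base = rng.uniform(7.0, 12.0, config.n_mirs)
    low_mir_candidates = np.setdiff1d(np.arange(config.n_mirs), de_mir_idx)
    n_low_mirs = int(round(config.frac_low_mirs * config.n_mirs))
    low_mirs = rng.choice(
        low_mir_candidates, size=min(n_low_mirs, low_mir_candidates.size), replace=False
    )
    mir_base[low_mirs] = rng.uniform(4.0, 5.5, low_mirs.size)
    mir_day_effect = rng.uniform(-0.3, 0.3, size=(config.n_mirs, len(DAYS)))
    mir_noise = rng.normal(0.0, config.sigma, size=(config.n_mirs, n_samples))

    cond_effect = np.zeros((config.n_mirs, n_samples))
    for k, mi in enumerate(de_mir_idx):
        cond_effect[mi] = np.where(is_transfected, mir_dir[k] * mir_mag[k, day_index], 0.0)
    mir_dev = cond_effect + mir_noise  # deviation seen by regulated genes
    mir_values = mir_base[:, None] + mir_day_effect[:, day_index] + mir_dev

    # --- gene expression
    gene_base = rng.uniform(7.0, 12.0, config.n_probes)
    gene_base[low_probes] = rng.uniform(4.0, 5.5, low_probes.size)
    probe_day_effect = rng.uniform(-0.3, 0.3, size=(config.n_probes, len(DAYS)))
    probe_day_effect[flat_probes] = 0.0
    gene_noise = rng.normal(0.0, config.sigma, size=(config.n_probes, n_samples))
    gene_noise[flat_probes] = rng.normal(0.0, 0.005, size=(flat_probes.size, n_samples))

    coupling = np.zeros((config.n_probes, n_samples))
    regulated_probes = np.flatnonzero(target_mask[probe_gene_idx])
    for p in regulated_probes:
        g = probe_gene_idx[p]
        k = gene_regulator[g]
        coupling[p] = gene_sign[g] * config.beta * mir_dev[de_mir_idx[k]]
    gene_values = gene_base[:, None] + probe_day_effect[:, day_index] + coupling + gene_noise

    genes = ExpressionMatrix(
        pd.DataFrame(gene_values, index=probe_names, columns=design.samples),
        platform="gene",
        probe_to_gene=probe_to_gene,
    )
    mirs = ExpressionMatrix(
        pd.DataFrame(mir_values, index=mir_names, columns=design.samples),
        platform="mir",
    )

    # --- truth ledger
    true_couples: set[tuple[str, str, str]] = set()
    de_genes: dict[int, set[tuple[str, str]]] = {d: set() for d in DAYS}
    de_mirs: dict[int, set[tuple[str, str]]] = {d: set() for d in DAYS}
    for k, mi in enumerate(de_mir_idx):
        direction = "up" if mir_dir[k] > 0 else "down"
        for d in DAYS:
            de_mirs[d].add((mir_names[mi], direction))
    for g in np.flatnonzero(target_mask):
        k = gene_regulator[g]
        mir = mir_names[de_mir_idx[k]]
        sign = "negative" if gene_sign[g] < 0 else "positive"
        true_couples.add((mir, gene_names[g], sign))
        gene_direction = "down" if gene_sign[g] * mir_dir[k] < 0 else "up"
        for d in DAYS:
            de_genes[d].add((gene_names[g], gene_direction))
    truth = TruthLedger(
        de_genes_by_day=de_genes,
        de_mirs_by_day=de_mirs,
        true_couples=true_couples,
        mir_names=frozenset(mir_names),
        gene_names=frozenset(gene_names),
    )

    # --- synthetic prediction databases
    ordered_true = sorted(true_couples)
    n_pairs = config.n_mirs * config.n_genes
    true_codes = {
        mir_names.index(m) * config.n_genes + gene_names.index(g)
        for m, g, _ in true_couples
    }
    predictions = []
    for db in DB_NAMES:
        pset = PredictionSet()
        listed = rng.random(len(ordered_true)) < config.db_sensitivity
        for (mir, gene, _), keep in zip(ordered_true, listed):
            if keep:
                pset.add(mir, gene, db)
        n_false = rng.binomial(n_pairs - len(true_codes), config.db_fpr)
        chosen: set[int] = set()
        while len(chosen) < n_false:
            draw = rng.integers(0, n_pairs, size=n_false - len(chosen))
            for code in draw:
                code = int(code)
                if code not in true_codes and code not in chosen:
                    chosen.add(code)
                    if len(chosen) == n_false:
                        break
        for code in sorted(chosen):
            pset.add(mir_names[code // config.n_genes], gene_names[code % config.n_genes], db)
        predictions.append(pset)

    return SimulatedDataset(genes=genes, mirs=mirs, design=design, predictions=predictions, truth=truth)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    per_day: pd.DataFrame  # day, n_reported, n_true_de, n_hit, precision, recall
    precision: float | None  # pooled over days; None when nothing was reported
    recall: float


def evaluate_recovery(
    reported_by_day: Mapping[int, Iterable[tuple[str, str]]],
    truth: TruthLedger,
) -> RecoveryReport:
    """Precision/recall of reported couples against the planted couples.

    Recall is measured against the true couples whose miR and gene are both
    planted DE on the given day (couples the screen could in principle see).
    An empty reported set leaves precision undefined (``None``/NaN) and sets
    recall to 0.
    """
    mir_ns = {normalize_mir(m) for m in truth.mir_names}
    gene_ns = {normalize_gene(g) for g in truth.gene_names}
    true_keys = truth.couple_keys()

    rows = []
    tot_reported = tot_hit = tot_true = 0
    for day in sorted(reported_by_day):
        reported = {normalize_couple(m, g) for m, g in reported_by_day[day]}
        for mir, gene in reported:
            if mir not in mir_ns:
                raise NamespaceError(f"unknown miR identifier {mir!r} on day {day}")
            if gene not in gene_ns:
                raise NamespaceError(f"unknown gene identifier {gene!r} on day {day}")
        de_m = {normalize_mir(m) for m in truth.de_mir_ids(day)}
        de_g = {normalize_gene(g) for g in truth.de_gene_ids(day)}
        true_day = {(m, g) for m, g in true_keys if m in de_m and g in de_g}
        hit = reported & true_day
        precision = len(hit) / len(reported) if reported else None
        recall = len(hit) / len(true_day) if true_day else 0.0
        rows.append(
            {
                "day": day,
                "n_reported": len(reported),
                "n_true_de": len(true_day),
                "n_hit": len(hit),
                "precision": precision,
                "recall": recall,
            }
        )
        tot_reported += len(reported)
        tot_hit += len(hit)
        tot_true += len(true_day)
    per_day = pd.DataFrame(rows)
    overall_precision = tot_hit / tot_reported if tot_reported else None
    overall_recall = tot_hit / tot_true if tot_true else 0.0
    return RecoveryReport(per_day=per_day, precision=overall_precision, recall=overall_recall)


# ---------------------------------------------------------------------------
# on-disk layout


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Persist matrices, design, probe map, prediction tables and the ledger.

    The ledger goes to its own files; the analysis pipeline never reads them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.tsv"
    write_matrix(ds.genes, paths["genes"])
    paths["mirs"] = outdir / "mirs.tsv"
    write_matrix(ds.mirs, paths["mirs"])
    paths["design"] = outdir / "design.tsv"
    ds.design.table.to_csv(paths["design"], sep="\t", index=False)

    paths["probe_map"] = outdir / "probe_map.tsv"
    pd.DataFrame(
        {"probe": list(ds.genes.probe_to_gene), "gene": list(ds.genes.probe_to_gene.values())}
    ).to_csv(paths["probe_map"], sep="\t", index=False)

    pred_dir = outdir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for db, pset in zip(DB_NAMES, ds.predictions):
        p = pred_dir / f"{db}.tsv"
        rows = [{"mir": m, "gene": g} for m, g in sorted(pset.couples)]
        pd.DataFrame(rows, columns=["mir", "gene"]).to_csv(p, sep="\t", index=False)
        paths[f"db:{db}"] = p

    paths["truth_couples"] = outdir / "truth_couples.tsv"
    pd.DataFrame(
        sorted(ds.truth.true_couples), columns=["mir", "gene", "sign"]
    ).to_csv(paths["truth_couples"], sep="\t", index=False)
    de_rows = [
        {"day": d, "feature": f, "direction": direction, "platform": platform}
        for platform, by_day in (
            ("gene", ds.truth.de_genes_by_day),
            ("mir", ds.truth.de_mirs_by_day),
        )
        for d, items in sorted(by_day.items())
        for f, direction in sorted(items)
    ]
    paths["truth_de"] = outdir / "truth_de.tsv"
    pd.DataFrame(de_rows, columns=["day", "feature", "direction", "platform"]).to_csv(
        paths["truth_de"], sep="\t", index=False
    )
    names = pd.DataFrame(
        [{"name": n, "kind": "mir"} for n in sorted(ds.truth.mir_names)]
        + [{"name": n, "kind": "gene"} for n in sorted(ds.truth.gene_names)]
    )
    paths["truth_names"] = outdir / "truth_names.tsv"
    names.to_csv(paths["truth_names"], sep="\t", index=False)
    return paths


def read_truth(outdir: str | Path) -> TruthLedger:
    outdir = Path(outdir)
    couples = pd.read_csv(outdir / "truth_couples.tsv", sep="\t")
    de = pd.read_csv(outdir / "truth_de.tsv", sep="\t")
    names = pd.read_csv(outdir / "truth_names.tsv", sep="\t")
    de_genes: dict[int, set[tuple[str, str]]] = {d: set() for d in DAYS}
    de_mirs: dict[int, set[tuple[str, str]]] = {d: set() for d in DAYS}
    for _, row in de.iterrows():
        target = de_genes if row["platform"] == "gene" else de_mirs
        target[int(row["day"])].add((row["feature"], row["direction"]))
    return TruthLedger(
        de_genes_by_day=de_genes,
        de_mirs_by_day=de_mirs,
        true_couples={tuple(r) for r in couples.itertuples(index=False)},
        mir_names=frozenset(names.loc[names["kind"] == "mir", "name"]),
        gene_names=frozenset(names.loc[names["kind"] == "gene", "name"]),
    )
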