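"""Sequence-based target-prediction tables and their union.

Predictions arrive as per-database TSV tables of (miR, gene) couples —
exports from tools in the TargetScan / miRanda / PicTar / DIANA-microT
family, or synthetic equivalents.  A couple is accepted when it is listed
in at least ``min_databases`` of the supplied tables (default 1, i.e. the
union); no per-database score threshold is applied.

Identifier matching is deliberately forgiving: miR names are compared
case-insensitively with any leading ``hsa-`` prefix stripped, while the
star suffix of passenger-strand names (``miR-425*``) is kept verbatim.
Gene symbols are compared upper-case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MatrixFormatError, ParameterError

logger = logging.getLogger(__name__)

Couple = tuple[str, str]


def normalize_mir(name: str) -> str:
    """Canonical form of a miR identifier: lower-case, 'hsa-' prefix stripped."""
    s = str(name).strip()
    if s.lower().startswith("hsa-"):
        s = s[4:]
    return s.lower()


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_couple(mir: str, gene: str) -> Couple:
    return (normalize_mir(mir), normalize_gene(gene))


@dataclass
class PredictionSet:
    """A set of (miR, gene) couples and the databases supporting each."""

    couples: set[Couple] = field(default_factory=set)
    sources: dict[Couple, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sources) != self.couples:
            raise ParameterError("sources keys must equal the couple set")

    def __len__(self) -> int:
        return len(self.couples)

    def __contains__(self, couple: Couple) -> bool:
        return normalize_couple(*couple) in self.couples

    def add(self, mir: str, gene: str, database: str) -> None:
        key = normalize_couple(mir, gene)
        self.couples.add(key)
        self.sources.setdefault(key, set()).add(database)

    def n_databases(self, mir: str, gene: str) -> int:
        return len(self.sources.get(normalize_couple(mir, gene), ()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mir": mir,
                "gene": gene,
                "n_databases": len(self.sources[(mir, gene)]),
                "databases": ";".join(sorted(self.sources[(mir, gene)])),
            }
            for mir, gene in sorted(self.couples)
        ]
        return pd.DataFrame(rows, columns=["mir", "gene", "n_databases", "databases"])


def load_prediction_table(path: str | Path, database_name: str) -> PredictionSet:
    """Read one database's TSV of (miR, gene) couples, deduplicated.

    The first two columns are taken as miR and gene (a header row naming
    them is accepted and skipped); malformed rows raise with their line
    number, an empty file yields an empty set with a warning.
    """
    path = Path(path)
    out = PredictionSet()
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [ln for ln in lines if ln.strip()]
    if not body:
        logger.warning("prediction table %s is empty", path)
        return out
    start = 0
    first = [c.strip().lower() for c in body[0].split("\t")]
    if first[:2] in (["mir", "gene"], ["mirna", "gene"], ["mir", "target"]):
        start = 1
    for lineno, line in enumerate(body[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise MatrixFormatError(
                f"{path.name}: malformed prediction row at line {lineno}: {line!r}"
            )
        out.add(parts[0], parts[1], database_name)
    return out


def union_predictions(
    sets: Sequence[PredictionSet], min_databases: int = 1
) -> PredictionSet:
    """Merge per-database sets, keeping couples with >= min_databases sources."""
    if not sets:
        raise ParameterError("need at least one prediction set")
    if min_databases < 1:
        raise ParameterError(f"min_databases must be >= 1, got {min_databases}")
    n_names = len({db for s in sets for dbs in s.sources.values() for db in dbs})
    if min_databases > max(n_names, len(sets)):
        raise ParameterError(
            f"min_databases={min_databases} exceeds the {len(sets)} supplied databases"
        )
    merged: dict[Couple, set[str]] = {}
    for s in sets:
        for couple, dbs in s.sources.items():
            merged.setdefault(couple, set()).update(dbs)
    kept = {c: dbs for c, dbs in merged.items() if len(dbs) >= min_databases}
    return PredictionSet(couples=set(kept), sources=kept)


def restrict_to_de(
    preds: PredictionSet,
    de_genes_by_day: Mapping[int, Iterable[str]],
    de_mirs_by_day: Mapping[int, Iterable[str]],
) -> dict[int, PredictionSet]:
    """Per-day subsets keeping couples whose miR and gene are both DE that day."""
    out: dict[int, PredictionSet] = {}
    for day in sorted(set(de_genes_by_day) | set(de_mirs_by_day)):
        mirs = {normalize_mir(m) for m in de_mirs_by_day.get(day, ())}
        genes = {normalize_gene(g) for g in de_genes_by_day.get(day, ())}
        kept = {
            c: set(dbs)
            for c, dbs in preds.sources.items()
            if c[0] in mirs and c[1] in genes
        }
        out[day] = PredictionSet(couples=set(kept), sources=kept)
    return out


def uncovered_mirs(preds: PredictionSet, mirs: Iterable[str]) -> list[str]:
    """miRs with no prediction coverage in any database (reported, not dropped)."""
    covered = {mir for mir, _ in preds.couples}
    return sorted(m for m in mirs if normalize_mir(m) not in covered)


def write_prediction_set(preds: PredictionSet, path: str | Path) -> None:
    preds.to_frame().to_csv(path, sep="\t", index=False)
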