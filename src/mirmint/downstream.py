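"""Gene-set over-representation and PCA ordination of samples.

The enrichment test is a plain one-sided hypergeometric over-representation
test of a query gene list against each set of a collection, with the array
gene list as background universe and Benjamini-Hochberg adjustment across
sets (significance at adjusted p <= 0.1 by default).  Ordination is
ordinary PCA on feature-centred log2 expression, projecting samples onto
the leading components; it is used to place experimental samples relative
to external reference profiles supplied as extra columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .errors import DegenerateInputError, ParameterError
from .predict import normalize_gene

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.sets = {
            name: {normalize_gene(g) for g in genes} for name, genes in self.sets.items()
        }
        self.universe = {normalize_gene(g) for g in self.universe}
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ParameterError(f"empty gene sets: {empty}")


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...) against a given universe."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParameterError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(sets=sets, universe=set(universe))


def fisher_enrichment(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a query list in each gene set.

    For a universe of N genes, a set with m members in the universe and a
    query of q genes with k in the set, p = P(X >= k) with
    X ~ Hypergeom(N, m, q).  p-values are BH-adjusted across sets and rows
    are sorted by p.  Query genes outside the universe are dropped with a
    warning; an empty query or universe is an error.
    """
    universe = collection.universe
    if not universe:
        raise ParameterError("empty universe")
    query = {normalize_gene(g) for g in query_genes}
    if not query:
        raise ParameterError("empty query gene list")
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
        if not query:
            raise ParameterError("no query genes remain inside the universe")
    N = len(universe)
    q = len(query)
    rows = []
    for name, genes in collection.sets.items():
        members = genes & universe
        m = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, m, q)) if m else 1.0
        rows.append({"set": name, "k": k, "q": q, "m": m, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] <= alpha
    return out.sort_values(["p", "set"]).reset_index(drop=True)


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # sample, PC1, PC2, ...
    variance_explained: np.ndarray  # fraction per component, non-increasing


def pca_ordinate(
    values: pd.DataFrame,
    feature_subset: Sequence[str] | None = None,
    n_components: int = 2,
) -> Ordination:
    """PCA of samples from feature-centred log2 expression.

    ``values`` is features x samples.  ``feature_subset`` restricts the
    projection (e.g. to DE genes at one day); features absent from the
    matrix are ignored, but an empty intersection is an error.
    """
    if values.shape[1] < 2:
        raise DegenerateInputError("ordination needs at least 2 samples")
    if feature_subset is not None:
        present = [f for f in feature_subset if f in values.index]
        if not present:
            raise ParameterError("feature_subset has no overlap with the matrix")
        values = values.loc[present]
    X = values.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    varexp = (s**2) / total if total > 0 else np.zeros_like(s)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    frame = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(k)], index=values.columns
    )
    frame.insert(0, "sample", frame.index)
    return Ordination(
        coordinates=frame.reset_index(drop=True), variance_explained=varexp[:k]
    )
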