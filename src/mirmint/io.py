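"""Reading, validation and probe-level filtering of expression matrices.

The entry point of the analysis is a pair of normalized log2 intensity
matrices (genes/probes and miRNAs) over a two-condition, three-time-point,
two-replicate design.  Two probe-level filters are applied before
differential expression:

* an intensity filter removing probes whose *raw* intensity (``2**log2``)
  is at or below a threshold in at least a given fraction of samples, and
* a variability filter removing probes whose inter-quartile range of log2
  signal is at or below the median IQR across probes.

Both boundaries are inclusive, exactly as the rules are usually stated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DesignError,
    MatrixFormatError,
    ParameterError,
)

CONDITIONS = ("transfected", "parental")
DAYS = (0, 7, 14)


@dataclass(frozen=True)
class SampleDesign:
    """Annotation of each array: condition, day and replicate index.

    The design is the contract every matrix is validated against: the three
    days {0, 7, 14}, the two conditions, and at least two replicates per
    (condition, day) cell so that a per-day two-group comparison has a
    defined within-group variance.
    """

    table: pd.DataFrame  # columns: sample, condition, day, replicate

    def __post_init__(self) -> None:
        required = {"sample", "condition", "day", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table lacks columns: {sorted(missing)}")
        t = self.table
        if t["sample"].duplicated().any():
            dups = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise DesignError(f"duplicate sample IDs in design: {dups}")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
        if set(t["day"]) != set(DAYS):
            raise DesignError(f"days must be exactly {set(DAYS)}, got {sorted(set(t['day']))}")
        counts = t.groupby(["condition", "day"]).size()
        if (counts < 2).any():
            thin = counts[counts < 2].index.tolist()
            raise DesignError(f"(condition, day) cells with <2 samples: {thin}")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_for(self, day: int, condition: str | None = None) -> list[str]:
        t = self.table
        mask = t["day"] == day
        if condition is not None:
            mask &= t["condition"] == condition
        return list(t.loc[mask, "sample"])

    def condition_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["sample"], self.table["condition"]))


@dataclass
class ExpressionMatrix:
    """A features x samples log2 intensity matrix with light validation.

    ``platform`` is ``"gene"`` or ``"mir"``; for gene platforms an optional
    probe -> gene-symbol map supports probe-level analyses that report at
    gene level.
    """

    data: pd.DataFrame
    platform: str = "gene"
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("gene", "mir"):
            raise ParameterError(f"platform must be 'gene' or 'mir', got {self.platform!r}")
        idx = self.data.index
        if idx.duplicated().any():
            raise MatrixFormatError(
                f"duplicate feature IDs: {sorted(set(idx[idx.duplicated()]))}"
            )
        cols = self.data.columns
        if cols.duplicated().any():
            raise MatrixFormatError(
                f"duplicate sample IDs: {sorted(set(cols[cols.duplicated()]))}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MatrixFormatError("matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            r, c = bad[0]
            raise MatrixFormatError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def gene_of(self, probe: str) -> str:
        """Gene symbol for a probe (identity when no map is attached)."""
        if self.probe_to_gene is None:
            return probe
        return self.probe_to_gene.get(probe, probe)

    def subset(self, features) -> "ExpressionMatrix":
        return dataclasses.replace(self, data=self.data.loc[list(features)])


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return SampleDesign(df)


def read_matrix(
    path: str | Path,
    design: SampleDesign,
    platform: str = "gene",
    probe_to_gene: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ID, header = samples).

    The header must match the design's sample set exactly; mismatches are
    reported by name rather than silently reordered away.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise MatrixFormatError(f"{path.name}: duplicated feature rows: {dups}")
    header = list(df.columns)
    design_samples = set(design.samples)
    unknown = [s for s in header if s not in design_samples]
    if unknown:
        raise DesignError(f"{path.name}: samples absent from design: {unknown}")
    absent = [s for s in design.samples if s not in header]
    if absent:
        raise DesignError(f"{path.name}: design samples missing from matrix: {absent}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise MatrixFormatError(
                    f"{path.name}: non-numeric cell at feature {row!r}, sample {col!r}"
                ) from exc
        raise MatrixFormatError(f"{path.name}: non-numeric data") from exc
    # keep design order for downstream group indexing
    df = df[design.samples]
    return ExpressionMatrix(df, platform=platform, probe_to_gene=probe_to_gene)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def filter_low_expression(
    m: ExpressionMatrix, raw_threshold: float = 100.0, frac: float = 0.75
) -> ExpressionMatrix:
    """Drop features lowly expressed in at least ``frac`` of samples.

    Values are log2; the rule is evaluated on raw intensities ``2**value``.
    A feature is removed when ``2**value <= raw_threshold`` in at least
    ``frac`` (inclusive) of the samples.  Feature order is preserved.
    """
    if not 0 < frac <= 1:
        raise ParameterError(f"frac must be in (0, 1], got {frac}")
    raw = np.power(2.0, m.data.to_numpy())
    n_low = (raw <= raw_threshold).sum(axis=1)
    n = raw.shape[1]
    # "at least frac of samples" is inclusive: exactly frac*n low samples removes
    keep = n_low < frac * n - 1e-9
    return m.subset(m.data.index[keep])


def feature_iqr(values: pd.DataFrame) -> pd.Series:
    """Per-feature IQR of log2 signal, quartiles by linear interpolation
    between order statistics (the common 'type 7' convention)."""
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75], axis=1, method="linear")
    return pd.Series(q3 - q1, index=values.index)


def filter_low_iqr(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features whose IQR is <= the median of per-feature IQRs.

    With all IQRs equal every feature sits at the (inclusive) boundary and
    all are removed; the caller is expected to apply this filter after the
    intensity filter, so the median is taken over the surviving features.
    """
    if len(m.data) < 2:
        raise DegenerateInputError("IQR filter needs at least 2 features")
    iqrs = feature_iqr(m.data)
    med = float(np.median(iqrs.to_numpy()))
    keep = iqrs > med
    return m.subset(m.data.index[keep])
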