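"""Per-day Pearson screening of DE miRs against DE gene probes.

For every day the expression of each differentially expressed miR is
correlated with each differentially expressed gene probe over that day's
paired arrays.  Significance uses the conjunction |r| >= r_min and
p <= p_max (defaults 0.7 and 0.05), with the asymptotic two-sided p-value
from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom; a Fisher-z
normal approximation is available as an alternative.  No multiplicity
correction is applied — the high |r| cut is the type-I error control.
Correlation is kept at probe level, so several significant records per
gene are possible and intentional.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, PairingError, ParameterError
from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

R_MIN = 0.7
P_MAX = 0.05

RECORD_COLUMNS = ["mir", "probe", "gene", "day", "r", "p", "sign", "significant"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise DegenerateInputError(f"need n >= 3 observations, got {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(xd @ yd) / (sx * sy)
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int, method: str = "t") -> float:
    """Asymptotic two-sided p-value for an observed Pearson r at sample size n.

    ``method='t'`` uses the exact-under-normality t transform with n-2 df;
    ``method='fisher-z'`` uses the normal approximation on atanh(r) with
    standard error 1/sqrt(n-3) (requires n >= 4).  |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ParameterError(f"need n >= 3, got {n}")
    if abs(r) > 1:
        raise ParameterError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    if method == "t":
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if method == "fisher-z":
        if n < 4:
            raise ParameterError("fisher-z needs n >= 4")
        z = math.atanh(r) * math.sqrt(n - 3)
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ParameterError(f"unknown p-value method {method!r}")


def correlate_day(
    mir_m: ExpressionMatrix,
    gene_m: ExpressionMatrix,
    design: SampleDesign,
    day: int,
    de_mirs: Iterable[str],
    de_probes: Iterable[str],
    sample_scope: str = "per_day",
    p_method: str = "t",
) -> pd.DataFrame:
    """All (DE miR x DE probe) correlation records for one day.

    ``sample_scope='per_day'`` correlates over the day's paired arrays (the
    default, 4 with two replicates per condition); ``'all_samples'`` uses
    every array of the design.  Constant vectors yield no record and are
    counted in a warning.  Records are returned unfiltered; apply
    :func:`filter_correlations` for the significance cut.
    """
    if sample_scope not in ("per_day", "all_samples"):
        raise ParameterError(f"unknown sample_scope {sample_scope!r}")
    samples = design.samples if sample_scope == "all_samples" else design.samples_for(day)
    missing_m = [s for s in samples if s not in mir_m.data.columns]
    missing_g = [s for s in samples if s not in gene_m.data.columns]
    if missing_m or missing_g:
        raise PairingError(
            f"day {day}: samples absent from {'miR' if missing_m else 'gene'} matrix: "
            f"{missing_m or missing_g}"
        )
    de_mirs = [m for m in de_mirs if m in mir_m.data.index]
    de_probes = [p for p in de_probes if p in gene_m.data.index]
    n = len(samples)
    if not de_mirs or not de_probes:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    X = mir_m.data.loc[de_mirs, samples].to_numpy(dtype=float)
    Y = gene_m.data.loc[de_probes, samples].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    yn = np.sqrt((Yc**2).sum(axis=1))
    const_m = xn == 0
    const_g = yn == 0
    n_skipped = int(const_m.sum()) * len(de_probes) + int(const_g.sum()) * len(de_mirs)
    if n_skipped:
        logger.warning(
            "day %d: skipped %d correlations involving constant vectors", day, n_skipped
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xn, yn)
    R = np.clip(R, -1.0, 1.0)

    rows = []
    for i, mir in enumerate(de_mirs):
        if const_m[i]:
            continue
        for j, probe in enumerate(de_probes):
            if const_g[j]:
                continue
            r = float(R[i, j])
            rows.append(
                {
                    "mir": mir,
                    "probe": probe,
                    "gene": gene_m.gene_of(probe),
                    "day": day,
                    "r": r,
                    "p": correlation_pvalue(r, n, method=p_method),
                    "sign": "positive" if r >= 0 else "negative",
                    "significant": False,
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def filter_correlations(
    records: pd.DataFrame, r_min: float = R_MIN, p_max: float = P_MAX
) -> pd.DataFrame:
    """Significant subset: |r| >= r_min AND p <= p_max (both inclusive).

    Positive and negative correlations are both retained; the ``significant``
    flag is set on the returned copy.
    """
    if r_min < 0:
        raise ParameterError(f"r_min must be >= 0, got {r_min}")
    if not 0 < p_max <= 1:
        raise ParameterError(f"p_max must be in (0, 1], got {p_max}")
    if records.empty:
        out = records.copy()
        return out
    mask = (records["r"].abs() >= r_min) & (records["p"] <= p_max)
    out = records.loc[mask].copy()
    out["significant"] = True
    return out
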