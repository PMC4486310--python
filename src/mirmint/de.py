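"""Per-day two-group differential expression with an empirical-Bayes moderated t.

A single linear model with one coefficient per (condition, day) cell is fitted
to each feature, pooling the residual variance across all six cells
(df = n_samples - 6 with the default 12-sample design).  Per-feature variances
``s_g^2`` are then shrunk toward a common prior by the standard
empirical-Bayes recipe: the prior degrees of freedom ``d0`` and prior variance
``s0^2`` are obtained by moment-matching the distribution of ``log s_g^2``
against a scaled F, using the closed-form digamma/trigamma relations with a
Newton inversion of the trigamma function.  The moderated statistic for the
day-d contrast (transfected - parental) is

    t_g = logFC_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

with d0 + d_g degrees of freedom (capped at the total pooled residual df).
Two-sided p-values are Benjamini-Hochberg adjusted within each day's contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateInputError, ParameterError
from .io import DAYS, ExpressionMatrix, SampleDesign

__all__ = [
    "ModerationParams",
    "estimate_moderation",
    "trigamma_inverse",
    "fit_moderated_t",
    "bh_adjust",
    "call_significant",
    "significant_sets",
    "logfc_to_fc",
]

# defaults mirroring the dual significance rules of the source protocol:
# genes: |logFC| >= 0.585 (fold change 1.5) and adjusted p <= 0.05
# miRs:  |logFC| >= 0.485 (fold change 1.4) and raw p <= 0.01
GENE_LFC_MIN = 0.585
GENE_P_MAX = 0.05
MIR_LFC_MIN = 0.485
MIR_P_MAX = 0.01


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for the per-feature variances.

    ``d0`` may be ``math.inf`` (complete shrinkage: every feature gets the
    prior variance) or 0 (no shrinkage: ordinary pooled t).
    """

    d0: float
    s0_sq: float
    d_g: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ParameterError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not (self.s0_sq >= 0):
            raise ParameterError(f"s0_sq must be >= 0, got {self.s0_sq}")

    def squeeze(self, s2: np.ndarray) -> np.ndarray:
        """Posterior (shrunken) variances for observed residual variances."""
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0_sq)
        if self.d0 == 0:
            return np.asarray(s2, dtype=float)
        return (self.d0 * self.s0_sq + self.d_g * s2) / (self.d0 + self.d_g)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing trigamma with the standard asymptotic
    starting point 0.5 + 1/y; for extreme arguments the asymptotic limits
    1/sqrt(y) (y small... large x) and 1/y are returned directly.
    """
    if y <= 0:
        raise ParameterError(f"trigamma_inverse requires y > 0, got {y}")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, d_g: float) -> ModerationParams:
    """Moment-match (d0, s0^2) from observed residual variances.

    Works on ``log s2`` whose mean and variance have closed forms in terms of
    digamma/trigamma; the excess variance of ``log s2`` beyond the sampling
    contribution ``trigamma(d_g/2)`` identifies ``d0``.  Non-positive
    variances (flat features) are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise DegenerateInputError("need >= 2 positive residual variances to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.sum((e - e_mean) ** 2) / (ok.sum() - 1))
    e_var -= float(special.polygamma(1, d_g / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationParams(d0=d0, s0_sq=s0_sq, d_g=d_g)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ParameterError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def _group_layout(m: ExpressionMatrix, design: SampleDesign):
    """Column indices of each (condition, day) cell, in design order."""
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    layout: dict[tuple[str, int], list[int]] = {}
    for _, row in design.table.iterrows():
        layout.setdefault((row["condition"], int(row["day"])), []).append(cols[row["sample"]])
    return layout


def fit_moderated_t(
    m: ExpressionMatrix,
    design: SampleDesign,
    moderation: ModerationParams | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression for every day's contrast.

    Returns a long DataFrame with columns ``feature, day, logFC, t, p,
    p_adj, zero_variance``; ``logFC`` is transfected minus parental on the
    log2 scale.  Pass ``moderation`` to force the prior (e.g. ``d0=0`` for
    an ordinary pooled t, ``d0=inf`` for full shrinkage); by default the
    prior is estimated from the data.
    """
    layout = _group_layout(m, design)
    X = m.data.to_numpy(dtype=float)
    n_samples = X.shape[1]
    n_groups = len(layout)
    d_g = n_samples - n_groups
    if d_g <= 0:
        raise DegenerateInputError(
            f"zero residual df: {n_samples} samples for {n_groups} groups"
        )

    means = {key: X[:, idx].mean(axis=1) for key, idx in layout.items()}
    rss = np.zeros(X.shape[0])
    for key, idx in layout.items():
        rss += ((X[:, idx] - means[key][:, None]) ** 2).sum(axis=1)
    s2 = rss / d_g
    zero_var = s2 <= 0

    params = moderation if moderation is not None else estimate_moderation(s2, d_g)
    s2_post = params.squeeze(s2)

    df_pooled = d_g * X.shape[0]
    df_total = min(params.d0 + d_g, df_pooled)

    frames = []
    for day in DAYS:
        idx_t = layout[("transfected", day)]
        idx_p = layout[("parental", day)]
        logfc = means[("transfected", day)] - means[("parental", day)]
        c = math.sqrt(1.0 / len(idx_t) + 1.0 / len(idx_p))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (np.sqrt(s2_post) * c)
        t = np.where(np.isfinite(t), t, 0.0)
        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        frames.append(
            pd.DataFrame(
                {
                    "feature": m.feature_ids,
                    "day": day,
                    "logFC": logfc,
                    "t": t,
                    "p": p,
                    "p_adj": bh_adjust(p),
                    "zero_variance": zero_var,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_significant(
    results: pd.DataFrame,
    lfc_min: float,
    p_max: float,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Subset of results passing |logFC| >= lfc_min and p <= p_max.

    ``use_adjusted`` selects the BH-adjusted column; both thresholds are
    inclusive.  Rows whose selected p-value is missing are never significant.
    """
    if lfc_min < 0:
        raise ParameterError(f"lfc_min must be >= 0, got {lfc_min}")
    if not 0 < p_max <= 1:
        raise ParameterError(f"p_max must be in (0, 1], got {p_max}")
    if results.empty:
        return results.copy()
    col = "p_adj" if use_adjusted else "p"
    pvals = pd.to_numeric(results[col], errors="coerce")
    mask = (results["logFC"].abs() >= lfc_min) & (pvals <= p_max)
    return results.loc[mask.fillna(False)].copy()


def significant_sets(significant: pd.DataFrame) -> dict[int, dict[str, str]]:
    """Per-day mapping feature -> direction ('up'/'down') from a significant subset."""
    out: dict[int, dict[str, str]] = {day: {} for day in DAYS}
    for _, row in significant.iterrows():
        out.setdefault(int(row["day"]), {})[row["feature"]] = (
            "up" if row["logFC"] > 0 else "down"
        )
    return out


def logfc_to_fc(logfc: float) -> float:
    """Linear fold change for a log2 fold change (2**logFC)."""
    if not np.all(np.isfinite(logfc)):
        raise ParameterError("logFC must be finite")
    return np.power(2.0, logfc)
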