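"""Bundled reference tables from a CD99-transfection osteosarcoma study.

Two small curated tables, transcribed from printed results of a Saos-2 /
Sa-CD99 osteoblast-differentiation time course, serve as worked examples
and regression fixtures for the reporting layer:

* a per-day miRNA differential-expression table (log2 fold change of
  transfected vs parental at days 0/7/14, with the raw p-value where the
  original analysis called the miR significant, blank otherwise), and
* the integrated miR:gene couples table (per-day Pearson r of the most
  correlated probe, blank where not significant), in which one miR/gene
  pair appears on two printed rows and is deliberately kept duplicated.

One printed p-value in the miRNA table (miR-425*, day 0) was missing its
decimal separator and is transcribed as 0.00841.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import DAYS

_P_COLS = {0: "p_day0", 7: "p_day7", 14: "p_day14"}
_LFC_COLS = {0: "logfc_day0", 7: "logfc_day7", 14: "logfc_day14"}


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("mirmint.data").joinpath(name)) as path:
        return pd.read_csv(path, sep="\t")


def load_mir_de_table() -> pd.DataFrame:
    """Wide miRNA DE table: mir, position, logfc/p per day (NaN = not significant)."""
    return _read("reference_mir_de.tsv")


def mir_de_long() -> pd.DataFrame:
    """Long form compatible with :func:`mirmint.de.call_significant`.

    Columns ``feature, day, logFC, p``; rows whose p was not printed carry
    NaN and therefore never pass a p threshold.
    """
    wide = load_mir_de_table()
    frames = []
    for day in DAYS:
        frames.append(
            pd.DataFrame(
                {
                    "feature": wide["mir"],
                    "day": day,
                    "logFC": wide[_LFC_COLS[day]],
                    "p": wide[_P_COLS[day]],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def load_couples_table() -> pd.DataFrame:
    """Wide integrated-couples table: mir, gene, r_day0, r_day7, r_day14."""
    return _read("reference_couples.tsv")
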