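"""Moderated-t differential expression, BH adjustment and significance calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirmint.de import (
    ModerationParams,
    bh_adjust,
    call_significant,
    estimate_moderation,
    fit_moderated_t,
    logfc_to_fc,
    significant_sets,
    trigamma_inverse,
)
from mirmint.errors import ParameterError
from mirmint.io import ExpressionMatrix, SampleDesign, read_design, read_matrix
from mirmint.reference import mir_de_long
from mirmint.simulate import make_design

from conftest import DATA_DIR


def bh_bruteforce(p):
    """Independent step-up oracle: adj_i = min_{rank >= rank_i} n * p_(k) / k."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running = min(running, n * p[i] / (pos + 1))
        adj[i] = running
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
        ids=["single", "ties", "step-up-collapse"],
    )
    def test_known_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.1, float("nan")])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_and_dominates_input(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_bruteforce(p))
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    def test_permutation_invariance(self, p):
        perm = list(reversed(p))
        assert sorted(bh_adjust(p)) == pytest.approx(sorted(bh_adjust(perm)))


class TestFoldChange:
    @pytest.mark.parametrize(
        "logfc, fc", [(0.585, 1.50), (0.485, 1.40), (0.0, 1.0), (1.0, 2.0)]
    )
    def test_values(self, logfc, fc):
        assert round(logfc_to_fc(logfc), 2) == fc

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            logfc_to_fc(float("inf"))


def _random_matrix(design: SampleDesign, n=30, seed=5) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = rng.normal(8.0, 1.0, size=(n, len(design.samples)))
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"f{i}" for i in range(n)], columns=design.samples)
    )


class TestModeratedT:
    def test_full_shrinkage_limit(self, design):
        """d0 = inf: every feature's t uses the common prior variance s0."""
        m = _random_matrix(design)
        s0_sq = 0.5
        res = fit_moderated_t(
            m, design, moderation=ModerationParams(d0=math.inf, s0_sq=s0_sq, d_g=6)
        )
        groups = design.table.groupby(["condition", "day"])["sample"].apply(list)
        for day in (0, 7, 14):
            sub = res[res["day"] == day]
            logfc = (
                m.data[groups[("transfected", day)]].mean(axis=1)
                - m.data[groups[("parental", day)]].mean(axis=1)
            )
            expected_t = logfc.to_numpy() / (math.sqrt(s0_sq) * math.sqrt(0.5 + 0.5))
            assert sub["t"].to_numpy() == pytest.approx(expected_t, abs=1e-12)

    def test_no_shrinkage_limit_is_pooled_t(self, design):
        """d0 = 0: t equals the ordinary t on the 6-group pooled variance."""
        m = _random_matrix(design, seed=6)
        res = fit_moderated_t(m, design, moderation=ModerationParams(d0=0, s0_sq=1.0, d_g=6))
        X = m.data
        groups = design.table.groupby(["condition", "day"])["sample"].apply(list)
        rss = np.zeros(len(X))
        for cols in groups:
            block = X[cols]
            rss += ((block.sub(block.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
        s2 = rss / 6.0
        for day in (0, 7, 14):
            sub = res[res["day"] == day]
            logfc = (
                X[groups[("transfected", day)]].mean(axis=1)
                - X[groups[("parental", day)]].mean(axis=1)
            ).to_numpy()
            expected_t = logfc / np.sqrt(s2 * (0.5 + 0.5))
            assert sub["t"].to_numpy() == pytest.approx(expected_t, rel=1e-12)

    def test_matches_reference_implementation(self):
        """50-feature fixture vs values frozen once from Bioconductor limma
        (lmFit + contrasts.fit + eBayes on the six-group model)."""
        design = read_design(DATA_DIR / "modt_design.tsv")
        m = read_matrix(DATA_DIR / "modt_input.tsv", design)
        res = fit_moderated_t(m, design)
        exp = pd.read_csv(DATA_DIR / "modt_expected_limma.tsv", sep="\t").set_index("feature")
        for day, tag in ((0, "d0"), (7, "d7"), (14, "d14")):
            sub = res[res["day"] == day].set_index("feature")
            for mine, theirs in (("logFC", f"logFC_{tag}"), ("t", f"t_{tag}"), ("p", f"p_{tag}")):
                diff = np.abs(sub[mine].to_numpy() - exp[theirs].to_numpy()).max()
                assert diff < 1e-6, f"{mine} day {day}: max diff {diff}"

    def test_antisymmetric_under_condition_swap(self, design):
        m = _random_matrix(design, seed=11)
        swapped_table = design.table.copy()
        swapped_table["condition"] = swapped_table["condition"].map(
            {"transfected": "parental", "parental": "transfected"}
        )
        swapped = SampleDesign(swapped_table)
        a = fit_moderated_t(m, design)
        b = fit_moderated_t(m, swapped)
        assert a["logFC"].to_numpy() == pytest.approx(-b["logFC"].to_numpy())
        assert a["t"].to_numpy() == pytest.approx(-b["t"].to_numpy())
        assert a["p"].to_numpy() == pytest.approx(b["p"].to_numpy())

    def test_moderation_recovers_planted_prior(self):
        rng = np.random.default_rng(42)
        d_g, d0, s0_sq = 6, 5.0, 0.09
        s2 = s0_sq * d0 / rng.chisquare(d0, size=20000) * rng.chisquare(d_g, size=20000) / d_g
        params = estimate_moderation(s2, d_g)
        assert params.d0 == pytest.approx(d0, rel=0.15)
        assert params.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.01, 0.5, 2.0, 50.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)

    def test_logfc_estimation_unbiased(self):
        """Planted logFC of +/-1 at sigma 0.25: the mean estimated |logFC|
        sits within 0.1 of the truth over 20 replicate simulations."""
        design = make_design()
        means = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            truth = rng.choice([-1.0, 1.0], size=50)
            is_tr = (design.table["condition"] == "transfected").to_numpy()
            vals = 8.0 + truth[:, None] * is_tr[None, :] + rng.normal(0, 0.25, (50, 12))
            m = ExpressionMatrix(
                pd.DataFrame(vals, index=[f"f{i}" for i in range(50)], columns=design.samples)
            )
            res = fit_moderated_t(m, design)
            means.append((res["logFC"].to_numpy() * np.tile(truth, 3)).mean())
        assert abs(np.mean(means) - 1.0) < 0.1


class TestSignificanceCalls:
    def test_reference_mir_counts_per_day(self):
        """The bundled miRNA DE table yields 7/4/16 significant miRs at the
        miR thresholds (|logFC| >= 0.485, raw p <= 0.01)."""
        long = mir_de_long()
        sig = call_significant(long, lfc_min=0.485, p_max=0.01, use_adjusted=False)
        counts = sig.groupby("day").size().to_dict()
        assert counts == {0: 7, 7: 4, 14: 16}

    def test_reference_day14_direction_split(self):
        long = mir_de_long()
        sig = call_significant(long, 0.485, 0.01, use_adjusted=False)
        d14 = sig[sig["day"] == 14]
        assert int((d14["logFC"] > 0).sum()) == 14
        assert int((d14["logFC"] < 0).sum()) == 2

    def test_empty_results(self):
        empty = pd.DataFrame(columns=["feature", "day", "logFC", "p", "p_adj"])
        assert call_significant(empty, 0.5, 0.05).empty

    def test_threshold_validation(self):
        df = pd.DataFrame({"feature": ["a"], "day": [0], "logFC": [1.0], "p": [0.001], "p_adj": [0.01]})
        with pytest.raises(ParameterError):
            call_significant(df, -1.0, 0.05)
        with pytest.raises(ParameterError):
            call_significant(df, 0.5, 0.0)

    def test_significant_sets_directions(self):
        df = pd.DataFrame(
            {
                "feature": ["a", "b"],
                "day": [0, 0],
                "logFC": [1.2, -0.9],
                "p": [0.001, 0.002],
                "p_adj": [0.01, 0.02],
            }
        )
        sets = significant_sets(df)
        assert sets[0] == {"a": "up", "b": "down"}
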