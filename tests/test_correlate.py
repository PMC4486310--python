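"""Pearson screening: coefficient, asymptotic p-value, per-day records, filter."""

import math

import numpy as np
import pandas as pd
import pytest

from mirmint.correlate import (
    correlate_day,
    correlation_pvalue,
    filter_correlations,
    pearson_r,
)
from mirmint.errors import DegenerateInputError, PairingError, ParameterError
from mirmint.io import ExpressionMatrix
from mirmint.simulate import SimulationConfig, generate_dataset


class TestPearsonR:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_sums(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        # independent arithmetic straight from the product-moment definition
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-9)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r)
        assert pearson_r(2.5 * x + 1, y) == pytest.approx(r)
        assert pearson_r(-2.5 * x + 1, y) == pytest.approx(-r)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


class TestPValue:
    def test_extremes(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)
        assert correlation_pvalue(1.0, 5) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_r095_n4_near_05(self):
        assert correlation_pvalue(0.95, 4) == pytest.approx(0.05, abs=0.005)

    def test_strictly_decreasing_in_abs_r(self):
        ps = [correlation_pvalue(r, 6) for r in np.linspace(0.0, 0.99, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_decreasing_in_n(self):
        ps = [correlation_pvalue(0.5, n) for n in (4, 6, 10, 20, 50)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            correlation_pvalue(0.5, 2)

    def test_fisher_z_alternative(self):
        # same direction of evidence, different approximation
        assert correlation_pvalue(0.9, 10, "fisher-z") < 0.01
        with pytest.raises(ParameterError):
            correlation_pvalue(0.5, 10, "spearman")


def _paired_matrices(design, mir_rows, gene_rows):
    mirs = ExpressionMatrix(
        pd.DataFrame.from_dict(mir_rows, orient="index", columns=design.samples),
        platform="mir",
    )
    genes = ExpressionMatrix(
        pd.DataFrame.from_dict(gene_rows, orient="index", columns=design.samples),
        platform="gene",
    )
    return mirs, genes


class TestCorrelateDay:
    def test_cardinality(self, design):
        rng = np.random.default_rng(1)
        mirs, genes = _paired_matrices(
            design,
            {f"m{i}": rng.normal(8, 1, 12) for i in range(2)},
            {f"p{i}": rng.normal(8, 1, 12) for i in range(3)},
        )
        rec = correlate_day(mirs, genes, design, 0, ["m0", "m1"], ["p0", "p1", "p2"])
        assert len(rec) == 6
        assert set(rec["day"]) == {0}

    def test_column_order_invariance(self, design):
        rng = np.random.default_rng(2)
        mirs, genes = _paired_matrices(
            design,
            {"m0": rng.normal(8, 1, 12)},
            {"p0": rng.normal(8, 1, 12)},
        )
        rec1 = correlate_day(mirs, genes, design, 7, ["m0"], ["p0"])
        shuffled = ExpressionMatrix(genes.data.iloc[:, ::-1], platform="gene")
        rec2 = correlate_day(mirs, shuffled, design, 7, ["m0"], ["p0"])
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_constant_vector_skipped_with_warning(self, design, caplog):
        rng = np.random.default_rng(4)
        mirs, genes = _paired_matrices(
            design,
            {"m0": rng.normal(8, 1, 12)},
            {"flat": np.full(12, 5.0), "p0": rng.normal(8, 1, 12)},
        )
        with caplog.at_level("WARNING"):
            rec = correlate_day(mirs, genes, design, 0, ["m0"], ["flat", "p0"])
        assert list(rec["probe"]) == ["p0"]
        assert "constant" in caplog.text

    def test_unpaired_samples_raise(self, design):
        rng = np.random.default_rng(5)
        mirs, genes = _paired_matrices(
            design, {"m0": rng.normal(8, 1, 12)}, {"p0": rng.normal(8, 1, 12)}
        )
        mirs_broken = ExpressionMatrix(
            mirs.data.rename(columns={design.samples[0]: "alien"}), platform="mir"
        )
        with pytest.raises(PairingError):
            correlate_day(mirs_broken, genes, design, 0, ["m0"], ["p0"])

    def test_planted_negative_couple_sign(self):
        """A repressive couple at beta=1.5, sigma=0.1 correlates negatively
        in nearly all replicate simulations."""
        n_neg = 0
        n_total = 0
        for seed in range(100):
            cfg = SimulationConfig(
                n_probes=60, n_genes=50, n_mirs=10, n_de_mirs=2,
                targets_per_mir=(3, 5), beta=1.5, sigma=0.1, seed=seed,
            )
            ds = generate_dataset(cfg)
            neg = [(m, g) for m, g, s in ds.truth.true_couples if s == "negative"]
            if not neg:
                continue
            mir, gene = neg[0]
            probe = next(p for p, g in ds.genes.probe_to_gene.items() if g == gene)
            rec = correlate_day(ds.mirs, ds.genes, ds.design, 0, [mir], [probe])
            n_total += 1
            if rec["r"].iloc[0] < 0:
                n_neg += 1
        assert n_total >= 90
        assert n_neg / n_total >= 0.95


class TestFilter:
    def _records(self, rows):
        return pd.DataFrame(
            [
                {"mir": "m", "probe": f"p{i}", "gene": f"g{i}", "day": 0,
                 "r": r, "p": p, "sign": "positive" if r >= 0 else "negative",
                 "significant": False}
                for i, (r, p) in enumerate(rows)
            ]
        )

    def test_boundary_inclusive_and_conjunction(self):
        rec = self._records([(0.7, 0.04), (0.99, 0.2), (-0.7, 0.05), (0.69, 0.001)])
        out = filter_correlations(rec)
        assert set(out["probe"]) == {"p0", "p2"}
        assert out["significant"].all()

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(9)
        rows = [(float(rng.uniform(-1, 1)), float(rng.uniform(0, 1))) for _ in range(10)]
        rec = self._records(rows)
        out = filter_correlations(rec, r_min=0.6, p_max=0.1)
        expected = {f"p{i}" for i, (r, p) in enumerate(rows) if abs(r) >= 0.6 and p <= 0.1}
        assert set(out["probe"]) == expected

    def test_parameter_validation(self):
        rec = self._records([(0.5, 0.5)])
        with pytest.raises(ParameterError):
            filter_correlations(rec, r_min=-0.1)
        with pytest.raises(ParameterError):
            filter_correlations(rec, p_max=0.0)
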