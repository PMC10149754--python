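"""Signature scoring, pseudo-TPM normalization and PD-L1 analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorio.signatures import (
    CorrelationResult,
    ExpressionMatrix,
    GeneSignature,
    QuantileReference,
    correlate_pdl1_with_signature,
    expression_score,
    metabolic_activity_score,
    pdl1_positive_fraction,
    pseudo_tpm_normalize,
)


class TestGeneSignature:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSignature([("A", 1.0), ("A", 2.0)])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            GeneSignature([("A", 0.0), ("B", 0.0)])

    def test_tsv_round_trip(self, tmp_path):
        sig = GeneSignature(
            [("VEGFA", 1.5), ("HIF1A", 0.5), ("SLC2A1", -1.0)],
            name="angio",
            role="angiogenesis",
        )
        path = tmp_path / "angio.tsv"
        sig.to_tsv(path)
        back = GeneSignature.from_tsv(path)
        assert back.entries == sig.entries
        assert back.role == "angiogenesis"


class TestExpressionScore:
    @pytest.mark.parametrize(
        "entries, profile, expected",
        [
            # one positive, one negative gene: 2.0 - 0.5
            ([("A", 1.0), ("B", -1.0)], {"A": 2.0, "B": 0.5}, 1.5),
            # weighted positive mean (6+0)/3 minus negative mean 1
            ([("A", 2.0), ("B", 1.0), ("C", -1.0)], {"A": 3.0, "B": 0.0, "C": 1.0}, 1.0),
            # positive-only group: plain weighted mean
            ([("A", 1.0), ("B", 3.0)], {"A": 0.0, "B": 2.0}, 1.5),
            # negative-only group: minus the weighted mean
            ([("A", -2.0)], {"A": 1.5}, -1.5),
        ],
    )
    def test_direct_formula(self, entries, profile, expected):
        assert expression_score(GeneSignature(entries), profile) == pytest.approx(expected)

    def test_missing_gene_policies(self):
        sig = GeneSignature([("A", 1.0), ("B", 1.0)])
        with pytest.raises(KeyError, match="absent"):
            expression_score(sig, {"A": 1.0})
        # drop-and-renormalize: remaining positive gene is the whole mean
        assert expression_score(sig, {"A": 3.0}, missing="drop") == pytest.approx(3.0)

    @given(
        shift=st.floats(-5, 5),
        e=st.lists(st.floats(0, 4), min_size=4, max_size=4),
    )
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance_with_both_sign_groups(self, shift, e):
        """Adding a constant to every log-expression cancels between the
        positive and negative group means."""
        sig = GeneSignature([("A", 1.0), ("B", 2.0), ("C", -0.5), ("D", -1.5)])
        genes = ["A", "B", "C", "D"]
        base = expression_score(sig, dict(zip(genes, e)))
        shifted = expression_score(sig, dict(zip(genes, [x + shift for x in e])))
        assert shifted == pytest.approx(base, abs=1e-9)

    @given(e=st.lists(st.floats(0, 4), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_score_bounds(self, e):
        """Score lies between (min positive E - max negative E) and
        (max positive E - min negative E): each term is a convex
        combination."""
        sig = GeneSignature([("A", 1.0), ("B", 2.0), ("C", -0.5), ("D", -1.5)])
        genes = ["A", "B", "C", "D"]
        s = expression_score(sig, dict(zip(genes, e)))
        lo = min(e[0], e[1]) - max(e[2], e[3])
        hi = max(e[0], e[1]) - min(e[2], e[3])
        assert lo - 1e-9 <= s <= hi + 1e-9

    def test_metabolic_activity_is_sum_of_subscores(self):
        rng = np.random.default_rng(0)
        primary = GeneSignature([("A", 1.0), ("B", -1.0)], role="primary_metabolism")
        secondary = GeneSignature([("C", 2.0), ("D", 1.0)], role="secondary_metabolism")
        profile = dict(zip("ABCD", rng.uniform(0, 3, size=4)))
        total = metabolic_activity_score(primary, secondary, profile)
        assert total == pytest.approx(
            expression_score(primary, profile) + expression_score(secondary, profile)
        )


class TestPseudoTpmNormalize:
    @staticmethod
    def _log_matrix(values: dict) -> ExpressionMatrix:
        return ExpressionMatrix(pd.DataFrame(values).T, unit="log10_tpm_plus1")

    def test_identity_when_quantiles_match(self):
        x = np.linspace(0.0, 2.0, 11)
        mat = self._log_matrix({"G": x})
        ref = QuantileReference(
            q0=pd.Series({"G": x.min()}),
            q90=pd.Series({"G": np.quantile(x, 0.9)}),
        )
        out = pseudo_tpm_normalize(mat, ref)
        np.testing.assert_allclose(out.values.loc["G"], x)

    def test_affine_map_doubles(self):
        x = np.linspace(0.0, 2.0, 11)  # observed quantiles (0, 1.8)
        mat = self._log_matrix({"G": x})
        ref = QuantileReference(
            q0=pd.Series({"G": 0.0}), q90=pd.Series({"G": 2 * np.quantile(x, 0.9)})
        )
        out = pseudo_tpm_normalize(mat, ref)
        np.testing.assert_allclose(out.values.loc["G"], 2 * x)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, size=50)
        mat = self._log_matrix({"G": x})
        ref = QuantileReference(q0=pd.Series({"G": 0.5}), q90=pd.Series({"G": 4.0}))
        out = pseudo_tpm_normalize(mat, ref).values.loc["G"].to_numpy()
        assert (np.argsort(out) == np.argsort(x)).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        raw = ExpressionMatrix(
            pd.DataFrame({"G": rng.uniform(0, 500, size=40), "H": rng.uniform(0, 80, 40)}).T,
            unit="raw_intensity",
        )
        ref = QuantileReference(
            q0=pd.Series({"G": 0.0, "H": 0.2}), q90=pd.Series({"G": 2.5, "H": 1.8})
        )
        once = pseudo_tpm_normalize(raw, ref)
        twice = pseudo_tpm_normalize(once, ref)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_zero_spread_gene_warns_and_maps_to_q0(self):
        mat = self._log_matrix({"G": np.full(10, 1.3)})
        ref = QuantileReference(q0=pd.Series({"G": 0.4}), q90=pd.Series({"G": 2.0}))
        with pytest.warns(UserWarning, match="zero spread"):
            out = pseudo_tpm_normalize(mat, ref)
        np.testing.assert_allclose(out.values.loc["G"], 0.4)

    def test_missing_reference_gene_errors(self):
        mat = self._log_matrix({"G": np.arange(5.0)})
        ref = QuantileReference(q0=pd.Series({"H": 0.0}), q90=pd.Series({"H": 1.0}))
        with pytest.raises(KeyError, match="absent"):
            pseudo_tpm_normalize(mat, ref)


class TestPdl1:
    def test_positive_fraction_counts_strictly_above_one(self, tiny_matrix):
        # CD274 TPMs are [0.5, 2, 3, 0] -> 2 of 4 strictly above 1
        assert pdl1_positive_fraction(tiny_matrix) == pytest.approx(0.5)

    def test_all_zero_and_boundary(self):
        zeros = ExpressionMatrix(
            pd.DataFrame({"c1": [0.0], "c2": [0.0]}, index=["CD274"]), unit="TPM"
        )
        assert pdl1_positive_fraction(zeros) == 0.0
        ones = ExpressionMatrix(
            pd.DataFrame({"c1": [1.0], "c2": [1.0]}, index=["CD274"]), unit="TPM"
        )
        assert pdl1_positive_fraction(ones) == 0.0  # strict inequality

    def test_requires_tpm_units_and_gene_presence(self, tiny_matrix):
        with pytest.raises(KeyError):
            pdl1_positive_fraction(tiny_matrix, pdl1_gene="PDCD1")
        logm = tiny_matrix.to_log10_tpm()
        with pytest.raises(ValueError, match="TPM"):
            pdl1_positive_fraction(logm)


class TestCorrelation:
    def test_affine_signature_gives_r_one(self):
        rng = np.random.default_rng(3)
        pdl1_log = rng.uniform(0, 2, size=100)
        tpm = 10.0**pdl1_log - 1.0
        # single positive gene tracking PD-L1 exactly -> score affine in PD-L1
        df = pd.DataFrame({"CD274": tpm, "G": tpm}).T
        df.columns = [f"c{i}" for i in range(100)]
        mat = ExpressionMatrix(df, unit="TPM")
        res = correlate_pdl1_with_signature(mat, GeneSignature([("G", 1.0)]))
        assert res.r == pytest.approx(1.0)
        assert res.n == 100

    def test_zero_variance_errors(self):
        df = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [1.0, 3.0], "c3": [1.0, 4.0]},
            index=["CD274", "G"],
        )
        mat = ExpressionMatrix(df, unit="TPM")
        with pytest.raises(ValueError, match="zero variance"):
            correlate_pdl1_with_signature(mat, GeneSignature([("G", 1.0)]))

    def test_needs_three_observations(self):
        df = pd.DataFrame({"c1": [1.0, 2.0], "c2": [2.0, 1.0]}, index=["CD274", "G"])
        with pytest.raises(ValueError, match="3 observations"):
            correlate_pdl1_with_signature(
                ExpressionMatrix(df, unit="TPM"), GeneSignature([("G", 1.0)])
            )

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrelationResult(r=1.5, p=0.5, n=10)
        with pytest.raises(ValueError):
            CorrelationResult(r=0.5, p=0.5, n=2)


class TestExpressionMatrixIO:
    def test_tsv_round_trip(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv.gz"
        tiny_matrix.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path, unit="TPM")
        pd.testing.assert_frame_equal(back.values, tiny_matrix.values)

    def test_mtx_round_trip(self, tiny_matrix, tmp_path):
        prefix = tmp_path / "m"
        tiny_matrix.to_mtx(prefix)
        back = ExpressionMatrix.from_mtx(prefix, unit="TPM")
        np.testing.assert_allclose(back.values, tiny_matrix.values)
        assert back.gene_ids == tiny_matrix.gene_ids
        assert back.obs_ids == tiny_matrix.obs_ids

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(pd.DataFrame({"c": [-1.0]}, index=["G"]), unit="TPM")
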