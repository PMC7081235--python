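"""NB Wald test, dispersion estimation, BH adjustment and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressregulon.core_io import ValidationError
from stressregulon.diffexp import (
    Contrast,
    bh_adjust,
    call_degs,
    estimate_dispersions,
    nb_wald,
)
from stressregulon.preprocess import size_factors

from conftest import make_experiment, two_group_experiment

CONTRAST = Contrast((None, None, "control"), (None, None, "early"))


def _ones_sf(exp):
    return pd.Series(1.0, index=exp.samples)


def _disp(exp, value):
    return pd.Series(value, index=exp.genes)


def _nb_draw(rng, mu, alpha, size):
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), size=size)


class TestDispersions:
    def test_poisson_genes_hit_floor_region(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(300, 8))
        exp = make_experiment(
            counts, timepoints=["control"] * 4 + ["early"] * 4,
            replicates=[1, 2, 3, 4, 1, 2, 3, 4])
        alpha = estimate_dispersions(exp, _ones_sf(exp))
        assert np.median(alpha) < 0.01

    def test_nb_alpha_point2_recovered_in_band(self):
        rng = np.random.default_rng(1)
        counts = _nb_draw(rng, 200.0, 0.2, (500, 8))
        exp = make_experiment(
            counts, timepoints=["control"] * 4 + ["early"] * 4,
            replicates=[1, 2, 3, 4, 1, 2, 3, 4])
        alpha = estimate_dispersions(exp, _ones_sf(exp))
        assert 0.1 <= np.median(alpha) <= 0.4

    def test_all_zero_gene_gets_trend_value(self):
        rng = np.random.default_rng(2)
        counts = _nb_draw(rng, 50.0, 0.1, (100, 8))
        counts[0] = 0
        exp = make_experiment(
            counts, timepoints=["control"] * 4 + ["early"] * 4,
            replicates=[1, 2, 3, 4, 1, 2, 3, 4])
        alpha = estimate_dispersions(exp, _ones_sf(exp))
        assert np.isfinite(alpha.iloc[0]) and alpha.iloc[0] > 0

    def test_single_replicate_cell_rejected(self):
        exp = make_experiment(np.ones((5, 3), dtype=int),
                              timepoints=["control", "control", "early"],
                              replicates=[1, 2, 1])
        with pytest.raises(ValidationError, match="<2 replicates"):
            estimate_dispersions(exp, _ones_sf(exp))


class TestNBWald:
    def test_identical_groups_null(self):
        block = np.array([[10, 20, 30, 40], [5, 5, 5, 5]])
        exp = two_group_experiment(block, block.copy())
        res = nb_wald(exp, CONTRAST, _disp(exp, 0.1), _ones_sf(exp))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_fourfold_means_give_lfc_2(self):
        rng = np.random.default_rng(3)
        ya = _nb_draw(rng, 100.0, 0.05, (200, 6))
        yb = _nb_draw(rng, 400.0, 0.05, (200, 6))
        exp = two_group_experiment(ya, yb)
        res = nb_wald(exp, CONTRAST, _disp(exp, 0.05), _ones_sf(exp))
        assert np.median(res["log2fc"]) == pytest.approx(2.0, abs=0.1)

    def test_swap_negates_lfc_and_preserves_p_exactly(self):
        rng = np.random.default_rng(4)
        ya = _nb_draw(rng, 80.0, 0.2, (50, 4))
        yb = _nb_draw(rng, 160.0, 0.2, (50, 4))
        exp = two_group_experiment(ya, yb)
        fwd = nb_wald(exp, CONTRAST, _disp(exp, 0.2), _ones_sf(exp))
        rev = nb_wald(exp, CONTRAST.swapped(), _disp(exp, 0.2), _ones_sf(exp))
        assert np.array_equal(fwd["log2fc"].to_numpy(),
                              -rev["log2fc"].to_numpy())
        assert np.array_equal(fwd["p"].to_numpy(), rev["p"].to_numpy())

    def test_all_zero_gene_is_null_row(self):
        ya = np.array([[0, 0, 0], [10, 12, 9]])
        yb = np.array([[0, 0, 0], [30, 29, 33]])
        exp = two_group_experiment(ya, yb)
        res = nb_wald(exp, CONTRAST, _disp(exp, 0.1), _ones_sf(exp))
        assert res.loc[0, "log2fc"] == 0.0 and res.loc[0, "p"] == 1.0

    def test_size_factor_offsets_remove_depth_effect(self):
        rng = np.random.default_rng(5)
        base = _nb_draw(rng, 100.0, 0.02, (300, 4))
        doubled = _nb_draw(rng, 200.0, 0.02, (300, 4))  # 2x depth, same biology
        exp = two_group_experiment(base, doubled)
        sf = pd.Series([1.0] * 4 + [2.0] * 4, index=exp.samples)
        res = nb_wald(exp, CONTRAST, _disp(exp, 0.02), sf)
        assert abs(np.median(res["log2fc"])) < 0.05

    def test_type_i_error_near_nominal_with_known_alpha(self):
        """Null NB data with the true dispersion: rejection at 0.05 ~ nominal."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(5):
            y = _nb_draw(rng, 150.0, 0.1, (400, 8))
            exp = two_group_experiment(y[:, :4], y[:, 4:])
            res = nb_wald(exp, CONTRAST, _disp(exp, 0.1), _ones_sf(exp))
            pvals.append(res["p"].to_numpy())
        rate = (np.concatenate(pvals) <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_agrees_with_reference_nb_implementation(self):
        """Independent cross-check against DESeq2's Python port on a planted
        two-group fixture: fold-change estimates track each other closely."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(7)
        G = 150
        mu = np.exp(rng.normal(4.5, 1.0, G)) + 5
        lfc = np.zeros(G)
        lfc[:30] = 2.0
        ya = _nb_draw(rng, mu[:, None], 0.05, (G, 4))
        yb = _nb_draw(rng, (mu * 2.0 ** lfc)[:, None], 0.05, (G, 4))
        exp = two_group_experiment(ya, yb)
        sf = size_factors(exp)
        disp = estimate_dispersions(exp, sf)
        ours = nb_wald(exp, CONTRAST, disp, sf)

        counts = pd.DataFrame(np.hstack([ya, yb]).T, columns=exp.genes)
        meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["condition", "B", "A"],
                               quiet=True)
            stats.summary()
        ref = stats.results_df["log2FoldChange"].to_numpy()
        corr = np.corrcoef(ours["log2fc"], ref)[0, 1]
        assert corr > 0.98
        # both recover the planted effect
        assert np.median(ours["log2fc"][:30]) == pytest.approx(2.0, abs=0.2)
        assert np.median(ref[:30]) == pytest.approx(2.0, abs=0.2)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.1, np.nan]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_dominates_raw_and_preserves_rank_order(self, ps):
        p = np.array(ps)
        padj = bh_adjust(p)
        assert np.all(padj >= p - 1e-15)
        assert np.all(padj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(padj[order]) >= -1e-15)


class TestCallDegs:
    def _frame(self, padj, lfc):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(padj))],
                             "log2fc": lfc, "p": padj, "padj": padj})

    def test_boundary_inclusive(self):
        table, up, _ = call_degs(self._frame([0.01], [0.5]))
        assert table["deg_call"].tolist() == ["up"]
        assert "g0" in up

    def test_small_p_small_fc_not_called(self):
        table, up, down = call_degs(self._frame([0.009], [-0.4]))
        assert table["deg_call"].tolist() == ["ns"]
        assert not up.genes and not down.genes

    def test_up_down_disjoint(self):
        rng = np.random.default_rng(8)
        table = self._frame(rng.uniform(0, 0.05, 50),
                            rng.normal(0, 1, 50))
        _, up, down = call_degs(table)
        assert not (up.genes & down.genes)

    def test_planted_recovery_single_contrast(self):
        """Planted lfc-2 genes at 4v4: sensitivity >= 0.9, FDR <= 0.05."""
        rng = np.random.default_rng(9)
        G, n_de = 500, 60
        mu = np.exp(rng.normal(5.0, 1.0, G)) + 20
        lfc = np.zeros(G)
        lfc[:n_de] = 2.0
        ya = _nb_draw(rng, mu[:, None], 0.05, (G, 4))
        yb = _nb_draw(rng, (mu * 2.0 ** lfc)[:, None], 0.05, (G, 4))
        exp = two_group_experiment(ya, yb)
        sf = size_factors(exp)
        disp = estimate_dispersions(exp, sf)
        res = nb_wald(exp, CONTRAST, disp, sf)
        table, up, _ = call_degs(res)
        called = {int(g[1:]) for g in up.genes}
        tp = len(called & set(range(n_de)))
        assert tp / n_de >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.05
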