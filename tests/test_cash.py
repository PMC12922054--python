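"""ADSV and the CASh resampling procedure."""

from itertools import combinations

import numpy as np
import pytest

from microgame import (
    CashConfig,
    DataError,
    ExpressionMatrix,
    GroupLabels,
    adsv,
    binarize,
    cash_pvalues,
    resample_labels,
    shapley_values,
    split_by_group,
)


class TestAdsv:
    def test_worked_example_values(self, table1):
        from conftest import ADSV_OVER, ADSV_UNDER

        X, labels = table1

        def observed(direction):
            B = binarize(X, labels, direction)
            B_ctrl, B_exp = split_by_group(B, labels)
            return adsv(shapley_values(B_ctrl).phi, shapley_values(B_exp).phi)

        np.testing.assert_array_equal(np.round(observed("over"), 3), ADSV_OVER)
        np.testing.assert_array_equal(np.round(observed("under"), 3), ADSV_UNDER)

    def test_identical_vectors_give_zero(self):
        phi = np.array([0.1, 0.2, 0.0])
        assert (adsv(phi, phi) == 0).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            adsv(np.zeros(3), np.zeros(4))


class TestResampleLabels:
    def _labels(self, n_control, n_experimental):
        assignment = {f"C{i}": "control" for i in range(n_control)}
        assignment.update({f"E{i}": "case" for i in range(n_experimental)})
        return GroupLabels(assignment)

    def test_permute_preserves_group_sizes(self):
        labels = self._labels(5, 5)
        rng = np.random.default_rng(0)
        for _ in range(100):
            new = resample_labels(labels, "permute_labels", rng)
            assert new.n_control == 5 and new.n_experimental == 5
            assert set(new.assignment) == set(labels.assignment)

    def test_seeded_reproducibility(self):
        labels = self._labels(4, 3)
        seq1 = [resample_labels(labels, "permute_labels", np.random.default_rng(42)).assignment
                for _ in range(1)]
        seq2 = [resample_labels(labels, "permute_labels", np.random.default_rng(42)).assignment
                for _ in range(1)]
        assert seq1 == seq2

    def test_permute_uniform_over_balanced_assignments(self):
        """2 controls + 1 experimental: each of the 3 balanced relabelings
        appears with frequency ~1/3."""
        labels = self._labels(2, 1)
        rng = np.random.default_rng(123)
        counts = {}
        n_draws = 3000
        for _ in range(n_draws):
            new = resample_labels(labels, "permute_labels", rng)
            key = tuple(sorted(s for s, v in new.assignment.items() if v == "control"))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / n_draws - 1 / 3) < 0.04  # ~4.6 sigma

    def test_bootstrap_respects_degeneracy_constraints(self):
        labels = self._labels(3, 2)
        rng = np.random.default_rng(7)
        for _ in range(200):
            new = resample_labels(labels, "bootstrap_labels", rng)
            assert new.n_control >= 2 and new.n_experimental >= 1

    def test_bootstrap_sizes_vary(self):
        labels = self._labels(5, 5)
        rng = np.random.default_rng(1)
        sizes = {resample_labels(labels, "bootstrap_labels", rng).n_control
                 for _ in range(100)}
        assert len(sizes) > 1


class TestCashPvalues:
    def test_zero_adsv_forces_p_one(self, table1):
        X, labels = table1
        for seed in (0, 17):
            comp = cash_pvalues(X, labels, "over",
                                CashConfig(n_resamples=25, seed=seed))
            assert comp.adsv[1] == 0.0          # gene2 never over-expressed
            assert comp.p[1] == 1.0
            assert (comp.p[comp.adsv == 0.0] == 1.0).all()

    def test_determinism_same_seed(self, table1):
        X, labels = table1
        cfg = CashConfig(n_resamples=100, seed=5)
        p1 = cash_pvalues(X, labels, "under", cfg).p
        p2 = cash_pvalues(X, labels, "under", cfg).p
        np.testing.assert_array_equal(p1, p2)

    def test_p_in_unit_interval(self, table1):
        X, labels = table1
        comp = cash_pvalues(X, labels, "under", CashConfig(n_resamples=37, seed=2))
        assert ((comp.p >= 0) & (comp.p <= 1)).all()

    def test_add_one_correction_bounds(self, table1):
        X, labels = table1
        B = 40
        comp = cash_pvalues(
            X, labels, "under",
            CashConfig(n_resamples=B, seed=2, add_one_correction=True),
        )
        assert (comp.p >= 1 / (B + 1)).all() and (comp.p <= 1.0).all()

    def test_exchangeable_groups_give_trivial_pvalues(self):
        """When control and experimental columns are identical copies the
        observed ADSV is 0 for every gene, so every p-value is 1."""
        rng = np.random.default_rng(3)
        half = rng.normal(size=(5, 3))
        X = ExpressionMatrix(
            tuple(f"g{i}" for i in range(5)),
            ("C1", "C2", "C3", "E1", "E2", "E3"),
            np.concatenate([half, half], axis=1),
        )
        labels = GroupLabels({s: ("control" if s.startswith("C") else "case")
                              for s in X.sample_ids})
        comp = cash_pvalues(X, labels, "under", CashConfig(n_resamples=30, seed=0))
        assert (comp.adsv == 0).all() and (comp.p == 1.0).all()

    def test_fixed_matrix_mode_runs_and_is_deterministic(self, table1):
        X, labels = table1
        cfg = CashConfig(n_resamples=60, seed=9, recompute_binarization=False)
        p1 = cash_pvalues(X, labels, "under", cfg).p
        p2 = cash_pvalues(X, labels, "under", cfg).p
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_bh_adjustment_monotone_and_bounded(self, table1):
        X, labels = table1
        comp = cash_pvalues(
            X, labels, "under",
            CashConfig(n_resamples=200, seed=4, adjust="benjamini_hochberg"),
        )
        assert comp.p_adjusted is not None
        assert ((comp.p_adjusted >= comp.p - 1e-12)
                & (comp.p_adjusted <= 1.0 + 1e-12)).all()

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Independent oracle: on a 4-sample problem the 6 balanced
        relabelings can be enumerated; the Monte-Carlo p-values must agree
        within sampling error."""
        rng = np.random.default_rng(11)
        values = rng.normal(loc=4.0, scale=0.2, size=(5, 4))
        X = ExpressionMatrix(
            tuple(f"g{i}" for i in range(5)), ("C1", "C2", "E1", "E2"), values
        )
        labels = GroupLabels({"C1": "control", "C2": "control",
                              "E1": "case", "E2": "case"})

        def adsv_for(ctrl_cols):
            ctrl = values[:, list(ctrl_cols)]
            exp_cols = [j for j in range(4) if j not in ctrl_cols]
            mu = ctrl.mean(axis=1, keepdims=True)
            sd = ctrl.std(axis=1, ddof=1, keepdims=True)
            bits = (values <= mu - sd).astype(float)

            def phi(cols):
                sub = bits[:, cols]
                sizes = np.maximum(sub.sum(axis=0), 1.0)
                return (sub / sizes).mean(axis=1)

            return np.abs(phi(list(ctrl_cols)) - phi(exp_cols))

        observed = adsv_for((0, 1))
        exact = np.zeros(5)
        for ctrl_cols in combinations(range(4), 2):
            exact += adsv_for(ctrl_cols) >= observed - 1e-12
        exact /= 6.0

        B = 3000
        comp = cash_pvalues(X, labels, "under", CashConfig(n_resamples=B, seed=21))
        # 3-sigma binomial tolerance per gene
        tol = 3 * np.sqrt(exact * (1 - exact) / B) + 1e-9
        np.testing.assert_array_less(np.abs(comp.p - exact), tol + 1e-9)
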