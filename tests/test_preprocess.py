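"""QC metric definitions, strict threshold semantics, normalization formula,
and the PCA contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from itlsig import (
    CountMatrix,
    QCThresholds,
    SimConfig,
    compute_qc,
    filter_cells,
    log_normalize,
    simulate_sc_counts,
    top_principal_components,
)
from itlsig.exceptions import EmptyResultError, ValidationError


class TestComputeQc:
    N_GENES, N_MITO = 2000, 200

    def qc_of(self, vec, **thr):
        m = CountMatrix(
            vec[:, None],
            [f"MT-{i}" if i < self.N_MITO else f"G{i}" for i in range(self.N_GENES)],
            ["c0"],
            np.arange(self.N_GENES) < self.N_MITO,
        )
        return compute_qc(m, QCThresholds(**thr) if thr else QCThresholds())

    def test_under_feature_threshold_fails(self):
        # 499 detected genes, 600 total counts, no mito
        v = np.zeros(self.N_GENES, dtype=np.int64)
        v[self.N_MITO : self.N_MITO + 499] = 1
        v[self.N_MITO] += 101
        qc = self.qc_of(v)
        assert qc.n_features.iloc[0] == 499 and qc.n_counts.iloc[0] == 600
        assert not qc.pass_qc.iloc[0]

    def test_high_mito_fails(self):
        # 800 detected genes, 2000 total, 500 mito -> 25% mito
        v = np.zeros(self.N_GENES, dtype=np.int64)
        v[0] = 500
        v[self.N_MITO : self.N_MITO + 799] = 1
        v[self.N_MITO] += 2000 - 500 - 799
        qc = self.qc_of(v)
        assert qc.n_features.iloc[0] == 800
        assert qc.pct_mito.iloc[0] == 25.0
        assert not qc.pass_qc.iloc[0]

    def test_boundaries_are_strict_so_boundary_cell_passes(self):
        # exactly 500 features, 500 counts, 20% mito -> pass
        v = np.zeros(self.N_GENES, dtype=np.int64)
        v[:100] = 1  # 100 mito genes at 1 count
        v[self.N_MITO : self.N_MITO + 400] = 1
        qc = self.qc_of(v)
        assert qc.n_features.iloc[0] == 500
        assert qc.n_counts.iloc[0] == 500
        assert qc.pct_mito.iloc[0] == 20.0
        assert qc.pass_qc.iloc[0]

    def test_all_zero_cell_defined_and_fails(self):
        qc = self.qc_of(np.zeros(self.N_GENES, dtype=np.int64))
        assert qc.n_features.iloc[0] == 0 and qc.pct_mito.iloc[0] == 0.0
        assert not qc.pass_qc.iloc[0]

    def test_invariant_under_gene_and_cell_permutation(self, rng):
        cfg = SimConfig(n_cells_per_state=10, n_background_genes=100, seed=1)
        m, _ = simulate_sc_counts(cfg)
        thr = QCThresholds(min_features=50, min_counts=100, max_pct_mito=20)
        base = compute_qc(m, thr)
        gp = rng.permutation(m.n_genes)
        cp = rng.permutation(m.n_cells)
        perm = CountMatrix(
            m.values[np.ix_(gp, cp)],
            [m.gene_ids[i] for i in gp],
            [m.cell_ids[i] for i in cp],
            m.mito_flags[gp],
        )
        got = compute_qc(perm, thr)
        pd.testing.assert_frame_equal(got.sort_index(), base.sort_index())


class TestFilterCells:
    def _matrix(self, seed=2):
        cfg = SimConfig(
            n_cells_per_state=10, n_background_genes=1200, frac_low_quality=0.1, seed=seed
        )
        return simulate_sc_counts(cfg)

    def test_all_pass_identity(self):
        m, _ = self._matrix()
        qc = compute_qc(m, QCThresholds(min_features=0, min_counts=0, max_pct_mito=100))
        out = filter_cells(m, qc)
        assert out.cell_ids == m.cell_ids
        assert np.array_equal(out.values, m.values)

    def test_removes_exactly_planted_low_quality_cells(self):
        m, truth = self._matrix()
        qc = compute_qc(m)
        removed = set(m.cell_ids) - set(filter_cells(m, qc).cell_ids)
        assert removed == set(truth.low_quality_cells)

    def test_idempotent(self):
        m, _ = self._matrix()
        once = filter_cells(m, compute_qc(m))
        twice = filter_cells(once, compute_qc(once))
        assert once.cell_ids == twice.cell_ids

    def test_zero_passing_cells_is_error(self):
        m, _ = self._matrix()
        qc = compute_qc(m, QCThresholds(min_features=10**6))
        with pytest.raises(EmptyResultError):
            filter_cells(m, qc)

    def test_input_unmodified(self):
        m, _ = self._matrix()
        before = m.values.copy()
        filter_cells(m, compute_qc(m))
        assert np.array_equal(m.values, before)


class TestLogNormalize:
    def test_formula_on_random_matrix_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 20, size=(20, 10))
        m = CountMatrix(
            counts, [f"G{i}" for i in range(20)], [f"c{i}" for i in range(10)],
            np.zeros(20, dtype=bool),
        )
        norm = log_normalize(m, scale=10_000.0)
        for g in range(20):
            for c in range(10):
                expected = np.log(1.0 + 10_000.0 * counts[g, c] / counts[:, c].sum())
                assert norm.values[g, c] == pytest.approx(expected, rel=1e-12)

    def test_zero_count_gives_zero_and_unit_case(self):
        # total == scale, so a count of 1 -> log 2 and a count of 0 -> 0
        counts = np.array([[9_999], [1], [0]], dtype=np.int64)
        m = CountMatrix(counts, ["a", "b", "c"], ["c0"], np.zeros(3, bool))
        norm = log_normalize(m, scale=10_000.0)
        assert norm.values[2, 0] == 0.0
        assert norm.values[1, 0] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_zero_total_cell_rejected(self):
        m = CountMatrix(np.zeros((3, 2), dtype=np.int64), ["a", "b", "c"], ["c0", "c1"],
                        np.zeros(3, bool))
        with pytest.raises(ValidationError):
            log_normalize(m)

    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=4, max_size=12))
    def test_monotone_within_cell(self, col):
        if sum(col) == 0:
            return
        counts = np.array(col, dtype=np.int64)[:, None]
        m = CountMatrix(counts, [f"g{i}" for i in range(len(col))], ["c0"],
                        np.zeros(len(col), bool))
        v = log_normalize(m).values[:, 0]
        for i in range(len(col)):
            for j in range(len(col)):
                if col[i] > col[j]:
                    assert v[i] > v[j]


class TestTopPrincipalComponents:
    def test_rank_one_matrix_single_dominant_component(self, norm_factory):
        norm = norm_factory(20, 10, seed=5)
        u = np.linspace(1, 2, 20)[:, None]
        v = np.linspace(-1, 1, 10)[None, :]
        norm.values = np.abs(u * v) + 1.0
        coords = top_principal_components(norm, k=1)
        total_var = ((norm.values - norm.values.mean(1, keepdims=True)) ** 2).sum()
        assert (coords.to_numpy() ** 2).sum() / total_var > 0.999

    def test_full_rank_reconstruction(self, norm_factory):
        norm = norm_factory(8, 5, seed=6)
        centered = norm.values - norm.values.mean(axis=1, keepdims=True)
        k = np.linalg.matrix_rank(centered)
        coords = top_principal_components(norm, k=k)
        # energy captured by all components equals total centered energy
        assert (coords.to_numpy() ** 2).sum() == pytest.approx((centered**2).sum(), rel=1e-9)

    def test_component_variances_match_eigendecomposition(self, norm_factory):
        norm = norm_factory(30, 15, seed=7)
        coords = top_principal_components(norm, k=10)
        centered = (norm.values - norm.values.mean(axis=1, keepdims=True)).T
        eig = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1][:10]
        got = (coords.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(got, eig, rtol=1e-8)

    def test_k_exceeding_rank_rejected(self, norm_factory):
        norm = norm_factory(6, 4, seed=8)
        norm.values = np.ones((6, 4))  # centered rank 0
        with pytest.raises(ValidationError):
            top_principal_components(norm, k=2)
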