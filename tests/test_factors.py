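"""PCA, varimax rotation and question-to-biomarker assignment.

The k = 2 varimax oracle is an exhaustive 1-parameter search over the
planar rotation angle, independent of the gradient-projection routine the
implementation delegates to.
"""

import numpy as np
import pandas as pd
import pytest

from daymark import (
    QUESTIONS,
    assign_questions,
    principal_components,
    select_complete_days,
    varimax_rotate,
)
from daymark.factors import LoadingsMatrix

# Published rotated factor loadings for the 11 monitoring questions
# (Factor 1, Factor 2, Factor 3), used as a fixed assignment input.
ROTATED_LOADINGS = pd.DataFrame(
    {
        "Factor1": [0.79, 0.71, 0.74, 0.67, 0.62, 0.19, 0.12, 0.54, 0.72, 0.26, 0.15],
        "Factor2": [0.19, 0.06, 0.04, 0.17, 0.27, 0.05, 0.09, 0.10, 0.27, 0.85, 0.89],
        "Factor3": [0.21, 0.17, 0.18, 0.16, 0.19, 0.70, 0.74, -0.37, -0.09, 0.08, 0.06],
    },
    index=list(QUESTIONS),
)


def _varimax_criterion(L):
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def _grid_varimax_k2(A, n_grid=200_000):
    """Brute-force planar varimax with Kaiser normalization."""
    h = np.sqrt((A**2).sum(axis=1))
    An = A / h[:, None]
    thetas = np.linspace(0, np.pi / 2, n_grid, endpoint=False)
    best_theta, best_v = 0.0, -np.inf
    for th in thetas:
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v = _varimax_criterion(An @ R)
        if v > best_v:
            best_theta, best_v = th, v
    R = np.array(
        [[np.cos(best_theta), -np.sin(best_theta)],
         [np.sin(best_theta), np.cos(best_theta)]]
    )
    return (An @ R) * h[:, None]


def _planted_data(rng, n=2000, noise=0.5):
    """11 variables generated from 3 orthogonal latent factors, grouped as
    (6, 2, 3) in canonical question order blocks."""
    groups = [list(range(6)), [6, 7], [8, 9, 10]]
    F = rng.normal(size=(n, 3))
    X = np.empty((n, 11))
    for j, cols in enumerate(groups):
        for c in cols:
            X[:, c] = F[:, j] + noise * rng.normal(size=n)
    return X, groups


class TestCompleteDays:
    def test_counts_complete_rows(self):
        rows = []
        for q in QUESTIONS:
            rows.append(("p1", "2020-01-01", q, 50))
            rows.append(("p1", "2020-01-02", q, 75))
        rows.append(("p1", "2020-01-03", "Sleep", 50))  # partial day
        table = pd.DataFrame(rows, columns=["patient_id", "date", "question", "value"])
        complete = select_complete_days(table)
        assert len(complete) == 2
        assert list(complete.columns) == list(QUESTIONS)

    def test_no_complete_days(self):
        table = pd.DataFrame(
            [("p1", "2020-01-01", "Sleep", 50)],
            columns=["patient_id", "date", "question", "value"],
        )
        assert len(select_complete_days(table)) == 0


class TestPCA:
    def test_independent_columns_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20_000, 11))
        L = principal_components(X, k=11)
        np.testing.assert_allclose(L.full_spectrum, 1.0, atol=0.06)
        np.testing.assert_allclose(L.full_spectrum.sum(), 11.0, atol=1e-8)

    def test_two_perfectly_correlated_columns(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        L = principal_components(np.column_stack([a, 2 * a + 1]), k=2)
        np.testing.assert_allclose(L.full_spectrum, [2.0, 0.0], atol=1e-8)

    def test_loadings_scaled_to_eigenvalues(self):
        rng = np.random.default_rng(2)
        X, _ = _planted_data(rng)
        L = principal_components(X, k=3)
        np.testing.assert_allclose(
            (L.loadings.to_numpy() ** 2).sum(axis=0), L.eigenvalues, atol=1e-8
        )

    def test_constant_column_raises(self):
        X = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.raises(ValueError, match="zero variance"):
            principal_components(X)

    def test_planted_blocks_dominate(self):
        rng = np.random.default_rng(3)
        X, groups = _planted_data(rng)
        L = principal_components(X)
        assert L.k == 3  # eigenvalue > 1 criterion retains the 3 factors
        assert L.full_spectrum[2] > 1.0 > L.full_spectrum[3]


class TestVarimax:
    def test_rotation_matrix_orthonormal(self):
        rng = np.random.default_rng(4)
        X, _ = _planted_data(rng)
        R = varimax_rotate(principal_components(X, k=3))
        np.testing.assert_allclose(R.rotation.T @ R.rotation, np.eye(3), atol=1e-8)

    def test_communalities_preserved(self):
        rng = np.random.default_rng(5)
        X, _ = _planted_data(rng)
        L = principal_components(X, k=3)
        R = varimax_rotate(L)
        np.testing.assert_allclose(
            (R.loadings.to_numpy() ** 2).sum(axis=1),
            (L.loadings.to_numpy() ** 2).sum(axis=1),
            atol=1e-8,
        )

    def test_perfect_simple_structure_unchanged(self):
        A = np.zeros((6, 2))
        A[:3, 0] = [0.9, 0.8, 0.85]
        A[3:, 1] = [0.7, 0.75, 0.8]
        L = LoadingsMatrix(
            loadings=pd.DataFrame(A),
            eigenvalues=np.array([2.0, 1.5]),
            explained_pct=np.array([40.0, 30.0]),
            full_spectrum=np.array([2.0, 1.5, 0.5]),
        )
        R = varimax_rotate(L).loadings.to_numpy()
        cols = sorted(range(2), key=lambda j: -abs(R[0, j]))
        np.testing.assert_allclose(np.abs(R[:, cols]), A, atol=1e-6)

    def test_k2_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        A = rng.normal(scale=0.5, size=(8, 2))
        L = LoadingsMatrix(
            loadings=pd.DataFrame(A),
            eigenvalues=np.array([2.0, 1.0]),
            explained_pct=np.array([25.0, 12.5]),
            full_spectrum=np.ones(8),
        )
        R = varimax_rotate(L).loadings.to_numpy()
        O = _grid_varimax_k2(A)
        # align oracle columns/signs to the implementation
        perm = [int(np.argmax(np.abs(O.T @ R[:, j]))) for j in range(2)]
        assert sorted(perm) == [0, 1]
        aligned = O[:, perm] * np.sign(np.sum(O[:, perm] * R, axis=0))
        np.testing.assert_allclose(R, aligned, atol=1e-4)

    def test_single_component_rejected(self):
        L = LoadingsMatrix(
            loadings=pd.DataFrame(np.ones((4, 1))),
            eigenvalues=np.array([2.0]),
            explained_pct=np.array([50.0]),
            full_spectrum=np.ones(4),
        )
        with pytest.raises(ValueError, match="at least 2"):
            varimax_rotate(L)


class TestAssignment:
    def test_published_loadings_recover_biomarker_split(self):
        defs = {d.name: set(d.questions) for d in assign_questions(ROTATED_LOADINGS)}
        assert defs["MotSC-i"] == {"Motivation", "SelfConf"}
        assert defs["WeBe-i"] == set(QUESTIONS) - {"Motivation", "SelfConf"}

    def test_identity_merge_map_gives_disjoint_factors(self):
        defs = assign_questions(ROTATED_LOADINGS, {"A": [1], "B": [2], "C": [3]})
        all_q = [q for d in defs for q in d.questions]
        assert sorted(all_q) == sorted(QUESTIONS)
        assert {d.name: len(d.questions) for d in defs} == {"A": 7, "B": 2, "C": 2}

    def test_tie_breaks_to_lowest_factor(self):
        L = pd.DataFrame({"Factor1": [0.5], "Factor2": [-0.5]}, index=["Sleep"])
        defs = assign_questions(L, {"A": [1], "B": [2]})
        assert defs[0].questions == ("Sleep",)

    def test_out_of_range_factor_index(self):
        with pytest.raises(ValueError, match="out of range"):
            assign_questions(ROTATED_LOADINGS, {"A": [1, 4]})
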