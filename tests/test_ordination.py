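"""Correspondence-analysis machinery against independent oracles.

The chi-square/total-inertia identity is checked against scipy's Pearson
chi-square routine; CCA eigenvalues against a brute-force generalized-
eigenproblem oracle assembled from the weighted cross-product matrices; and
one fixed instance against R vegan (an entirely independent implementation).
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from scalepart import cca, chi_square_transform, drop_empty, partition_variance, pcca
from scalepart.environment import VariableGroup

from conftest import random_count_matrix


def brute_force_cca_eigenvalues(Y, X):
    """CCA eigenvalues via the generalized eigenproblem B⁻¹ A Aᵀ.

    A = Xwᵀ Q and B = Xwᵀ Xw are the weighted cross-product matrices; the
    nonzero eigenvalues of B⁻¹ A Aᵀ equal the squared singular values of the
    projection of Q onto span(Xw).  Deliberately a different route from the
    implementation (which projects and runs an SVD).
    """
    dec = chi_square_transform(Y)
    r = dec.row_masses
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc
    A = Xw.T @ dec.Q
    B = Xw.T @ Xw
    vals = np.linalg.eigvals(np.linalg.solve(B, A @ A.T))
    vals = np.real(vals)
    return np.sort(vals[vals > 1e-12])[::-1]


class TestChiSquareTransform:
    def test_independence_table_has_zero_inertia(self):
        dec = chi_square_transform(np.array([[1, 1], [1, 1]]))
        assert dec.total_inertia == pytest.approx(0.0, abs=1e-15)

    def test_diagonal_table_inertia_is_one(self):
        # chi-square of [[2,0],[0,2]] is 4, grand total 4
        dec = chi_square_transform(np.array([[2, 0], [0, 2]]))
        assert dec.total_inertia == pytest.approx(1.0, abs=1e-12)

    def test_masses_sum_to_one(self):
        rng = np.random.default_rng(0)
        Y = random_count_matrix(rng)
        dec = chi_square_transform(Y)
        assert dec.row_masses.sum() == pytest.approx(1.0)
        assert dec.col_masses.sum() == pytest.approx(1.0)

    def test_inertia_equals_pearson_chisq_over_total(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            Y = random_count_matrix(rng)
            expected = stats.chi2_contingency(Y, correction=False).statistic / Y.sum()
            got = chi_square_transform(Y).total_inertia
            worst = max(worst, abs(got - expected))
        assert worst < 1e-10

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            chi_square_transform(np.zeros((3, 3)))

    def test_zero_rows_must_be_dropped_first(self):
        Y = np.array([[1, 2], [0, 0], [3, 1]])
        with pytest.raises(ValueError, match="drop_empty"):
            chi_square_transform(Y)
        Yr, rows, cols = drop_empty(Y)
        assert Yr.shape == (2, 2)
        assert rows.tolist() == [True, False, True]


class TestCCA:
    def test_saturated_indicators_capture_total_inertia(self):
        rng = np.random.default_rng(1)
        Y = random_count_matrix(rng, max_rows=8, max_cols=6)
        res = cca(Y, np.eye(Y.shape[0]))
        assert res.constrained_inertia == pytest.approx(res.total_inertia, rel=1e-10)

    def test_constant_column_explains_nothing(self):
        rng = np.random.default_rng(2)
        Y = random_count_matrix(rng, max_rows=8, max_cols=6)
        res = cca(Y, np.ones((Y.shape[0], 1)))
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.rank == 0

    def test_eigenvalues_match_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        Y = rng.integers(0, 8, size=(6, 4)).astype(float) + 1
        X = rng.normal(size=(6, 2))
        res = cca(Y, X)
        oracle = brute_force_cca_eigenvalues(Y, X)
        assert res.eigenvalues == pytest.approx(oracle, abs=1e-10)

    def test_eigenvalues_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Y = random_count_matrix(rng, max_rows=12, max_cols=8)
            X = rng.normal(size=(Y.shape[0], 3))
            res = cca(Y, X)
            assert (np.diff(res.eigenvalues) <= 1e-12).all()
            assert -1e-10 <= res.constrained_inertia <= res.total_inertia + 1e-10

    def test_adding_a_column_never_decreases_constrained_inertia(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Y = random_count_matrix(rng, max_rows=12, max_cols=8)
            X = rng.normal(size=(Y.shape[0], 2))
            extra = rng.normal(size=(Y.shape[0], 1))
            base = cca(Y, X).constrained_inertia
            bigger = cca(Y, np.hstack([X, extra])).constrained_inertia
            assert bigger >= base - 1e-10


class TestPartialCCA:
    def test_empty_condition_reduces_to_cca(self):
        rng = np.random.default_rng(5)
        Y = random_count_matrix(rng)
        X = rng.normal(size=(Y.shape[0], 2))
        assert pcca(Y, X, None).constrained_inertia == pytest.approx(
            cca(Y, X).constrained_inertia
        )

    def test_x_inside_span_of_z_explains_nothing(self):
        rng = np.random.default_rng(6)
        Y = random_count_matrix(rng)
        Z = rng.normal(size=(Y.shape[0], 2))
        X = Z @ rng.normal(size=(2, 2))  # X ⊂ span(Z)
        assert pcca(Y, X, Z).constrained_inertia == pytest.approx(0.0, abs=1e-10)

    def test_additivity_identity_on_random_instances(self):
        # pcca(Y, X | Z) = cca(Y, [X Z]) − cca(Y, Z), an exact projection identity
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            Y = random_count_matrix(rng, max_rows=15, max_cols=10)
            X = rng.normal(size=(Y.shape[0], rng.integers(1, 4)))
            Z = rng.normal(size=(Y.shape[0], rng.integers(1, 4)))
            lhs = pcca(Y, X, Z).constrained_inertia
            rhs = (
                cca(Y, np.hstack([X, Z])).constrained_inertia
                - cca(Y, Z).constrained_inertia
            )
            worst = max(worst, abs(lhs - rhs))
        assert worst < 1e-8


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestVeganCrossCheck:
    """One fixed instance against the vegan package (independent implementation)."""

    def test_cca_and_pcca_match_vegan(self, tmp_path):
        rng = np.random.default_rng(42)
        Y = rng.integers(0, 8, size=(10, 6)).astype(float)
        Y[0, :] += 1
        X = rng.normal(size=(10, 3))
        Z = rng.normal(size=(10, 2))
        Yr, rows, _ = drop_empty(Y)
        Xr, Zr = X[rows], Z[rows]

        np.savetxt(tmp_path / "Y.csv", Yr, delimiter=",")
        np.savetxt(tmp_path / "XZ.csv", np.hstack([Xr, Zr]), delimiter=",")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            Y <- as.matrix(read.csv(file.path(args[1], "Y.csv"), header=FALSE))
            d <- as.data.frame(read.csv(file.path(args[1], "XZ.csv"), header=FALSE))
            colnames(d) <- c("a","b","c","d","e")
            m <- cca(Y ~ a+b+c, data=d)
            mp <- cca(Y ~ a+b+c + Condition(d+e), data=d)
            cat(sprintf("%.12f %.12f %.12f\\n", m$tot.chi, m$CCA$tot.chi, mp$CCA$tot.chi))
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path)],
            capture_output=True,
            text=True,
            check=True,
        )
        vegan_total, vegan_cca, vegan_pcca = map(float, out.stdout.split())

        res = cca(Yr, Xr)
        pres = pcca(Yr, Xr, Zr)
        assert res.total_inertia == pytest.approx(vegan_total, abs=1e-9)
        assert res.constrained_inertia == pytest.approx(vegan_cca, abs=1e-9)
        assert pres.constrained_inertia == pytest.approx(vegan_pcca, abs=1e-9)


class TestPartitionVariance:
    @staticmethod
    def _groups(names_and_members):
        return [VariableGroup(n, tuple(m)) for n, m in names_and_members]

    def test_orthogonal_groups_have_no_overlap(self):
        # constraints orthogonalized under row-mass weighting → exclusive
        # fractions add up to the joint fraction
        rng = np.random.default_rng(8)
        Y = random_count_matrix(rng, max_rows=15, max_cols=10)
        n = Y.shape[0]
        dec = chi_square_transform(Y)
        r = dec.row_masses
        raw = rng.normal(size=(n, 4))
        # weighted Gram–Schmidt against the intercept and each other
        cols = []
        w = np.sqrt(r)
        basis = [w / np.linalg.norm(w)]
        for j in range(raw.shape[1]):
            v = w * raw[:, j]
            for b in basis:
                v = v - (b @ v) * b
            v = v / np.linalg.norm(v)
            basis.append(v)
            cols.append(v / w)  # undo the weighting so pcca re-applies it
        X = np.column_stack(cols)
        import pandas as pd

        env = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        groups = self._groups([("g1", ["a", "b"]), ("g2", ["c", "d"])])
        part = partition_variance(Y, env, groups)
        assert part.overlap_pct == pytest.approx(0.0, abs=1e-8)
        assert sum(part.exclusive_pct.values()) == pytest.approx(
            part.joint_pct, abs=1e-8
        )

    def test_duplicated_groups_share_everything(self):
        rng = np.random.default_rng(9)
        Y = random_count_matrix(rng, max_rows=12, max_cols=8)
        import pandas as pd

        x = rng.normal(size=Y.shape[0])
        env = pd.DataFrame({"a": x, "b": x})
        groups = self._groups([("g1", ["a"]), ("g2", ["b"])])
        part = partition_variance(Y, env, groups)
        assert part.exclusive_pct["g1"] == pytest.approx(0.0, abs=1e-8)
        assert part.exclusive_pct["g2"] == pytest.approx(0.0, abs=1e-8)
        assert part.overlap_pct == pytest.approx(part.joint_pct, abs=1e-8)

    def test_saturated_single_group_explains_everything(self):
        rng = np.random.default_rng(10)
        Y = random_count_matrix(rng, max_rows=6, max_cols=8)
        import pandas as pd

        n = Y.shape[0]
        env = pd.DataFrame(np.eye(n), columns=[f"i{k}" for k in range(n)])
        groups = self._groups([("g1", [f"i{k}" for k in range(n)])])
        part = partition_variance(Y, env, groups)
        assert part.exclusive_pct["g1"] == pytest.approx(100.0, abs=1e-8)
        assert part.joint_pct == pytest.approx(100.0, abs=1e-8)
        assert part.overlap_pct == pytest.approx(0.0, abs=1e-8)

    def test_joint_invariant_to_group_order(self):
        rng = np.random.default_rng(11)
        Y = random_count_matrix(rng, max_rows=12, max_cols=8)
        import pandas as pd

        env = pd.DataFrame(rng.normal(size=(Y.shape[0], 4)), columns=list("abcd"))
        g12 = self._groups([("g1", ["a", "b"]), ("g2", ["c", "d"])])
        g21 = self._groups([("g2", ["c", "d"]), ("g1", ["a", "b"])])
        p1 = partition_variance(Y, env, g12)
        p2 = partition_variance(Y, env, g21)
        assert p1.joint_pct == pytest.approx(p2.joint_pct, abs=1e-10)
        for g in ("g1", "g2"):
            assert p1.exclusive_pct[g] == pytest.approx(p2.exclusive_pct[g], abs=1e-10)
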