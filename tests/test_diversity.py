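"""Incidence statistics: Jaccard/UPGMA, accumulation, jackknife, Poisson GLM."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from amazodex.core import TaxonEntry, Taxonomy
from amazodex.diversity import (
    IncidenceMatrix,
    accumulation_curve,
    build_incidence,
    cut,
    incidence_by_year,
    jaccard_similarity,
    jackknife1,
    jackknife2,
    poisson_glm,
    richness_endemism,
    upgma_cluster,
)
from conftest import make_record


def matrix_from(rows, units=None, species=None):
    arr = np.asarray(rows, dtype=bool)
    units = units or [f"u{i}" for i in range(arr.shape[0])]
    species = species or [f"sp{i}" for i in range(arr.shape[1])]
    return IncidenceMatrix(pd.DataFrame(arr, index=units, columns=species))


def test_incidence_counts(incidence_5x5):
    m = incidence_5x5
    assert (m.m, m.S_obs, m.Q1, m.Q2) == (5, 5, 0, 3)
    assert m.Q1 + m.Q2 <= m.S_obs
    assert m.m_i.between(0, m.m).all()


def test_build_incidence_collapses_duplicates():
    records = [make_record(f"r{i}", name=f"sp{i % 3}") for i in range(30)]
    assignments = {r.record_id: "only" for r in records}
    matrix = build_incidence(assignments, records)
    assert matrix.S_obs == 3 and matrix.Q1 == 3 and matrix.Q2 == 0


def test_incidence_by_year_drops_undated():
    records = [make_record(f"r{i}", year=2000 + i % 2) for i in range(6)]
    records.append(make_record("nodate", year=None))
    matrix = incidence_by_year(records)
    assert matrix.units == [2000, 2001]


def test_richness_endemism_membership_rule():
    taxonomy = Taxonomy(
        [
            TaxonEntry("A a", biome_codes={"AM"}),
            TaxonEntry("B b", biome_codes={"AM", "CE"}),
        ]
    )
    matrix = matrix_from([[1, 1], [0, 0]], species=["A a", "B b"])
    table = richness_endemism(matrix, taxonomy)
    assert table.loc["u0", "richness"] == 2
    assert table.loc["u0", "endemic_count"] == 1  # only codes == {AM} counts
    assert (table.loc["u1"] == 0).all()


def test_jaccard_values():
    matrix = matrix_from(
        [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 0]],
        species=list("abcd"),
    )
    with pytest.warns(UserWarning):
        sim = jaccard_similarity(matrix)
    assert sim.loc["u0", "u2"] == 1.0  # identical compositions
    assert sim.loc["u0", "u1"] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}
    assert sim.loc["u0", "u3"] == 0.0  # vs empty
    assert sim.loc["u3", "u3"] == 1.0
    assert np.allclose(sim, sim.T) and ((sim >= 0) & (sim <= 1)).all().all()


def test_upgma_worked_three_leaf_example():
    sim = pd.DataFrame(
        1.0 - np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]]),
        index=list("ABC"),
        columns=list("ABC"),
    )
    dendro = upgma_cluster(sim)
    assert dendro.heights() == pytest.approx([0.2, 0.7])
    assert sorted(dendro.merges[0][:2]) == [0, 1]  # (A, B) first
    groups = cut(dendro, min_similarity=0.40)  # distance threshold 0.6
    assert sorted(sorted(g) for g in groups) == [["A", "B"], ["C"]]


def test_upgma_heights_monotone_on_random_matrices():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random((8, 30)) < 0.3
        matrix = matrix_from(p)
        sim = jaccard_similarity(matrix)
        heights = upgma_cluster(sim).heights()
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_cut_identical_units_single_group():
    matrix = matrix_from([[1, 1, 0]] * 4)
    groups = cut(upgma_cluster(jaccard_similarity(matrix)), min_similarity=0.99)
    assert len(groups) == 1


def test_accumulation_exact_small_cases(incidence_5x5):
    # m=2: one shared species contributes 1.0, one singleton contributes 0.5
    two = matrix_from([[1, 1], [1, 0]])
    curve = accumulation_curve(two, method="exact")
    assert curve["richness"].tolist() == pytest.approx([1.5, 2.0])
    # frozen from the vegan 'specaccum(exact)' oracle on the same matrix
    curve5 = accumulation_curve(incidence_5x5, method="exact")
    assert curve5["richness"].tolist() == pytest.approx([2.4, 3.9, 4.7, 5.0, 5.0], abs=1e-9)


def test_accumulation_properties():
    rng = np.random.default_rng(11)
    matrix = matrix_from(rng.random((10, 20)) < 0.25)
    curve = accumulation_curve(matrix, method="exact")
    assert (curve["richness"].diff().dropna() >= -1e-12).all()  # non-decreasing
    assert curve["richness"].iloc[-1] == pytest.approx(matrix.S_obs)


def test_permutation_accumulation_matches_exact_within_3sigma():
    rng = np.random.default_rng(19)
    matrix = matrix_from(rng.random((10, 20)) < 0.3)
    exact = accumulation_curve(matrix, method="exact")["richness"].to_numpy()
    n_perm = 500
    perm = accumulation_curve(matrix, method="permutation", n_perm=n_perm, seed=5)
    # per-permutation curve values are bounded by S_obs: sd <= S_obs/2
    sigma = matrix.S_obs / 2.0 / np.sqrt(n_perm)
    assert np.all(np.abs(perm["richness"].to_numpy() - exact) <= 3.0 * sigma)
    assert perm["richness"].iloc[-1] == pytest.approx(matrix.S_obs)
    with pytest.raises(ValueError):
        accumulation_curve(matrix, method="permutation", n_perm=0)


def test_jackknife2_formula(incidence_5x5):
    # S=10, Q1=3, Q2=2, m=5 -> 10 + 3*7/5 - 2*9/20 = 13.3
    rows = np.zeros((5, 10), dtype=bool)
    for j in range(10):
        rows[:, j] = False
    # 5 species in >=3 units, 3 singletons, 2 doubletons
    for j in range(5):
        rows[0:3, j] = True
    for j in range(5, 8):
        rows[j - 5, j] = True
    rows[0:2, 8] = True
    rows[2:4, 9] = True
    matrix = matrix_from(rows)
    assert (matrix.S_obs, matrix.Q1, matrix.Q2) == (10, 3, 2)
    assert jackknife2(matrix) == pytest.approx(13.3)
    # vegan-verified fixture: jack2 = 3.65
    assert jackknife2(incidence_5x5) == pytest.approx(3.65)
    assert jackknife1(incidence_5x5) == pytest.approx(5.0)  # Q1 = 0


def test_jackknife2_requires_two_units():
    with pytest.raises(ValueError):
        jackknife2(matrix_from([[1, 0, 1]]))


def test_jackknife2_converges_to_sobs_under_complete_census():
    # every species in many units: Q1 = Q2 = 0 and the estimator returns S_obs
    matrix = matrix_from(np.ones((12, 30), dtype=bool))
    assert jackknife2(matrix) == matrix.S_obs == 30


def test_jackknife2_agrees_with_vegan_on_random_matrix():
    rng = np.random.default_rng(101)
    mat = (rng.random((8, 25)) < 0.3).astype(int)
    mat[:, mat.sum(axis=0) == 0] = 0  # vegan ignores all-zero columns, as do we
    ours = jackknife2(matrix_from(mat))
    script = textwrap.dedent(
        f"""
        suppressMessages(library(vegan))
        x <- matrix(c({",".join(str(v) for v in mat.flatten())}),
                    nrow={mat.shape[0]}, byrow=TRUE)
        cat(specpool(x)$jack2)
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-6)


def test_poisson_glm_intercept_only_mle():
    # regression on a constant covariate reduces to the Poisson mean MLE
    fit = poisson_glm([1, 2, 3], [100.0, 100.0, 100.0], covariate="log_area")
    assert fit.intercept + fit.slope * np.log(100.0) == pytest.approx(np.log(2.0), abs=1e-6)


def test_poisson_glm_recovers_slope_within_3se():
    rng = np.random.default_rng(37)
    n = 500
    area = rng.uniform(1e3, 1e6, size=n)
    true_b0, true_b1 = -2.0, 0.5
    mu = np.exp(true_b0 + true_b1 * np.log(area))
    y = rng.poisson(mu)
    fit = poisson_glm(y, area, covariate="log_area")
    se = abs(fit.slope / fit.z_slope)
    assert abs(fit.slope - true_b1) <= 3.0 * se


def test_poisson_glm_agrees_with_direct_likelihood_optimum():
    rng = np.random.default_rng(41)
    area = rng.uniform(1e3, 1e5, size=40)
    y = rng.poisson(np.exp(0.3 + 0.4 * np.log(area)))
    fit = poisson_glm(y, area, covariate="log_area")
    x = np.log(area)

    def nll(params):
        eta = params[0] + params[1] * x
        return float(np.sum(np.exp(eta) - y * eta + gammaln(y + 1)))

    opt = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
    assert fit.intercept == pytest.approx(opt.x[0], abs=1e-6)
    assert fit.slope == pytest.approx(opt.x[1], abs=1e-6)


def test_poisson_glm_input_validation():
    with pytest.raises(ValueError):
        poisson_glm([1, 2], [1.0, 2.0])
    with pytest.raises(ValueError):
        poisson_glm([1, 2, 3], [1.0, -2.0, 3.0])
    with pytest.raises(ValueError):
        poisson_glm([1, 2, 3], [1.0, 2.0, 3.0], covariate="sqrt")
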