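import numpy as np
import pandas as pd
import pytest

import ssrhyb as sh
from ssrhyb.null_models import NullEMResult
from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracle: per-population textbook computation, written from the
# estimator's definition with explicit loops (no shared code paths).
# ---------------------------------------------------------------------------

def oracle_theta(genotypes_by_pop):
    """genotypes_by_pop: list of (n_i, L, 2) arrays, -1 = missing."""
    L = genotypes_by_pop[0].shape[1]
    A = 1 + max(int(g[g >= 0].max()) for g in genotypes_by_pop)
    num = den = 0.0
    bc_b = bc_c = 0.0
    for l in range(L):
        per_pop = []
        for g in genotypes_by_pop:
            gl = g[:, l]
            gl = gl[gl[:, 0] >= 0]
            per_pop.append(gl)
        per_pop = [g for g in per_pop if len(g) >= 1]
        r = len(per_pop)
        if r < 2:
            continue
        ns = [len(g) for g in per_pop]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
        for a in range(A):
            ps, hs = [], []
            for g in per_pop:
                ps.append(((g == a).sum()) / (2 * len(g)))
                hs.append(((g[:, 0] != g[:, 1]) & ((g == a).any(axis=1))).mean())
            if sum(ps) == 0:
                continue
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a_comp = (nbar / nc) * (
                s2 - 1.0 / (nbar - 1) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0))
            b_comp = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_comp = hbar / 2.0
            num += a_comp
            den += a_comp + b_comp + c_comp
            bc_b += b_comp
            bc_c += c_comp
    return num / den, 1.0 - bc_c / (bc_b + bc_c)


def two_allele_closed_form(p1, p2, n, h1, h2):
    """Two populations, equal size, two alleles: closed-form components for
    the variant allele."""
    r, nbar = 2, n
    nc = (r * nbar - (2 * n * n) / (r * nbar)) / (r - 1)
    pbar = (p1 + p2) / 2
    s2 = (n * (p1 - pbar) ** 2 + n * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (h1 + h2) / 2
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_theta_matches_independent_oracle():
    """Random 3-population, 2-locus dataset: agreement to 1e-12."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        gs = [np.sort(rng.integers(0, 4, size=(8, 2, 2)), axis=2).astype(np.int32)
              for _ in range(3)]
        calls = np.concatenate(gs)
        m, meta = make_matrix(calls, ["P1-A"] * 8 + ["P2-A"] * 8 + ["P3-A"] * 8)
        res = sh.wc_theta(m, meta.populations)
        t_o, f_o = oracle_theta(gs)
        assert res.theta_global == pytest.approx(t_o, abs=1e-12)
        assert res.f_global == pytest.approx(f_o, abs=1e-12)


def test_theta_two_allele_closed_form():
    rng = np.random.default_rng(5)
    calls = np.sort(rng.integers(0, 2, size=(24, 1, 2)), axis=2).astype(np.int32)
    m, meta = make_matrix(calls, ["P1-A"] * 12 + ["P2-A"] * 12)
    res = sh.wc_theta(m, meta.populations)
    g1, g2 = calls[:12, 0], calls[12:, 0]
    comps = [
        two_allele_closed_form(
            (g1 == a).mean(), (g2 == a).mean(), 12,
            (g1[:, 0] != g1[:, 1]).mean(), (g2[:, 0] != g2[:, 1]).mean())
        for a in (0, 1)
    ]
    a = sum(c[0] for c in comps)
    tot = sum(sum(c) for c in comps)
    assert res.theta_global == pytest.approx(a / tot, abs=1e-12)


def test_identical_populations_give_small_theta(two_species_dataset):
    _, mat, meta, _ = two_species_dataset
    # duplicate one population's genotypes under two labels
    sub = mat.subset(np.arange(30))
    both = sh.GenotypeMatrix(
        [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)],
        sub.loci, np.concatenate([sub.calls, sub.calls]), sub.allele_labels)
    meta2 = sh.SampleMetadata.from_populations(
        both.individuals, ["X-A"] * 30 + ["Y-A"] * 30)
    assert abs(sh.wc_theta(both, meta2.populations).theta_global) < 0.02


def test_fixed_difference_gives_theta_one():
    calls = np.zeros((40, 2, 2), dtype=np.int32)
    calls[20:] = 1
    m, meta = make_matrix(calls, ["X-A"] * 20 + ["Y-A"] * 20)
    assert sh.wc_theta(m, meta.populations).theta_global == pytest.approx(1.0)


def test_theta_invariant_to_relabeling_and_locus_order():
    rng = np.random.default_rng(9)
    calls = np.sort(rng.integers(0, 4, size=(30, 3, 2)), axis=2).astype(np.int32)
    m, meta = make_matrix(calls, ["P1-A"] * 15 + ["P2-A"] * 15)
    base = sh.wc_theta(m, meta.populations).theta_global
    relabel = np.array([2, 0, 3, 1])
    m2, _ = make_matrix(np.sort(relabel[calls], axis=2), ["P1-A"] * 15 + ["P2-A"] * 15)
    assert sh.wc_theta(m2, meta.populations).theta_global == pytest.approx(base, abs=1e-12)
    m3, _ = make_matrix(calls[:, ::-1, :], ["P1-A"] * 15 + ["P2-A"] * 15)
    assert sh.wc_theta(m3, meta.populations).theta_global == pytest.approx(base, abs=1e-12)


def test_island_model_parameter_recovery():
    """Balding–Nichols frequencies with concentration c = (1-F)/F at
    F = 0.2 (the island-model expectation at Nm = 1): realized global theta
    lands in [0.14, 0.26] at 17 loci x 4 demes x 50 individuals."""
    fm = sh.simulate_frequencies(4, 17, 10, divergence=4.0, null_max=0.0, seed=21)
    plan = sh.CrossPlan([(f"P{s}-{s}", s, 50) for s in fm.species])
    mat, meta, _ = sh.simulate_individuals(fm, plan, sh.ObservationModel(), seed=22)
    assert 0.14 <= sh.wc_theta(mat, meta.populations).theta_global <= 0.26


def test_single_group_rejected():
    calls = np.zeros((4, 1, 2), dtype=np.int32)
    calls[::2] = 1
    m, meta = make_matrix(calls, ["P-A"] * 4)
    with pytest.raises(ValueError):
        sh.wc_theta(m, meta.populations)


# --- ENA ---------------------------------------------------------------

def test_ena_is_identity_when_pi_zero(two_species_dataset):
    """EM results with pi-hat = 0 leave every component untouched."""
    _, mat, meta, _ = two_species_dataset
    em = {}
    counts = sh.allele_counts(mat, meta.populations)
    for pop, (cnt, miss) in counts.items():
        for l, locus in enumerate(mat.loci):
            p = cnt[l] / cnt[l].sum()
            em[(pop, locus)] = NullEMResult(0.0, p, 0, True, 0.0)
    res = sh.ena_theta(mat, meta.populations, em, n_boot=50, seed=1)
    assert res["cfst"].theta_global == pytest.approx(
        res["fst"].theta_global, abs=1e-6)
    assert np.allclose(res["cfst"].theta_per_locus, res["fst"].theta_per_locus,
                       atol=1e-6)


def test_ena_reduces_null_allele_bias():
    """pi ~ 0.2: cF_ST is closer than F_ST to the pre-observation truth in
    well over 70% of replicates."""
    from ssrhyb.differentiation import (
        _pop_inputs, _theta_from_components, _wc_components)
    from ssrhyb.geno_io import GenotypeMatrix
    wins = 0
    n_rep = 25
    for rep in range(n_rep):
        fm = sh.simulate_frequencies(4, 17, 10, divergence=8, null_max=0.0, seed=rep)
        fm.null[:] = 0.2
        fm.visible *= 0.8
        plan = sh.CrossPlan([(f"P{s}-{s}", s, 30) for s in fm.species])
        mat, meta, truth = sh.simulate_individuals(
            fm, plan, sh.ObservationModel(), seed=900 + rep)
        tc = truth.true_calls.copy()
        tc[tc == -2] = fm.alleles_per_locus
        mf = GenotypeMatrix(mat.individuals, mat.loci,
                            np.sort(tc, axis=2).astype(np.int32), {})
        pops, n, p, h = _pop_inputs(mf, meta.populations)
        mask = np.ones((17, p.shape[2]), bool)
        mask[:, fm.alleles_per_locus] = False
        true_theta = _theta_from_components(
            _wc_components(n, p, h, allele_mask=mask), mat.loci).theta_global
        em = sh.em_null_all(mat, meta.populations)
        res = sh.ena_theta(mat, meta.populations, em, n_boot=10, seed=rep)
        wins += (abs(res["cfst"].theta_global - true_theta)
                 < abs(res["fst"].theta_global - true_theta))
    assert wins >= 0.7 * n_rep


def test_bootstrap_ci_is_seed_deterministic(four_species_dataset):
    _, mat, meta, _ = four_species_dataset
    em = sh.em_null_all(mat, meta.populations)
    r1 = sh.ena_theta(mat, meta.populations, em, n_boot=500, seed=77)
    r2 = sh.ena_theta(mat, meta.populations, em, n_boot=500, seed=77)
    assert r1["cfst"].ci == r2["cfst"].ci and r1["fst"].ci == r2["fst"].ci
    lo, hi = r1["fst"].ci
    assert lo <= r1["fst"].theta_global <= hi


# --- G_ST / G'_ST and gene flow ---------------------------------------

def test_gst_private_alleles():
    calls = np.zeros((40, 2, 2), dtype=np.int32)
    calls[20:] = 1
    m, meta = make_matrix(calls, ["X-A"] * 20 + ["Y-A"] * 20)
    tab = sh.hedrick_gst(m, meta.populations)
    assert tab.loc["overall", "G_ST"] == pytest.approx(1.0)
    assert tab.loc["overall", "Gp_ST"] == pytest.approx(1.0)


def test_gst_identical_populations_near_zero(two_species_dataset):
    _, mat, meta, _ = two_species_dataset
    sub = mat.subset(np.arange(30))
    both = sh.GenotypeMatrix(
        [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)],
        sub.loci, np.concatenate([sub.calls, sub.calls]), sub.allele_labels)
    meta2 = sh.SampleMetadata.from_populations(
        both.individuals, ["X-A"] * 30 + ["Y-A"] * 30)
    tab = sh.hedrick_gst(both, meta2.populations)
    assert abs(tab.loc["overall", "G_ST"]) < 0.02
    assert abs(tab.loc["overall", "Gp_ST"]) < 0.2


def test_hedrick_formula_oracle(four_species_dataset):
    """G'_ST recomputed by hand from the same H_S, H_T to 1e-12."""
    _, mat, meta, _ = four_species_dataset
    tab = sh.hedrick_gst(mat, meta.populations)
    s = meta.populations.nunique()
    for locus, row in tab.iterrows():
        gst = (row["H_T"] - row["H_S"]) / row["H_T"]
        gpst = gst * (s - 1 + row["H_S"]) / ((s - 1) * (1 - row["H_S"]))
        assert row["G_ST"] == pytest.approx(gst, abs=1e-12)
        assert row["Gp_ST"] == pytest.approx(gpst, abs=1e-12)
        if row["G_ST"] >= 0:
            assert row["Gp_ST"] >= row["G_ST"] - 1e-12


@pytest.mark.parametrize("value,tag,expected", [
    (0.2, "wright", 1.0),
    (1 / 3, "gst", 1.0),
    (1.0, "wright", 0.0),
])
def test_gene_flow_formulas(value, tag, expected):
    assert sh.gene_flow(value, tag) == pytest.approx(expected)


def test_gene_flow_nonpositive_is_infinite():
    assert np.isinf(sh.gene_flow(0.0, "wright"))
    assert np.isinf(sh.gene_flow(-0.01, "gst"))


# --- pairwise / strata / PCoA ------------------------------------------

def test_pairwise_matrix_shape_and_symmetry():
    rng = np.random.default_rng(10)
    pops = [f"S{i}-{sp}" for i, sp in enumerate("AVFBA")]
    labels = np.repeat(pops, 8)
    calls = np.sort(rng.integers(0, 5, size=(40, 2, 2)), axis=2).astype(np.int32)
    m, meta = make_matrix(calls, list(labels))
    pw = sh.pairwise_fst(m, meta.populations)
    v = pw.values
    assert v.shape == (5, 5)
    assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)


def test_stratum_means_ordering():
    """Within-species divergence below between-species divergence makes the
    allopatric homologous mean the smallest stratum mean."""
    fm = sh.simulate_frequencies(2, 10, 8, divergence=3, null_max=0.0, seed=30)
    plan = sh.CrossPlan([
        ("S1-A", "A", 15), ("S1-V", "V", 15),
        ("S2-A", "A", 15), ("S2-V", "V", 15),
    ])
    mat, meta, _ = sh.simulate_individuals(fm, plan, sh.ObservationModel(), seed=31)
    pw = sh.pairwise_fst(mat, meta.populations)
    means = sh.stratify_pairs(pw, meta)["mean_fst"]
    assert means["allopatric_homologous"] < means["sympatric_heterogeneous"]
    assert means["allopatric_homologous"] < means["allopatric_heterogeneous"]


def test_stratum_all_near_zero_for_duplicated_population(two_species_dataset):
    _, mat, meta, _ = two_species_dataset
    sub = mat.subset(np.arange(30))
    calls = np.concatenate([sub.calls] * 4)
    inds = [f"i{k}" for k in range(120)]
    pops = ["S1-A"] * 30 + ["S1-V"] * 30 + ["S2-A"] * 30 + ["S2-V"] * 30
    m2 = sh.GenotypeMatrix(inds, sub.loci, calls, sub.allele_labels)
    meta2 = sh.SampleMetadata.from_populations(inds, pops)
    pw = sh.pairwise_fst(m2, meta2.populations)
    means = sh.stratify_pairs(pw, meta2)["mean_fst"]
    assert (means.abs() < 0.02).all()


def test_pcoa_collinear_points():
    D = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                     index=list("abc"), columns=list("abc"), dtype=float)
    res = sh.pcoa(D)
    assert res.percent_variance[0] == pytest.approx(100.0)


def test_pcoa_euclidean_round_trip():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(7, 2))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    res = sh.pcoa(pd.DataFrame(D, index=list("abcdefg"), columns=list("abcdefg")))
    Y = res.coordinates.to_numpy()[:, :2]
    D2 = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
    assert np.allclose(D, D2, atol=1e-8)


def test_pcoa_zero_matrix_degenerate():
    D = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
    res = sh.pcoa(D)
    assert res.degenerate
    assert np.allclose(res.eigenvalues, 0, atol=1e-12)


def test_pcoa_requires_symmetry():
    D = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"),
                     dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        sh.pcoa(D)


# --- permutation test ---------------------------------------------------

def test_theta_permutation_floor_on_fixed_difference():
    calls = np.zeros((40, 2, 2), dtype=np.int32)
    calls[20:] = 1
    m, meta = make_matrix(calls, ["X-A"] * 20 + ["Y-A"] * 20)
    res = sh.theta_permutation_test(m, meta.populations, n_perm=999, seed=1)
    assert res["p_global"] == pytest.approx(1 / 1000)


def test_theta_permutation_seed_reproducible(four_species_dataset):
    _, mat, meta, _ = four_species_dataset
    r1 = sh.theta_permutation_test(mat, meta.populations, n_perm=99, seed=5)
    r2 = sh.theta_permutation_test(mat, meta.populations, n_perm=99, seed=5)
    assert r1["p_global"] == r2["p_global"]
    assert (r1["p_per_locus"] == r2["p_per_locus"]).all()
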