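import numpy as np
import pandas as pd
import pytest

import ssrhyb as sh
from ssrhyb.clustering import DistanceMatrix
from conftest import make_matrix


# --- Nei distance -------------------------------------------------------

def test_nei_identical_populations_near_zero(two_species_dataset):
    _, mat, meta, _ = two_species_dataset
    sub = mat.subset(np.arange(30))
    both = sh.GenotypeMatrix(
        [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)],
        sub.loci, np.concatenate([sub.calls, sub.calls]), sub.allele_labels)
    meta2 = sh.SampleMetadata.from_populations(
        both.individuals, ["X-A"] * 30 + ["Y-A"] * 30)
    d = sh.nei_distance(both, meta2.populations)
    assert d.values[0, 1] == pytest.approx(0.0, abs=0.02)


def test_nei_fixed_difference_is_infinite():
    calls = np.zeros((20, 2, 2), dtype=np.int32)
    calls[10:] = 1
    m, meta = make_matrix(calls, ["X-A"] * 10 + ["Y-A"] * 10)
    d = sh.nei_distance(m, meta.populations)
    assert np.isinf(d.values[0, 1])
    assert any("infinite" in f for f in d.flags)


def test_nei_formula_oracle():
    """Hand-evaluated Nei-1978 from the same allele counts to 1e-12."""
    rng = np.random.default_rng(3)
    calls = np.sort(rng.integers(0, 4, size=(24, 3, 2)), axis=2).astype(np.int32)
    m, meta = make_matrix(calls, ["X-A"] * 12 + ["Y-A"] * 12)
    d = sh.nei_distance(m, meta.populations)
    jx, jy, jxy = [], [], []
    for l in range(3):
        cx = np.bincount(calls[:12, l].ravel(), minlength=4)
        cy = np.bincount(calls[12:, l].ravel(), minlength=4)
        px, py = cx / 24, cy / 24
        jx.append((24 * (px**2).sum() - 1) / 23)
        jy.append((24 * (py**2).sum() - 1) / 23)
        jxy.append((px * py).sum())
    expected = -np.log(np.mean(jxy) / np.sqrt(np.mean(jx) * np.mean(jy)))
    assert d.values[0, 1] == pytest.approx(max(expected, 0.0), abs=1e-12)


# --- individual distance ------------------------------------------------

def test_individual_distance_trivial_cases():
    # identical; disjoint; F1 against each fixed parent
    calls = np.array([
        [[0, 1], [0, 0]],
        [[0, 1], [0, 0]],
        [[2, 3], [1, 1]],
        [[0, 2], [0, 1]],
    ], dtype=np.int32)
    m, _ = make_matrix(calls, ["P-A"] * 4)
    D = sh.individual_distance(m).to_frame()
    assert D.iloc[0, 1] == 0.0
    assert D.iloc[0, 2] == 1.0
    # fixed-difference parents and their F1
    parents = np.array([[[0, 0], [0, 0]], [[1, 1], [1, 1]]], dtype=np.int32)
    f1 = np.array([[[0, 1], [0, 1]]], dtype=np.int32)
    m2, _ = make_matrix(np.concatenate([parents, f1]), ["P-A"] * 3)
    D2 = sh.individual_distance(m2).to_frame()
    assert D2.iloc[2, 0] == pytest.approx(0.5)
    assert D2.iloc[2, 1] == pytest.approx(0.5)


# --- NJ -----------------------------------------------------------------

def test_nj_recovers_additive_four_taxon_tree():
    """Distances generated from (A:1,B:2,(C:3,D:4):5) are inverted exactly."""
    D = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
    path = {("A", "B"): 3, ("A", "C"): 9, ("A", "D"): 10,
            ("B", "C"): 10, ("B", "D"): 11, ("C", "D"): 7}
    for (i, j), v in path.items():
        D.loc[i, j] = D.loc[j, i] = v
    tree = sh.nj_tree(DistanceMatrix(list("ABCD"), D.to_numpy(), "test"))
    tips = {t.name: t for t in tree.tips()}
    for (i, j), v in path.items():
        assert tips[i].distance(tips[j]) == pytest.approx(v, abs=1e-9)


def test_nj_three_taxa_exact():
    vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = sh.nj_tree(DistanceMatrix(list("abc"), vals, "test"))
    tips = {t.name: t for t in tree.tips()}
    assert tips["a"].distance(tips["b"]) == pytest.approx(3)
    assert tips["a"].distance(tips["c"]) == pytest.approx(4)
    assert tips["b"].distance(tips["c"]) == pytest.approx(5)


def _random_additive_matrix(n_taxa, seed):
    """Random binary tree by sequential random joins; returns leaf labels,
    the additive leaf-to-leaf distance matrix, and the tree as newick."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{lab}:{rng.uniform(0.1, 1.0):.6f}" for lab in labels]
    members = [[i] for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    depth = [dict.fromkeys(m, 0.0) for m in members]
    for i, lab in enumerate(labels):
        depth[i][i] = float(nodes[i].split(":")[1])
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bl = rng.uniform(0.1, 1.0)
        for a, da in depth[i].items():
            for b, db in depth[j].items():
                D[a, b] = D[b, a] = da + db
        new = f"({nodes[i]},{nodes[j]}):{bl:.6f}"
        merged = {k: v + bl for d in (depth[i], depth[j]) for k, v in d.items()}
        for idx in (j, i):
            nodes.pop(idx)
            depth.pop(idx)
        nodes.append(new)
        depth.append(merged)
    for a, da in depth[0].items():
        for b, db in depth[1].items():
            D[a, b] = D[b, a] = da + db
    newick = f"({nodes[0]},{nodes[1]});"
    return labels, D, newick


def test_nj_topology_recovery_50_taxa():
    """NJ on a 50-taxon additive matrix recovers the generating topology
    (Robinson–Foulds distance 0)."""
    import dendropy
    labels, D, newick = _random_additive_matrix(50, 23)
    nj = sh.nj_tree(DistanceMatrix(labels, D, "test"))
    ns = dendropy.TaxonNamespace(labels)
    true_tree = dendropy.Tree.get(data=newick, schema="newick",
                                  taxon_namespace=ns)
    recovered = dendropy.Tree.get(data=str(nj), schema="newick",
                                  taxon_namespace=ns)
    true_tree.encode_bipartitions()
    recovered.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(true_tree, recovered)
    assert rf == 0


def test_nj_rejects_infinite_entries():
    vals = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError, match="infinite"):
        sh.nj_tree(DistanceMatrix(list("abc"), vals, "test"))


def test_newick_output_round_trips(tmp_path):
    vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = sh.nj_tree(DistanceMatrix(list("abc"), vals, "test"))
    p = tmp_path / "t.nwk"
    sh.write_newick(tree, p)
    import skbio
    t2 = skbio.TreeNode.read(str(p))
    assert {t.name for t in t2.tips()} == {"a", "b", "c"}


def test_deep_split_separates_species_groups(two_species_dataset):
    """The individual NJ tree's deepest bipartition separates the two
    divergent species."""
    _, mat, meta, _ = two_species_dataset
    d = sh.individual_distance(mat)
    tree = sh.nj_tree(d)
    tree = tree.root_at_midpoint()
    kids = tree.children
    side = {t.name for t in kids[0].tips()} if not kids[0].is_tip() else {kids[0].name}
    sp = meta.species
    a_set = set(sp[sp == "A"].index)
    frac = max(len(side & a_set), len(side - a_set)) / len(side)
    assert frac >= 0.95


# --- trait clustering ---------------------------------------------------

def test_trait_cluster_separates_planted_clusters():
    rng = np.random.default_rng(8)
    X = np.concatenate([rng.normal(0, 1, (20, 3)), rng.normal(10, 1, (20, 3))])
    traits = pd.DataFrame(X, index=[f"i{k}" for k in range(40)])
    dend = sh.trait_cluster(traits)
    cut = dend.cut(2)
    first = cut.iloc[:20]
    second = cut.iloc[20:]
    assert first.nunique() == 1 and second.nunique() == 1
    assert first.iloc[0] != second.iloc[0]


def test_trait_cluster_standardization_invariance():
    rng = np.random.default_rng(9)
    traits = pd.DataFrame(rng.normal(size=(12, 4)),
                          index=[f"i{k}" for k in range(12)])
    scaled = traits.copy()
    scaled.iloc[:, 0] *= 1000.0
    d1 = sh.trait_cluster(traits)
    d2 = sh.trait_cluster(scaled)
    assert d1.to_newick() == d2.to_newick()


def test_trait_cluster_drops_constant_columns():
    traits = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": 5.0},
                          index=list("wxyz"))
    dend = sh.trait_cluster(traits)
    assert dend.dropped_traits == ["b"]


def test_trait_cluster_population_level(four_species_dataset):
    fm, mat, meta, truth = four_species_dataset
    means = np.array([[0.0, 0.0], [8.0, 8.0], [4.0, -4.0], [-4.0, 4.0]])
    traits = sh.simulate_traits(truth, means, noise_sd=0.5, seed=3)
    dend = sh.trait_cluster(traits, meta.populations, level="population")
    assert sorted(dend.labels) == sorted(meta.populations.unique())


# --- partition comparison ----------------------------------------------

def test_ari_identical_partitions():
    a = pd.Series([1, 1, 2, 2, 3], index=list("abcde"))
    res = sh.compare_partitions(a, a)
    assert res.ari == pytest.approx(1.0)


def test_ari_single_class_is_zero():
    a = pd.Series([1, 1, 1, 1], index=list("abcd"))
    b = pd.Series([1, 2, 1, 2], index=list("abcd"))
    assert sh.compare_partitions(a, b).ari == pytest.approx(0.0)


def test_ari_mismatched_items_rejected():
    a = pd.Series([1, 2], index=["x", "y"])
    b = pd.Series([1, 2], index=["x", "z"])
    with pytest.raises(ValueError, match="different item sets"):
        sh.compare_partitions(a, b)


def test_ari_null_calibration():
    """Independent random labelings (k=4, n=300): mean ARI ~ 0 +- 0.05."""
    rng = np.random.default_rng(12)
    aris = []
    for _ in range(100):
        a = pd.Series(rng.integers(0, 4, 300))
        b = pd.Series(rng.integers(0, 4, 300))
        aris.append(sh.compare_partitions(a, b).ari)
    assert abs(np.mean(aris)) < 0.05
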