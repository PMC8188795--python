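"""Per-locus / per-population diversity statistics and HWE / LD tests.

Statistics: allele count N_A, effective allele count N_E = 1/sum(p^2),
observed heterozygosity H_O, unbiased expected heterozygosity
H_E = 2n/(2n-1) (1 - sum p^2), within-population gene diversity H_S
(mean over populations of unbiased within-population diversity), allelic
richness A_R rarefied to a fixed number of gene copies, and PIC.

HWE and LD are tested by permutation: HWE re-pairs the 2n sampled allele
copies into random diploids; LD permutes one locus's genotypes across
individuals within the population.  Both use the add-one p-value
correction (b+1)/(n_perm+1).  The multiple-comparison level for LD over
all locus pairs is alpha / C(n_loci, 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geno_io import MISSING, GenotypeMatrix, allele_counts, child_rng


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_perm: int
    adjusted_level: float | None = None
    defined: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# Closed-form statistics
# ---------------------------------------------------------------------------

def effective_alleles(p: np.ndarray) -> float:
    return 1.0 / float((p**2).sum())


def unbiased_expected_het(p: np.ndarray, n: int) -> float:
    """Nei's unbiased gene diversity: 2n/(2n-1) * (1 - sum p^2)."""
    if n < 1:
        return np.nan
    return (2 * n / (2 * n - 1)) * (1.0 - float((p**2).sum()))


def pic(p: np.ndarray) -> float:
    """Polymorphic information content (Botstein et al.)."""
    s2 = float((p**2).sum())
    cross = float(np.outer(p**2, p**2).sum() - (p**4).sum()) / 2.0
    return 1.0 - s2 - 2.0 * cross


def allelic_richness(counts: np.ndarray, g: int) -> float:
    """Rarefied allele count: sum_a [1 - C(N - N_a, g) / C(N, g)].

    ``counts`` are allele-copy counts; ``g`` the rarefaction size in gene
    copies.  Computed with log-gammas for numerical safety.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g > N:
        return np.nan
    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    terms = np.where(
        N - counts >= g,
        np.exp(logC(N - counts, g) - logC(N, g)),
        0.0,
    )
    return float((1.0 - terms).sum())


def _locus_group_stats(counts, missing, n_group, g):
    """Stats for one locus in one group from copy counts."""
    N = int(counts.sum())
    n = N // 2  # non-missing individuals
    if n == 0:
        return dict(N_A=np.nan, N_E=np.nan, H_E=np.nan, A_R=np.nan, PIC=np.nan, n=0)
    p = counts[counts > 0] / N
    return dict(
        N_A=int((counts > 0).sum()),
        N_E=effective_alleles(p),
        H_E=unbiased_expected_het(p, n),
        A_R=allelic_richness(counts, g) if n >= g / 2 else np.nan,
        PIC=pic(p),
        n=n,
    )


def observed_het(matrix: GenotypeMatrix, rows: np.ndarray, locus: int) -> float:
    calls = matrix.calls[rows, locus, :]
    ok = calls[:, 0] != MISSING
    if ok.sum() == 0:
        return np.nan
    return float((calls[ok, 0] != calls[ok, 1]).mean())


def diversity_table(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    rarefaction_g: int = 20,
) -> pd.DataFrame:
    """Per-locus diversity statistics, per group and pooled.

    The pooled rows additionally carry H_S = mean over groups of the
    unbiased within-group gene diversity (groups with data at the locus).
    Rows are indexed by (group, locus) with group "pooled" for the pooled
    panel.  A_R cells for groups smaller than rarefaction_g/2 individuals
    are undefined (NaN).
    """
    grouping = grouping.reindex(matrix.individuals)
    counts = allele_counts(matrix, grouping)
    ind_pos = {ind: i for i, ind in enumerate(matrix.individuals)}
    rows_of = {
        g: np.array([ind_pos[i] for i in idx])
        for g, idx in grouping.groupby(grouping).groups.items()
    }
    records = []
    pooled_counts = None
    for g, (cnt, miss) in counts.items():
        if pooled_counts is None:
            pooled_counts = cnt.copy().astype(float)
            pooled_missing = miss.copy().astype(float)
        else:
            A = max(pooled_counts.shape[1], cnt.shape[1])
            if cnt.shape[1] < A:
                cnt = np.pad(cnt, ((0, 0), (0, A - cnt.shape[1])))
            if pooled_counts.shape[1] < A:
                pooled_counts = np.pad(pooled_counts, ((0, 0), (0, A - pooled_counts.shape[1])))
            pooled_counts += cnt
            pooled_missing += miss
        for l, locus in enumerate(matrix.loci):
            st = _locus_group_stats(cnt[l], miss[l], len(rows_of[g]), rarefaction_g)
            st["H_O"] = observed_het(matrix, rows_of[g], l)
            records.append((g, locus, st))

    hs = {}  # locus -> mean within-group unbiased diversity
    for l, locus in enumerate(matrix.loci):
        vals = [
            unbiased_expected_het(
                cnt[l][cnt[l] > 0] / cnt[l].sum(), int(cnt[l].sum()) // 2
            )
            for g, (cnt, miss) in counts.items()
            if cnt[l].sum() > 0
        ]
        hs[locus] = float(np.mean(vals)) if vals else np.nan

    all_rows = np.arange(matrix.n_individuals)
    for l, locus in enumerate(matrix.loci):
        st = _locus_group_stats(
            pooled_counts[l], pooled_missing[l], matrix.n_individuals, rarefaction_g
        )
        st["H_O"] = observed_het(matrix, all_rows, l)
        st["H_S"] = hs[locus]
        records.append(("pooled", locus, st))

    df = pd.DataFrame(
        [
            dict(group=g, locus=locus, **st)
            for g, locus, st in records
        ]
    ).set_index(["group", "locus"])
    cols = ["N_A", "N_E", "H_O", "H_E", "A_R", "PIC", "n"]
    if "H_S" in df.columns:
        cols = cols[:5] + ["H_S"] + cols[5:]
    return df[cols]


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _wc_f_single(calls: np.ndarray) -> float:
    """Within-population inbreeding estimate f = 1 - H_O / H_E(unbiased)."""
    ok = calls[:, 0] != MISSING
    calls = calls[ok]
    n = len(calls)
    flat = calls.ravel()
    cnt = np.bincount(flat)
    p = cnt[cnt > 0] / flat.size
    he = unbiased_expected_het(p, n)
    if he <= 0:
        return np.nan
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    return 1.0 - ho / he


def hwe_test(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    population: str,
    locus: str,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Permutation HWE test within one population at one locus.

    Statistic: inbreeding estimate f; null: re-pair the sampled 2n allele
    copies into random diploids; two-sided p on |f|.
    """
    rows = np.array(
        [i for i, ind in enumerate(matrix.individuals)
         if grouping.get(ind) == population]
    )
    l = matrix.loci.index(locus)
    calls = matrix.calls[rows, l, :]
    calls = calls[calls[:, 0] != MISSING]
    n = len(calls)
    if n < 5:
        return TestResult("hwe", np.nan, np.nan, n_perm, defined=False,
                          note="fewer than 5 non-missing individuals")
    alleles = calls.ravel()
    if np.unique(alleles).size < 2:
        return TestResult("hwe", np.nan, np.nan, n_perm, defined=False,
                          note="monomorphic locus")
    f_obs = _wc_f_single(calls)
    rng = child_rng(seed, "hwe", population, locus)
    # vectorized: one shuffle per permutation, then pairwise f
    perms = np.argsort(rng.random((n_perm, alleles.size)), axis=1)
    shuffled = alleles[perms].reshape(n_perm, n, 2)
    het = (shuffled[:, :, 0] != shuffled[:, :, 1]).mean(axis=1)
    he = unbiased_expected_het(
        np.bincount(alleles)[np.bincount(alleles) > 0] / alleles.size, n
    )
    f_null = 1.0 - het / he
    b = int((np.abs(f_null) >= abs(f_obs) - 1e-12).sum())
    p = (b + 1) / (n_perm + 1)
    return TestResult("hwe", f_obs, p, n_perm)


def _g_statistic(gt1: np.ndarray, gt2: np.ndarray) -> float:
    """Log-likelihood ratio G on the two-locus genotype contingency table."""
    k1 = gt1.max() + 1
    tab = np.bincount(gt1 * (gt2.max() + 1) + gt2,
                      minlength=k1 * (gt2.max() + 1)).reshape(k1, -1).astype(float)
    rs, cs = tab.sum(1, keepdims=True), tab.sum(0, keepdims=True)
    E = rs * cs / tab.sum()
    mask = tab > 0
    return 2.0 * float((tab[mask] * np.log(tab[mask] / E[mask])).sum())


def _genotype_ids(calls: np.ndarray) -> np.ndarray:
    """Encode sorted diploid calls as dense genotype category ids."""
    key = calls[:, 0].astype(np.int64) * 10_000 + calls[:, 1]
    _, ids = np.unique(key, return_inverse=True)
    return ids


def ld_test(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    population: str,
    locus_pair: tuple[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Permutation test of genotypic linkage disequilibrium in a population.

    Statistic: G on the two-locus genotype table; null: permute one locus's
    genotypes across individuals.
    """
    rows = np.array(
        [i for i, ind in enumerate(matrix.individuals)
         if grouping.get(ind) == population]
    )
    l1 = matrix.loci.index(locus_pair[0])
    l2 = matrix.loci.index(locus_pair[1])
    c1 = matrix.calls[rows, l1, :]
    c2 = matrix.calls[rows, l2, :]
    ok = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
    c1, c2 = c1[ok], c2[ok]
    if len(c1) < 5:
        return TestResult("ld", np.nan, np.nan, n_perm, defined=False,
                          note="fewer than 5 doubly-genotyped individuals")
    g1, g2 = _genotype_ids(c1), _genotype_ids(c2)
    if g1.max() == 0 or g2.max() == 0:
        return TestResult("ld", np.nan, np.nan, n_perm, defined=False,
                          note="a locus is monomorphic in this population")
    g_obs = _g_statistic(g1, g2)
    rng = child_rng(seed, "ld", population, *locus_pair)
    b = 0
    for _ in range(n_perm):
        b += _g_statistic(g1, rng.permutation(g2)) >= g_obs - 1e-12
    p = (b + 1) / (n_perm + 1)
    return TestResult("ld", g_obs, p, n_perm)


def adjusted_level(alpha: float, n_loci: int) -> float:
    """Adjusted nominal level for all C(n_loci, 2) pairwise LD comparisons."""
    return alpha / comb(n_loci, 2)
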