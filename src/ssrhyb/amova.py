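"""Hierarchical analysis of molecular variance (AMOVA).

Inter-individual squared distance = number of allele differences between
the two diploid genotypes (0, 1 or 2 per locus), summed over loci both
individuals have typed and rescaled by (total loci / shared loci).  Sums
of squares come from within-partition pairwise distance sums (the
distance-matrix formulation); variance components solve the mean-square
expectations with unequal-size coefficients.  Fixation indices:
F_CT = s_a/s_T, F_SC = s_b/(s_b + s_c), F_ST = (s_a + s_b)/s_T, each
tested by its own permutation scheme (populations among groups;
individuals among populations within groups; individuals among all
populations) with the add-one p-value correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, child_rng


@dataclass
class AmovaResult:
    table: pd.DataFrame           # df, SS, variance component, % of variation
    f_ct: float
    f_sc: float
    f_st: float
    p_values: dict
    n_perm: int
    degenerate: bool = False
    flags: list = None


def amova_distance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Squared-distance matrix: allele differences per shared locus,
    rescaled by total/shared loci.  Pairs sharing no typed locus get NaN."""
    n, L = matrix.n_individuals, matrix.n_loci
    if n < 2:
        raise ValueError("need at least two individuals")
    calls = matrix.calls
    typed = calls[:, :, 0] != MISSING
    # per-locus allele difference count: 2 - multiset intersection size
    D = np.zeros((n, n))
    shared = typed.astype(np.int32) @ typed.astype(np.int32).T
    for l in range(L):
        a = calls[:, l, :]  # sorted pairs
        # matches between sorted pairs (x1,x2) and (y1,y2):
        x1, x2 = a[:, 0][:, None], a[:, 1][:, None]
        y1, y2 = a[:, 0][None, :], a[:, 1][None, :]
        both_same = (x1 == y1) & (x2 == y2)
        one = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
        diff = np.where(both_same, 0, np.where(one, 1, 2)).astype(float)
        ok = typed[:, l]
        diff[~ok, :] = 0.0
        diff[:, ~ok] = 0.0
        D += diff
    with np.errstate(divide="ignore", invalid="ignore"):
        D = D * (L / shared)
    D[shared == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.individuals, columns=matrix.individuals)


def _ss_within(D: np.ndarray, members: np.ndarray) -> float:
    """SS of a partition cell: sum of pairwise d^2 / cell size."""
    sub = D[np.ix_(members, members)]
    return float(sub.sum() / (2 * len(members)))


def _amova_core(D, pop_codes, grp_of_pop):
    """SS decomposition + variance components for one assignment."""
    N = len(pop_codes)
    pops = np.unique(pop_codes)
    groups = np.unique([grp_of_pop[p] for p in pops])
    P, g = len(pops), len(groups)

    ss_total = float(D.sum() / (2 * N))
    ss_wp = 0.0
    n_p = {}
    for p in pops:
        members = np.where(pop_codes == p)[0]
        n_p[p] = len(members)
        ss_wp += _ss_within(D, members)
    ss_ag_plus = 0.0  # SS among pops within groups, via group totals
    N_g = {}
    grp_arr = np.array([grp_of_pop[p] for p in pop_codes])
    for gr in groups:
        members = np.where(grp_arr == gr)[0]
        N_g[gr] = len(members)
        ss_ag_plus += _ss_within(D, members)
    ss_ap = ss_ag_plus - ss_wp
    ss_ag = ss_total - ss_ag_plus

    df_ag, df_ap, df_wp = g - 1, P - g, N - P
    ms_wp = ss_wp / df_wp if df_wp else np.nan
    sigma_c = ms_wp
    # unequal-size coefficients
    sum_np2_over_Ng = sum(
        sum(n_p[p] ** 2 for p in pops if grp_of_pop[p] == gr) / N_g[gr]
        for gr in groups
    )
    sum_np2_over_N = sum(n_p[p] ** 2 for p in pops) / N
    sum_Ng2_over_N = sum(N_g[gr] ** 2 for gr in groups) / N
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap else np.nan
    n2 = (sum_np2_over_Ng - sum_np2_over_N) / df_ag if df_ag else np.nan
    n3 = (N - sum_Ng2_over_N) / df_ag if df_ag else np.nan

    sigma_b = (ss_ap / df_ap - sigma_c) / n1 if df_ap else np.nan
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3 if df_ag else np.nan
    return dict(
        ss=(ss_ag, ss_ap, ss_wp),
        df=(df_ag, df_ap, df_wp),
        sigma=(sigma_a, sigma_b, sigma_c),
    )


def _indices(sigma):
    sa, sb, sc = sigma
    st = sa + sb + sc
    if st == 0:
        return np.nan, np.nan, np.nan
    f_ct = sa / st
    f_sc = sb / (sb + sc) if (sb + sc) != 0 else np.nan
    f_st = (sa + sb) / st
    return f_ct, f_sc, f_st


def amova(
    matrix: GenotypeMatrix,
    group_assignment: pd.Series,
    pop_assignment: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Two-level hierarchical AMOVA (groups / populations / individuals).

    group_assignment and pop_assignment map individuals to their group
    (region or species) and population.  Permutation schemes: F_CT permutes
    whole populations among groups; F_SC permutes individuals among
    populations within groups; F_ST permutes individuals among all
    populations.
    """
    inds = matrix.individuals
    pops = pop_assignment.reindex(inds).to_numpy()
    grp_of_pop = (
        pd.DataFrame({"pop": pops, "grp": group_assignment.reindex(inds).to_numpy()})
        .drop_duplicates()
        .set_index("pop")["grp"]
        .to_dict()
    )
    if len(set(grp_of_pop.values())) < 2:
        raise ValueError("need at least two groups")
    flags = []
    sizes = pd.Series(pops).value_counts()
    if (sizes == 1).any():
        flags.append(f"single-individual population(s): {list(sizes.index[sizes == 1])}")

    Dm = amova_distance_matrix(matrix)
    D = np.nan_to_num(Dm.to_numpy(), nan=0.0)
    if np.isnan(Dm.to_numpy()).any():
        flags.append("pairs sharing zero loci treated as distance 0")

    core = _amova_core(D, pops, grp_of_pop)
    sa, sb, sc = core["sigma"]
    if min(sa, sb, sc) < 0:
        flags.append("negative variance component retained")
    f_ct, f_sc, f_st = _indices(core["sigma"])
    degenerate = D.sum() == 0

    rng = child_rng(seed, "amova")
    uniq_pops = np.unique(pops)
    pop_groups = np.array([grp_of_pop[p] for p in uniq_pops])
    exceed = {"F_CT": 0, "F_SC": 0, "F_ST": 0}
    for _ in range(n_perm):
        # F_CT: permute whole populations among groups
        gperm = rng.permutation(pop_groups)
        gmap = dict(zip(uniq_pops, gperm))
        c = _amova_core(D, pops, gmap)
        v = _indices(c["sigma"])[0]
        if not np.isnan(v) and v >= f_ct - 1e-12:
            exceed["F_CT"] += 1
        # F_SC: permute individuals among populations within groups
        perm_pops = pops.copy()
        grp_arr = np.array([grp_of_pop[p] for p in pops])
        for gr in np.unique(grp_arr):
            m = grp_arr == gr
            perm_pops[m] = rng.permutation(pops[m])
        c = _amova_core(D, perm_pops, grp_of_pop)
        v = _indices(c["sigma"])[1]
        if not np.isnan(v) and v >= f_sc - 1e-12:
            exceed["F_SC"] += 1
        # F_ST: permute individuals among all populations
        c = _amova_core(D, rng.permutation(pops), grp_of_pop)
        v = _indices(c["sigma"])[2]
        if not np.isnan(v) and v >= f_st - 1e-12:
            exceed["F_ST"] += 1
    p_values = {k: (v + 1) / (n_perm + 1) for k, v in exceed.items()}

    sig = np.array(core["sigma"], dtype=float)
    pct = 100 * sig / sig.sum() if sig.sum() > 0 else np.full(3, np.nan)
    table = pd.DataFrame(
        {
            "df": core["df"],
            "SS": core["ss"],
            "variance": core["sigma"],
            "percent": pct,
        },
        index=["among_groups", "among_populations_within_groups", "within_populations"],
    )
    return AmovaResult(
        table=table,
        f_ct=f_ct, f_sc=f_sc, f_st=f_st,
        p_values=p_values,
        n_perm=n_perm,
        degenerate=degenerate,
        flags=flags,
    )
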