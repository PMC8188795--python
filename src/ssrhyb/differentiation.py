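"""Population differentiation: Weir–Cockerham theta, the "exclusion null
alleles" (ENA) corrected cF_ST, Hedrick's G'_ST, gene-flow N_m, pairwise
F_ST with sympatric/allopatric stratification, and PCoA.

The theta estimator follows the multi-allelic variance-components form:
per allele and locus, components a (among populations), b (among
individuals within populations) and c (within individuals) are computed
from sample sizes, allele frequencies and observed heterozygote
frequencies; theta = sum(a) / sum(a+b+c) over alleles and loci (ratio of
sums, not mean of ratios).  Negative estimates are reported as-is.

The ENA correction replaces each population's allele-frequency inputs with
the EM-corrected visible-allele frequencies and sums components over
visible alleles only (the null class is excluded); 95% CIs come from a
percentile bootstrap over loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, child_rng
from .diversity import unbiased_expected_het


@dataclass
class ThetaResult:
    theta_per_locus: pd.Series
    theta_global: float
    f_global: float                      # Weir–Cockerham f (F_IS) by-product
    components: np.ndarray               # (L, 3) summed a, b, c per locus
    ci: tuple[float, float] | None = None
    per_locus_p: pd.Series | None = None


@dataclass
class PairwiseFstMatrix:
    values: pd.DataFrame                 # symmetric, zero diagonal
    strata: pd.DataFrame | None = None   # per-pair stratum labels


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Weir–Cockerham components
# ---------------------------------------------------------------------------

def _pop_inputs(matrix: GenotypeMatrix, grouping: pd.Series, with_missing=False):
    """Per population & locus: n (typed individuals), allele freqs, and
    per-allele observed heterozygote frequencies."""
    grouping = grouping.reindex(matrix.individuals)
    pops = list(pd.unique(grouping))
    ind_pos = {ind: i for i, ind in enumerate(matrix.individuals)}
    rows_of = {
        g: np.array([ind_pos[i] for i in idx])
        for g, idx in grouping.groupby(grouping).groups.items()
    }
    L = matrix.n_loci
    A = max(matrix.n_alleles(l) for l in range(L))
    r = len(pops)
    n = np.zeros((r, L))
    p = np.zeros((r, L, A))
    h = np.zeros((r, L, A))  # per-allele heterozygote frequency
    miss = np.zeros((r, L))
    for gi, g in enumerate(pops):
        calls = matrix.calls[rows_of[g]]
        for l in range(L):
            c = calls[:, l, :]
            typed = c[c[:, 0] != MISSING]
            m = len(typed)
            n[gi, l] = m
            miss[gi, l] = len(c) - m
            if m == 0:
                continue
            cnt = np.bincount(typed.ravel(), minlength=A)
            p[gi, l, :] = cnt / (2 * m)
            het = typed[typed[:, 0] != typed[:, 1]]
            if het.size:
                hcnt = np.bincount(het.ravel(), minlength=A)
                h[gi, l, :] = hcnt / m
    if with_missing:
        return pops, n, p, h, miss
    return pops, n, p, h


def _wc_components(n, p, h, allele_mask=None):
    """Per-locus summed (a, b, c) from per-population inputs.

    n: (r, L); p, h: (r, L, A).  allele_mask: (L, A) bool of alleles to
    include (for the ENA visible-only summation).
    """
    r, L, A = p.shape
    comps = np.zeros((L, 3))
    for l in range(L):
        use = n[:, l] >= 1
        nl = n[use, l]
        ri = int(use.sum())
        if ri < 2:
            continue
        nbar = nl.mean()
        if nbar <= 1:
            continue
        nc = (ri * nbar - (nl**2).sum() / (ri * nbar)) / (ri - 1)
        for a in range(A):
            if allele_mask is not None and not allele_mask[l, a]:
                continue
            pa = p[use, l, a]
            ha = h[use, l, a]
            if np.all(pa == 0):
                continue
            pbar = (nl * pa).sum() / (ri * nbar)
            s2 = (nl * (pa - pbar) ** 2).sum() / ((ri - 1) * nbar)
            hbar = (nl * ha).sum() / (ri * nbar)
            a_c = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (ri - 1) / ri - hbar / 4) / (nbar - 1)
            )
            b_c = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (ri - 1) / ri - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_c = hbar / 2
            comps[l] += (a_c, b_c, c_c)
    return comps


def wc_theta(matrix: GenotypeMatrix, grouping: pd.Series) -> ThetaResult:
    """Weir–Cockerham theta, per locus and global (ratio of summed
    components), plus the within-population f (F_IS)."""
    grouping = grouping.reindex(matrix.individuals)
    if pd.unique(grouping).size < 2:
        raise ValueError("need at least two groups")
    pops, n, p, h = _pop_inputs(matrix, grouping)
    comps = _wc_components(n, p, h)
    return _theta_from_components(comps, matrix.loci)


def _theta_from_components(comps, loci) -> ThetaResult:
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = comps[:, 0] / comps.sum(axis=1)
    tot = comps.sum(axis=0)
    theta_g = float(tot[0] / tot.sum()) if tot.sum() != 0 else np.nan
    bc = tot[1] + tot[2]
    f_g = float(1 - tot[2] / bc) if bc != 0 else np.nan
    return ThetaResult(
        theta_per_locus=pd.Series(per_locus, index=list(loci), name="theta"),
        theta_global=theta_g,
        f_global=f_g,
        components=comps,
    )


def _bootstrap_ci(comps, n_boot, rng) -> tuple[float, float]:
    """Percentile bootstrap over loci of the global ratio-of-sums theta."""
    L = comps.shape[0]
    idx = rng.integers(0, L, size=(n_boot, L))
    sums = comps[idx].sum(axis=1)  # (n_boot, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = sums[:, 0] / sums.sum(axis=1)
    lo, hi = np.nanquantile(thetas, [0.025, 0.975])
    return float(lo), float(hi)


def ena_theta(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    em_results: dict,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """ENA-corrected cF_ST with bootstrap CIs (and the uncorrected theta
    with its CI, from the same resampling scheme).

    ``em_results`` maps (population, locus) -> NullEMResult (visible
    frequencies summing to 1 - pi).

    The correction reconstructs complete-data inputs with the null class
    as a hidden allele: visible-allele frequencies come from the EM;
    the sample size becomes all individuals (null homozygotes are the
    structural missing); and each visible allele's heterozygote frequency
    is augmented by the expected (allele, null) genotypes scored as
    apparent homozygotes, 2 p_a pi.  Components are then summed over
    visible alleles only.  With pi-hat = 0 everywhere the correction is
    the identity.
    """
    grouping = grouping.reindex(matrix.individuals)
    pops, n, p, h, miss = _pop_inputs(matrix, grouping, with_missing=True)
    L, A = p.shape[1], p.shape[2]
    p_corr = p.copy()
    h_corr = h.copy()
    n_corr = n.copy()
    for gi, g in enumerate(pops):
        for l, locus in enumerate(matrix.loci):
            key = (g, locus)
            if key not in em_results:
                raise ValueError(f"missing EM result for {key}")
            res = em_results[key]
            vf = res.visible_freqs
            p_corr[gi, l, : vf.size] = vf
            p_corr[gi, l, vf.size:] = 0.0
            n_full = n[gi, l] + miss[gi, l]
            if n_full > 0 and res.pi > 0:
                n_corr[gi, l] = n_full
                # observed het counts stay valid (visible-visible pairs are
                # never masked); add the expected hidden (a, null) hets
                h_corr[gi, l, : vf.size] = (
                    h[gi, l, : vf.size] * n[gi, l] + 2 * vf * res.pi * n_full
                ) / n_full
                h_corr[gi, l, vf.size:] = 0.0
    mask = np.ones((L, A), dtype=bool)  # null class never enters p arrays
    comps_raw = _wc_components(n, p, h)
    comps_ena = _wc_components(n_corr, p_corr, h_corr, allele_mask=mask)
    raw = _theta_from_components(comps_raw, matrix.loci)
    ena = _theta_from_components(comps_ena, matrix.loci)
    rng = child_rng(seed, "ena-bootstrap")
    raw.ci = _bootstrap_ci(comps_raw, n_boot, rng)
    rng = child_rng(seed, "ena-bootstrap-corrected")
    ena.ci = _bootstrap_ci(comps_ena, n_boot, rng)
    return {"fst": raw, "cfst": ena}


# ---------------------------------------------------------------------------
# G_ST / G'_ST and gene flow
# ---------------------------------------------------------------------------

def hedrick_gst(matrix: GenotypeMatrix, grouping: pd.Series) -> pd.DataFrame:
    """Nei G_ST and Hedrick's standardized G'_ST, per locus and overall.

    H_S = mean over populations of unbiased within-population diversity;
    H_T = unbiased total diversity on the pooled sample;
    G'_ST = G_ST (s - 1 + H_S) / [(s - 1)(1 - H_S)].
    """
    grouping = grouping.reindex(matrix.individuals)
    pops, n, p, h = _pop_inputs(matrix, grouping)
    s = len(pops)
    if s < 2:
        raise ValueError("need at least two groups")
    rows = []
    hs_list, ht_list = [], []
    for l, locus in enumerate(matrix.loci):
        hs_vals = [
            unbiased_expected_het(p[gi, l][p[gi, l] > 0], int(n[gi, l]))
            for gi in range(s) if n[gi, l] > 0
        ]
        H_S = float(np.mean(hs_vals))
        ntot = int(n[:, l].sum())
        pooled = (n[:, l:l + 1] * p[:, l, :]).sum(axis=0) / ntot
        H_T = unbiased_expected_het(pooled[pooled > 0], ntot)
        hs_list.append(H_S)
        ht_list.append(H_T)
        rows.append(_gst_row(locus, H_S, H_T, s))
    rows.append(_gst_row("overall", float(np.mean(hs_list)), float(np.mean(ht_list)), s))
    return pd.DataFrame(rows).set_index("locus")


def _gst_row(locus, H_S, H_T, s):
    if H_T <= 0:
        return dict(locus=locus, H_S=H_S, H_T=H_T, G_ST=np.nan, Gp_ST=np.nan,
                    defined=False)
    gst = (H_T - H_S) / H_T
    gpst = gst * (s - 1 + H_S) / ((s - 1) * (1 - H_S)) if H_S < 1 else np.nan
    return dict(locus=locus, H_S=H_S, H_T=H_T, G_ST=gst, Gp_ST=gpst, defined=True)


def gene_flow(value: float, formula_tag: str = "wright") -> float:
    """Indirect N_m from differentiation.

    wright: N_m = (1 - F_ST) / (4 F_ST); gst: N_m = 0.5 (1 - G_ST) / G_ST.
    Non-positive input -> +inf (undefined / unbounded gene flow).
    """
    if value <= 0:
        return np.inf
    if value > 1:
        raise ValueError("differentiation index must be in (0, 1]")
    if formula_tag == "wright":
        return (1 - value) / (4 * value)
    if formula_tag == "gst":
        return 0.5 * (1 - value) / value
    raise ValueError(f"unknown formula_tag {formula_tag!r}")


# ---------------------------------------------------------------------------
# Pairwise F_ST, stratification, PCoA
# ---------------------------------------------------------------------------

def pairwise_fst(matrix: GenotypeMatrix, grouping: pd.Series) -> PairwiseFstMatrix:
    """Weir–Cockerham theta for every population pair (negatives kept)."""
    grouping = grouping.reindex(matrix.individuals)
    pops = list(pd.unique(grouping))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    ind = np.array(matrix.individuals)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            sel = grouping.isin([a, b])
            sub_rows = np.where(sel.reindex(matrix.individuals).to_numpy())[0]
            sub = matrix.subset(sub_rows)
            th = wc_theta(sub, grouping.loc[ind[sub_rows]])
            vals.loc[a, b] = vals.loc[b, a] = th.theta_global
    return PairwiseFstMatrix(values=vals)


def stratify_pairs(
    pw: PairwiseFstMatrix, metadata
) -> pd.DataFrame:
    """Assign each population pair a sympatry/homology stratum and report
    stratum means.

    same site + different species -> sympatric heterogeneous;
    different site + same species -> allopatric homologous;
    different site + different species -> allopatric heterogeneous.
    Same site + same species cannot occur (one population per species per
    site in the study design) — asserted.
    """
    tab = metadata.table.drop_duplicates("population").set_index("population")
    pops = list(pw.values.index)
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            same_site = tab.loc[a, "site"] == tab.loc[b, "site"]
            same_sp = tab.loc[a, "species"] == tab.loc[b, "species"]
            if same_site and same_sp:
                raise AssertionError(
                    f"populations {a}, {b} share both site and species"
                )
            if same_site:
                stratum = "sympatric_heterogeneous"
            elif same_sp:
                stratum = "allopatric_homologous"
            else:
                stratum = "allopatric_heterogeneous"
            rows.append(dict(pop_a=a, pop_b=b, stratum=stratum,
                             fst=pw.values.loc[a, b]))
    pairs = pd.DataFrame(rows)
    pw.strata = pairs
    means = pairs.groupby("stratum")["fst"].mean().rename("mean_fst")
    return means.to_frame()


def pcoa(pw: PairwiseFstMatrix | pd.DataFrame) -> PCoAResult:
    """Principal coordinate analysis (Gower double-centering of -0.5 D*D).

    Negative eigenvalues are reported but excluded from the percentages.
    """
    D = pw.values if isinstance(pw, PairwiseFstMatrix) else pw
    M = D.to_numpy(dtype=float)
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M * M) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    degenerate = not pos.any()
    coords = np.zeros((n, int(pos.sum())))
    if pos.any():
        coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = np.zeros_like(evals)
    if pos.any():
        pct[pos] = 100.0 * evals[pos] / evals[pos].sum()
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=D.index, columns=axes),
        eigenvalues=evals,
        percent_variance=pct,
        degenerate=degenerate,
    )


def _inputs_from_codes(calls: np.ndarray, codes: np.ndarray, r: int, A: int):
    """Numpy-only per-population inputs (n, p, h) for permutation loops."""
    L = calls.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L, A))
    h = np.zeros((r, L, A))
    for gi in range(r):
        c = calls[codes == gi]
        for l in range(L):
            cl = c[:, l, :]
            typed = cl[cl[:, 0] != MISSING]
            m = len(typed)
            n[gi, l] = m
            if m == 0:
                continue
            p[gi, l, :] = np.bincount(typed.ravel(), minlength=A) / (2 * m)
            het = typed[typed[:, 0] != typed[:, 1]]
            if het.size:
                h[gi, l, :] = np.bincount(het.ravel(), minlength=A) / m
    return n, p, h


def theta_permutation_test(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permute individuals among populations; add-one-corrected exceedance
    p-values for per-locus and global theta."""
    grouping = grouping.reindex(matrix.individuals)
    obs = wc_theta(matrix, grouping)
    rng = child_rng(seed, "theta-perm")
    codes, uniq = pd.factorize(grouping)
    r = len(uniq)
    A = max(matrix.n_alleles(l) for l in range(matrix.n_loci))
    calls = matrix.calls
    exceed_locus = np.zeros(matrix.n_loci)
    exceed_global = 0
    obs_locus = obs.theta_per_locus.to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        n, p, h = _inputs_from_codes(calls, perm, r, A)
        comps = _wc_components(n, p, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            tl = comps[:, 0] / comps.sum(axis=1)
        tot = comps.sum(axis=0)
        tg = tot[0] / tot.sum() if tot.sum() != 0 else np.nan
        exceed_locus += tl >= obs_locus - 1e-12
        exceed_global += tg >= obs.theta_global - 1e-12
    p_locus = (exceed_locus + 1) / (n_perm + 1)
    obs.per_locus_p = pd.Series(p_locus, index=matrix.loci, name="p")
    return {
        "theta": obs,
        "p_global": (exceed_global + 1) / (n_perm + 1),
        "p_per_locus": obs.per_locus_p,
    }
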