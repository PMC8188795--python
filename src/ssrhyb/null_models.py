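"""Null-allele frequency estimation.

Two estimators per locus x population:

* an EM maximum-likelihood estimator under HWE with the classical
  null-allele observation model (true heterozygote (i, j) observed as is;
  true (i, null) observed as the apparent homozygote (i, i); true
  (null, null) observed as missing) — this feeds the ENA-corrected F_ST;

* a Bayesian model with null alleles (n), a population-level inbreeding
  coefficient (f) and a genotyping failure rate (b), sampled by data
  augmentation (conjugate Gibbs), with DIC comparison of the full ``nfb``
  model against the reduced ``fb`` model (null frequencies pinned at 0).
  The posterior mean of f under ``nfb`` is the corrected inbreeding
  coefficient F_IS'.

Observed-data likelihood shared by both (per call, visible freqs p, null
freq pi, inbreeding f, failure b):

  het (i, j):   (1-b) (1-f) 2 p_i p_j
  hom (i, i):   (1-b) [ f p_i + (1-f) (p_i^2 + 2 p_i pi) ]
  missing:      b + (1-b) [ f pi + (1-f) pi^2 ]

The EM estimator is the f=0, b=0 special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, child_rng


@dataclass
class NullEMResult:
    pi: float
    visible_freqs: np.ndarray  # sums to 1 - pi
    n_iter: int
    converged: bool
    log_likelihood: float


@dataclass
class NFBResult:
    pi_mean: np.ndarray          # per locus
    pi_ci: np.ndarray            # (L, 2) 95% credible intervals
    f_mean: float
    f_ci: tuple[float, float]
    b_mean: float
    b_ci: tuple[float, float]
    dic: float
    model: str                   # "nfb" or "fb"
    n_samples: int
    traces: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _locus_classes(matrix: GenotypeMatrix, rows: np.ndarray, locus_index: int):
    """Split calls into het pairs, homozygote counts and missing count."""
    calls = matrix.calls[rows, locus_index, :]
    miss = calls[:, 0] == MISSING
    calls = calls[~miss]
    het = calls[calls[:, 0] != calls[:, 1]]
    hom = calls[calls[:, 0] == calls[:, 1], 0]
    A = matrix.n_alleles(locus_index)
    hom_counts = np.bincount(hom, minlength=A) if hom.size else np.zeros(A, int)
    het_counts = np.zeros(A, dtype=np.int64)
    if het.size:
        het_counts = np.bincount(het.ravel(), minlength=A)
    return het_counts, hom_counts, int(miss.sum()), len(calls)


def _em_loglik(p, pi, het_counts, hom_counts, n_missing):
    ll = 0.0
    vis = hom_counts > 0
    if vis.any():
        ll += float((hom_counts[vis] * np.log(p[vis] ** 2 + 2 * p[vis] * pi)).sum())
    hetv = het_counts > 0
    # per-copy contribution of het calls: each copy of allele i appears once
    # (the 2 p_i p_j factor splits into per-copy log p terms plus a constant)
    if hetv.any():
        ll += float((het_counts[hetv] * np.log(p[hetv])).sum())
    if n_missing:
        ll += n_missing * 2 * np.log(max(pi, 1e-300))
    return ll


def em_null(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    population: str,
    locus: str,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> NullEMResult:
    """EM estimate of the null-allele frequency at one locus in one group.

    E-step: a fraction 2 p_i pi / (p_i^2 + 2 p_i pi) of each apparent
    homozygote class is attributed to (i, null); all structural missing to
    (null, null).  M-step re-normalizes expected allele-copy counts.
    The log-likelihood is non-decreasing; convergence when the largest
    frequency change drops below ``tol``.
    """
    rows = np.array(
        [i for i, ind in enumerate(matrix.individuals)
         if grouping.get(ind) == population]
    )
    l = matrix.loci.index(locus)
    het_counts, hom_counts, n_missing, n_typed = _locus_classes(matrix, rows, l)
    A = het_counts.size
    n_calls = n_typed + n_missing
    if n_typed < 5:
        raise ValueError(
            f"{population}/{locus}: fewer than 5 non-missing individuals"
        )
    if hom_counts.sum() == 0 and n_missing == 0:
        p = het_counts / het_counts.sum()
        return NullEMResult(0.0, p, 0, True,
                            _em_loglik(p, 0.0, het_counts, hom_counts, 0))

    total_copies = 2 * n_calls
    # init: visible freqs from observed copies scaled to 0.9, pi = 0.1
    obs = het_counts + 2 * hom_counts
    p = 0.9 * obs / obs.sum()
    pi = 0.1
    last_ll = -np.inf
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(
                hom_counts > 0, 2 * p * pi / (p**2 + 2 * p * pi), 0.0
            )
        w = np.nan_to_num(w)
        # expected copies: het copies + hom classes split into (i,i) / (i,null)
        exp_i = het_counts + hom_counts * (2 * (1 - w) + w)
        exp_null = float((hom_counts * w).sum()) + 2 * n_missing
        new_p = exp_i / total_copies
        new_pi = exp_null / total_copies
        ll = _em_loglik(new_p, new_pi, het_counts, hom_counts, n_missing)
        if ll < last_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        delta = max(float(np.max(np.abs(new_p - p))), abs(new_pi - pi))
        p, pi, last_ll = new_p, new_pi, ll
        if delta < tol:
            return NullEMResult(float(pi), p, it, True, last_ll)
    return NullEMResult(float(pi), p, max_iter, False, last_ll)


def em_null_all(
    matrix: GenotypeMatrix, grouping: pd.Series, tol: float = 1e-8
) -> dict[tuple[str, str], NullEMResult]:
    """EM results for every population x locus combination."""
    out = {}
    for pop in pd.unique(grouping.reindex(matrix.individuals)):
        for locus in matrix.loci:
            out[(pop, locus)] = em_null(matrix, grouping, pop, locus, tol=tol)
    return out


def null_frequency_table(em_results: dict) -> pd.DataFrame:
    """Locus x population table of EM null-frequency estimates."""
    ser = pd.Series({k: v.pi for k, v in em_results.items()})
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["population", "locus"])
    return ser.unstack("population")


def flag_usable_loci(
    em_results: dict | pd.DataFrame,
    max_thresh: float = 0.2,
    mean_thresh: float = 0.1,
) -> pd.Series:
    """Keep a locus iff max pi < max_thresh AND mean pi < mean_thresh
    across populations (both bounds strict)."""
    tab = em_results if isinstance(em_results, pd.DataFrame) else null_frequency_table(em_results)
    return (tab.max(axis=1) < max_thresh) & (tab.mean(axis=1) < mean_thresh)


# ---------------------------------------------------------------------------
# Bayesian nfb model (conjugate Gibbs via data augmentation)
# ---------------------------------------------------------------------------

def _deviance(p_list, pi, f, b, class_data):
    """-2 log likelihood of the observed calls."""
    ll = 0.0
    for l, (het_pairs, hom, n_missing) in enumerate(class_data):
        p = p_list[l]
        pil = pi[l]
        if het_pairs.size:
            terms = (1 - b) * (1 - f) * 2 * p[het_pairs[:, 0]] * p[het_pairs[:, 1]]
            ll += float(np.log(np.maximum(terms, 1e-300)).sum())
        if hom.size:
            ph = p[hom]
            terms = (1 - b) * (f * ph + (1 - f) * (ph**2 + 2 * ph * pil))
            ll += float(np.log(np.maximum(terms, 1e-300)).sum())
        if n_missing:
            ll += n_missing * np.log(max(b + (1 - b) * (f * pil + (1 - f) * pil**2), 1e-300))
    return -2.0 * ll


def nfb_mcmc(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    population: str,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 10,
    seed: int = 0,
    include_nulls: bool = True,
) -> NFBResult:
    """Gibbs sampler for the null-allele / inbreeding / failure model.

    Latent-variable augmentation makes every conditional conjugate:
    each observed call is assigned a latent state (IBD or not; carrying a
    null copy or not; a failure or not), after which allele frequencies
    (visible + null) get a Dirichlet update per locus, and f and b get
    Beta updates.  Priors are flat: Dirichlet(1) over (p, pi) per locus,
    Uniform(0,1) for f and b.  ``include_nulls=False`` fits the reduced
    ``fb`` model (pi pinned at 0).

    DIC = mean deviance + p_D with p_D = mean deviance - deviance at the
    posterior means.
    """
    rows = np.array(
        [i for i, ind in enumerate(matrix.individuals)
         if grouping.get(ind) == population]
    )
    if rows.size < 10:
        raise ValueError(f"{population}: fewer than 10 individuals")
    rng = child_rng(seed, "nfb", population, int(include_nulls))
    L = matrix.n_loci

    class_data = []
    for l in range(L):
        calls = matrix.calls[rows, l, :]
        miss = calls[:, 0] == MISSING
        typed = calls[~miss]
        het_pairs = typed[typed[:, 0] != typed[:, 1]]
        hom = typed[typed[:, 0] == typed[:, 1], 0]
        class_data.append((het_pairs, hom, int(miss.sum())))

    n_alleles = [matrix.n_alleles(l) for l in range(L)]
    # state
    p_list = [np.full(A, 1.0 / (A + 1)) for A in n_alleles]
    pi = np.full(L, 1.0 / (np.array(n_alleles) + 1.0)) if include_nulls else np.zeros(L)
    f, b = 0.1, 0.05

    keep = max((n_iter - burn_in) // thin, 1)
    tr_pi = np.empty((keep, L))
    tr_f = np.empty(keep)
    tr_b = np.empty(keep)
    tr_dev = np.empty(keep)
    tr_p = [np.empty((keep, A)) for A in n_alleles]
    k = 0

    for sweep in range(n_iter):
        n_ibd = n_out = 0        # IBD vs outbred latent calls
        n_fail = n_ok = 0        # failed vs successful calls
        for l in range(L):
            het_pairs, hom, n_missing = class_data[l]
            p = p_list[l]
            pil = pi[l]
            A = n_alleles[l]
            copy_counts = np.zeros(A + 1)  # last slot: null copies

            if het_pairs.size:
                np.add.at(copy_counts, het_pairs[:, 0], 1)
                np.add.at(copy_counts, het_pairs[:, 1], 1)
                n_out += len(het_pairs)
                n_ok += len(het_pairs)

            if hom.size:
                ph = p[hom]
                w_ibd = f * ph
                w_hom = (1 - f) * ph**2
                w_null = (1 - f) * 2 * ph * pil
                tot = w_ibd + w_hom + w_null
                u = rng.random(hom.size) * tot
                ibd = u < w_ibd
                carries_null = (u >= w_ibd + w_hom)
                # IBD: one independent copy; outbred hom: two; (i,null): one + null
                np.add.at(copy_counts, hom[ibd], 1)
                np.add.at(copy_counts, hom[~ibd & ~carries_null], 2)
                np.add.at(copy_counts, hom[carries_null], 1)
                copy_counts[A] += int(carries_null.sum())
                n_ibd += int(ibd.sum())
                n_out += int(hom.size - ibd.sum())
                n_ok += hom.size

            if n_missing:
                w_fail = b
                w_ibd = (1 - b) * f * pil
                w_nn = (1 - b) * (1 - f) * pil**2
                tot = w_fail + w_ibd + w_nn
                u = rng.random(n_missing) * tot
                failed = int((u < w_fail).sum())
                ibd_null = int(((u >= w_fail) & (u < w_fail + w_ibd)).sum())
                nn = n_missing - failed - ibd_null
                copy_counts[A] += ibd_null + 2 * nn
                n_fail += failed
                n_ok += n_missing - failed
                n_ibd += ibd_null
                n_out += nn

            if include_nulls:
                draw = rng.gamma(1.0 + copy_counts)
                draw /= draw.sum()
                p_list[l] = draw[:A]
                pi[l] = draw[A]
            else:
                draw = rng.gamma(1.0 + copy_counts[:A])
                p_list[l] = draw / draw.sum()

        f = rng.beta(1 + n_ibd, 1 + n_out)
        b = rng.beta(1 + n_fail, 1 + n_ok)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and k < keep:
            tr_pi[k] = pi
            tr_f[k] = f
            tr_b[k] = b
            for l in range(L):
                tr_p[l][k] = p_list[l]
            tr_dev[k] = _deviance(p_list, pi, f, b, class_data)
            k += 1

    tr_pi, tr_f, tr_b, tr_dev = tr_pi[:k], tr_f[:k], tr_b[:k], tr_dev[:k]
    if not np.isfinite(tr_dev).all():
        raise RuntimeError(
            f"{population}: non-finite deviance in chain "
            f"(f~{tr_f.mean():.3f}, b~{tr_b.mean():.3f})"
        )
    p_mean = []
    for l in range(L):
        pm = tr_p[l][:k].mean(axis=0)
        p_mean.append(pm)
    pi_mean = tr_pi.mean(axis=0)
    # renormalize posterior means onto the simplex before plugging in
    for l in range(L):
        s = p_mean[l].sum() + (pi_mean[l] if include_nulls else 0.0)
        p_mean[l] = p_mean[l] / s
        if include_nulls:
            pi_mean[l] = pi_mean[l] / s
    d_bar = float(tr_dev.mean())
    d_hat = _deviance(p_mean, pi_mean if include_nulls else np.zeros(L),
                      float(tr_f.mean()), float(tr_b.mean()), class_data)
    dic = d_bar + (d_bar - d_hat)

    def ci(x):
        return tuple(np.quantile(x, [0.025, 0.975]))

    return NFBResult(
        pi_mean=pi_mean,
        pi_ci=np.quantile(tr_pi, [0.025, 0.975], axis=0).T,
        f_mean=float(tr_f.mean()),
        f_ci=ci(tr_f),
        b_mean=float(tr_b.mean()),
        b_ci=ci(tr_b),
        dic=float(dic),
        model="nfb" if include_nulls else "fb",
        n_samples=k,
        traces={"pi": tr_pi, "f": tr_f, "b": tr_b, "deviance": tr_dev},
    )


def nfb_model_comparison(
    matrix: GenotypeMatrix,
    grouping: pd.Series,
    population: str,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 10,
    seed: int = 0,
) -> dict:
    """Fit nfb and fb; report both DICs and which the criterion favors.

    DIC differences below 2 are reported as "indistinguishable".
    """
    full = nfb_mcmc(matrix, grouping, population, n_iter, burn_in, thin, seed, True)
    reduced = nfb_mcmc(matrix, grouping, population, n_iter, burn_in, thin, seed, False)
    diff = reduced.dic - full.dic
    if abs(diff) < 2:
        favored = "indistinguishable"
    else:
        favored = "nfb" if full.dic < reduced.dic else "fb"
    return {
        "nfb": full,
        "fb": reduced,
        "dic_nfb": full.dic,
        "dic_fb": reduced.dic,
        "favored": favored,
        "f_is_corrected": full.f_mean,
    }
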