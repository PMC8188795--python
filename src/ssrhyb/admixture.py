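"""Bayesian admixture clustering and model selection.

Gibbs sampler for the admixture model with uncorrelated cluster allele
frequencies: each allele copy gets a latent cluster of origin Z sampled
proportionally to q_ik * p_kla; cluster frequencies P get a
Dirichlet(lambda + counts) update (lambda = 1); individual ancestries Q a
Dirichlet(alpha + per-cluster copy counts) update; missing allele copies
are skipped.

The shared admixture parameter alpha is held fixed at a moderate value
(0.5) by default.  Inferring alpha (Metropolis step, uniform prior on
(0, 10)) is available via ``infer_alpha=True``, but when most sampled
individuals are purebred the alpha posterior collapses toward zero and
acts as a sparsity prior that biases admixed individuals' ancestries
toward the corners — which systematically misclassifies backcrosses as
purebreds.  A fixed symmetric Dirichlet(0.5) prior avoids that collapse
while remaining diffuse enough not to manufacture admixture.

The model evidence proxy reported per run is the usual
ln P(X|K) ~= mean(lnL) - var(lnL)/2 over post-burn-in sweeps, and the
optimal K is chosen by the Evanno second-difference statistic
DeltaK = mean|L(K+1) - 2L(K) + L(K-1)| / sd(L(K)) over replicate runs.

Replicate runs are aligned by minimizing the summed squared difference of
their Q matrices to an incrementally built reference; the objective
decomposes per cluster column, so the Hungarian assignment gives the
exact optimal label permutation for any K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .geno_io import MISSING, GenotypeMatrix, child_rng


@dataclass
class AdmixtureRun:
    K: int
    Q: pd.DataFrame                  # individuals x clusters, rows sum to 1
    P: np.ndarray                    # (K, L, A) posterior-mean frequencies
    alpha_mean: float
    ln_prob: float                   # estimated ln P(X | K)
    lnl_mean: float
    lnl_var: float
    n_burnin: int
    n_iter: int
    seed: int


@dataclass
class KSelection:
    table: pd.DataFrame              # per K: L mean, sd, delta_k
    selected_k: int
    flags: list = field(default_factory=list)


def _flatten_copies(matrix: GenotypeMatrix):
    """(ind_idx, locus_idx, allele) arrays over all non-missing copies."""
    n, L = matrix.n_individuals, matrix.n_loci
    calls = matrix.calls
    ii, ll, aa = [], [], []
    for j in (0, 1):
        c = calls[:, :, j]
        ok = c != MISSING
        idx = np.nonzero(ok)
        ii.append(idx[0])
        ll.append(idx[1])
        aa.append(c[ok])
    return (
        np.concatenate(ii).astype(np.int64),
        np.concatenate(ll).astype(np.int64),
        np.concatenate(aa).astype(np.int64),
    )


def structure_mcmc(
    matrix: GenotypeMatrix,
    K: int,
    n_burnin: int = 1000,
    n_iter: int = 2000,
    seed: int = 0,
    alpha0: float = 0.5,
    lambda_: float = 1.0,
    infer_alpha: bool = False,
    alpha_proposal_sd: float = 0.05,
    alpha_max: float = 10.0,
) -> AdmixtureRun:
    """One admixture-model MCMC run at a fixed K.

    Returns posterior-mean Q and P plus the ln P(X|K) estimate.  Default
    chain lengths are scaled down for desk-scale work; longer (program-
    scale) runs are a config choice.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n, L = matrix.n_individuals, matrix.n_loci
    ii, ll, aa = _flatten_copies(matrix)
    n_copies = ii.size
    if K > n_copies:
        raise ValueError("K exceeds the number of observed allele copies")
    A = max(matrix.n_alleles(l) for l in range(L))
    valid = np.zeros((L, A))
    for l in range(L):
        valid[l, : matrix.n_alleles(l)] = 1.0
    rng = child_rng(seed, "structure", K)

    lam = lambda_ * valid[None, :, :].repeat(K, axis=0)  # (K, L, A)
    Q = np.full((n, K), 1.0 / K)
    P = np.where(valid > 0, 1.0, 0.0)
    P = (P / P.sum(axis=1, keepdims=True))[None].repeat(K, axis=0)
    alpha = alpha0

    flat_la = ll * A + aa  # index into (L*A) frequency tables
    Q_acc = np.zeros((n, K))
    P_acc = np.zeros((K, L, A))
    alpha_acc = 0.0
    lnls = []
    kept = 0

    total = n_burnin + n_iter
    for sweep in range(total):
        # --- Z | Q, P ---
        Pf = P.reshape(K, L * A)
        W = Q[ii, :] * Pf[:, flat_la].T          # (n_copies, K)
        tot = W.sum(axis=1)
        if K == 1:
            Z = np.zeros(n_copies, dtype=np.int64)
        else:
            u = rng.random(n_copies) * tot
            Z = (np.cumsum(W, axis=1) < u[:, None]).sum(axis=1)
            Z = np.minimum(Z, K - 1)
        # --- P | Z ---
        cnt = np.bincount(Z * (L * A) + flat_la, minlength=K * L * A).reshape(K, L, A)
        draw = rng.gamma(lam + cnt)  # gamma(0) == 0 keeps invalid alleles at 0
        P = draw / np.maximum(draw.sum(axis=2, keepdims=True), 1e-300)
        # --- Q | Z ---
        cik = np.bincount(ii * K + Z, minlength=n * K).reshape(n, K).astype(float)
        qdraw = rng.gamma(alpha + cik)
        Q = qdraw / qdraw.sum(axis=1, keepdims=True)
        # --- alpha | Q (Metropolis) ---
        if infer_alpha and K > 1:
            prop = alpha + rng.normal(0.0, alpha_proposal_sd)
            if 0 < prop < alpha_max:
                lq = np.log(np.maximum(Q, 1e-300)).sum()
                cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * lq
                new = n * (gammaln(K * prop) - K * gammaln(prop)) + (prop - 1) * lq
                if np.log(rng.random()) < new - cur:
                    alpha = prop
        # --- bookkeeping ---
        if sweep >= n_burnin:
            Pf = P.reshape(K, L * A)
            mix = (Q[ii, :] * Pf[:, flat_la].T).sum(axis=1)
            lnl = float(np.log(np.maximum(mix, 1e-300)).sum())
            if not np.isfinite(lnl):
                raise RuntimeError("non-finite likelihood in admixture chain")
            lnls.append(lnl)
            Q_acc += Q
            P_acc += P
            alpha_acc += alpha
            kept += 1

    lnls = np.array(lnls)
    Qm = Q_acc / kept
    Qm = Qm / Qm.sum(axis=1, keepdims=True)
    lnl_mean = float(lnls.mean())
    lnl_var = float(lnls.var(ddof=1)) if lnls.size > 1 else 0.0
    return AdmixtureRun(
        K=K,
        Q=pd.DataFrame(Qm, index=matrix.individuals,
                       columns=[f"cluster{k + 1}" for k in range(K)]),
        P=P_acc / kept,
        alpha_mean=alpha_acc / kept,
        ln_prob=lnl_mean - lnl_var / 2.0,
        lnl_mean=lnl_mean,
        lnl_var=lnl_var,
        n_burnin=n_burnin,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Run alignment (label switching)
# ---------------------------------------------------------------------------

def _best_permutation(Q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Column permutation of Q minimizing ||Q[:, perm] - ref||^2 (exact)."""
    K = Q.shape[1]
    cost = np.empty((K, K))
    for j in range(K):  # candidate source column j -> target position k
        cost[j] = ((Q[:, j][:, None] - ref) ** 2).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm


def align_runs(runs: list[AdmixtureRun]) -> dict:
    """Align replicate runs' cluster labels; returns aligned Q matrices and
    their mean (consensus).  The reference is built incrementally: each run
    is matched to the running mean of the already-aligned runs."""
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    K = runs[0].K
    inds = list(runs[0].Q.index)
    for r in runs[1:]:
        if r.K != K or list(r.Q.index) != inds:
            raise ValueError("runs differ in K or individuals")
    aligned = [runs[0].Q.to_numpy()]
    perms = [np.arange(K)]
    for r in runs[1:]:
        ref = np.mean(aligned, axis=0)
        perm = _best_permutation(r.Q.to_numpy(), ref)
        aligned.append(r.Q.to_numpy()[:, perm])
        perms.append(perm)
    consensus = np.mean(aligned, axis=0)
    consensus = consensus / consensus.sum(axis=1, keepdims=True)
    cols = [f"cluster{k + 1}" for k in range(K)]
    return {
        "aligned": [pd.DataFrame(a, index=inds, columns=cols) for a in aligned],
        "permutations": perms,
        "consensus": pd.DataFrame(consensus, index=inds, columns=cols),
    }


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(l_table: pd.DataFrame) -> KSelection:
    """Evanno's DeltaK from a runs x K table of ln P(X|K).

    DeltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K),
    defined for interior K only; the selected K maximizes DeltaK.
    """
    ks = sorted(int(k) for k in l_table.columns)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if (np.diff(ks) != 1).any():
        raise ValueError("K values must be consecutive")
    if len(l_table) < 2:
        raise ValueError("need at least two runs per K")
    means = l_table.mean(axis=0)
    sds = l_table.std(axis=0, ddof=1)
    flags = []
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            sd = sds[k]
            if sd == 0:
                flags.append(f"sd of L is zero at K={k}; DeltaK undefined there")
            else:
                dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd
        rows.append(dict(K=k, L_mean=means[k], L_sd=sds[k], delta_k=dk))
    tab = pd.DataFrame(rows).set_index("K")
    if tab["delta_k"].notna().any():
        selected = int(tab["delta_k"].idxmax())
    else:
        selected = int(means.idxmax())
        flags.append("DeltaK undefined everywhere; fell back to max mean L")
    return KSelection(tab, selected, flags)


def k_scan(
    matrix: GenotypeMatrix,
    k_values: range,
    n_runs: int = 5,
    n_burnin: int = 500,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, list[AdmixtureRun]]]:
    """Replicate admixture runs across a K range; returns the L(K) table
    (runs x K) and all runs keyed by K."""
    l_rows = np.empty((n_runs, len(list(k_values))))
    runs: dict[int, list[AdmixtureRun]] = {}
    for kj, K in enumerate(k_values):
        runs[K] = []
        for rep in range(n_runs):
            run = structure_mcmc(
                matrix, K, n_burnin=n_burnin, n_iter=n_iter,
                seed=(seed * 1_000 + K * 100 + rep) % (2**31 - 1),
            )
            runs[K].append(run)
            l_rows[rep, kj] = run.ln_prob
    table = pd.DataFrame(l_rows, columns=list(k_values))
    return table, runs
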