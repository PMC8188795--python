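"""Synthetic SSR genotype generator with truth labels.

Emulates the study design the analysis stack assumes: four oak-like species
(codes A, V, F, B), ten populations across four sites, 17 microsatellite
loci with ~21 alleles each, interspecific hybrids (F1, backcross,
trihybrid), locus-specific null alleles, inbreeding, and genotyping
failure.  Every stage draws from a stream derived from one integer seed.

The observation layer mirrors the classical null-allele process: a drawn
null allele is invisible, so a true (i, null) genotype is scored as the
apparent homozygote (i, i) and a true (null, null) genotype as missing;
independently any call may fail (missing) with probability b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import (
    MISSING,
    GenotypeMatrix,
    SampleMetadata,
    _normalize_calls,
    child_rng,
    validate_matrix,
)

SPECIES = ("A", "V", "F", "B")

#: study-emulation population sizes (site-species code -> n)
STUDY_POPULATIONS = {
    "BY-A": 31, "BY-V": 29, "LT-F": 38, "LT-B": 22, "ZW-V": 30,
    "ZW-B": 30, "ZJ-A": 30, "ZJ-V": 30, "ZJ-F": 33, "ZJ-B": 27,
}


@dataclass
class SpeciesFreqModel:
    """Per-species, per-locus allele frequencies including a null class.

    ``visible[s, l, :k_l]`` are the visible-allele frequencies and
    ``null[s, l]`` the null-allele frequency; together they sum to 1.
    Species frequencies are Dirichlet draws around a shared base frequency
    with concentration ``divergence`` (Balding–Nichols style: smaller
    concentration -> larger F_ST, roughly 1/(1+c)).
    """

    species: tuple[str, ...]
    n_loci: int
    alleles_per_locus: int
    visible: np.ndarray  # (S, L, A)
    null: np.ndarray     # (S, L)
    divergence: float

    def __post_init__(self):
        tot = self.visible.sum(axis=2) + self.null
        if not np.allclose(tot, 1.0, atol=1e-9):
            raise ValueError("visible + null frequencies must sum to 1")


@dataclass
class CrossPlan:
    """List of (population code, class spec, count).

    Class specs: ``"A"`` (purebred species A), ``"F1:A+V"``,
    ``"BX:A+V"`` (backcross toward A), ``"TRI:A+V+F"``.
    """

    entries: list[tuple[str, str, int]]

    def __post_init__(self):
        for pop, spec, count in self.entries:
            if count < 1:
                raise ValueError(f"{pop}: count must be >= 1")
            parse_class(spec)  # validates


@dataclass
class ObservationModel:
    """Per-population inbreeding f and genotyping failure rate b."""

    inbreeding: dict[str, float] = field(default_factory=dict)
    failure: dict[str, float] = field(default_factory=dict)
    default_f: float = 0.0
    default_b: float = 0.0

    def f(self, pop: str) -> float:
        v = self.inbreeding.get(pop, self.default_f)
        if not 0 <= v < 1:
            raise ValueError(f"inbreeding f={v} out of [0,1)")
        return v

    def b(self, pop: str) -> float:
        v = self.failure.get(pop, self.default_b)
        if not 0 <= v < 1:
            raise ValueError(f"failure b={v} out of [0,1)")
        return v


@dataclass
class TruthLabels:
    """Ground truth: ancestry vectors, class labels, pre-observation calls."""

    ancestry: pd.DataFrame          # individuals x species, rows sum to 1
    classes: pd.Series              # purebred / F1 / backcross / trihybrid
    class_spec: pd.Series           # the originating class spec string
    true_calls: np.ndarray          # (n, L, 2) with null coded as -2
    allele_origin: np.ndarray       # (n, L, 2) species index of each copy


NULL_CODE = -2


def parse_class(spec: str) -> tuple[str, tuple[str, ...]]:
    """Parse a class spec into (kind, species tuple)."""
    if ":" not in spec:
        return "purebred", (spec,)
    kind, rest = spec.split(":", 1)
    parents = tuple(rest.split("+"))
    if kind == "F1" and len(parents) == 2:
        return "F1", parents
    if kind == "BX" and len(parents) == 2:
        return "backcross", parents
    if kind == "TRI" and len(parents) == 3:
        return "trihybrid", parents
    raise ValueError(f"bad class spec {spec!r}")


def expected_ancestry(spec: str, species: tuple[str, ...]) -> np.ndarray:
    kind, parents = parse_class(spec)
    v = np.zeros(len(species))
    idx = {s: i for i, s in enumerate(species)}
    for s in parents:
        if s not in idx:
            raise ValueError(f"class spec {spec!r} references unknown species {s!r}")
    if kind == "purebred":
        v[idx[parents[0]]] = 1.0
    elif kind == "F1":
        v[idx[parents[0]]] = v[idx[parents[1]]] = 0.5
    elif kind == "backcross":
        v[idx[parents[0]]] = 0.75
        v[idx[parents[1]]] = 0.25
    else:  # trihybrid
        v[idx[parents[0]]] = 0.5
        v[idx[parents[1]]] = v[idx[parents[2]]] = 0.25
    return v


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def simulate_frequencies(
    n_species: int = 4,
    n_loci: int = 17,
    alleles_per_locus: int = 21,
    divergence: float = 8.0,
    null_max: float = 0.2,
    seed: int = 0,
    species: tuple[str, ...] | None = None,
) -> SpeciesFreqModel:
    """Draw a species frequency model.

    Base frequencies per locus are a flat-Dirichlet draw over
    ``alleles_per_locus`` alleles; each species' visible frequencies are
    Dirichlet(divergence * base).  Null frequencies are Uniform(0, null_max)
    per species x locus; visible frequencies are scaled by (1 - null).
    """
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    if n_species < 1 or n_loci < 1:
        raise ValueError("n_species and n_loci must be positive")
    species = tuple(species or SPECIES[:n_species])
    if len(species) != n_species:
        raise ValueError("species tuple length != n_species")
    rng = child_rng(seed, "frequencies")
    A = alleles_per_locus
    base = rng.dirichlet(np.ones(A), size=n_loci)  # (L, A)
    visible = np.empty((n_species, n_loci, A))
    for s in range(n_species):
        for l in range(n_loci):
            alpha = np.maximum(divergence * base[l], 1e-6)
            visible[s, l] = rng.dirichlet(alpha)
    null = rng.uniform(0.0, null_max, size=(n_species, n_loci))
    visible *= (1.0 - null)[:, :, None]
    return SpeciesFreqModel(species, n_loci, A, visible, null, divergence)


def calibrate_divergence(
    target_theta: float,
    seed: int = 0,
    n_per_species: int = 50,
    tol: float = 0.01,
    max_iter: int = 20,
    **freq_kwargs,
) -> float:
    """Bisection on the divergence concentration to hit a realized global
    theta on purebred samples (no nulls, no inbreeding, no failures)."""
    from .differentiation import wc_theta

    def realized(c: float) -> float:
        fm = simulate_frequencies(divergence=c, null_max=0.0, seed=seed, **freq_kwargs)
        plan = CrossPlan([(f"P{s}", s, n_per_species) for s in fm.species])
        mat, meta, _ = simulate_individuals(fm, plan, ObservationModel(), seed=seed + 1)
        return wc_theta(mat, meta.populations).theta_global

    lo, hi = 0.5, 512.0  # theta decreasing in c
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        th = realized(mid)
        if abs(th - target_theta) < tol:
            return mid
        if th > target_theta:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------

def _draw_copies(rng, freqs_with_null: np.ndarray, size: int) -> np.ndarray:
    """Draw allele codes from a frequency vector; last slot = null (NULL_CODE)."""
    k = freqs_with_null.size
    draws = rng.choice(k, size=size, p=freqs_with_null)
    codes = draws.astype(np.int32)
    codes[codes == k - 1] = NULL_CODE
    return codes


def simulate_individuals(
    freq_model: SpeciesFreqModel,
    cross_plan: CrossPlan,
    observation_model: ObservationModel,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SampleMetadata, TruthLabels]:
    """Simulate genotypes under the cross plan, then apply the observation
    layer (null alleles -> apparent homozygotes/missing; failures -> missing).

    Per-locus transmission: purebreds draw two independent copies from their
    species pool, except with probability f (inbreeding) a single draw is
    duplicated (identity by descent).  F1: one copy from each parent pool.
    Backcross toward s1: one copy from s1; the other from s1 with prob 0.5
    else s2 (gametic model, loci independent).  Trihybrid: one copy from s1;
    the other from s2 or s3 with equal probability.
    """
    rng = child_rng(seed, "individuals")
    fm = freq_model
    sp_index = {s: i for i, s in enumerate(fm.species)}
    L = fm.n_loci
    loci = [f"L{l + 1:02d}" for l in range(L)]

    individuals, pops, class_specs = [], [], []
    for pop, spec, count in cross_plan.entries:
        parse_class(spec)
        for s in parse_class(spec)[1]:
            if s not in sp_index:
                raise ValueError(f"cross plan references unknown species {s!r}")
        for k in range(count):
            individuals.append(f"{pop}_{spec.replace(':', '').replace('+', '')}_{k + 1:03d}")
            pops.append(pop)
            class_specs.append(spec)
    n = len(individuals)

    # pooled per-species frequency vectors with the null class appended
    pool = np.concatenate([fm.visible, fm.null[:, :, None]], axis=2)  # (S,L,A+1)

    true_calls = np.full((n, L, 2), MISSING, dtype=np.int32)
    origin = np.full((n, L, 2), -1, dtype=np.int32)
    ancestry = np.zeros((n, len(fm.species)))
    classes = []
    for i in range(n):
        spec = class_specs[i]
        kind, parents = parse_class(spec)
        classes.append(kind)
        ancestry[i] = expected_ancestry(spec, fm.species)
        f = observation_model.f(pops[i]) if kind == "purebred" else 0.0
        for l in range(L):
            if kind == "purebred":
                s = sp_index[parents[0]]
                if f > 0 and rng.random() < f:
                    a = _draw_copies(rng, pool[s, l], 1)[0]
                    pair = (a, a)
                else:
                    pair = tuple(_draw_copies(rng, pool[s, l], 2))
                orig = (s, s)
            elif kind == "F1":
                s1, s2 = sp_index[parents[0]], sp_index[parents[1]]
                pair = (
                    _draw_copies(rng, pool[s1, l], 1)[0],
                    _draw_copies(rng, pool[s2, l], 1)[0],
                )
                orig = (s1, s2)
            elif kind == "backcross":
                s1, s2 = sp_index[parents[0]], sp_index[parents[1]]
                s_other = s1 if rng.random() < 0.5 else s2
                pair = (
                    _draw_copies(rng, pool[s1, l], 1)[0],
                    _draw_copies(rng, pool[s_other, l], 1)[0],
                )
                orig = (s1, s_other)
            else:  # trihybrid
                s1 = sp_index[parents[0]]
                s_other = sp_index[parents[1]] if rng.random() < 0.5 else sp_index[parents[2]]
                pair = (
                    _draw_copies(rng, pool[s1, l], 1)[0],
                    _draw_copies(rng, pool[s_other, l], 1)[0],
                )
                orig = (s1, s_other)
            true_calls[i, l] = pair
            origin[i, l] = orig

    # observation layer
    obs = true_calls.copy()
    both_null = (true_calls == NULL_CODE).all(axis=2)
    one_null = (true_calls == NULL_CODE).any(axis=2) & ~both_null
    # (i, null) -> apparent homozygote (i, i)
    vis = np.where(true_calls == NULL_CODE, true_calls[:, :, ::-1], true_calls)
    obs[one_null] = vis[one_null]
    obs[both_null] = MISSING
    b_per_ind = np.array([observation_model.b(p) for p in pops])
    fail = rng.random((n, L)) < b_per_ind[:, None]
    obs[fail] = MISSING
    obs = _normalize_calls(obs)

    labels = {
        locus: [str(a + 1) for a in range(fm.alleles_per_locus)] for locus in loci
    }
    matrix = GenotypeMatrix(individuals, loci, obs, labels)
    validate_matrix(matrix)
    meta = SampleMetadata.from_populations(individuals, pops)
    truth = TruthLabels(
        ancestry=pd.DataFrame(ancestry, index=individuals, columns=list(fm.species)),
        classes=pd.Series(classes, index=individuals, name="class"),
        class_spec=pd.Series(class_specs, index=individuals, name="class_spec"),
        true_calls=true_calls,
        allele_origin=origin,
    )
    return matrix, meta, truth


def simulate_traits(
    truth: TruthLabels,
    trait_means: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> pd.DataFrame:
    """Trait matrix: ancestry-weighted species means plus Gaussian noise."""
    trait_means = np.asarray(trait_means, dtype=float)
    S = truth.ancestry.shape[1]
    if trait_means.ndim != 2 or trait_means.shape[0] != S:
        raise ValueError(
            f"trait_means must be (n_species={S}, n_traits); got {trait_means.shape}"
        )
    rng = child_rng(seed, "traits")
    mu = truth.ancestry.to_numpy() @ trait_means
    vals = mu + rng.normal(0.0, noise_sd, size=mu.shape)
    cols = trait_names or [f"trait{j + 1}" for j in range(trait_means.shape[1])]
    return pd.DataFrame(vals, index=truth.ancestry.index, columns=cols)


def study_cross_plan(
    hybrid_fraction: float = 0.0,
    populations: dict[str, int] | None = None,
) -> CrossPlan:
    """The four-oak, ten-population study layout (300 individuals).

    With ``hybrid_fraction`` > 0, that fraction of each population is split
    evenly between F1 and backcross hybrids with the within-group partner
    (A<->V, F<->B), mirroring the dominant hybrid types observed in mixed
    oak stands.
    """
    partner = {"A": "V", "V": "A", "F": "B", "B": "F"}
    entries = []
    for pop, n in (populations or STUDY_POPULATIONS).items():
        sp = pop.rsplit("-", 1)[1]
        n_h = int(round(hybrid_fraction * n))
        n_f1 = n_h // 2
        n_bx = n_h - n_f1
        n_pure = n - n_h
        if n_pure:
            entries.append((pop, sp, n_pure))
        if n_f1:
            entries.append((pop, f"F1:{sp}+{partner[sp]}", n_f1))
        if n_bx:
            entries.append((pop, f"BX:{sp}+{partner[sp]}", n_bx))
    return CrossPlan(entries)


def write_truth_labels(truth: TruthLabels, path) -> None:
    """Write truth labels (class + ancestry per species) as a CSV."""
    out = truth.ancestry.copy()
    out.insert(0, "class_spec", truth.class_spec)
    out.insert(0, "class", truth.classes)
    out.to_csv(path, index_label="individual")
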