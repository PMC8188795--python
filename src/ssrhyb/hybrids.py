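"""Threshold classification of admixture coefficients into purebreds and
hybrid classes, and hybridization-rate reporting.

With q_max the largest ancestry coefficient: q_max > 0.9 -> purebred of
that cluster; 0.6 < q_max <= 0.9 -> backcross toward that cluster;
q_max <= 0.6 -> F1 between the top two clusters; and, regardless of
q_max, three or more ancestries each above 0.1 -> trihybrid.  All
thresholds configurable.  Hybridization rate per reporting unit:
H_r = (NH_F1 + NH_backcross + NH_trihybrid) / N as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Thresholds:
    purebred: float = 0.9
    backcross: float = 0.6
    f1_low: float = 0.4
    minor: float = 0.1


@dataclass
class HybridCall:
    individual: str
    ancestry: np.ndarray
    class_: str                       # purebred | F1 | backcross | trihybrid
    assigned_cluster: int | None      # for purebred / backcross direction
    ht_clusters: tuple[int, ...]      # contributing clusters, desc ancestry


def classify_individual(
    ancestry, thresholds: Thresholds = Thresholds(), individual: str = ""
) -> HybridCall:
    """Classify one ancestry vector (must lie on the simplex)."""
    q = np.asarray(ancestry, dtype=float)
    if q.ndim != 1 or (q < -1e-9).any() or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError(f"ancestry vector must be a simplex vector, got {q}")
    t = thresholds
    order = np.argsort(-q, kind="stable")  # ties keep ascending cluster index
    qmax = q[order[0]]
    major = tuple(int(i) for i in order if q[i] > t.minor)
    if len(major) >= 3:
        return HybridCall(individual, q, "trihybrid", None, major)
    if qmax > t.purebred:
        return HybridCall(individual, q, "purebred", int(order[0]), ())
    if qmax > t.backcross:
        return HybridCall(individual, q, "backcross", int(order[0]),
                          (int(order[0]), int(order[1])))
    return HybridCall(individual, q, "F1", None, (int(order[0]), int(order[1])))


def classify_q_matrix(
    Q: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> list[HybridCall]:
    return [
        classify_individual(row.to_numpy(), thresholds, individual=str(ind))
        for ind, row in Q.iterrows()
    ]


def name_hybrid_type(
    call: HybridCall, cluster_to_species: dict[int, str]
) -> str | None:
    """HT label: species codes of contributing clusters joined by '-' in
    descending ancestry order; purebreds have no HT."""
    if call.class_ == "purebred":
        return None
    parts = []
    for c in call.ht_clusters:
        if c not in cluster_to_species:
            raise ValueError(f"cluster {c} has no species mapping")
        parts.append(cluster_to_species[c])
    return "-".join(parts)


def map_clusters_to_species(
    calls: list[HybridCall], species: pd.Series
) -> dict[int, str]:
    """Majority species among purebreds assigned to each cluster."""
    votes: dict[int, dict[str, int]] = {}
    for c in calls:
        if c.class_ == "purebred" and c.assigned_cluster is not None:
            sp = species.get(c.individual)
            votes.setdefault(c.assigned_cluster, {}).setdefault(sp, 0)
            votes[c.assigned_cluster][sp] += 1
    return {k: max(v, key=v.get) for k, v in votes.items()}


@dataclass
class HybridReport:
    per_population: pd.DataFrame
    per_species: pd.DataFrame
    overall: pd.Series
    flags: list = field(default_factory=list)


def _tally(group: pd.DataFrame) -> dict:
    nh_f1 = int((group["class"] == "F1").sum())
    nh_bx = int((group["class"] == "backcross").sum())
    nh_tri = int((group["class"] == "trihybrid").sum())
    n = len(group)
    nh = nh_f1 + nh_bx + nh_tri
    ht_counts = group.loc[group["HT"].notna(), "HT"].value_counts()
    return dict(
        HT=ht_counts.index[0] if len(ht_counts) else None,
        NH_F1=nh_f1, NH_BX=nh_bx, NH_TRI=nh_tri, NH=nh, N=n,
        H_r=100.0 * nh / n,
    )


def hybrid_report(
    calls: list[HybridCall],
    metadata,
    cluster_to_species: dict[int, str] | None = None,
) -> HybridReport:
    """Counts and hybridization rates at population, species and overall
    levels.  Rates are kept at full precision; round only for display."""
    if cluster_to_species is None:
        cluster_to_species = map_clusters_to_species(calls, metadata.species)
    rows = []
    flags = []
    for c in calls:
        if c.individual not in metadata.table.index:
            raise ValueError(f"no metadata for individual {c.individual!r}")
        rows.append(dict(
            individual=c.individual,
            population=metadata.populations[c.individual],
            species=metadata.species[c.individual],
            **{"class": c.class_},
            HT=name_hybrid_type(c, cluster_to_species),
        ))
    df = pd.DataFrame(rows)
    per_pop = pd.DataFrame(
        {pop: _tally(g) for pop, g in df.groupby("population")}
    ).T.rename_axis("population")
    per_sp = pd.DataFrame(
        {sp: _tally(g) for sp, g in df.groupby("species")}
    ).T.rename_axis("species")
    overall = pd.Series(_tally(df), name="overall")
    empty = set(metadata.populations.unique()) - set(per_pop.index)
    if empty:
        flags.append(f"populations with no classified individuals omitted: {sorted(empty)}")
    return HybridReport(per_pop, per_sp, overall, flags)


def report_from_counts(
    counts: pd.DataFrame, pop_to_species: dict[str, str] | None = None
) -> HybridReport:
    """Build a report from per-population counts (NH_F1, NH_BX, N[, NH_TRI]).

    Convenience for recomputing published-style rate tables from printed
    counts; synthesizes one call per counted individual and reuses the
    standard aggregation, so the arithmetic path is identical.
    """
    from .geno_io import SampleMetadata

    calls, inds, pops = [], [], []
    for pop, row in counts.iterrows():
        spec = [("F1", int(row["NH_F1"])), ("backcross", int(row["NH_BX"])),
                ("trihybrid", int(row.get("NH_TRI", 0)))]
        n_hyb = sum(k for _, k in spec)
        spec.append(("purebred", int(row["N"]) - n_hyb))
        j = 0
        for klass, count in spec:
            for _ in range(count):
                j += 1
                name = f"{pop}#{j:03d}"
                q = {"purebred": np.array([0.95, 0.05]),
                     "F1": np.array([0.5, 0.5]),
                     "backcross": np.array([0.75, 0.25]),
                     "trihybrid": np.array([0.5, 0.3, 0.2])}[klass]
                calls.append(classify_individual(q, individual=name))
                inds.append(name)
                pops.append(pop)
    pop_map = None
    if pop_to_species is not None:
        pop_map = {p: (s, p.split("-")[0]) for p, s in pop_to_species.items()}
    meta = SampleMetadata.from_populations(inds, pops, pop_map)
    c2s = {0: "X", 1: "Y", 2: "Z"}
    return hybrid_report(calls, meta, cluster_to_species=c2s)
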