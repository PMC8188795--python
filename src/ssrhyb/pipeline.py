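"""Configuration-driven orchestration of the full analysis.

Stage order: simulate (or load) -> diversity -> null models ->
differentiation -> AMOVA -> clustering -> admixture -> hybrid report.
All reports are plain delimited text; a JSON manifest records every
output file with its stage and a parameter hash.  Sub-seeds are derived
per stage from the global seed by stable hashing of the stage name, so
toggling one stage never shifts another's random stream.  Completed
stages are skipped on rerun when their parameter hash is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geno_io, synthetic, clustering, hybrids
from .admixture import align_runs, evanno_delta_k, k_scan
from .amova import amova as run_amova
from .differentiation import (
    ena_theta, gene_flow, hedrick_gst, pairwise_fst, pcoa, stratify_pairs,
)
from .diversity import diversity_table
from .null_models import (
    em_null_all, flag_usable_loci, nfb_model_comparison, null_frequency_table,
)

log = logging.getLogger("ssrhyb")


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "ssrhyb_out"
    # input: either a genotype file or a simulation block
    genotypes: str | None = None
    genotype_format: str = "delimited-wide"
    simulate: dict = field(default_factory=lambda: {
        "n_species": 4, "n_loci": 17, "alleles_per_locus": 21,
        "divergence": 8.0, "null_max": 0.2, "hybrid_fraction": 0.2,
        "inbreeding": 0.1, "failure": 0.02,
    })
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "diversity", "nulls", "diff", "amova",
        "cluster", "admix", "hybrids",
    ])
    rarefaction_g: int = 20
    n_perm: int = 199
    n_boot: int = 200
    nfb: dict = field(default_factory=lambda: {
        "n_iter": 4000, "burn_in": 500, "thin": 5})
    admix: dict = field(default_factory=lambda: {
        "k_min": 1, "k_max": 4, "n_runs": 3,
        "n_burnin": 300, "n_iter": 600})
    hybrid_thresholds: dict = field(default_factory=lambda: {
        "purebred": 0.9, "backcross": 0.6, "f1_low": 0.4, "minor": 0.1})
    null_locus_filter: dict = field(default_factory=lambda: {
        "max_thresh": 0.2, "mean_thresh": 0.1})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        known = {"simulate", "diversity", "nulls", "diff", "amova",
                 "cluster", "admix", "hybrids"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if "hybrids" in self.stages and "admix" not in self.stages:
            raise ValueError(
                "the hybrids stage needs admixture q-values; enable the "
                "'admix' stage or drop 'hybrids'"
            )
        if self.genotypes is None and "simulate" not in self.stages:
            raise ValueError("no input: provide genotypes or enable 'simulate'")
        th = self.hybrid_thresholds
        if not 0 < th["minor"] < th["f1_low"] < th["backcross"] < th["purebred"] < 1:
            raise ValueError("hybrid thresholds must be ordered in (0,1)")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


def _params_hash(cfg: PipelineConfig, stage: str) -> str:
    payload = json.dumps({"stage": stage, "cfg": asdict(cfg)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    def done(stage, files):
        h = _params_hash(config, stage)
        entry = manifest.get(stage)
        if entry and entry["hash"] == h and all((out / f).exists() for f in entry["files"]):
            log.info("stage %s unchanged; skipping", stage)
            return True
        return False

    def record(stage, files):
        manifest[stage] = {"hash": _params_hash(config, stage), "files": files}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    state = {}
    for stage in config.stages:
        try:
            _run_stage(stage, config, out, state, manifest, done, record)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    config.to_yaml(out / "config.yaml")
    return out


def _load_inputs(config: PipelineConfig, out: Path, state: dict):
    if "matrix" in state:
        return
    if config.genotypes:
        m, meta = geno_io.read_genotypes(config.genotypes, config.genotype_format)
    else:
        m, meta = geno_io.read_genotypes(out / "genotypes.csv", "delimited-wide")
    state["matrix"], state["meta"] = m, meta


def _run_stage(stage, config, out, state, manifest, done, record):
    seed = _stage_seed(config.seed, stage)
    if stage == "simulate":
        files = ["genotypes.csv", "genotypes_structure.txt", "truth_labels.csv",
                 "traits.csv"]
        if done(stage, files):
            _load_inputs(config, out, state)
            return
        sc = config.simulate
        fm = synthetic.simulate_frequencies(
            n_species=sc["n_species"], n_loci=sc["n_loci"],
            alleles_per_locus=sc["alleles_per_locus"],
            divergence=sc["divergence"], null_max=sc["null_max"], seed=seed,
        )
        plan = synthetic.study_cross_plan(
            sc.get("hybrid_fraction", 0.0), sc.get("populations"))
        obs = synthetic.ObservationModel(
            default_f=sc.get("inbreeding", 0.0), default_b=sc.get("failure", 0.0))
        m, meta, truth = synthetic.simulate_individuals(fm, plan, obs, seed=seed)
        geno_io.write_genotypes(m, meta, out / "genotypes.csv", "delimited-wide")
        geno_io.write_genotypes(m, meta, out / "genotypes_structure.txt",
                                "structure-two-row")
        synthetic.write_truth_labels(truth, out / "truth_labels.csv")
        means = np.arange(sc["n_species"] * 9, dtype=float).reshape(sc["n_species"], 9)
        traits = synthetic.simulate_traits(truth, means, noise_sd=1.0, seed=seed)
        geno_io.write_traits(traits, out / "traits.csv")
        state.update(matrix=m, meta=meta, truth=truth, traits=traits)
        record(stage, files)
        return

    _load_inputs(config, out, state)
    m, meta = state["matrix"], state["meta"]
    pops = meta.populations

    if stage == "diversity":
        files = ["diversity_per_locus.csv", "diversity_per_population.csv"]
        if done(stage, files):
            return
        tab = diversity_table(m, pops, config.rarefaction_g)
        tab.xs("pooled").to_csv(out / "diversity_per_locus.csv")
        per_pop = (
            tab.drop("pooled", level="group")
            .groupby("group").mean(numeric_only=True)
        )
        per_pop.to_csv(out / "diversity_per_population.csv")
        record(stage, files)
    elif stage == "nulls":
        files = ["null_frequencies.csv", "locus_filter.csv", "nfb_summary.csv"]
        if done(stage, files):
            state["em"] = _reload_em(m, pops)
            return
        em = em_null_all(m, pops)
        state["em"] = em
        tab = null_frequency_table(em)
        tab.to_csv(out / "null_frequencies.csv")
        keep = flag_usable_loci(tab, **config.null_locus_filter)
        keep.rename("keep").to_csv(out / "locus_filter.csv")
        rows = []
        for pop in pd.unique(pops):
            cmp = nfb_model_comparison(
                m, pops, pop, seed=seed, **config.nfb)
            rows.append(dict(
                population=pop, null_mean=float(cmp["nfb"].pi_mean.mean()),
                f_is_corrected=cmp["f_is_corrected"], b=cmp["nfb"].b_mean,
                dic_nfb=cmp["dic_nfb"], dic_fb=cmp["dic_fb"],
                favored=cmp["favored"],
            ))
        pd.DataFrame(rows).set_index("population").to_csv(out / "nfb_summary.csv")
        record(stage, files)
    elif stage == "diff":
        files = ["theta_per_locus.csv", "pairwise_fst.csv", "stratum_means.csv",
                 "pcoa_coordinates.csv"]
        if done(stage, files):
            return
        if "em" not in state:
            state["em"] = em_null_all(m, pops)
        res = ena_theta(m, pops, state["em"],
                                        n_boot=config.n_boot, seed=seed)
        gst = hedrick_gst(m, pops)
        per_locus = pd.DataFrame({
            "F_ST": res["fst"].theta_per_locus,
            "cF_ST": res["cfst"].theta_per_locus,
            "Gp_ST": gst["Gp_ST"].drop("overall"),
        })
        per_locus["N_m"] = [
            gene_flow(v, "wright") if v > 0 else np.inf
            for v in per_locus["F_ST"]
        ]
        overall = pd.DataFrame({
            "F_ST": [res["fst"].theta_global],
            "cF_ST": [res["cfst"].theta_global],
            "Gp_ST": [gst.loc["overall", "Gp_ST"]],
            "N_m": [gene_flow(res["fst"].theta_global, "wright")],
        }, index=["overall"])
        pd.concat([per_locus, overall]).to_csv(out / "theta_per_locus.csv")
        pw = pairwise_fst(m, pops)
        pw.values.to_csv(out / "pairwise_fst.csv")
        stratify_pairs(pw, meta).to_csv(out / "stratum_means.csv")
        pcoa(pw).coordinates.to_csv(out / "pcoa_coordinates.csv")
        state["pairwise"] = pw
        record(stage, files)
    elif stage == "amova":
        files = ["amova_regions.csv", "amova_species.csv"]
        if done(stage, files):
            return
        for name, grp in (("regions", meta.sites), ("species", meta.species)):
            res = run_amova(m, grp, pops, n_perm=config.n_perm, seed=seed)
            tab = res.table.copy()
            tab["fixation"] = [res.f_ct, res.f_sc, res.f_st]
            tab["p"] = [res.p_values["F_CT"], res.p_values["F_SC"],
                        res.p_values["F_ST"]]
            tab.to_csv(out / f"amova_{name}.csv")
        record(stage, files)
    elif stage == "cluster":
        files = ["nei_distance.csv", "nj_populations.nwk", "nj_individuals.nwk"]
        if done(stage, files):
            return
        nd = clustering.nei_distance(m, pops)
        nd.to_frame().to_csv(out / "nei_distance.csv")
        if np.isfinite(nd.values).all():
            clustering.write_newick(clustering.nj_tree(nd), out / "nj_populations.nwk")
        idist = clustering.individual_distance(m)
        clustering.write_newick(clustering.nj_tree(idist), out / "nj_individuals.nwk")
        if "traits" in state:
            dend = clustering.trait_cluster(state["traits"], pops, "population")
            (out / "trait_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        record(stage, files)
    elif stage == "admix":
        files = ["k_selection.csv", "q_matrix.csv"]
        if done(stage, files):
            state["Q"] = pd.read_csv(out / "q_matrix.csv", index_col=0)
            return
        ac = config.admix
        table, runs = k_scan(
            m, range(ac["k_min"], ac["k_max"] + 1), n_runs=ac["n_runs"],
            n_burnin=ac["n_burnin"], n_iter=ac["n_iter"], seed=seed,
        )
        sel = evanno_delta_k(table)
        sel.table.to_csv(out / "k_selection.csv")
        best_k = max(sel.selected_k, 2)
        aligned = align_runs(runs[best_k])
        Q = aligned["consensus"]
        Q.to_csv(out / "q_matrix.csv")
        state["Q"] = Q
        state["selected_k"] = sel.selected_k
        record(stage, files)
    elif stage == "hybrids":
        files = ["hybrid_per_population.csv", "hybrid_per_species.csv",
                 "hybrid_overall.csv"]
        if done(stage, files):
            return
        if "Q" not in state:
            raise RuntimeError(
                "hybrid classification needs admixture output; run the "
                "'admix' stage first"
            )
        th = hybrids.Thresholds(**config.hybrid_thresholds)
        calls = hybrids.classify_q_matrix(state["Q"], th)
        rep = hybrids.hybrid_report(calls, meta)
        rep.per_population.to_csv(out / "hybrid_per_population.csv")
        rep.per_species.to_csv(out / "hybrid_per_species.csv")
        rep.overall.to_frame().T.to_csv(out / "hybrid_overall.csv")
        record(stage, files)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")


def _reload_em(m, pops):
    return em_null_all(m, pops)
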