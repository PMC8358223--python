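"""End-to-end orchestration of the analysis on synthetic inputs.

``run_pipeline`` executes the full workflow - simulate inputs, extract
primary-metabolism traits, ordinate and test, cluster with bootstrap
support, compare trees, partition pangenomes and fit the model layer -
writing TSV/JSON results plus a manifest (seed, config hash, versions)
that suffices to reproduce every output exactly.  Every stochastic stage
receives a child seed derived from the global seed and the stage name, so
stage order never changes results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import child_seed, logger
from .io import (
    write_fasta_alignment,
    write_function_table,
    write_newick,
    write_presence_absence,
    write_test_results,
)
from .models import anova_with_covariate, beta_regression, lrt, pearson_correlation, quasibinomial_glm
from .multivariate import (
    bray_curtis,
    jaccard_binary,
    mantel,
    multiscale_bootstrap_support,
    pairwise_permanova,
    pcoa,
    permanova,
    procrustes_test,
)
from .pangenome import (
    accessory_enrichment,
    distribution_index,
    orthogroup_incidence_test,
    partition_pangenome,
    residue_diversity,
)
from .simulate import (
    study_config,
    simulate_alignment,
    simulate_bm_trait,
    simulate_function_table,
    simulate_pangenome,
    simulate_trait_counts,
    simulate_tree,
)
from .traits import count_unique_roles, filter_primary_metabolism
from .trees import cophenetic_from_tree, pagel_lambda, patristic_root_distances, robinson_foulds


@dataclass
class PipelineConfig:
    """Run-wide settings: seeds, permutation/bootstrap effort, thresholds."""

    seed: int = 0
    out_dir: str | Path = "pantrait_run"
    n_permutations: int = 999
    n_boot: int = 1000
    boot_scales: tuple[float, ...] = tuple(round(0.5 + 0.1 * k, 1) for k in range(10))
    min_genomes: int = 3
    core_fraction: float = 1.0
    au_threshold: float = 0.95
    q_threshold: float = 0.05
    sim_overrides: dict = field(default_factory=dict)
    write_inputs: bool = True

    def __post_init__(self):
        if self.n_permutations < 1 or self.n_boot < 1:
            raise ValueError("permutation and bootstrap counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "boot_scales" in raw:
            raw["boot_scales"] = tuple(raw["boot_scales"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dump_json(obj, path: Path):
    def default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (frozenset, set)):
            return sorted(x)
        return str(x)

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the study-shaped synthetic data set.

    Returns a nested dict of the headline quantities; all stage outputs are
    also written under ``config.out_dir``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}

    # -- simulate ----------------------------------------------------------
    sim = study_config(seed=child_seed(seed, "sim"), **config.sim_overrides)
    meta = sim.strain_table().set_index("strain_id")
    tree = simulate_tree(sim)
    traits = simulate_trait_counts(sim)
    table = simulate_function_table(sim, traits)
    pa, annotations, species_factor = simulate_pangenome(sim)
    logger.info("simulated %d genomes, %d prevalent strains", sim.n_genomes, len(species_factor))
    if config.write_inputs:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        write_newick(tree, inputs / "phylogeny.nwk")
        write_function_table(table, inputs / "annotations.tsv")
        write_presence_absence(pa, inputs / "orthogroups.tsv")
        meta.to_csv(inputs / "strain_metadata.tsv", sep="\t")

    # -- extract -----------------------------------------------------------
    extracted = count_unique_roles(filter_primary_metabolism(table))
    extracted.counts.to_csv(out / "trait_counts.tsv", sep="\t")
    extracted.relative.to_csv(out / "trait_relative.tsv", sep="\t")
    results["n_genomes"] = len(extracted.counts)
    results["n_subcategories"] = extracted.counts.shape[1]

    # -- ordination + PERMANOVA -------------------------------------------
    rel = extracted.relative
    order_factor = meta.loc[rel.index, "order"]
    d_bc = bray_curtis(rel)
    flat_rel = rel.copy()
    flat_rel.columns = [f"{c}|{s}" for c, s in rel.columns]
    ord_bc = pcoa(d_bc, variables=flat_rel)
    ord_bc.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    perm = permanova(d_bc, order_factor, n_perm=config.n_permutations,
                     seed=child_seed(seed, "permanova"))
    pairwise = pairwise_permanova(d_bc, order_factor, n_perm=config.n_permutations,
                                  seed=child_seed(seed, "pairwise"))
    write_test_results([perm] + pairwise, out / "permanova.json")
    results["permanova"] = {
        "pseudo_F": perm.statistic, "R2": perm.effect, "p": perm.p_value,
        "df": perm.df,
    }
    results["pairwise_significant"] = int(
        sum(r.adjusted_p < config.q_threshold for r in pairwise)
    )
    results["pcoa_percent_axis1"] = float(ord_bc.percent_variance[0])
    results["pcoa_percent_axis2"] = float(ord_bc.percent_variance[1])

    # -- clustering with bootstrap support --------------------------------
    support = multiscale_bootstrap_support(
        rel, scales=list(config.boot_scales), n_boot=config.n_boot,
        seed=child_seed(seed, "boot"),
    )
    support.table.assign(cluster=support.table["cluster"].map(sorted)).to_csv(
        out / "cluster_support.tsv", sep="\t", index=False
    )
    (out / "trait_dendrogram.nwk").write_text(support.dendrogram.to_newick() + "\n")
    results["n_significant_clusters_au"] = int(
        (support.table["au"] >= config.au_threshold).sum()
    )
    # do the three orders come out as high-BP clusters?
    order_sets = {
        frozenset(meta.index[meta["order"] == o]) & frozenset(rel.index)
        for o in meta["order"].unique()
    }
    found = support.table[support.table["cluster"].isin(order_sets)]
    results["order_clusters_recovered"] = int((found["bp"] >= 0.5).sum())

    # -- tree-trait congruence --------------------------------------------
    dend_tree = support.dendrogram.to_phylotree()
    nrf = robinson_foulds(dend_tree, tree)
    d_phylo = cophenetic_from_tree(tree)
    mant = mantel(d_phylo, d_bc, method="spearman", n_perm=config.n_permutations,
                  seed=child_seed(seed, "mantel"))
    write_test_results([nrf, mant], out / "congruence.json")
    results["nrf_traits_vs_phylogeny"] = nrf.statistic
    results["mantel_r"] = mant.statistic
    results["mantel_p"] = mant.p_value

    # -- orthogroup ordination + Procrustes -------------------------------
    strains = list(species_factor.index)
    all_j = jaccard_binary(pa.cells.T)
    metabolic = [g for g in pa.gene_ids if g in annotations]
    met_j = jaccard_binary(pa.cells.loc[metabolic].T)
    ord_all = pcoa(all_j)
    ord_met = pcoa(met_j)
    proc = procrustes_test(ord_met, ord_all, n_perm=config.n_permutations,
                           seed=child_seed(seed, "procrustes"))
    write_test_results(proc, out / "procrustes.json")
    results["procrustes_m2"] = proc.extra["m2"]
    results["procrustes_r"] = proc.effect

    # -- pangenome ---------------------------------------------------------
    partitions = partition_pangenome(pa, species_factor, core_fraction=config.core_fraction)
    part_rows = []
    d_series = []
    for p in partitions:
        d_series.append(distribution_index(p))
        part_rows.append({
            "species": p.species, "n_strains": len(p.strain_ids),
            "core": p.n_core, "accessory": p.n_pangenome - p.n_core,
            "pangenome": p.n_pangenome,
            "max_strain_accessory": max(p.per_strain_accessory.values()),
        })
    part_df = pd.DataFrame(part_rows).set_index("species")
    part_df.to_csv(out / "pangenome_partition.tsv", sep="\t")
    dvals = pd.concat(d_series, keys=[p.species for p in partitions],
                      names=["species", "strain"]).rename("D")
    dvals.to_csv(out / "distribution_index.tsv", sep="\t")
    results["pangenome"] = {
        "core_min": int(part_df["core"].min()), "core_max": int(part_df["core"].max()),
        "pangenome_min": int(part_df["pangenome"].min()),
        "pangenome_max": int(part_df["pangenome"].max()),
        "max_strain_accessory": int(part_df["max_strain_accessory"].max()),
        "n_species": len(partitions),
    }

    # beta regression of D by species + LRT against intercept-only
    ddf = dvals.reset_index()
    full = beta_regression(ddf["D"].to_numpy(), ddf["species"].to_numpy())
    nullf = beta_regression(ddf["D"].to_numpy())
    lr = lrt(full, nullf)
    write_test_results(lr, out / "betareg_lrt.json")
    results["betareg_lrt"] = {"chi2": lr.statistic, "df": lr.df, "p": lr.p_value}

    # incidence + enrichment
    incidence = orthogroup_incidence_test(
        pa, species_factor, min_genomes=config.min_genomes,
        seed=child_seed(seed, "incidence"),
    )
    n_sig = int(sum(r.adjusted_p < config.q_threshold for r in incidence))
    results["orthogroups_tested"] = len(incidence)
    results["orthogroups_significant"] = n_sig
    enr_all = []
    for p in partitions:
        enr_all.extend(accessory_enrichment(p, annotations))
    if enr_all:
        pd.DataFrame([r.to_dict() for r in enr_all]).to_csv(
            out / "accessory_enrichment.tsv", sep="\t", index=False
        )
    results["enriched_subsystems"] = int(
        sum(r.adjusted_p < config.q_threshold for r in enr_all)
    )

    # -- strain diversity vs accessory size -------------------------------
    acc_mean = {
        p.species: float(np.mean(list(p.per_strain_accessory.values())))
        for p in partitions
    }
    top = max(acc_mean.values()) or 1.0
    lo, hi = sim.species_rate_span
    rates = {sp: lo + (hi - lo) * acc_mean[sp] / top for sp in acc_mean}
    aln = simulate_alignment(sim, tree, species_rates=rates, alphabet="aa")
    if config.write_inputs:
        write_fasta_alignment(aln, out / "inputs" / "concatenated_aa.fasta")
    diversity = {
        p.species: residue_diversity(aln, p.strain_ids) for p in partitions
    }
    species_order = sorted(acc_mean)
    pear = pearson_correlation(
        [acc_mean[s] for s in species_order], [diversity[s] for s in species_order]
    )
    write_test_results(pear, out / "diversity_correlation.json")
    results["diversity_pearson_r"] = pear.statistic
    results["diversity_pearson_p"] = pear.p_value

    # -- phylogenetic signal on genome features ---------------------------
    bm = simulate_bm_trait(sim, tree, name="genome_size_bm")
    fit = pagel_lambda(tree, bm)
    root_d = patristic_root_distances(tree)
    tips = sorted(bm)
    anova = anova_with_covariate(
        [bm[t] for t in tips], [meta.loc[t, "order"] for t in tips],
        [root_d[t] for t in tips],
    )
    gc_base = simulate_bm_trait(sim, tree, name="gc_bm")
    z = np.array([gc_base[t] for t in tips])
    gc = 0.37 + 0.23 / (1.0 + np.exp(-1.5 * (z - z.mean()) / (z.std() or 1.0)))
    glm = quasibinomial_glm(gc, [meta.loc[t, "order"] for t in tips],
                            [root_d[t] for t in tips])
    write_test_results([fit.as_test_result()] + anova + glm, out / "phylosignal.json")
    results["pagel_lambda"] = fit.lambda_hat
    results["pagel_lambda_p"] = fit.p_value
    results["anova_group_F"] = anova[0].statistic
    results["glm_group_chi2"] = glm[0].statistic

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package": "pantrait",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "n_genomes": sim.n_genomes,
        "runtime_s": round(time.time() - t0, 2),
    }
    _dump_json({k: v for k, v in manifest.items() if k != "runtime_s"},
               out / "manifest.json")
    _dump_json(results, out / "results.json")
    return results
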