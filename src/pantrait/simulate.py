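"""Seeded generators for every input the pipeline consumes.

The default configuration emulates the study design the package targets: 96
gut-bacterial genomes in three orders (Enterobacterales, Lactobacillales,
Rhodospirillales), seven prevalent species with 4-13 strains each,
order-structured metabolic-function count profiles over 38 primary-
metabolism subcategories, species pangenomes with core genomes of 264-488
genes and per-strain accessory counts up to ~100, amino-acid/nucleotide
alignments with controllable within-species diversity, and continuous
genome features evolving on the phylogeny under a lambda-scaled Brownian
motion.

Everything is deterministic under (seed, config); each generator derives an
independent child stream from the global seed and its own name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import child_seed, rng_for
from .datatypes import AlignmentBlock, FunctionTable, PresenceAbsenceMatrix
from .traits import TraitCountMatrix

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

# 38 retained primary-metabolism subcategories grouped under the six
# categories, mirroring the subsystem hierarchy shape of RAST exports.
DEFAULT_SUBCATEGORIES: dict[str, list[str]] = {
    "amino acids and derivatives": [
        "alanine, serine, and glycine",
        "arginine; urea cycle, polyamines",
        "aromatic amino acids and derivatives",
        "branched-chain amino acids",
        "glutamine, glutamate, aspartate, asparagine; ammonia assimilation",
        "histidine metabolism",
        "lysine, threonine, methionine, and cysteine",
        "proline and 4-hydroxyproline",
        "other",
    ],
    "carbohydrates": [
        "aminosugars",
        "central carbohydrate metabolism",
        "di- and oligosaccharides",
        "fermentation",
        "glycoside hydrolases",
        "monosaccharides",
        "one-carbon metabolism",
        "organic acids",
        "polysaccharides",
        "sugar alcohols",
        "other",
    ],
    "cofactors, vitamins, prosthetic groups, pigments": [
        "biotin",
        "coenzyme a",
        "folate and pterines",
        "nad and nadp",
        "pyridoxine",
        "quinone cofactors",
        "riboflavin, fmn, fad",
        "tetrapyrroles",
        "other",
    ],
    "fatty acids, lipids, and isoprenoids": [
        "fatty acids",
        "isoprenoids",
        "phospholipids",
        "other",
    ],
    "nitrogen metabolism": [
        "ammonia assimilation",
        "nitrate and nitrite ammonification",
        "other",
    ],
    "nucleosides and nucleotides": [
        "purines",
        "pyrimidines",
    ],
}

DEFAULT_SUBSYSTEMS = [
    "glycolysis and gluconeogenesis",
    "tca cycle",
    "trehalose uptake and utilization",
    "mannose metabolism",
    "gluconate utilization",
    "citrate metabolism",
    "butyrate fermentation",
    "methionine salvage",
    "purine biosynthesis",
    "thiamine transport",
    "folate biosynthesis",
    "ammonia assimilation",
    "allantoin utilization",
    "fatty acid biosynthesis",
    "phospholipid metabolism",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    ``orders`` maps each bacterial order to its species' strain counts;
    species with >= ``prevalent_min_strains`` strains form the pangenome
    panel.  ``delta`` is the between-order effect size on subcategory
    profiles (0 = exchangeable genomes); ``concentration`` the Dirichlet
    concentration of per-genome profiles around the order profile.
    """

    seed: int = 0
    orders: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            # 28 + 18 + 50 = 96 genomes; seven species with >= 5 strains
            "Enterobacterales": (6, 5, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1),
            "Lactobacillales": (6, 5, 1, 1, 1, 1, 1, 1, 1),
            "Rhodospirillales": (13, 6, 5, 3, 3, 3, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1),
        }
    )
    prevalent_min_strains: int = 5
    subcategories: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SUBCATEGORIES.items()}
    )
    # trait-count model
    concentration: float = 400.0
    delta: float = 0.52
    delta_species: float = 0.12
    functions_per_genome: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "Enterobacterales": (650, 968),
            "Lactobacillales": (286, 500),
            "Rhodospirillales": (380, 650),
        }
    )
    # pangenome model
    core_size_range: tuple[int, int] = (264, 488)
    shared_core_fraction: float = 0.55
    pangenome_cap: int = 538
    accessory_mean_range: tuple[float, float] = (1.0, 55.0)
    accessory_pool_cap: int = 102
    accessory_sharing: float = 0.6
    enriched_subsystem: str = "trehalose uptake and utilization"
    enrichment_odds: float = 4.0  # 1 = no planted enrichment
    annotated_fraction: float = 0.85  # genes carrying a metabolic annotation
    # alignment model
    alignment_length: int = 600
    base_substitution_rate: float = 0.4
    species_rate_span: tuple[float, float] = (0.2, 3.0)
    # continuous-trait model
    bm_sigma2: float = 1.0
    bm_lambda: float = 1.0
    # tree branch-length scales by level (order stem, species stem, strain)
    branch_scales: tuple[float, float, float] = (0.5, 0.15, 0.02)

    def strain_table(self) -> pd.DataFrame:
        """Strain metadata: strain_id, order, species, fly_of_origin."""
        rng = rng_for(self.seed, "metadata")
        rows = []
        for order in sorted(self.orders):
            abbr = order[:3]
            for si, n_strains in enumerate(self.orders[order], start=1):
                species = f"{abbr}_sp{si:02d}"
                n_flies = max(1, int(np.ceil(n_strains * 0.8)))
                for k in range(1, n_strains + 1):
                    rows.append(
                        {
                            "strain_id": f"{species}_st{k:02d}",
                            "order": order,
                            "species": species,
                            "fly_of_origin": f"fly_{rng.integers(1, n_flies + 1):03d}",
                        }
                    )
        return pd.DataFrame(rows)

    def prevalent_species(self) -> list[str]:
        meta = self.strain_table()
        sizes = meta.groupby("species").size()
        return sorted(sizes[sizes >= self.prevalent_min_strains].index)

    @property
    def n_genomes(self) -> int:
        return sum(sum(v) for v in self.orders.values())


def study_config(seed: int = 0, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def _random_binary_newick(leaves: list[str], rng, scale: float) -> str:
    """Random binary subtree over the given leaves with exp branch lengths."""
    nodes = [f"{l}:{rng.exponential(scale) + scale * 0.1:.6g}" for l in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        length = rng.exponential(scale) + scale * 0.1
        nodes.append(f"({a},{b}):{length:.6g}")
    return nodes[0]


def simulate_tree(cfg: SimConfig):
    """Order/species-structured random phylogeny, deterministic under seed."""
    from .io import read_newick

    rng = rng_for(cfg.seed, "tree")
    meta = cfg.strain_table()
    s_order, s_species, s_strain = cfg.branch_scales
    order_subtrees = []
    for order in sorted(cfg.orders):
        species_subtrees = []
        for species, grp in sorted(meta[meta["order"] == order].groupby("species")):
            leaves = list(grp["strain_id"])
            if len(leaves) == 1:
                sub = f"{leaves[0]}:{rng.exponential(s_strain) + s_strain * 0.1:.6g}"
            else:
                sub = _random_binary_newick(leaves, rng, s_strain)
            stem = rng.exponential(s_species) + 0.02
            species_subtrees.append(_restem(sub, stem))
        joined = species_subtrees[0]
        for sub in species_subtrees[1:]:
            length = rng.exponential(s_species) + 0.02
            joined = f"({joined},{sub}):{length:.6g}"
        order_subtrees.append(_restem(joined, rng.exponential(s_order) + 0.1))
    tree = order_subtrees[0]
    for sub in order_subtrees[1:]:
        tree = f"({tree},{sub}):{rng.exponential(s_order) + 0.1:.6g}"
    newick = _strip_root_length(tree) + ";"
    return read_newick(newick)


def _restem(subtree: str, stem: float) -> str:
    """Replace the outermost branch length of a newick fragment."""
    head, _, _ = subtree.rpartition(":")
    return f"{head}:{stem:.6g}"


def _strip_root_length(subtree: str) -> str:
    head, _, tail = subtree.rpartition(":")
    return head if head.endswith(")") else subtree


# ---------------------------------------------------------------------------
# trait counts
# ---------------------------------------------------------------------------

def _subcategory_columns(cfg: SimConfig) -> list[tuple[str, str]]:
    return [(cat, sub) for cat in cfg.subcategories for sub in cfg.subcategories[cat]]


def simulate_trait_counts(cfg: SimConfig) -> TraitCountMatrix:
    """Order-structured subcategory count profiles.

    Per genome: counts ~ Multinomial(N_g, p) with p ~ Dirichlet(alpha * (base
    + delta * order_shift + delta_species * species_shift)).  delta = 0 and
    delta_species = 0 make genomes exchangeable; delta concentrates each
    order on its own subcategory block, delta_species adds the finer
    species-level structure seen in trait dendrograms.  Row sums equal the
    drawn per-genome function totals.
    """
    rng = rng_for(cfg.seed, "trait_counts")
    cols = _subcategory_columns(cfg)
    k = len(cols)
    base = rng.dirichlet(np.full(k, 5.0))
    meta = cfg.strain_table()
    orders = sorted(cfg.orders)
    # disjoint subcategory blocks favored by each order
    blocks = np.array_split(rng.permutation(k), len(orders))
    shifts = {}
    for order, block in zip(orders, blocks):
        shift = np.zeros(k)
        shift[block] = 1.0 / len(block)
        shifts[order] = shift
    sp_shifts = {
        sp: rng.dirichlet(np.full(k, 0.5)) for sp in sorted(meta["species"].unique())
    }
    counts = np.zeros((len(meta), k), dtype=int)
    for gi, row in enumerate(meta.itertuples()):
        p_mean = (base + cfg.delta * shifts[row.order]
                  + cfg.delta_species * sp_shifts[row.species])
        p_mean = p_mean / p_mean.sum()
        p = rng.dirichlet(cfg.concentration * p_mean)
        lo, hi = cfg.functions_per_genome[row.order]
        n_g = int(rng.integers(lo, hi + 1))
        counts[gi] = rng.multinomial(n_g, p)
    df = pd.DataFrame(
        counts,
        index=pd.Index(meta["strain_id"], name="genome_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["category", "subcategory"]),
    ).sort_index()
    return TraitCountMatrix(counts=df)


_NOISE_RECORDS = [
    ("virulence, disease and defense", "resistance to antibiotics", "beta-lactamase", "beta-lactamase (ec 3.5.2.6)"),
    ("membrane transport", "abc transporters", "abc transporter alkylphosphonate", "phosphonate abc transporter"),
    ("nitrogen metabolism", "no subcategory", "nitrosative stress", "flavohemoglobin"),
    ("carbohydrates", "no subcategory", "polyhydroxybutyrate metabolism", "phb synthase"),
    ("nucleosides and nucleotides", "detoxification", "nudix hydrolases", "adp-ribose pyrophosphatase"),
    ("nucleosides and nucleotides", "no subcategory", "orphan nucleotide genes", "uncharacterized nucleotide protein"),
]


def simulate_function_table(cfg: SimConfig, traits: TraitCountMatrix | None = None) -> FunctionTable:
    """Long-format annotation records realizing a trait-count matrix.

    Emits one role record per planted count (roles named per subcategory so
    distinct-role counting recovers the matrix exactly), duplicates a
    fraction of records to exercise unique-role counting, writes the
    "other" subcategory as the literal "no subcategory", and adds
    out-of-scope and removed-subsystem records that extraction must drop.
    """
    rng = rng_for(cfg.seed, "function_table")
    traits = traits if traits is not None else simulate_trait_counts(cfg)
    rows = []
    for genome_id, row in traits.counts.iterrows():
        for (cat, sub), count in row.items():
            written_sub = "no subcategory" if sub == "other" else sub
            for i in range(int(count)):
                subsystem = f"{sub} subsystem {i % 3 + 1}"
                rows.append(
                    (genome_id, cat, written_sub, subsystem, f"{cat}|{sub}|role {i + 1:03d}")
                )
        for rec in _NOISE_RECORDS:
            rows.append((genome_id,) + rec)
    df = pd.DataFrame(rows, columns=["genome_id", "category", "subcategory", "subsystem", "role"])
    # duplicated gene features annotated with the same role
    dup = df.sample(n=len(df) // 10, random_state=int(child_seed(cfg.seed, "dups")) % (2**32))
    return FunctionTable(pd.concat([df, dup], ignore_index=True))


# ---------------------------------------------------------------------------
# pangenome
# ---------------------------------------------------------------------------

def simulate_pangenome(
    cfg: SimConfig,
) -> tuple[PresenceAbsenceMatrix, dict[str, tuple[str, str]], pd.Series]:
    """Species pangenomes for the prevalent-species panel.

    Per species: a core block present in every strain (size drawn from
    ``core_size_range``), and an accessory pool (capped at
    ``accessory_pool_cap``) from which each strain draws Poisson(mu_s)
    genes - a 'shared' sub-pool (probability ``accessory_sharing``) gives
    accessory genes recurring across strains, the rest are strain-private.
    With ``enrichment_odds`` rho > 1, accessory genes pick the configured
    subsystem with rho-fold odds relative to core genes.

    Returns the combined presence/absence matrix over all prevalent
    strains, the gene -> (subsystem, role) annotation map, and the
    strain -> species factor.
    """
    rng = rng_for(cfg.seed, "pangenome")
    meta = cfg.strain_table()
    prevalent = cfg.prevalent_species()
    meta = meta[meta["species"].isin(prevalent)]
    subsystems = list(DEFAULT_SUBSYSTEMS)
    w = np.ones(len(subsystems))
    w_enriched = w.copy()
    if cfg.enriched_subsystem in subsystems:
        w_enriched[subsystems.index(cfg.enriched_subsystem)] *= cfg.enrichment_odds
    p_core = w / w.sum()
    p_acc = w_enriched / w_enriched.sum()

    annotations: dict[str, tuple[str, str]] = {}
    gene_rows: list[str] = []
    presence: dict[str, set[str]] = {}
    # a shared core carried by every strain of every species, so a portion
    # of orthogroups shows no between-species incidence signal
    n_shared_core = int(round(cfg.shared_core_fraction * cfg.core_size_range[0]))
    shared_core = [f"shared_core{i:04d}" for i in range(n_shared_core)]
    for g in shared_core:
        if rng.random() < cfg.annotated_fraction:
            sub = subsystems[rng.choice(len(subsystems), p=p_core)]
            annotations[g] = (sub, f"{g} role")
    gene_rows.extend(shared_core)
    mus = np.linspace(*cfg.accessory_mean_range, num=len(prevalent))
    mus = rng.permutation(mus)
    for sp, mu in zip(prevalent, mus):
        strains = list(meta.loc[meta["species"] == sp, "strain_id"])
        core_n = int(rng.integers(cfg.core_size_range[0], cfg.core_size_range[1] + 1))
        pool_n = int(min(cfg.accessory_pool_cap, max(10, round(mu * 2.2)),
                         max(0, cfg.pangenome_cap - core_n)))
        core_genes = shared_core + [f"{sp}_core{i:04d}" for i in range(core_n - n_shared_core)]
        pool_genes = [f"{sp}_acc{i:04d}" for i in range(pool_n)]
        n_shared = int(round(cfg.accessory_sharing * pool_n))
        shared_pool = pool_genes[:n_shared]
        private_pool = pool_genes[n_shared:]
        for g in core_genes[n_shared_core:]:
            if rng.random() < cfg.annotated_fraction:
                sub = subsystems[rng.choice(len(subsystems), p=p_core)]
                annotations[g] = (sub, f"{g} role")
        for g in pool_genes:
            if rng.random() < cfg.annotated_fraction:
                sub = subsystems[rng.choice(len(subsystems), p=p_acc)]
                annotations[g] = (sub, f"{g} role")
        gene_rows.extend(core_genes[n_shared_core:])
        gene_rows.extend(pool_genes)
        used_private: set[str] = set()
        for s in strains:
            n_acc = int(rng.poisson(mu))
            chosen: set[str] = set()
            for _ in range(n_acc):
                if shared_pool and rng.random() < cfg.accessory_sharing:
                    chosen.add(shared_pool[rng.integers(len(shared_pool))])
                else:
                    free = [g for g in private_pool if g not in used_private and g not in chosen]
                    if free:
                        g = free[rng.integers(len(free))]
                        chosen.add(g)
                        used_private.add(g)
                    elif shared_pool:
                        chosen.add(shared_pool[rng.integers(len(shared_pool))])
            presence[s] = set(core_genes) | chosen
    all_strains = list(meta["strain_id"])
    mat = pd.DataFrame(0, index=pd.Index(gene_rows, name="gene_id"), columns=all_strains, dtype=np.int8)
    for s in all_strains:
        mat.loc[sorted(presence[s]), s] = 1
    # drop pool genes never realized in any strain
    mat = mat[mat.sum(axis=1) > 0]
    annotations = {g: annotations[g] for g in mat.index if g in annotations}
    species_factor = meta.set_index("strain_id")["species"]
    return PresenceAbsenceMatrix(mat, annotations), annotations, species_factor


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _species_of(tip: str) -> str:
    return tip.rsplit("_st", 1)[0]


def simulate_alignment(
    cfg: SimConfig,
    tree,
    species_rates: Mapping[str, float] | None = None,
    alphabet: str = "aa",
) -> AlignmentBlock:
    """i.i.d.-site substitution simulation along the tree.

    Jukes-Cantor-like for nucleotides, uniform exchange over the 20 amino
    acids otherwise.  Edge rates are ``base_substitution_rate`` scaled by
    the species multiplier wherever every descendant tip belongs to that
    species, so within-species diversity is controlled per species.
    """
    rng = rng_for(cfg.seed, f"alignment_{alphabet}")
    alpha = NT if alphabet == "nt" else AA
    k = len(alpha)
    L = cfg.alignment_length
    species_rates = dict(species_rates or {})
    dt = tree.dendropy_tree
    root_seq = rng.integers(0, k, size=L)
    seqs: dict[str, np.ndarray] = {}

    def clade_rate(node) -> float:
        tips = {_species_of(l.taxon.label) for l in node.leaf_iter()}
        if len(tips) == 1:
            return species_rates.get(next(iter(tips)), 1.0)
        return 1.0

    def walk(node, seq):
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * cfg.base_substitution_rate * clade_rate(child)
            p_change = (k - 1) / k * (1.0 - np.exp(-k / (k - 1) * t))
            child_seq = seq.copy()
            hits = np.flatnonzero(rng.random(L) < p_change)
            if hits.size:
                # draw a different state uniformly at each hit site
                shift = rng.integers(1, k, size=hits.size)
                child_seq[hits] = (child_seq[hits] + shift) % k
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(dt.seed_node, root_seq)
    ids = sorted(seqs)
    alpha_arr = np.array(list(alpha))
    return AlignmentBlock(ids, ["".join(alpha_arr[seqs[i]]) for i in ids], alphabet)


# ---------------------------------------------------------------------------
# continuous traits
# ---------------------------------------------------------------------------

def simulate_bm_trait(
    cfg: SimConfig, tree, lam: float | None = None, name: str = "bm_trait"
) -> dict[str, float]:
    """Multivariate-normal draw under the lambda-transformed BM covariance."""
    from .trees import bm_covariance

    lam = cfg.bm_lambda if lam is None else float(lam)
    rng = rng_for(cfg.seed, name)
    C, labels = bm_covariance(tree)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    V = cfg.bm_sigma2 * V
    y = rng.multivariate_normal(np.zeros(len(labels)), V, method="cholesky")
    return dict(zip(labels, y.tolist()))
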