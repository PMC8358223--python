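"""Pangenome core/accessory statistics for prevalent species.

Partitions each species' gene-family incidence matrix into core genes
(present in every strain, threshold configurable) and accessory genes,
computes the per-strain distribution index
D = (n_core - n_accessory(strain)) / n_pangenome, scores within-species
sequence diversity (mean per-column Shannon entropy of amino-acid
alignments; nucleotide diversity pi), and runs the two exact-test
procedures: a two-sided Fisher test of orthogroup incidence between
species (Freeman-Halton for r x 2 tables) and a one-sided Fisher
enrichment test of subsystems in the accessory versus core genome, both
with Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger
from .datatypes import AlignmentBlock, PresenceAbsenceMatrix, TestResult

GAP_CHARS = frozenset("-.")


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

@dataclass
class PangenomePartition:
    """Core/accessory split of one species' gene families."""

    species: str
    strain_ids: list[str]
    core_genes: list[str]
    accessory_genes: list[str]
    per_strain_accessory: dict[str, int]

    @property
    def n_core(self) -> int:
        return len(self.core_genes)

    @property
    def n_pangenome(self) -> int:
        return len(self.core_genes) + len(self.accessory_genes)

    def __post_init__(self):
        for s, cnt in self.per_strain_accessory.items():
            if cnt > self.n_pangenome - self.n_core:
                raise ValueError(f"strain {s}: accessory count exceeds accessory genome")


def partition_pangenome(
    pa: PresenceAbsenceMatrix,
    species: Mapping[str, str] | pd.Series,
    core_fraction: float = 1.0,
) -> list[PangenomePartition]:
    """Split each species' genes into core and accessory.

    A gene is core iff present in at least ``core_fraction`` (default 1.0,
    i.e. 100%) of that species' strains; genes absent from every strain of
    the species do not belong to its pangenome.  Species with a single
    strain are skipped with a warning.
    """
    if isinstance(species, pd.Series):
        species = species.to_dict()
    missing = [s for s in pa.strain_ids if s not in species]
    if missing:
        raise ValueError(f"species assignment missing for strains: {missing[:5]}")
    out = []
    by_species: dict[str, list[str]] = {}
    for s in pa.strain_ids:
        by_species.setdefault(str(species[s]), []).append(s)
    for sp in sorted(by_species):
        strains = by_species[sp]
        if len(strains) < 2:
            logger.warning("species %r has a single strain; skipped", sp)
            continue
        sub = pa.cells[strains]
        n_present = sub.sum(axis=1)
        in_pan = n_present > 0
        is_core = n_present >= math.ceil(core_fraction * len(strains))
        core = list(sub.index[in_pan & is_core])
        accessory = list(sub.index[in_pan & ~is_core])
        acc_block = sub.loc[accessory]
        per_strain = {s: int(acc_block[s].sum()) for s in strains}
        out.append(
            PangenomePartition(
                species=sp,
                strain_ids=strains,
                core_genes=core,
                accessory_genes=accessory,
                per_strain_accessory=per_strain,
            )
        )
    return out


def distribution_index(p: PangenomePartition) -> pd.Series:
    """Per-strain D = (n_core - n_accessory(strain)) / n_pangenome.

    D = 1 means an all-core pangenome; D near 0 means a strain carries as
    many accessory genes as there are core genes.  D can go negative when a
    strain's accessory exceeds the core (flagged).
    """
    if p.n_pangenome == 0:
        raise ValueError(f"species {p.species}: empty pangenome")
    vals = {
        s: (p.n_core - acc) / p.n_pangenome for s, acc in p.per_strain_accessory.items()
    }
    out = pd.Series(vals, name=p.species).sort_index()
    if (out < 0).any():
        logger.warning(
            "species %s: strain accessory exceeds core (negative D)", p.species
        )
    return out


# ---------------------------------------------------------------------------
# alignment diversity
# ---------------------------------------------------------------------------

def residue_diversity(
    aln: AlignmentBlock, strain_subset: Sequence[str] | None = None, base: float = 2.0
) -> float:
    """Mean per-column Shannon entropy of the alignment rows of a subset.

    Gaps are excluded from each column's residue distribution; columns that
    become empty for the subset are skipped.  Entropy is in bits by default
    (``base`` switchable).
    """
    sub = aln.subset(list(strain_subset)) if strain_subset is not None else aln
    if sub.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    arr = sub.to_array()
    entropies = []
    for col in arr.T:
        residues = [c for c in col if c not in GAP_CHARS]
        if not residues:
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        entropies.append(float(-(p * np.log(p)).sum() / np.log(base)))
    if not entropies:
        raise ValueError("alignment has no non-gap columns for the subset")
    return float(np.mean(entropies))


def nucleotide_diversity(aln: AlignmentBlock) -> float:
    """Nucleotide diversity pi: mean pairwise differences per compared site.

    Gap positions are pairwise-deleted; 'N' is treated as missing.
    """
    if aln.alphabet != "nt":
        raise ValueError("nucleotide diversity requires a nucleotide alignment")
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    arr = aln.to_array()
    missing = np.isin(arr, list(GAP_CHARS | {"N"}))
    vals = []
    for i, j in itertools.combinations(range(arr.shape[0]), 2):
        ok = ~missing[i] & ~missing[j]
        n_sites = int(ok.sum())
        if n_sites == 0:
            continue
        vals.append(float((arr[i, ok] != arr[j, ok]).sum() / n_sites))
    if not vals:
        raise ValueError("no comparable (gap-free) sites in any pair")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _log_binom(n, k):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _table_prob(table: np.ndarray) -> float:
    """Probability of an r x 2 table under fixed margins (hypergeometric)."""
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    n = int(t.sum())
    c1 = int(t[:, 0].sum())
    lp = _log_binom(rows, t[:, 0]).sum() - _log_binom(n, c1)
    return float(np.exp(lp))


def _half_profiles(rows: np.ndarray) -> dict[int, np.ndarray]:
    """log prod-of-binomials for every first-column fill of a row subset,
    grouped by the total filled."""
    combos = {0: np.array([0.0])}
    for r in rows:
        lb = _log_binom(int(r), np.arange(int(r) + 1))
        new: dict[int, list] = {}
        for u, arr in combos.items():
            for a in range(int(r) + 1):
                new.setdefault(u + a, []).append(arr + lb[a])
        combos = {u: np.concatenate(v) for u, v in new.items()}
    return combos


def fisher_exact_rx2(
    table,
    enum_max: int = 60,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided exact test of independence for an r x 2 table.

    The Freeman-Halton extension of Fisher's exact test: the p-value sums
    the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (relative
    tolerance 1e-7, as in the standard implementations).  Enumeration
    splits the rows in two halves and combines their fill profiles through
    sorted prefix sums, so r x 2 tables with moderate margins are exact and
    fast.  Tables with total > ``enum_max`` fall back to seeded Monte-Carlo
    sampling of the margin-fixed null with a reported standard error.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    rows = t.sum(axis=1)
    n = int(t.sum())
    c1 = int(t[:, 0].sum())
    lc = float(_log_binom(n, c1))
    lp_obs = float(_log_binom(rows, t[:, 0]).sum()) - lc
    thr = lp_obs + 1e-7  # numerator threshold, in log units
    if n <= enum_max:
        half = len(rows) // 2 if len(rows) > 1 else 1
        A = _half_profiles(rows[:half])
        B = _half_profiles(rows[half:]) if half < len(rows) else {0: np.array([0.0])}
        total = 0.0
        for u, arr_a in A.items():
            v = c1 - u
            if v not in B:
                continue
            arr_b = np.sort(B[v])
            prefix = np.cumsum(np.exp(arr_b))
            # accept pairs with (a + b - lc) <= thr  <=>  b <= thr + lc - a
            pos = np.searchsorted(arr_b, thr + lc - arr_a, side="right")
            total += float(np.sum(np.exp(arr_a) * np.where(pos > 0, prefix[pos - 1], 0.0)))
        p = total * math.exp(-lc)
        return TestResult(
            name="Fisher exact (r x 2)",
            statistic=math.exp(lp_obs),
            p_value=min(1.0, p),
            extra={"method": "enumeration", "n": n},
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(rows, c1, size=n_mc)
    lp = _log_binom(rows[None, :], draws).sum(axis=1) - lc
    hits = int(np.sum(lp <= thr))
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return TestResult(
        name="Fisher exact (r x 2)",
        statistic=math.exp(lp_obs),
        p_value=p,
        n_permutations=n_mc,
        seed=seed,
        extra={"method": "monte-carlo", "mc_se": se, "n": n},
    )


def orthogroup_incidence_test(
    pa: PresenceAbsenceMatrix,
    species: Mapping[str, str] | pd.Series,
    min_genomes: int = 3,
    enum_max: int = 60,
    seed: int | None = None,
) -> list[TestResult]:
    """Two-sided Fisher tests of orthogroup incidence between species.

    Orthogroups present in fewer than ``min_genomes`` genomes are excluded.
    Each retained orthogroup yields a species x {present, absent} table of
    strain counts; p-values are BH-adjusted across orthogroups.
    """
    if isinstance(species, pd.Series):
        species = species.to_dict()
    missing = [s for s in pa.strain_ids if s not in species]
    if missing:
        raise ValueError(f"species assignment missing for strains: {missing[:5]}")
    sp = np.array([str(species[s]) for s in pa.strain_ids])
    levels = sorted(set(sp))
    if len(levels) < 2:
        raise ValueError("need at least 2 species")
    cells = pa.cells.to_numpy()
    keep = cells.sum(axis=1) >= min_genomes
    results = []
    cache: dict[bytes, TestResult] = {}
    for gi in np.flatnonzero(keep):
        row = cells[gi]
        table = np.array(
            [[int(row[sp == lv].sum()), int((sp == lv).sum() - row[sp == lv].sum())]
             for lv in levels]
        )
        key = table.tobytes()
        if key in cache:
            r = cache[key]
        else:
            sub_seed = None if seed is None else seed + 1 + int(gi)
            r = fisher_exact_rx2(table, enum_max=enum_max, seed=sub_seed)
            cache[key] = r
        results.append(
            TestResult(
                name=pa.gene_ids[gi],
                statistic=r.statistic,
                p_value=r.p_value,
                extra={"species": levels, "present": table[:, 0].tolist(),
                       "method": r.extra.get("method")},
            )
        )
    qs = bh_fdr([r.p_value for r in results])
    return [r.with_q(q) for r, q in zip(results, qs)]


def accessory_enrichment(
    partition: PangenomePartition,
    annotations: Mapping[str, tuple[str, str]],
) -> list[TestResult]:
    """One-sided Fisher enrichment of subsystems in the accessory genome.

    Units are function counts: distinct roles per subsystem in the
    accessory versus core compartments.  For subsystem s the 2 x 2 table is
    [[s-in-accessory, other-in-accessory], [s-in-core, other-in-core]];
    the p-value is the upper hypergeometric tail and the sample odds ratio
    is (a*d)/(b*c) with a Haldane 0.5 correction when any cell is zero.
    q-values are BH-adjusted across subsystems.  Genes without a role
    annotation are excluded from both compartments.
    """

    def roles_by_subsystem(genes):
        d: dict[str, set[str]] = {}
        for g in genes:
            ann = annotations.get(g)
            if ann is None:
                continue
            subsystem, role = ann
            d.setdefault(subsystem, set()).add(role)
        return d

    acc = roles_by_subsystem(partition.accessory_genes)
    core = roles_by_subsystem(partition.core_genes)
    n_acc = sum(len(v) for v in acc.values())
    n_core = sum(len(v) for v in core.values())
    if n_acc == 0:
        logger.warning("species %s: empty annotated accessory genome; no tests",
                       partition.species)
        return []
    results = []
    for subsystem in sorted(set(acc) | set(core)):
        a = len(acc.get(subsystem, ()))
        c = len(core.get(subsystem, ()))
        if a == 0 and c == 0:
            continue
        b = n_acc - a
        d = n_core - c
        # upper tail: P(X >= a) with X ~ Hypergeom(N, a+c, a+b)
        p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        results.append(
            TestResult(
                name=subsystem,
                statistic=float(orr),
                p_value=min(1.0, p),
                effect=float(orr),
                effect_name="OR",
                extra={"table": [[a, b], [c, d]], "species": partition.species},
            )
        )
    qs = bh_fdr([r.p_value for r in results])
    return [r.with_q(q) for r, q in zip(results, qs)]
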