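"""Turn raw subsystem annotations into primary-metabolism trait matrices.

The extraction keeps six annotation categories (amino acids and derivatives;
carbohydrates; cofactors/vitamins/prosthetic groups/pigments; fatty
acids/lipids/isoprenoids; nitrogen metabolism; nucleosides and nucleotides),
drops five secondary-metabolism subsystems, drops the "detoxification" and
"no subcategory" subcategories of the nucleoside/nucleotide category, and
relabels "no subcategory" as "other" elsewhere.  Counting is of *distinct
role strings* per genome and subcategory: a function annotated on several
genes (duplications, fragmented genes) is counted once.  Relative counts
scale each genome's subcategory counts to its total count over the retained
subcategories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import logger
from .datatypes import NO_SUBCATEGORY, FunctionTable


def _norm(s: str) -> str:
    return " ".join(str(s).split()).casefold()


@dataclass(frozen=True)
class ExtractionRules:
    retained_categories: tuple[str, ...]
    removed_subsystems: frozenset[str]
    removed_subcategories: dict  # normalized category -> set of normalized subcategories
    no_subcategory_relabel: str = "other"

    @classmethod
    def default(cls) -> "ExtractionRules":
        text = (
            resources.files("pantrait") / "rules" / "default_rules.yaml"
        ).read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml(cls, path) -> "ExtractionRules":
        return cls.from_yaml_text(Path(path).read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "ExtractionRules":
        raw = yaml.safe_load(text)
        return cls(
            retained_categories=tuple(raw["retained_categories"]),
            removed_subsystems=frozenset(_norm(s) for s in raw.get("removed_subsystems", [])),
            removed_subcategories={
                _norm(cat): {_norm(s) for s in subs}
                for cat, subs in (raw.get("removed_subcategories") or {}).items()
            },
            no_subcategory_relabel=raw.get("no_subcategory_relabel", "other"),
        )

    @property
    def category_order(self) -> dict[str, int]:
        return {_norm(c): i for i, c in enumerate(self.retained_categories)}


@dataclass
class TraitCountMatrix:
    """Distinct-role counts per genome and subcategory, plus relative counts.

    ``counts`` columns are a (category, subcategory) MultiIndex ordered by
    the rules' category listing, then alphabetically by subcategory.
    ``relative`` rows sum to 1; genomes with zero retained roles are dropped
    from it.
    """

    counts: pd.DataFrame
    relative: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.relative is None:
            totals = self.counts.sum(axis=1)
            keep = totals > 0
            if not keep.all():
                dropped = list(self.counts.index[~keep])
                logger.warning(
                    "%d genome(s) with zero retained roles dropped from the "
                    "relative matrix: %s", len(dropped), dropped[:5],
                )
            self.relative = self.counts.loc[keep].div(totals[keep], axis=0)
        sums = self.relative.sum(axis=1).to_numpy()
        if len(sums) and np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("relative rows do not sum to 1")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subcategory_labels(self) -> list[str]:
        return [f"{c}|{s}" for c, s in self.counts.columns]


def filter_primary_metabolism(
    table: FunctionTable, rules: ExtractionRules | None = None
) -> FunctionTable:
    """Apply the primary-metabolism extraction rules to an annotation table.

    Category selection is applied first, then subsystem and subcategory
    removals, then the "no subcategory" -> "other" relabeling.  Idempotent.
    """
    rules = rules or ExtractionRules.default()
    if len(table) == 0:
        raise ValueError("empty function table")
    df = table.records.copy()
    cat_n = df["category"].map(_norm)
    keep = cat_n.isin(rules.category_order)
    df, cat_n = df[keep], cat_n[keep]
    keep = ~df["subsystem"].map(_norm).isin(rules.removed_subsystems)
    df, cat_n = df[keep], cat_n[keep]
    sub_n = df["subcategory"].map(_norm)
    drop = pd.Series(False, index=df.index)
    for cat, subs in rules.removed_subcategories.items():
        drop |= (cat_n == cat) & sub_n.isin(subs)
    df, cat_n, sub_n = df[~drop], cat_n[~drop], sub_n[~drop]
    relabel = sub_n == _norm(NO_SUBCATEGORY)
    # "other" only applies to subcategories that survived the removals above
    df.loc[relabel, "subcategory"] = rules.no_subcategory_relabel
    if df.empty:
        logger.warning("no records retained by the extraction rules")
    return FunctionTable(df.reset_index(drop=True))


def count_unique_roles(
    table: FunctionTable, rules: ExtractionRules | None = None
) -> TraitCountMatrix:
    """Count distinct roles per genome x subcategory on a filtered table.

    Role identity is the case-folded, whitespace-normalized role string.  A
    role annotated under two subcategories counts once in each (no
    cross-subcategory deduplication); duplicated records never inflate
    counts.
    """
    rules = rules or ExtractionRules.default()
    df = table.records.copy()
    df["_role"] = df["role"].map(_norm)
    df["_cat"] = df["category"].map(_norm)
    df["_sub"] = df["subcategory"].map(_norm)
    order = rules.category_order
    unknown = set(df["_cat"]) - set(order)
    if unknown:
        raise ValueError(
            f"table contains categories outside the rules: {sorted(unknown)[:3]}; "
            "run filter_primary_metabolism first"
        )
    grouped = (
        df.groupby(["genome_id", "_cat", "_sub"])["_role"].nunique().reset_index()
    )
    # display labels: first-seen original spelling per normalized pair
    label_of = (
        df.drop_duplicates(["_cat", "_sub"])
        .set_index(["_cat", "_sub"])[["category", "subcategory"]]
    )
    wide = grouped.pivot_table(
        index="genome_id", columns=["_cat", "_sub"], values="_role",
        fill_value=0, aggfunc="first",
    ).astype(int)
    cols = sorted(wide.columns, key=lambda cs: (order[cs[0]], cs[1]))
    wide = wide.loc[:, cols]
    wide.columns = pd.MultiIndex.from_tuples(
        [tuple(label_of.loc[cs]) for cs in cols], names=["category", "subcategory"]
    )
    wide = wide.sort_index()
    return TraitCountMatrix(counts=wide)
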