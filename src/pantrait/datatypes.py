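"""Shared domain types used across the pipeline.

Strain/genome identifiers are opaque strings everywhere; joins between
inputs are by exact label match (see :func:`pantrait.io.label_report`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FUNCTION_COLUMNS = ("genome_id", "category", "subcategory", "subsystem", "role")

NO_SUBCATEGORY = "no subcategory"

_NT_CHARS = set("ACGTUN-")


class FormatError(ValueError):
    """Raised when an input file does not satisfy a reader's contract."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single statistical test.

    Houses the pseudo-F/R² of a PERMANOVA, Mantel r, Procrustes m²/r,
    likelihood-ratio χ², Fisher odds ratios, Pagel's λ and their p/q values.
    """

    name: str
    statistic: float
    p_value: float
    df: tuple | float | None = None
    effect: float | None = None
    effect_name: str | None = None
    adjusted_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if self.adjusted_p is not None and not (
            np.isnan(self.adjusted_p) or 0.0 <= self.adjusted_p <= 1.0
        ):
            raise ValueError(f"adjusted p outside [0, 1]: {self.adjusted_p}")

    def with_q(self, q: float) -> "TestResult":
        return TestResult(
            name=self.name,
            statistic=self.statistic,
            p_value=self.p_value,
            df=self.df,
            effect=self.effect,
            effect_name=self.effect_name,
            adjusted_p=q,
            n_permutations=self.n_permutations,
            seed=self.seed,
            extra=dict(self.extra),
        )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.df is not None:
            d["df"] = self.df
        if self.effect is not None:
            d["effect"] = self.effect
            d["effect_name"] = self.effect_name
        if self.adjusted_p is not None:
            d["q_value"] = self.adjusted_p
        if self.n_permutations is not None:
            d["n_permutations"] = self.n_permutations
        if self.seed is not None:
            d["seed"] = self.seed
        d.update(self.extra)
        return d


class DistanceMatrix:
    """Square symmetric nonnegative dissimilarity matrix with unique labels.

    Asymmetry beyond 1e-12, negative entries, and nonzero diagonals are
    rejected at construction.
    """

    _SYM_TOL = 1e-12

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"distance matrix must be square, got {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > self._SYM_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
        if np.abs(np.diag(values)).max(initial=0.0) > self._SYM_TOL:
            raise ValueError("diagonal entries must be zero")
        if values.min(initial=0.0) < 0:
            raise ValueError("negative dissimilarities are not allowed")
        v = 0.5 * (values + values.T)
        np.fill_diagonal(v, 0.0)
        self._values = v
        self._labels = list(labels)
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self._values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns arranged in the given label order."""
        missing = set(labels) - set(self._labels)
        if missing or len(labels) != len(self._labels):
            raise KeyError(f"label mismatch in reorder: missing={sorted(missing)}")
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(self._values[np.ix_(idx, idx)], labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise KeyError(f"labels absent from distance matrix: {missing}")
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(self._values[np.ix_(idx, idx)], labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._labels, columns=self._labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


@dataclass
class FunctionTable:
    """Long-format genome x (category, subcategory, subsystem, role) records.

    The shape of a RAST-style subsystem export.  ``"no subcategory"`` is a
    legal literal; no field is empty after normalization.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = [c for c in FUNCTION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"function table missing columns: {missing}")
        df = df.loc[:, list(FUNCTION_COLUMNS)].copy()
        for c in FUNCTION_COLUMNS:
            df[c] = df[c].astype(str).str.strip()
        df.loc[df["subcategory"] == "", "subcategory"] = NO_SUBCATEGORY
        for c in ("genome_id", "category", "subsystem", "role"):
            if (df[c] == "").any():
                raise FormatError(f"empty values in required column '{c}'")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.records["genome_id"].unique())

    def equals(self, other: "FunctionTable") -> bool:
        a = self.records.sort_values(list(FUNCTION_COLUMNS)).reset_index(drop=True)
        b = other.records.sort_values(list(FUNCTION_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


class PresenceAbsenceMatrix:
    """Binary gene/orthogroup x strain incidence matrix.

    ``annotations`` optionally maps gene ids to ``(subsystem, role)`` pairs;
    its keys must be a subset of the gene ids.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        annotations: Mapping[str, tuple[str, str]] | None = None,
    ):
        arr = cells.to_numpy()
        uniq = np.unique(arr)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"non-binary entries in presence/absence matrix: {uniq[:5]}")
        if cells.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if cells.columns.duplicated().any():
            raise ValueError("duplicate strain ids")
        self.cells = cells.astype(np.int8)
        self.cells.index = self.cells.index.astype(str)
        self.cells.columns = self.cells.columns.astype(str)
        self.annotations = dict(annotations) if annotations else {}
        unknown = set(self.annotations) - set(self.cells.index)
        if unknown:
            raise ValueError(f"annotation keys not in gene ids: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cells.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.cells.columns)

    def subset_strains(self, strains: Sequence[str]) -> "PresenceAbsenceMatrix":
        missing = [s for s in strains if s not in self.cells.columns]
        if missing:
            raise KeyError(f"strains absent from matrix: {missing}")
        return PresenceAbsenceMatrix(self.cells.loc[:, list(strains)], self.annotations)


@dataclass
class AlignmentBlock:
    """Equal-length gapped sequences with an alphabet tag ('aa' or 'nt')."""

    ids: list[str]
    sequences: list[str]
    alphabet: str  # "aa" | "nt"

    def __post_init__(self):
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"alphabet must be 'aa' or 'nt', got {self.alphabet!r}")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.alphabet == "nt":
            bad = set("".join(self.sequences)) - _NT_CHARS
            if bad:
                raise FormatError(f"non-nucleotide characters: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def subset(self, ids: Sequence[str]) -> "AlignmentBlock":
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"sequence ids absent from alignment: {missing}")
        return AlignmentBlock(
            list(ids), [self.sequences[index[i]] for i in ids], self.alphabet
        )

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences], dtype="U1")


def warn(msg: str):
    warnings.warn(msg, stacklevel=3)
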