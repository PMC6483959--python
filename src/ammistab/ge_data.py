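"""Data containers and I/O for balanced genotype-by-environment trials.

Two layouts are supported: a *wide* table of cell means (rows = genotypes,
columns = environments) and a *long* table of replicate-level records
(genotype, environment, replicate, value).  The analysis modules operate on
:class:`GEMatrix`, a validated, strictly balanced table of cell means; the
replicate count ``r`` behind each mean is carried along because all sums of
squares are reported on the replicate-total scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GEDataError",
    "BalancedDesignError",
    "DuplicateRecordError",
    "GEMatrix",
    "GenotypeMeta",
    "ReplicateTable",
    "read_wide_csv",
    "read_long_csv",
    "load_spring_barley",
]


class GEDataError(ValueError):
    """Invalid genotype-by-environment input."""


class BalancedDesignError(GEDataError):
    """The design is unbalanced (missing cells or unequal replication)."""


class DuplicateRecordError(GEDataError):
    """The same (genotype, environment, replicate) triple appears twice."""


@dataclass(frozen=True)
class GenotypeMeta:
    """Per-genotype metadata: parental status and seed type."""

    genotype_id: str
    role: str = "dh_line"  # "parent" or "dh_line"
    seed_type: str = "unknown"  # "hulled", "hull_less" or "unknown"

    def __post_init__(self) -> None:
        if self.role not in ("parent", "dh_line"):
            raise GEDataError(f"unknown role {self.role!r} for {self.genotype_id!r}")
        if self.seed_type not in ("hulled", "hull_less", "unknown"):
            raise GEDataError(
                f"unknown seed_type {self.seed_type!r} for {self.genotype_id!r}"
            )


@dataclass(frozen=True)
class GEMatrix:
    """Balanced table of phenotype cell means (g), genotypes x environments.

    Parameters
    ----------
    values
        ``(G, E)`` array of cell means.  Every cell must be finite: the
        downstream two-way decomposition requires a complete balanced design
        and this container refuses missing data rather than imputing.
    genotype_ids, environment_ids
        Unique row and column labels.
    replicates
        Number ``r`` of replicate observations behind each cell mean
        (1 when unknown).  Used to put sums of squares on the
        replicate-total scale.
    """

    values: np.ndarray
    genotype_ids: tuple[str, ...]
    environment_ids: tuple[str, ...]
    replicates: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "genotype_ids", tuple(str(g) for g in self.genotype_ids))
        object.__setattr__(
            self, "environment_ids", tuple(str(e) for e in self.environment_ids)
        )
        if values.ndim != 2:
            raise GEDataError("values must be a 2-D genotype x environment array")
        G, E = values.shape
        if G != len(self.genotype_ids) or E != len(self.environment_ids):
            raise GEDataError("label lengths do not match the value matrix shape")
        if G < 3 or E < 3:
            raise GEDataError(
                "need at least 3 genotypes and 3 environments; the interaction "
                f"decomposition is degenerate for a {G}x{E} table"
            )
        bad = ~np.isfinite(values)
        if bad.any():
            g, e = np.argwhere(bad)[0]
            raise BalancedDesignError(
                "missing or non-finite cell at genotype "
                f"{self.genotype_ids[g]!r}, environment {self.environment_ids[e]!r}; "
                "the design must be complete and balanced"
            )
        if len(set(self.genotype_ids)) != G:
            raise GEDataError("genotype labels are not unique")
        if len(set(self.environment_ids)) != E:
            raise GEDataError("environment labels are not unique")
        if int(self.replicates) < 1:
            raise GEDataError("replicates must be a positive integer")
        object.__setattr__(self, "replicates", int(self.replicates))

    # -- basic accessors -------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]

    def grand_mean(self) -> float:
        return float(self.values.mean())

    def genotype_means(self) -> pd.Series:
        return pd.Series(self.values.mean(axis=1), index=list(self.genotype_ids))

    def environment_means(self) -> pd.Series:
        return pd.Series(self.values.mean(axis=0), index=list(self.environment_ids))

    def genotype_index(self, genotype_id: str) -> int:
        try:
            return self.genotype_ids.index(genotype_id)
        except ValueError:
            raise KeyError(f"unknown genotype {genotype_id!r}") from None

    # -- conversions -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.genotype_ids),
            columns=list(self.environment_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, replicates: int = 1) -> "GEMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            genotype_ids=tuple(map(str, frame.index)),
            environment_ids=tuple(map(str, frame.columns)),
            replicates=replicates,
        )

    def select_genotypes(self, ids: Sequence[str]) -> "GEMatrix":
        idx = [self.genotype_index(g) for g in ids]
        return GEMatrix(
            self.values[idx], tuple(ids), self.environment_ids, self.replicates
        )

    def to_json(self, path: str | Path) -> None:
        """Write an explicit-ordering JSON representation."""
        payload = {
            "genotype_ids": list(self.genotype_ids),
            "environment_ids": list(self.environment_ids),
            "replicates": self.replicates,
            "values": self.values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GEMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            values=np.asarray(payload["values"], dtype=float),
            genotype_ids=tuple(payload["genotype_ids"]),
            environment_ids=tuple(payload["environment_ids"]),
            replicates=int(payload.get("replicates", 1)),
        )


@dataclass(frozen=True)
class ReplicateTable:
    """Replicate-level trial records from a randomized complete block design."""

    records: pd.DataFrame = field(repr=False)

    REQUIRED = ("genotype", "environment", "replicate", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise GEDataError(f"replicate table lacks columns {missing}")
        if df.empty:
            raise GEDataError("replicate table is empty")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(subset=["genotype", "environment", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicate record for genotype "
                f"{row['genotype']!r}, environment {row['environment']!r}, "
                f"replicate {row['replicate']!r}"
            )
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise GEDataError("replicate table contains non-finite values")
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_replicates(self) -> int:
        """Common replicate count r; raises if the design is unbalanced."""
        counts = self.records.groupby(["genotype", "environment"]).size()
        genotypes = self.records["genotype"].unique()
        environments = self.records["environment"].unique()
        if len(counts) != len(genotypes) * len(environments):
            raise BalancedDesignError(
                "some genotype x environment cells have no records"
            )
        if counts.nunique() != 1:
            raise BalancedDesignError(
                "unequal replication across cells: counts range from "
                f"{counts.min()} to {counts.max()}"
            )
        return int(counts.iloc[0])

    def to_matrix(self) -> GEMatrix:
        """Aggregate replicates to cell means, preserving first-seen order."""
        r = self.n_replicates
        df = self.records
        g_order = list(dict.fromkeys(df["genotype"]))
        e_order = list(dict.fromkeys(df["environment"]))
        wide = df.pivot_table(
            index="genotype", columns="environment", values="value", aggfunc="mean"
        ).reindex(index=g_order, columns=e_order)
        return GEMatrix.from_frame(wide, replicates=r)

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# file readers

def read_wide_csv(path: str | Path, replicates: int = 1) -> GEMatrix:
    """Read a wide CSV (first column = genotype labels, rest = environments)."""
    raw = pd.read_csv(path, index_col=0, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise GEDataError(f"{path}: no data rows/columns found")
    values = np.empty(raw.shape, dtype=float)
    for i, g in enumerate(raw.index):
        for j, e in enumerate(raw.columns):
            cell = raw.iat[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise BalancedDesignError(
                    f"{path}: missing cell at genotype {g!r}, environment {e!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise GEDataError(
                    f"{path}: non-numeric cell {cell!r} at genotype {g!r}, "
                    f"environment {e!r}"
                ) from None
    return GEMatrix(
        values=values,
        genotype_ids=tuple(map(str, raw.index)),
        environment_ids=tuple(map(str, raw.columns)),
        replicates=replicates,
    )


def read_long_csv(path: str | Path) -> ReplicateTable:
    """Read a long CSV with columns genotype, environment, replicate, value."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise GEDataError(f"{path}: file is empty") from None
    return ReplicateTable(df)


def load_spring_barley() -> tuple[GEMatrix, list[GenotypeMeta]]:
    """Load the embedded spring-barley 1000-kernel-weight trial.

    A balanced multi-environment trial of 32 spring barley genotypes — two
    parental genotypes (breeding line 1N86 and DH line RK63/1) and 30
    doubled-haploid lines derived from their F1 hybrids — grown over six
    seasons (2008-2013) at one location in South Poland, three replicates
    per plot.  Cell values are 1000-kernel weight means in grams, recorded
    to two decimals; ``replicates`` is 3.

    Returns
    -------
    (GEMatrix, list[GenotypeMeta])
        The 32 x 6 table of cell means and per-genotype metadata
        (parent / DH line; hulled / hull-less seed).
    """
    from importlib.resources import files

    path = files("ammistab.data").joinpath("barley_tkw.csv")
    with path.open("r") as fh:
        raw = pd.read_csv(fh, dtype={"genotype": str})
    meta = [
        GenotypeMeta(row.genotype, row.role, row.seed_type)
        for row in raw.itertuples(index=False)
    ]
    wide = raw.set_index("genotype").drop(columns=["role", "seed_type"])
    return GEMatrix.from_frame(wide, replicates=3), meta
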