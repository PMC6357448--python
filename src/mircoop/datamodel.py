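"""Core data containers, file IO, and normalization shared by all stages.

Expression data live in :class:`ExpressionMatrix` — a features x samples table
of log2 expression values, optionally median-centered per feature so that 0
marks "typical expression" for each gene or miRNA. Clinical follow-up lives in
:class:`ClinicalTable` (overall-survival time in months, event indicator, and
ER/PR/HER2 receptor status, from which triple-negative status is derived).
:func:`assemble_cohort` aligns all components on their shared samples.

All readers accept plain tab-separated text and tolerate CRLF line endings and
quoted fields. Missing values are kept explicit (NaN) and excluded pairwise in
correlations and per-feature in medians.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CohortBundle",
    "LoadError",
    "AssemblyError",
    "load_expression_matrix",
    "load_clinical_table",
    "load_integer_matrix",
    "median_center",
    "assemble_cohort",
]

_RECEPTOR_LEVELS = {"pos", "neg", "missing"}


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


class AssemblyError(ValueError):
    """Raised when cohort components cannot be aligned."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise LoadError(f"duplicate {what} id {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples log2 expression table.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        NaN marks an explicitly missing measurement.
    centered
        True if every feature row has median 0 over its non-missing entries.
    """

    values: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            i, j = np.argwhere(np.isinf(arr))[0]
            raise LoadError(
                f"non-finite value at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.centered:
            med = np.nanmedian(arr, axis=1)
            bad = np.where(np.abs(med) > 1e-9)[0]
            if bad.size:
                raise ValueError(
                    f"matrix flagged centered but feature "
                    f"{self.values.index[bad[0]]!r} has median {med[bad[0]]:.3g}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature(self, feature_id: str) -> pd.Series:
        """Per-sample values for one feature."""
        return self.values.loc[feature_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        # Subsetting can change per-row medians, so drop the centered flag.
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], centered=False)

    def to_tsv(self, path: str | Path, missing_token: str = "NA") -> None:
        df = self.values.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", na_rep=missing_token, float_format="%.17g")


def load_expression_matrix(path: str | Path, missing_token: str = "NA") -> ExpressionMatrix:
    """Read a tab-separated feature-by-sample matrix.

    First column holds feature ids, first row sample ids. Cells must be
    numeric or equal to ``missing_token``. Duplicate feature or sample ids,
    malformed headers and non-numeric cells are rejected with an error naming
    the offending row/column.
    """
    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False, skipinitialspace=True
    )
    if raw.columns.size == 0:
        raise LoadError(f"{path}: malformed header (no sample columns)")
    dup = raw.index[raw.index.duplicated()]
    if dup.size:
        raise LoadError(f"{path}: duplicate feature id {dup[0]!r}")
    dupc = raw.columns[raw.columns.duplicated()]
    if dupc.size:
        raise LoadError(f"{path}: duplicate sample id {dupc[0]!r}")
    out = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cell = raw[col].str.strip()
        is_missing = (cell == missing_token) | (cell == "")
        # np.float64 string parsing is correctly rounded (bit-exact round trip),
        # unlike pandas' fast to_numeric path
        try:
            out[:, j] = np.where(is_missing, "nan", cell).astype(np.float64)
        except ValueError:
            for i, (s, miss) in enumerate(zip(cell, is_missing)):
                if miss:
                    continue
                try:
                    float(s)
                except ValueError:
                    raise LoadError(
                        f"{path}: non-numeric cell at feature {raw.index[i]!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
    values = pd.DataFrame(out, index=raw.index.astype(str), columns=raw.columns.astype(str))
    return ExpressionMatrix(values, centered=False)


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median over non-missing entries.

    Idempotent and shift-equivariant; missing entries are preserved. A row
    with no finite entry has no defined median and is rejected.
    """
    arr = m.values.to_numpy(dtype=float)
    n_finite = np.isfinite(arr).sum(axis=1)
    if (n_finite == 0).any():
        feat = m.values.index[np.argmax(n_finite == 0)]
        raise ValueError(f"feature {feat!r} is entirely missing; cannot median-center")
    med = np.nanmedian(arr, axis=1)
    centered = pd.DataFrame(arr - med[:, None], index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(centered, centered=True)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival follow-up and receptor status.

    ``table`` is indexed by sample id with columns ``os_time_months`` (>= 0),
    ``os_event`` (1 = death observed, 0 = censored), and ``er``/``pr``/``her2``
    each in {pos, neg, missing}. ``is_tnbc`` is derived: 1 iff all three
    receptors are negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        required = ["os_time_months", "os_event", "er", "pr", "her2"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise LoadError(f"clinical table missing columns {missing}")
        t = self.table["os_time_months"].to_numpy(dtype=float)
        if (t < 0).any() or np.isnan(t).any():
            raise LoadError("os_time_months must be non-negative and non-missing")
        ev = self.table["os_event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise LoadError("os_event must be binary (0/1)")
        for col in ("er", "pr", "her2"):
            bad = set(self.table[col]) - _RECEPTOR_LEVELS
            if bad:
                raise LoadError(f"{col} has values outside {{pos,neg,missing}}: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> pd.Series:
        return self.table["os_time_months"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.table["os_event"].astype(int)

    @property
    def is_tnbc(self) -> pd.Series:
        t = self.table
        return ((t["er"] == "neg") & (t["pr"] == "neg") & (t["her2"] == "neg")).astype(int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)].copy())

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def load_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, keep_default_na=False)
    df.index = df.index.astype(str)
    df["os_time_months"] = pd.to_numeric(df["os_time_months"])
    df["os_event"] = pd.to_numeric(df["os_event"]).astype(int)
    return ClinicalTable(df)


def load_integer_matrix(
    path: str | Path, allowed: Sequence[int], what: str = "value"
) -> pd.DataFrame:
    """Read a gene-by-sample integer matrix (CNA codes or mutation flags)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    arr = df.to_numpy()
    mask = ~np.isin(arr, list(allowed))
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise LoadError(
            f"{path}: invalid {what} {arr[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return df.astype(int)


@dataclass(frozen=True)
class CohortBundle:
    """Matched expression, clinical, and optional genomic components.

    All components share an identical, identically ordered sample id set.
    """

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    clinical: ClinicalTable
    cna: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    dropped: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.mrna.sample_ids
        for name, ids in [
            ("mirna", self.mirna.sample_ids),
            ("clinical", self.clinical.sample_ids),
        ]:
            if ids != ref:
                raise AssemblyError(f"{name} sample ids not aligned with mrna")
        for name, df in [("cna", self.cna), ("mutations", self.mutations)]:
            if df is not None and list(df.columns) != ref:
                raise AssemblyError(f"{name} sample ids not aligned with mrna")

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortBundle":
        ids = list(sample_ids)
        return CohortBundle(
            mrna=self.mrna.subset_samples(ids),
            mirna=self.mirna.subset_samples(ids),
            clinical=self.clinical.subset_samples(ids),
            cna=None if self.cna is None else self.cna.loc[:, ids],
            mutations=None if self.mutations is None else self.mutations.loc[:, ids],
        )

    def center_expression(self) -> "CohortBundle":
        """Median-center both expression components (per feature)."""
        return replace(self, mrna=median_center(self.mrna), mirna=median_center(self.mirna))


def assemble_cohort(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    clinical: ClinicalTable,
    cna: pd.DataFrame | None = None,
    mutations: pd.DataFrame | None = None,
) -> CohortBundle:
    """Align all components on their shared samples (set intersection).

    Sample order follows the mRNA matrix. The returned bundle records how
    many samples each component lost to the intersection.
    """
    shared = set(mrna.sample_ids) & set(mirna.sample_ids) & set(clinical.sample_ids)
    if cna is not None:
        shared &= set(cna.columns)
    if mutations is not None:
        shared &= set(mutations.columns)
    if not shared:
        raise AssemblyError("empty sample intersection across cohort components")
    order = [s for s in mrna.sample_ids if s in shared]
    dropped = {
        "mrna": len(mrna.sample_ids) - len(order),
        "mirna": len(mirna.sample_ids) - len(order),
        "clinical": len(clinical.sample_ids) - len(order),
    }
    if cna is not None:
        dropped["cna"] = cna.shape[1] - len(order)
    if mutations is not None:
        dropped["mutations"] = mutations.shape[1] - len(order)
    return CohortBundle(
        mrna=mrna.subset_samples(order),
        mirna=mirna.subset_samples(order),
        clinical=clinical.subset_samples(order),
        cna=None if cna is None else cna.loc[:, order],
        mutations=None if mutations is None else mutations.loc[:, order],
        dropped=dropped,
    )
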