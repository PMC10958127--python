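"""Domain containers and flat-file readers/writers.

The pipeline moves four kinds of data around: gene expression matrices
(genes x samples), cell-type labels for sorted reference samples, gene-set
collections (GMT) and per-patient survival tables.  Everything is backed by
pandas; the containers mostly add invariant checking and a declared
expression scale (``linear`` vs ``log2``), because mixing the two silently
is the classic deconvolution mistake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellTypeLabels",
    "GeneSetCollection",
    "SurvivalTable",
    "HEMATO_CELL_TYPES",
    "collapse_duplicate_genes",
    "read_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
]

#: The nine flow-sorted hematopoietic populations of the HemLin9 reference:
#: AML blasts, committed myeloid progenitors (CMP/GMP/MEP), stem and
#: multipotent compartments (HSC/MPP), leukemic populations (LPC/LSC) and
#: the CD45RA+ Lin-CD34+CD38-CD90- population from healthy donors.
HEMATO_CELL_TYPES = (
    "AML_blast", "CMP", "GMP", "HSC", "LPC", "LSC", "MEP", "MPP", "RApos",
)

#: Harmonise compound cytogenetic-risk labels to the three-level scheme.
CYTO_RISK_ALIASES = {
    "FavorableOrIntermediate": "Favorable",
    "IntermediateOrAdverse": "Intermediate",
    "Adverse": "Poor",
    "Favorable": "Favorable",
    "Intermediate": "Intermediate",
    "Poor": "Poor",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id.  Finite numeric.
    scale : {"linear", "log2"}
        The units the values are in.  Downstream operations state which
        scale they require; nothing is sniffed.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.size == 0:
            raise ValueError("expression matrix is empty")
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.columns = self.values.columns.astype(str).str.strip()
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate gene ids {dups[:5]}; collapse with collapse_duplicate_genes first"
            )
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x applied if currently log2)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.power(2.0, self.values), scale="linear")

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale copy, log2(x + pseudocount) if currently linear."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + pseudocount), scale="log2")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)

    def write_tsv(self, path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="gene_id")


@dataclass
class CellTypeLabels:
    """sample_id -> cell_type mapping for sorted reference profiles."""

    mapping: dict[str, str]
    cell_types: tuple[str, ...] = HEMATO_CELL_TYPES

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        unknown = set(self.mapping.values()) - set(self.cell_types)
        if unknown:
            raise ValueError(f"labels use cell types outside the vocabulary: {sorted(unknown)}")

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s, t in self.mapping.items() if t == cell_type]

    def validate_against(self, expr: ExpressionMatrix, min_per_type: int = 2) -> None:
        """Check every labeled sample exists and each type has enough replicates."""
        missing = set(self.mapping) - set(expr.sample_ids)
        if missing:
            raise ValueError(f"labeled samples missing from matrix: {sorted(missing)[:5]}")
        for ct in self.present_types():
            n = len(self.samples_of(ct))
            if n < min_per_type:
                raise ValueError(f"cell type {ct!r} has {n} samples; need >= {min_per_type}")

    def present_types(self) -> list[str]:
        seen = set(self.mapping.values())
        return [t for t in self.cell_types if t in seen]


@dataclass
class GeneSetCollection:
    """Ordered gene sets: name -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (desc, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(genes))  # preserve first-seen order
            self.sets[name] = (desc, deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def write_gmt(self, path) -> None:
        write_gmt(self, path)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event data with optional clinical covariates.

    ``data`` is indexed by sample id and has at least columns ``time``
    (non-negative, unit recorded in ``time_unit``) and ``event``
    (1 = death observed, 0 = censored).  Extra columns (age, sex,
    cytogenetic_risk, external scores, ...) ride along untouched.
    """

    data: pd.DataFrame
    time_unit: str = "days"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("survival table needs 'time' and 'event' columns")
        self.data.index = self.data.index.astype(str)
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy(dtype=float)
        if np.isnan(t).any() or np.isnan(e).any():
            raise ValueError("time/event contain missing values; drop rows before construction")
        if (t < 0).any():
            raise ValueError("negative survival time")
        if not np.isin(e, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = self.data.assign(time=t, event=e.astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)

    def align(self, sample_ids) -> "SurvivalTable":
        """Reindex to ``sample_ids`` (all must be present)."""
        missing = set(map(str, sample_ids)) - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples missing from survival table: {sorted(missing)[:5]}")
        return SurvivalTable(self.data.loc[list(map(str, sample_ids))].copy(),
                             time_unit=self.time_unit, n_dropped=self.n_dropped)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene symbol to their per-sample median.

    Mirrors the usual microarray probe-to-gene reduction: a symbol mapped to
    several probes gets the median expression of those probes, sample by
    sample.  Even row counts use the mean of the two middle values.
    Idempotent on already-unique input.
    """
    if not values.index.duplicated().any():
        return values
    return values.groupby(level=0, sort=False).median()


def read_expression_matrix(path, fmt: str = "tsv", scale: str = "linear") -> ExpressionMatrix:
    """Read a genes-as-rows expression table (first column = gene ids).

    Duplicate gene rows are median-collapsed before the matrix is returned.
    A non-numeric body cell raises a parse error naming its location.
    """
    sep = {"tsv": "\t", "csv": ","}[fmt]
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.size == 0:
        raise ValueError(f"{path}: empty expression matrix")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}")
    numeric.index = numeric.index.astype(str).str.strip()
    return ExpressionMatrix(collapse_duplicate_genes(numeric), scale=scale)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB gene1 TAB ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical_table(
    path,
    sep: str = "\t",
    time_col: str = "time",
    event_col: str = "event",
    time_unit: str = "days",
) -> SurvivalTable:
    """Read a clinical table; drop rows with missing time/event, count them.

    Cytogenetic-risk labels are normalised to {Favorable, Intermediate, Poor}
    ("FavorableOrIntermediate" -> "Favorable", "IntermediateOrAdverse" ->
    "Intermediate", "Adverse" -> "Poor").  Missing covariates are tolerated;
    only time and event are mandatory.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in (time_col, event_col):
        if col not in raw.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    raw = raw.rename(columns={time_col: "time", event_col: "event"})
    n_input = len(raw)
    keep = raw["time"].notna() & raw["event"].notna()
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} rows with missing survival data")
    kept = raw.loc[keep].copy()
    if "cytogenetic_risk" in kept.columns:
        risk = kept["cytogenetic_risk"]
        known = risk.notna() & risk.isin(CYTO_RISK_ALIASES)
        unknown = risk.notna() & ~risk.isin(CYTO_RISK_ALIASES)
        if unknown.any():
            warnings.warn(
                f"{path}: {int(unknown.sum())} unrecognised cytogenetic-risk labels set to missing"
            )
        kept.loc[unknown, "cytogenetic_risk"] = np.nan
        kept.loc[known, "cytogenetic_risk"] = risk[known].map(CYTO_RISK_ALIASES)
    table = SurvivalTable(kept, time_unit=time_unit, n_dropped=dropped)
    assert len(table) + dropped == n_input
    return table
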