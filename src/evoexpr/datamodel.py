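"""Core data types and readers/writers for tabular inputs and outputs.

All external tables are plain TSV. The count matrix convention is
genes-in-rows, samples-in-columns; the design table carries one row per
sample with the four experimental factors (regime, line, sex, tissue).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountDataset",
    "GeneSetMap",
    "HomologyHitTable",
    "ValidationError",
    "ParseError",
    "REGIMES",
    "SEXES",
    "TISSUES",
    "read_counts",
    "write_table",
    "read_gmt",
    "read_homology_hits",
]

REGIMES = ("E", "L")
SEXES = ("F", "M")
TISSUES = ("abdomen", "head_thorax")

_TISSUE_ALIASES = {
    "abdomen": "abdomen",
    "head_thorax": "head_thorax",
    "head-thorax": "head_thorax",
    "headthorax": "head_thorax",
    "soma": "head_thorax",
}


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True)
class SampleInfo:
    regime: str
    line: int
    sex: str
    tissue: str


@dataclass
class CountDataset:
    """An integer count matrix bound to a per-sample factor design.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer counts.
    design : dict mapping sample id -> SampleInfo
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    design: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.design]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        extra = [s for s in self.design if s not in set(self.sample_ids)]
        if extra:
            raise ValidationError(f"design rows without counts: {extra}")
        combos = [
            (i.regime, i.line, i.sex, i.tissue)
            for i in (self.design[s] for s in self.sample_ids)
        ]
        if len(set(combos)) != len(combos):
            raise ValidationError("duplicate (regime, line, sex, tissue) combination")
        for s, info in self.design.items():
            if info.regime not in REGIMES:
                raise ValidationError(f"sample {s!r}: unknown regime {info.regime!r}")
            if info.sex not in SEXES:
                raise ValidationError(f"sample {s!r}: unknown sex {info.sex!r}")
            if info.tissue not in TISSUES:
                raise ValidationError(f"sample {s!r}: unknown tissue {info.tissue!r}")

    # -- conveniences ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def factor(self, name: str) -> np.ndarray:
        """Vector of a design factor in sample order."""
        return np.array([getattr(self.design[s], name) for s in self.sample_ids])

    def subset_genes(self, keep: np.ndarray) -> "CountDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountDataset(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx],
            design=dict(self.design),
        )

    def subset_samples(self, keep: np.ndarray) -> "CountDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        sample_ids = [self.sample_ids[i] for i in idx]
        return CountDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=sample_ids,
            counts=self.counts[:, idx],
            design={s: self.design[s] for s in sample_ids},
        )


@dataclass
class GeneSetMap:
    """Mapping of term ids to member gene sets, with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValidationError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class HomologyHitTable:
    """Rows of a 12-column tabular homology search result."""

    rows: pd.DataFrame

    COLUMNS = (
        "query_id", "subject_id", "percent_identity", "alignment_length",
        "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
        "e_value", "bit_score",
    )

    def __post_init__(self) -> None:
        if list(self.rows.columns) != list(self.COLUMNS):
            raise ValidationError("homology table has wrong columns")
        if len(self.rows) and (self.rows["e_value"] < 0).any():
            raise ValidationError("negative e-value")
        if len(self.rows) and not np.isfinite(self.rows["bit_score"]).all():
            raise ValidationError("non-finite bit score")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _canon_factor(value: str, field_name: str, sample: str) -> str:
    v = value.strip()
    if field_name in ("regime", "sex"):
        v = v.upper()
        allowed = REGIMES if field_name == "regime" else SEXES
        if v not in allowed:
            raise ValidationError(
                f"sample {sample!r}: unknown {field_name} level {value!r}"
            )
        return v
    v = v.lower().replace(" ", "_")
    if v not in _TISSUE_ALIASES:
        raise ValidationError(f"sample {sample!r}: unknown tissue level {value!r}")
    return _TISSUE_ALIASES[v]


def read_counts(path, design_path) -> CountDataset:
    """Read a genes x samples count TSV plus its sample design TSV."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse counts file {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ParseError(f"duplicate gene ids in {path}")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]

    values = df.to_numpy()
    numeric = pd.to_numeric(df.stack(), errors="coerce").unstack()
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    values = numeric.to_numpy()
    frac = np.mod(values, 1)
    if np.any(frac != 0):
        g, s = np.argwhere(frac != 0)[0]
        raise ValidationError(
            f"non-integer count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )

    try:
        ddf = pd.read_csv(design_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse design file {design_path}: {exc}") from exc
    required = {"sample", "regime", "line", "sex", "tissue"}
    if not required.issubset(ddf.columns):
        raise ParseError(
            f"design file missing columns: {sorted(required - set(ddf.columns))}"
        )
    design: dict[str, SampleInfo] = {}
    for _, row in ddf.iterrows():
        s = str(row["sample"])
        try:
            line = int(row["line"])
        except (TypeError, ValueError):
            raise ValidationError(f"sample {s!r}: line {row['line']!r} is not an integer")
        design[s] = SampleInfo(
            regime=_canon_factor(row["regime"], "regime", s),
            line=line,
            sex=_canon_factor(row["sex"], "sex", s),
            tissue=_canon_factor(row["tissue"], "tissue", s),
        )

    missing = sorted(set(sample_ids) - set(design))
    if missing:
        raise ValidationError(f"design missing samples: {missing}")
    extra = sorted(set(design) - set(sample_ids))
    if extra:
        raise ValidationError(f"design has samples absent from counts: {extra}")

    return CountDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=values.astype(np.int64),
        design=design,
    )


def write_table(rows, path) -> None:
    """Write a tabular result to TSV with header and full float precision.

    ``rows`` may be a DataFrame or a dict of equal-length columns. Floats are
    rendered with repr-level precision so a re-read reproduces the values.
    """
    if isinstance(rows, dict):
        lengths = {k: len(v) for k, v in rows.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"columns have mixed lengths: {lengths}")
        rows = pd.DataFrame(rows)
    if not isinstance(rows, pd.DataFrame):
        raise TypeError("rows must be a DataFrame or dict of columns")
    if rows.empty:
        raise ValidationError("refusing to write an empty table")
    rows.to_csv(path, sep="\t", index=False, float_format="%.10g",
                quoting=csv.QUOTE_NONE)


def read_gmt(path) -> GeneSetMap:
    """Read a GMT file: term, description, then member genes (tab-separated)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 fields, got {len(fields)}")
            term, desc, *members = fields
            sets[term] = {m for m in members if m}
            descriptions[term] = desc
    return GeneSetMap(sets=sets, descriptions=descriptions)


def read_homology_hits(path) -> HomologyHitTable:
    """Read a 12-column tab-separated homology hit table (no header)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            records.append(fields)
    df = pd.DataFrame(records, columns=list(HomologyHitTable.COLUMNS))
    if len(df):
        for col in ("percent_identity", "e_value", "bit_score"):
            df[col] = df[col].astype(float)
        for col in ("alignment_length", "mismatches", "gap_opens",
                    "q_start", "q_end", "s_start", "s_end"):
            df[col] = df[col].astype(int)
    else:
        df = df.astype({
            "percent_identity": float, "e_value": float, "bit_score": float,
            "alignment_length": int, "mismatches": int, "gap_opens": int,
            "q_start": int, "q_end": int, "s_start": int, "s_end": int,
        })
    return HomologyHitTable(rows=df)
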