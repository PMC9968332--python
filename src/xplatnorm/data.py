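"""Core data containers and TSV input/output.

Expression data live in :class:`ExpressionMatrix` objects: a genes x samples
float matrix with a platform tag (``"array"`` for continuous log2 intensities,
``"rnaseq"`` for nonnegative counts or FPKM-like values).  A
:class:`MatchedPairSet` holds one matrix per platform over the same patients,
and a :class:`LabelTable` carries per-patient subtype classes and optional
binary mutation status.

File format: UTF-8 tab-separated text, first row ``gene_id`` followed by
sample identifiers, one gene per row.  Missing cells (empty or ``NA``) are
set to zero on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

ARRAY = "array"
RNASEQ = "rnaseq"
PLATFORMS = (ARRAY, RNASEQ)

# values treated as missing in expression TSVs; both platforms use the
# same rule (missing -> 0)
_NA_VALUES = ["", "NA", "NaN", "nan"]


class ParseError(ValueError):
    """Raised when an expression or label TSV is malformed."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a platform tag.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows); must be unique.
    samples
        Ordered sample identifiers (columns); must be unique.
    values
        Float matrix of shape ``(len(genes), len(samples))``.
    platform
        ``"array"`` or ``"rnaseq"``.
    """

    genes: List[str]
    samples: List[str]
    values: np.ndarray
    platform: str

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        self.samples = list(map(str, self.samples))
        self.values = np.asarray(self.values, dtype=float)
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise ParseError(f"duplicate gene identifier {dup!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise ParseError(f"duplicate sample identifier {dup!r}")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains NaN after ingestion")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same genes/samples/platform, new values (used by normalizers)."""
        return ExpressionMatrix(list(self.genes), list(self.samples),
                                np.asarray(values, dtype=float), self.platform)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.genes), list(sample_ids),
                                self.values[:, cols], self.platform)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene identifiers: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.samples),
                                self.values[rows, :], self.platform)


def _first_duplicate(items: Iterable[str]) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class MatchedPairSet:
    """Array and RNA-seq matrices over the same patients.

    Both matrices share an identical gene list; every patient has exactly
    one sample on each platform, recorded in ``mapping`` as
    ``patient -> (array_sample_id, rnaseq_sample_id)``.
    """

    array_matrix: ExpressionMatrix
    rnaseq_matrix: ExpressionMatrix
    patient_ids: List[str]
    mapping: Dict[str, tuple]

    def __post_init__(self) -> None:
        if self.array_matrix.genes != self.rnaseq_matrix.genes:
            raise ValueError("matched matrices must share an identical gene list")
        arr_samples = set(self.array_matrix.samples)
        seq_samples = set(self.rnaseq_matrix.samples)
        for p in self.patient_ids:
            if p not in self.mapping:
                raise ValueError(f"patient {p!r} has no platform mapping")
            a, s = self.mapping[p]
            if a not in arr_samples:
                raise ValueError(f"array sample {a!r} for patient {p!r} missing")
            if s not in seq_samples:
                raise ValueError(f"rnaseq sample {s!r} for patient {p!r} missing")

    @property
    def genes(self) -> List[str]:
        return self.array_matrix.genes

    def array_samples_for(self, patients: Sequence[str]) -> List[str]:
        return [self.mapping[p][0] for p in patients]

    def rnaseq_samples_for(self, patients: Sequence[str]) -> List[str]:
        return [self.mapping[p][1] for p in patients]


@dataclass
class LabelTable:
    """Per-patient subtype and optional binary mutation labels.

    ``mutation`` maps a gene-of-interest name to a ``patient -> {0,1}``
    dict; patients absent from a mutation dict are excluded from that
    mutation task (mirroring cohorts with incomplete mutation calls).
    """

    patient_ids: List[str]
    subtype: Dict[str, str]
    mutation: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in self.patient_ids if p not in self.subtype]
        if missing:
            raise ValueError(f"patients without subtype label: {missing[:5]}")

    def subtypes_of(self, patients: Sequence[str]) -> np.ndarray:
        return np.asarray([self.subtype[p] for p in patients])


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

def read_expression_matrix(path, platform: str) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row is ``gene_id`` plus sample identifiers; one gene per row.
    Missing cells (empty or NA) are set to zero.  Duplicate gene or sample
    identifiers and non-numeric cells raise :class:`ParseError` naming the
    offending row/column.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found in header")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    raw = df.to_numpy(dtype=str)
    stripped = np.char.strip(raw)
    missing = np.isin(stripped, _NA_VALUES)
    parsed = pd.to_numeric(pd.Series(stripped[~missing].ravel()),
                           errors="coerce").to_numpy()
    values = np.zeros(raw.shape, dtype=float)
    values[~missing] = parsed
    if np.isnan(parsed).any():
        i, j = next(zip(*np.nonzero(~missing & np.isnan(values))))
        raise ParseError(
            f"{path}: non-numeric value {stripped[i, j]!r} at gene "
            f"{genes[i]!r}, sample {samples[j]!r}")
    return ExpressionMatrix(genes, samples, values, platform)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; round-trip stable to >= 10 significant digits."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("refusing to write an empty expression matrix")
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_label_table(path) -> LabelTable:
    """Read a label TSV with columns ``patient_id``, ``subtype`` and any
    number of ``mutation_<gene>`` columns (binary, blank = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "subtype"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    patients = [str(p) for p in df["patient_id"]]
    if len(set(patients)) != len(patients):
        raise ParseError(f"{path}: duplicate patient_id")
    subtype = dict(zip(patients, df["subtype"].astype(str)))
    mutation: Dict[str, Dict[str, int]] = {}
    for col in df.columns:
        if not col.startswith("mutation_"):
            continue
        gene = col[len("mutation_"):]
        calls: Dict[str, int] = {}
        for p, v in zip(patients, df[col]):
            v = v.strip()
            if v in ("", "NA"):
                continue
            if v not in ("0", "1"):
                raise ParseError(f"{path}: mutation value {v!r} for {p!r} "
                                 "must be 0 or 1")
            calls[p] = int(v)
        mutation[gene] = calls
    return LabelTable(patients, subtype, mutation)


def write_label_table(labels: LabelTable, path) -> None:
    cols = {"patient_id": labels.patient_ids,
            "subtype": [labels.subtype[p] for p in labels.patient_ids]}
    for gene, calls in labels.mutation.items():
        cols[f"mutation_{gene}"] = [
            str(calls[p]) if p in calls else "" for p in labels.patient_ids
        ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-platform gene filtering
# ---------------------------------------------------------------------------

def intersect_genes(array: ExpressionMatrix, rnaseq: ExpressionMatrix,
                    mapping: Dict[str, tuple],
                    patient_ids: Optional[Sequence[str]] = None,
                    ) -> MatchedPairSet:
    """Restrict both platforms to genes measured on both.

    The shared gene list is sorted lexicographically so output order is
    deterministic regardless of input order.  An empty intersection is an
    error.
    """
    shared = sorted(set(array.genes) & set(rnaseq.genes))
    if not shared:
        raise ValueError("no genes measured on both platforms")
    if patient_ids is None:
        patient_ids = sorted(mapping)
    return MatchedPairSet(array.subset_genes(shared),
                          rnaseq.subset_genes(shared),
                          list(patient_ids), dict(mapping))


def filter_degenerate_genes(pair: MatchedPairSet,
                            rnaseq_subsets: Sequence[Iterable[str]],
                            ) -> MatchedPairSet:
    """Drop genes whose RNA-seq values are constant within any given subset.

    The subsets are the sample groups that will be normalized together
    (holdout samples, plus the RNA-seq titration portion at every level):
    a gene that is all-equal inside any one of them carries no rank
    information there and would break rank-based normalizers.  Removal is
    applied to both platforms so the gene lists stay aligned.
    """
    seq = pair.rnaseq_matrix
    col_index = {s: j for j, s in enumerate(seq.samples)}
    keep = np.ones(seq.n_genes, dtype=bool)
    for subset in rnaseq_subsets:
        ids = list(subset)
        if len(ids) < 2:
            # a 0- or 1-sample group carries no variability information
            continue
        unknown = [s for s in ids if s not in col_index]
        if unknown:
            raise KeyError(f"subset contains non-RNA-seq samples: {unknown[:5]}")
        block = seq.values[:, [col_index[s] for s in ids]]
        constant = np.all(block == block[:, :1], axis=1)
        keep &= ~constant
    genes = [g for g, k in zip(seq.genes, keep) if k]
    return MatchedPairSet(pair.array_matrix.subset_genes(genes),
                          pair.rnaseq_matrix.subset_genes(genes),
                          list(pair.patient_ids), dict(pair.mapping))
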