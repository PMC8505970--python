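"""Data containers and tab-separated readers/writers shared by all pipeline stages.

The canonical in-memory layout for expression data is genes x samples, values on
the log2 scale (the upstream microarray normalisation that produces log2
intensities is assumed, not performed here). All readers validate their input
and raise :class:`FormatError` rather than silently repairing it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "Phenotype",
    "GeneWeightTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_series_matrix",
    "read_weights",
    "write_weights",
    "load_published_weights",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

VALID_DIRECTIONS = ("up", "down")


class FormatError(ValueError):
    """Raised when an input file or table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    if len(ids) == 0:
        raise FormatError(f"{what} list is empty")
    seen: dict = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = True
    if dups:
        raise FormatError(f"duplicate {what}(s): {sorted(set(map(str, dups)))}")


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Invariants: unique non-empty gene and sample ids, finite values, dimensions
    matching the id lists. ``metadata`` carries processing notices (e.g. batch
    confounding warnings) and never affects the numbers.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            metadata=metadata or {},
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; missing genes are an error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows, :])


@dataclass
class Phenotype:
    """Per-sample response label and batch (source dataset) assignment."""

    sample_ids: list[str]
    response: list[str]  # RESPONDER / NON_RESPONDER
    batch: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.response = [str(r) for r in self.response]
        self.batch = [str(b) for b in self.batch]
        _check_unique(self.sample_ids, "sample id")
        if not (len(self.sample_ids) == len(self.response) == len(self.batch)):
            raise FormatError("phenotype columns have unequal lengths")
        bad = sorted({r for r in self.response if r not in (RESPONDER, NON_RESPONDER)})
        if bad:
            raise FormatError(
                f"unknown response label(s) {bad}; expected "
                f"{RESPONDER!r} or {NON_RESPONDER!r}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, sample_ids: list[str]) -> "Phenotype":
        """Reorder rows to match ``sample_ids``; every sample must have exactly one row."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise FormatError(f"samples without a phenotype row: {missing}")
        rows = [index[s] for s in sample_ids]
        return Phenotype(
            [self.sample_ids[i] for i in rows],
            [self.response[i] for i in rows],
            [self.batch[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "response": self.response, "batch": self.batch}
        )


@dataclass
class GeneWeightTable:
    """Signature gene -> scalar weight with direction relative to responders.

    ``direction`` is "up" for genes expressed higher in responders and "down"
    for genes higher in non-responders, matching the fold-change orientation
    used throughout the package.
    """

    gene_ids: list[str]
    weights: np.ndarray
    directions: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        self.directions = [str(d) for d in self.directions]
        _check_unique(self.gene_ids, "gene id")
        if not (len(self.gene_ids) == len(self.weights) == len(self.directions)):
            raise FormatError("weight table columns have unequal lengths")
        if not np.all(np.isfinite(self.weights)):
            raise FormatError("non-finite weight")
        bad = sorted({d for d in self.directions if d not in VALID_DIRECTIONS})
        if bad:
            raise FormatError(f"unknown direction(s) {bad}; expected 'up' or 'down'")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def weight_of(self, gene: str) -> float:
        try:
            return float(self.weights[self.gene_ids.index(gene)])
        except ValueError:
            raise KeyError(f"no weight for gene {gene!r}") from None

    def direction_of(self, gene: str) -> str:
        try:
            return self.directions[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"no direction for gene {gene!r}") from None


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    ``orientation`` is "genes-in-rows" (first column = gene ids, header =
    sample ids) or "samples-in-rows" (transposed). Duplicate gene ids are
    rejected: collapsing probe-level duplicates is an explicit, separate step.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise FormatError(f"{path}: empty table or missing header row")
    probe = frame.apply(pd.to_numeric, errors="coerce")
    if probe.isna().any().any():
        r, c = next(zip(*np.where(probe.isna().to_numpy())))
        raise FormatError(
            f"{path}: non-numeric cell at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    # numpy's parser is correctly rounded; pd.to_numeric can be off by one ulp
    numeric = frame.astype(float)
    if orientation == "samples-in-rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression_tsv(matrix: ExpressionMatrix, path, comment: str | None = None) -> None:
    """Write genes-in-rows TSV; ``comment`` becomes a leading '#' header line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# phenotype TSV


def read_phenotype_tsv(path) -> Phenotype:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "response", "batch"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: phenotype table needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    return Phenotype(
        list(frame["sample_id"]), list(frame["response"]), list(frame["batch"])
    )


def write_phenotype_tsv(pheno: Phenotype, path, comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pheno.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GEO series-matrix dialect (miniature convenience reader)

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(path) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Parse the text "series matrix" dialect used by GEO exports.

    Returns the expression table (genes x samples) and a mapping of
    ``!Sample_*`` annotation keys to their per-sample values. Only the plain
    tab-separated table block between the begin/end markers is understood.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    annotations: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    for line in lines:
        stripped = line.strip()
        if stripped == _TABLE_BEGIN:
            in_table, saw_begin = True, True
            continue
        if stripped == _TABLE_END:
            in_table, saw_end = False, True
            continue
        if in_table:
            if stripped:
                table_lines.append(line)
        elif stripped.startswith("!Sample_"):
            key, *vals = stripped.split("\t")
            annotations[key.lstrip("!")] = [v.strip('"') for v in vals]
    if not saw_begin or not saw_end:
        raise FormatError(
            f"{path}: missing {_TABLE_BEGIN!r}/{_TABLE_END!r} table delimiters"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table block")
    header = [h.strip('"') for h in table_lines[0].split("\t")][1:]
    gene_ids, rows = [], []
    for line in table_lines[1:]:
        cells = line.split("\t")
        gene_ids.append(cells[0].strip('"'))
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {cells[0]!r}") from exc
    return ExpressionMatrix(gene_ids, header, np.array(rows)), annotations


# ---------------------------------------------------------------------------
# gene-weight TSV


def read_weights(path) -> GeneWeightTable:
    """Read a ``gene<TAB>weight[<TAB>direction]`` table.

    When the direction column is absent all genes are taken as "down"
    (the majority orientation of the published signature).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.shape[0] == 0 or frame.shape[1] < 2:
        raise FormatError(f"{path}: weight table needs >=1 row and >=2 columns")
    cols = list(frame.columns)
    gene_col, weight_col = cols[0], cols[1]
    probe = pd.to_numeric(frame[weight_col], errors="coerce")
    if probe.isna().any():
        bad = frame.loc[probe.isna(), gene_col].iloc[0]
        raise FormatError(f"{path}: non-numeric weight for gene {bad!r}")
    weights = frame[weight_col].to_numpy(dtype=str).astype(float)
    if "direction" in frame.columns:
        directions = list(frame["direction"])
    elif len(cols) >= 3:
        directions = list(frame[cols[2]])
    else:
        directions = ["down"] * len(frame)
    return GeneWeightTable(list(frame[gene_col]), weights, directions)


def write_weights(table: GeneWeightTable, path, comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pd.DataFrame(
            {"gene": table.gene_ids, "weight": table.weights, "direction": table.directions}
        ).to_csv(fh, sep="\t", index=False)


def load_published_weights() -> GeneWeightTable:
    """Load the packaged 30-gene training Gene Weight table.

    These are the published weights of the infliximab-response signature:
    28 genes expressed lower in responders ("down") and 2 higher (C10orf99,
    ADH1C, "up"). Used for worked examples and for scoring cohorts without
    retraining.
    """
    resource = importlib.resources.files("ifxmps.data") / "published_gene_weights.tsv"
    with importlib.resources.as_file(resource) as path:
        table = read_weights(path)
    if len(table) != 30:
        raise FormatError("packaged weight table must have exactly 30 entries")
    return table
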