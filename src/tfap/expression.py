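"""Expression-matrix container and text I/O.

The pipeline operates on a genes x samples matrix of log-scale, already
normalised expression values together with per-sample metadata naming the
perturbing drug, the cell line and the replicate number.  Control (vehicle)
samples carry the reserved drug id :data:`CONTROL`.

Two text dialects are supported: a plain tab-delimited table with a header
row of sample ids, and GCT 1.2 (leading ``#1.2`` line, dimension line, and a
``Description`` column that is ignored on input).  Sample metadata always
travels in a separate tab-delimited table with columns
``sample_id``, ``drug_id``, ``cell_line``, ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Reserved drug id marking vehicle/control samples.
CONTROL = "CONTROL"

META_COLUMNS = ("drug_id", "cell_line", "replicate")


class ParseError(ValueError):
    """Malformed input table; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Structurally valid input that violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values (genes x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``drug_id``,
        ``cell_line`` and ``replicate``; must cover exactly the samples of
        ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns {missing}")
        vs, ms = set(self.values.columns), set(self.sample_meta.index)
        if vs != ms:
            diff = sorted(vs.symmetric_difference(ms))
            raise ValidationError(
                f"sample ids differ between matrix and metadata: {diff}"
            )
        # keep metadata in matrix column order
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.sample_meta["cell_line"].unique())

    def drugs(self, cell_line: str | None = None) -> list[str]:
        """Non-control drug ids, optionally restricted to one cell line."""
        meta = self.sample_meta
        if cell_line is not None:
            meta = meta[meta["cell_line"] == cell_line]
        out = meta.loc[meta["drug_id"] != CONTROL, "drug_id"].unique()
        return sorted(out)

    def samples_for(self, drug_id: str, cell_line: str) -> list[str]:
        meta = self.sample_meta
        mask = (meta["drug_id"] == drug_id) & (meta["cell_line"] == cell_line)
        return list(meta.index[mask])


# -- reading -------------------------------------------------------------------


def _read_matrix_lines(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty expression table", 1)
    offset = 0
    expected_shape: tuple[int, int] | None = None
    gct = lines[0].strip().startswith("#1.2")
    if gct:
        if len(lines) < 3:
            raise ParseError("truncated GCT file", len(lines))
        dims = lines[1].split("\t")
        try:
            expected_shape = (int(dims[0]), int(dims[1]))
        except (ValueError, IndexError):
            raise ParseError("bad GCT dimension line", 2) from None
        offset = 2
    header = lines[offset].rstrip("\n").split("\t")
    # GCT: NAME, Description, <samples>; plain: gene id column + samples
    n_id_cols = 2 if gct else 1
    sample_ids = header[n_id_cols:]
    if not sample_ids:
        raise ParseError("no sample columns in header", offset + 1)
    ncol = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[offset + 1 :], start=offset + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"expected {ncol} fields, found {len(fields)}", i
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(x) for x in fields[n_id_cols:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell ({exc})", i) from None
    df = pd.DataFrame(
        rows,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
        dtype=float,
    )
    if expected_shape is not None and df.shape != expected_shape:
        raise ParseError(
            f"GCT dimensions {expected_shape} do not match body {df.shape}", 2
        )
    return df


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # ragged/unreadable
        raise ParseError(f"cannot parse metadata table: {exc}") from exc
    required = ("sample_id",) + META_COLUMNS
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata lacks columns {missing}", 1)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r} in metadata")
    return meta.set_index("sample_id")


def read_expression_table(
    expr_path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    """Read a TSV or GCT 1.2 expression table plus its metadata table."""
    values = _read_matrix_lines(Path(expr_path))
    meta = read_sample_metadata(meta_path)
    missing = sorted(set(values.columns) - set(meta.index))
    if missing:
        raise ParseError(f"metadata missing sample ids {missing}")
    extra = sorted(set(meta.index) - set(values.columns))
    if extra:
        raise ParseError(f"metadata names unknown sample ids {extra}")
    return ExpressionMatrix(values=values, sample_meta=meta)


# -- writing -------------------------------------------------------------------


def write_expression_table(
    expr: ExpressionMatrix,
    expr_path: str | Path,
    meta_path: str | Path,
    gct: bool = False,
) -> None:
    """Write the matrix (TSV or GCT 1.2) and the metadata table."""
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    if gct:
        with open(expr_path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{len(expr.sample_ids)}\n")
            fh.write("NAME\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
            for gene, row in expr.values.iterrows():
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{gene}\tna\t{vals}\n")
    else:
        with open(expr_path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
            for gene, row in expr.values.iterrows():
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{gene}\t{vals}\n")
    meta = expr.sample_meta.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(meta_path, sep="\t", index=False)
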