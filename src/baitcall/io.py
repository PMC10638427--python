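"""Protein-list input/output.

The unit of identification is the protein group as reported by the
upstream search engine (MaxQuant-style): one row per protein group with
an accession ID, gene name, description, contaminant/decoy flags, and
one raw summed-intensity column per LC-MS/MS run. A raw intensity of 0
(or an empty cell) means the protein was not detected in that run.

Accessions are treated as opaque keys; multi-accession groups are not
split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

PROTEIN_COLUMNS = ("gene", "description", "contaminant", "reverse")

# Header synonyms accepted on input; first match wins.
_ACCESSION_HEADERS = ("Protein IDs", "Majority protein IDs", "accession", "Accession")
_GENE_HEADERS = ("Gene names", "gene", "Gene")
_DESCRIPTION_HEADERS = ("Protein names", "description", "Description")
_CONTAMINANT_HEADERS = ("Potential contaminant", "Contaminant", "contaminant")
_REVERSE_HEADERS = ("Reverse", "reverse")
_INTENSITY_PREFIX = "Intensity "


@dataclass
class IntensityTable:
    """Protein groups x runs matrix of raw intensities plus metadata.

    Attributes
    ----------
    proteins:
        DataFrame indexed by accession with columns ``gene``,
        ``description``, ``contaminant`` (bool), ``reverse`` (bool).
    intensities:
        DataFrame with the same index, one float column per run code.
        All values are >= 0; 0 encodes "not detected".
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.intensities.index):
            raise DataError("protein metadata and intensity rows do not align")
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].unique()
            raise DataError(f"duplicate accession(s): {list(dupes)[:5]}")
        self.intensities = self.intensities.astype(float)
        vals = self.intensities.to_numpy()
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise DataError("intensities must be nonnegative finite numbers")
        for col in PROTEIN_COLUMNS:
            if col not in self.proteins.columns:
                raise DataError(f"protein metadata missing column {col!r}")

    # -- convenience --------------------------------------------------------

    @property
    def accessions(self) -> pd.Index:
        return self.proteins.index

    @property
    def run_codes(self) -> tuple[str, ...]:
        return tuple(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def column(self, run_code: str) -> pd.Series:
        if run_code not in self.intensities.columns:
            raise DataError(f"run {run_code!r} not present in intensity table")
        return self.intensities[run_code]

    def equals(self, other: "IntensityTable") -> bool:
        return self.proteins.equals(other.proteins) and self.intensities.equals(
            other.intensities
        )

    def subset_runs(self, run_codes) -> "IntensityTable":
        missing = [r for r in run_codes if r not in self.intensities.columns]
        if missing:
            raise DataError(f"run(s) not in table: {missing}")
        return IntensityTable(self.proteins.copy(), self.intensities[list(run_codes)].copy())


def make_table(
    accessions,
    run_codes,
    values,
    genes=None,
    descriptions=None,
    contaminant=None,
    reverse=None,
) -> IntensityTable:
    """Assemble an IntensityTable from plain arrays (mostly for tests and
    the simulator)."""
    accessions = list(accessions)
    n = len(accessions)
    proteins = pd.DataFrame(
        {
            "gene": list(genes) if genes is not None else [""] * n,
            "description": list(descriptions) if descriptions is not None else [""] * n,
            "contaminant": list(contaminant) if contaminant is not None else [False] * n,
            "reverse": list(reverse) if reverse is not None else [False] * n,
        },
        index=pd.Index(accessions, name="accession"),
    )
    intensities = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=proteins.index,
        columns=list(run_codes),
    )
    return IntensityTable(proteins, intensities)


def _find_header(columns, candidates) -> str | None:
    for c in candidates:
        if c in columns:
            return c
    return None


def _frame_to_table(df: pd.DataFrame, run_codes=None) -> IntensityTable:
    acc_col = _find_header(df.columns, _ACCESSION_HEADERS)
    if acc_col is None:
        raise FormatError(
            f"no accession column found (looked for {_ACCESSION_HEADERS})"
        )
    accessions = df[acc_col].astype(str)
    if accessions.duplicated().any():
        dupes = accessions[accessions.duplicated()].unique()
        raise DataError(f"duplicate accession(s): {list(dupes)[:5]}")

    gene_col = _find_header(df.columns, _GENE_HEADERS)
    desc_col = _find_header(df.columns, _DESCRIPTION_HEADERS)
    cont_col = _find_header(df.columns, _CONTAMINANT_HEADERS)
    rev_col = _find_header(df.columns, _REVERSE_HEADERS)

    def flag(col):
        if col is None:
            return [False] * len(df)
        return df[col].fillna("").astype(str).str.strip().isin(["+", "True", "true", "1"]).tolist()

    meta_cols = {c for c in (acc_col, gene_col, desc_col, cont_col, rev_col) if c}
    # Intensity columns: "Intensity <run>" headers, bare headers matching the
    # declared run codes, or (fallback) every non-metadata column.
    intensity_map: dict[str, str] = {}
    for c in df.columns:
        if isinstance(c, str) and c.startswith(_INTENSITY_PREFIX):
            intensity_map[c] = c[len(_INTENSITY_PREFIX):]
    if run_codes is not None:
        for c in df.columns:
            if c in meta_cols or c in intensity_map:
                continue
            if str(c) in set(run_codes):
                intensity_map[c] = str(c)
    if not intensity_map:
        for c in df.columns:
            if c not in meta_cols:
                intensity_map[c] = str(c)
    if not intensity_map:
        raise FormatError("no intensity columns found")

    def to_float(x):
        # empty cell = not detected; float(str) is correctly rounded, so the
        # write/read round trip is value-exact
        if pd.isna(x) or (isinstance(x, str) and not x.strip()):
            return 0.0
        try:
            return float(x)
        except ValueError as exc:
            raise FormatError(f"non-numeric intensity cell {x!r}") from exc

    values = df[list(intensity_map)].map(to_float)
    if (values.to_numpy() < 0).any():
        raise DataError("negative intensity value in protein list")
    values.columns = [intensity_map[c] for c in values.columns]

    return make_table(
        accessions,
        values.columns,
        values.to_numpy(),
        genes=df[gene_col].fillna("").astype(str) if gene_col else None,
        descriptions=df[desc_col].fillna("").astype(str) if desc_col else None,
        contaminant=flag(cont_col),
        reverse=flag(rev_col),
    )


def read_protein_list(path: str | Path, dialect: str = "tsv", run_codes=None) -> IntensityTable:
    """Read a protein list into an :class:`IntensityTable`.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` for a tab-separated table (one header row), or
        ``"xlsx"`` for a spreadsheet. A spreadsheet may hold everything in
        one sheet, or one sheet per sample; sheets are outer-joined on
        accession and missing cells become 0 (not detected).
    run_codes:
        Optional iterable of run codes used to recognise bare intensity
        column headers (in addition to the ``"Intensity <run>"``
        convention).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=object)
        return _frame_to_table(df, run_codes=run_codes)
    if dialect == "xlsx":
        sheets = pd.read_excel(path, sheet_name=None, dtype=object)
        frames = list(sheets.values())
        if len(frames) == 1:
            return _frame_to_table(frames[0], run_codes=run_codes)
        tables = [_frame_to_table(f, run_codes=run_codes) for f in frames]
        return merge_tables(tables)
    raise FormatError(f"unknown dialect {dialect!r} (expected 'tsv' or 'xlsx')")


def merge_tables(tables) -> IntensityTable:
    """Outer-join tables on accession; absent cells become 0."""
    if not tables:
        raise DataError("no tables to merge")
    proteins = tables[0].proteins
    for t in tables[1:]:
        extra = t.proteins.loc[~t.proteins.index.isin(proteins.index)]
        proteins = pd.concat([proteins, extra])
    mats = [
        t.intensities.reindex(proteins.index).fillna(0.0) for t in tables
    ]
    intensities = pd.concat(mats, axis=1)
    if intensities.columns.has_duplicates:
        raise DataError("duplicate run columns across sheets")
    return IntensityTable(proteins, intensities)


def write_maxquant_like(table: IntensityTable, path: str | Path) -> Path:
    """Write the tab-separated dialect accepted by :func:`read_protein_list`.

    Columns: ``Protein IDs``, ``Gene names``, ``Protein names``,
    ``Reverse``, ``Potential contaminant`` (flags as ``+``), then one
    ``Intensity <run>`` column per run. Zeros are written explicitly; the
    round trip is value-exact for double-precision inputs.
    """
    path = Path(path)
    out = pd.DataFrame(
        {
            "Protein IDs": table.accessions,
            "Gene names": table.proteins["gene"].to_numpy(),
            "Protein names": table.proteins["description"].to_numpy(),
            "Reverse": ["+" if f else "" for f in table.proteins["reverse"]],
            "Potential contaminant": [
                "+" if f else "" for f in table.proteins["contaminant"]
            ],
        }
    )
    for run in table.run_codes:
        out[_INTENSITY_PREFIX + run] = table.intensities[run].to_numpy()
    out.to_csv(path, sep="\t", index=False)
    return path


def filter_flagged(table: IntensityTable) -> IntensityTable:
    """Drop rows flagged as contaminant or decoy (reverse) hits.

    Remaining rows are unchanged and keep their original order; the
    operation is idempotent.
    """
    keep = ~(table.proteins["contaminant"] | table.proteins["reverse"])
    return IntensityTable(
        table.proteins.loc[keep].copy(), table.intensities.loc[keep].copy()
    )
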