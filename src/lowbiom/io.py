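"""Readers and writers for the package's plain-text formats.

All formats are tab-separated text:

* OTU table — classic QIIME-style layout, header
  ``#OTU ID<TAB>sample1<TAB>...[<TAB>taxonomy]``, one OTU per row.  The
  optional trailing ``taxonomy`` column holds a rank-prefixed lineage
  string (``k__Bacteria; ...; g__Burkholderia``; separator configurable).
* Sample metadata — columns ``sample_id``, ``density``,
  ``replicate_group`` (required) and ``community_id``, ``treatment``,
  ``is_control`` (optional).
* Expected composition — columns ``community_id``, ``taxon``, ``fraction``.
* Taxonomy — columns ``otu_id``, ``taxonomy``.

Writing then reading an :class:`~lowbiom.datamodel.OtuTable` is the
identity on ids and counts.
"""
from __future__ import annotations

import os
from collections import defaultdict

import pandas as pd

from .datamodel import ExpectedComposition, OtuTable, SampleMetadata, TaxonomyMap
from .exceptions import FormatError, ValidationError

OTU_ID_HEADER = "#OTU ID"
TAXONOMY_COLUMN = "taxonomy"


def read_otu_table(
    path: str | os.PathLike, lineage_sep: str = ";"
) -> tuple[OtuTable, TaxonomyMap | None]:
    """Read a TSV OTU table; returns the table and, if present, its taxonomy.

    The first column holds OTU identifiers; remaining columns are per-sample
    read counts, except an optional trailing column named ``taxonomy``.
    """
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected an OTU id column plus >= 1 sample column")
    id_col = frame.columns[0]
    if id_col not in (OTU_ID_HEADER, "OTU ID", "otu_id"):
        raise FormatError(
            f"{path}: first header field is {id_col!r}, expected {OTU_ID_HEADER!r}"
        )
    if frame.shape[0] == 0:
        raise ValidationError(f"{path}: no OTUs")
    frame = frame.set_index(id_col)

    taxonomy = None
    if frame.columns[-1] == TAXONOMY_COLUMN:
        tax_strings = frame[TAXONOMY_COLUMN].fillna("")
        frame = frame.drop(columns=[TAXONOMY_COLUMN])
        taxonomy = TaxonomyMap.from_strings(
            {otu: s for otu, s in tax_strings.items() if s}, sep=lineage_sep
        )
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    try:
        counts = frame.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric count cell ({exc})") from exc
    return OtuTable(counts), taxonomy


def write_otu_table(
    table: OtuTable,
    path: str | os.PathLike,
    taxonomy: TaxonomyMap | None = None,
    drop_empty: bool = False,
) -> None:
    """Write an OTU table (optionally with a trailing taxonomy column)."""
    if drop_empty:
        table = table.drop_empty_otus()
    out = table.counts.copy()
    out.index.name = OTU_ID_HEADER
    if taxonomy is not None:
        out[TAXONOMY_COLUMN] = [
            str(taxonomy[otu]) if otu in taxonomy else "" for otu in out.index
        ]
    out.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    """Read per-sample metadata from TSV."""
    try:
        frame = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    for col in SampleMetadata.REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    meta.frame.to_csv(path, sep="\t")


def read_taxonomy(path: str | os.PathLike, lineage_sep: str = ";") -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("otu_id", TAXONOMY_COLUMN):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    strings = dict(zip(frame["otu_id"], frame[TAXONOMY_COLUMN].fillna("")))
    return TaxonomyMap.from_strings({k: v for k, v in strings.items() if v},
                                    sep=lineage_sep)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | os.PathLike) -> None:
    rows = [(otu, str(lin)) for otu, lin in taxonomy.items()]
    pd.DataFrame(rows, columns=["otu_id", TAXONOMY_COLUMN]).to_csv(
        path, sep="\t", index=False
    )


def read_expected(path: str | os.PathLike) -> dict[str, ExpectedComposition]:
    """Read expected mock compositions; returns community_id -> composition."""
    frame = pd.read_csv(path, sep="\t", header=0)
    for col in ("community_id", "taxon", "fraction"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    per_community: dict[str, dict[str, float]] = defaultdict(dict)
    for _, row in frame.iterrows():
        per_community[str(row["community_id"])][str(row["taxon"])] = float(
            row["fraction"]
        )
    return {
        cid: ExpectedComposition(cid, fractions)
        for cid, fractions in per_community.items()
    }


def write_expected(
    expected: dict[str, ExpectedComposition], path: str | os.PathLike
) -> None:
    rows = [
        (cid, taxon, frac)
        for cid, comp in expected.items()
        for taxon, frac in comp.fractions.items()
    ]
    pd.DataFrame(rows, columns=["community_id", "taxon", "fraction"]).to_csv(
        path, sep="\t", index=False
    )
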