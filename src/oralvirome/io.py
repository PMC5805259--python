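"""Readers and writers for the tabular formats the pipeline touches.

All text I/O is UTF-8 and tab-delimited; lines starting with ``#`` are
comments (the first ``#`` line of a metadata file may be its header, as in
QIIME mapping files). Alignment hits arrive in the 12-column BLAST tabular
dialect (outfmt 6), optionally extended with a 13th ``qlen`` column; when the
column is absent, read lengths come from a separate two-column TSV.

Taxon tables are written either as plain TSV (taxa × samples, lineage-string
row labels) or as BIOM 1.0 JSON with ``matrix_type: "sparse"``.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .constants import DB_LABELS, SEX_LEVELS, UNDETERMINED
from .errors import ConfigurationError, HitTableParseError, ValidationError
from .tables import TaxonTable
from .taxonomy import TaxonNode, TaxonomyTree

PathLike = Union[str, Path]

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org"


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One read-vs-reference alignment record.

    ``alignment_length / query_length`` is the read-coverage fraction used by
    the hit filter; alignment_length may exceed query_length when the
    alignment is gapped.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_length: Optional[int]
    db_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValidationError("alignment_length must be ≥ 1")
        if self.e_value < 0:
            raise ValidationError("e_value must be non-negative")
        if self.query_length is not None and self.query_length < 1:
            raise ValidationError("query_length must be ≥ 1")
        if self.db_label not in DB_LABELS:
            raise ValidationError(f"db_label must be one of {DB_LABELS}")

    @property
    def coverage(self) -> float:
        """Fraction of the read covered by the alignment."""
        if self.query_length is None:
            raise ConfigurationError(
                f"query {self.query_id!r} has no query_length; supply a qlen "
                "column or a read-length table"
            )
        return self.alignment_length / self.query_length


def read_read_lengths(path: PathLike) -> dict[str, int]:
    """Read a two-column ``query_id<TAB>length`` TSV."""
    lengths: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitTableParseError(
                    f"{path}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path}:{lineno}: non-integer read length {fields[1]!r}"
                ) from exc
    return lengths


def read_hit_table(
    path: PathLike,
    db_label: str,
    read_lengths: Optional[Mapping[str, int]] = None,
) -> list[AlignmentHit]:
    """Parse a BLAST tabular (outfmt 6) hit table, preserving row order.

    Each data row must have 12 tab-separated columns, or 13 when the last
    column carries the query length. Without a qlen column, every query id
    must appear in ``read_lengths``; a query with no known length is a
    configuration error because the coverage filter cannot be applied.
    """
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise HitTableParseError(
                    f"{path}:{lineno}: expected 12 or 13 columns, "
                    f"found {len(fields)}"
                )
            try:
                identity = float(fields[2])
                length = int(fields[3])
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path}:{lineno}: non-numeric field: {exc}"
                ) from exc
            query_id = fields[0]
            if len(fields) == 13:
                try:
                    query_length: Optional[int] = int(fields[12])
                except ValueError as exc:
                    raise HitTableParseError(
                        f"{path}:{lineno}: non-integer qlen {fields[12]!r}"
                    ) from exc
            elif read_lengths is not None:
                query_length = read_lengths.get(query_id)
                if query_length is None:
                    raise ConfigurationError(
                        f"{path}:{lineno}: no read length for query {query_id!r}"
                    )
            else:
                raise ConfigurationError(
                    f"{path}:{lineno}: table has no qlen column and no "
                    "read-length table was supplied"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=fields[1],
                        percent_identity=identity,
                        alignment_length=length,
                        e_value=e_value,
                        bit_score=bit_score,
                        query_length=query_length,
                        db_label=db_label,
                    )
                )
            except ValidationError as exc:
                raise HitTableParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: list[AlignmentHit], path: PathLike) -> None:
    """Write hits as 13-column BLAST tabular (qlen last). Unused positional
    columns (mismatches, gaps, coordinates) are written as zeros."""
    with open(path, "w", encoding="utf-8") as handle:
        for h in hits:
            qlen = h.query_length if h.query_length is not None else 0
            handle.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t0\t0\t0\t0\t{h.e_value:.3g}\t"
                f"{h.bit_score:.1f}\t{qlen}\n"
            )


def read_taxonomy(nodes_path: PathLike, subjects_path: PathLike) -> TaxonomyTree:
    """Read taxonomy nodes and the subject→taxon map into a validated tree.

    ``nodes_path``: TSV with columns taxon_id, name, rank, parent_id (empty
    parent for roots). ``subjects_path``: TSV with columns subject_id,
    taxon_id, viral_class.
    """
    nodes_df = pd.read_csv(
        nodes_path, sep="\t", comment=None, dtype=str, keep_default_na=False
    )
    _require_columns(nodes_df, ("taxon_id", "name", "rank", "parent_id"), nodes_path)
    nodes = [
        TaxonNode(
            taxon_id=row.taxon_id,
            name=row.name,
            rank=row.rank,
            parent_id=row.parent_id or None,
        )
        for row in nodes_df.itertuples(index=False)
    ]
    subjects_df = pd.read_csv(
        subjects_path, sep="\t", dtype=str, keep_default_na=False
    )
    _require_columns(
        subjects_df, ("subject_id", "taxon_id", "viral_class"), subjects_path
    )
    subject_map = {
        row.subject_id: (row.taxon_id, row.viral_class)
        for row in subjects_df.itertuples(index=False)
    }
    return TaxonomyTree(nodes, subject_map)


def write_taxonomy(tree: TaxonomyTree, nodes_path: PathLike, subjects_path: PathLike) -> None:
    with open(nodes_path, "w", encoding="utf-8") as handle:
        handle.write("taxon_id\tname\trank\tparent_id\n")
        for node in tree.nodes.values():
            handle.write(
                f"{node.taxon_id}\t{node.name}\t{node.rank}\t{node.parent_id or ''}\n"
            )
    with open(subjects_path, "w", encoding="utf-8") as handle:
        handle.write("subject_id\ttaxon_id\tviral_class\n")
        for subject_id, (taxon_id, viral_class) in tree.subject_map.items():
            handle.write(f"{subject_id}\t{taxon_id}\t{viral_class}\n")


def read_sample_metadata(path: PathLike) -> pd.DataFrame:
    """Read a QIIME-mapping-like metadata TSV (first column = sample id).

    Returns a DataFrame indexed by sample id with a validated ``sex`` column
    restricted to F/M. Duplicate sample ids and unknown sex levels are
    rejected.
    """
    with open(path, encoding="utf-8") as handle:
        first = handle.readline()
    header = first.lstrip("#").rstrip("\n").split("\t")
    df = pd.read_csv(
        path, sep="\t", skiprows=1, names=header, dtype=str, keep_default_na=False
    )
    if "sex" not in header[1:]:
        raise ValidationError(f"{path}: metadata must have a 'sex' column")
    sample_col = header[0]
    if df[sample_col].duplicated().any():
        dupes = sorted(df[sample_col][df[sample_col].duplicated()].unique())
        raise ValidationError(f"{path}: duplicate sample ids {dupes}")
    bad_sex = sorted(set(df["sex"]) - set(SEX_LEVELS))
    if bad_sex:
        raise ValidationError(
            f"{path}: sex values {bad_sex} outside {list(SEX_LEVELS)}"
        )
    df = df.rename(columns={sample_col: "sample_id"}).set_index("sample_id")
    return df


def write_sample_metadata(metadata: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#sample_id\tsex\n")
        for sample_id, row in metadata.iterrows():
            handle.write(f"{sample_id}\t{row['sex']}\n")


# -- taxon tables ----------------------------------------------------------


def write_taxon_table(
    table: TaxonTable, path: PathLike, format: str = "tsv"
) -> None:
    """Write a taxon table as TSV or BIOM 1.0 JSON (sparse).

    The TSV carries the table rank in a leading ``#`` line so that a
    write/read round trip reproduces the object; the BIOM output stores the
    lineage label as the row id and sample sex (if known) as column metadata.
    """
    if table.counts.empty and format == "biom_json":
        raise ValidationError("refusing to write an empty BIOM table")
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"# rank: {table.rank}\n")
            handle.write("taxon\t" + "\t".join(table.samples) + "\n")
            for taxon, row in table.counts.iterrows():
                handle.write(
                    str(taxon) + "\t" + "\t".join(str(v) for v in row) + "\n"
                )
    elif format == "biom_json":
        rows = [{"id": str(t), "metadata": None} for t in table.taxa]
        columns = []
        for sample in table.samples:
            meta = None
            if table.metadata is not None and sample in table.metadata.index:
                meta = {"sex": table.metadata.loc[sample, "sex"]}
            columns.append({"id": sample, "metadata": meta})
        dense = table.counts.to_numpy()
        data = [
            [int(r), int(c), int(dense[r, c])]
            for r, c in zip(*np.nonzero(dense))
        ]
        payload = {
            "id": None,
            "format": _BIOM_FORMAT,
            "format_url": _BIOM_URL,
            "type": "OTU table",
            "generated_by": "oralvirome",
            "date": datetime.datetime.now().isoformat(timespec="seconds"),
            "rows": rows,
            "columns": columns,
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(rows), len(columns)],
            "oralvirome:rank": table.rank,
            "data": data,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle)
    else:
        raise ValidationError(f"unknown taxon-table format {format!r}")


def read_taxon_table(path: PathLike, format: str = "tsv") -> TaxonTable:
    """Read a taxon table previously written by :func:`write_taxon_table`."""
    if format == "tsv":
        rank = "species"
        with open(path, encoding="utf-8") as handle:
            first = handle.readline()
            if first.startswith("# rank:"):
                rank = first.split(":", 1)[1].strip()
        counts = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, dtype={0: str}
        ).astype(np.int64)
        counts.index.name = "taxon"
        counts.index = counts.index.astype(str)
        return TaxonTable(rank, counts)
    if format == "biom_json":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        if payload.get("format") != _BIOM_FORMAT:
            raise ValidationError(f"{path}: not a BIOM 1.0 JSON table")
        taxa = [row["id"] for row in payload["rows"]]
        samples = [col["id"] for col in payload["columns"]]
        dense = np.zeros(payload["shape"], dtype=np.int64)
        for r, c, v in payload["data"]:
            dense[r, c] = v
        counts = pd.DataFrame(
            dense, index=pd.Index(taxa, name="taxon"), columns=samples
        )
        return TaxonTable(payload.get("oralvirome:rank", "species"), counts)
    raise ValidationError(f"unknown taxon-table format {format!r}")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


__all__ = [
    "AlignmentHit",
    "read_hit_table",
    "write_hit_table",
    "read_read_lengths",
    "read_taxonomy",
    "write_taxonomy",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_taxon_table",
    "read_taxon_table",
    "UNDETERMINED",
]
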