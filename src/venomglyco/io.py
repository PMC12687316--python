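"""Readers, writers and format validation for the pipeline's tabular formats.

All tables are UTF-8, tab-delimited, header row required, "." decimal mark.
Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .sequons import PeptideIdentification, ProteinRecord

__all__ = [
    "read_proteins",
    "read_deglyco_table",
    "read_intact_table",
    "read_glycan_db",
    "peptide_identifications",
    "SchemaError",
]

DEGLYCO_COLUMNS = (
    "sample_id", "replicate", "fraction", "peptide", "deamidation_positions",
    "protein_id", "start", "missed_cleavages",
)
INTACT_COLUMNS = (
    "sample_id", "backbone", "protein_id", "site", "composition", "neutral_mass", "score",
)
GLYCAN_DB_COLUMNS = ("id", "composition")


class SchemaError(ValueError):
    """A table is missing required columns or violates basic constraints."""


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_proteins(fasta_path, annotation_path=None) -> dict[str, ProteinRecord]:
    """Protein FASTA plus optional annotation TSV (protein_id, toxin_class,
    domain, start, end; one row per domain, empty domain row for the class)."""
    classes: dict[str, str] = {}
    domains: dict[str, list] = defaultdict(list)
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
        _require(ann, ("protein_id", "toxin_class"), "annotation table")
        for _, row in ann.iterrows():
            classes[row["protein_id"]] = row["toxin_class"]
            if row.get("domain", ""):
                domains[row["protein_id"]].append(
                    (row["domain"], int(row["start"]), int(row["end"]))
                )
    proteins = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        pid = rec.id
        proteins[pid] = ProteinRecord(
            pid, str(rec.seq).upper(),
            toxin_class=classes.get(pid, "other"),
            domain_annotations=tuple(domains.get(pid, ())),
        )
    if not proteins:
        raise SchemaError(f"no sequences in {fasta_path}")
    return proteins


def read_deglyco_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"deamidation_positions": str},
                     keep_default_na=False, na_values=[])
    _require(df, DEGLYCO_COLUMNS, "de-glyco identification table")
    return df


def peptide_identifications(df: pd.DataFrame) -> list[PeptideIdentification]:
    """Turn de-glyco table rows into replicate-level identification records."""
    out = []
    for _, row in df.iterrows():
        deam_raw = str(row["deamidation_positions"]).strip()
        deam = tuple(
            int(x) for x in deam_raw.split(";") if x.strip()
        ) if deam_raw and deam_raw.lower() != "nan" else ()
        out.append(
            PeptideIdentification(
                sample_id=str(row["sample_id"]),
                replicate=int(row["replicate"]),
                fraction=str(row["fraction"]),
                peptide=str(row["peptide"]),
                deamidation_positions=deam,
                protein_mappings=((str(row["protein_id"]), int(row["start"])),),
                missed_cleavages=int(row["missed_cleavages"]),
            )
        )
    return out


def read_intact_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, INTACT_COLUMNS, "intact glycopeptide table")
    return df


def read_glycan_db(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, GLYCAN_DB_COLUMNS, "glycan database")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
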