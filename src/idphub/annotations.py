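"""Proteome sequences and protein-level annotation tables.

Readers for the FASTA proteome, the annotation TSV (TF flag, stress-pathway
memberships, subcellular localizations with source tags, optional conflict
flag) and the per-protein pLLPS TSV, plus the localization classification
used to summarise where proteins live (unique / diverse / ambiguous).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "STRESS_PATHWAYS",
    "read_fasta",
    "read_annotation_table",
    "read_pllps_table",
    "localization_class",
    "write_unmatched_report",
]

#: Stress signaling pathway vocabulary (five yeast stress maps); extensible
#: through the pipeline configuration.
STRESS_PATHWAYS = (
    "heat_shock",
    "ion_homeostasis",
    "nutrient_adaptation",
    "oxidative",
    "osmotic",
)


@dataclass
class ProteinRecord:
    """Identity plus functional annotation for one protein."""

    protein_id: str
    length: int
    is_tf: bool = False
    pathways: frozenset[str] = field(default_factory=frozenset)
    localizations: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    loc_conflict: bool = False
    pllps: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")
        if self.pllps is not None and not (0.0 <= self.pllps <= 1.0):
            raise ValueError(f"{self.protein_id}: pllps outside [0, 1]")

    @property
    def compartments(self) -> frozenset[str]:
        return frozenset(c for c, _src in self.localizations)


def read_fasta(path) -> dict[str, str]:
    """Read a proteome FASTA into an ordered {id: sequence} mapping.

    Duplicate ids and empty sequences are rejected with the offending
    record named.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA record: {rec.id}")
        proteome[rec.id] = seq
    return proteome


def _split_multi(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [tok for tok in str(cell).split(";") if tok]


def _parse_localizations(cell: object, line_no: int) -> frozenset[tuple[str, str]]:
    locs = set()
    for tok in _split_multi(cell):
        if ":" in tok:
            comp, src = tok.split(":", 1)
        else:
            comp, src = tok, "unspecified"
        if not comp:
            raise ValueError(f"annotation line {line_no}: empty compartment in {tok!r}")
        locs.add((comp, src))
    return frozenset(locs)


def read_annotation_table(
    path, proteome: Mapping[str, str] | None = None
) -> tuple[list[ProteinRecord], list[str]]:
    """Read the annotation TSV into ProteinRecords.

    Columns: protein_id, is_tf (0/1), pathways (semicolon-separated),
    localizations (semicolon-separated ``compartment:source`` tokens),
    optional loc_conflict (0/1), optional length.  When a ``proteome`` is
    given, lengths come from it and ids absent from the proteome are
    returned in the unmatched list (reported, never silently dropped).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise ValueError(f"annotation table {path}: missing protein_id column")
    records: list[ProteinRecord] = []
    unmatched: list[str] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        pid = row["protein_id"]
        if proteome is not None and pid not in proteome:
            unmatched.append(pid)
            continue
        try:
            if proteome is not None:
                length = len(proteome[pid])
            elif "length" in df.columns:
                length = int(row["length"])
            else:
                raise ValueError("no proteome given and no length column present")
            is_tf = bool(int(row["is_tf"])) if "is_tf" in df.columns else False
            pathways = frozenset(_split_multi(row.get("pathways")))
            locs = _parse_localizations(row.get("localizations"), line_no)
            conflict = (
                bool(int(row["loc_conflict"]))
                if "loc_conflict" in df.columns and not pd.isna(row["loc_conflict"])
                else False
            )
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    length=length,
                    is_tf=is_tf,
                    pathways=pathways,
                    localizations=locs,
                    loc_conflict=conflict,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"annotation table {path} line {line_no}: {exc}") from exc
    return records, unmatched


def read_pllps_table(path) -> dict[str, float]:
    """Read the per-protein pLLPS TSV (protein_id, pllps)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"protein_id": str}, float_precision="round_trip"
    )
    missing = {"protein_id", "pllps"} - set(df.columns)
    if missing:
        raise ValueError(f"pLLPS table {path}: missing columns {sorted(missing)}")
    vals = df["pllps"].astype(float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError(f"pLLPS table {path}: values outside [0, 1]")
    return dict(zip(df["protein_id"], vals))


def localization_class(record: ProteinRecord) -> str:
    """Classify a protein's subcellular localization evidence.

    ``unique``: exactly one compartment across sources; ``diverse``: more
    than one compartment without a conflict flag; ``ambiguous``: the input
    marks the compartment assertions as contradictory.  Proteins without
    localization data return ``unknown`` (not an error).
    """
    if not record.localizations:
        return "unknown"
    if record.loc_conflict:
        return "ambiguous"
    return "unique" if len(record.compartments) == 1 else "diverse"


def write_unmatched_report(unmatched: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# annotation ids absent from the proteome\nprotein_id\n")
        for pid in unmatched:
            fh.write(f"{pid}\n")
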