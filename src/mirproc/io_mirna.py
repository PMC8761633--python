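"""Reading and writing of hairpin, annotation, and expression tables.

Hairpin sequences come in as FASTA (DNA or RNA alphabet; T is normalized to
U). Mature-arm coordinates come either from a miRBase-style GFF3 with
hairpin-relative ``miRNA`` features or from a flat TSV. All coordinates are
1-based inclusive throughout the package, matching the biological convention
for miRNA annotation.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass
class PriMiRNARecord:
    """A pri-miRNA hairpin with its annotated mature arm(s)."""
    id: str
    species: str
    sequence: str
    mir5p_span: tuple[int, int] | None = None
    mir3p_span: tuple[int, int] | None = None
    family: str | None = None
    is_conserved: bool = False

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        n = len(self.sequence)
        for name, span in (("mir5p_span", self.mir5p_span),
                           ("mir3p_span", self.mir3p_span)):
            if span is not None:
                a, b = span
                if not (1 <= a <= b <= n):
                    raise ValueError(
                        f"{self.id}: {name} {span} outside sequence of length {n}")
        if self.mir5p_span and self.mir3p_span:
            if self.mir5p_span[1] >= self.mir3p_span[0]:
                raise ValueError(
                    f"{self.id}: 5p span {self.mir5p_span} does not precede "
                    f"3p span {self.mir3p_span}")

    @property
    def has_annotation(self) -> bool:
        return self.mir5p_span is not None or self.mir3p_span is not None


@dataclass
class ExpressionRecord:
    """Combined small-RNA read counts for one miRNA hairpin."""
    mirna_id: str
    reads_5p: float
    reads_3p: float

    @property
    def total(self) -> float:
        return self.reads_5p + self.reads_3p


def normalize_rna(sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters after normalization: {sorted(bad)}")
    return seq


def _species_from_id(mirna_id: str) -> str:
    return mirna_id.split("-", 1)[0] if "-" in mirna_id else ""


def _read_tsv_annotation(path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t")
    required = {"id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV missing columns {required - set(df.columns)}")
    out = {}
    for _, row in df.iterrows():
        entry: dict = {}
        if pd.notna(row.get("5p_start")) and pd.notna(row.get("5p_end")):
            entry["mir5p_span"] = (int(row["5p_start"]), int(row["5p_end"]))
        if pd.notna(row.get("3p_start")) and pd.notna(row.get("3p_end")):
            entry["mir3p_span"] = (int(row["3p_start"]), int(row["3p_end"]))
        if "family" in df.columns and pd.notna(row.get("family")):
            entry["family"] = str(row["family"])
        out[str(row["id"])] = entry
    return out


def _read_gff3_annotation(path) -> dict[str, dict]:
    """Minimal miRBase-dialect GFF3: ``miRNA`` features carry hairpin-relative
    1-based coordinates in seqid = hairpin id; arm identity from the Name
    attribute suffix (-5p / -3p) or relative order."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "miRNA":
                continue
            seqid, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            name = attr.get("Name", attr.get("ID", ""))
            entry = out.setdefault(seqid, {})
            if name.endswith("-5p"):
                entry["mir5p_span"] = (start, end)
            elif name.endswith("-3p"):
                entry["mir3p_span"] = (start, end)
            else:  # unlabeled arm: assign by position later
                entry.setdefault("_unlabeled", []).append((start, end))
    for entry in out.values():
        for span in entry.pop("_unlabeled", []):
            key = "mir5p_span" if "mir5p_span" not in entry else "mir3p_span"
            entry[key] = span
    return out


def read_hairpins(fasta_path, annotation_path) -> list[PriMiRNARecord]:
    """Assemble hairpin records from a FASTA plus an arm-coordinate table.

    Every annotation id must exist in the FASTA; hairpins without any arm
    annotation are kept and flagged by ``has_annotation == False``.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann_path = Path(annotation_path)
    if ann_path.suffix.lower() in {".gff", ".gff3"}:
        ann = _read_gff3_annotation(ann_path)
    else:
        ann = _read_tsv_annotation(ann_path)
    missing = sorted(set(ann) - set(seqs))
    if missing:
        raise ValueError(f"annotation references absent hairpin ids: {missing}")
    records = []
    for rid, seq in seqs.items():
        entry = ann.get(rid, {})
        if not entry:
            logger.warning("hairpin %s has no arm annotation", rid)
        records.append(PriMiRNARecord(
            id=rid, species=_species_from_id(rid), sequence=seq,
            mir5p_span=entry.get("mir5p_span"),
            mir3p_span=entry.get("mir3p_span"),
            family=entry.get("family")))
    return records


def write_hairpins(records: Iterable[PriMiRNARecord], fasta_path, tsv_path) -> None:
    """Round-trippable FASTA + flat TSV serialization of hairpin records."""
    rows = []
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
            rows.append({
                "id": r.id,
                "5p_start": r.mir5p_span[0] if r.mir5p_span else None,
                "5p_end": r.mir5p_span[1] if r.mir5p_span else None,
                "3p_start": r.mir3p_span[0] if r.mir3p_span else None,
                "3p_end": r.mir3p_span[1] if r.mir3p_span else None,
                "family": r.family,
            })
    df = pd.DataFrame(rows)
    for c in ("5p_start", "5p_end", "3p_start", "3p_end"):
        df[c] = df[c].astype("Int64")
    df.to_csv(tsv_path, sep="\t", index=False)


def read_expression_table(tsv_path, combine: str = "sum") -> list[ExpressionRecord]:
    """Merge per-arm expression rows into per-hairpin 5p+3p totals.

    The table has columns ``mirna_id``, ``arm`` (5p/3p) and one column per
    tissue. Tissue columns are combined (sum by default, mean optionally)
    into a single value per arm before the 5p+3p sum; a missing arm counts
    as zero reads.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    for col in ("mirna_id", "arm"):
        if col not in df.columns:
            raise ValueError(f"expression table missing column {col!r}")
    tissue_cols = [c for c in df.columns if c not in ("mirna_id", "arm")]
    if not tissue_cols:
        raise ValueError("expression table has no tissue columns")
    vals = df[tissue_cols]
    if (vals < 0).any().any():
        raise ValueError("negative read counts in expression table")
    if combine == "sum":
        df["_combined"] = vals.sum(axis=1)
    elif combine == "mean":
        df["_combined"] = vals.mean(axis=1)
    else:
        raise ValueError(f"unknown tissue combination rule {combine!r}")
    out = []
    for mirna_id, grp in df.groupby("mirna_id", sort=True):
        arms = grp.groupby("arm")["_combined"].sum()
        out.append(ExpressionRecord(
            mirna_id=str(mirna_id),
            reads_5p=float(arms.get("5p", 0.0)),
            reads_3p=float(arms.get("3p", 0.0))))
    return out


_HUMAN_ID = re.compile(r"^hsa-(?:mir|let|miR)-?(\d+)", re.IGNORECASE)


def filter_human_mirna_number(records, max_number: int = 1000) -> list:
    """Keep human miRNAs whose name/number is below ``max_number``.

    Later-numbered human annotations are less likely to be genuine canonical
    miRNAs. Non-human records pass through unfiltered; unparsable human ids
    are excluded with a warning.
    """
    out = []
    for r in records:
        rid = getattr(r, "id", None) or getattr(r, "mirna_id")
        if not rid.lower().startswith("hsa-"):
            out.append(r)
            continue
        m = _HUMAN_ID.match(rid)
        if m is None:
            logger.warning("unparsable human miRNA id %r excluded", rid)
            continue
        if int(m.group(1)) < max_number:
            out.append(r)
    return out
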