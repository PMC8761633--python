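"""Positional scanning of Microprocessor-associated sequence motifs.

Three presence/absence motifs are scored at their canonical positions
relative to the Drosha cleavage sites (the pre-miRNA ends):

* **UG** — basal UG dinucleotide at positions -14/-13 upstream of the
  pre-miRNA 5′ end;
* **UGU** — apical UGU within the first four nucleotides of the terminal
  loop region;
* **CNNC** — a C-N-N-C spaced pair in the 3′ flank whose first C lies
  16-18 nt downstream of the pre-miRNA 3′ end.

The bulged-GHG (mGHG) basal-stem determinant is scored by table lookup on a
structural key describing the 3-nt window on the 3′ strand centered 5 nt
below the 3′-side Drosha site: each window position contributes its base and
pairing status (partner base, or ``.`` if unpaired) from the pri-miRNA
structure. Score values are external data supplied as a TSV; keys absent
from the table yield no score (no imputation).

All windows are configurable; the defaults follow the positions established
in the primary literature on these motifs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fold_engine import FoldResult
from .hairpin_domains import DomainPartition
from .io_mirna import PriMiRNARecord

logger = logging.getLogger(__name__)

UG_OFFSETS = (-14, -13)       # relative to pre-miRNA 5' end (1-based shifts)
UGU_LOOP_WINDOW = 4           # first N nt of the terminal loop region
CNNC_OFFSETS = (16, 18)       # first C this many nt past the pre-miRNA 3' end
MGHG_CENTER_OFFSET = 5        # window center, nt below the 3' Drosha site


@dataclass
class MotifProfile:
    """Presence flags, canonical positions, and mGHG score for one hairpin."""
    mirna_id: str
    has_ug: bool = False
    has_ugu: bool = False
    has_cnnc: bool = False
    mghg_score: float | None = None
    positions: dict = field(default_factory=dict)

    @property
    def motif_count(self) -> int:
        return int(self.has_ug) + int(self.has_ugu) + int(self.has_cnnc)


class MghgTable:
    """Lookup table mapping basal-window structural keys to mGHG scores."""

    def __init__(self, entries: dict[str, float], provenance: str = ""):
        self.entries = dict(entries)
        self.provenance = provenance

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None) -> "MghgTable":
        df = pd.read_csv(path, sep="\t")
        if not {"key", "score"} <= set(df.columns):
            raise ValueError("mGHG table needs 'key' and 'score' columns")
        return cls(dict(zip(df["key"].astype(str), df["score"].astype(float))),
                   provenance or str(path))

    @classmethod
    def synthetic_default(cls) -> "MghgTable":
        """Placeholder table over the synthetic cohort's window keys (the
        published score values are external data and are not shipped)."""
        path = resources.files("mirproc").joinpath("data/mghg_synthetic.tsv")
        return cls.from_tsv(path, provenance="synthetic placeholder table")

    def lookup(self, key: str) -> float | None:
        return self.entries.get(key)

    def __len__(self) -> int:
        return len(self.entries)


def mghg_window_key(record: PriMiRNARecord, pri_fold: FoldResult,
                    pre_end: int,
                    center_offset: int = MGHG_CENTER_OFFSET) -> str | None:
    """Structural key of the 3-nt basal window below the 3′ Drosha site.

    ``None`` when the window falls outside the sequence (flank too short).
    """
    n = len(record.sequence)
    center = pre_end + center_offset
    lo, hi = center - 1, center + 1
    if lo < 1 or hi > n:
        return None
    parts = []
    for pos in range(lo, hi + 1):
        base = record.sequence[pos - 1]
        q = pri_fold.partner(pos)
        partner = record.sequence[q - 1] if q else "."
        parts.append(f"{base}{partner}")
    return "/".join(parts)


def mghg_score(record: PriMiRNARecord, pri_fold: FoldResult,
               mghg_table: MghgTable, pre_end: int,
               center_offset: int = MGHG_CENTER_OFFSET) -> float | None:
    """Deterministic table lookup; ``None`` when the window is unresolvable
    or the key is not in the table."""
    key = mghg_window_key(record, pri_fold, pre_end, center_offset)
    if key is None:
        return None
    return mghg_table.lookup(key)


def scan_motifs(record: PriMiRNARecord, partition: DomainPartition,
                pri_fold: FoldResult,
                mghg_table: MghgTable | None = None,
                ug_offsets: tuple[int, int] = UG_OFFSETS,
                ugu_window: int = UGU_LOOP_WINDOW,
                cnnc_offsets: tuple[int, int] = CNNC_OFFSETS) -> MotifProfile:
    """Score UG/UGU/CNNC presence and the mGHG table lookup for one hairpin."""
    seq = record.sequence
    n = len(seq)
    pre_start, pre_end = partition.pre_span
    prof = MotifProfile(mirna_id=record.id)

    # UG at -14/-13 relative to the pre-miRNA 5' end
    p_ug = pre_start + ug_offsets[0]
    if p_ug >= 1 and pre_start + ug_offsets[1] <= n:
        if seq[p_ug - 1] == "U" and seq[pre_start + ug_offsets[1] - 1] == "G":
            prof.has_ug = True
            prof.positions["UG"] = p_ug
    else:
        logger.warning("%s: 5' flank too short for the UG window", record.id)

    # UGU within the first `ugu_window` nt of the terminal loop
    loop_a, loop_b = partition.terminal_loop_region
    if loop_a <= loop_b:
        win = seq[loop_a - 1:min(loop_a - 1 + ugu_window, loop_b)]
        idx = win.find("UGU")
        if idx >= 0:
            prof.has_ugu = True
            prof.positions["UGU"] = loop_a + idx

    # CNNC with first C 16-18 nt past the pre-miRNA 3' end
    for off in range(cnnc_offsets[0], cnnc_offsets[1] + 1):
        p = pre_end + off
        if p + 3 > n:
            logger.warning("%s: 3' flank too short for the CNNC window",
                           record.id)
            break
        if seq[p - 1] == "C" and seq[p + 2] == "C":
            prof.has_cnnc = True
            prof.positions["CNNC"] = p
            break

    if mghg_table is not None and len(mghg_table):
        prof.mghg_score = mghg_score(record, pri_fold, mghg_table, pre_end)
    return prof


def stratify_by_motif_count(profiles: list[MotifProfile],
                            measurements: dict[str, float]) -> pd.DataFrame:
    """Group response values by UG/UGU/CNNC motif count (0-3).

    Returns one row per stratum with n, mean, and SD; empty strata are
    reported with n = 0.
    """
    by_count: dict[int, list[float]] = {k: [] for k in range(4)}
    for p in profiles:
        if p.mirna_id in measurements:
            by_count[p.motif_count].append(measurements[p.mirna_id])
    rows = []
    for count in range(4):
        vals = np.asarray(by_count[count], dtype=float)
        rows.append({
            "motif_count": count,
            "n": vals.size,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else
                  (0.0 if vals.size == 1 else np.nan),
        })
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[MotifProfile]) -> pd.DataFrame:
    """Flat motif report table."""
    return pd.DataFrame([{
        "mirna_id": p.mirna_id,
        "has_ug": p.has_ug,
        "has_ugu": p.has_ugu,
        "has_cnnc": p.has_cnnc,
        "motif_count": p.motif_count,
        "mghg_score": p.mghg_score,
    } for p in profiles])
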