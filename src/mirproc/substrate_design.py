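"""In-silico construction of pri-/pre-miRNA transcription substrates.

Models how in-vitro transcription templates are designed: pri-miRNA
substrates carry ~30 extra nucleotides 5′ and ~40 nt 3′ of the pre-miRNA,
and pre-miRNA substrates respect the T7 polymerase requirement for a 5′ G —
if the first residue is not G it is substituted, together with its pairing
partner (changed to C) so the predicted secondary structure is maintained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .fold_engine import EnergyModel, FoldResult, default_model, fold_mfe

logger = logging.getLogger(__name__)

DEFAULT_FLANK5 = 30
DEFAULT_FLANK3 = 40


@dataclass
class SubstrateDesign:
    id: str
    rna: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    flank5: int = 0
    flank3: int = 0


def design_pri_substrate(substrate_id: str, genomic_context: str,
                         pre_span: tuple[int, int],
                         flank5: int = DEFAULT_FLANK5,
                         flank3: int = DEFAULT_FLANK3) -> SubstrateDesign:
    """Excise pre-miRNA plus flanks from a genomic context sequence.

    ``pre_span`` is 1-based inclusive on ``genomic_context``; flanks are
    clipped (with a warning) when the context is too short.
    """
    n = len(genomic_context)
    a, b = pre_span
    if not (1 <= a <= b <= n):
        raise ValueError(f"pre_span {pre_span} outside context of length {n}")
    lo = a - flank5
    if lo < 1:
        logger.warning("%s: context short by %d nt on the 5' side",
                       substrate_id, 1 - lo)
        lo = 1
    hi = b + flank3
    if hi > n:
        logger.warning("%s: context short by %d nt on the 3' side",
                       substrate_id, hi - n)
        hi = n
    rna = genomic_context[lo - 1:hi].upper().replace("T", "U")
    return SubstrateDesign(id=substrate_id, rna=rna, edits=[],
                           flank5=a - lo, flank3=hi - b)


def design_pre_substrate(substrate_id: str, pre_rna: str,
                         pre_fold: FoldResult | None = None,
                         model: EnergyModel | None = None) -> SubstrateDesign:
    """Apply the T7 5′-G substitution rule to a pre-miRNA.

    If position 1 is already G, nothing changes. Otherwise position 1
    becomes G and, if it is paired in the pre-miRNA MFE structure, its
    partner becomes C so the closing pair is retained. Idempotent.
    """
    model = model or default_model()
    pre_rna = pre_rna.upper().replace("T", "U")
    if pre_fold is None:
        pre_fold = fold_mfe(pre_rna, model)
    if pre_fold.sequence != pre_rna:
        raise ValueError("pre_fold does not match pre_rna")
    if pre_rna[0] == "G":
        return SubstrateDesign(id=substrate_id, rna=pre_rna, edits=[])
    edits = [(1, pre_rna[0], "G")]
    seq = list(pre_rna)
    seq[0] = "G"
    q = pre_fold.partner(1)
    if q:
        edits.append((q, pre_rna[q - 1], "C"))
        seq[q - 1] = "C"
    return SubstrateDesign(id=substrate_id, rna="".join(seq), edits=edits)


def position1_pair_preserved(design: SubstrateDesign,
                             original_fold: FoldResult,
                             model: EnergyModel | None = None) -> bool:
    """Check that refolding the edited substrate keeps the position-1 pair
    of the original structure (trivially true when position 1 was unpaired)."""
    model = model or default_model()
    q = original_fold.partner(1)
    if q == 0:
        return True
    refolded = fold_mfe(design.rna, model)
    return refolded.partner(1) == q
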