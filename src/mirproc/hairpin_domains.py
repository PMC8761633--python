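"""Demarcation of pri-miRNA hairpins into named domains with per-domain ΔG.

A pri-miRNA decomposes into the pre-miRNA moiety (terminal loop region plus
miRNA duplex) and the flanking region (proximal domain, a.k.a. basal stem,
plus distal domain):

* terminal loop region — from the first nucleotide after the 3′ end of the
  (actual or predicted) miR-5p to the corresponding nucleotide on the 3′ arm,
  operationalized as the interior of the loop-anchoring pair: the last paired
  position at or 5′-ward of the miR-5p 3′ end and its pairing partner.
* duplex region — the rest of the pre-miRNA; its ΔG is defined by
  subtraction (pre-miRNA ΔG minus terminal-loop ΔG) so the identity
  ``dg_duplex + dg_loop == dg_pre`` holds by construction.
* proximal domain — up to 12-nt extensions immediately beyond both
  pre-miRNA ends, clipped at the sequence boundary.
* distal domain — all remaining flank positions.

Loop/proximal/distal ΔG values are region-attributed energies on the
pri-miRNA MFE structure; the pre-miRNA ΔG comes from refolding the
pre-miRNA subsequence on its own.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .fold_engine import EnergyModel, FoldResult, default_model, fold_mfe, region_energy
from .io_mirna import PriMiRNARecord

logger = logging.getLogger(__name__)

PROXIMAL_EXTENSION = 12  # nt beyond each pre-miRNA end


@dataclass
class DomainPartition:
    """Coordinate spans (1-based inclusive) and ΔG (kcal/mol) per domain."""
    pre_span: tuple[int, int]
    terminal_loop_region: tuple[int, int]
    duplex_region: list[tuple[int, int]]
    proximal_domain: list[tuple[int, int]]
    distal_domain: list[tuple[int, int]]
    dg_loop: float | None = None
    dg_duplex: float | None = None
    dg_pre: float | None = None
    dg_proximal: float | None = None
    dg_distal: float | None = None
    dg_pri: float | None = None


def _resolve_5p_span(record: PriMiRNARecord, pri_fold: FoldResult) -> tuple[int, int]:
    if record.mir5p_span is not None:
        return record.mir5p_span
    return predict_missing_arm(record, pri_fold)


def terminal_loop_region(record: PriMiRNARecord,
                         pri_fold: FoldResult) -> tuple[int, int]:
    """Apical loop interval ``[k+1, q-1]``: k is the miR-5p 3′ end, q the
    partner of the loop-anchoring pair (scanning 5′-ward from k when k itself
    is unpaired)."""
    span5 = _resolve_5p_span(record, pri_fold)
    k = span5[1]
    anchor = None
    for pos in range(k, span5[0] - 1, -1):
        if pri_fold.partner(pos) != 0:
            anchor = pos
            break
    if anchor is None:
        raise ValueError(f"{record.id}: no anchoring pair — miR-5p entirely "
                         f"unpaired in the pri-miRNA structure")
    q = pri_fold.partner(anchor)
    if q <= anchor:
        raise ValueError(f"{record.id}: miR-5p anchoring pair points 5'-ward; "
                         f"not a hairpin-arm geometry")
    return (k + 1, q - 1)


def predict_missing_arm(record: PriMiRNARecord,
                        pri_fold: FoldResult) -> tuple[int, int]:
    """Predict the unannotated arm from the annotated one.

    The predicted partner arm spans the pairing partners of the annotated
    arm's (nearest-paired) ends, shifted by the canonical 2-nt 3′ overhang
    of the Drosha/Dicer duplex.
    """
    if record.mir5p_span is not None and record.mir3p_span is not None:
        raise ValueError(f"{record.id}: both arms annotated, nothing to predict")
    if record.mir5p_span is None and record.mir3p_span is None:
        raise ValueError(f"{record.id}: neither arm annotated")

    def anchored_partner(pos: int, inward: int, limit: int) -> tuple[int, int]:
        # scan from pos toward the arm interior to the nearest paired
        # position; return its partner and the offset scanned
        off = 0
        p = pos
        while True:
            if 1 <= p <= len(record.sequence) and pri_fold.partner(p) != 0:
                return pri_fold.partner(p), off
            p += inward
            off += 1
            if (inward > 0 and p > limit) or (inward < 0 and p < limit):
                raise ValueError(f"{record.id}: annotated arm fully unpaired")

    n = len(record.sequence)
    if record.mir3p_span is not None:
        s3, e3 = record.mir3p_span
        part_s, off_s = anchored_partner(s3, +1, e3)
        part_e, off_e = anchored_partner(e3, -1, s3)
        # partner(start of 3p) sits near the 5p 3' end; shift back out by the
        # scan offset, then apply the 2-nt 3' overhang register
        end5 = part_s + off_s - 2
        start5 = part_e - off_e - 2
    else:
        s5, e5 = record.mir5p_span
        part_s, off_s = anchored_partner(s5, +1, e5)
        part_e, off_e = anchored_partner(e5, -1, s5)
        start3 = part_e - off_e + 2
        end3 = part_s + off_s + 2
        start5, end5 = start3, end3  # reuse clip below
    a = max(1, min(start5, end5))
    b = min(n, max(start5, end5))
    if a >= b:
        raise ValueError(f"{record.id}: degenerate predicted arm span")
    return (a, b)


def _pre_span(record: PriMiRNARecord, pri_fold: FoldResult) -> tuple[int, int]:
    span5 = record.mir5p_span
    span3 = record.mir3p_span
    if span5 is None:
        span5 = predict_missing_arm(record, pri_fold)
    if span3 is None:
        span3 = predict_missing_arm(record, pri_fold)
    return (span5[0], span3[1])


def partition_domains(record: PriMiRNARecord,
                      pri_fold: FoldResult) -> DomainPartition:
    """Tile the pri-miRNA into pre-miRNA, proximal and distal domains.

    The three top-level regions partition [1, L] exactly; the proximal
    domain is clipped (with a warning) when a flank is shorter than 12 nt.
    """
    n = len(record.sequence)
    pre = _pre_span(record, pri_fold)
    loop = terminal_loop_region(record, pri_fold)
    if not (pre[0] <= loop[0] and loop[1] <= pre[1]):
        raise ValueError(f"{record.id}: terminal loop {loop} escapes "
                         f"pre-miRNA span {pre}")
    prox = []
    lo5 = pre[0] - PROXIMAL_EXTENSION
    if lo5 < 1:
        logger.warning("%s: 5' flank shorter than %d nt; proximal clipped",
                       record.id, PROXIMAL_EXTENSION)
        lo5 = 1
    if lo5 <= pre[0] - 1:
        prox.append((lo5, pre[0] - 1))
    hi3 = pre[1] + PROXIMAL_EXTENSION
    if hi3 > n:
        logger.warning("%s: 3' flank shorter than %d nt; proximal clipped",
                       record.id, PROXIMAL_EXTENSION)
        hi3 = n
    if pre[1] + 1 <= hi3:
        prox.append((pre[1] + 1, hi3))
    distal = []
    if lo5 > 1:
        distal.append((1, lo5 - 1))
    if hi3 < n:
        distal.append((hi3 + 1, n))
    duplex = [(pre[0], loop[0] - 1), (loop[1] + 1, pre[1])]
    duplex = [(a, b) for a, b in duplex if a <= b]
    return DomainPartition(pre_span=pre, terminal_loop_region=loop,
                           duplex_region=duplex, proximal_domain=prox,
                           distal_domain=distal)


def domain_deltaG(record: PriMiRNARecord, pri_fold: FoldResult,
                  model: EnergyModel | None = None) -> DomainPartition:
    """Fill all five domain ΔG values.

    ``dg_loop``, ``dg_proximal`` and ``dg_distal`` are region-attributed
    energies on the pri-miRNA structure; ``dg_pre`` refolds the pre-miRNA
    subsequence; ``dg_duplex`` is the subtraction ``dg_pre - dg_loop``.
    """
    model = model or default_model()
    part = partition_domains(record, pri_fold)
    seq, db = pri_fold.sequence, pri_fold.dotbracket
    loop = part.terminal_loop_region
    part.dg_loop = (region_energy(seq, db, [loop], model)
                    if loop[0] <= loop[1] else 0.0)
    pre_seq = record.sequence[part.pre_span[0] - 1:part.pre_span[1]]
    part.dg_pre = fold_mfe(pre_seq, model).delta_g
    part.dg_duplex = part.dg_pre - part.dg_loop
    part.dg_proximal = (region_energy(seq, db, part.proximal_domain, model)
                        if part.proximal_domain else 0.0)
    part.dg_distal = (region_energy(seq, db, part.distal_domain, model)
                      if part.distal_domain else 0.0)
    part.dg_pri = pri_fold.delta_g
    return part
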