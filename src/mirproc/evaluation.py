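"""Replication-style evaluation harnesses over synthetic cohorts.

These routines re-run the full pipeline over many independently seeded
cohorts to measure its statistical operating characteristics: false-positive
calibration under a null generator, power and sign recovery for planted
effects, the agreement of end-point assays with time-course areas under the
curve, and the reliability of the T7 substrate-design rule.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .fold_engine import fold_mfe
from .pipeline import analyze_cohort
from .quant_stats import spearman, timecourse_summary
from .substrate_design import design_pre_substrate, position1_pair_preserved
from .synthetic_data import (GeneratorConfig, generate_cohort,
                             generate_timecourse_cohort)

EFFICIENCY_RESPONSES = ("Drosha efficiency", "Dicer efficiency")


def _drosha_rows(cohort):
    bundle = analyze_cohort(cohort.records, cohort.lanes, None,
                            cohort.mghg_table)
    return bundle["correlations"]


def null_calibration(seeds: Sequence[int], n_mirnas: int = 150) -> dict:
    """Fraction of feature-efficiency Spearman tests with p < 0.05 when all
    planted effect sizes are zero."""
    pvals = []
    for seed in seeds:
        cfg = GeneratorConfig(n_mirnas=n_mirnas, seed=int(seed)).null()
        rep = _drosha_rows(generate_cohort(cfg))
        rows = rep[rep["response"].isin(EFFICIENCY_RESPONSES)]
        pvals.extend(rows["p"].dropna().tolist())
    pvals = np.asarray(pvals)
    return {"fraction_significant": float(np.mean(pvals < 0.05)),
            "n_tests": int(pvals.size)}


SIGNED_TARGETS = {  # feature -> expected correlation sign with cleavage
    "dg_proximal": -1,
    "dg_loop": +1,
    "mghg_score": +1,
}


def signed_recovery(seeds: Sequence[int], n_mirnas: int = 150) -> dict:
    """Per planted feature: in how many seeded cohorts the Drosha-efficiency
    correlation is significant (p < 0.05) with the planted sign."""
    hits = {f: 0 for f in SIGNED_TARGETS}
    for seed in seeds:
        cfg = GeneratorConfig(n_mirnas=n_mirnas, seed=int(seed))
        rep = _drosha_rows(generate_cohort(cfg))
        rows = rep[rep["response"] == "Drosha efficiency"].set_index("feature")
        for feat, sign in SIGNED_TARGETS.items():
            rho, p = rows.loc[feat, "rho"], rows.loc[feat, "p"]
            if p < 0.05 and np.sign(rho) == sign:
                hits[feat] += 1
    return {"hits": hits, "n_seeds": len(seeds)}


def endpoint_auc_agreement(seeds: Sequence[int], n_substrates: int = 20,
                           min_rho: float = 0.9) -> dict:
    """How often the end-point cleavage ratio ranks substrates like the full
    time-course area under the curve (Spearman >= ``min_rho``)."""
    agree = 0
    for seed in seeds:
        lanes, _ = generate_timecourse_cohort(n_substrates=n_substrates,
                                              seed=int(seed))
        summ = timecourse_summary(lanes)
        wide = summ.pivot(index="substrate_id", columns="timepoint",
                          values="mean_ratio")
        tps = np.array(sorted(wide.columns))
        auc = np.trapezoid(wide[tps].values, tps, axis=1)
        endpoint = wide[tps[-1]].values
        if spearman(endpoint, auc).rho >= min_rho:
            agree += 1
    return {"n_agree": agree, "n_seeds": len(seeds)}


def t7_rule_reliability(seed: int, n_pres: int = 200) -> dict:
    """Position-1 pair preservation and idempotence of the 5'-G substitution
    over generated pre-miRNAs."""
    cohort = generate_cohort(GeneratorConfig(n_mirnas=n_pres, seed=int(seed)))
    preserved = total = 0
    idempotent = True
    for rec in cohort.records:
        a, b = rec.mir5p_span[0], rec.mir3p_span[1]
        pre = rec.sequence[a - 1:b]
        fold = fold_mfe(pre)
        design = design_pre_substrate(rec.id, pre, fold)
        total += 1
        preserved += position1_pair_preserved(design, fold)
        again = design_pre_substrate(rec.id, design.rna)
        idempotent &= (again.rna == design.rna and again.edits == [])
    return {"n_preserved": preserved, "n_total": total,
            "idempotent": bool(idempotent)}
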