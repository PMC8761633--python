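"""Synthetic hairpin cohorts with planted ground truth.

The generator emulates the statistical structure of a pri-miRNA processing
study: a cohort of hairpins with controllable stem/loop/flank architecture
and planted sequence motifs; latent log cleavage efficiencies that follow a
log-linear model over standardized structural features (domain ΔG values of
the *designed* structure, motif count, mGHG score) plus Gaussian noise;
gel-lane intensities back-computed so that the raw cleavage ratio recovers
the latent efficiency through a logistic link; and small-RNA expression
counts drawn negative-binomially around a mean coupled to the relative
efficiency, split into 5p/3p arms and two tissue columns.

Hairpin architecture (1-based, flanks 30 nt 5' / 40 nt 3' by default)::

    distal5 | basal stem (6-12 bp) | 5p arm | loop | 3p arm | basal | distal3
              ^ proximal domain                               ^ proximal

The mGHG basal window (3' strand, 4-6 nt below the 3' Drosha site) is
planted as G-C pairs flanking a middle position drawn from eight variants
(four pairs, four same-base mismatches) scored by the packaged synthetic
lookup table. A single designated control substrate per (enzyme, batch)
anchors the relative-efficiency scale at 100.

One seeded generator is threaded through all draws in a fixed order, so a
seed fixes the full output byte stream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fold_engine import evaluate_structure_energy, region_energy, default_model
from .io_mirna import ExpressionRecord, PriMiRNARecord
from .motif_scan import MghgTable

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))
_MGHG_VARIANTS = ["C.", "A.", "U.", "G.", "AU", "UA", "CG", "GC"]

ENZYMES = ("Drosha", "Dicer")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""
    n_mirnas: int = 150
    arm_length_range: tuple[int, int] = (20, 24)
    loop_size_range: tuple[int, int] = (4, 28)
    basal_stem_range: tuple[int, int] = (6, 12)
    duplex_mismatch_range: tuple[int, int] = (0, 3)
    p_loop_stem: float = 0.7    # chance a large loop carries an inner stem
    p_distal_stem: float = 0.5  # chance of a small hairpin in the 3' flank
    flank5: int = 30
    flank3: int = 40
    p_ug: float = 0.5
    p_ugu: float = 0.5
    p_cnnc: float = 0.5
    mghg_key_weights: tuple[float, ...] = (1.0,) * len(_MGHG_VARIANTS)
    # effect sizes on standardized features
    beta0: float = 0.0
    beta_prox: float = -0.5
    beta_loop: float = 0.5
    beta_duplex: float = -0.3
    beta_distal: float = 0.2
    beta_motif: float = 0.3
    beta_mghg: float = 0.5
    noise_sd: float = 0.5
    # expression coupling
    expression_slope: float = 20.0
    expression_dispersion: float = 5.0
    p_family: float = 0.5
    n_batches: int = 1
    seed: int = 0

    def null(self) -> "GeneratorConfig":
        """Same conditions with every effect size zeroed."""
        return replace(self, beta_prox=0.0, beta_loop=0.0, beta_duplex=0.0,
                       beta_distal=0.0, beta_motif=0.0, beta_mghg=0.0)


@dataclass
class Cohort:
    records: list[PriMiRNARecord]
    true_features: pd.DataFrame
    lanes: pd.DataFrame
    expression: pd.DataFrame
    mghg_table: MghgTable = field(default_factory=MghgTable.synthetic_default)


def _rand_seq(rng, n: int, gc: float = 0.3) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _build_hairpin(rng, cfg: GeneratorConfig):
    """One designed hairpin: sequence, intended dot-bracket, metadata."""
    m = int(rng.integers(cfg.arm_length_range[0], cfg.arm_length_range[1] + 1))
    loop = int(rng.integers(cfg.loop_size_range[0], cfg.loop_size_range[1] + 1))
    b = int(rng.integers(cfg.basal_stem_range[0], cfg.basal_stem_range[1] + 1))
    n_mm = int(rng.integers(cfg.duplex_mismatch_range[0],
                            cfg.duplex_mismatch_range[1] + 1))
    f5, f3 = cfg.flank5, cfg.flank3
    pre_start = f5 + 1
    pre_len = 2 * m + loop
    pre_end = f5 + pre_len
    n = f5 + pre_len + f3

    seq = _rand_seq(rng, n)
    arm5 = list(rng.choice(_BASES, size=m, p=[0.3, 0.2, 0.2, 0.3]))
    loop_seq = list(rng.choice(_BASES, size=loop))
    seq[pre_start - 1:pre_start - 1 + m] = arm5
    seq[pre_start - 1 + m:pre_start - 1 + m + loop] = loop_seq
    # 3p arm: reverse complement of the 5p arm (duplex pairing i <-> pre_end-i)
    for i in range(m):
        seq[pre_end - 1 - i] = _COMP[arm5[i]]
    # plant duplex mismatches away from the duplex ends and the loop closure
    mm_offsets = []
    if n_mm and m > 6:
        mm_offsets = sorted(rng.choice(np.arange(2, m - 2), size=n_mm,
                                       replace=False).tolist())
        for i in mm_offsets:
            seq[pre_end - 1 - i] = arm5[i]  # same base: cannot pair
    # basal stem: flank positions pre_start-t <-> pre_end+t for t = 1..b
    for t in range(1, b + 1):
        seq[pre_end - 1 + t] = _COMP[seq[pre_start - 1 - t]]
    # mGHG basal window: G-C pairs at offsets 4 and 6, drawn middle variant
    for t in (4, 6):
        seq[pre_start - 1 - t] = "C"
        seq[pre_end - 1 + t] = "G"
    weights = np.asarray(cfg.mghg_key_weights, dtype=float)
    variant = _MGHG_VARIANTS[int(rng.choice(len(_MGHG_VARIANTS),
                                            p=weights / weights.sum()))]
    mid_unpaired = variant[1] == "."
    seq[pre_end - 1 + 5] = variant[0]
    seq[pre_start - 1 - 5] = variant[0] if mid_unpaired else variant[1]
    # UG at -14/-13
    has_ug = bool(rng.random() < cfg.p_ug)
    if has_ug:
        seq[pre_start - 15] = "U"
        seq[pre_start - 14] = "G"
    elif seq[pre_start - 15] == "U" and seq[pre_start - 14] == "G":
        seq[pre_start - 14] = "A"
    # UGU in the first 4 loop nt
    loop_start = pre_start - 1 + m
    has_ugu = bool(rng.random() < cfg.p_ugu)
    if has_ugu:
        seq[loop_start:loop_start + 3] = list("UGU")
    else:
        while "UGU" in "".join(seq[loop_start:loop_start + 4]):
            seq[loop_start:loop_start + 4] = list(rng.choice(_BASES, size=4))
    # CNNC with first C 16-18 nt past the pre-miRNA 3' end
    has_cnnc = bool(rng.random() < cfg.p_cnnc)
    if has_cnnc:
        off = int(rng.integers(16, 19))
        seq[pre_end - 1 + off] = "C"
        seq[pre_end - 1 + off + 3] = "C"
    else:
        for off in range(16, 19):
            if seq[pre_end - 1 + off] == "C" and seq[pre_end - 1 + off + 3] == "C":
                seq[pre_end - 1 + off] = "A"

    # intended structure
    db = ["."] * n
    for i in range(m):
        if i in mm_offsets:
            continue
        db[pre_start - 1 + i] = "("
        db[pre_end - 1 - i] = ")"
    for t in range(1, b + 1):
        if t == 5 and mid_unpaired:
            continue
        db[pre_start - 1 - t] = "("
        db[pre_end - 1 + t] = ")"

    # large terminal loops may carry an inner stem (structured loop region);
    # the first 4 loop nt stay single-stranded for the UGU logic
    loop_stem = 0
    g5, g3 = 4, int(rng.integers(1, 3))
    ls_max = (loop - g5 - g3 - 3) // 2
    if ls_max >= 4 and rng.random() < cfg.p_loop_stem:
        loop_stem = int(min(rng.integers(4, 8), ls_max))
        for i in range(loop_stem):
            a = loop_start + g5 + i
            c = loop_start + loop - 1 - g3 - i
            x = str(rng.choice(_BASES, p=[0.0, 0.5, 0.5, 0.0]))
            seq[a], seq[c] = x, _COMP[x]
            db[a], db[c] = "(", ")"

    # optional small hairpin in the 3' distal flank, past the CNNC window
    distal_stem = 0
    if rng.random() < cfg.p_distal_stem:
        distal_stem = int(rng.integers(4, 8))
        d0 = pre_end - 1 + 23  # 0-based left end of the distal helix
        for i in range(distal_stem):
            a = d0 + i
            c = d0 + 2 * distal_stem + 3 - i
            x = str(rng.choice(_BASES, p=[0.0, 0.5, 0.5, 0.0]))
            seq[a], seq[c] = x, _COMP[x]
            db[a], db[c] = "(", ")"

    meta = {
        "arm_len": m, "loop_size": loop, "basal_stem": b,
        "n_mismatch": len(mm_offsets), "mghg_variant": variant,
        "loop_stem": loop_stem, "distal_stem": distal_stem,
        "has_ug": has_ug, "has_ugu": has_ugu, "has_cnnc": has_cnnc,
        "pre_start": pre_start, "pre_end": pre_end,
    }
    return "".join(seq), "".join(db), meta


def _true_domain_features(seq: str, db: str, meta: dict, model) -> dict:
    """Domain ΔG of the intended structure, attributed as the pipeline does."""
    pre_start, pre_end = meta["pre_start"], meta["pre_end"]
    m = meta["arm_len"]
    loop_region = [(pre_start + m, pre_end - m)]
    prox = [(pre_start - 12, pre_start - 1), (pre_end + 1, pre_end + 12)]
    distal = [(1, pre_start - 13), (pre_end + 13, len(seq))]
    dg_loop = region_energy(seq, db, loop_region, model)
    dg_pre = region_energy(seq, db, [(pre_start, pre_end)], model)
    return {
        "dg_loop_true": dg_loop,
        "dg_pre_true": dg_pre,
        "dg_duplex_true": dg_pre - dg_loop,
        "dg_proximal_true": region_energy(seq, db, prox, model),
        "dg_distal_true": region_energy(seq, db, distal, model),
        "dg_pri_true": evaluate_structure_energy(seq, db, model),
    }


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate hairpins, ground-truth features, gel lanes and expression."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    model = default_model()
    mghg_table = MghgTable.synthetic_default()

    records, feat_rows = [], []
    for idx in range(cfg.n_mirnas):
        seq, db, meta = _build_hairpin(rng, cfg)
        fam = (f"fam{int(rng.integers(max(cfg.n_mirnas // 3, 1)))}"
               if rng.random() < cfg.p_family else None)
        rid = f"syn-mir-{idx + 1}"
        m = meta["arm_len"]
        records.append(PriMiRNARecord(
            id=rid, species="syn", sequence=seq,
            mir5p_span=(meta["pre_start"], meta["pre_start"] + m - 1),
            mir3p_span=(meta["pre_end"] - m + 1, meta["pre_end"]),
            family=fam))
        row = {"mirna_id": rid, **meta}
        row.update(_true_domain_features(seq, db, meta, model))
        row["motif_count_true"] = int(meta["has_ug"]) + int(meta["has_ugu"]) \
            + int(meta["has_cnnc"])
        row["mghg_score_true"] = mghg_table.lookup(
            f"GC/{meta['mghg_variant']}/GC")
        feat_rows.append(row)
    truth = pd.DataFrame(feat_rows)

    z = {name: _zscore(truth[col].values) for name, col in [
        ("prox", "dg_proximal_true"), ("loop", "dg_loop_true"),
        ("duplex", "dg_duplex_true"), ("distal", "dg_distal_true"),
        ("motif", "motif_count_true"), ("mghg", "mghg_score_true")]}
    linear = (cfg.beta0
              + cfg.beta_prox * z["prox"] + cfg.beta_loop * z["loop"]
              + cfg.beta_duplex * z["duplex"] + cfg.beta_distal * z["distal"]
              + cfg.beta_motif * z["motif"] + cfg.beta_mghg * z["mghg"])

    lanes_rows = []
    for enzyme in ENZYMES:
        latent = linear + rng.normal(0.0, cfg.noise_sd, cfg.n_mirnas)
        raw = 1.0 / (1.0 + np.exp(-latent))
        truth[f"latent_log_eff_{enzyme}"] = latent
        truth[f"raw_ratio_{enzyme}"] = raw
        for batch in range(cfg.n_batches):
            lanes_rows.append(generate_control_lane(enzyme, batch))
            for rec, r in zip(records, raw):
                total = rng.lognormal(np.log(10000.0), 0.3)
                lanes_rows.append({
                    "substrate_id": rec.id, "enzyme": enzyme, "batch": batch,
                    "timepoint": np.nan,
                    "product_intensity": r * total,
                    "substrate_intensity": (1 - r) * total,
                    "control_flag": False,
                })
    lanes = pd.DataFrame(lanes_rows)

    # expression: NB around slope x relative Drosha efficiency (control=0.5)
    rel = 100.0 * truth["raw_ratio_Drosha"].values / 0.5
    mean_expr = np.maximum(cfg.expression_slope * rel / 100.0, 0.05)
    r_disp = cfg.expression_dispersion
    lam = rng.gamma(shape=r_disp, scale=mean_expr / r_disp)
    counts = rng.poisson(lam)
    frac5 = rng.beta(2.0, 2.0, cfg.n_mirnas)
    reads5 = rng.binomial(counts, frac5)
    reads3 = counts - reads5
    expr_rows = []
    for rec, r5, r3 in zip(records, reads5, reads3):
        t1_5 = rng.binomial(r5, 0.5)
        t1_3 = rng.binomial(r3, 0.5)
        expr_rows.append({"mirna_id": rec.id, "arm": "5p",
                          "tissue1": t1_5, "tissue2": r5 - t1_5})
        expr_rows.append({"mirna_id": rec.id, "arm": "3p",
                          "tissue1": t1_3, "tissue2": r3 - t1_3})
    expression = pd.DataFrame(expr_rows)

    return Cohort(records=records, true_features=truth, lanes=lanes,
                  expression=expression, mghg_table=mghg_table)


def generate_control_lane(enzyme: str, batch: int = 0) -> dict:
    """The designated normalization-control lane: raw ratio exactly 0.5."""
    return {
        "substrate_id": f"ctrl-{enzyme}", "enzyme": enzyme, "batch": batch,
        "timepoint": np.nan,
        "product_intensity": 5000.0, "substrate_intensity": 5000.0,
        "control_flag": True,
    }


def generate_timecourse_cohort(n_substrates: int = 20,
                               timepoints=(10.0, 30.0, 60.0, 90.0),
                               n_replicates: int = 2,
                               rate_sigma: float = 0.8,
                               noise_sd: float = 0.02,
                               seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Saturating cleavage kinetics: ratio(t) = plateau * (1 - exp(-k t)).

    Returns (lanes with timepoints, truth with per-substrate rate/plateau).
    Used to check that end-point assays rank substrates like full
    time-course areas under the curve.
    """
    rng = np.random.default_rng(seed)
    ks = rng.lognormal(np.log(0.02), rate_sigma, n_substrates)
    plateaus = rng.uniform(0.85, 0.95, n_substrates)
    rows = []
    for i in range(n_substrates):
        for t in timepoints:
            for _ in range(n_replicates):
                r = plateaus[i] * (1 - np.exp(-ks[i] * t))
                r = float(np.clip(r + rng.normal(0, noise_sd), 1e-4, 1 - 1e-4))
                total = rng.lognormal(np.log(10000.0), 0.3)
                rows.append({
                    "substrate_id": f"tc-{i + 1}", "enzyme": "Drosha",
                    "batch": 0, "timepoint": t,
                    "product_intensity": r * total,
                    "substrate_intensity": (1 - r) * total,
                    "control_flag": False,
                })
    truth = pd.DataFrame({
        "substrate_id": [f"tc-{i + 1}" for i in range(n_substrates)],
        "rate": ks, "plateau": plateaus,
    })
    return pd.DataFrame(rows), truth
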