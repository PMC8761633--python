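"""End-to-end orchestration: fold -> domains -> motifs -> quantification ->
statistics, with a serializable run configuration for reproducibility."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fold_engine import EnergyModel, default_model, fold_mfe
from .hairpin_domains import domain_deltaG
from .io_mirna import (ExpressionRecord, PriMiRNARecord, read_expression_table,
                       read_hairpins)
from .motif_scan import MghgTable, scan_motifs
from .quant_stats import (compute_relative_efficiencies, conserved_vs_unique,
                          correlation_report)

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["dg_loop", "dg_duplex", "dg_pre", "dg_proximal",
                   "dg_distal", "dg_pri", "mghg_score", "motif_count"]


@dataclass
class RunConfig:
    fasta: str | None = None
    annotation: str | None = None
    lanes: str | None = None
    expression: str | None = None
    mghg_table: str | None = None
    replicate_aggregation: str = "mean"
    tissue_combination: str = "sum"
    out_dir: str = "mirproc_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("fasta", "annotation", "lanes"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config missing required input {name!r}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def extract_features(records: list[PriMiRNARecord],
                     mghg_table: MghgTable | None = None,
                     model: EnergyModel | None = None) -> pd.DataFrame:
    """Fold every hairpin and compute domain ΔG plus motif columns.

    Records whose domains cannot be demarcated (e.g. the miR-5p never pairs
    in the predicted structure) keep their row with missing feature values.
    """
    model = model or default_model()
    rows = []
    for rec in records:
        row: dict = {"mirna_id": rec.id}
        try:
            pri_fold = fold_mfe(rec.sequence, model)
            part = domain_deltaG(rec, pri_fold, model)
            prof = scan_motifs(rec, part, pri_fold, mghg_table)
            row.update({
                "dg_loop": part.dg_loop, "dg_duplex": part.dg_duplex,
                "dg_pre": part.dg_pre, "dg_proximal": part.dg_proximal,
                "dg_distal": part.dg_distal, "dg_pri": part.dg_pri,
                "pre_start": part.pre_span[0], "pre_end": part.pre_span[1],
                "loop_start": part.terminal_loop_region[0],
                "loop_end": part.terminal_loop_region[1],
                "has_ug": prof.has_ug, "has_ugu": prof.has_ugu,
                "has_cnnc": prof.has_cnnc, "motif_count": prof.motif_count,
                "mghg_score": prof.mghg_score,
            })
        except ValueError as exc:
            logger.warning("feature extraction failed for %s: %s", rec.id, exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id")


def analyze_cohort(records: list[PriMiRNARecord], lanes: pd.DataFrame,
                   expression: list[ExpressionRecord] | None = None,
                   mghg_table: MghgTable | None = None,
                   model: EnergyModel | None = None,
                   replicate_aggregation: str = "mean") -> dict:
    """Full analysis of an assembled cohort; returns a report bundle."""
    features = extract_features(records, mghg_table, model)
    efficiencies = compute_relative_efficiencies(
        lanes, aggregate=replicate_aggregation)
    responses: dict[str, pd.Series] = {}
    for enzyme, grp in efficiencies.groupby("enzyme"):
        grp = grp[~grp["control_flag"]]
        responses[f"{enzyme} efficiency"] = pd.Series(
            grp["relative_efficiency"].values, index=grp["substrate_id"])
    expr_series = None
    if expression:
        expr_series = pd.Series({e.mirna_id: e.total for e in expression})
        responses["expression"] = expr_series

    numeric = features[[c for c in FEATURE_COLUMNS if c in features.columns]]
    numeric = numeric.astype(float)
    report = correlation_report(numeric, responses)

    profiles = []
    strata = {}
    if "motif_count" in features.columns:
        for resp_name, resp in responses.items():
            merged = pd.concat([features["motif_count"], resp], axis=1,
                               join="inner").dropna()
            groups = []
            for count in range(4):
                vals = merged[merged["motif_count"] == count].iloc[:, 1]
                groups.append({
                    "motif_count": count, "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else
                          (0.0 if len(vals) == 1 else np.nan)})
            strata[resp_name] = pd.DataFrame(groups)

    conservation = None
    if any(r.family for r in records):
        drosha = responses.get("Drosha efficiency")
        if drosha is not None:
            conservation = conserved_vs_unique(records, drosha.to_dict())

    return {
        "features": features,
        "efficiencies": efficiencies,
        "correlations": report,
        "motif_strata": strata,
        "conservation": conservation,
        "expression_totals": expr_series,
    }


def run_full(config: RunConfig) -> dict:
    """File-driven end-to-end run; writes every report to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump({**dataclasses.asdict(config),
                        "mirproc_version": __version__}, fh)
    records = read_hairpins(config.fasta, config.annotation)
    lanes = pd.read_csv(config.lanes, sep="\t")
    expression = (read_expression_table(config.expression,
                                        combine=config.tissue_combination)
                  if config.expression else None)
    mghg = (MghgTable.from_tsv(config.mghg_table) if config.mghg_table
            else None)
    bundle = analyze_cohort(records, lanes, expression, mghg,
                            replicate_aggregation=config.replicate_aggregation)
    bundle["features"].to_csv(out / "features.tsv", sep="\t")
    bundle["efficiencies"].to_csv(out / "efficiencies.tsv", sep="\t",
                                  index=False)
    bundle["correlations"].to_csv(out / "correlations.tsv", sep="\t",
                                  index=False)
    for resp, df in bundle["motif_strata"].items():
        safe = resp.replace(" ", "_")
        df.to_csv(out / f"motif_strata_{safe}.tsv", sep="\t", index=False)
    if bundle["conservation"] is not None:
        with open(out / "conservation.json", "w") as fh:
            json.dump(bundle["conservation"], fh, indent=2)
    return bundle
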