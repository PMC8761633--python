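"""Cleavage quantification and the rank statistics linking hairpin features
to processing efficiency and miRNA expression.

Band intensities from processing gels become raw cleavage ratios
(product / (product + remaining substrate)), which are normalized to the
control RNA carried in every experiment (control = 100) to give relative
cleavage efficiencies comparable across gels. Feature-response association
uses Spearman rank correlation (two-sided; t-approximation, exact
permutation at small n) and group comparisons use the two-tailed
Mann-Whitney U test (tie-corrected normal approximation, exact enumeration
when both groups are small). Missing values are dropped pairwise per
comparison, so reported N can differ between rows of the same report.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPEARMAN_EXACT_N = 9
MANNWHITNEY_EXACT_N = 8


@dataclass
class CleavageMeasurement:
    substrate_id: str
    enzyme: str
    product_intensity: float
    substrate_intensity: float
    timepoint: float | None = None
    raw_ratio: float | None = None
    relative_efficiency: float | None = None

    def __post_init__(self):
        if self.raw_ratio is None:
            self.raw_ratio = raw_cleavage_ratio(self.product_intensity,
                                                self.substrate_intensity)


@dataclass
class CorrelationResult:
    feature: str
    response: str
    n: int
    rho: float
    p_value: float


def raw_cleavage_ratio(product_intensity: float,
                       substrate_intensity: float) -> float:
    """Fraction of signal in cleavage products: product / (product + substrate)."""
    if product_intensity < 0 or substrate_intensity < 0:
        raise ValueError("negative band intensity")
    total = product_intensity + substrate_intensity
    if total == 0:
        raise ValueError("empty lane: both band intensities are zero")
    return product_intensity / total


def relative_efficiency(raw: float, control_raw: float) -> float:
    """Raw ratio rescaled so the control substrate is exactly 100."""
    if control_raw <= 0:
        raise ValueError("unusable control: control raw ratio is zero")
    return 100.0 * raw / control_raw


# --------------------------------------------------------------------------
# rank statistics
# --------------------------------------------------------------------------

def spearman(x, y, exact_n: int = SPEARMAN_EXACT_N,
             feature: str = "x", response: str = "y") -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Pairs with a missing value in either vector are dropped (N reflects the
    drop). The p-value uses the t-approximation except at n <= ``exact_n``,
    where the full permutation distribution is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry)[0])
    if n <= exact_n:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y)[1])
    return CorrelationResult(feature, response, n, rho, min(p, 1.0))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all orderings of one rank vector."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ys = ry[perms]
    rxc = rx - rx.mean()
    ysc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (ysc ** 2).sum(axis=1))
    rhos = (ysc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def mann_whitney_u(group_a, group_b,
                   exact_n: int = MANNWHITNEY_EXACT_N) -> float:
    """Two-tailed Mann-Whitney U p-value, symmetric under group swap.

    Exact enumeration of all labelings when both groups have at most
    ``exact_n`` members; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if a.size <= exact_n and b.size <= exact_n:
        return _mann_whitney_exact_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic")[1])


def _mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p: the fraction of labelings whose U deviates from
    its mean at least as much as the observed U (midranks handle ties)."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# --------------------------------------------------------------------------
# lane quantification
# --------------------------------------------------------------------------

def compute_relative_efficiencies(lanes: pd.DataFrame,
                                  aggregate: str = "mean") -> pd.DataFrame:
    """Turn a lane table into per-substrate relative cleavage efficiencies.

    Expected columns: substrate_id, enzyme, batch, timepoint (empty for
    end-point lanes), product_intensity, substrate_intensity, control_flag.
    End-point lanes are normalized within (enzyme, batch) to that batch's
    control lane; replicates are combined by ``aggregate`` (mean or median).
    """
    df = lanes.copy()
    if "batch" not in df.columns:
        df["batch"] = 0
    if "timepoint" in df.columns:
        df = df[df["timepoint"].isna()]
    rows = []
    for (enzyme, batch), grp in df.groupby(["enzyme", "batch"]):
        raws = grp.apply(lambda r: raw_cleavage_ratio(
            r["product_intensity"], r["substrate_intensity"]), axis=1)
        ctl = grp["control_flag"].astype(bool)
        if ctl.sum() == 0:
            raise ValueError(f"unusable control: no control lane for "
                             f"enzyme={enzyme} batch={batch}")
        control_raw = float(raws[ctl.values].mean())
        for (_, lane), raw in zip(grp.iterrows(), raws):
            rows.append({
                "substrate_id": lane["substrate_id"],
                "enzyme": enzyme,
                "batch": batch,
                "raw_ratio": float(raw),
                "relative_efficiency": relative_efficiency(raw, control_raw),
                "control_flag": bool(lane["control_flag"]),
            })
    eff = pd.DataFrame(rows)
    agg_fn = {"mean": "mean", "median": "median"}[aggregate]
    out = (eff.groupby(["substrate_id", "enzyme"], as_index=False)
              .agg(relative_efficiency=("relative_efficiency", agg_fn),
                   n_replicates=("relative_efficiency", "size"),
                   control_flag=("control_flag", "any")))
    return out


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def correlation_report(features: pd.DataFrame,
                       responses: dict[str, pd.Series]) -> pd.DataFrame:
    """Per (feature, response) Spearman N / rho / p table.

    ``features`` is indexed by miRNA id with one column per feature;
    ``responses`` maps response names (e.g. Drosha efficiency, expression)
    to Series indexed the same way. Constant features are flagged and get
    no correlation. A Benjamini-Hochberg column is included for reference;
    calls in the report are based on the raw p-values.
    """
    rows = []
    for resp_name, resp in responses.items():
        resp = pd.Series(resp, dtype=float)
        for feat in features.columns:
            joined = pd.concat([features[feat], resp], axis=1,
                               join="inner").dropna()
            n = len(joined)
            x, y = joined.iloc[:, 0].values, joined.iloc[:, 1].values
            if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"feature": feat, "response": resp_name, "n": n,
                             "rho": np.nan, "p": np.nan, "flag": "constant"})
                continue
            res = spearman(x, y, feature=feat, response=resp_name)
            rows.append({"feature": feat, "response": resp_name, "n": res.n,
                         "rho": res.rho, "p": res.p_value, "flag": ""})
    report = pd.DataFrame(rows)
    report["p_bh"] = _benjamini_hochberg(report["p"].values)
    return report


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def conserved_vs_unique(records, values: dict[str, float]) -> dict:
    """Compare a response between conserved miRNAs (family with >= 2 members
    among the given records) and unique ones (singleton or no family)."""
    fam_sizes: dict[str, int] = {}
    for r in records:
        if r.family:
            fam_sizes[r.family] = fam_sizes.get(r.family, 0) + 1
    cons, uniq = [], []
    for r in records:
        if r.id not in values or values[r.id] is None:
            continue
        v = float(values[r.id])
        if r.family and fam_sizes[r.family] >= 2:
            cons.append(v)
        else:
            uniq.append(v)
    out = {
        "conserved": _group_summary(cons),
        "unique": _group_summary(uniq),
        "p": None,
    }
    if not cons or not uniq:
        logger.warning("conserved/unique comparison skipped: empty group")
        return out
    out["p"] = mann_whitney_u(cons, uniq)
    return out


def _group_summary(vals: list[float]) -> dict:
    arr = np.asarray(vals, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()) if arr.size else math.nan,
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else
              (0.0 if arr.size == 1 else math.nan),
    }


def timecourse_summary(lanes: pd.DataFrame) -> pd.DataFrame:
    """Per (substrate, timepoint) mean/SD of the raw cleavage ratio, plus a
    per-substrate flag for monotone nondecreasing mean ratios over time."""
    df = lanes[lanes["timepoint"].notna()].copy()
    if df.empty:
        raise ValueError("no time-course lanes (timepoint column empty)")
    df["raw_ratio"] = [
        raw_cleavage_ratio(p, s) for p, s in
        zip(df["product_intensity"], df["substrate_intensity"])]
    summary = (df.groupby(["substrate_id", "timepoint"], as_index=False)
                 .agg(mean_ratio=("raw_ratio", "mean"),
                      sd_ratio=("raw_ratio", lambda v: v.std(ddof=1)
                                if len(v) > 1 else 0.0),
                      n=("raw_ratio", "size")))
    flags = []
    for sid, grp in summary.groupby("substrate_id"):
        grp = grp.sort_values("timepoint")
        if len(grp) < 2:
            raise ValueError(f"{sid}: need >= 2 timepoints")
        flags.append({"substrate_id": sid,
                      "monotone": bool(np.all(np.diff(grp["mean_ratio"]) >= 0))})
    return summary.merge(pd.DataFrame(flags), on="substrate_id")
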