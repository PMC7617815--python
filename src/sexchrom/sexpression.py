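"""Allele-aware expression bias on the sex chromosomes.

Works on allele-resolved counts (X copy vs Y copy per gene per individual,
e.g. from diagnostic-SNP read assignment or the simulator): CPM
normalization, paired X-vs-Y expression tests within males, per-gene
female:male bias, and Welch tests of bias between chromosome regions.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_cpm",
    "xy_expression_test",
    "bias_summaries",
    "region_bias_compare",
]

_REQUIRED = {"gene_id", "sample_id", "sex", "counts_x", "counts_y", "library_size"}


def _check(records: pd.DataFrame) -> None:
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    if (records["library_size"] <= 0).any():
        raise ValueError("library_size must be > 0")


def normalize_cpm(records: pd.DataFrame) -> pd.DataFrame:
    """Add cpm_x / cpm_y / cpm_total columns (counts × 1e6 / library size)."""
    _check(records)
    out = records.copy()
    scale = 1e6 / out["library_size"]
    out["cpm_x"] = out["counts_x"] * scale
    out["cpm_y"] = out["counts_y"] * scale
    out["cpm_total"] = out["cpm_x"] + out["cpm_y"]
    return out


def xy_expression_test(records: pd.DataFrame) -> dict[str, float]:
    """Paired t-test of X-copy vs Y-copy expression within males.

    Per gene, male CPM of the X and Y copies are averaged over samples; the
    two-sided paired t-test is applied across genes (>= 3 required).
    Identical X and Y values give t = 0, p = 1.
    """
    cpm = normalize_cpm(records)
    males = cpm[cpm["sex"] == "M"]
    per_gene = males.groupby("gene_id")[["cpm_x", "cpm_y"]].mean()
    n = len(per_gene)
    if n < 3:
        raise ValueError(f"paired test requires >= 3 genes with male data, got {n}")
    diffs = per_gene["cpm_x"] - per_gene["cpm_y"]
    if np.allclose(diffs.std(ddof=1), 0):
        t_stat, p = (0.0, 1.0) if np.allclose(diffs, 0) else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(per_gene["cpm_x"], per_gene["cpm_y"])
    return {"t": float(t_stat), "p": float(p), "n": n}


def bias_summaries(records: pd.DataFrame, regions: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-gene female:male expression bias summary.

    Total (X+Y in males, X+X in females) CPM is averaged by sex per gene;
    log2_bias = log2(female/male) is defined only when both means are
    positive. xy_ratio_male is the Y share of male allele counts.
    """
    cpm = normalize_cpm(records)
    if regions is not None:
        cpm = cpm.assign(region=cpm["gene_id"].map(regions))
    elif "region" not in cpm.columns:
        cpm = cpm.assign(region=None)
    rows = []
    for gene, sub in cpm.groupby("gene_id"):
        f = sub.loc[sub["sex"] == "F", "cpm_total"].mean()
        m = sub.loc[sub["sex"] == "M", "cpm_total"].mean()
        male = sub[sub["sex"] == "M"]
        cx, cy = male["counts_x"].sum(), male["counts_y"].sum()
        rows.append(
            {
                "gene_id": gene,
                "region": sub["region"].iloc[0],
                "mean_female_cpm": f,
                "mean_male_cpm": m,
                "log2_bias": np.log2(f / m) if f > 0 and m > 0 else np.nan,
                "xy_ratio_male": cy / (cx + cy) if (cx + cy) > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def region_bias_compare(bias: pd.DataFrame, min_genes: int = 3) -> pd.DataFrame:
    """Welch two-sample t-tests of log2 female:male bias between region pairs.

    Region pairs where either side has fewer than ``min_genes`` genes with a
    defined bias are skipped with a warning. Returns t, Welch df and p per
    pair.
    """
    groups = {
        region: sub["log2_bias"].dropna().to_numpy(float)
        for region, sub in bias.groupby("region")
    }
    rows = []
    for ra, rb in combinations(sorted(groups), 2):
        a, b = groups[ra], groups[rb]
        if len(a) < min_genes or len(b) < min_genes:
            warnings.warn(f"region pair {ra}:{rb} skipped (<{min_genes} genes)")
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {"region_a": ra, "region_b": rb, "mean_a": a.mean(), "mean_b": b.mean(),
             "t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
             "n_a": len(a), "n_b": len(b)}
        )
    return pd.DataFrame(rows)
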