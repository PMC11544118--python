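"""Clinicopathological / immune-fraction associations and qPCR arithmetic.

Associations between hub expression and clinical factors dispatch on the
number of factor levels: two levels use the Wilcoxon rank-sum test, more
use Kruskal-Wallis.  Immune cell fractions are compared between high and
low expression groups (one rank-sum test per cell type, BH-adjusted
across the 22 types) and correlated with expression by Spearman.

Relative qPCR quantification follows Livak: 2^-dCt normalises the mean
target Ct of each sample's replicates to the reference gene, and
2^-ddCt additionally normalises to the mean dCt of a control condition,
so control fold changes centre at one by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rankstats import (TestResult, bh_adjust, kruskal_wallis, spearman,
                        wilcoxon_rank_sum, wilcoxon_signed_rank)

__all__ = [
    "clinical_association", "fraction_group_compare",
    "fraction_expression_correlation", "delta_ct", "delta_delta_ct",
    "paired_expression_compare", "validate_fraction_table",
]


def validate_fraction_table(fractions: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-type x sample fraction table's simplex invariants."""
    vals = fractions.to_numpy(float)
    if (vals < -1e-9).any():
        raise ValueError("fractions must be non-negative")
    sums = vals.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = fractions.columns[np.argmax(np.abs(sums - 1.0))]
        raise ValueError(f"fractions of sample {bad!r} do not sum to 1")
    return fractions


def clinical_association(values: pd.Series, factor: pd.Series) -> dict:
    """Expression vs a clinical factor: rank-sum (2 levels) or KW (>2).

    Returns the test result plus per-level medians and sizes.
    """
    values = pd.Series(values).astype(float)
    factor = pd.Series(factor).reindex(values.index)
    keep = factor.notna() & values.notna()
    values, factor = values[keep], factor[keep]
    levels = sorted(factor.unique(), key=str)
    if len(levels) < 2:
        raise ValueError("factor must have at least two non-empty levels")
    groups = [values[factor == lev].to_numpy(float) for lev in levels]
    if len(levels) == 2:
        test = wilcoxon_rank_sum(groups[0], groups[1])
    else:
        test = kruskal_wallis(groups)
    medians = {str(lev): float(np.median(g)) for lev, g in zip(levels, groups)}
    sizes = {str(lev): int(g.size) for lev, g in zip(levels, groups)}
    return {"test": test, "levels": [str(l) for l in levels],
            "medians": medians, "sizes": sizes}


def fraction_group_compare(fractions: pd.DataFrame,
                           groups: pd.Series) -> pd.DataFrame:
    """Rank-sum test per cell type between high and low expression groups.

    BH adjustment spans the cell types of this one comparison (the
    smallest defensible family); ``higher_in`` is the group with the
    larger median fraction.
    """
    validate_fraction_table(fractions)
    groups = pd.Series(groups)
    shared = fractions.columns.intersection(groups.index)
    groups = groups.loc[shared]
    high = shared[groups == "high"]
    low = shared[groups == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for cell in fractions.index:
        a = fractions.loc[cell, high].to_numpy(float)
        b = fractions.loc[cell, low].to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            test = TestResult(statistic=np.nan, p=1.0, method="degenerate")
            higher = "tie"
        else:
            test = wilcoxon_rank_sum(a, b)
            med_h, med_l = np.median(a), np.median(b)
            higher = "high" if med_h > med_l else ("low" if med_l > med_h else "tie")
        rows.append({"cell_type": cell, "statistic": test.statistic,
                     "p": test.p, "higher_in": higher})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out.attrs["bh_family"] = f"{len(out)} cell types, one group comparison"
    return out


def fraction_expression_correlation(fractions: pd.DataFrame,
                                    values: pd.Series) -> pd.DataFrame:
    """Spearman of each cell type's fraction with one gene's expression."""
    validate_fraction_table(fractions)
    values = pd.Series(values).astype(float)
    shared = fractions.columns.intersection(values.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for cell in fractions.index:
        res = spearman(fractions.loc[cell, shared].to_numpy(float),
                       values.loc[shared].to_numpy(float))
        rows.append({"cell_type": cell, "rho": res.rho, "p": res.p,
                     "n": res.n})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["adj_p"] = bh_adjust(np.nan_to_num(out["p"].to_numpy(), nan=1.0))
    out.attrs["bh_family"] = f"{len(out)} cell types, one expression correlation"
    return out


# ---------------------------------------------------------------------------
# qPCR relative quantification


def _mean_ct(ct: pd.DataFrame, gene: str) -> pd.Series:
    sub = ct[ct["gene"] == gene]
    return sub.groupby("sample_id")["ct"].mean()


def delta_ct(ct: pd.DataFrame, target_gene: str,
             reference_gene: str) -> pd.Series:
    """Per-sample 2^-dCt of a target gene against the reference gene.

    dCt is the difference of replicate-mean Ct values (target minus
    reference) within each sample.
    """
    for col in ("sample_id", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    target = _mean_ct(ct, target_gene)
    reference = _mean_ct(ct, reference_gene)
    if target.empty:
        raise ValueError(f"no wells for target gene {target_gene!r}")
    missing = target.index.difference(reference.index)
    if len(missing):
        raise ValueError(f"sample {missing[0]!r} lacks the reference gene")
    dct = target - reference.loc[target.index]
    return np.power(2.0, -dct).rename(f"2^-dCt[{target_gene}]")


def delta_delta_ct(ct: pd.DataFrame, target_gene: str, reference_gene: str,
                   control_condition: str) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes relative to a control condition.

    ddCt subtracts the control-condition mean dCt, so the control group's
    folds have geometric mean one by construction.
    """
    if "condition" not in ct.columns:
        raise ValueError("Ct table lacks a 'condition' column")
    rel = delta_ct(ct, target_gene, reference_gene)
    dct = -np.log2(rel)
    cond = ct[["sample_id", "condition"]].drop_duplicates().set_index("sample_id")
    cond = cond["condition"].reindex(dct.index)
    control = dct[cond == control_condition]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} is empty")
    ddct = dct - control.mean()
    return pd.DataFrame({
        "condition": cond,
        "fold": np.power(2.0, -ddct),
    })


def paired_expression_compare(tumor: pd.Series, adjacent: pd.Series,
                              pair_ids=None) -> dict:
    """Matched tumor vs adjacent comparison (Wilcoxon signed-rank).

    When ``pair_ids`` is given, both Series are indexed by sample and the
    pairing maps each sample to its partner label; otherwise the Series
    are assumed aligned by position/index.
    """
    tumor = pd.Series(tumor).astype(float)
    adjacent = pd.Series(adjacent).astype(float)
    if pair_ids is not None:
        t_pairs = pd.Series(pair_ids).reindex(tumor.index)
        a_pairs = pd.Series(pair_ids).reindex(adjacent.index)
        if t_pairs.isna().any() or a_pairs.isna().any():
            raise ValueError("unmatched pair ids")
        tumor = tumor.groupby(t_pairs).mean().sort_index()
        adjacent = adjacent.groupby(a_pairs).mean().sort_index()
        if not tumor.index.equals(adjacent.index):
            raise ValueError("unmatched pair ids")
    elif len(tumor) != len(adjacent):
        raise ValueError("unmatched pair ids")
    test = wilcoxon_signed_rank(tumor.to_numpy(), adjacent.to_numpy())
    diff = float(np.median(tumor.to_numpy() - adjacent.to_numpy()))
    direction = "tumor_higher" if diff > 0 else (
        "adjacent_higher" if diff < 0 else "tie")
    return {"test": test, "n_pairs": int(len(tumor)),
            "median_difference": diff, "direction": direction}
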