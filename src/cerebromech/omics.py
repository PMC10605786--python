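"""Label-free proteomics statistics: collagen composition and differential
expression.

Collagen composition: each quantified collagen type's abundance as a
percentage of the summed collagen abundance per sample, compared between
groups by two-sided Welch t-tests on the percentages with Bonferroni
correction over the number of quantified types.

Differential expression: per protein, zeros imputed by half the minimum
observed abundance for that protein, log2 transform, two-sided Welch
t-test between groups, Benjamini-Hochberg adjustment across tested
proteins; significance at FDR < 0.05.  Proteins missing in more than half
the samples of a group are flagged and excluded from testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_ALPHA = 0.05


class OmicsError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Protein x sample abundance matrix with group labels and collagen
    annotation.

    ``data``: DataFrame, rows = proteins, columns = samples, non-negative.
    ``groups``: Series mapping sample -> group label.
    ``collagen_type``: Series mapping protein -> collagen type (e.g. "I"),
    NaN for non-collagen proteins.
    """

    data: pd.DataFrame
    groups: pd.Series
    collagen_type: pd.Series

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise OmicsError("abundances must be non-negative")
        missing = set(self.data.columns) - set(self.groups.index)
        if missing:
            raise OmicsError(f"samples without a group label: {sorted(missing)}")

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == label]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.data.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class CompositionResult:
    percentages: pd.DataFrame  # collagen types x samples, sums to 100 per sample
    summary: pd.DataFrame  # per type: group means/SDs, raw p, adjusted p, significance
    excluded_samples: list[str]


def collagen_composition(
    table: AbundanceTable, group_a: str | None = None, group_b: str | None = None
) -> CompositionResult:
    """Relative collagen composition per sample and its group comparison.

    Per sample, collagen-type abundances (summed over proteins of the same
    type) are expressed as percentages of total collagen abundance.
    Samples with zero total collagen are excluded with a warning.
    """
    is_col = table.collagen_type.notna()
    if not is_col.any():
        raise OmicsError("no collagen-annotated proteins in the table")
    col_data = table.data.loc[is_col.index[is_col]]
    by_type = col_data.groupby(table.collagen_type.loc[col_data.index]).sum()

    totals = by_type.sum(axis=0)
    excluded = [s for s in by_type.columns if totals[s] <= 0]
    if excluded:
        warnings.warn(f"samples with zero total collagen excluded: {excluded}", stacklevel=2)
    kept = [s for s in by_type.columns if s not in excluded]
    pct = by_type[kept].div(totals[kept], axis=1) * 100.0

    if group_a is None or group_b is None:
        labels = table.group_labels
        if len(labels) != 2:
            raise OmicsError("specify group_a/group_b when labels are not exactly two")
        group_a, group_b = labels

    sa = [s for s in table.group_samples(group_a) if s in kept]
    sb = [s for s in table.group_samples(group_b) if s in kept]
    rows = []
    for ctype in pct.index:
        va, vb = pct.loc[ctype, sa].to_numpy(float), pct.loc[ctype, sb].to_numpy(float)
        if len(va) >= 2 and len(vb) >= 2:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "collagen_type": ctype,
                f"mean_{group_a}": va.mean() if len(va) else np.nan,
                f"sd_{group_a}": va.std(ddof=1) if len(va) >= 2 else np.nan,
                f"mean_{group_b}": vb.mean() if len(vb) else np.nan,
                f"sd_{group_b}": vb.std(ddof=1) if len(vb) >= 2 else np.nan,
                "pvalue": p,
            }
        )
    summary = pd.DataFrame(rows).set_index("collagen_type")
    # Bonferroni family = number of quantified types actually tested
    m = int(summary["pvalue"].notna().sum())
    summary["pvalue_bonferroni"] = np.minimum(summary["pvalue"] * m, 1.0)
    summary["significant"] = summary["pvalue_bonferroni"] < 0.05
    return CompositionResult(percentages=pct, summary=summary, excluded_samples=excluded)


def differential_expression(
    table: AbundanceTable,
    group_a: str | None = None,
    group_b: str | None = None,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-protein log2 fold change and BH-adjusted Welch t-test p-values.

    Returns a DataFrame indexed by protein with columns ``log2fc`` (group_b
    minus group_a), ``pvalue``, ``fdr``, ``significant`` and ``tested``.
    Untested (too-missing) proteins carry NaN statistics.
    """
    if group_a is None or group_b is None:
        labels = table.group_labels
        if len(labels) != 2:
            raise OmicsError("specify group_a/group_b when labels are not exactly two")
        group_a, group_b = labels
    sa, sb = table.group_samples(group_a), table.group_samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise OmicsError("need >=2 samples per group for differential expression")

    out = pd.DataFrame(index=table.data.index)
    out["tested"] = True
    log2fc, pvals = [], []
    for prot, row in table.data.iterrows():
        va, vb = row[sa].to_numpy(float), row[sb].to_numpy(float)
        frac_zero_a = np.mean(va == 0)
        frac_zero_b = np.mean(vb == 0)
        if frac_zero_a > max_missing_frac or frac_zero_b > max_missing_frac:
            out.loc[prot, "tested"] = False
            log2fc.append(np.nan)
            pvals.append(np.nan)
            continue
        pos = row[sa + sb].to_numpy(float)
        pos = pos[pos > 0]
        half_min = pos.min() / 2.0  # tested proteins always have a positive value
        la = np.log2(np.where(va > 0, va, half_min))
        lb = np.log2(np.where(vb > 0, vb, half_min))
        log2fc.append(lb.mean() - la.mean())
        if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
            pvals.append(1.0)  # identical constant groups: no evidence
        else:
            pvals.append(float(stats.ttest_ind(la, lb, equal_var=False).pvalue))
    out["log2fc"] = log2fc
    out["pvalue"] = pvals

    tested = out["tested"] & out["pvalue"].notna()
    fdr = np.full(len(out), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = multipletests(out.loc[tested, "pvalue"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < FDR_ALPHA
    return out


def read_abundance_csv(abundance_path, annotation_path) -> AbundanceTable:
    """Load an abundance matrix CSV (rows proteins, columns samples) plus an
    annotation CSV with ``protein,collagen_type`` and ``sample,group`` blocks.

    The annotation file has columns ``kind,key,value`` with kind in
    {protein, sample}; protein rows map protein -> collagen type ("" for
    non-collagen), sample rows map sample -> group.
    """
    data = pd.read_csv(abundance_path, index_col=0)
    ann = pd.read_csv(annotation_path, dtype=str).fillna("")
    prot = ann[ann["kind"] == "protein"].set_index("key")["value"].replace("", np.nan)
    samp = ann[ann["kind"] == "sample"].set_index("key")["value"]
    collagen = prot.reindex(data.index)
    return AbundanceTable(data=data, groups=samp, collagen_type=collagen)
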