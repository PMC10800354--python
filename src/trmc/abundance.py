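"""tRNA abundance quantification and the differential-expression rule.

Counts are weighted sums of alignment hits per isodecoder group,
normalized to counts per million mapped reads (CPM).  The published
pipeline delegates differential testing to a negative-binomial engine;
here only its stated decision rule is reproduced — significant when
p <= 0.05 AND fold change >= 1.5 in either direction (both boundaries
inclusive) — on top of a simple documented test: a two-proportion exact
test on pooled counts when either side has fewer than 3 replicates,
otherwise Welch's t-test on log2 CPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alnpile import AlignmentHit

__all__ = ["TrnaCountTable", "quantify", "de_test", "class_compare"]

PSEUDOCOUNT = 0.5


@dataclass
class TrnaCountTable:
    """Weighted counts per isodecoder group x library."""

    counts: pd.DataFrame  # index: group, columns: library ids
    library_sizes: pd.Series  # mapped-read totals per library

    @property
    def cpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.library_sizes


def quantify(hits_by_library: Mapping[str, Iterable[AlignmentHit]]) -> TrnaCountTable:
    """Weighted per-group read counts and CPM normalization.

    Each library's weighted counts sum to its mapped-read total (a read
    split over k groups contributes 1/k to each).
    """
    columns: dict[str, pd.Series] = {}
    for lib, hits in hits_by_library.items():
        acc: dict[str, float] = {}
        for h in hits:
            acc[h.ref_id] = acc.get(h.ref_id, 0.0) + h.weight
        if not acc or sum(acc.values()) == 0:
            raise ValueError(f"library {lib!r} has zero mapped reads")
        columns[lib] = pd.Series(acc)
    counts = pd.DataFrame(columns).fillna(0.0).sort_index()
    sizes = counts.sum(axis=0)
    return TrnaCountTable(counts, sizes)


def de_test(
    table: TrnaCountTable,
    control_ids: Sequence[str],
    kd_ids: Sequence[str],
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Apply the fold-change / p-value rule per isodecoder group.

    fold_change = (mean KD CPM + 0.5) / (mean control CPM + 0.5);
    is_DE is True iff p <= alpha and (FC >= threshold or
    FC <= 1/threshold), boundaries inclusive.
    """
    if not control_ids or not kd_ids:
        raise ValueError("need at least one library per side")
    for lib in (*control_ids, *kd_ids):
        if lib not in table.counts.columns:
            raise KeyError(f"library {lib!r} absent from count table")
    cpm = table.cpm
    mean_ctrl = cpm[list(control_ids)].mean(axis=1)
    mean_kd = cpm[list(kd_ids)].mean(axis=1)
    fc = (mean_kd + PSEUDOCOUNT) / (mean_ctrl + PSEUDOCOUNT)

    few_reps = min(len(control_ids), len(kd_ids)) < 3
    pvals = np.ones(len(fc))
    if few_reps:
        n_ctrl = int(round(table.library_sizes[list(control_ids)].sum()))
        n_kd = int(round(table.library_sizes[list(kd_ids)].sum()))
        c_ctrl = table.counts[list(control_ids)].sum(axis=1).round().astype(int)
        c_kd = table.counts[list(kd_ids)].sum(axis=1).round().astype(int)
        for i, g in enumerate(fc.index):
            tab = [
                [c_kd[g], n_kd - c_kd[g]],
                [c_ctrl[g], n_ctrl - c_ctrl[g]],
            ]
            pvals[i] = stats.fisher_exact(tab)[1]
        method = "pooled two-proportion exact test"
    else:
        log_ctrl = np.log2(cpm[list(control_ids)] + PSEUDOCOUNT)
        log_kd = np.log2(cpm[list(kd_ids)] + PSEUDOCOUNT)
        res = stats.ttest_ind(log_kd, log_ctrl, axis=1, equal_var=False)
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        method = "Welch t-test on log2 CPM"

    df = pd.DataFrame(
        {
            "isodecoder_group": fc.index,
            "mean_cpm_control": mean_ctrl.to_numpy(),
            "mean_cpm_kd": mean_kd.to_numpy(),
            "fold_change": fc.to_numpy(),
            "p_value": pvals,
        }
    )
    df["is_DE"] = (df["p_value"] <= alpha) & (
        (df["fold_change"] >= fc_threshold)
        | (df["fold_change"] <= 1.0 / fc_threshold)
    )
    df.attrs["test"] = method
    return df


def class_compare(
    table: TrnaCountTable,
    ac4c_groups: Sequence[str],
    control_ids: Sequence[str],
    kd_ids: Sequence[str],
) -> dict:
    """Compare KD/control fold changes between modified and unmodified
    tRNA classes with a rank-based two-sample test."""
    ac4c = set(ac4c_groups)
    unknown = ac4c - set(table.counts.index)
    if unknown:
        raise KeyError(f"unknown groups in ac4c set: {sorted(unknown)}")
    cpm = table.cpm
    logfc = np.log2(
        (cpm[list(kd_ids)].mean(axis=1) + PSEUDOCOUNT)
        / (cpm[list(control_ids)].mean(axis=1) + PSEUDOCOUNT)
    )
    in_class = logfc.index.isin(ac4c)
    fc_mod = logfc[in_class]
    fc_unmod = logfc[~in_class]
    if len(fc_mod) == 0 or len(fc_unmod) == 0:
        raise ValueError("one of the tRNA classes is empty")
    if fc_mod.nunique() == 1 and fc_unmod.nunique() == 1 and (
        fc_mod.iloc[0] == fc_unmod.iloc[0]
    ):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(fc_mod, fc_unmod, alternative="two-sided")[1])
    return {
        "mean_log2fc_ac4c": float(fc_mod.mean()),
        "mean_log2fc_other": float(fc_unmod.mean()),
        "difference": float(fc_mod.mean() - fc_unmod.mean()),
        "p_value": p,
        "log2fc": logfc,
    }
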