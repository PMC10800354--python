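"""ac4C site calling from the three-condition chemistry design.

A position is a candidate when the reference base is C and all three
condition tracks (reduced, deacetylated, mock) cover it at
``min_depth``.  Evidence is a one-sided exact conditional test on the
2x2 table of (mismatch, match) counts, reduced vs deacetylated — the
deacetylated library shares the reduction treatment minus the acetyl
group and is therefore the matched negative control; the mock track
enters through the effect-size gate only.  Benjamini-Hochberg control
is applied across all candidates, and a call additionally requires the
dominant alternative base to be T (the chemistry's signature), a
minimum reduced-condition rate, and a minimum rate excess over the
larger of the two controls.

The same exact-test machinery, two-sided, powers differential
modification between biological conditions at an externally supplied
site list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .refset import ReferenceRecord, records_by_id
from .tableio import write_table

__all__ = [
    "CallParams",
    "call_sites",
    "diff_modification",
    "summarize_sites",
    "export_bed",
]


@dataclass(frozen=True)
class CallParams:
    """Decision-rule thresholds (toolkit defaults; tune via config)."""

    min_depth: float = 50.0
    min_rate: float = 0.05
    min_delta: float = 0.05
    fdr: float = 0.05


def _counts(track: pd.DataFrame) -> pd.DataFrame:
    """Integer (mismatch, match) counts per (ref, pos) from a rate track."""
    depth = track["depth"].round().astype(int)
    ref_count = track["ref_count"].round().astype(int)
    out = track[["ref", "pos", "ref_base"]].copy()
    out["depth"] = depth
    out["mismatch"] = (depth - ref_count).clip(lower=0)
    out["match"] = depth - out["mismatch"]
    out["rate"] = track["misinc_rate"]
    out["dominant_alt"] = track["dominant_alt"]
    return out


def _fisher(mm1, n1, mm2, n2, alternative: str) -> float:
    table = [[mm1, n1 - mm1], [mm2, n2 - mm2]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def call_sites(
    track_reduced: pd.DataFrame,
    track_deacetylated: pd.DataFrame,
    track_mock: pd.DataFrame,
    params: CallParams = CallParams(),
) -> pd.DataFrame:
    """Call modified C positions from the three condition rate tracks.

    Returns one row per C position covered in all three tracks with
    per-condition rates/depths, p and BH q values, and a verdict in
    {called, not_called, low_coverage}; sorted by (ref, pos).
    """
    keys = ["ref", "pos"]
    tracks = {
        "reduced": _counts(track_reduced),
        "deacetylated": _counts(track_deacetylated),
        "mock": _counts(track_mock),
    }
    refs = {tuple(sorted(t["ref"].unique())) for t in tracks.values()}
    if len(refs) != 1:
        raise ValueError("the three condition tracks cover different reference sets")

    merged = tracks["reduced"].rename(
        columns={
            "depth": "depth_reduced",
            "mismatch": "mm_reduced",
            "match": "match_reduced",
            "rate": "rate_reduced",
        }
    )
    for cond in ("deacetylated", "mock"):
        sub = tracks[cond][keys + ["depth", "mismatch", "rate"]].rename(
            columns={
                "depth": f"depth_{cond}",
                "mismatch": f"mm_{cond}",
                "rate": f"rate_{cond}",
            }
        )
        merged = merged.merge(sub, on=keys, how="inner")

    merged = merged[merged["ref_base"] == "C"].reset_index(drop=True)
    covered = (
        (merged["depth_reduced"] >= params.min_depth)
        & (merged["depth_deacetylated"] >= params.min_depth)
        & (merged["depth_mock"] >= params.min_depth)
    )

    pvals = np.full(len(merged), np.nan)
    cand = merged[covered]
    for i, row in cand.iterrows():
        pvals[i] = _fisher(
            row["mm_reduced"],
            row["depth_reduced"],
            row["mm_deacetylated"],
            row["depth_deacetylated"],
            "greater",
        )
    merged["p_value"] = pvals
    qvals = np.full(len(merged), np.nan)
    mask = covered.to_numpy()
    if mask.any():
        qvals[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    merged["q_value"] = qvals

    delta = merged["rate_reduced"] - np.maximum(
        merged["rate_deacetylated"], merged["rate_mock"]
    )
    called = (
        mask
        & (merged["q_value"] <= params.fdr)
        & (merged["rate_reduced"] >= params.min_rate)
        & (delta >= params.min_delta)
        & (merged["dominant_alt"] == "T")
    )
    merged["verdict"] = np.where(
        called, "called", np.where(mask, "not_called", "low_coverage")
    )
    cols = [
        "ref",
        "pos",
        "ref_base",
        "rate_reduced",
        "rate_deacetylated",
        "rate_mock",
        "depth_reduced",
        "depth_deacetylated",
        "depth_mock",
        "dominant_alt",
        "p_value",
        "q_value",
        "verdict",
    ]
    return merged[cols].sort_values(["ref", "pos"]).reset_index(drop=True)


def diff_modification(
    track_control: pd.DataFrame,
    track_kd: pd.DataFrame,
    site_list: Sequence[tuple[str, int]],
    params: CallParams = CallParams(),
) -> pd.DataFrame:
    """Two-sided exact test of rate change at known sites.

    BH correction runs across the adequately covered sites only; sites
    under ``min_depth`` in either condition are flagged low_coverage and
    excluded from the family.
    """
    ctrl = _counts(track_control).set_index(["ref", "pos"])
    kd = _counts(track_kd).set_index(["ref", "pos"])
    rows = []
    for ref, pos in site_list:
        key = (ref, pos)
        if key not in ctrl.index or key not in kd.index:
            raise KeyError(f"site {ref}:{pos} missing from a rate track")
        c, k = ctrl.loc[key], kd.loc[key]
        ok = c["depth"] >= params.min_depth and k["depth"] >= params.min_depth
        p = (
            _fisher(k["mismatch"], k["depth"], c["mismatch"], c["depth"], "two-sided")
            if ok
            else np.nan
        )
        rows.append(
            {
                "ref": ref,
                "pos": pos,
                "rate_control": c["rate"],
                "rate_kd": k["rate"],
                "depth_control": c["depth"],
                "depth_kd": k["depth"],
                "p_value": p,
                "low_coverage": not ok,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    tested = ~df["low_coverage"]
    if tested.any():
        df.loc[tested, "q_value"] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    direction = np.where(
        df["low_coverage"],
        "low_coverage",
        np.where(
            (df["q_value"] <= params.fdr) & (df["rate_kd"] < df["rate_control"]),
            "decreased",
            np.where(
                (df["q_value"] <= params.fdr) & (df["rate_kd"] > df["rate_control"]),
                "increased",
                "unchanged",
            ),
        ),
    )
    df["direction"] = direction
    return df


def summarize_sites(
    calls: pd.DataFrame, references: Sequence[ReferenceRecord]
) -> dict:
    """Counts of called sites / isodecoders / isoacceptors, with per-
    isoacceptor site lists."""
    called = calls[calls["verdict"] == "called"]
    group_rec = {r.isodecoder_group: r for r in references}
    by_iso: dict[str, list[tuple[str, int]]] = {}
    for _, row in called.iterrows():
        rec = group_rec.get(row["ref"])
        iso = rec.isoacceptor if rec is not None else row["ref"]
        by_iso.setdefault(iso, []).append((row["ref"], int(row["pos"])))
    return {
        "n_sites": int(len(called)),
        "n_isodecoders": int(called["ref"].nunique()),
        "n_isoacceptors": len(by_iso),
        "sites_by_isoacceptor": by_iso,
    }


def export_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """BED-like export in reference space (0-based half-open)."""
    called = calls[calls["verdict"] == "called"]
    q = called["q_value"].clip(lower=1e-30)
    score = (-10 * np.log10(q)).round().astype(int)
    bed = pd.DataFrame(
        {
            "chrom": called["ref"],
            "start": called["pos"].astype(int) - 1,
            "end": called["pos"].astype(int),
            "name": "ac4C",
            "score": score,
            "strand": "+",
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_site_table(calls: pd.DataFrame, path: str | Path) -> None:
    write_table(calls, path)
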