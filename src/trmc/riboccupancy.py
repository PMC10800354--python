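"""Ribosome-profiling and translation readouts.

Footprints of 26-32 nt whose 5' end plus a fixed P-site offset lands in
frame 0 are kept; the P-site codon is (offset_in_CDS + p_site_offset)/3
and the A-site is the next codon.  Per-codon occupancy is the mean
A-site event count over that codon's occurrences, normalized by the
basal occupancy: the mean count at the +1/+2/+3 codons downstream of
the A-site at those same occurrences.  TE (and TR) are per-gene ratios
of ribosome-channel CPM to input CPM.

The fixed 12-nt offset (configurable per run) and the exclusion of the
first/last 5 codons are toolkit defaults, documented as such.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "assign_psites",
    "codon_occupancy",
    "occupancy_diff",
    "compute_te",
    "codon_freq_by_class",
]

LENGTH_RANGE = (26, 32)
DEFAULT_OFFSET = 12
EDGE_EXCLUDE = 5

_STOPS = {"TAA", "TAG", "TGA"}


def assign_psites(
    placements: pd.DataFrame,
    cds_lengths: Mapping[str, int],
    p_site_offset: int = DEFAULT_OFFSET,
    length_range: tuple[int, int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Filter footprints and infer P/A-site codons.

    ``placements`` needs columns read_id, transcript_id,
    five_prime_cds_offset (0-based nt from CDS start) and length.
    Reads outside ``length_range`` or not in frame 0 are dropped;
    transcripts whose CDS length is not a multiple of 3 are skipped
    with a warning.
    """
    required = {"read_id", "transcript_id", "five_prime_cds_offset", "length"}
    missing = required - set(placements.columns)
    if missing:
        raise ValueError(f"placements missing columns: {sorted(missing)}")

    bad_tx = {tx for tx, L in cds_lengths.items() if L % 3}
    for tx in sorted(bad_tx):
        logger.warning("skipping transcript %s: CDS length not divisible by 3", tx)

    df = placements[
        placements["transcript_id"].isin(set(cds_lengths) - bad_tx)
    ].copy()
    lo, hi = length_range
    df = df[(df["length"] >= lo) & (df["length"] <= hi)]
    shifted = df["five_prime_cds_offset"] + p_site_offset
    df["frame"] = shifted % 3
    df = df[df["frame"] == 0].copy()
    df["p_site_codon"] = shifted[df.index] // 3
    df["a_site_codon"] = df["p_site_codon"] + 1
    n_codons = df["transcript_id"].map(lambda t: cds_lengths[t] // 3)
    df = df[df["a_site_codon"] < n_codons]
    return df.reset_index(drop=True)


def _codon_counts(
    assignments: pd.DataFrame,
    cds_lengths: Mapping[str, int],
    site: str,
) -> dict[str, np.ndarray]:
    col = "a_site_codon" if site == "A" else "p_site_codon"
    counts = {tx: np.zeros(L // 3) for tx, L in cds_lengths.items() if L % 3 == 0}
    for tx, sub in assignments.groupby("transcript_id"):
        idx = sub[col].to_numpy()
        np.add.at(counts[tx], idx, 1.0)
    return counts


def codon_occupancy(
    assignments: pd.DataFrame,
    cds_sequences: Mapping[str, str],
    site: str = "A",
    edge_exclude: int = EDGE_EXCLUDE,
) -> pd.DataFrame:
    """Raw and basal-normalized per-codon occupancy.

    Occurrences within 3 codons of the stop are excluded (the downstream
    window must exist), as are the first/last ``edge_exclude`` codons.
    Codons with no occurrence, or zero basal occupancy, get NaN
    normalized values.
    """
    if site not in ("A", "P"):
        raise ValueError("site must be 'A' or 'P'")
    cds = {tx: s.upper().replace("U", "T") for tx, s in cds_sequences.items()}
    lengths = {tx: len(s) for tx, s in cds.items()}
    counts = _codon_counts(assignments, lengths, site)

    occ_sum: dict[str, float] = {}
    basal_sum: dict[str, float] = {}
    n_occ: dict[str, int] = {}
    for tx, seq in cds.items():
        if len(seq) % 3:
            continue
        n = len(seq) // 3
        vec = counts[tx]
        last_sense = n - 2  # n-1 is the stop codon
        for j in range(edge_exclude, n - edge_exclude):
            if j > last_sense - 3:
                break
            codon = seq[3 * j : 3 * j + 3]
            if codon in _STOPS:
                continue
            occ_sum[codon] = occ_sum.get(codon, 0.0) + vec[j]
            basal_sum[codon] = basal_sum.get(codon, 0.0) + vec[j + 1 : j + 4].mean()
            n_occ[codon] = n_occ.get(codon, 0) + 1

    rows = []
    for codon in sorted(occ_sum):
        n = n_occ[codon]
        raw = occ_sum[codon] / n
        basal = basal_sum[codon] / n
        rows.append(
            {
                "codon": codon,
                "n_occurrences": n,
                "raw_occupancy": raw,
                "basal_occupancy": basal,
                "normalized_occupancy": raw / basal if basal > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def occupancy_diff(
    table_kd: pd.DataFrame,
    table_control: pd.DataFrame,
    ac4c_codons: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-codon (KD - control) normalized occupancy and a rank test of
    the modified-decoder codons against the rest."""
    if not ac4c_codons:
        raise ValueError("ac4c_codons must be non-empty")
    merged = table_kd.merge(
        table_control, on="codon", suffixes=("_kd", "_control")
    )
    if merged.empty:
        raise ValueError("codon sets of the two tables are disjoint")
    merged["occupancy_diff"] = (
        merged["normalized_occupancy_kd"] - merged["normalized_occupancy_control"]
    )
    merged["is_ac4c_codon"] = merged["codon"].isin(set(ac4c_codons))
    sub = merged.dropna(subset=["occupancy_diff"])
    grp = sub[sub["is_ac4c_codon"]]["occupancy_diff"]
    rest = sub[~sub["is_ac4c_codon"]]["occupancy_diff"]
    if len(grp) and len(rest) and (grp.nunique() > 1 or rest.nunique() > 1 or grp.iloc[0] != rest.iloc[0]):
        stat, p = stats.mannwhitneyu(grp, rest, alternative="two-sided")
        test = {"statistic": float(stat), "p_value": float(p)}
    else:
        test = {"statistic": np.nan, "p_value": np.nan}
    return merged, test


def compute_te(
    input_counts: pd.Series,
    ribo_counts: pd.Series,
    mode: str = "TE",
    log2_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene translation efficiency (RPF/input) or ratio (RNC/input).

    Counts are CPM-normalized per library before the ratio; genes with
    zero input get NaN.  Classes: up/down when |log2 ratio| >= threshold
    and a two-proportion z-test p <= alpha, else non (toolkit defaults —
    the published volcano cutoffs are not printed).
    """
    if mode not in ("TE", "TR"):
        raise ValueError("mode must be 'TE' or 'TR'")
    genes = input_counts.index
    if not genes.equals(ribo_counts.index):
        ribo_counts = ribo_counts.reindex(genes)
        if ribo_counts.isna().any():
            raise ValueError("gene sets of the two count tables differ")
    n_in = float(input_counts.sum())
    n_ribo = float(ribo_counts.sum())
    cpm_in = input_counts * 1e6 / n_in
    cpm_ribo = ribo_counts * 1e6 / n_ribo
    ratio = cpm_ribo / cpm_in.replace(0, np.nan)

    # two-proportion z-test per gene on (count, library size)
    p1 = ribo_counts / n_ribo
    p2 = input_counts / n_in
    pooled = (ribo_counts + input_counts) / (n_ribo + n_in)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_ribo + 1 / n_in))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    log2r = np.log2(ratio)
    cls = np.where(
        ratio.isna(),
        "NA",
        np.where(
            (log2r >= log2_threshold) & (pvals <= alpha),
            "up",
            np.where((log2r <= -log2_threshold) & (pvals <= alpha), "down", "non"),
        ),
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "input_count": input_counts.to_numpy(),
            f"{mode.lower()}_count": ribo_counts.to_numpy(),
            mode: ratio.to_numpy(),
            "log2_ratio": log2r.to_numpy(),
            "p_value": pvals,
            "te_class": cls,
        }
    ).set_index("gene_id")


def codon_freq_by_class(
    te_table: pd.DataFrame,
    cds_sequences: Mapping[str, str],
    focus_codons: Sequence[str],
) -> dict:
    """Per-gene focus-codon frequency grouped by TE class, with a
    Kruskal-Wallis test across the up/down/non classes."""
    focus = {c.upper() for c in focus_codons}
    if not focus:
        raise ValueError("focus_codons must be non-empty")
    freqs: dict[str, float] = {}
    for gene in te_table.index:
        seq = cds_sequences.get(gene)
        if seq is None:
            raise KeyError(f"gene {gene!r} has no CDS sequence")
        seq = seq.upper().replace("U", "T")
        codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        if not codons:
            raise ValueError(f"gene {gene!r} has an empty CDS")
        freqs[gene] = sum(c in focus for c in codons) / len(codons)

    freq_series = pd.Series(freqs)
    groups = {}
    for cls in ("up", "down", "non"):
        members = te_table.index[te_table["te_class"] == cls]
        if len(members) < 2:
            raise ValueError(f"TE class {cls!r} has fewer than 2 genes")
        groups[cls] = freq_series[members].to_numpy()

    samples = list(groups.values())
    if all(np.ptp(s) == 0 for s in samples) and len(
        {s[0] for s in samples}
    ) == 1:
        stat, p = np.nan, np.nan  # degenerate: all values identical
    else:
        stat, p = stats.kruskal(*samples)
    return {
        "frequencies": freq_series,
        "by_class": groups,
        "medians": {cls: float(np.median(v)) for cls, v in groups.items()},
        "kruskal_statistic": float(stat) if stat == stat else np.nan,
        "p_value": float(p) if p == p else np.nan,
    }
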