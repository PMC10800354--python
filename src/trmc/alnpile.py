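"""Ungapped alignment to a small reference set and base-count pileups.

The built-in aligner exhaustively scans every read against every
isodecoder-group representative at every ungapped offset, keeps the
placements with the global minimum mismatch count (capped at
``max_mismatch``, default 2), and splits ties across distinct groups
into fractional weights of 1/k so pileups stay deterministic and rates
unbiased.  External SAM/BAM alignments can be ingested instead; hits
above the mismatch cap are dropped either way.

Internal coordinates are 0-based half-open; everything reported is
1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .refset import ReferenceRecord
from .simreads import FastqRead
from .tableio import write_table

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "align_reads",
    "ingest_sam",
    "build_pileup",
    "compute_rates",
    "Pileup",
    "trim_adapter",
]

_ENC = np.full(256, 4, dtype=np.uint8)  # N and anything else -> 4 (mismatch)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@dataclass(frozen=True)
class AlignmentHit:
    """One (possibly fractional) placement of a read on an isodecoder group."""

    read_id: str
    ref_id: str  # isodecoder group id
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_mismatch: int
    weight: float


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def trim_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Exact-prefix 3' adapter trimming.

    Removes the read suffix at the first position where the remainder of
    the read equals a prefix of the adapter of length >= ``min_overlap``
    (or the full adapter occurs).  Reads without the adapter pass
    through unchanged.
    """
    if not adapter:
        return seq
    full = seq.find(adapter)
    if full >= 0:
        return seq[:full]
    max_tail = min(len(adapter) - 1, len(seq))
    for k in range(max_tail, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def _group_representatives(
    references: Sequence[ReferenceRecord],
) -> list[tuple[str, np.ndarray]]:
    reps: dict[str, np.ndarray] = {}
    for rec in references:
        if rec.isodecoder_group not in reps:
            reps[rec.isodecoder_group] = _encode(rec.sequence)
    return sorted(reps.items())


def _best_placements(
    read_arr: np.ndarray, reps: list[tuple[str, np.ndarray]]
) -> tuple[int, list[tuple[str, int]]]:
    """Global-best ungapped placements of one read over all groups.

    Returns (best_mismatch, [(group, 0-based offset), ...]); one
    placement per group (the leftmost best offset within that group).
    """
    m = len(read_arr)
    best = m + 1
    placements: list[tuple[str, int, int]] = []
    for group, ref_arr in reps:
        n = len(ref_arr)
        if m > n:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, m)
        mism = (windows != read_arr).sum(axis=1)
        k = int(mism.min())
        placements.append((group, int(mism.argmin()), k))
        if k < best:
            best = k
    hits = [(g, off) for g, off, k in placements if k == best]
    return best, hits


def align_reads(
    reads: Iterable[FastqRead],
    references: Sequence[ReferenceRecord],
    max_mismatch: int = 2,
    adapter: str | None = None,
) -> list[AlignmentHit]:
    """Align reads ungapped against isodecoder-group representatives.

    Reads with more than 50% N are skipped with a warning; reads whose
    best placement exceeds ``max_mismatch`` are left unmapped.
    """
    if not references:
        raise ValueError("empty reference set")
    reps = _group_representatives(references)

    # identical read sequences share one alignment computation
    by_seq: dict[str, list[str]] = {}
    n_skipped = 0
    for r in reads:
        seq = trim_adapter(r.sequence, adapter) if adapter else r.sequence
        if not seq or seq.count("N") / len(seq) > 0.5:
            n_skipped += 1
            continue
        by_seq.setdefault(seq, []).append(r.read_id)
    if n_skipped:
        logger.warning("skipped %d reads with >50%% N or empty after trim", n_skipped)

    hits: list[AlignmentHit] = []
    n_unmapped = 0
    for seq, read_ids in by_seq.items():
        read_arr = _encode(seq)
        best, placements = _best_placements(read_arr, reps)
        if best > max_mismatch or not placements:
            n_unmapped += len(read_ids)
            continue
        w = 1.0 / len(placements)
        for read_id in read_ids:
            for group, off in placements:
                hits.append(
                    AlignmentHit(
                        read_id, group, off + 1, off + len(seq), best, w
                    )
                )
    if n_unmapped:
        logger.info("%d reads unmapped (best > %d mismatches)", n_unmapped, max_mismatch)
    return hits


def ingest_sam(
    sam: str | Path,
    references: Sequence[ReferenceRecord],
    max_mismatch: int = 2,
) -> list[AlignmentHit]:
    """Convert primary SAM/BAM alignments to hits, honoring the mismatch cap.

    The NM tag supplies the mismatch count when present; otherwise it is
    computed from the read and reference sequences (ungapped records
    only).  Unknown target names raise.
    """
    by_id = {r.ref_id: r for r in references}
    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in by_id:
                raise ValueError(
                    f"alignment target {rec.reference_name!r} is not a loaded reference"
                )
            ref = by_id[rec.reference_name]
            start0 = rec.reference_start
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                seq = rec.query_sequence or ""
                segment = ref.sequence[start0 : start0 + len(seq)]
                nm = sum(a != b for a, b in zip(seq, segment))
            if nm > max_mismatch:
                continue
            length = rec.query_length or len(rec.query_sequence or "")
            hits.append(
                AlignmentHit(
                    rec.query_name,
                    ref.isodecoder_group,
                    start0 + 1,
                    start0 + length,
                    nm,
                    1.0,
                )
            )
    return hits


class Pileup:
    """Per-reference base-count matrices with read-end tracks.

    ``base_counts[group]`` is a (4, L) float array in A,C,G,T order;
    ``five_prime`` / ``three_prime`` hold weighted read-end counts.
    """

    def __init__(self, references: Sequence[ReferenceRecord]):
        self.sequences: dict[str, str] = {}
        self.base_counts: dict[str, np.ndarray] = {}
        self.five_prime: dict[str, np.ndarray] = {}
        self.three_prime: dict[str, np.ndarray] = {}
        for rec in references:
            g = rec.isodecoder_group
            if g in self.sequences:
                continue
            self.sequences[g] = rec.sequence
            L = rec.length
            self.base_counts[g] = np.zeros((4, L))
            self.five_prime[g] = np.zeros(L)
            self.three_prime[g] = np.zeros(L)

    def depth(self, group: str) -> np.ndarray:
        return self.base_counts[group].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.sequences):
            counts = self.base_counts[group]
            seq = self.sequences[group]
            depth = counts.sum(axis=0)
            for i in range(len(seq)):
                rows.append(
                    (
                        group,
                        i + 1,
                        seq[i],
                        counts[0, i],
                        counts[1, i],
                        counts[2, i],
                        counts[3, i],
                        depth[i],
                        self.five_prime[group][i],
                        self.three_prime[group][i],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "ref",
                "pos",
                "ref_base",
                "A",
                "C",
                "G",
                "T",
                "depth",
                "five_prime_ends",
                "three_prime_ends",
            ],
        )

    def write(self, path: str | Path) -> None:
        write_table(self.to_frame(), path)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, references: Sequence[ReferenceRecord]
    ) -> "Pileup":
        pile = cls(references)
        for group, sub in df.groupby("ref"):
            if group not in pile.base_counts:
                raise ValueError(f"pileup table references unknown group {group!r}")
            idx = sub["pos"].to_numpy() - 1
            for bi, base in enumerate("ACGT"):
                pile.base_counts[group][bi, idx] = sub[base].to_numpy()
            pile.five_prime[group][idx] = sub["five_prime_ends"].to_numpy()
            pile.three_prime[group][idx] = sub["three_prime_ends"].to_numpy()
        return pile


def build_pileup(
    hits: Iterable[AlignmentHit],
    reads: Mapping[str, str] | Iterable[FastqRead],
    references: Sequence[ReferenceRecord],
) -> Pileup:
    """Accumulate weighted base counts and read-end counts from hits."""
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r.sequence for r in reads}
    pile = Pileup(references)
    for hit in hits:
        seq = reads[hit.read_id]
        if hit.ref_id not in pile.base_counts:
            raise ValueError(f"hit on unknown group {hit.ref_id!r}")
        L = len(pile.sequences[hit.ref_id])
        if hit.start < 1 or hit.end > L or hit.end - hit.start + 1 != len(seq):
            raise ValueError(
                f"hit {hit} inconsistent with read length {len(seq)} / reference length {L}"
            )
        codes = _encode(seq)
        positions = np.arange(hit.start - 1, hit.end)
        valid = codes < 4
        np.add.at(
            pile.base_counts[hit.ref_id],
            (codes[valid], positions[valid]),
            hit.weight,
        )
        pile.five_prime[hit.ref_id][hit.start - 1] += hit.weight
        pile.three_prime[hit.ref_id][hit.end - 1] += hit.weight
    return pile


def compute_rates(
    pile: Pileup,
    references: Sequence[ReferenceRecord] | None = None,
    min_depth: float = 50,
) -> pd.DataFrame:
    """Per-position misincorporation and stop rates.

    Returns a frame with one row per (ref, pos): base counts, depth,
    ``ref_count``, ``misinc_rate`` = 1 - ref_count/depth, the dominant
    alternative base, ``ct_rate`` (T/depth, defined at C positions
    only), ``stop_rate`` (3'-end count / depth) and a ``low_coverage``
    flag for depth < ``min_depth``.  Rates are NaN at depth 0.
    """
    df = pile.to_frame()
    counts = df[["A", "C", "G", "T"]].to_numpy()
    ref_idx = df["ref_base"].map({"A": 0, "C": 1, "G": 2, "T": 3}).to_numpy()
    rows = np.arange(len(df))
    ref_count = counts[rows, ref_idx]
    depth = df["depth"].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        misinc = np.where(depth > 0, 1.0 - ref_count / depth, np.nan)
        stop = np.where(depth > 0, df["three_prime_ends"].to_numpy() / depth, np.nan)
        ct = np.where(
            (depth > 0) & (df["ref_base"] == "C"),
            counts[:, 3] / np.where(depth > 0, depth, 1),
            np.nan,
        )

    alt = counts.copy()
    alt[rows, ref_idx] = -1.0
    dominant = np.array(list("ACGT"))[alt.argmax(axis=1)]

    out = df.copy()
    out["ref_count"] = ref_count
    out["misinc_rate"] = misinc
    out["dominant_alt"] = dominant
    out["ct_rate"] = ct
    out["stop_rate"] = stop
    out["low_coverage"] = depth < min_depth
    return out
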