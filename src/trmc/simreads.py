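"""Seeded read and count-table simulator.

Generates synthetic libraries carrying the reduction chemistry's
signature: in the reduced condition an acetylated C is read as T with a
configurable misincorporation probability (and, optionally, produces an
RT stop just before the site).  Deacetylated and mock conditions are
statistically identical to background, because stripping the acetyl
group beforehand prevents reduction from marking the base.

Also provides ribosome-footprint and RPF/RNC/input count-table fixtures
so the translation readouts are testable without external data, and a
builder of synthetic reference sets mirroring the published site
inventories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .refset import ReferenceRecord, records_by_id

__all__ = [
    "Site",
    "SimConfig",
    "SimTruth",
    "FastqRead",
    "simulate_library",
    "simulate_kd_pair",
    "simulate_rpf",
    "simulate_counts",
    "write_fastq",
    "read_fastq",
    "AC4C_SEQ_INVENTORY",
    "TRMC_INVENTORY",
    "synthetic_references",
    "synthetic_rrna",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_CONDITIONS = ("reduced", "deacetylated", "mock")
MIN_READ_LENGTH = 15  # truncation products shorter than this are dropped


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


class Site(NamedTuple):
    """An embedded modification site on a reference C."""

    ref_id: str
    position: int  # 1-based
    misinc_rate: float
    stop_rate: float = 0.0


@dataclass
class SimConfig:
    """Full specification of one synthetic library."""

    references: Sequence[ReferenceRecord]
    sites: Sequence[Site]
    condition: str = "reduced"
    depth_per_ref: int = 1000
    background_error: float = 0.002
    truncation_background: float = 0.0
    seed: int = 0
    depth_overrides: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")
        if self.depth_per_ref < 0:
            raise ValueError("depth_per_ref must be >= 0")
        if not 0 <= self.background_error <= 1:
            raise ValueError("background_error must be in [0, 1]")
        index = records_by_id(self.references)
        for site in self.sites:
            rec = index.get(site.ref_id)
            if rec is None:
                raise ValueError(f"site on unknown reference {site.ref_id!r}")
            if not 1 <= site.position <= rec.length:
                raise ValueError(
                    f"site position {site.position} outside {site.ref_id} "
                    f"(length {rec.length})"
                )
            if rec.sequence[site.position - 1] != "C":
                raise ValueError(
                    f"site {site.ref_id}:{site.position} reference base is "
                    f"{rec.sequence[site.position - 1]!r}, must be C"
                )
            if not 0 <= site.misinc_rate <= 1 or not 0 <= site.stop_rate <= 1:
                raise ValueError("site rates must be in [0, 1]")

    def depth_for(self, ref_id: str) -> int:
        return int(self.depth_overrides.get(ref_id, self.depth_per_ref))


@dataclass
class SimTruth:
    """What was actually embedded, for downstream checks."""

    condition: str
    seed: int
    sites: list[Site]
    realized_mismatches: dict[tuple[str, int], int]
    depths: dict[str, int]


def _mutate_background(
    mat: np.ndarray, rng: np.random.Generator, error: float
) -> None:
    """Apply uniform substitution errors in place (codes 0..3)."""
    if error <= 0:
        return
    hit = rng.random(mat.shape) < error
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        mat[hit] = (mat[hit] + shift) % 4


def simulate_library(config: SimConfig) -> tuple[list[FastqRead], SimTruth]:
    """Simulate one library under the three-group chemistry design.

    Per reference, ``depth_for(ref)`` reads are emitted (full length;
    truncation may shorten but never deletes a read unless it falls
    below MIN_READ_LENGTH).  In the reduced condition each embedded site
    converts C->T with its misincorporation rate and truncates the read
    just before the site with its stop rate; deacetylated and mock
    behave exactly like background.  All randomness derives from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites_by_ref: dict[str, list[Site]] = {}
    for site in config.sites:
        sites_by_ref.setdefault(site.ref_id, []).append(site)

    reads: list[FastqRead] = []
    realized: dict[tuple[str, int], int] = {}
    depths: dict[str, int] = {}
    t_code = 3  # 'T'

    for rec in sorted(config.references, key=lambda r: r.ref_id):
        depth = config.depth_for(rec.ref_id)
        depths[rec.ref_id] = depth
        if depth == 0:
            continue
        ref_arr = _ENC[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)]
        mat = np.tile(ref_arr, (depth, 1))
        _mutate_background(mat, rng, config.background_error)

        # read end positions (1-based inclusive); truncation shortens 3' end
        ends = np.full(depth, rec.length, dtype=np.int64)
        if config.truncation_background > 0:
            stop = rng.random(depth) < config.truncation_background
            cut = rng.integers(MIN_READ_LENGTH, rec.length + 1, size=depth)
            ends[stop] = np.minimum(ends[stop], cut[stop])

        for site in sites_by_ref.get(rec.ref_id, []):
            if config.condition == "reduced":
                hit = rng.random(depth) < site.misinc_rate
                mat[hit, site.position - 1] = t_code
                if site.stop_rate > 0:
                    stop = rng.random(depth) < site.stop_rate
                    ends[stop] = np.minimum(ends[stop], site.position - 1)
            realized[(rec.ref_id, site.position)] = int(
                (mat[:, site.position - 1] != _ENC[ord("C")]).sum()
            )

        chars = _BASES[mat]
        for i in range(depth):
            end = ends[i]
            if end < MIN_READ_LENGTH:
                continue
            seq = chars[i, :end].tobytes().decode()
            reads.append(
                FastqRead(
                    f"{rec.ref_id}|{config.condition}|{i}", seq, "I" * end
                )
            )

    truth = SimTruth(
        condition=config.condition,
        seed=config.seed,
        sites=list(config.sites),
        realized_mismatches=realized,
        depths=depths,
    )
    return reads, truth


def simulate_kd_pair(
    config_control: SimConfig,
    misinc_multiplier: float,
    abundance_multiplier: float,
    kd_seed: int | None = None,
) -> tuple[
    tuple[list[FastqRead], SimTruth], tuple[list[FastqRead], SimTruth]
]:
    """Simulate a control library and a knockdown library.

    The knockdown scales every embedded site's misincorporation rate by
    ``misinc_multiplier`` and the depth of every site-carrying reference
    by ``abundance_multiplier``; other references are untouched.
    """
    for name, mult in (
        ("misinc_multiplier", misinc_multiplier),
        ("abundance_multiplier", abundance_multiplier),
    ):
        if not 0 <= mult <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {mult}")
    config_control.validate()
    control = simulate_library(config_control)

    kd_sites = [
        Site(s.ref_id, s.position, s.misinc_rate * misinc_multiplier, s.stop_rate)
        for s in config_control.sites
    ]
    modified_refs = {s.ref_id for s in config_control.sites}
    overrides = dict(config_control.depth_overrides)
    for ref_id in modified_refs:
        base = config_control.depth_for(ref_id)
        overrides[ref_id] = int(round(base * abundance_multiplier))
    kd_config = SimConfig(
        references=config_control.references,
        sites=kd_sites,
        condition=config_control.condition,
        depth_per_ref=config_control.depth_per_ref,
        background_error=config_control.background_error,
        truncation_background=config_control.truncation_background,
        seed=config_control.seed + 1 if kd_seed is None else kd_seed,
        depth_overrides=overrides,
    )
    kd = simulate_library(kd_config)
    return control, kd


def simulate_rpf(
    cds_sequences: Mapping[str, str],
    pause_codons: Iterable[str],
    pause_factor: float = 1.0,
    n_reads: int = 10000,
    length_range: tuple[int, int] = (26, 32),
    seed: int = 0,
    p_site_offset: int = 12,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate ribosome footprints over CDS sequences.

    Reads are placed so that 5' end + ``p_site_offset`` lands in frame 0
    with the A-site codon drawn with weight ``pause_factor`` when it is
    in ``pause_codons`` and 1 otherwise; lengths are uniform over
    ``length_range``.  Returns the reads and a truth table of
    transcript-space placements (read_id, transcript_id,
    five_prime_cds_offset, length, a_site_codon_index, codon).
    """
    if not cds_sequences:
        raise ValueError("empty CDS set")
    if pause_factor < 1:
        raise ValueError("pause_factor must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("invalid length_range")
    pause = {c.upper() for c in pause_codons}
    rng = np.random.default_rng(seed)
    cds_norm = {
        tx: s.upper().replace("U", "T") for tx, s in cds_sequences.items()
    }

    placements: list[tuple[str, int, int, str]] = []  # tx, fp, a_idx, codon
    weights: list[float] = []
    for tx, seq in sorted(cds_norm.items()):
        if len(seq) % 3:
            raise ValueError(f"CDS {tx!r} length {len(seq)} not divisible by 3")
        n_codons = len(seq) // 3
        for a_idx in range(n_codons):
            fp = (a_idx - 1) * 3 - p_site_offset
            if fp < 0 or fp + hi > len(seq):
                continue
            codon = seq[a_idx * 3 : a_idx * 3 + 3]
            placements.append((tx, fp, a_idx, codon))
            weights.append(pause_factor if codon in pause else 1.0)
    if not placements:
        raise ValueError("no valid footprint placements; CDSs too short")

    w = np.asarray(weights)
    w /= w.sum()
    choice = rng.choice(len(placements), size=n_reads, p=w)
    lengths = rng.integers(lo, hi + 1, size=n_reads)

    reads: list[FastqRead] = []
    rows = []
    for i, (k, length) in enumerate(zip(choice, lengths)):
        tx, fp, a_idx, codon = placements[k]
        seq = cds_norm[tx][fp : fp + length]
        read_id = f"rpf|{i}"
        reads.append(FastqRead(read_id, seq, "I" * len(seq)))
        rows.append((read_id, tx, fp, int(length), a_idx, codon))
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "transcript_id",
            "five_prime_cds_offset",
            "length",
            "a_site_codon",
            "codon",
        ],
    )
    return reads, truth


def simulate_counts(
    n_genes: int,
    te_effects: Sequence[float] | None = None,
    library_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate matched input/RPF/RNC count tables.

    Gene base abundances are log-normal; the RPF and RNC channels
    multiply each gene's sampling weight by its ``te_effect``, so a gene
    with te_effect f has expected TE (relative to the rest) of about f.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if te_effects is None:
        te_effects = np.ones(n_genes)
    te_effects = np.asarray(te_effects, dtype=float)
    if te_effects.shape != (n_genes,) or (te_effects < 0).any():
        raise ValueError("te_effects must be n_genes non-negative values")
    sizes = {"input": 1_000_000, "rpf": 1_000_000, "rnc": 1_000_000}
    if library_sizes:
        sizes.update(library_sizes)
    if any(v < 0 for v in sizes.values()):
        raise ValueError("library sizes must be non-negative")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    p_input = base / base.sum()
    p_ribo = base * te_effects
    p_ribo = p_ribo / p_ribo.sum()
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "input": rng.multinomial(sizes["input"], p_input),
            "rpf": rng.multinomial(sizes["rpf"], p_ribo),
            "rnc": rng.multinomial(sizes["rnc"], p_ribo),
        }
    )
    return df


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(FastqRead(header[1:].strip(), seq, qual))
    return reads


# ---------------------------------------------------------------------------
# Built-in synthetic reference sets mirroring the published site inventories.
# Positions are 1-based linear coordinates on the mature sequence (with CCA).
# ---------------------------------------------------------------------------

# Small-RNA-free (total RNA) assay: 13 sites on 13 isodecoders spanning
# 9 isoacceptors.  Each entry: (amino acid, anticodon, copy, length,
# site positions on that isodecoder).
AC4C_SEQ_INVENTORY: tuple[tuple[str, str, int, int, tuple[int, ...]], ...] = (
    ("Ser", "GCT", 1, 82, (12,)),
    ("Ser", "GCT", 2, 82, (12,)),
    ("Leu", "TAA", 1, 85, (79,)),
    ("Leu", "TAA", 2, 85, (79,)),
    ("Leu", "TAG", 1, 83, (12,)),
    ("Ser", "TGA", 1, 82, (12,)),
    ("Ser", "TGA", 2, 82, (12,)),
    ("Ser", "AGA", 1, 82, (12,)),
    ("Ser", "CGA", 1, 82, (12,)),
    ("Ser", "CGA", 2, 82, (12,)),
    ("Arg", "TCG", 1, 76, (4,)),
    ("Leu", "AAG", 1, 83, (6,)),
    ("Leu", "CAA", 1, 83, (12,)),
)

# Small-RNA-enriched assay: 17 sites on 16 isodecoders spanning 10
# isoacceptors, adding the acceptor-stem / variable-loop positions 3,
# 50 and 65 to the inventory above.
TRMC_INVENTORY: tuple[tuple[str, str, int, int, tuple[int, ...]], ...] = (
    ("Ser", "GCT", 1, 82, (12,)),
    ("Ser", "GCT", 2, 82, (12,)),
    ("Leu", "TAA", 1, 85, (79,)),
    ("Leu", "TAA", 2, 85, (79,)),
    ("Leu", "TAG", 1, 83, (12,)),
    ("Leu", "TAG", 2, 83, (12,)),
    ("Ser", "TGA", 1, 82, (12,)),
    ("Ser", "TGA", 2, 82, (12,)),
    ("Ser", "AGA", 1, 82, (12,)),
    ("Ser", "CGA", 1, 82, (3, 12)),
    ("Ser", "CGA", 2, 82, (12,)),
    ("Arg", "TCG", 1, 76, (4,)),
    ("Leu", "AAG", 1, 83, (6,)),
    ("Leu", "AAG", 2, 83, (50,)),
    ("Leu", "CAA", 1, 83, (12,)),
    ("Val", "AAC", 1, 76, (65,)),
)

_ANTICODON_START = 34  # 1-based position of the anticodon in the body


def _synthesize_trna(
    rng: np.random.Generator,
    length: int,
    anticodon: str,
    site_positions: Sequence[int],
) -> str:
    """Random tRNA-like sequence with fixed anticodon, CCA tail and a C
    at each requested site position."""
    arr = rng.integers(0, 4, size=length)
    seq = list("ACGT"[b] for b in arr)
    seq[-3:] = list("CCA")
    seq[_ANTICODON_START - 1 : _ANTICODON_START + 2] = list(anticodon)
    for pos in site_positions:
        if pos > length - 3 or _ANTICODON_START <= pos <= _ANTICODON_START + 2:
            raise ValueError(f"site position {pos} collides with fixed elements")
        seq[pos - 1] = "C"
    return "".join(seq)


def synthetic_references(
    inventory: Sequence[tuple[str, str, int, int, tuple[int, ...]]],
    seed: int = 20240122,
) -> tuple[list[ReferenceRecord], list[Site]]:
    """Build distinct synthetic isodecoder sequences for an inventory.

    Returns normalized :class:`ReferenceRecord` objects (singleton
    isodecoder groups — sequences are random and distinct) and the
    :class:`Site` list (rates left at 0; callers set them).
    """
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    sites: list[Site] = []
    seen: set[str] = set()
    for aa, anticodon, copy, length, positions in inventory:
        ref_id = f"tRNA-{aa}-{anticodon}-{copy}-1"
        while True:
            seq = _synthesize_trna(rng, length, anticodon, positions)
            if seq not in seen:
                break
        seen.add(seq)
        records.append(ReferenceRecord(ref_id, aa, anticodon, seq, ref_id))
        for pos in positions:
            sites.append(Site(ref_id, pos, 0.0))
    return records, sites


def synthetic_rrna(
    length: int = 150, site_positions: Sequence[int] = (60, 120), seed: int = 7
) -> tuple[list[ReferenceRecord], list[Site]]:
    """A synthetic small-subunit rRNA stand-in with embedded C sites."""
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[b] for b in rng.integers(0, 4, size=length))
    for pos in site_positions:
        seq[pos - 1] = "C"
    rec = ReferenceRecord("rRNA-18S-like", "rRNA", "", "".join(seq), "rRNA-18S-like")
    return [rec], [Site(rec.ref_id, pos, 0.0) for pos in site_positions]


def with_rates(
    sites: Sequence[Site], misinc_rate: float, stop_rate: float = 0.0
) -> list[Site]:
    """Copy a site list with uniform rates applied."""
    return [Site(s.ref_id, s.position, misinc_rate, stop_rate) for s in sites]
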