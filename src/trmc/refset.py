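"""Reference handling for small-RNA modification calling.

Loads mature tRNA (and rRNA) sequences, normalizes them (uppercase,
U->T, terminal CCA completion), collapses byte-identical isodecoders
into groups, and maps anticodons to the codons they decode.

Coordinates everywhere in this package are 1-based on the normalized
mature sequence (including the appended CCA).  Site labels such as
"position 12" are linear sequence positions, not structural alignment
numbering; this is a documented convention of the toolkit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceRecord",
    "load_references",
    "normalize_sequence",
    "complete_cca",
    "anticodon_to_codon",
    "reverse_complement",
    "ac4c_decoder_codons",
    "export_reference_table",
    "records_by_id",
    "AC4C_ISOACCEPTORS",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = set("ACGT")

# Isoacceptors (amino acid, anticodon) observed to carry at least one
# called acetylation site in the small-RNA assay; used as the default
# decoder set for the translation analyses.
AC4C_ISOACCEPTORS: tuple[tuple[str, str], ...] = (
    ("Ser", "GCT"),
    ("Leu", "TAA"),
    ("Leu", "TAG"),
    ("Ser", "TGA"),
    ("Ser", "AGA"),
    ("Ser", "CGA"),
    ("Arg", "TCG"),
    ("Leu", "AAG"),
    ("Leu", "CAA"),
    ("Val", "AAC"),
)

# gtRNAdb-style id, e.g. "tRNA-Ser-GCT-1-1" or "Homo_sapiens_tRNA-Ser-GCT-2-1"
_GTRNADB_RE = re.compile(r"tRNA-([A-Za-z]{3}|iMet|fMet|SeC|Sup|Und)-([ACGTUacgtu]{3})")


@dataclass(frozen=True)
class ReferenceRecord:
    """One mature tRNA (or rRNA) reference sequence.

    Attributes
    ----------
    ref_id : str
        FASTA identifier.
    amino_acid : str
        3-letter amino-acid code, or ``"rRNA"``, or ``"unknown"``.
    anticodon : str
        3-mer over {A,C,G,T}; empty for rRNA / unknown dialects.
    sequence : str
        Normalized mature sequence (uppercase DNA, tRNAs end in CCA).
    isodecoder_group : str
        Identifier shared by records with byte-identical sequences.
    """

    ref_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    isodecoder_group: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def isoacceptor(self) -> str:
        """Amino-acid + anticodon label, e.g. ``"Ser-GCT"``."""
        if not self.anticodon:
            return self.amino_acid
        return f"{self.amino_acid}-{self.anticodon}"

    @property
    def decoded_codon(self) -> str:
        return anticodon_to_codon(self.anticodon) if self.anticodon else ""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_to_codon(anticodon: str) -> str:
    """Codon decoded by an anticodon: its reverse complement.

    >>> anticodon_to_codon("GCT")
    'AGC'
    """
    if len(anticodon) != 3:
        raise ValueError(f"anticodon must be a 3-mer, got {anticodon!r}")
    if not set(anticodon) <= _VALID:
        raise ValueError(f"anticodon must be over ACGT, got {anticodon!r}")
    return reverse_complement(anticodon)


def normalize_sequence(seq: str, ref_id: str = "?") -> str:
    """Uppercase and convert U to T; reject anything outside ACGTU."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - _VALID
    if bad:
        raise ValueError(
            f"record {ref_id!r} contains non-ACGTU characters: {sorted(bad)}"
        )
    return out


def complete_cca(seq: str) -> str:
    """Append the missing suffix so the sequence ends in CCA.

    Only the part of "CCA" not already present is appended, so a
    normalized sequence is left unchanged (idempotent).
    """
    if seq.endswith("CCA"):
        return seq
    if seq.endswith("CC"):
        return seq + "A"
    if seq.endswith("C"):
        return seq + "CA"
    return seq + "CCA"


def _parse_header(rec_id: str, description: str) -> tuple[str, str]:
    """Infer (amino_acid, anticodon) from a FASTA header.

    Accepts the gtRNAdb dialect ("tRNA-Ser-GCT-1-1" anywhere in the id)
    and a plain ">id aa anticodon" dialect; anything else falls back to
    ("unknown", "").
    """
    m = _GTRNADB_RE.search(rec_id) or _GTRNADB_RE.search(description)
    if m:
        aa = m.group(1)
        anticodon = m.group(2).upper().replace("U", "T")
        return aa, anticodon
    fields = description.split()
    if len(fields) >= 3 and re.fullmatch(r"[ACGTUacgtu]{3}", fields[2]):
        return fields[1], fields[2].upper().replace("U", "T")
    return "unknown", ""


def load_references(
    fasta: str | Path,
    kind: str = "tRNA",
    add_his_g1: bool = False,
) -> list[ReferenceRecord]:
    """Load and normalize reference sequences from a FASTA file.

    Parameters
    ----------
    fasta : path
        FASTA of mature sequences.
    kind : {"tRNA", "rRNA"}
        tRNAs get CCA completion and header parsing for amino acid /
        anticodon; rRNAs are only uppercased/U->T converted.
    add_his_g1 : bool
        Prepend the extra G-1 to His tRNAs lacking it (off by default).

    Returns records sorted by ``ref_id`` with isodecoder groups assigned
    (identical sequences share a group named after the lexicographically
    first member).
    """
    if kind not in ("tRNA", "rRNA"):
        raise ValueError(f"kind must be 'tRNA' or 'rRNA', got {kind!r}")
    raw = list(SeqIO.parse(str(fasta), "fasta"))
    if not raw:
        raise ValueError(f"no FASTA records found in {fasta}")

    records: list[ReferenceRecord] = []
    seen_ids: set[str] = set()
    for rec in raw:
        if rec.id in seen_ids:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        seen_ids.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if kind == "tRNA":
            aa, anticodon = _parse_header(rec.id, rec.description)
            seq = complete_cca(seq)
            if add_his_g1 and aa == "His" and not seq.startswith("G"):
                seq = "G" + seq
            if not 60 <= len(seq) <= 120:
                raise ValueError(
                    f"tRNA record {rec.id!r} has length {len(seq)} "
                    "outside the plausible mature range [60, 120]"
                )
        else:
            aa, anticodon = "rRNA", ""
        records.append(ReferenceRecord(rec.id, aa, anticodon, seq))

    records.sort(key=lambda r: r.ref_id)
    by_seq: dict[str, str] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, rec.ref_id)
    return [replace(r, isodecoder_group=by_seq[r.sequence]) for r in records]


def records_by_id(records: Iterable[ReferenceRecord]) -> dict[str, ReferenceRecord]:
    return {r.ref_id: r for r in records}


def ac4c_decoder_codons(
    records: Sequence[ReferenceRecord],
    site_table: Iterable,
) -> set[str]:
    """Decoded-codon set of all isoacceptors carrying at least one site.

    ``site_table`` may contain reference ids, (ref_id, position) tuples,
    or objects with a ``ref_id`` attribute.  Unknown ids raise.
    """
    index = records_by_id(records)
    group_index = {r.isodecoder_group: r for r in records}
    codons: set[str] = set()
    for entry in site_table:
        if isinstance(entry, str):
            ref_id = entry
        elif hasattr(entry, "ref_id"):
            ref_id = entry.ref_id
        else:
            ref_id = entry[0]
        rec = index.get(ref_id) or group_index.get(ref_id)
        if rec is None:
            raise KeyError(f"unknown reference / isoacceptor {ref_id!r}")
        if rec.anticodon:
            codons.add(rec.decoded_codon)
    return codons


def default_ac4c_codons() -> set[str]:
    """Decoded codons of the default modified isoacceptor set."""
    return {anticodon_to_codon(ac) for _, ac in AC4C_ISOACCEPTORS}


def export_reference_table(
    records: Sequence[ReferenceRecord], path: str | Path
) -> pd.DataFrame:
    """Write the reference table as TSV (header line starts with '#')."""
    df = pd.DataFrame(
        {
            "ref_id": [r.ref_id for r in records],
            "amino_acid": [r.amino_acid for r in records],
            "anticodon": [r.anticodon for r in records],
            "isodecoder_group": [r.isodecoder_group for r in records],
            "length": [r.length for r in records],
            "decoded_codon": [r.decoded_codon for r in records],
        }
    )
    from .tableio import write_table

    write_table(df, path)
    return df
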