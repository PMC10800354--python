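import textwrap
from pathlib import Path

import pytest

from trmc import refset, simreads


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "refs.fasta") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def trio_refs(write_fasta):
    """Three distinct synthetic tRNAs loaded through the normal path."""
    records, _ = simreads.synthetic_references(
        (
            ("Ser", "GCT", 1, 76, (12,)),
            ("Leu", "TAA", 1, 85, (79,)),
            ("Arg", "TCG", 1, 76, (4,)),
        )
    )
    path = write_fasta({r.ref_id: r.sequence for r in records})
    return refset.load_references(path, kind="tRNA")
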