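"""Shared fixtures: small panels and hand-constructed read tables."""

from __future__ import annotations

import pandas as pd
import pytest

from smmiphet.panel import ProbePanel, ProbeTarget


def make_reads(rows: list[tuple[str, str, str, str, str]]) -> pd.DataFrame:
    """Rows of (sample_id, probe_id, tag, base_calls, base_qualities)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "probe_id", "molecular_tag", "base_calls", "base_qualities"]
    )


def uniform_quals(length: int, phred: int = 37) -> str:
    return chr(phred + 33) * length


@pytest.fixture
def tiny_panel() -> ProbePanel:
    """Two genes, one probe each, hand-written 20 bp targets.

    GENEA_p0 contains a 5-base A run (offsets 5-9) for homopolymer tests.
    """
    return ProbePanel(
        [
            ProbeTarget("GENEA_p0", "GENEA", "chr1", 100, 120, 0.50,
                        "CGTGCAAAAAGTCGTACGTC"),
            ProbeTarget("GENEB_p0", "GENEB", "chr2", 500, 520, 0.60,
                        "ACGTACGTGCGCATGCATGC"),
        ]
    )


def int_tag(i: int, length: int = 6) -> str:
    """Fixed-length ACGT encoding of an integer (distinct, deterministic tags)."""
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(digits))
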