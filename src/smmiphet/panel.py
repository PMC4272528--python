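"""Probe panel: the targeted capture design.

A panel is a collection of probe targets, each a contiguous genomic interval
(0-based, half-open) with its reference sequence and GC fraction.  The probe
is the unit of coverage counting for copy-number analysis and provides the
reference context for pileups and the homopolymer filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class ProbeTarget:
    """One capture target.

    Coordinates are 0-based half-open on ``chrom``; ``sequence`` is the
    reference sequence of the captured target and ``gc_fraction`` its
    G+C proportion.
    """

    probe_id: str
    gene: str
    chrom: str
    start: int
    end: int
    gc_fraction: float
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"probe {self.probe_id}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"probe {self.probe_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"probe {self.probe_id}: gc_fraction outside [0, 1]")
        gc = sum(self.sequence.upper().count(b) for b in "GC") / len(self.sequence)
        if abs(gc - self.gc_fraction) > 1.0 / len(self.sequence) + 1e-9:
            raise ValueError(
                f"probe {self.probe_id}: gc_fraction {self.gc_fraction:.4f} does not "
                f"match sequence GC {gc:.4f}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ProbePanel:
    """An ordered set of probe targets.

    Probes are stored sorted by (chrom, start).  Within a gene, probe
    intervals must not overlap; every gene has at least one probe.
    """

    def __init__(self, probes: Iterable[ProbeTarget]):
        probes = sorted(probes, key=lambda p: (p.chrom, p.start))
        if not probes:
            raise ValueError("panel must contain at least one probe")
        ids = [p.probe_id for p in probes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe_id in panel")
        by_gene: dict[str, list[ProbeTarget]] = {}
        for p in probes:
            by_gene.setdefault(p.gene, []).append(p)
        for gene, ps in by_gene.items():
            for a, b in zip(ps, ps[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"gene {gene}: overlapping probes {a.probe_id}, {b.probe_id}")
        self.probes: list[ProbeTarget] = probes
        self.by_id: dict[str, ProbeTarget] = {p.probe_id: p for p in probes}
        self.by_gene: dict[str, list[ProbeTarget]] = by_gene

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def genes(self) -> list[str]:
        return sorted(self.by_gene)

    def probes_for_gene(self, gene: str) -> list[ProbeTarget]:
        return list(self.by_gene[gene])

    def has_overlapping_targets(self) -> bool:
        """True if any two probe targets (any gene) share a genomic position."""
        for a, b in zip(self.probes, self.probes[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return True
        return False

    def probe_covering(self, chrom: str, pos: int) -> ProbeTarget | None:
        """Return the probe whose target contains (chrom, pos), if any."""
        for p in self.probes:
            if p.chrom == chrom and p.start <= pos < p.end:
                return p
        return None

    # ------------------------------------------------------------------ I/O

    HEADER = ["chrom", "start", "end", "probe_id", "gene", "gc_fraction", "target_sequence"]

    def to_bed(self, path: str | Path) -> None:
        """Write the panel as a BED-like TSV (0-based half-open)."""
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.HEADER) + "\n")
            for p in self.probes:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t{p.gene}"
                    f"\t{p.gc_fraction:.6f}\t{p.sequence}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "ProbePanel":
        probes = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chrom, start, end, probe_id, gene, gc, seq = line.split("\t")
                probes.append(
                    ProbeTarget(
                        probe_id=probe_id,
                        gene=gene,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        gc_fraction=float(gc),
                        sequence=seq,
                    )
                )
        return cls(probes)
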