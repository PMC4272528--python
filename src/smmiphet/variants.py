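"""Pileups and somatic point-mutation filtering.

Candidate variants are called directly from per-site pileups over the probe
targets (the panel is small and fully covered by design) and carried through
six filters: base quality, minimum depth, neighboring homopolymer run,
minimum allele balance, population-database membership (COSMIC-stripped),
and recurrence in control samples.  Candidates at any allele fraction are
retained with per-filter status, because trace-level evidence (down to a
couple of reads) matters for the heterogeneity classification.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import ProbePanel

FILTER_NAMES = [
    "base_quality",
    "min_depth",
    "homopolymer",
    "min_ab",
    "population_db",
    "control_recurrence",
]

_BASES = ["A", "C", "G", "T"]

VariantKey = tuple[str, int, str, str]


class PopulationVariantSet:
    """A set of known variants (population database or COSMIC list).

    Entries are (chrom, pos, ref, alt) with 0-based positions; set semantics.
    """

    def __init__(self, entries: Iterable[VariantKey] = (), label: str = ""):
        self.entries: set[VariantKey] = {(c, int(p), r, a) for c, p, r, a in entries}
        self.label = label

    def __contains__(self, key: VariantKey) -> bool:
        return (key[0], int(key[1]), key[2], key[3]) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\n")  # pos is 0-based
            for c, p, r, a in sorted(self.entries):
                fh.write(f"{c}\t{p}\t{r}\t{a}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "PopulationVariantSet":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                c, p, r, a = line.split("\t")[:4]
                entries.append((c, int(p), r, a))
        return cls(entries, label=label or str(path))

    @classmethod
    def from_vcf(cls, path: str | Path, label: str = "") -> "PopulationVariantSet":
        import pysam

        entries = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    entries.append((rec.chrom, rec.start, rec.ref, alt))
        return cls(entries, label=label or str(path))

    @classmethod
    def load(cls, path: str | Path, label: str = "") -> "PopulationVariantSet":
        if str(path).endswith((".vcf", ".vcf.gz")):
            return cls.from_vcf(path, label)
        return cls.from_tsv(path, label)


# ------------------------------------------------------------------- pileups


def build_pileup(
    dedup_reads: pd.DataFrame, panel: ProbePanel, min_base_quality: int = 30
) -> pd.DataFrame:
    """Per-site base counts from deduplicated reads.

    Bases below ``min_base_quality`` are excluded from all counts; positions
    with zero qualifying reads are omitted.  Returns one row per
    (sample, chrom, pos) with columns ``ref``, ``depth`` and per-base counts.
    """
    if len(dedup_reads) == 0:
        return pd.DataFrame(columns=["sample_id", "chrom", "pos", "ref", *_BASES, "depth"])
    from .dedup import _canonical_order, _group_bounds

    order, keys = _canonical_order(dedup_reads, ["sample_id", "probe_id"])
    samp = dedup_reads["sample_id"].to_numpy()[order]
    prob = dedup_reads["probe_id"].to_numpy()[order]
    base_list = dedup_reads["base_calls"].to_numpy()[order]
    qual_list = dedup_reads["base_qualities"].to_numpy()[order]
    starts = _group_bounds(keys, len(dedup_reads))
    ends = np.append(starts[1:], len(dedup_reads))

    sample_col: list[tuple[str, int]] = []
    chrom_col: list[tuple[str, int]] = []
    pos_parts, ref_parts = [], []
    count_parts = {b: [] for b in _BASES}
    for a, b_end in zip(starts, ends):
        probe = panel.by_id.get(prob[a])
        if probe is None:
            raise ValueError(f"reads reference unknown probe {prob[a]}")
        n, L = b_end - a, probe.length
        joined = "".join(base_list[a:b_end])
        if len(joined) != n * L:
            raise ValueError(f"probe {probe.probe_id}: read length mismatch with panel target")
        bmat = np.frombuffer(joined.encode(), dtype=np.uint8).reshape(n, L)
        qmat = np.frombuffer("".join(qual_list[a:b_end]).encode(), dtype=np.uint8).reshape(n, L)
        ok = qmat >= min_base_quality + 33
        sample_col.append((samp[a], L))
        chrom_col.append((probe.chrom, L))
        pos_parts.append(probe.start + np.arange(L))
        ref_parts.append(np.frombuffer(probe.sequence.encode(), dtype=np.uint8))
        for base in _BASES:
            count_parts[base].append(((bmat == ord(base)) & ok).sum(axis=0))

    refs = np.concatenate(ref_parts)
    pile = pd.DataFrame(
        {
            "sample_id": np.repeat([v for v, _ in sample_col], [n for _, n in sample_col]),
            "chrom": np.repeat([v for v, _ in chrom_col], [n for _, n in chrom_col]),
            "pos": np.concatenate(pos_parts),
            "ref": refs.view("S1").astype(str),
        }
    )
    for base in _BASES:
        pile[base] = np.concatenate(count_parts[base])
    # aggregate only if distinct probes can cover the same position
    if panel.has_overlapping_targets():
        pile = pile.groupby(["sample_id", "chrom", "pos", "ref"], as_index=False)[_BASES].sum()
    pile["depth"] = pile[_BASES].sum(axis=1)
    return pile[pile["depth"] > 0].reset_index(drop=True)


# ------------------------------------------------------------------- filters


def homopolymer_pass(reference_context: str, index: int, run_length: int = 4) -> bool:
    """True unless a single-base run of >= run_length abuts or contains ``index``.

    ``reference_context`` is the reference sequence around the variant (the
    probe target, clipped at its edges); ``index`` is the variant's offset
    within it.
    """
    n = len(reference_context)
    if not 0 <= index < n:
        raise ValueError("index outside reference context")
    i = 0
    while i < n:
        j = i
        while j < n and reference_context[j] == reference_context[i]:
            j += 1
        if j - i >= run_length and i - 1 <= index <= j:
            return False
        i = j
    return True


def _homopolymer_pass_vector(sequence: str, run_length: int) -> np.ndarray:
    """Per-offset homopolymer pass flags for a probe target sequence."""
    n = len(sequence)
    passes = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= run_length:
            passes[max(i - 1, 0) : min(j + 1, n)] = False
        i = j
    return passes


def call_candidates(
    pileup: pd.DataFrame,
    panel: ProbePanel,
    min_depth: int = 30,
    min_ab: float = 0.05,
    homopolymer_run: int = 4,
) -> pd.DataFrame:
    """One candidate per (site, non-reference allele with count > 0).

    Candidates at any allele fraction are retained; ``filter_min_depth`` fails
    iff depth < min_depth, ``filter_min_ab`` fails iff allele balance is below
    the (inclusive) threshold, ``filter_homopolymer`` fails next to reference
    homopolymer runs.  Base quality is enforced structurally by the pileup
    mask, so ``filter_base_quality`` is True for every emitted candidate.
    """
    hp_pass: dict[tuple[str, int], bool] = {}
    for probe in panel.probes:
        flags = _homopolymer_pass_vector(probe.sequence, homopolymer_run)
        for off in range(probe.length):
            hp_pass[(probe.chrom, probe.start + off)] = bool(flags[off])

    rows = []
    for alt in _BASES:
        sub = pileup[(pileup["ref"] != alt) & (pileup[alt] > 0)]
        if len(sub) == 0:
            continue
        sub = sub[["sample_id", "chrom", "pos", "ref", "depth", alt]].rename(
            columns={alt: "alt_count"}
        )
        sub["alt"] = alt
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_count",
                     "allele_balance", "filter_base_quality", "filter_min_depth",
                     "filter_homopolymer", "filter_min_ab"]
        )
    calls = pd.concat(rows, ignore_index=True)
    calls["allele_balance"] = calls["alt_count"] / calls["depth"]
    calls["filter_base_quality"] = True
    calls["filter_min_depth"] = calls["depth"] >= min_depth
    calls["filter_homopolymer"] = [
        hp_pass.get((c, p), True) for c, p in zip(calls["chrom"], calls["pos"])
    ]
    calls["filter_min_ab"] = calls["allele_balance"] >= min_ab
    order = ["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_count",
             "allele_balance", "filter_base_quality", "filter_min_depth",
             "filter_homopolymer", "filter_min_ab"]
    return calls[order].sort_values(["sample_id", "chrom", "pos", "alt"]).reset_index(drop=True)


def somatic_filters(
    calls: pd.DataFrame,
    popdb: PopulationVariantSet,
    cosmic: PopulationVariantSet,
    control_calls: pd.DataFrame | None = None,
    control_min_ab: float = 0.05,
    control_min_samples: int = 2,
) -> pd.DataFrame:
    """Apply the population-database and control-recurrence filters.

    ``filter_population_db`` fails iff the variant is in the population
    database but *not* in COSMIC (the database is stripped of COSMIC entries
    so recurrent somatic hotspots are not discarded as polymorphisms).
    ``filter_control_recurrence`` fails iff the variant has allele balance
    >= ``control_min_ab`` in >= ``control_min_samples`` distinct control
    samples.  Adds ``emitted`` (all six filters pass) and ``trace`` (fails
    only the allele-balance filter).
    """
    out = calls.copy()
    keys = list(zip(out["chrom"], out["pos"], out["ref"], out["alt"]))
    out["filter_population_db"] = [not (k in popdb and k not in cosmic) for k in keys]

    recurrent: set[VariantKey] = set()
    if control_calls is not None and len(control_calls):
        hot = control_calls[control_calls["allele_balance"] >= control_min_ab]
        counts = hot.groupby(["chrom", "pos", "ref", "alt"])["sample_id"].nunique()
        recurrent = {k for k, n in counts.items() if n >= control_min_samples}
    out["filter_control_recurrence"] = [k not in recurrent for k in keys]

    flt = [f"filter_{n}" for n in FILTER_NAMES]
    out["emitted"] = out[flt].all(axis=1)
    others = [f"filter_{n}" for n in FILTER_NAMES if n != "min_ab"]
    out["trace"] = out[others].all(axis=1) & ~out["filter_min_ab"]
    return out


# ----------------------------------------------------------------------- I/O


def write_vcf(calls: pd.DataFrame, path: str | Path, panel: ProbePanel | None = None) -> None:
    """Write candidate calls as VCF 4.2 (FILTER lists failed filter names)."""
    contigs: dict[str, int] = {}
    if panel is not None:
        for p in panel.probes:
            contigs[p.chrom] = max(contigs.get(p.chrom, 0), p.end + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Deduplicated depth">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt read count">\n')
        fh.write('##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        for name in FILTER_NAMES:
            fh.write(f'##FILTER=<ID={name},Description="Failed {name} filter">\n')
        for chrom, length in sorted(contigs.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.sort_values(["chrom", "pos", "alt", "sample_id"]).itertuples():
            failed = [n for n in FILTER_NAMES if not getattr(row, f"filter_{n}", True)]
            filt = "PASS" if not failed else ";".join(failed)
            info = (
                f"DP={row.depth};AC={row.alt_count};AB={row.allele_balance:.6g}"
                f";SAMPLE={row.sample_id}"
            )
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\t{info}\n")
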