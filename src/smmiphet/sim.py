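"""Synthetic multi-region tumor generator for smMIP capture data.

Emulates the statistical structure a multi-region targeted-capture analysis
assumes: a clone tree with truncal and region-restricted subclonal point
mutations at purity-scaled allele fractions, focal multi-probe gene
amplifications, GC-dependent capture efficiency, PCR duplication over
molecular tags, sequencing error, germline heterozygous variants, and tumor
contamination of the "normal" control tissue.

Reads are produced as tagged records (sample, probe, molecular tag, base
calls, base qualities) — the post-alignment representation the downstream
modules consume — together with ground-truth tables (true allele fractions,
true copy ratios, true molecules per probe) for calibration tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ProbePanel, ProbeTarget
from .util import substream

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODES = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)

READ_COLUMNS = ["sample_id", "probe_id", "molecular_tag", "base_calls", "base_qualities"]


# --------------------------------------------------------------------- truth


@dataclass
class Clone:
    """A tumor subclone with per-region cell fractions.

    ``cell_fraction[r]`` is the fraction of *tumor* cells in region ``r`` that
    belong to this clone (cumulative down the tree: a clone's cells include
    its descendants', so a child's fraction never exceeds its parent's).
    A germline "clone" marks variants carried by every cell of the patient.
    """

    clone_id: str
    parent_id: str | None
    cell_fraction: Mapping[str, float]
    germline: bool = False


@dataclass(frozen=True)
class Mutation:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    clone_id: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Amplification:
    gene: str
    total_copies: int  # total copies of the locus in cells of the clone
    clone_id: str


@dataclass
class CloneTree:
    """Clonal structure of one tumor: clones, point mutations, amplifications."""

    clones: list[Clone]
    mutations: list[Mutation] = field(default_factory=list)
    amplifications: list[Amplification] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {c.clone_id: c for c in self.clones}
        if len(by_id) != len(self.clones):
            raise ValueError("duplicate clone_id")
        for c in self.clones:
            if c.parent_id is not None:
                parent = by_id.get(c.parent_id)
                if parent is None:
                    raise ValueError(f"clone {c.clone_id}: unknown parent {c.parent_id}")
                for r, f in c.cell_fraction.items():
                    pf = parent.cell_fraction.get(r, 0.0)
                    if f > pf + 1e-9:
                        raise ValueError(
                            f"clone {c.clone_id}: cell fraction {f} in region {r} "
                            f"exceeds parent's {pf}"
                        )
        for a in self.amplifications:
            if a.total_copies < 2:
                raise ValueError("amplification total_copies must be >= 2")
        self._by_id = by_id

    def clone(self, clone_id: str) -> Clone:
        return self._by_id[clone_id]

    def carrier_fraction(self, clone_id: str, region_id: str, purity: float) -> float:
        """Fraction of all cells in a region that carry the clone's events."""
        c = self._by_id[clone_id]
        if c.germline:
            return 1.0
        return purity * c.cell_fraction.get(region_id, 0.0)


@dataclass
class RegionTruth:
    """Expected allele fractions and coverage ratios for one tissue piece."""

    region_id: str
    purity: float
    expected_af: dict[tuple[str, int, str, str], float]
    expected_ratio: dict[str, float]
    is_control: bool = False


def region_truth(
    tree: CloneTree,
    panel: ProbePanel,
    region_id: str,
    purity: float,
    is_control: bool = False,
) -> RegionTruth:
    """Derive expected AFs and coverage ratios for one region.

    A heterozygous mutation carried by a cell fraction ``A`` of all cells has
    expected allele fraction ``A / D`` where ``D`` is the mean copies per cell
    at the locus (2 without amplification).  A gene amplified to ``C`` total
    copies in a cell fraction ``A`` has expected coverage ratio
    ``(A*C + (1-A)*2) / 2`` versus a diploid control.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    ratios: dict[str, float] = {g: 1.0 for g in panel.genes}
    amp_carrier: dict[str, float] = {}
    for a in tree.amplifications:
        A = tree.carrier_fraction(a.clone_id, region_id, purity)
        amp_carrier[a.gene] = amp_carrier.get(a.gene, 0.0) + A
        ratios[a.gene] = ratios.get(a.gene, 1.0) + A * (a.total_copies - 2) / 2.0
    afs: dict[tuple[str, int, str, str], float] = {}
    for m in tree.mutations:
        probe = panel.probe_covering(m.chrom, m.pos)
        if probe is None:
            raise ValueError(f"mutation {m.key} falls outside all probe targets")
        carrier = tree.carrier_fraction(m.clone_id, region_id, purity)
        copies = 2.0
        if probe.gene in amp_carrier:
            A = amp_carrier[probe.gene]
            C = next(a.total_copies for a in tree.amplifications if a.gene == probe.gene)
            copies = A * C + (1.0 - A) * 2.0
        afs[m.key] = carrier / copies
    return RegionTruth(region_id, purity, afs, ratios, is_control=is_control)


# --------------------------------------------------------------------- panel


def gaussian_gc_bias(k: float = 6.0, center: float = 0.45) -> Callable[[float], float]:
    """Capture-efficiency multiplier exp(-k*(gc - center)^2), shared across samples."""

    def bias(gc: float) -> float:
        return float(np.exp(-k * (gc - center) ** 2))

    return bias


def build_panel(
    n_genes: int,
    probes_per_gene: int | tuple[int, int],
    tag_length: int = 10,
    gc_profile: tuple[float, float] | Callable[[np.random.Generator], float] = (0.2, 0.7),
    target_length: int = 100,
    genes_per_chrom: int = 2,
    gene_names: Sequence[str] | None = None,
    seed: int = 0,
) -> ProbePanel:
    """Generate a synthetic capture panel.

    Each gene occupies a contiguous block of non-overlapping probe targets;
    genes are laid out ``genes_per_chrom`` per chromosome so that downstream
    segmentation sees multi-gene stretches with forced chromosome breaks.
    GC fractions are drawn from ``gc_profile`` (uniform(low, high) by default)
    and the reference sequence is generated to match.  Deterministic for a
    fixed seed.  ``tag_length`` is recorded by the simulator, not the panel.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if isinstance(probes_per_gene, int):
        if probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        n_probes = [probes_per_gene] * n_genes
    else:
        lo, hi = probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid probes_per_gene range")
        n_probes = None  # drawn below
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    rng = substream(seed, "panel")
    if n_probes is None:
        lo, hi = probes_per_gene  # type: ignore[misc]
        n_probes = [int(rng.integers(lo, hi + 1)) for _ in range(n_genes)]
    if gene_names is None:
        gene_names = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    elif len(gene_names) < n_genes:
        raise ValueError("gene_names shorter than n_genes")

    probes: list[ProbeTarget] = []
    for gi in range(n_genes):
        gene = gene_names[gi]
        chrom = f"chr{gi // genes_per_chrom + 1}"
        slot = gi % genes_per_chrom
        gene_start = 1_000_000 + slot * 5_000_000
        for k in range(n_probes[gi]):
            start = gene_start + k * (target_length + 100)
            if callable(gc_profile):
                gc_target = float(gc_profile(rng))
            else:
                gc_target = float(rng.uniform(gc_profile[0], gc_profile[1]))
            # realize the drawn GC fraction exactly (to rounding), so panel GC
            # composition is controlled by the profile, not binomial noise
            n_gc = int(round(gc_target * target_length))
            is_gc = np.zeros(target_length, dtype=bool)
            is_gc[rng.permutation(target_length)[:n_gc]] = True
            within = rng.integers(0, 2, target_length)
            codes = np.where(is_gc, np.where(within == 0, 2, 1), np.where(within == 0, 0, 3))
            seq = _BASE_ARR[codes].tobytes().decode()
            gc_actual = float(is_gc.mean())
            probes.append(
                ProbeTarget(
                    probe_id=f"{gene}_p{k:03d}",
                    gene=gene,
                    chrom=chrom,
                    start=start,
                    end=start + target_length,
                    gc_fraction=gc_actual,
                    sequence=seq,
                )
            )
    return ProbePanel(probes)


# ---------------------------------------------------------------- simulation


def _sequential_tags(n: int, tag_length: int, start: int = 0) -> np.ndarray:
    """Collision-free tags: base-4 encoding of the molecule index over ACGT."""
    if n > 4**tag_length:
        raise ValueError("tag space exhausted in sequential mode")
    idx = np.arange(start, start + n, dtype=np.int64)
    codes = np.empty((n, tag_length), dtype=np.uint8)
    for j in range(tag_length - 1, -1, -1):
        codes[:, j] = idx % 4
        idx //= 4
    return codes


def _codes_to_strings(codes: np.ndarray, alphabet: np.ndarray) -> np.ndarray:
    """Rows of a (n, L) code matrix as an array of length-L strings."""
    L = codes.shape[1]
    ascii_rows = np.ascontiguousarray(alphabet[codes]).view(f"S{L}").ravel()
    return ascii_rows.astype(f"U{L}")


class _StringColumnBuilder:
    """Accumulates per-probe ASCII code matrices; converts to strings in bulk.

    Converting many small (reads x length) matrices one by one dominates
    simulation time; batching rows of equal width into one fixed-width
    conversion is much cheaper.
    """

    def __init__(self) -> None:
        self._parts: list[np.ndarray] = []  # ascii matrices
        self._rows = 0

    def append(self, ascii_matrix: np.ndarray) -> None:
        self._parts.append(ascii_matrix)
        self._rows += ascii_matrix.shape[0]

    def build(self) -> np.ndarray:
        out = np.empty(self._rows, dtype=object)
        by_width: dict[int, list[tuple[int, np.ndarray]]] = {}
        row = 0
        for m in self._parts:
            by_width.setdefault(m.shape[1], []).append((row, m))
            row += m.shape[0]
        for L, items in by_width.items():
            block = np.vstack([m for _, m in items])
            strings = block.view(f"S{L}").ravel().astype(f"U{L}").astype(object)
            off = 0
            for start, m in items:
                out[start : start + m.shape[0]] = strings[off : off + m.shape[0]]
                off += m.shape[0]
        return out


def simulate_reads(
    panel: ProbePanel,
    tree: CloneTree,
    regions: Sequence[RegionTruth],
    *,
    tumor_id: str | None = None,
    depth: float = 500.0,
    gc_bias: Callable[[float], float] | None = None,
    dup_rate: float = 1.0,
    error_rate: float = 0.001,
    low_quality_rate: float = 0.02,
    low_quality_phred: int = 20,
    high_quality_phred: int = 37,
    tag_length: int = 10,
    tag_mode: str = "random",
    dup_allele_bias: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate tagged reads for every region of one tumor.

    Per probe, the unique molecule count is Poisson(depth * gc_bias(gc) *
    expected_ratio(gene)); each molecule receives a molecular tag (random, or
    sequential in collision-free mode) and ``1 + Geometric`` PCR copies with
    mean extra copies ``dup_rate``; each molecule carries a mutant allele with
    probability equal to the region's expected AF at that locus; per-read base
    errors are injected i.i.d. at ``error_rate``; a fraction of base calls get
    low quality scores.  ``dup_allele_bias`` multiplies the duplication rate of
    mutant molecules (allele-correlated PCR amplification).

    Returns the reads table and ground-truth tables (``true_variants``,
    ``true_copy``, ``true_molecules``, ``region_purity``).  Deterministic for
    fixed inputs and seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if dup_rate < 0:
        raise ValueError("dup_rate must be >= 0")
    if tag_mode not in ("random", "sequential"):
        raise ValueError("tag_mode must be 'random' or 'sequential'")
    if gc_bias is None:
        gc_bias = gaussian_gc_bias()
    for m in tree.mutations:
        if panel.probe_covering(m.chrom, m.pos) is None:
            raise ValueError(f"mutation at {m.chrom}:{m.pos} outside all probe targets")

    # mutations indexed per probe
    muts_by_probe: dict[str, list[Mutation]] = {}
    for m in tree.mutations:
        probe = panel.probe_covering(m.chrom, m.pos)
        assert probe is not None
        if probe.sequence[m.pos - probe.start] != m.ref:
            raise ValueError(f"mutation ref {m.ref} mismatches panel reference at {m.chrom}:{m.pos}")
        muts_by_probe.setdefault(probe.probe_id, []).append(m)

    col_sample: list[tuple[str, int]] = []  # (value, run length) — expanded at the end
    col_probe: list[tuple[str, int]] = []
    col_tags = _StringColumnBuilder()
    col_calls = _StringColumnBuilder()
    col_quals = _StringColumnBuilder()
    truth_mol = []
    truth_var = []
    truth_copy = []
    truth_purity = []
    n_collisions = 0

    for region in regions:
        sample_id = f"{tumor_id}_{region.region_id}" if tumor_id else region.region_id
        rng_mol = substream(seed, "molecules", sample_id)
        rng_tags = substream(seed, "tags", sample_id)
        rng_err = substream(seed, "errors", sample_id)
        truth_purity.append(
            {"sample_id": sample_id, "region_id": region.region_id, "purity": region.purity,
             "is_control": region.is_control}
        )
        for gene in panel.genes:
            truth_copy.append(
                {"sample_id": sample_id, "gene": gene,
                 "expected_ratio": region.expected_ratio.get(gene, 1.0)}
            )
        for m in tree.mutations:
            truth_var.append(
                {"sample_id": sample_id, "chrom": m.chrom, "pos": m.pos, "ref": m.ref,
                 "alt": m.alt, "clone_id": m.clone_id,
                 "germline": tree.clone(m.clone_id).germline,
                 "expected_af": region.expected_af.get(m.key, 0.0)}
            )

        for probe in panel.probes:
            L = probe.length
            lam = depth * gc_bias(probe.gc_fraction) * region.expected_ratio.get(probe.gene, 1.0)
            n = int(rng_mol.poisson(lam))
            truth_mol.append(
                {"sample_id": sample_id, "probe_id": probe.probe_id, "gene": probe.gene,
                 "n_molecules": n, "expected_molecules": lam})
            if n == 0:
                continue

            muts = muts_by_probe.get(probe.probe_id, [])
            mut_flags = np.zeros((n, len(muts)), dtype=bool)
            for j, m in enumerate(muts):
                af = region.expected_af.get(m.key, 0.0)
                if af > 0:
                    mut_flags[:, j] = rng_mol.random(n) < af

            if tag_mode == "sequential":
                tag_codes = _sequential_tags(n, tag_length)
            else:
                tag_codes = rng_tags.integers(0, 4, size=(n, tag_length)).astype(np.uint8)
                if tag_length <= 31:  # birthday collisions, counted on packed tags
                    packed = tag_codes @ (4 ** np.arange(tag_length, dtype=np.int64))
                    n_collisions += n - len(np.unique(packed))

            if dup_rate > 0:
                rate = np.full(n, dup_rate)
                if dup_allele_bias != 1.0 and muts:
                    rate[mut_flags.any(axis=1)] = dup_rate * dup_allele_bias
                extra = rng_mol.geometric(1.0 / (1.0 + rate)) - 1
            else:
                extra = np.zeros(n, dtype=np.int64)
            copies = 1 + extra
            rep = np.repeat(np.arange(n), copies)
            n_reads = rep.size

            ref_codes = np.array([_BASE_CODES[b] for b in probe.sequence], dtype=np.uint8)
            mol_codes = np.tile(ref_codes, (n, 1))
            for j, m in enumerate(muts):
                mol_codes[mut_flags[:, j], m.pos - probe.start] = _BASE_CODES[m.alt]
            read_codes = mol_codes[rep]

            # errors and low-quality bases are placed by sampling a Binomial
            # number of flat positions (duplicate draws are vanishingly rare
            # at these rates and probe sizes)
            if error_rate > 0:
                k = int(rng_err.binomial(n_reads * L, error_rate))
                if k:
                    flat = rng_err.integers(0, n_reads * L, size=k)
                    shift = rng_err.integers(1, 4, size=k).astype(np.uint8)
                    codes_flat = read_codes.reshape(-1)
                    codes_flat[flat] = (codes_flat[flat] + shift) % 4
            quals = np.full((n_reads, L), high_quality_phred, dtype=np.uint8)
            if low_quality_rate > 0:
                k = int(rng_err.binomial(n_reads * L, low_quality_rate))
                if k:
                    flat = rng_err.integers(0, n_reads * L, size=k)
                    quals.reshape(-1)[flat] = low_quality_phred

            col_sample.append((sample_id, n_reads))
            col_probe.append((probe.probe_id, n_reads))
            col_tags.append(_BASE_ARR[tag_codes][rep])
            col_calls.append(_BASE_ARR[read_codes])
            col_quals.append(quals + 33)

    if n_collisions:
        logger.info("random molecular tags: %d birthday collisions across probes", n_collisions)
    if col_sample:
        reads = pd.DataFrame(
            {
                "sample_id": np.repeat([v for v, _ in col_sample], [n for _, n in col_sample]),
                "probe_id": np.repeat([v for v, _ in col_probe], [n for _, n in col_probe]),
                "molecular_tag": col_tags.build(),
                "base_calls": col_calls.build(),
                "base_qualities": col_quals.build(),
            }
        )
    else:
        reads = pd.DataFrame({c: [] for c in READ_COLUMNS})
    truth = {
        "true_variants": pd.DataFrame(truth_var),
        "true_copy": pd.DataFrame(truth_copy),
        "true_molecules": pd.DataFrame(truth_mol),
        "region_purity": pd.DataFrame(truth_purity),
    }
    return reads, truth


def simulate_molecule_counts(
    panel: ProbePanel,
    regions: Sequence[RegionTruth],
    *,
    tumor_id: str | None = None,
    depth: float = 500.0,
    gc_bias: Callable[[float], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Unique-molecule counts per (sample, probe) without read-level detail.

    This is exactly the count stage of :func:`simulate_reads` (same substream,
    same Poisson model); it is the natural input for coverage-ratio analyses
    where the read-level content is irrelevant.
    """
    if gc_bias is None:
        gc_bias = gaussian_gc_bias()
    rows = []
    for region in regions:
        sample_id = f"{tumor_id}_{region.region_id}" if tumor_id else region.region_id
        rng_mol = substream(seed, "molecules", sample_id)
        for probe in panel.probes:
            lam = depth * gc_bias(probe.gc_fraction) * region.expected_ratio.get(probe.gene, 1.0)
            rows.append(
                {"sample_id": sample_id, "probe_id": probe.probe_id, "gene": probe.gene,
                 "count": int(rng_mol.poisson(lam))}
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- output


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False, columns=READ_COLUMNS)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return df[READ_COLUMNS]


def write_reads_sam(reads: pd.DataFrame, panel: ProbePanel, path: str | Path) -> None:
    """Optional SAM export: reads placed at their probe target, tag in the RX field."""
    import pysam

    contigs: dict[str, int] = {}
    for p in panel.probes:
        contigs[p.chrom] = max(contigs.get(p.chrom, 0), p.end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(contigs.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(reads.itertuples()):
            probe = panel.by_id[row.probe_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{row.sample_id}.{row.probe_id}.{i}"
            a.query_sequence = row.base_calls
            a.query_qualities = pysam.qualitystring_to_array(row.base_qualities)
            a.reference_name = probe.chrom
            a.reference_start = probe.start
            a.cigarstring = f"{probe.length}M"
            a.mapping_quality = 60
            a.set_tag("RX", row.molecular_tag)
            a.set_tag("RG", row.sample_id)
            out.write(a)


def write_truth_tables(truth: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in truth.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.8g")
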