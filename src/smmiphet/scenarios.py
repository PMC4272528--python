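"""Preset multi-region tumor scenarios.

The cohort preset emulates a 14-tumor glioma study: each tumor dissected
into 3-5 regions (A-E) plus one grossly-uninvolved control tissue (X), with
three tumors carrying genuine subclonal driver events anchored by truncal
evidence (point-mutation heterogeneity with a truncal point anchor; subclonal
receptor-kinase amplification with a truncal amplification anchor; subclonal
amplification with a truncal point-mutation anchor), one cellularity-
confounded tumor (subset amplification with no truncal anchor), one
hypermutated tumor dominated by C>A-class transversions, and homogeneous
tumors for the remainder.  Germline heterozygous variants populate the
population database; driver mutations populate the COSMIC list; controls are
lightly contaminated with tumor cells except the designated clean one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .sim import (
    Amplification,
    Clone,
    CloneTree,
    Mutation,
    RegionTruth,
    build_panel,
    region_truth,
    simulate_reads,
)
from .util import substream
from .variants import PopulationVariantSet

GLIOMA_GENES = [
    "TP53", "RB1", "IDH1", "EGFR", "PDGFRA", "KIT", "PTEN", "NF1", "PIK3CA", "ATM",
]
_MUT_GENE_POOL = ["TP53", "RB1", "IDH1", "PTEN", "NF1", "PIK3CA", "ATM"]
_AMP_COPIES = 10

PLANTED_HETEROGENEOUS = {"T05", "T06", "T09"}


@dataclass
class TumorScenario:
    tumor_id: str
    kind: str
    tree: CloneTree
    regions: list[RegionTruth]
    planted_heterogeneous: bool
    contamination: float


@dataclass
class CohortScenario:
    panel: ProbePanel
    tumors: list[TumorScenario]
    popdb: PopulationVariantSet
    cosmic: PopulationVariantSet
    planted: set[str] = field(default_factory=lambda: set(PLANTED_HETEROGENEOUS))

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for t in self.tumors:
            for r in t.regions:
                rows.append(
                    {
                        "sample_id": f"{t.tumor_id}_{r.region_id}",
                        "tumor_id": t.tumor_id,
                        "region_id": r.region_id,
                        "is_control": r.is_control,
                    }
                )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------- mutations


def _hp_safe_offsets(sequence: str, run_length: int = 4) -> np.ndarray:
    from .variants import _homopolymer_pass_vector

    return np.flatnonzero(_homopolymer_pass_vector(sequence, run_length))


def _pick_locus(
    panel: ProbePanel,
    gene: str,
    rng: np.random.Generator,
    used: set,
    ref_in: str | None = None,
) -> tuple[str, int, str]:
    """A variant position in a gene that survives the homopolymer filter."""
    probes = panel.probes_for_gene(gene)
    for _ in range(200):
        probe = probes[int(rng.integers(len(probes)))]
        offs = _hp_safe_offsets(probe.sequence)
        # keep clear of target edges so local context is fully within the probe
        offs = offs[(offs >= 2) & (offs < probe.length - 2)]
        if len(offs) == 0:
            continue
        off = int(offs[int(rng.integers(len(offs)))])
        pos = probe.start + off
        ref = probe.sequence[off]
        if (probe.chrom, pos) in used:
            continue
        if ref_in is not None and ref not in ref_in:
            continue
        used.add((probe.chrom, pos))
        return probe.chrom, pos, ref
    raise RuntimeError(f"could not place a mutation in gene {gene}")


def _alt_base(ref: str, rng: np.random.Generator, exclude: str = "") -> str:
    choices = [b for b in "ACGT" if b != ref and b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def _mutation(panel, gene, rng, used, clone_id, spectrum_class=None) -> Mutation:
    if spectrum_class == "C>A":
        chrom, pos, ref = _pick_locus(panel, gene, rng, used, ref_in="CG")
        alt = "A" if ref == "C" else "T"
    elif spectrum_class == "not_C>A":
        chrom, pos, ref = _pick_locus(panel, gene, rng, used)
        # exclude the C>A-class substitution for this reference base
        exclude = {"C": "A", "G": "T"}.get(ref, "")
        alt = _alt_base(ref, rng, exclude=exclude)
    else:
        chrom, pos, ref = _pick_locus(panel, gene, rng, used)
        alt = _alt_base(ref, rng)
    return Mutation(chrom, pos, ref, alt, clone_id)


def _germline_clone(region_ids: list[str]) -> Clone:
    return Clone("germline", None, {r: 1.0 for r in region_ids}, germline=True)


# -------------------------------------------------------------------- tumors


def _finish(tumor_id, kind, panel, tree, letters, purities, contamination, planted):
    regions = [
        region_truth(tree, panel, letter, purity)
        for letter, purity in zip(letters, purities)
    ]
    regions.append(region_truth(tree, panel, "X", contamination, is_control=True))
    return TumorScenario(tumor_id, kind, tree, regions, planted, contamination)


def make_tumor(
    kind: str,
    tumor_id: str,
    panel: ProbePanel,
    rng: np.random.Generator,
    used_loci: set,
    contamination: float = 0.0,
    n_regions: int = 5,
    n_mutations: int = 2,
    amp_gene: str | None = None,
) -> TumorScenario:
    """Build the clone tree and region truths for one tumor of a given kind."""
    letters = list("ABCDE"[:n_regions])
    all_regions = letters + ["X"]
    trunk_cf = {r: 1.0 for r in letters} | {"X": 1.0}

    if kind == "homogeneous":
        purities = rng.uniform(0.35, 0.85, n_regions)
        clones = [_germline_clone(all_regions), Clone("trunk", None, trunk_cf)]
        muts = [_mutation(panel, _MUT_GENE_POOL[int(rng.integers(len(_MUT_GENE_POOL)))],
                          rng, used_loci, "trunk") for _ in range(n_mutations)]
        # high-level truncal amplification: stays above the 3x call threshold
        # even in the lowest-purity regions of the draw
        amps = [Amplification(amp_gene, 2 * _AMP_COPIES, "trunk")] if amp_gene else []
        tree = CloneTree(clones, muts, amps)
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, False)

    if kind == "point_heterogeneous":
        # truncal point anchor; two high-AF subclonal mutations in disjoint
        # region pairs, each at trace level in the shared middle region
        purities = rng.uniform(0.72, 0.90, 5)
        sub1_cf = {"A": 1.0, "B": 1.0, "C": 0.02, "D": 0.0, "E": 0.0, "X": 0.0}
        sub2_cf = {"A": 0.0, "B": 0.0, "C": 0.02, "D": 1.0, "E": 1.0, "X": 0.0}
        clones = [
            _germline_clone(all_regions),
            Clone("trunk", None, trunk_cf),
            Clone("sub1", "trunk", sub1_cf),
            Clone("sub2", "trunk", sub2_cf),
        ]
        muts = [
            _mutation(panel, "IDH1", rng, used_loci, "trunk"),
            _mutation(panel, "TP53", rng, used_loci, "sub1"),
            _mutation(panel, "RB1", rng, used_loci, "sub2"),
        ]
        tree = CloneTree(clones, muts, [])
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, True)

    if kind == "amp_heterogeneous":
        # truncal amplification anchor; subclonal adjacent-gene amplifications
        purities = rng.uniform(0.70, 0.90, 5)
        sub_cf = {"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0, "E": 0.0, "X": 0.0}
        clones = [
            _germline_clone(all_regions),
            Clone("trunk", None, trunk_cf),
            Clone("sub", "trunk", sub_cf),
        ]
        amps = [
            Amplification("EGFR", _AMP_COPIES, "trunk"),
            Amplification("PDGFRA", _AMP_COPIES, "sub"),
            Amplification("KIT", _AMP_COPIES, "sub"),
        ]
        tree = CloneTree(clones, [], amps)
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, True)

    if kind == "amp_single_region":
        # truncal point-mutation anchor; one-region amplification
        purities = np.concatenate([rng.uniform(0.70, 0.90, 1), rng.uniform(0.55, 0.85, 4)])
        sub_cf = {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0, "X": 0.0}
        clones = [
            _germline_clone(all_regions),
            Clone("trunk", None, trunk_cf),
            Clone("sub", "trunk", sub_cf),
        ]
        muts = [_mutation(panel, "PTEN", rng, used_loci, "trunk")]
        amps = [
            Amplification("PDGFRA", _AMP_COPIES + 2, "sub"),
            Amplification("KIT", _AMP_COPIES + 2, "sub"),
        ]
        tree = CloneTree(clones, muts, amps)
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, True)

    if kind == "amp_confounded":
        # subset amplification with no truncal anchor: the cellularity trap
        purities = rng.uniform(0.55, 0.80, 5)
        sub_cf = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 1.0, "E": 1.0, "X": 0.0}
        clones = [
            _germline_clone(all_regions),
            Clone("trunk", None, trunk_cf),
            Clone("sub", "trunk", sub_cf),
        ]
        amps = [Amplification("EGFR", _AMP_COPIES + 2, "sub")]
        tree = CloneTree(clones, [], amps)
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, False)

    if kind == "hypermutated":
        purities = rng.uniform(0.50, 0.85, n_regions)
        clones = [_germline_clone(all_regions), Clone("trunk", None, trunk_cf)]
        muts = []
        for i in range(16):
            gene = _MUT_GENE_POOL[int(rng.integers(len(_MUT_GENE_POOL)))]
            cls = "C>A" if i < 8 else "not_C>A"
            muts.append(_mutation(panel, gene, rng, used_loci, "trunk", spectrum_class=cls))
        tree = CloneTree(clones, muts, [])
        return _finish(tumor_id, kind, panel, tree, letters, purities, contamination, False)

    raise ValueError(f"unknown tumor kind: {kind}")


def _add_germline(
    scenario: TumorScenario, panel: ProbePanel, rng: np.random.Generator,
    used_loci: set, n: int = 5,
) -> list[Mutation]:
    genes = panel.genes
    muts = []
    for _ in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        muts.append(_mutation(panel, gene, rng, used_loci, "germline"))
    tree = scenario.tree
    tree.mutations.extend(muts)
    # refresh region truths to include the new loci
    scenario.regions = [
        region_truth(tree, panel, r.region_id, r.purity, is_control=r.is_control)
        for r in scenario.regions
    ]
    return muts


# -------------------------------------------------------------------- cohort

_COHORT_SPECS = [
    ("T01", "homogeneous", dict(n_mutations=2, n_regions=5)),
    ("T02", "homogeneous", dict(n_mutations=2, n_regions=5, amp_gene="EGFR")),
    ("T03", "homogeneous", dict(n_mutations=1, n_regions=5)),
    ("T04", "homogeneous", dict(n_mutations=3, n_regions=5, amp_gene="PDGFRA")),
    ("T05", "amp_heterogeneous", {}),
    ("T06", "amp_single_region", {}),
    ("T07", "homogeneous", dict(n_mutations=0, n_regions=4)),
    ("T08", "homogeneous", dict(n_mutations=3, n_regions=5)),
    ("T09", "point_heterogeneous", {}),
    ("T10", "homogeneous", dict(n_mutations=1, n_regions=3)),
    ("T11", "homogeneous", dict(n_mutations=2, n_regions=4)),
    ("T12", "hypermutated", dict(n_regions=5)),
    ("T13", "homogeneous", dict(n_mutations=3, n_regions=3)),
    ("T14", "amp_confounded", {}),
]


def cohort_panel(seed: int = 0, probes_per_gene: int = 16, target_length: int = 80) -> ProbePanel:
    return build_panel(
        n_genes=len(GLIOMA_GENES),
        probes_per_gene=probes_per_gene,
        gc_profile=(0.30, 0.60),
        target_length=target_length,
        gene_names=GLIOMA_GENES,
        seed=seed,
    )


def cohort_scenario(seed: int = 0, panel: ProbePanel | None = None) -> CohortScenario:
    """The 14-tumor preset: 3 planted heterogeneous tumors, 11 others."""
    if panel is None:
        panel = cohort_panel(seed=seed)
    rng = substream(seed, "scenario")
    used: set = set()
    tumors = []
    germline_keys = []
    driver_keys = []
    for tumor_id, kind, kwargs in _COHORT_SPECS:
        contamination = 0.0 if kind == "hypermutated" else float(rng.uniform(0.0, 0.06))
        t = make_tumor(kind, tumor_id, panel, rng, used, contamination=contamination, **kwargs)
        germline_keys.extend(m.key for m in _add_germline(t, panel, rng, used, n=5))
        driver_keys.extend(
            m.key for m in t.tree.mutations if not t.tree.clone(m.clone_id).germline
        )
        tumors.append(t)
    # decoy entries so the databases are not exactly the truth sets
    decoys_pop = [_mutation(panel, panel.genes[int(rng.integers(len(panel.genes)))],
                            rng, used, "decoy").key for _ in range(20)]
    decoys_cos = [_mutation(panel, panel.genes[int(rng.integers(len(panel.genes)))],
                            rng, used, "decoy").key for _ in range(10)]
    popdb = PopulationVariantSet(germline_keys + decoys_pop, label="population_db")
    cosmic = PopulationVariantSet(driver_keys + decoys_cos, label="cosmic")
    return CohortScenario(panel=panel, tumors=tumors, popdb=popdb, cosmic=cosmic)


def tumor_scenario(
    kind: str, seed: int = 0, tumor_id: str | None = None, panel: ProbePanel | None = None
) -> tuple[ProbePanel, TumorScenario, PopulationVariantSet, PopulationVariantSet]:
    """A single-tumor scenario (same panel construction as the cohort preset)."""
    if panel is None:
        panel = cohort_panel(seed=seed)
    rng = substream(seed, "scenario", kind)
    used: set = set()
    t = make_tumor(kind, tumor_id or kind.upper(), panel, rng, used)
    germ = _add_germline(t, panel, rng, used, n=5)
    popdb = PopulationVariantSet([m.key for m in germ], label="population_db")
    drivers = [m.key for m in t.tree.mutations if not t.tree.clone(m.clone_id).germline]
    cosmic = PopulationVariantSet(drivers, label="cosmic")
    return panel, t, popdb, cosmic


def simulate_cohort(
    scenario: CohortScenario,
    seed: int = 0,
    depth: float = 100.0,
    dup_rate: float = 0.2,
    error_rate: float = 0.001,
    **sim_kwargs,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate tagged reads for every sample of the cohort preset."""
    all_reads = []
    all_truth: dict[str, list[pd.DataFrame]] = {}
    for t in scenario.tumors:
        reads, truth = simulate_reads(
            scenario.panel,
            t.tree,
            t.regions,
            tumor_id=t.tumor_id,
            depth=depth,
            dup_rate=dup_rate,
            error_rate=error_rate,
            seed=seed,
            **sim_kwargs,
        )
        all_reads.append(reads)
        for k, v in truth.items():
            all_truth.setdefault(k, []).append(v)
    reads = pd.concat(all_reads, ignore_index=True)
    truth = {k: pd.concat(v, ignore_index=True) for k, v in all_truth.items()}
    return reads, truth
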