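"""Event matrices, the cellularity guard, verdicts, and mutation spectra."""

from __future__ import annotations

import pandas as pd
import pytest

import smmiphet as sp
from smmiphet.heterogeneity import (
    ABSENT,
    HETEROGENEOUS,
    HOMOGENEOUS,
    INDETERMINATE,
    NO_EVENTS,
    NOT_ASSAYABLE,
    PRESENT,
    PRESENT_HIGH,
    TRACE,
)


def snv_call(sample, pos, ab, depth=400, ref="C", alt="T", chrom="chr1", **filters):
    row = {
        "sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "depth": depth, "alt_count": int(round(ab * depth)), "allele_balance": ab,
        "filter_base_quality": True, "filter_min_depth": True, "filter_homopolymer": True,
        "filter_min_ab": ab >= 0.05, "filter_population_db": True,
        "filter_control_recurrence": True,
    }
    row.update({f"filter_{k}": v for k, v in filters.items()})
    flt = [c for c in row if c.startswith("filter_")]
    row["emitted"] = all(row[c] for c in flt)
    row["trace"] = all(row[c] for c in flt if c != "filter_min_ab") and not row["filter_min_ab"]
    return row


def est_table(per_gene: dict[str, float], not_assayable=()) -> pd.DataFrame:
    rows = []
    for gene, e in per_gene.items():
        if gene in not_assayable:
            call = "not_assayable"
        elif e > 6:
            call = "highly_amplified"
        elif e > 3:
            call = "amplified"
        else:
            call = "none"
        rows.append({"gene": gene, "n_eligible_probes": 16, "R": e, "estimate": e, "call": call})
    return pd.DataFrame(rows)


def build(tumor_id, region_afs: dict[str, dict[int, float]], amp_est=None, **kwargs):
    """region_afs: region -> {pos: AF}; amp_est: region -> {gene: estimate}."""
    regions = sorted(region_afs)
    region_samples = {r: f"{tumor_id}_{r}" for r in regions}
    rows = [snv_call(f"{tumor_id}_{r}", pos, ab) for r, afs in region_afs.items()
            for pos, ab in afs.items()]
    calls = pd.DataFrame(rows) if rows else pd.DataFrame(columns=list(snv_call("s", 0, 0.1)))
    genes = sorted({g for d in (amp_est or {}).values() for g in d})
    estimates = {
        f"{tumor_id}_{r}": est_table({g: (amp_est or {}).get(r, {}).get(g, 1.0) for g in genes}
                                     or {"DUMMY": 1.0})
        for r in regions
    }
    return sp.build_event_matrix(tumor_id, region_samples, calls, estimates, **kwargs)


def test_status_thresholds():
    m = build("T", {"A": {10: 0.35, 20: 0.005, 30: 0.15}, "B": {20: 0.40}},
              amp_est={"A": {"EGFR": 2.9, "PDGFRA": 3.1}, "B": {"EGFR": 4.0, "PDGFRA": 1.0}})
    sa = m.statuses["A"]
    assert sa["chr1:10:C>T"] == PRESENT_HIGH          # AF > 0.30
    assert sa["chr1:30:C>T"] == PRESENT               # 0.05 <= AF <= 0.30
    assert sa["chr1:20:C>T"] == TRACE                 # AF < 1% with >= 2 reads
    assert m.statuses["B"]["chr1:10:C>T"] == ABSENT
    assert sa["amp:EGFR"] == ABSENT                   # estimate 2.9 and assayable
    assert sa["amp:PDGFRA"] == PRESENT                # estimate > 3


def test_trace_needs_two_reads():
    m = build("T", {"A": {10: 0.3, 20: 0.004}, "B": {10: 0.3, 20: 0.3}})
    # 0.004 * 400 = 1.6 -> rounds to 2 reads: trace
    assert m.statuses["A"]["chr1:20:C>T"] == TRACE
    calls = pd.DataFrame([snv_call("T_A", 10, 0.3), snv_call("T_A", 20, 0.0025),
                          snv_call("T_B", 10, 0.3), snv_call("T_B", 20, 0.3)])
    m2 = sp.build_event_matrix("T", {"A": "T_A", "B": "T_B"}, calls,
                               {"T_A": est_table({"D": 1.0}), "T_B": est_table({"D": 1.0})})
    assert m2.statuses["A"]["chr1:20:C>T"] == ABSENT  # single supporting read


def test_subthreshold_band_counts_as_present_when_filters_pass():
    m = build("T", {"A": {10: 0.3, 20: 0.03}, "B": {10: 0.3, 20: 0.2}})
    assert m.statuses["A"]["chr1:20:C>T"] == PRESENT


def test_classify_point_heterogeneous_matrix():
    """Truncal anchor everywhere; two events in disjoint pairs, trace in the middle."""
    afs = {
        "A": {1: 0.40, 10: 0.38},
        "B": {1: 0.41, 10: 0.36},
        "C": {1: 0.39, 10: 0.006, 20: 0.007},
        "D": {1: 0.42, 20: 0.35},
        "E": {1: 0.40, 20: 0.37},
    }
    report = sp.classify(build("T09", afs))
    assert report.verdict == HETEROGENEOUS
    assert report.truncal_events == ["chr1:1:C>T"]
    het = {e["event"]: set(e["present_in"]) for e in report.heterogeneous_events}
    assert het == {"chr1:10:C>T": {"A", "B"}, "chr1:20:C>T": {"D", "E"}}


def test_classify_amp_confounded_matrix():
    """Subset amplification without truncal anchor: cellularity indeterminate."""
    amp = {r: {"EGFR": (4.5 if r in "DE" else 1.2)} for r in "ABCDE"}
    report = sp.classify(build("T15", {r: {} for r in "ABCDE"}, amp_est=amp))
    assert report.verdict == INDETERMINATE
    assert report.truncal_events == []


def test_classify_homogeneous_and_no_events():
    afs = {r: {1: 0.3, 2: 0.2} for r in "ABC"}
    assert sp.classify(build("T", afs)).verdict == HOMOGENEOUS
    assert sp.classify(build("T", {r: {} for r in "ABC"})).verdict == NO_EVENTS


def test_not_assayable_blocks_heterogeneity_call():
    """An amplification 'missing' only where the gene is unassayable is not
    evidence of heterogeneity."""
    amp = {"A": {"EGFR": 5.0}, "B": {"EGFR": 5.0}, "C": {"EGFR": 1.0}}
    afs = {r: {1: 0.3} for r in "ABC"}
    m = build("T", afs, amp_est=amp)
    m.statuses.loc["amp:EGFR", "C"] = NOT_ASSAYABLE
    report = sp.classify(m)
    assert report.verdict == HOMOGENEOUS
    m.statuses.loc["amp:EGFR", "C"] = ABSENT
    assert sp.classify(m).verdict == HETEROGENEOUS


def test_passenger_flagged_when_gene_has_distinct_truncal_event():
    """A subset event in a gene already truncally mutated is a likely passenger."""
    panel = sp.build_panel(2, 2, target_length=50, gc_profile=(0.4, 0.5), seed=1)
    g1 = panel.genes[0]
    probes = panel.probes_for_gene(g1)
    pos_truncal = probes[0].start + 10
    pos_sub = probes[1].start + 10
    ref_t = probes[0].sequence[10]
    ref_s = probes[1].sequence[10]
    afs = {
        "A": {pos_truncal: 0.40, pos_sub: 0.20},
        "B": {pos_truncal: 0.42},
    }
    calls = pd.DataFrame(
        [snv_call(f"T_{r}", pos, ab, ref=(ref_t if pos == pos_truncal else ref_s),
                  alt=("A" if (ref_t if pos == pos_truncal else ref_s) != "A" else "G"),
                  chrom=probes[0].chrom)
         for r, d in afs.items() for pos, ab in d.items()]
    )
    est = est_table({"DUMMY": 1.0})
    m = sp.build_event_matrix("T", {"A": "T_A", "B": "T_B"}, calls,
                              {"T_A": est, "T_B": est}, panel=panel)
    report = sp.classify(m)
    assert report.verdict == HETEROGENEOUS
    assert len(report.passenger_flags) == 1


def test_region_relabeling_symmetry():
    afs = {
        "A": {1: 0.40, 10: 0.38}, "B": {1: 0.41, 10: 0.36},
        "C": {1: 0.39}, "D": {1: 0.42, 20: 0.35}, "E": {1: 0.40, 20: 0.37},
    }
    base = sp.classify(build("T", afs))
    relabel = {"A": "E", "B": "D", "C": "C", "D": "B", "E": "A"}
    afs2 = {relabel[r]: d for r, d in afs.items()}
    flipped = sp.classify(build("T", afs2))
    assert flipped.verdict == base.verdict == HETEROGENEOUS
    assert len(flipped.heterogeneous_events) == len(base.heterogeneous_events)


def test_cellularity_guard_flip_is_one_directional():
    """Scaling one region's AFs down can only move heterogeneous ->
    indeterminate (when the truncal anchor drops), never the reverse."""
    def afs_with_purity_factor(f):
        return {
            "A": {1: 0.40, 10: 0.38}, "B": {1: 0.41, 10: 0.36},
            "C": {1: 0.39 * f, 20: 0.35 * f}, "D": {1: 0.42, 20: 0.35},
            "E": {1: 0.40},
        }
    verdicts = [sp.classify(build("T", afs_with_purity_factor(f))).verdict
                for f in (1.0, 0.5, 0.2, 0.02)]
    assert verdicts[0] == HETEROGENEOUS
    # once the anchor is lost the verdict degrades and stays degraded
    seen_indeterminate = False
    for v in verdicts:
        if v == INDETERMINATE:
            seen_indeterminate = True
        assert not (seen_indeterminate and v == HETEROGENEOUS)
    assert verdicts[-1] == INDETERMINATE


def test_single_region_not_computable():
    with pytest.raises(ValueError, match="single-region"):
        sp.classify(build("T", {"A": {1: 0.3}}))


def test_spectrum_complement_collapse():
    assert sp.spectrum([("G", "T"), ("G", "T"), ("C", "A")]) == {
        "C>A": 3, "C>G": 0, "C>T": 0, "T>A": 0, "T>C": 0, "T>G": 0,
    }
    empty = sp.spectrum([])
    assert sum(empty.values()) == 0
    with pytest.warns(UserWarning):
        out = sp.spectrum([("AT", "A"), ("C", "T")])
    assert out["C>T"] == 1 and sum(out.values()) == 1


def test_hypermutator_spectrum_fraction():
    """16 mutations, 8 of the C>A class: transversion fraction 0.5 and the
    hypermutation flag trips against a cohort median of 2."""
    subs = [("G", "T")] * 5 + [("C", "A")] * 3 + [("C", "T")] * 4 + [("T", "G")] * 4
    spec = sp.spectrum(subs)
    assert spec["C>A"] == 8
    assert spec["C>A"] / sum(spec.values()) == pytest.approx(0.5)
    afs = {r: {i: 0.3 for i in range(16)} for r in "AB"}
    report = sp.classify(build("T", afs), cohort_median_somatic=2.0)
    assert report.n_somatic == 16
    assert report.hypermutation_flag
    report = sp.classify(build("T", afs), cohort_median_somatic=4.0)
    assert not report.hypermutation_flag  # 16 is not > 5 x 4
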