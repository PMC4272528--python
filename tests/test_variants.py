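"""Pileups and the six somatic filters: thresholds at their printed boundaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smmiphet as sp
from smmiphet.variants import homopolymer_pass, write_vcf

from conftest import make_reads, uniform_quals


def probe_reads(panel, probe_id, n_ref, alt_specs=(), sample="S1"):
    """Reads over one probe: n_ref reference reads plus (offset, alt, count, phred) specs."""
    probe = panel.by_id[probe_id]
    rows = []
    i = 0

    def tag(k):
        digits = []
        for _ in range(8):
            digits.append("ACGT"[k % 4])
            k //= 4
        return "".join(digits)

    for _ in range(n_ref):
        rows.append((sample, probe_id, tag(i), probe.sequence, uniform_quals(probe.length)))
        i += 1
    for off, alt, count, phred in alt_specs:
        seq = probe.sequence[:off] + alt + probe.sequence[off + 1 :]
        quals = uniform_quals(probe.length)
        quals = quals[:off] + chr(phred + 33) + quals[off + 1 :]
        for _ in range(count):
            rows.append((sample, probe_id, tag(i), seq, quals))
            i += 1
    return make_reads(rows)


def test_pileup_homozygous_reference(tiny_panel):
    reads = probe_reads(tiny_panel, "GENEB_p0", 40)
    pile = sp.build_pileup(reads, tiny_panel)
    probe = tiny_panel.by_id["GENEB_p0"]
    assert len(pile) == probe.length
    assert (pile["depth"] == 40).all()
    for row in pile.itertuples():
        assert getattr(row, row.ref) == 40


def test_pileup_low_quality_bases_masked(tiny_panel):
    """4 alt reads at phred 20 contribute nothing: depth 36, alt count 0."""
    reads = probe_reads(tiny_panel, "GENEB_p0", 36, [(5, "T", 4, 20)])
    pile = sp.build_pileup(reads, tiny_panel, min_base_quality=30)
    site = pile[pile["pos"] == tiny_panel.by_id["GENEB_p0"].start + 5].iloc[0]
    assert site["depth"] == 36
    assert site["T"] == 0
    calls = sp.call_candidates(pile, tiny_panel)
    assert not ((calls["pos"] == site["pos"]) & (calls["alt"] == "T")).any()
    # the same support at phred 30 is counted and yields a candidate
    reads = probe_reads(tiny_panel, "GENEB_p0", 36, [(5, "T", 4, 30)])
    pile = sp.build_pileup(reads, tiny_panel, min_base_quality=30)
    site = pile[pile["pos"] == tiny_panel.by_id["GENEB_p0"].start + 5].iloc[0]
    assert site["depth"] == 40 and site["T"] == 4
    calls = sp.call_candidates(pile, tiny_panel)
    assert ((calls["pos"] == site["pos"]) & (calls["alt"] == "T")).any()


def test_pileup_allele_balance_arithmetic(tiny_panel):
    reads = probe_reads(tiny_panel, "GENEB_p0", 30, [(7, "A", 5, 37)])
    pile = sp.build_pileup(reads, tiny_panel)
    calls = sp.call_candidates(pile, tiny_panel)
    pos = tiny_panel.by_id["GENEB_p0"].start + 7
    row = calls[(calls["pos"] == pos) & (calls["alt"] == "A")].iloc[0]
    assert row["depth"] == 35
    assert row["allele_balance"] == pytest.approx(5 / 35)


def test_min_depth_and_min_ab_boundaries(tiny_panel):
    # depth 29 (28 ref + 1 alt): min_depth fails
    reads = probe_reads(tiny_panel, "GENEB_p0", 28, [(0, "T", 1, 37)])
    calls = sp.call_candidates(sp.build_pileup(reads, tiny_panel), tiny_panel)
    row = calls[(calls["alt"] == "T")].iloc[0]
    assert row["depth"] == 29 and not row["filter_min_depth"]
    # alt 5 of depth 100: AB exactly 0.05 passes (inclusive threshold)
    reads = probe_reads(tiny_panel, "GENEB_p0", 95, [(0, "T", 5, 37)])
    calls = sp.call_candidates(sp.build_pileup(reads, tiny_panel), tiny_panel)
    row = calls[(calls["alt"] == "T")].iloc[0]
    assert row["depth"] == 100 and row["filter_min_ab"] and row["filter_min_depth"]
    # alt 4 of depth 100 fails
    reads = probe_reads(tiny_panel, "GENEB_p0", 96, [(0, "T", 4, 37)])
    calls = sp.call_candidates(sp.build_pileup(reads, tiny_panel), tiny_panel)
    assert not calls[(calls["alt"] == "T")].iloc[0]["filter_min_ab"]


def test_homopolymer_contexts():
    assert not homopolymer_pass("CAAAAAG", 1)   # adjacent run of 5
    assert homopolymer_pass("CGTACGT", 3)       # no run
    assert homopolymer_pass("AAATGGG", 3)       # flanking runs of 3 only
    assert not homopolymer_pass("TTTTAC", 4)    # variant adjacent after run
    assert not homopolymer_pass("GAAAAG", 2)    # variant inside the run


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=30), st.data())
def test_homopolymer_matches_run_scan_oracle(context, data):
    index = data.draw(st.integers(min_value=0, max_value=len(context) - 1))
    # oracle: enumerate every maximal run by exhaustive scanning
    fail = False
    for a in range(len(context)):
        for b in range(a + 4, len(context) + 1):
            if len(set(context[a:b])) == 1 and (a == 0 or context[a - 1] != context[a]) \
               and (b == len(context) or context[b] != context[a]):
                if a - 1 <= index <= b:
                    fail = True
    assert homopolymer_pass(context, index, run_length=4) == (not fail)


def _call_row(chrom="chr2", pos=505, ref="C", alt="T", ab=0.2, sample="S1", depth=100):
    return {
        "sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "depth": depth, "alt_count": int(round(ab * depth)), "allele_balance": ab,
        "filter_base_quality": True, "filter_min_depth": True,
        "filter_homopolymer": True, "filter_min_ab": ab >= 0.05,
    }


def test_population_db_filter_is_cosmic_stripped():
    calls = pd.DataFrame([_call_row(pos=10), _call_row(pos=20)])
    popdb = sp.PopulationVariantSet([("chr2", 10, "C", "T"), ("chr2", 20, "C", "T")])
    cosmic = sp.PopulationVariantSet([("chr2", 20, "C", "T")])
    out = sp.somatic_filters(calls, popdb, cosmic)
    assert not out[out["pos"] == 10]["filter_population_db"].iloc[0]
    assert out[out["pos"] == 20]["filter_population_db"].iloc[0]  # in COSMIC: kept


def test_control_recurrence_boundary():
    calls = pd.DataFrame([_call_row()])
    controls_2 = pd.DataFrame([_call_row(ab=0.06, sample="X1"), _call_row(ab=0.06, sample="X2")])
    controls_1 = pd.DataFrame([_call_row(ab=0.06, sample="X1"), _call_row(ab=0.04, sample="X2")])
    empty = sp.PopulationVariantSet()
    out = sp.somatic_filters(calls, empty, empty, controls_2)
    assert not out["filter_control_recurrence"].iloc[0]
    out = sp.somatic_filters(calls, empty, empty, controls_1)
    assert out["filter_control_recurrence"].iloc[0]


def test_emitted_and_trace_flags():
    calls = pd.DataFrame([
        _call_row(pos=1, ab=0.20),                       # all pass -> emitted
        _call_row(pos=2, ab=0.03),                       # only min_ab fails -> trace
        dict(_call_row(pos=3, ab=0.03), filter_homopolymer=False),  # two failures
    ])
    empty = sp.PopulationVariantSet()
    out = sp.somatic_filters(calls, empty, empty)
    assert list(out["emitted"]) == [True, False, False]
    assert list(out["trace"]) == [False, True, False]


def test_filters_order_independent_and_monotone(tiny_panel):
    """Each filter column depends only on its own inputs; raising thresholds
    never adds emitted variants."""
    reads = probe_reads(tiny_panel, "GENEB_p0", 50, [(0, "T", 6, 37), (8, "A", 3, 37)])
    pile = sp.build_pileup(reads, tiny_panel)
    strict = sp.call_candidates(pile, tiny_panel, min_depth=60, min_ab=0.10)
    loose = sp.call_candidates(pile, tiny_panel, min_depth=30, min_ab=0.05)
    # non-threshold columns agree regardless of the threshold settings
    for col in ["filter_base_quality", "filter_homopolymer"]:
        assert list(strict[col]) == list(loose[col])
    empty = sp.PopulationVariantSet()
    em_strict = sp.somatic_filters(strict, empty, empty)["emitted"]
    em_loose = sp.somatic_filters(loose, empty, empty)["emitted"]
    assert not (em_strict & ~em_loose).any()


def test_germline_suppression_and_truncal_emission():
    """Simulated tumor at high depth, no error: truncal mutations emitted in
    every region; germline variants removed via the population database; no
    call outside truth."""
    panel = sp.build_panel(2, 3, target_length=60, gc_profile=(0.4, 0.5), seed=31)
    g1, g2 = panel.genes
    p1 = panel.probes_for_gene(g1)[0]
    p2 = panel.probes_for_gene(g2)[0]
    ref1, ref2 = p1.sequence[20], p2.sequence[30]
    alt1 = "ACGT"[("ACGT".index(ref1) + 1) % 4]
    alt2 = "ACGT"[("ACGT".index(ref2) + 1) % 4]
    germ = sp.Clone("germline", None, {}, germline=True)
    trunk = sp.Clone("trunk", None, {"A": 1.0, "B": 1.0})
    driver = sp.Mutation(p1.chrom, p1.start + 20, ref1, alt1, "trunk")
    germline = sp.Mutation(p2.chrom, p2.start + 30, ref2, alt2, "germline")
    tree = sp.CloneTree([germ, trunk], [driver, germline])
    rts = [sp.region_truth(tree, panel, r, purity=0.25) for r in "AB"]  # AF 0.125 > 0.08
    reads, _ = sp.simulate_reads(panel, tree, rts, depth=5000, dup_rate=0.0,
                                 error_rate=0.0, low_quality_rate=0.0, seed=32)
    dd = sp.deduplicate(reads, seed=33)
    calls = sp.call_candidates(sp.build_pileup(dd, panel), panel)
    popdb = sp.PopulationVariantSet([germline.key])
    cosmic = sp.PopulationVariantSet([driver.key])
    out = sp.somatic_filters(calls, popdb, cosmic)
    emitted = out[out["emitted"]]
    for region in "AB":
        sub = emitted[emitted["sample_id"] == region]
        assert set(zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])) == {driver.key}
    # germline present as a candidate but filtered
    germ_rows = out[(out["pos"] == germline.pos) & (out["alt"] == alt2)]
    assert len(germ_rows) == 2 and not germ_rows["filter_population_db"].any()


def test_vcf_round_trip_via_pysam(tiny_panel, tmp_path):
    import pysam

    reads = probe_reads(tiny_panel, "GENEB_p0", 60, [(0, "T", 12, 37)])
    calls = sp.call_candidates(sp.build_pileup(reads, tiny_panel), tiny_panel)
    empty = sp.PopulationVariantSet()
    calls = sp.somatic_filters(calls, empty, empty)
    path = tmp_path / "calls.vcf"
    write_vcf(calls, path, tiny_panel)
    with pysam.VariantFile(str(path)) as vf:
        recs = list(vf)
    emitted = [r for r in recs if "PASS" in r.filter]
    assert len(recs) == len(calls)
    assert len(emitted) == int(calls["emitted"].sum())
    r = emitted[0]
    assert r.pos - 1 == tiny_panel.by_id["GENEB_p0"].start  # VCF is 1-based
    assert r.info["DP"] == 72


def test_population_set_tsv_round_trip(tmp_path):
    s = sp.PopulationVariantSet([("chr1", 5, "A", "T"), ("chr2", 9, "G", "C")], label="x")
    s.to_tsv(tmp_path / "db.tsv")
    back = sp.PopulationVariantSet.from_tsv(tmp_path / "db.tsv")
    assert back.entries == s.entries
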