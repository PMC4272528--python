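"""Multi-region integration: event matrices, heterogeneity verdicts, spectra.

The central confounder in multi-region tumor panels is cellularity: a region
with few tumor cells loses every mutation at once, mimicking heterogeneity.
The classifier therefore only declares a tumor heterogeneous when every
region shares at least one truncal event (a point mutation or amplification
present everywhere) anchoring adequate tumor content, and some other event is
present in a proper subset of regions and absent — not merely unassayable —
elsewhere.  Subset events without a truncal anchor yield an
"indeterminate cellularity" verdict instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import ProbePanel

# per-region event statuses
PRESENT_HIGH = "present_high"
PRESENT = "present"
TRACE = "trace"
ABSENT = "absent"
NOT_ASSAYABLE = "not_assayable"

# verdicts
HETEROGENEOUS = "heterogeneous"
HOMOGENEOUS = "homogeneous"
INDETERMINATE = "indeterminate_cellularity"
NO_EVENTS = "no_events"

SPECTRUM_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RegionEventMatrix:
    """Per-region status of every observed event in one tumor.

    ``statuses``: DataFrame indexed by event id, one column per tumor region
    (control excluded).  ``values`` holds the attached allele fraction or copy
    estimate.  ``events`` maps event id to metadata (kind, gene, variant key).
    """

    tumor_id: str
    regions: list[str]
    statuses: pd.DataFrame
    values: pd.DataFrame
    events: dict[str, dict]
    control_region: str | None = None
    control_diagnostic: float | None = None


@dataclass
class TumorReport:
    tumor_id: str
    regions: list[str]
    verdict: str
    truncal_events: list[str]
    heterogeneous_events: list[dict]
    passenger_flags: list[str]
    spectrum: dict[str, int]
    n_somatic: int
    hypermutation_flag: bool = False
    control_diagnostic: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tumor_id": self.tumor_id,
            "regions": list(self.regions),
            "verdict": self.verdict,
            "truncal_events": list(self.truncal_events),
            "heterogeneous_events": [dict(e) for e in self.heterogeneous_events],
            "passenger_flags": list(self.passenger_flags),
            "spectrum": dict(self.spectrum),
            "n_somatic": self.n_somatic,
            "hypermutation_flag": self.hypermutation_flag,
            "control_diagnostic": self.control_diagnostic,
            "notes": list(self.notes),
        }


def _snv_status(
    af: float,
    alt_count: int,
    non_ab_pass: bool,
    high_af: float,
    min_ab: float,
    trace_af: float,
    trace_min_reads: int,
    low_band_requires_filters: bool,
) -> str:
    if alt_count <= 0:
        return ABSENT
    if af > high_af:
        return PRESENT_HIGH
    if af >= min_ab:
        return PRESENT
    if af >= trace_af:
        # sub-emission band between trace and the reporting threshold; like
        # trace, it needs >= trace_min_reads to rule out single-error artifacts
        if alt_count >= trace_min_reads and (non_ab_pass or not low_band_requires_filters):
            return PRESENT
        return ABSENT
    if alt_count >= trace_min_reads:
        return TRACE
    return ABSENT


def build_event_matrix(
    tumor_id: str,
    region_samples: Mapping[str, str],
    variant_calls: pd.DataFrame,
    estimates: Mapping[str, pd.DataFrame],
    panel: ProbePanel | None = None,
    control_sample: str | None = None,
    high_af: float = 0.30,
    min_ab: float = 0.05,
    trace_af: float = 0.01,
    trace_min_reads: int = 2,
    amp_threshold: float = 3.0,
    low_band_requires_filters: bool = True,
) -> RegionEventMatrix:
    """Assemble the per-region status matrix for one tumor.

    ``region_samples`` maps region id -> sample id (tumor regions only, in
    display order); ``variant_calls`` is the filtered candidate table for all
    of the tumor's samples (including sub-threshold and trace candidates);
    ``estimates`` maps sample id -> per-gene copy estimate table.  Events are
    point mutations emitted in at least one region plus genes called amplified
    (estimate above ``amp_threshold``, assayable) in at least one region.
    """
    regions = list(region_samples)
    samples = set(region_samples.values())
    calls = variant_calls[variant_calls["sample_id"].isin(samples)]
    missing_est = samples - set(estimates)
    if missing_est:
        raise ValueError(f"estimates missing for samples: {sorted(missing_est)}")

    events: dict[str, dict] = {}
    for row in calls[calls["emitted"]].itertuples():
        key = (row.chrom, row.pos, row.ref, row.alt)
        eid = f"{row.chrom}:{row.pos}:{row.ref}>{row.alt}"
        gene = None
        if panel is not None:
            probe = panel.probe_covering(row.chrom, row.pos)
            gene = probe.gene if probe else None
        events.setdefault(eid, {"kind": "snv", "key": key, "gene": gene})
    for sample_id, est in estimates.items():
        if sample_id not in samples:
            continue
        amped = est[est["call"].isin(["amplified", "highly_amplified"])]
        for gene in amped["gene"]:
            events.setdefault(f"amp:{gene}", {"kind": "amp", "gene": gene})

    call_index: dict[tuple, pd.Series] = {}
    for row in calls.itertuples():
        call_index[(row.sample_id, row.chrom, row.pos, row.ref, row.alt)] = row

    statuses = pd.DataFrame(index=sorted(events), columns=regions, dtype=object)
    values = pd.DataFrame(index=sorted(events), columns=regions, dtype=float)
    non_ab_cols = ["filter_base_quality", "filter_min_depth", "filter_homopolymer",
                   "filter_population_db", "filter_control_recurrence"]
    for eid in statuses.index:
        ev = events[eid]
        for region, sample_id in region_samples.items():
            if ev["kind"] == "snv":
                c, p, r, a = ev["key"]
                row = call_index.get((sample_id, c, p, r, a))
                if row is None:
                    statuses.loc[eid, region] = ABSENT
                    values.loc[eid, region] = 0.0
                else:
                    non_ab = all(getattr(row, col, True) for col in non_ab_cols)
                    statuses.loc[eid, region] = _snv_status(
                        row.allele_balance, row.alt_count, non_ab, high_af, min_ab,
                        trace_af, trace_min_reads, low_band_requires_filters,
                    )
                    values.loc[eid, region] = row.allele_balance
            else:
                est = estimates[sample_id]
                row_df = est[est["gene"] == ev["gene"]]
                if len(row_df) == 0 or row_df.iloc[0]["call"] == "not_assayable":
                    statuses.loc[eid, region] = NOT_ASSAYABLE
                    values.loc[eid, region] = np.nan
                else:
                    e = float(row_df.iloc[0]["estimate"])
                    statuses.loc[eid, region] = PRESENT if e > amp_threshold else ABSENT
                    values.loc[eid, region] = e
    return RegionEventMatrix(
        tumor_id=tumor_id,
        regions=regions,
        statuses=statuses,
        values=values,
        events=events,
        control_region=control_sample,
    )


def classify(
    matrix: RegionEventMatrix,
    cohort_median_somatic: float | None = None,
    hypermutation_multiple: float = 5.0,
) -> TumorReport:
    """Tumor-level heterogeneity verdict with the cellularity guard.

    Truncal events are present (or present_high) in every region; an event is
    heterogeneous when present in a proper nonempty subset of regions and
    absent (trace allowed, not_assayable not) elsewhere.  A tumor is
    heterogeneous only with truncal evidence; subset events without it give
    ``indeterminate_cellularity``.  Heterogeneous events in a gene that also
    carries a distinct truncal event are flagged as likely passengers.
    """
    regions = matrix.regions
    if len(regions) < 2:
        raise ValueError(
            f"tumor {matrix.tumor_id}: single-region tumor, heterogeneity verdict not computable"
        )
    present = {PRESENT, PRESENT_HIGH}
    truncal: list[str] = []
    subset_restricted: list[str] = []
    heterogeneous: list[dict] = []
    for eid in matrix.statuses.index:
        st = matrix.statuses.loc[eid]
        present_in = [r for r in regions if st[r] in present]
        if len(present_in) == len(regions):
            truncal.append(eid)
        elif present_in:
            subset_restricted.append(eid)
            rest = [r for r in regions if r not in present_in]
            if all(st[r] in (ABSENT, TRACE) for r in rest):
                heterogeneous.append(
                    {"event": eid, "present_in": present_in, "absent_in": rest}
                )

    if not truncal and not subset_restricted:
        verdict = NO_EVENTS
    elif not truncal:
        verdict = INDETERMINATE
    elif heterogeneous:
        verdict = HETEROGENEOUS
    else:
        verdict = HOMOGENEOUS

    truncal_genes = {
        matrix.events[t].get("gene") for t in truncal if matrix.events[t].get("gene")
    }
    passenger = []
    for h in heterogeneous:
        gene = matrix.events[h["event"]].get("gene")
        if gene and gene in truncal_genes:
            passenger.append(h["event"])

    snv_events = [
        (eid, ev) for eid, ev in matrix.events.items() if ev["kind"] == "snv"
    ]
    spec = spectrum([ev["key"][2:4] for _, ev in snv_events])
    n_somatic = len(snv_events)
    hyper = False
    if cohort_median_somatic is not None and cohort_median_somatic > 0:
        hyper = n_somatic > hypermutation_multiple * cohort_median_somatic
    return TumorReport(
        tumor_id=matrix.tumor_id,
        regions=regions,
        verdict=verdict,
        truncal_events=sorted(truncal),
        heterogeneous_events=heterogeneous,
        passenger_flags=sorted(passenger),
        spectrum=spec,
        n_somatic=n_somatic,
        hypermutation_flag=hyper,
        control_diagnostic=matrix.control_diagnostic,
    )


def spectrum(substitutions: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Counts over the six pyrimidine-context substitution classes.

    Each (ref, alt) single-base substitution is collapsed to its
    pyrimidine-reference representation (G>T counts as C>A, etc.).  Non-SNV
    entries are skipped with a warning.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for ref, alt in substitutions:
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            warnings.warn(f"skipping non-SNV substitution {ref}>{alt}")
            continue
        if ref == alt:
            warnings.warn(f"skipping degenerate substitution {ref}>{alt}")
            continue
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return counts


def matrix_to_tsv(matrix: RegionEventMatrix, path) -> None:
    """Human-readable event-by-region table (status/value per cell)."""
    out = matrix.statuses.copy()
    for eid in out.index:
        for region in out.columns:
            v = matrix.values.loc[eid, region]
            cell = str(out.loc[eid, region])
            if pd.notna(v):
                cell += f"/{v:.4g}"
            out.loc[eid, region] = cell
    out.index.name = "event"
    out.to_csv(path, sep="\t")
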