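"""End-to-end pipeline driver: dedup -> variants -> copy number -> verdicts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .copynumber import call_copy_number
from .dedup import correct_and_deduplicate
from .heterogeneity import RegionEventMatrix, TumorReport, build_event_matrix, classify, matrix_to_tsv
from .panel import ProbePanel
from .variants import PopulationVariantSet, build_pileup, call_candidates, somatic_filters, write_vcf

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ["sample_id", "tumor_id", "region_id", "is_control"]


class SampleSheet:
    """Maps samples to tumors and regions; flags control tissues."""

    def __init__(self, df: pd.DataFrame):
        missing = set(SHEET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        df = df.copy()
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        df["is_control"] = df["is_control"].astype(bool)
        for tumor_id, grp in df.groupby("tumor_id"):
            if (~grp["is_control"]).sum() < 1:
                raise ValueError(f"tumor {tumor_id} has no (non-control) regions")
            if grp["is_control"].sum() > 1:
                raise ValueError(f"tumor {tumor_id} has more than one control")
        self.df = df

    @property
    def tumor_ids(self) -> list[str]:
        return sorted(self.df["tumor_id"].unique())

    @property
    def control_samples(self) -> list[str]:
        return sorted(self.df.loc[self.df["is_control"], "sample_id"])

    def region_samples(self, tumor_id: str) -> dict[str, str]:
        """region_id -> sample_id for a tumor's non-control regions, ordered."""
        grp = self.df[(self.df["tumor_id"] == tumor_id) & ~self.df["is_control"]]
        grp = grp.sort_values("region_id")
        return dict(zip(grp["region_id"], grp["sample_id"]))

    def control_for(self, tumor_id: str) -> str | None:
        grp = self.df[(self.df["tumor_id"] == tumor_id) & self.df["is_control"]]
        return None if len(grp) == 0 else grp["sample_id"].iloc[0]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tumor_id": str,
                                                      "region_id": str}))


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    coverage: dict[str, pd.Series]
    ratios: dict[str, pd.DataFrame]
    estimates: dict[str, pd.DataFrame]
    matrices: dict[str, RegionEventMatrix]
    reports: dict[str, TumorReport]
    summary: pd.DataFrame
    universal_control: str
    family_hist: pd.DataFrame
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _control_diagnostic(candidates: pd.DataFrame, sample_id: str,
                        cosmic: PopulationVariantSet) -> float:
    """Max allele fraction of known pathogenic variants in a control sample."""
    sub = candidates[candidates["sample_id"] == sample_id]
    afs = [
        row.allele_balance
        for row in sub.itertuples()
        if (row.chrom, row.pos, row.ref, row.alt) in cosmic
    ]
    return float(max(afs)) if afs else 0.0


def pick_universal_control(
    candidates: pd.DataFrame,
    control_samples: list[str],
    cosmic: PopulationVariantSet,
    choice: str = "auto",
) -> str:
    """The designated control, or (auto) the one least contaminated by tumor."""
    if not control_samples:
        raise ValueError(
            "CNV stage requires at least one control sample: mark one sample "
            "per tumor (or a cohort-level universal control) with is_control=True"
        )
    if choice != "auto":
        if choice not in control_samples:
            raise ValueError(f"designated universal control {choice!r} is not a control sample")
        return choice
    diags = {s: _control_diagnostic(candidates, s, cosmic) for s in control_samples}
    return min(sorted(diags), key=lambda s: diags[s])


def run_pipeline(
    reads: pd.DataFrame,
    panel: ProbePanel,
    popdb: PopulationVariantSet,
    cosmic: PopulationVariantSet,
    sheet: SampleSheet,
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis: per-sample dedup and variant filtering, per-region
    copy number versus the universal control, and per-tumor heterogeneity
    verdicts with a cohort summary.  Deterministic for fixed inputs and seed.
    """
    config = config or PipelineConfig()
    known = set(sheet.df["sample_id"])
    seen = set(reads["sample_id"].unique())
    if seen - known:
        raise ValueError(f"reads contain samples absent from sheet: {sorted(seen - known)[:5]}")

    logger.info("dedup: correcting tags (max distance %d)", config.max_tag_distance)
    dd, hist, pair_counts = correct_and_deduplicate(
        reads, max_distance=config.max_tag_distance, seed=seed, method=config.dedup_method
    )
    logger.info("dedup: %d reads -> %d unique molecules", len(reads), len(dd))

    pileup = build_pileup(dd, panel, min_base_quality=config.min_base_quality)
    candidates = call_candidates(
        pileup, panel, min_depth=config.min_depth, min_ab=config.min_ab,
        homopolymer_run=config.homopolymer_run,
    )
    controls = sheet.control_samples
    control_calls = candidates[candidates["sample_id"].isin(controls)]
    candidates = somatic_filters(
        candidates, popdb, cosmic, control_calls,
        control_min_ab=config.control_min_ab,
        control_min_samples=config.control_min_samples,
    )

    universal = pick_universal_control(candidates, controls, cosmic, config.universal_control)
    logger.info("copy number: universal control %s", universal)
    probe_ids = [p.probe_id for p in panel.probes]
    counts = pair_counts.set_index(["sample_id", "probe_id"])["count"]
    coverage = {
        s: counts.loc[s].reindex(probe_ids, fill_value=0).astype(int)
        for s in sorted(seen)
    }
    ratios: dict[str, pd.DataFrame] = {}
    estimates: dict[str, pd.DataFrame] = {}
    for sample_id in sorted(seen):
        if sheet.df.loc[sheet.df["sample_id"] == sample_id, "is_control"].iloc[0]:
            continue
        r, e = call_copy_number(
            coverage[sample_id], coverage[universal], panel,
            gc_min=config.gc_min, gc_max=config.gc_max,
            control_min_coverage=config.control_min_coverage,
            min_probes=config.min_probes,
            amp_threshold=config.amp_threshold,
            high_amp_threshold=config.high_amp_threshold,
            alpha=config.cbs_alpha, n_perm=config.cbs_n_perm,
            min_width=config.cbs_min_width,
            use_segmented=config.use_segmented_R, seed=seed,
        )
        ratios[sample_id] = r
        estimates[sample_id] = e

    matrices: dict[str, RegionEventMatrix] = {}
    for tumor_id in sheet.tumor_ids:
        region_samples = sheet.region_samples(tumor_id)
        matrix = build_event_matrix(
            tumor_id, region_samples, candidates, estimates, panel=panel,
            control_sample=sheet.control_for(tumor_id),
            high_af=config.high_af, min_ab=config.min_ab,
            trace_af=config.trace_af, trace_min_reads=config.trace_min_reads,
            amp_threshold=config.amp_threshold,
            low_band_requires_filters=config.low_band_requires_filters,
        )
        ctrl = sheet.control_for(tumor_id)
        if ctrl is not None:
            matrix.control_diagnostic = _control_diagnostic(candidates, ctrl, cosmic)
            if matrix.control_diagnostic > config.contamination_warn_af:
                logger.warning(
                    "tumor %s: control %s carries pathogenic variants at AF %.3f "
                    "(possible tumor contamination)",
                    tumor_id, ctrl, matrix.control_diagnostic,
                )
        matrices[tumor_id] = matrix

    n_somatic = {t: sum(1 for e in m.events.values() if e["kind"] == "snv")
                 for t, m in matrices.items()}
    cohort_median = float(np.median(list(n_somatic.values()))) if n_somatic else 0.0
    reports = {
        t: classify(m, cohort_median_somatic=cohort_median,
                    hypermutation_multiple=config.hypermutation_multiple)
        for t, m in matrices.items()
    }

    summary = pd.DataFrame(
        [
            {
                "tumor_id": t,
                "n_regions": len(r.regions),
                "verdict": r.verdict,
                "n_truncal": len(r.truncal_events),
                "n_heterogeneous": len(r.heterogeneous_events),
                "n_somatic": r.n_somatic,
                "hypermutation": r.hypermutation_flag,
                "control_diagnostic": r.control_diagnostic,
                "amplified_genes": ";".join(
                    sorted(e["gene"] for eid, e in matrices[t].events.items()
                           if e["kind"] == "amp")
                ),
            }
            for t, r in sorted(reports.items())
        ]
    )
    result = PipelineResult(
        candidates=candidates, coverage=coverage, ratios=ratios, estimates=estimates,
        matrices=matrices, reports=reports, summary=summary,
        universal_control=universal, family_hist=hist, config=config,
    )
    if outdir is not None:
        write_result(result, panel, outdir, seed=seed)
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_result(result: PipelineResult, panel: ProbePanel, outdir: str | Path,
                 seed: int = 0) -> None:
    """Write the report bundle: summary, per-tumor reports/matrices, per-sample
    variant VCFs and copy-number tables, a family-size histogram and run log."""
    out = Path(outdir)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)
    (out / "copy_number").mkdir(exist_ok=True)
    result.summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False,
                          float_format="%.6g")
    result.family_hist.to_csv(out / "family_sizes.tsv", sep="\t", index=False)
    for tumor_id, report in result.reports.items():
        with open(out / "reports" / f"{tumor_id}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=_json_default, sort_keys=True)
            fh.write("\n")
        matrix_to_tsv(result.matrices[tumor_id], out / "reports" / f"{tumor_id}_matrix.tsv")
    for sample_id in sorted(result.candidates["sample_id"].unique()):
        write_vcf(result.candidates[result.candidates["sample_id"] == sample_id],
                  out / "variants" / f"{sample_id}.vcf", panel)
    for sample_id, est in result.estimates.items():
        est.to_csv(out / "copy_number" / f"{sample_id}_genes.tsv", sep="\t",
                   index=False, float_format="%.6g")
        result.ratios[sample_id].to_csv(
            out / "copy_number" / f"{sample_id}_probes.tsv", sep="\t", index=False,
            float_format="%.6g")
    from . import __version__

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {"version": __version__, "seed": seed,
             "universal_control": result.universal_control,
             "config": result.config.to_dict()},
            fh, indent=2, default=_json_default, sort_keys=True,
        )
        fh.write("\n")
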