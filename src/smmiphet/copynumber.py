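"""Gene-amplification calling from probe coverage ratios versus a control.

Per-probe deduplicated coverage in the tumor is compared against a control
tissue.  Probes are eligible when the control has more than 30 deduplicated
reads and the target GC fraction lies in [0.30, 0.60]; genes with fewer than
15 eligible probes are not assayable.  Eligible log2 ratios, ordered by
genomic position with boundaries forced at chromosome breaks, are segmented
by circular binary segmentation; R, the gene's mean coverage ratio, is the
mean back-transformed segmented value over the gene's eligible probes, and
the copy estimate is R divided by the per-sample median of R across assayable
genes.  Estimates above 3 are called amplified, above 6 highly amplified;
estimates below 1 are never called (deletions are out of scope by design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .segmentation import cbs_segment

CALL_NONE = "none"
CALL_AMPLIFIED = "amplified"
CALL_HIGH = "highly_amplified"
CALL_NOT_ASSAYABLE = "not_assayable"


@dataclass(frozen=True)
class GeneCopyEstimate:
    gene: str
    n_eligible_probes: int
    R: float
    estimate: float
    call: str


def coverage_from_reads(dedup_reads: pd.DataFrame, panel: ProbePanel, sample_id: str) -> pd.Series:
    """Deduplicated read count per probe for one sample (zero-filled over the panel)."""
    sub = dedup_reads[dedup_reads["sample_id"] == sample_id]
    counts = sub["probe_id"].value_counts()
    unknown = set(counts.index) - set(panel.by_id)
    if unknown:
        raise ValueError(f"reads reference probes not in panel: {sorted(unknown)[:5]}")
    return counts.reindex([p.probe_id for p in panel.probes], fill_value=0).astype(int)


def compute_ratios(
    tumor_coverage: pd.Series,
    control_coverage: pd.Series,
    panel: ProbePanel,
    gc_min: float = 0.30,
    gc_max: float = 0.60,
    control_min_coverage: int = 30,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-probe tumor/control coverage ratios with eligibility flags.

    Eligibility requires control coverage strictly above ``control_min_coverage``
    and GC fraction within [gc_min, gc_max] (closed interval).  Tumor counts
    are scaled to the control library size (total over eligible probes), then
    the pseudocount is added to both scaled-tumor and control counts before
    ratio formation; the pseudocount therefore guards against zero tumor
    coverage without breaking exact invariance to global tumor-count scaling.
    Ineligible probes are carried with ratio undefined (NaN).
    """
    probe_ids = [p.probe_id for p in panel.probes]
    t = tumor_coverage.reindex(probe_ids)
    c = control_coverage.reindex(probe_ids)
    if t.isna().any() or c.isna().any():
        raise ValueError("tumor/control coverage missing panel probes (probe sets differ)")
    df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene": [p.gene for p in panel.probes],
            "chrom": [p.chrom for p in panel.probes],
            "start": [p.start for p in panel.probes],
            "gc_fraction": [p.gc_fraction for p in panel.probes],
            "tumor_coverage": t.to_numpy(dtype=float),
            "control_coverage": c.to_numpy(dtype=float),
        }
    )
    df["eligible"] = (
        (df["control_coverage"] > control_min_coverage)
        & (df["gc_fraction"] >= gc_min)
        & (df["gc_fraction"] <= gc_max)
    )
    elig = df["eligible"]
    tumor_total = df.loc[elig, "tumor_coverage"].sum()
    control_total = df.loc[elig, "control_coverage"].sum()
    if tumor_total <= 0 or control_total <= 0:
        raise ValueError("no eligible coverage to scale against")
    scale = control_total / tumor_total
    ratio = (df["tumor_coverage"] * scale + pseudocount) / (df["control_coverage"] + pseudocount)
    df["ratio"] = np.where(elig, ratio, np.nan)
    df["log2_ratio"] = np.log2(df["ratio"])
    return df


def filter_genes(ratios: pd.DataFrame, min_probes: int = 15) -> set[str]:
    """Genes with at least ``min_probes`` eligible probes (assayable for CNV)."""
    counts = ratios[ratios["eligible"]].groupby("gene").size()
    return set(counts[counts >= min_probes].index)


def segment_ratios(
    ratios: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """CBS over eligible probes in genomic order, per chromosome.

    Segment boundaries are forced at chromosome breaks.  Returns the input
    with a ``segment_log2`` column (segment mean of the probe's stretch;
    NaN for ineligible probes).
    """
    out = ratios.copy()
    out["segment_log2"] = np.nan
    elig = out[out["eligible"]].sort_values(["chrom", "start"], kind="mergesort")
    for _, chrom_df in elig.groupby("chrom", sort=True):
        vals = chrom_df["log2_ratio"].to_numpy()
        seg_means = np.empty_like(vals)
        for seg in cbs_segment(vals, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed):
            seg_means[seg.start : seg.end] = seg.mean
        out.loc[chrom_df.index, "segment_log2"] = seg_means
    return out


def gene_estimates(
    ratios: pd.DataFrame,
    assayable_genes: set[str],
    amp_threshold: float = 3.0,
    high_amp_threshold: float = 6.0,
    min_probes: int = 15,
    use_segmented: bool = True,
) -> pd.DataFrame:
    """Per-gene copy estimates and amplification calls.

    R(gene) is the mean of back-transformed segmented ratios over the gene's
    eligible probes (or of raw ratios with ``use_segmented=False``); the
    estimate divides R by the median of R across assayable genes.
    """
    if not assayable_genes:
        raise ValueError("zero assayable genes: cannot median-normalize")
    col = "segment_log2" if use_segmented else "log2_ratio"
    if use_segmented and "segment_log2" not in ratios.columns:
        raise ValueError("ratios not segmented; run segment_ratios first")
    elig = ratios[ratios["eligible"]]
    R = (2.0 ** elig[col]).groupby(elig["gene"]).mean()
    n_probes = elig.groupby("gene").size()
    median_R = R.reindex(sorted(assayable_genes)).median()
    rows = []
    for gene in sorted(set(ratios["gene"])):
        n = int(n_probes.get(gene, 0))
        r = float(R.get(gene, np.nan))
        est = r / median_R if np.isfinite(r) else np.nan
        if gene not in assayable_genes or n < min_probes:
            call = CALL_NOT_ASSAYABLE
        elif est > high_amp_threshold:
            call = CALL_HIGH
        elif est > amp_threshold:
            call = CALL_AMPLIFIED
        else:
            call = CALL_NONE
        rows.append({"gene": gene, "n_eligible_probes": n, "R": r, "estimate": est, "call": call})
    return pd.DataFrame(rows)


def call_copy_number(
    tumor_coverage: pd.Series,
    control_coverage: pd.Series,
    panel: ProbePanel,
    gc_min: float = 0.30,
    gc_max: float = 0.60,
    control_min_coverage: int = 30,
    min_probes: int = 15,
    amp_threshold: float = 3.0,
    high_amp_threshold: float = 6.0,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    use_segmented: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratio computation, gene filtering, segmentation and calling in one step.

    Returns (per-probe ratio table with segmented values, per-gene estimates).
    """
    ratios = compute_ratios(
        tumor_coverage,
        control_coverage,
        panel,
        gc_min=gc_min,
        gc_max=gc_max,
        control_min_coverage=control_min_coverage,
    )
    assayable = filter_genes(ratios, min_probes=min_probes)
    if use_segmented:
        ratios = segment_ratios(ratios, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)
    estimates = gene_estimates(
        ratios,
        assayable,
        amp_threshold=amp_threshold,
        high_amp_threshold=high_amp_threshold,
        min_probes=min_probes,
        use_segmented=use_segmented,
    )
    return ratios, estimates
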