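"""Two-round filter cascade reducing raw caller output to high-confidence
bi-allelic candidates.

The cascade mirrors the published design process: keep only sites supported
by both callers, apply quality/coverage/hom-call filters (round 1), drop
sites in high-copy-number or poorly mapped regions (round 2), require 20 bp
clearance to the nearest neighboring variant on at least one flank, and
restrict to bi-allelic records.  Heterozygous sequencing calls are masked to
missing before any per-line frequency accounting, because in a largely
inbred panel they are dominated by paralog-induced false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HET, HOM_ALT, HOM_REF, MISSING, FilterReport, VariantCallSet
from .errors import ValidationError

__all__ = [
    "intersect_callers",
    "apply_round1_filters",
    "apply_round2_filters",
    "flanking_distance_filter",
    "restrict_biallelic",
    "mask_heterozygous_calls",
    "fdr_by_class",
    "nonref_frequency",
    "run_discovery_cascade",
    "FdrResult",
]


def _record_step(report: FilterReport, name: str, ids, keep: np.ndarray) -> None:
    report.record(name, keep.size, int(keep.sum()))
    for vid in np.asarray(ids)[~keep]:
        report.first_fail.setdefault(vid, name)


def intersect_callers(callset: VariantCallSet) -> tuple[VariantCallSet, FilterReport]:
    """Retain only records supported by both variant callers."""
    sites = callset.sites
    for col in ("samtools_call", "gatk_call"):
        if col not in sites.columns or sites[col].isna().any():
            raise ValidationError(f"caller-support flag {col!r} missing on some records")
    keep = (sites["samtools_call"] & sites["gatk_call"]).to_numpy()
    report = FilterReport()
    _record_step(report, "caller_intersection", sites["variant_id"], keep)
    return callset.subset(keep), report


def apply_round1_filters(
    callset: VariantCallSet,
    quality_min: float = 50.0,
    depth_low: int = 50,
    depth_high: int = 3000,
    min_hom_nonref_lines: int = 2,
) -> tuple[VariantCallSet, FilterReport]:
    """Round-1 filters: site quality >= 50; 50 <= DP < 3000 (upper bound
    excluded); at least one line carrying the reference allele (a hom-ref
    call); homozygous non-reference calls in >= 2 lines."""
    if depth_low >= depth_high:
        raise ValidationError("depth_low must be below depth_high")
    sites = callset.sites
    ids = sites["variant_id"]
    report = FilterReport()
    out = callset

    qual = out.sites["qual"].to_numpy() >= quality_min
    _record_step(report, "site_quality", out.sites["variant_id"], qual)
    out = out.subset(qual)

    dp = out.sites["dp"].to_numpy()
    cov = (dp >= depth_low) & (dp < depth_high)
    _record_step(report, "site_depth", out.sites["variant_id"], cov)
    out = out.subset(cov)

    has_ref = (out.genotypes == HOM_REF).sum(axis=1) >= 1
    _record_step(report, "reference_allele_present", out.sites["variant_id"], has_ref)
    out = out.subset(has_ref)

    n_hom_alt = (out.genotypes == HOM_ALT).sum(axis=1)
    enough_alt = n_hom_alt >= min_hom_nonref_lines
    _record_step(report, "hom_nonref_lines", out.sites["variant_id"], enough_alt)
    out = out.subset(enough_alt)
    return out, report


def apply_round2_filters(
    callset: VariantCallSet,
    cn_max: int = 50,
    mq0_max: float = 0.05,
    coverage_fold_max: float = 6.0,
    quality_min: float = 100.0,
    mean_coverage: float | None = None,
) -> tuple[VariantCallSet, FilterReport]:
    """Round-2 filters: remove records with copy number >= ``cn_max``, MQ0
    fraction > ``mq0_max``, site coverage > ``coverage_fold_max`` times the
    panel mean, or quality < ``quality_min``.

    ``mean_coverage`` defaults to the mean site depth over the input records
    (the panel-wide mean over all candidate sites).
    """
    sites = callset.sites
    for col in ("cn", "mq0f"):
        if col not in sites.columns or sites[col].isna().any():
            raise ValidationError(f"annotation {col!r} missing on some records")
    if mean_coverage is None:
        mean_coverage = float(sites["dp"].mean()) if len(sites) else 0.0

    report = FilterReport()
    out = callset

    cn_ok = out.sites["cn"].to_numpy() < cn_max
    _record_step(report, "copy_number", out.sites["variant_id"], cn_ok)
    out = out.subset(cn_ok)

    mq0_ok = out.sites["mq0f"].to_numpy() <= mq0_max
    _record_step(report, "mq0_fraction", out.sites["variant_id"], mq0_ok)
    out = out.subset(mq0_ok)

    cov_ok = out.sites["dp"].to_numpy() <= coverage_fold_max * mean_coverage
    _record_step(report, "excess_coverage", out.sites["variant_id"], cov_ok)
    out = out.subset(cov_ok)

    qual_ok = out.sites["qual"].to_numpy() >= quality_min
    _record_step(report, "recalibrated_quality", out.sites["variant_id"], qual_ok)
    out = out.subset(qual_ok)
    return out, report


def flanking_distance_filter(
    callset: VariantCallSet, min_distance: int = 20
) -> tuple[VariantCallSet, FilterReport]:
    """Retain a record iff its nearest neighboring variant is at least
    ``min_distance`` bp away on at least one side (chromosome ends count as a
    clear side).  Input is sorted internally if needed."""
    sites = callset.sites
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        callset = callset.subset(order)
        sites = callset.sites

    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    left = np.full(len(sites), np.inf)
    right = np.full(len(sites), np.inf)
    same_prev = np.zeros(len(sites), bool)
    same_prev[1:] = chrom[1:] == chrom[:-1]
    left[same_prev] = (pos[1:] - pos[:-1])[same_prev[1:]]
    right[:-1][same_prev[1:]] = (pos[1:] - pos[:-1])[same_prev[1:]]
    keep = (left >= min_distance) | (right >= min_distance)

    report = FilterReport()
    _record_step(report, "flanking_distance", sites["variant_id"], keep)
    return callset.subset(keep), report


def restrict_biallelic(callset: VariantCallSet) -> tuple[VariantCallSet, FilterReport]:
    """Remove records with more than one alternate allele."""
    n_alt = callset.sites["alt"].astype(str).str.count(",") + 1
    keep = (n_alt == 1).to_numpy()
    report = FilterReport()
    _record_step(report, "biallelic", callset.sites["variant_id"], keep)
    return callset.subset(keep), report


def mask_heterozygous_calls(callset: VariantCallSet) -> VariantCallSet:
    """Set every heterozygous genotype to missing (idempotent)."""
    out = callset.copy()
    out.genotypes[out.genotypes == HET] = MISSING
    return out


@dataclass
class FdrResult:
    """False-discovery rates of het and hom sequencing calls versus truth.

    A rate is ``nan`` (undefined, not zero) when no call of that class has a
    non-missing truth counterpart.
    """

    fdr_het: float
    fdr_hom: float
    n_het: int
    n_hom: int


def fdr_by_class(seq_calls: np.ndarray, truth_calls: np.ndarray) -> FdrResult:
    """FDR of class c = (# class-c sequencing calls disagreeing with a
    non-missing truth call) / (# class-c calls with non-missing truth)."""
    seq = np.asarray(seq_calls)
    truth = np.asarray(truth_calls)
    if seq.shape != truth.shape:
        raise ValidationError(
            f"call matrices must share sample x variant index, got {seq.shape} vs {truth.shape}"
        )
    have_truth = truth != MISSING

    het_mask = (seq == HET) & have_truth
    hom_mask = ((seq == HOM_REF) | (seq == HOM_ALT)) & have_truth
    n_het = int(het_mask.sum())
    n_hom = int(hom_mask.sum())
    fdr_het = float((truth[het_mask] != HET).mean()) if n_het else float("nan")
    fdr_hom = float((truth[hom_mask] != seq[hom_mask]).mean()) if n_hom else float("nan")
    return FdrResult(fdr_het, fdr_hom, n_het, n_hom)


def nonref_frequency(callset: VariantCallSet, pool_samples) -> np.ndarray:
    """Per-variant ratio of homozygous non-reference calls to all available
    (non-missing) calls within the given pool; ``nan`` where the pool has no
    calls.  Heterozygous calls are expected to be masked already."""
    pool = [s for s in pool_samples]
    if not pool:
        raise ValidationError("pool_samples is empty")
    idx = [callset.samples.index(s) for s in pool]
    gt = callset.genotypes[:, idx]
    called = gt != MISSING
    n_called = called.sum(axis=1)
    n_alt = (gt == HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)
    return freq


def run_discovery_cascade(
    callset: VariantCallSet, **round_params
) -> tuple[VariantCallSet, FilterReport]:
    """The documented filter order: caller intersection, round-1, round-2,
    flanking distance, bi-allelic restriction.  Returns the surviving set and
    a combined report whose per-step counts reconcile."""
    report = FilterReport()
    out, rep = intersect_callers(callset)
    report.extend(rep)
    out, rep = apply_round1_filters(
        out, **{k: v for k, v in round_params.items()
                if k in ("quality_min", "depth_low", "depth_high", "min_hom_nonref_lines")}
    )
    report.extend(rep)
    out, rep = apply_round2_filters(
        out, **{k: v for k, v in round_params.items()
                if k in ("cn_max", "mq0_max", "coverage_fold_max", "mean_coverage")},
        quality_min=round_params.get("round2_quality_min", 100.0),
    )
    report.extend(rep)
    out, rep = flanking_distance_filter(
        out, min_distance=round_params.get("min_distance", 20)
    )
    report.extend(rep)
    out, rep = restrict_biallelic(out)
    report.extend(rep)
    return out, report
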