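"""Tumor mutational burden: nonsynonymous mutations and indels per megabase.

Two routes produce a :class:`TMBResult`:

* paired mode — the caller's matched-normal comparison already separates
  somatic from germline (the somatic-status tag), so TMB is computed
  directly from the filtered call set;
* tumor-only mode — the full optimized pipeline: false-positive filters,
  SGZ somatic/germline classification against the fitted purity/ploidy
  model, background-library filtering, then the same count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import sgz as _sgz
from .background import BackgroundLibrary, BackgroundPolicy, background_filter
from .filters import apply_filters
from .sgz import (
    SGZCall,
    SGZConfig,
    TumorModel,
    classify_variant,
    collect_het_afs,
    estimate_baseline_depth,
    find_segment,
    fit_purity_ploidy,
    segment_coverage,
    variant_logratio,
)
from .variantio import TargetRegions, VariantRecord


@dataclass
class TMBResult:
    n_mutations: int
    footprint_mb: float
    tmb: float
    mode: str

    def as_dict(self) -> dict:
        return {
            "n_mutations": self.n_mutations,
            "footprint_mb": self.footprint_mb,
            "tmb": self.tmb,
            "mode": self.mode,
        }


@dataclass
class TumorOnlyResult:
    """TMB plus the intermediate products of the tumor-only pipeline."""

    tmb: TMBResult
    model: TumorModel
    calls: list[SGZCall]
    somatic: list[VariantRecord]
    stage_counts: dict[str, int] = field(default_factory=dict)


def compute_tmb(
    records: Sequence[VariantRecord],
    regions: TargetRegions,
    mode: str = "tumor_only",
    count_hotspots: bool = True,
) -> TMBResult:
    """Count qualifying mutations inside the panel and divide by footprint.

    Qualifying = nonsynonymous SNV or coding indel, position inside the
    target regions.  ``count_hotspots=False`` additionally drops hotspot
    driver mutations from the numerator (some assays exclude them).
    """
    footprint = regions.footprint_mb
    if footprint <= 0:
        raise ValueError("panel footprint must be positive")
    n = sum(
        1
        for r in records
        if r.is_nonsynonymous
        and regions.contains(r.chrom, r.pos)
        and (count_hotspots or r.hotspot == ".")
    )
    return TMBResult(n_mutations=n, footprint_mb=footprint, tmb=n / footprint, mode=mode)


def tmb_paired(
    records: Sequence[VariantRecord], regions: TargetRegions
) -> tuple[TMBResult, list[VariantRecord]]:
    """Paired-mode TMB: filter cascade, then count; germline is removed by
    the caller's somatic status (basic filter).  Returns (result, kept)."""
    if records and records[0].n_samples < 2:
        raise ValueError("tmb_paired requires paired-mode records")
    kept, _ = apply_filters(records, mode="paired")
    result = compute_tmb(kept, regions, mode="paired")
    return result, kept


def tmb_tumor_only(
    records: Sequence[VariantRecord],
    coverage_bins,
    lib: Optional[BackgroundLibrary],
    regions: TargetRegions,
    purity: Optional[float] = None,
    config: Optional[SGZConfig] = None,
    policy: Optional[BackgroundPolicy] = None,
) -> TumorOnlyResult:
    """The optimized tumor-only pipeline.

    Stages: false-positive filters -> coverage segmentation -> purity/ploidy
    fit (seeded with background-recurrent SNPs as heterozygous-germline
    probes when a library is supplied, or with a fixed ``purity``) -> SGZ
    classification -> background filtering of the somatic-labeled records ->
    TMB over the panel footprint.
    """
    cfg = config or SGZConfig()
    stage: dict[str, int] = {"input": len(records)}

    kept, _ = apply_filters(records, mode="tumor_only")
    stage["post_filters"] = len(kept)

    segments = segment_coverage(coverage_bins)
    recurrent = lib.recurrent_keys() if lib is not None else None
    het_afs = collect_het_afs(kept, segments, recurrent_keys=recurrent)
    if recurrent is not None and sum(a.size for a in het_afs) < 10:
        het_afs = collect_het_afs(kept, segments)  # library too sparse; use all
    model = fit_purity_ploidy(segments, het_afs, cfg, fixed_purity=purity)

    baseline = None
    try:
        baseline = estimate_baseline_depth(kept, segments)
    except ValueError:
        pass

    calls: list[SGZCall] = []
    somatic: list[VariantRecord] = []
    for r in kept:
        try:
            seg = find_segment(segments, r.chrom, r.pos)
        except _sgz.SegmentAssignmentError:
            continue
        var_lr = None
        if baseline is not None and r.dp[0]:
            var_lr = variant_logratio(r.dp[0], baseline)
        seen = lib.count(r.key) >= 1 if lib is not None else None
        call = classify_variant(r, seg, model, cfg, var_lr=var_lr, seen_in_background=seen)
        calls.append(call)
        if call.label == "somatic":
            somatic.append(r)
    stage["sgz_somatic"] = len(somatic)

    if lib is not None:
        somatic, removed = background_filter(somatic, lib, policy)
        stage["post_background"] = len(somatic)

    result = compute_tmb(somatic, regions, mode="tumor_only")
    return TumorOnlyResult(
        tmb=result, model=model, calls=calls, somatic=somatic, stage_counts=stage
    )


@dataclass
class ConcordanceResult:
    """Per-sample TMB from both pipeline arms plus pooled call overlap."""

    sample_ids: list[str]
    tmb_paired: list[float]
    tmb_tumor_only: list[float]
    n_paired_calls: int
    n_recovered_calls: int

    @property
    def pearson_r(self) -> float:
        import numpy as np

        return float(np.corrcoef(self.tmb_paired, self.tmb_tumor_only)[0, 1])

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered_calls / max(self.n_paired_calls, 1)


def concordance_study(cohort, lib: Optional[BackgroundLibrary]) -> ConcordanceResult:
    """Run the paired and tumor-only pipelines over a simulated cohort.

    The paired-mode call set is the reference arm; concordance is reported as
    the Pearson correlation of the two per-sample TMB vectors and the pooled
    fraction of paired-mode calls also labeled somatic by the tumor-only arm.
    """
    ids, tp, tt = [], [], []
    n_paired = n_recovered = 0
    for s in cohort.samples:
        paired_res, paired_kept = tmb_paired(s.paired, cohort.regions)
        to_res = tmb_tumor_only(
            s.tumor_only, s.coverage_bins, lib, cohort.regions
        )
        ids.append(s.sample_id)
        tp.append(paired_res.tmb)
        tt.append(to_res.tmb.tmb)
        paired_keys = {r.key for r in paired_kept}
        tumor_only_keys = {r.key for r in to_res.somatic}
        n_paired += len(paired_keys)
        n_recovered += len(paired_keys & tumor_only_keys)
    return ConcordanceResult(
        sample_ids=ids, tmb_paired=tp, tmb_tumor_only=tt,
        n_paired_calls=n_paired, n_recovered_calls=n_recovered,
    )
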