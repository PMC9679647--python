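"""False-positive variant filters for panel sequencing call sets.

Four exclusion predicates are applied in order: a basic sanity filter
(allele length, caller somatic status), a lenient filter for known hotspot
positions, a false-positive/germline database filter, and a strict
"normal" filter of fifteen artifact-signature clauses for non-hotspot
variants.  A record is removed when any predicate matches; the verdict
records which clause fired first for each predicate.

Missing tags never fire a clause: a comparison against an absent numeric
tag (``None``) or the string sentinel ``"."`` evaluates false, which is the
conservative choice (the clause cannot establish the artifact signature).
In tumor-only mode the sub-conditions indexing the matched normal sample
(``DP[1]``, ``NM[1]``) are skipped the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .variantio import MISSING, VariantKey, VariantRecord


@dataclass
class FilterVerdict:
    key: VariantKey
    excluded: bool
    reasons: list[str] = field(default_factory=list)


def _lt(x: Optional[float], t: float) -> bool:
    return x is not None and x < t


def _gt(x: Optional[float], t: float) -> bool:
    return x is not None and x > t


def _get(xs: Sequence, i: int):
    return xs[i] if i < len(xs) else None


def _bias_codes(bias: str) -> tuple[str, str]:
    """Split a strand-bias category string into (forward, reverse) codes."""
    parts = bias.split(";")
    fwd = parts[0] if parts and parts[0] else MISSING
    rev = parts[1] if len(parts) > 1 and parts[1] else MISSING
    return fwd, rev


def basic_filter(v: VariantRecord) -> bool:
    """Exclude over-long alleles and calls the caller did not mark somatic."""
    return basic_filter_reason(v) is not None


def basic_filter_reason(v: VariantRecord) -> Optional[str]:
    if len(v.ref) > 50 or len(v.alt) > 50:
        return "allele_len_gt_50"
    if v.status != MISSING and "Somatic" not in v.status:
        return "status_not_somatic"
    return None


def hotspot_filter(v: VariantRecord) -> bool:
    """Lenient exclusion applied only at hotspot positions."""
    return hotspot_filter_reason(v) is not None


def hotspot_filter_reason(v: VariantRecord) -> Optional[str]:
    if v.hotspot == MISSING:
        return None
    if v.sor is not None and v.sor != 0 and v.sor < 3:
        return "sor_lt_3"
    if _lt(v.vd, 5):
        return "vd_lt_5"
    if _lt(v.af, 0.007):
        return "af_lt_0.007"
    if _gt(v.ssf, 0.05):
        return "ssf_gt_0.05"
    return None


def fpdb_filter(v: VariantRecord) -> bool:
    """Exclude non-hotspot variants tagged in the FP or germline database."""
    return fpdb_filter_reason(v) is not None


def fpdb_filter_reason(v: VariantRecord) -> Optional[str]:
    if v.hotspot != MISSING:
        return None
    if v.fpdb not in ("0", MISSING):
        return "fpdb_tagged"
    if v.germline_tag not in ("0", MISSING):
        return "germline_tagged"
    return None


def normal_filter(v: VariantRecord, tumor_only: bool | None = None) -> bool:
    """Strict fifteen-clause artifact exclusion for non-hotspot variants."""
    return normal_filter_reason(v, tumor_only) is not None


def normal_filter_reason(
    v: VariantRecord, tumor_only: bool | None = None
) -> Optional[str]:
    if v.hotspot != MISSING:
        return None
    if tumor_only is None:
        tumor_only = v.n_samples < 2
    # paired-normal sub-conditions are skipped in tumor-only mode
    dp1 = None if tumor_only else _get(v.dp, 1)
    nm1 = None if tumor_only else _get(v.nm, 1)

    if v.germline_tag != MISSING:
        return "germline_tag_set"
    if _lt(_get(v.pmean, 0), 20):
        return "pmean_lt_20"
    if (v.sor is not None and v.sor != 0 and v.sor < 5) or _lt(v.af, 0.02) or _gt(
        v.ssf, 0.01
    ):
        return "sor_af_ssf"
    if _lt(v.af, 0.05) and _lt(_get(v.mq, 0), 50):
        return "lowaf_mq_lt_50"
    if _lt(_get(v.mq, 0), 30):
        return "mq_lt_30"
    if _lt(v.af, 0.05) and _lt(_get(v.qual, 0), 30):
        return "lowaf_qual_lt_30"
    if (_gt(v.msi, 10) or (_gt(v.msilen, 1) and _gt(v.msi, 4))) and _lt(v.af, 0.3):
        return "msi_lowaf"
    if (
        v.vtype != "snp"
        and _gt(v.msi, 3)
        and v.msilen is not None
        and (v.msilen == len(v.ref) - 1 or v.msilen == len(v.alt) - 1)
        and _lt(v.af, 0.1)
    ):
        return "indel_msi_lowaf"
    if _gt(_get(v.nm, 0), 2) and _lt(_get(v.mq, 0), 60) and _lt(v.af, 0.2):
        return "nm_gt_2_mq_lowaf"
    if _gt(_get(v.nm, 0), 3) and (_lt(_get(v.mq, 0), 55) or _gt(nm1, 3)):
        return "nm_gt_3"
    if _lt(_get(v.dp, 0), 30) or _lt(dp1, 30):
        return "dp_lt_30"
    if _lt(v.vd, 10):
        return "vd_lt_10"
    fwd, rev = _bias_codes(_get(v.bias, 0) or MISSING)
    if fwd == "2" and rev == "1":
        return "strand_bias_codes"
    if _lt(_get(v.sbf, 0), 0.05) and _lt(_get(v.vd_s, 0), 50):
        return "sbf_lowvd"
    if (v.sor is not None and v.sor != 0 and v.sor < 10) and _lt(_get(v.mq, 0), 60):
        return "sor_lt_10_mq_lt_60"
    return None


def evaluate(v: VariantRecord, mode: str = "tumor_only") -> FilterVerdict:
    """Run all four predicates on one record and collect firing clauses."""
    tumor_only = mode == "tumor_only"
    reasons = []
    r = basic_filter_reason(v)
    if r:
        reasons.append(f"basicfilter:{r}")
    r = hotspot_filter_reason(v)
    if r:
        reasons.append(f"hotspotfilter:{r}")
    r = fpdb_filter_reason(v)
    if r:
        reasons.append(f"fpdbfilter:{r}")
    r = normal_filter_reason(v, tumor_only)
    if r:
        reasons.append(f"normalfilter:{r}")
    return FilterVerdict(key=v.key, excluded=bool(reasons), reasons=reasons)


def apply_filters(
    records: Iterable[VariantRecord], mode: str = "tumor_only"
) -> tuple[list[VariantRecord], list[FilterVerdict]]:
    """Apply the exclusion cascade; returns (kept records, all verdicts)."""
    kept: list[VariantRecord] = []
    verdicts: list[FilterVerdict] = []
    for v in records:
        verdict = evaluate(v, mode)
        verdicts.append(verdict)
        if not verdict.excluded:
            kept.append(v)
    return kept, verdicts


def write_verdicts(verdicts: Sequence[FilterVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\texcluded\treasons\n")
        for v in verdicts:
            fh.write(
                f"{v.key.chrom}\t{v.key.pos}\t{v.key.ref}\t{v.key.alt}\t"
                f"{int(v.excluded)}\t{','.join(v.reasons) or '.'}\n"
            )
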