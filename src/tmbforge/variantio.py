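"""Domain types and readers/writers for variant, region, and cohort data.

Conventions
-----------
* VCF positions are 1-based inclusive; BED is 0-based half-open. All
  in-memory positions are 1-based.
* Multiallelic VCF records are split into one :class:`VariantRecord` per
  alternate allele, and alleles are normalized (shared prefix/suffix
  trimmed) before keying, so the same variant gets the same
  :class:`VariantKey` in every sample.
* Missing string tags carry the VCF sentinel ``"."``; missing numeric tags
  are ``None``.  Downstream filter clauses treat a missing tag as
  "condition false" (a clause referencing an absent tag never fires).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
import pysam

MISSING = "."

#: annotation classes counted as nonsynonymous for TMB purposes
NONSYNONYMOUS_EFFECTS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)
#: indel annotation classes in coding regions (always TMB-eligible)
CODING_INDEL_EFFECTS = frozenset(
    {
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "disruptive_inframe_insertion",
        "disruptive_inframe_deletion",
    }
)

CLINICAL_COLUMNS = [
    "patient_id",
    "tmb",
    "response",
    "sd_duration_weeks",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "age",
    "gender",
    "drug",
    "cancer_type",
]


class VariantKey(NamedTuple):
    """Normalized (chrom, pos, ref, alt) identity of a variant across samples."""

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix from an allele pair, keeping >= 1 base.

    This canonicalizes redundant padding (e.g. ``pos=100 CAT>CGT`` becomes
    ``pos=101 A>G``) so that keys match across call sets.  Full left-alignment
    against the reference sequence is out of scope; trimming is sufficient for
    records produced by splitting multiallelics.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantRecord:
    """One called variant with every attribute the filter engine consumes.

    Per-sample attributes (``pmean``, ``mq``, ``qual``, ``nm``, ``dp``,
    ``bias``, ``sbf``, ``vd_s``) are lists indexed ``[0]`` = tumor and
    ``[1]`` = matched normal; tumor-only records have exactly one entry.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    status: str = MISSING
    hotspot: str = MISSING
    sor: Optional[float] = None
    vd: Optional[int] = None
    af: Optional[float] = None
    ssf: Optional[float] = None
    fpdb: str = MISSING
    germline_tag: str = MISSING
    msi: Optional[float] = None
    msilen: Optional[float] = None
    effect: str = MISSING
    pmean: list[Optional[float]] = field(default_factory=lambda: [None])
    mq: list[Optional[float]] = field(default_factory=lambda: [None])
    qual: list[Optional[float]] = field(default_factory=lambda: [None])
    nm: list[Optional[float]] = field(default_factory=lambda: [None])
    dp: list[Optional[int]] = field(default_factory=lambda: [None])
    bias: list[str] = field(default_factory=lambda: [MISSING])
    sbf: list[Optional[float]] = field(default_factory=lambda: [None])
    vd_s: list[Optional[int]] = field(default_factory=lambda: [None])

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele fraction out of [0, 1]: {self.af}")

    @property
    def vtype(self) -> str:
        return "snp" if len(self.ref) == len(self.alt) else "indel"

    @property
    def n_samples(self) -> int:
        return len(self.dp)

    @property
    def key(self) -> VariantKey:
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        return VariantKey(self.chrom, pos, ref, alt)

    @property
    def is_nonsynonymous(self) -> bool:
        """Nonsynonymous SNV, or any indel in a coding region."""
        if self.vtype == "indel":
            return self.effect in CODING_INDEL_EFFECTS or self.effect in NONSYNONYMOUS_EFFECTS
        return self.effect in NONSYNONYMOUS_EFFECTS


@dataclass(frozen=True)
class TargetRegions:
    """Merged panel target intervals (0-based half-open) and their footprint."""

    intervals: tuple[tuple[str, int, int], ...]

    @property
    def footprint_mb(self) -> float:
        return sum(e - s for _, s, e in self.intervals) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        p = pos - 1
        return any(c == chrom and s <= p < e for c, s, e in self.intervals)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "TargetRegions":
        return cls(tuple(merge_intervals(intervals)))


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


class VcfParseError(ValueError):
    pass


class ModeError(ValueError):
    pass


def _scalar(value, alt_index: int, n_alts: int):
    """Pick the per-alt element of a possibly tuple-valued tag."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            value = value[alt_index]
        else:
            value = value[0]
    return value


def _info_get(rec, tag: str):
    # undeclared tags raise in htslib; treat them the same as absent ones
    try:
        return rec.info.get(tag)
    except (KeyError, ValueError):
        return None


def _info_str(rec, tag: str, alt_index: int, n_alts: int) -> str:
    v = _scalar(_info_get(rec, tag), alt_index, n_alts)
    return MISSING if v is None else str(v)


def _info_num(rec, tag: str, alt_index: int, n_alts: int, cast=float):
    v = _scalar(_info_get(rec, tag), alt_index, n_alts)
    if v is None:
        return None
    v = cast(v)
    return None if isinstance(v, float) and math.isnan(v) else v


def _fmt_num(sample, tag: str, cast=float):
    try:
        v = sample.get(tag)
    except (KeyError, ValueError):
        return None
    if isinstance(v, tuple):
        v = v[0] if v else None
    if v is None:
        return None
    v = cast(v)
    return None if isinstance(v, float) and math.isnan(v) else v


def _fmt_str(sample, tag: str) -> str:
    try:
        return sample.get(tag) or MISSING
    except (KeyError, ValueError):
        return MISSING


def read_vcf(path: str | Path, mode: str = "tumor_only") -> list[VariantRecord]:
    """Read an annotated VCF into :class:`VariantRecord` objects.

    Multiallelic sites are split into one record per alternate allele.
    ``mode`` is ``"tumor_only"`` (one sample column) or ``"paired"``
    (two columns, tumor first).
    """
    if mode not in ("tumor_only", "paired"):
        raise ModeError(f"unknown mode {mode!r}")
    records: list[VariantRecord] = []
    verbosity = pysam.set_verbosity(0)  # htslib tag-sanity chatter
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)
    with vcf:
        n_cols = len(vcf.header.samples)
        want = 2 if mode == "paired" else 1
        if n_cols < want:
            raise ModeError(
                f"mode {mode!r} requires {want} sample column(s); {path} has {n_cols}"
            )
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                n = len(alts)
                samples = [rec.samples[s] for s in list(vcf.header.samples)[:want]]
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        status=_info_str(rec, "STATUS", i, n),
                        hotspot=_info_str(rec, "HOTSPOT", i, n),
                        sor=_info_num(rec, "SOR", i, n),
                        vd=_info_num(rec, "VD", i, n, cast=int),
                        af=_info_num(rec, "AF", i, n),
                        ssf=_info_num(rec, "SSF", i, n),
                        fpdb=_info_str(rec, "FPDB", i, n),
                        germline_tag=_info_str(rec, "GERMLINE", i, n),
                        msi=_info_num(rec, "MSI", i, n),
                        msilen=_info_num(rec, "MSILEN", i, n),
                        effect=_info_str(rec, "EFFECT", i, n),
                        pmean=[_fmt_num(s, "PMEAN") for s in samples],
                        mq=[_fmt_num(s, "MQ") for s in samples],
                        qual=[_fmt_num(s, "QUAL") for s in samples],
                        nm=[_fmt_num(s, "NM") for s in samples],
                        dp=[_fmt_num(s, "DP", cast=int) for s in samples],
                        bias=[_fmt_str(s, "BIAS") for s in samples],
                        sbf=[_fmt_num(s, "SBF") for s in samples],
                        vd_s=[_fmt_num(s, "VD", cast=int) for s in samples],
                    )
                )
    return records


def _build_header(records: Sequence[VariantRecord], mode: str) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom in sorted({r.chrom for r in records} or {"chr1"}):
        h.contigs.add(chrom, length=500_000_000)
    h.info.add("STATUS", 1, "String", "Caller somatic status")
    h.info.add("HOTSPOT", 1, "String", "Hotspot tag ('.' = not a hotspot)")
    h.info.add("SOR", 1, "Float", "Strand odds ratio")
    h.info.add("VD", 1, "Integer", "Variant-supporting read count (tumor)")
    h.info.add("AF", 1, "Float", "Variant allele fraction (tumor)")
    h.info.add("SSF", 1, "Float", "Somatic significance p-value")
    h.info.add("FPDB", 1, "String", "False-positive database tag")
    h.info.add("GERMLINE", 1, "String", "Germline database tag")
    h.info.add("MSI", 1, "Float", "Microsatellite run count")
    h.info.add("MSILEN", 1, "Float", "Microsatellite unit length")
    h.info.add("EFFECT", 1, "String", "Functional annotation class")
    h.formats.add("DP", 1, "Integer", "Total depth")
    h.formats.add("VD", 1, "Integer", "Variant depth")
    h.formats.add("PMEAN", 1, "Float", "Mean position of variant in reads")
    h.formats.add("MQ", 1, "Float", "Mean mapping quality")
    h.formats.add("QUAL", 1, "Float", "Mean base quality")
    h.formats.add("NM", 1, "Float", "Mean mismatch count")
    h.formats.add("BIAS", 1, "String", "Strand bias category codes 'fwd;rev'")
    h.formats.add("SBF", 1, "Float", "Strand bias Fisher p-value")
    h.add_sample("TUMOR")
    if mode == "paired":
        h.add_sample("NORMAL")
    return h


def write_variants(
    records: Sequence[VariantRecord], path: str | Path, mode: str | None = None
) -> None:
    """Write records to a VCF; round-trips every typed field through read_vcf."""
    if mode is None:
        mode = "paired" if records and records[0].n_samples == 2 else "tumor_only"
    want = 2 if mode == "paired" else 1
    for r in records:
        if r.n_samples != want:
            raise ModeError("records do not share a single tumor-only/paired mode")
    header = _build_header(records, mode)
    names = list(header.samples)
    verbosity = pysam.set_verbosity(0)
    try:
        out_file = pysam.VariantFile(str(path), "w", header=header)
    finally:
        pysam.set_verbosity(verbosity)
    with out_file as out:
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt))
            rec.info["STATUS"] = r.status
            rec.info["HOTSPOT"] = r.hotspot
            rec.info["FPDB"] = r.fpdb
            rec.info["GERMLINE"] = r.germline_tag
            rec.info["EFFECT"] = r.effect
            for tag, val in (
                ("SOR", r.sor),
                ("VD", r.vd),
                ("AF", r.af),
                ("SSF", r.ssf),
                ("MSI", r.msi),
                ("MSILEN", r.msilen),
            ):
                if val is not None:
                    rec.info[tag] = val
            for si, name in enumerate(names):
                s = rec.samples[name]
                for tag, vals in (
                    ("DP", r.dp),
                    ("VD", r.vd_s),
                    ("PMEAN", r.pmean),
                    ("MQ", r.mq),
                    ("QUAL", r.qual),
                    ("NM", r.nm),
                    ("SBF", r.sbf),
                ):
                    if vals[si] is not None:
                        s[tag] = vals[si]
                if r.bias[si] != MISSING:
                    s["BIAS"] = r.bias[si]
            out.write(rec)


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path) -> TargetRegions:
    """Read a 3+ column BED (0-based half-open) into merged TargetRegions."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    if not intervals:
        raise BedFormatError(f"{path}: no intervals")
    return TargetRegions.from_intervals(intervals)


def write_bed(regions: TargetRegions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated clinical table used by the cutoff analysis."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def copy_record(record: VariantRecord, **changes) -> VariantRecord:
    return replace(record, **changes)
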