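"""Panel-of-normals background library for tumor-only germline filtering.

A background library counts, per normalized variant key, in how many normal
samples of the target population the variant was observed.  Tumor-only calls
recurring in the library (more than five contributing samples by default)
are removed as presumptive germline or systematic artifacts; calls whose
observed allele fraction exceeds 0.9 are exempt under the literal policy
(they are handled by the zygosity classifier's high-AF germline rule), or
removed under the alternative ``high_vaf_germline`` policy which treats
high-AF calls as homozygous germline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .variantio import VariantKey, VariantRecord, read_vcf


@dataclass
class BackgroundPolicy:
    max_occurrences: int = 5  # exclude when count > this
    high_af: float = 0.9
    mode: str = "literal"  # literal | high_vaf_germline


@dataclass
class BackgroundLibrary:
    counts: dict[VariantKey, int] = field(default_factory=dict)
    n_samples: int = 0
    provenance: str = ""

    def count(self, key: VariantKey) -> int:
        return self.counts.get(key, 0)

    def recurrent_keys(self, min_count: int = 6) -> set[VariantKey]:
        return {k for k, c in self.counts.items() if c >= min_count}

    def merge(self, other: "BackgroundLibrary") -> "BackgroundLibrary":
        counts = dict(self.counts)
        for k, c in other.counts.items():
            counts[k] = counts.get(k, 0) + c
        return BackgroundLibrary(
            counts=counts,
            n_samples=self.n_samples + other.n_samples,
            provenance=f"{self.provenance}+{other.provenance}".strip("+"),
        )


def add_sample(lib: BackgroundLibrary, records: Iterable[VariantRecord]) -> None:
    """Count one normal sample's variants (deduplicated within the sample)."""
    seen = {r.key for r in records}
    for key in seen:
        lib.counts[key] = lib.counts.get(key, 0) + 1
    lib.n_samples += 1


def build_library(
    normal_vcfs: Sequence[str | Path], provenance: str = ""
) -> BackgroundLibrary:
    """Build a library from one VCF per normal sample."""
    if not normal_vcfs:
        raise ValueError("at least one normal-sample VCF is required")
    lib = BackgroundLibrary(provenance=provenance)
    for path in normal_vcfs:
        add_sample(lib, read_vcf(path, mode="tumor_only"))
    return lib


def build_library_from_records(
    samples: Sequence[Sequence[VariantRecord]], provenance: str = ""
) -> BackgroundLibrary:
    """Build a library from already-parsed per-sample record lists."""
    if not samples:
        raise ValueError("at least one normal sample is required")
    lib = BackgroundLibrary(provenance=provenance)
    for records in samples:
        add_sample(lib, records)
    return lib


def background_filter(
    records: Sequence[VariantRecord],
    lib: BackgroundLibrary,
    policy: Optional[BackgroundPolicy] = None,
) -> tuple[list[VariantRecord], list[tuple[VariantKey, int]]]:
    """Remove library-recurrent calls; returns (kept, removal log).

    Literal policy: exclude iff count > max_occurrences AND af <= high_af
    (high-AF calls are retained).  ``high_vaf_germline`` policy: exclude iff
    count > max_occurrences OR af > high_af.
    """
    policy = policy or BackgroundPolicy()
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantKey, int]] = []
    for r in records:
        count = lib.count(r.key)
        af = r.af if r.af is not None else 0.0
        if policy.mode == "high_vaf_germline":
            exclude = count > policy.max_occurrences or af > policy.high_af
        else:
            exclude = count > policy.max_occurrences and af <= policy.high_af
        if exclude:
            removed.append((r.key, count))
        else:
            kept.append(r)
    return kept, removed


def write_library(lib: BackgroundLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_samples={lib.n_samples}\n")
        if lib.provenance:
            fh.write(f"#provenance={lib.provenance}\n")
        fh.write("chrom\tpos\tref\talt\tcount\n")
        for key in sorted(lib.counts):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{lib.counts[key]}\n")


def read_library(path: str | Path) -> BackgroundLibrary:
    lib = BackgroundLibrary()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#n_samples="):
                lib.n_samples = int(line.split("=", 1)[1])
            elif line.startswith("#provenance="):
                lib.provenance = line.split("=", 1)[1]
            elif line.startswith("#") or line.startswith("chrom\t") or not line:
                continue
            else:
                chrom, pos, ref, alt, count = line.split("\t")
                lib.counts[VariantKey(chrom, int(pos), ref, alt)] = int(count)
    return lib
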