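"""Synthetic tumor / normal panel-sequencing cohorts with known truth.

The generator emulates the data layout of a targeted-panel study of
tumor-only TMB estimation: a shared catalogue of germline SNP sites at
population allele frequencies across the panel footprint, private clonal
somatic mutations at a per-sample mutation rate, segment-level copy-number
states with tumor purity, Poisson depths and binomially sampled alt reads
(defaults 1027x tumor / 455x matched normal), a cohort of background normal
samples for the panel-of-normals library, and a clinical outcome layer in
which durable clinical benefit and survival depend on the true TMB.

Observed allele fractions follow the same purity / copy-number expectation
formulas the SGZ classifier models, so classification accuracy on this data
measures the classifier, not a distribution mismatch.  Every draw descends
from a single integer seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .sgz import expected_logratio
from .variantio import (
    TargetRegions,
    VariantRecord,
    write_bed,
    write_variants,
)

BASES = ("A", "C", "G", "T")

GERMLINE_EFFECTS = (("missense_variant", 0.45), ("synonymous_variant", 0.55))
SOMATIC_EFFECTS = (
    ("missense_variant", 0.60),
    ("stop_gained", 0.08),
    ("splice_donor_variant", 0.02),
    ("synonymous_variant", 0.20),
    ("frameshift_variant", 0.07),
    ("inframe_deletion", 0.03),
)


@dataclass
class ClinicalModel:
    dcb_center: float = 7.0  # mut/Mb at which P(DCB) = 0.5
    dcb_slope: float = 1.0  # logistic slope per mut/Mb
    os_base_hazard: float = 0.0578  # per month; median OS ~ 12 months (high TMB)
    os_hazard_ratio: float = 2.5  # low-TMB vs high-TMB hazard
    pfs_hazard_multiplier: float = 2.0
    censor_rate: float = 0.02  # per month, independent exponential


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 62
    n_background_normals: int = 100
    n_regions: int = 14
    region_length: int = 100_000  # 14 x 100 kb = 1.4 Mb panel footprint
    bin_size: int = 1_000
    # (population allele frequency, number of catalogue sites)
    germline_spectrum: tuple = (
        (0.50, 800),
        (0.25, 900),
        (0.10, 1200),
        (0.05, 2000),
        (0.01, 5000),
    )
    somatic_rate_range: tuple = (1.0, 30.0)  # mut/Mb, uniform per sample
    purity_range: tuple = (0.4, 0.9)
    # (probability, total copies C, minor copies M) per panel region
    cn_profile: tuple = ((0.5, 2, 1), (0.2, 1, 0), (0.2, 3, 1), (0.1, 2, 0))
    mean_depth_tumor: float = 1027.0
    mean_depth_normal: float = 455.0
    logratio_noise_sd: float = 0.05
    hotspot_fraction: float = 0.02  # somatic calls marked as hotspot positions
    clinical: ClinicalModel = field(default_factory=ClinicalModel)

    def __post_init__(self) -> None:
        if self.n_regions * self.region_length <= 0:
            raise ValueError("panel footprint must be positive")
        if self.mean_depth_tumor < 1 or self.mean_depth_normal < 1:
            raise ValueError("mean depths must be >= 1")


@dataclass
class SimulatedSample:
    sample_id: str
    purity: float
    ploidy: float
    region_cn: list[tuple[int, int]]  # (C, M) per panel region
    tumor_only: list[VariantRecord]
    paired: list[VariantRecord]
    coverage_bins: pd.DataFrame
    truth: pd.DataFrame  # key columns + origin + true_af + C + M
    true_tmb: float


@dataclass
class SimulatedCohort:
    config: SimConfig
    regions: TargetRegions
    catalogue: pd.DataFrame
    samples: list[SimulatedSample]
    background_normals: list[list[VariantRecord]]

    @property
    def truth_table(self) -> pd.DataFrame:
        frames = []
        for s in self.samples:
            t = s.truth.copy()
            t.insert(0, "sample_id", s.sample_id)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _panel_regions(cfg: SimConfig) -> TargetRegions:
    intervals = [
        (f"chr{i + 1}", 1_000_000, 1_000_000 + cfg.region_length)
        for i in range(cfg.n_regions)
    ]
    return TargetRegions.from_intervals(intervals)


def _draw_effects(rng: np.random.Generator, table, n: int) -> np.ndarray:
    effects = np.array([e for e, _ in table])
    probs = np.array([p for _, p in table])
    return rng.choice(effects, size=n, p=probs / probs.sum())


def _make_catalogue(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared germline SNP sites: position, population AF, alleles, effect."""
    regions = _panel_regions(cfg)
    rows = []
    for pop_af, n_sites in cfg.germline_spectrum:
        for _ in range(n_sites):
            ri = int(rng.integers(0, cfg.n_regions))
            chrom, start, end = regions.intervals[ri]
            pos = int(rng.integers(start + 1, end + 1))  # 1-based
            ref, alt = rng.choice(len(BASES), size=2, replace=False)
            rows.append((chrom, pos, BASES[ref], BASES[alt], pop_af, ri))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "pop_af", "region"])
    df = df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    df["effect"] = _draw_effects(rng, GERMLINE_EFFECTS, len(df))
    return df


def _passing_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    af: float,
    vd: int,
    dp_t: int,
    effect: str,
    paired: bool,
    dp_n: Optional[int] = None,
    status: Optional[str] = None,
    hotspot: str = ".",
) -> VariantRecord:
    """A record whose QC tags comfortably pass every filter clause."""
    ns = 2 if paired else 1
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        status=status if status is not None else ".",
        hotspot=hotspot,
        sor=0.0,
        vd=vd,
        af=round(af, 6),
        ssf=0.001,
        fpdb=".",
        germline_tag=".",
        msi=0.0,
        msilen=0.0,
        effect=effect,
        pmean=[35.0] * ns,
        mq=[60.0] * ns,
        qual=[35.0] * ns,
        nm=[1.0] * ns,
        dp=[dp_t, dp_n][:ns],
        bias=["2;2"] * ns,
        sbf=[1.0] * ns,
        vd_s=[vd, 0][:ns],
    )


def _germline_genotypes(
    catalogue: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg genotype (0/1/2 alt alleles) per catalogue site."""
    q = catalogue["pop_af"].to_numpy()
    u = rng.random(len(q))
    gt = np.zeros(len(q), dtype=int)
    gt[u < 2 * q * (1 - q) + q * q] = 1
    gt[u < q * q] = 2
    return gt


def _somatic_sites(
    cfg: SimConfig,
    rng: np.random.Generator,
    n: int,
    regions: TargetRegions,
    taken: set,
) -> pd.DataFrame:
    rows = []
    effects = _draw_effects(rng, SOMATIC_EFFECTS, n)
    for j in range(n):
        while True:
            ri = int(rng.integers(0, cfg.n_regions))
            chrom, start, end = regions.intervals[ri]
            pos = int(rng.integers(start + 1, end + 1))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                break
        effect = effects[j]
        if effect in ("frameshift_variant", "inframe_deletion"):
            dlen = 1 if effect == "frameshift_variant" else 3
            bases = rng.choice(len(BASES), size=dlen + 1)
            ref = "".join(BASES[b] for b in bases)
            alt = ref[0]
        else:
            r, a = rng.choice(len(BASES), size=2, replace=False)
            ref, alt = BASES[r], BASES[a]
        hotspot = "HS" if rng.random() < cfg.hotspot_fraction else "."
        rows.append((chrom, pos, ref, alt, ri, effect, hotspot))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "region", "effect", "hotspot"]
    )


def _sample_depth_reads(
    rng: np.random.Generator, mean_depth: float, true_af: np.ndarray, cn_ratio: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    dp = rng.poisson(mean_depth * cn_ratio).astype(int)
    dp = np.maximum(dp, 1)
    alt = rng.binomial(dp, np.clip(true_af, 0.0, 1.0))
    return dp, alt


def simulate_sample(
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str,
    catalogue: pd.DataFrame,
    regions: TargetRegions,
) -> SimulatedSample:
    footprint = regions.footprint_mb
    purity = float(rng.uniform(*cfg.purity_range))
    probs = np.array([p for p, _, _ in cfg.cn_profile])
    picks = rng.choice(len(cfg.cn_profile), size=cfg.n_regions, p=probs / probs.sum())
    region_cn = [(cfg.cn_profile[i][1], cfg.cn_profile[i][2]) for i in picks]
    ploidy = float(np.mean([c for c, _ in region_cn]))

    q = 1.0 - purity
    denom_ploidy = purity * ploidy + 2.0 * q

    # --- germline layer
    gt = _germline_genotypes(catalogue, rng)
    g = catalogue[gt > 0].copy().reset_index(drop=True)
    g_gt = gt[gt > 0]
    C = np.array([region_cn[r][0] for r in g["region"]])
    M = np.array([region_cn[r][1] for r in g["region"]])
    D = purity * C + 2.0 * q
    # heterozygous allele sits on the minor or the major parental copies
    on_minor = rng.random(len(g)) < 0.5
    m_het = np.where(on_minor, M, C - M)
    af_het = (purity * m_het + q) / D
    af_hom = (purity * C + 2.0 * q) / D  # == 1
    g_af = np.where(g_gt == 2, af_hom, af_het)
    g_m = np.where(g_gt == 2, C, m_het)

    # --- somatic layer (clonal, one mutated copy)
    rate = float(rng.uniform(*cfg.somatic_rate_range))
    n_som = int(rng.poisson(rate * footprint))
    taken = set(zip(catalogue["chrom"], catalogue["pos"]))
    som = _somatic_sites(cfg, rng, n_som, regions, taken)
    sC = np.array([region_cn[r][0] for r in som["region"]], dtype=int)
    sD = purity * sC + 2.0 * q
    s_af = np.where(sD > 0, purity * 1.0 / np.where(sD > 0, sD, 1.0), 0.0)

    # --- observed reads (tumor reads shared by both pipeline modes)
    cn_ratio_g = D / denom_ploidy
    cn_ratio_s = sD / denom_ploidy
    dp_g, alt_g = _sample_depth_reads(rng, cfg.mean_depth_tumor, g_af, cn_ratio_g)
    dp_s, alt_s = _sample_depth_reads(rng, cfg.mean_depth_tumor, s_af, cn_ratio_s)
    dpn_g = rng.poisson(cfg.mean_depth_normal, len(g)).astype(int)
    dpn_s = rng.poisson(cfg.mean_depth_normal, len(som)).astype(int)

    tumor_only: list[VariantRecord] = []
    paired: list[VariantRecord] = []
    truth_rows = []
    for i in range(len(g)):
        if alt_g[i] == 0:
            continue
        af_obs = alt_g[i] / dp_g[i]
        args = dict(
            chrom=g["chrom"][i], pos=int(g["pos"][i]), ref=g["ref"][i],
            alt=g["alt"][i], af=float(af_obs), vd=int(alt_g[i]),
            dp_t=int(dp_g[i]), effect=g["effect"][i],
        )
        tumor_only.append(_passing_record(paired=False, **args))
        paired.append(
            _passing_record(paired=True, dp_n=int(dpn_g[i]), status="Germline", **args)
        )
        truth_rows.append(
            (g["chrom"][i], int(g["pos"][i]), g["ref"][i], g["alt"][i], "germline",
             "hom" if g_gt[i] == 2 else "het", float(g_af[i]), int(C[i]),
             int(g_m[i]), g["effect"][i])
        )
    for i in range(len(som)):
        truth_rows.append(
            (som["chrom"][i], int(som["pos"][i]), som["ref"][i], som["alt"][i],
             "somatic", ".", float(s_af[i]), int(sC[i]), 1, som["effect"][i])
        )
        if alt_s[i] == 0:
            continue
        af_obs = alt_s[i] / dp_s[i]
        args = dict(
            chrom=som["chrom"][i], pos=int(som["pos"][i]), ref=som["ref"][i],
            alt=som["alt"][i], af=float(af_obs), vd=int(alt_s[i]),
            dp_t=int(dp_s[i]), effect=som["effect"][i], hotspot=som["hotspot"][i],
        )
        tumor_only.append(_passing_record(paired=False, **args))
        paired.append(
            _passing_record(
                paired=True, dp_n=int(dpn_s[i]), status="StrongSomatic", **args
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "origin", "genotype", "true_af",
                 "C", "M", "effect"],
    )
    nonsyn = truth["effect"].isin(
        {e for e, _ in SOMATIC_EFFECTS if e != "synonymous_variant"}
    )
    true_tmb = float(((truth["origin"] == "somatic") & nonsyn).sum() / footprint)

    # --- binned coverage log-ratios
    bin_rows = []
    for ri, (chrom, start, end) in enumerate(regions.intervals):
        c, _ = region_cn[ri]
        lr = expected_logratio(purity, c, ploidy) if purity * c + 2 * q > 0 else -5.0
        for b in range(start, end, cfg.bin_size):
            bin_rows.append((chrom, b, min(b + cfg.bin_size, end), lr))
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end", "logratio"])
    bins["logratio"] += rng.normal(0.0, cfg.logratio_noise_sd, len(bins))

    return SimulatedSample(
        sample_id=sample_id,
        purity=purity,
        ploidy=ploidy,
        region_cn=region_cn,
        tumor_only=tumor_only,
        paired=paired,
        coverage_bins=bins,
        truth=truth,
        true_tmb=true_tmb,
    )


def simulate_normal(
    cfg: SimConfig, rng: np.random.Generator, catalogue: pd.DataFrame
) -> list[VariantRecord]:
    """One background normal sample: germline catalogue sites only."""
    gt = _germline_genotypes(catalogue, rng)
    g = catalogue[gt > 0].reset_index(drop=True)
    g_gt = gt[gt > 0]
    true_af = np.where(g_gt == 2, 1.0, 0.5)
    dp = np.maximum(rng.poisson(cfg.mean_depth_normal, len(g)), 1)
    alt = rng.binomial(dp, true_af)
    records = []
    for i in range(len(g)):
        if alt[i] == 0:
            continue
        records.append(
            _passing_record(
                chrom=g["chrom"][i], pos=int(g["pos"][i]), ref=g["ref"][i],
                alt=g["alt"][i], af=float(alt[i] / dp[i]), vd=int(alt[i]),
                dp_t=int(dp[i]), effect=g["effect"][i], paired=False,
            )
        )
    return records


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate the full study: tumors (paired + tumor-only views), background
    normals, coverage profiles and per-variant truth; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    regions = _panel_regions(cfg)
    catalogue = _make_catalogue(cfg, rng)
    samples = [
        simulate_sample(cfg, rng, f"S{i + 1:03d}", catalogue, regions)
        for i in range(cfg.n_samples)
    ]
    normals = [
        simulate_normal(cfg, rng, catalogue) for _ in range(cfg.n_background_normals)
    ]
    return SimulatedCohort(
        config=cfg, regions=regions, catalogue=catalogue, samples=samples,
        background_normals=normals,
    )


def simulate_clinical(
    tmb_values: Sequence[float],
    model: Optional[ClinicalModel] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical outcome layer: DCB via a logistic model on TMB, exponential
    survival with a hazard ratio between TMB groups, independent censoring."""
    m = model or ClinicalModel()
    rng = np.random.default_rng(seed)
    tmb = np.asarray(tmb_values, dtype=float)
    n = len(tmb)
    p_dcb = expit(m.dcb_slope * (tmb - m.dcb_center))
    dcb = rng.random(n) < p_dcb

    responses, durations = [], []
    for d in dcb:
        if d:
            if rng.random() < 0.3:
                responses.append("SD")
                durations.append(float(rng.uniform(24, 60)))
            else:
                responses.append(rng.choice(["CR", "PR"], p=[0.15, 0.85]))
                durations.append(np.nan)
        else:
            if rng.random() < 0.3:
                responses.append("SD")
                durations.append(float(rng.uniform(4, 23.9)))
            else:
                responses.append("PD")
                durations.append(np.nan)

    high = tmb >= m.dcb_center
    os_hazard = np.where(high, m.os_base_hazard, m.os_base_hazard * m.os_hazard_ratio)
    os_true = rng.exponential(1.0 / os_hazard)
    pfs_true = rng.exponential(1.0 / (os_hazard * m.pfs_hazard_multiplier))
    cens_os = rng.exponential(1.0 / m.censor_rate, n)
    cens_pfs = rng.exponential(1.0 / m.censor_rate, n)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "tmb": np.round(tmb, 4),
            "response": responses,
            "sd_duration_weeks": np.round(durations, 1),
            "os_months": np.round(np.minimum(os_true, cens_os), 3),
            "os_event": (os_true <= cens_os).astype(int),
            "pfs_months": np.round(np.minimum(pfs_true, cens_pfs), 3),
            "pfs_event": (pfs_true <= cens_pfs).astype(int),
            "age": rng.integers(35, 85, n),
            "gender": rng.choice(["M", "F"], n, p=[0.6, 0.4]),
            "drug": rng.choice(["anti-PD-1", "anti-PD-L1"], n, p=[0.7, 0.3]),
            "cancer_type": rng.choice(["LUAD", "LUSC", "other"], n, p=[0.55, 0.3, 0.15]),
        }
    )


# ---------------------------------------------------------------------------
# artifact injection: records built to trip exactly one filter clause


ARTIFACT_SPECS: dict[str, dict] = {
        "allele_len_gt_50": {"ref": "A" * 60, "alt": "A"},
        "status_not_somatic": {"status": "Germline"},
        "hotspot_sor_lt_3": {"hotspot": "HS", "sor": 2.0},
        "hotspot_vd_lt_5": {"hotspot": "HS", "vd": 4, "vd_s": [4]},
        "hotspot_af_lt_0.007": {"hotspot": "HS", "af": 0.006},
        "hotspot_ssf_gt_0.05": {"hotspot": "HS", "ssf": 0.06},
        "fpdb_tagged": {"fpdb": "3"},
        "germline_tagged": {"germline_tag": "rs123"},
        "germline_tag_set": {"germline_tag": "0"},
        "pmean_lt_20": {"pmean": [15.0]},
        "sor_af_ssf": {"ssf": 0.02},
        "lowaf_mq_lt_50": {"af": 0.04, "mq": [45.0]},
        "mq_lt_30": {"mq": [25.0]},
        "lowaf_qual_lt_30": {"af": 0.04, "qual": [25.0]},
        "msi_lowaf": {"msi": 12.0, "af": 0.25},
        "indel_msi_lowaf": {"ref": "AT", "alt": "A", "msi": 4.0, "msilen": 1.0, "af": 0.08},
        "nm_gt_2_mq_lowaf": {"nm": [3.0], "mq": [59.0], "af": 0.15},
        "nm_gt_3": {"nm": [4.0], "mq": [54.0]},
        "dp_lt_30": {"dp": [25]},
        "vd_lt_10": {"vd": 9, "vd_s": [9]},
        "strand_bias_codes": {"bias": ["2;1"]},
        "sbf_lowvd": {"sbf": [0.01], "vd_s": [40]},
        "sor_lt_10_mq_lt_60": {"sor": 9.0, "mq": [59.0]},
}

ARTIFACT_CLAUSES = tuple(ARTIFACT_SPECS)


def inject_artifacts(
    records: Sequence[VariantRecord], artifact_spec: Sequence[str], start_pos: int = 1
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Append, per named clause, one record failing that clause (and only it).

    Returns (records + injected, injected).  Unknown clause names raise.
    """
    unknown = [c for c in artifact_spec if c not in ARTIFACT_SPECS]
    if unknown:
        raise ValueError(f"unknown artifact clause(s): {unknown}")
    injected: list[VariantRecord] = []
    pos = start_pos
    for name in artifact_spec:
        changes = dict(ARTIFACT_SPECS[name])
        rec = _passing_record(
            chrom="chr1", pos=pos, ref=changes.pop("ref", "A"),
            alt=changes.pop("alt", "T"), af=0.3, vd=60, dp_t=200,
            effect="missense_variant", paired=False,
        )
        for attr, value in changes.items():
            setattr(rec, attr, value)
        injected.append(rec)
        pos += 10
    return list(records) + injected, injected


# ---------------------------------------------------------------------------
# on-disk emission


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Emit VCFs, BED, coverage TSVs, truth and clinical tables to a directory."""
    out = Path(outdir)
    (out / "tumor_only").mkdir(parents=True, exist_ok=True)
    (out / "paired").mkdir(exist_ok=True)
    (out / "normals").mkdir(exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    write_bed(cohort.regions, out / "panel.bed")
    for s in cohort.samples:
        write_variants(s.tumor_only, out / "tumor_only" / f"{s.sample_id}.vcf")
        write_variants(s.paired, out / "paired" / f"{s.sample_id}.vcf", mode="paired")
        s.coverage_bins.to_csv(
            out / "coverage" / f"{s.sample_id}.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
    for i, records in enumerate(cohort.background_normals):
        write_variants(records, out / "normals" / f"N{i + 1:03d}.vcf")
    cohort.truth_table.to_csv(
        out / "truth.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort.samples],
            "purity": [round(s.purity, 4) for s in cohort.samples],
            "ploidy": [round(s.ploidy, 4) for s in cohort.samples],
            "true_tmb": [round(s.true_tmb, 4) for s in cohort.samples],
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
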