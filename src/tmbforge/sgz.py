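"""Somatic-germline-zygosity (SGZ) model for tumor-only variant calls.

The copy-number model: a specimen with tumor purity ``P`` and tumor ploidy
``Psi`` containing a segment at integer total copy number ``C`` produces an
expected coverage log-ratio

    log2( (P*C + 2*(1-P)) / (P*Psi + 2*(1-P)) )

relative to a normal diploid genome.  A germline allele present on ``m`` of
the ``C`` tumor copies has expected allele fraction ``(P*m + (1-P)) / D``
(heterozygous) or ``(P*m + 2*(1-P)) / D`` (homozygous), and a clonal somatic
allele on ``k`` copies has ``k*P / D``, where ``D = P*C + 2*(1-P)``.

Fitting proceeds in three steps: the binned coverage profile is segmented
(least-squares binary changepoint search with a penalized stopping rule),
then purity and ploidy are estimated by an exhaustive grid search in which
every candidate ``(P, Psi)`` assigns each segment the integer ``(C, M)``
minimizing the squared mismatch between expected and observed log-ratio and
between expected and observed heterozygous-SNP allele fractions, and finally
each variant is classified somatic / germline / ambiguous by comparing its
observed allele fraction with the nearest member of each expectation family,
gated on the "error log ratio" (the absolute difference between the
variant-level and segment-level log-ratio, a model-fit diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .variantio import VariantKey, VariantRecord

NEG_INF = float("-inf")


@dataclass
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    observed_logratio: float
    n_bins: int = 1
    C: Optional[int] = None
    M: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TumorModel:
    purity: float
    ploidy: float
    segments: list[Segment]
    fit_score: float = 0.0
    identifiable: bool = True


@dataclass
class SGZCall:
    key: VariantKey
    label: str  # somatic | germline | ambiguous
    error_logratio: float
    expected_af_germline: float
    expected_af_somatic: float
    observed_af: float


@dataclass
class SGZConfig:
    """Tunable knobs of the fit and the classifier."""

    purity_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    )
    ploidy_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.0, 6.0 + 1e-9, 0.05), 2)
    )
    max_copy_number: int = 8
    af_weight: float = 1.0  # weight of the het-SNP AF term vs the log-ratio term
    tau_af: float = 0.1  # max distance of observed AF to the nearest family
    tau_lr: float = 0.5  # max tolerated error log ratio
    germline_margin_z: float = 2.0  # somatic must beat germline by z binomial SDs
    high_af_germline: float = 0.9  # observed AF above this is called germline
    default_purity: float = 0.5  # reported when the fit is unidentifiable
    flat_lr_eps: float = 0.1  # |log-ratio| below this carries no CN signal
    flat_af_eps: float = 0.05  # mean |AF - 0.5| below this carries no signal


class SegmentAssignmentError(ValueError):
    pass


def expected_logratio(purity: float, copy_number: float, ploidy: float) -> float:
    """Expected coverage log2-ratio of a segment at copy number C.

    Returns ``-inf`` for the degenerate pure-tumor homozygous deletion
    (P = 1, C = 0) where no reads originate from the segment.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be > 0, got {ploidy}")
    if copy_number < 0:
        raise ValueError(f"copy number must be >= 0, got {copy_number}")
    num = purity * copy_number + 2.0 * (1.0 - purity)
    den = purity * ploidy + 2.0 * (1.0 - purity)
    if num == 0.0:
        return NEG_INF
    return math.log2(num / den)


def expected_af_germline_het(purity: float, m: int, C: int) -> float:
    """Expected AF of a heterozygous germline allele on m of C tumor copies."""
    D = purity * C + 2.0 * (1.0 - purity)
    return (purity * m + (1.0 - purity)) / D if D > 0 else float("nan")


def expected_af_germline_hom(purity: float, m: int, C: int) -> float:
    D = purity * C + 2.0 * (1.0 - purity)
    return (purity * m + 2.0 * (1.0 - purity)) / D if D > 0 else float("nan")


def expected_af_somatic(purity: float, k: int, C: int) -> float:
    """Expected AF of a clonal somatic allele on k of C tumor copies."""
    D = purity * C + 2.0 * (1.0 - purity)
    return purity * k / D if D > 0 else float("nan")


def variant_logratio(depth: float, baseline_depth: float) -> float:
    """Variant-level log-ratio: local depth normalized like coverage bins."""
    if depth <= 0 or baseline_depth <= 0:
        raise ValueError("depths must be positive")
    return math.log2(depth / baseline_depth)


# ---------------------------------------------------------------------------
# segmentation


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of a series by least squares.

    Returns (index, gain) where index i splits into x[:i] | x[i:] and gain is
    the RSS reduction relative to no split.
    """
    n = len(x)
    if n < 2:
        return 0, 0.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_rss = csq[-1] - csum[-1] ** 2 / n
    i = np.arange(1, n)
    left = csq[i - 1] - csum[i - 1] ** 2 / i
    rsum = csum[-1] - csum[i - 1]
    rsq = csq[-1] - csq[i - 1]
    right = rsq - rsum**2 / (n - i)
    rss = left + right
    j = int(np.argmin(rss))
    return j + 1, float(total_rss - rss[j])


def _segment_series(x: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    """Greedy binary segmentation; returns sorted changepoint indices."""
    boundaries = [0, len(x)]
    changed = True
    while changed:
        changed = False
        best = (0.0, None, None)
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a < 2 * min_size:
                continue
            j, gain = _best_split(x[a:b])
            if min_size <= j <= (b - a) - min_size and gain > best[0]:
                best = (gain, a + j, None)
        if best[1] is not None and best[0] > penalty:
            boundaries.append(best[1])
            boundaries.sort()
            changed = True
    return boundaries


def segment_coverage(bins: pd.DataFrame | Sequence[tuple]) -> list[Segment]:
    """Segment a binned coverage log-ratio profile into constant pieces.

    ``bins`` has columns (chrom, start, end, logratio) with 0-based
    half-open bin coordinates, sorted within each chromosome.
    """
    if not isinstance(bins, pd.DataFrame):
        bins = pd.DataFrame(bins, columns=["chrom", "start", "end", "logratio"])
    if len(bins) == 0:
        raise ValueError("no coverage bins")
    segments: list[Segment] = []
    all_lr = bins["logratio"].to_numpy(dtype=float)
    # noise scale from first differences, robust to true level shifts
    if len(all_lr) >= 8:
        sigma = float(np.median(np.abs(np.diff(all_lr)))) / (math.sqrt(2) * 0.6745)
    else:
        sigma = float(np.std(all_lr))
    sigma = max(sigma, 1e-4)
    penalty = 3.0 * sigma**2 * math.log(max(len(all_lr), 2))
    for chrom in bins["chrom"].unique():
        sub = bins[bins["chrom"] == chrom]
        x = sub["logratio"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bounds = _segment_series(x, penalty)
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[a]) + 1,
                    end=int(ends[b - 1]),
                    observed_logratio=float(np.mean(x[a:b])),
                    n_bins=b - a,
                )
            )
    return segments


def find_segment(segments: Sequence[Segment], chrom: str, pos: int) -> Segment:
    for seg in segments:
        if seg.chrom == chrom and seg.start <= pos <= seg.end:
            return seg
    raise SegmentAssignmentError(f"{chrom}:{pos} falls outside all segments")


# ---------------------------------------------------------------------------
# purity / ploidy fit


def _af_term(
    het_afs: np.ndarray, P: np.ndarray, C: int
) -> tuple[np.ndarray, np.ndarray]:
    """Min over M of the mean squared AF mismatch; returns (term, argmin M).

    ``P`` is the purity grid; result shapes are (len(P),).
    """
    nP = len(P)
    if het_afs.size == 0:
        return np.zeros(nP), np.zeros(nP, dtype=int)
    q = 1.0 - P
    D = np.maximum(P * C + 2.0 * q, 1e-12)
    best = np.full(nP, np.inf)
    bestM = np.zeros(nP, dtype=int)
    for M in range(C // 2 + 1):
        e1 = (P * M + q) / D  # allele on the minor copies
        e2 = (P * (C - M) + q) / D  # allele on the major copies
        d = np.minimum(
            np.abs(het_afs[None, :] - e1[:, None]),
            np.abs(het_afs[None, :] - e2[:, None]),
        )
        term = np.mean(d**2, axis=1)
        upd = term < best
        best[upd] = term[upd]
        bestM[upd] = M
    return best, bestM


def fit_purity_ploidy(
    segments: Sequence[Segment],
    het_afs: Optional[Sequence[np.ndarray]] = None,
    config: Optional[SGZConfig] = None,
    fixed_purity: Optional[float] = None,
) -> TumorModel:
    """Estimate (purity, ploidy) and per-segment (C, M) by grid search.

    ``het_afs`` supplies, per segment, the observed allele fractions of
    candidate heterozygous germline SNPs; they resolve the degeneracy of the
    log-ratio term (any purity fits a flat diploid genome).  Ties in the
    integer (C, M) assignment break toward the lowest C (parsimony).
    """
    cfg = config or SGZConfig()
    segments = list(segments)
    if not segments:
        raise ValueError("no segments")
    if het_afs is None:
        het_afs = [np.empty(0)] * len(segments)
    het_afs = [np.asarray(a, dtype=float) for a in het_afs]
    if len(het_afs) != len(segments):
        raise ValueError("het_afs must align with segments")

    lr_obs = np.array([s.observed_logratio for s in segments])
    weights = np.array([max(s.n_bins, 1) for s in segments], dtype=float)
    weights /= weights.sum()

    informative = bool(np.any(np.abs(lr_obs) > cfg.flat_lr_eps)) or any(
        a.size > 0 and np.mean(np.abs(a - 0.5)) > cfg.flat_af_eps for a in het_afs
    )
    if not informative and fixed_purity is None:
        p0 = cfg.default_purity
        for s in segments:
            s.C, s.M = 2, 1
        return TumorModel(
            purity=p0, ploidy=2.0, segments=segments, fit_score=float("inf"),
            identifiable=False,
        )

    P = (
        np.array([float(fixed_purity)])
        if fixed_purity is not None
        else np.asarray(cfg.purity_grid, dtype=float)
    )
    Psi = np.asarray(cfg.ploidy_grid, dtype=float)
    Cs = np.arange(0, cfg.max_copy_number + 1)
    q = 1.0 - P
    numer = P[:, None] * Cs[None, :] + 2.0 * q[:, None]  # (nP, nC)
    denom = P[:, None] * Psi[None, :] + 2.0 * q[:, None]  # (nP, nPsi)
    with np.errstate(divide="ignore"):
        x = np.log2(np.maximum(numer, 1e-12))
        y = np.log2(denom)
    lr_exp = x[:, None, :] - y[:, :, None]  # (nP, nPsi, nC)

    afterm = np.stack(
        [np.stack([_af_term(a, P, int(C))[0] for C in Cs], axis=1) for a in het_afs],
        axis=0,
    )  # (nseg, nP, nC)

    # mild prior against whole-segment homozygous deletions: C = 0 over a
    # full segment is implausible at panel scale and otherwise aliases a
    # halved-purity solution exactly on noiseless data
    c0_penalty = np.zeros(len(Cs))
    c0_penalty[0] = 1e-3
    obj = np.zeros((len(P), len(Psi)))
    for si in range(len(segments)):
        term = (
            (lr_exp - lr_obs[si]) ** 2
            + cfg.af_weight * afterm[si][:, None, :]
            + c0_penalty[None, None, :]
        )
        obj += weights[si] * term.min(axis=2)

    # Doubling (P', 2*Psi, 2C) reproduces the same log-ratios and allele
    # fractions, so near-equal optima recur at multiples of the true ploidy;
    # among candidates within quantization noise of the minimum, take the
    # lowest-ploidy cluster (parsimony), then its best point.
    obj_min = float(obj.min())
    cand = np.argwhere(obj <= 3.0 * obj_min + 1e-6)
    psi_low = float(Psi[cand[:, 1]].min())
    cluster = cand[Psi[cand[:, 1]] <= psi_low + 0.25]
    pi, yi = min(cluster, key=lambda ij: (obj[ij[0], ij[1]], -P[ij[0]]))
    purity, ploidy = float(P[pi]), float(Psi[yi])
    score = float(obj[pi, yi])

    # final integer (C, M) per segment at the winning (purity, ploidy)
    Pv = np.array([purity])
    for si, seg in enumerate(segments):
        best = (np.inf, 0, 0)
        for C in Cs:
            lrterm = (
                expected_logratio(purity, int(C), ploidy) - lr_obs[si]
            ) ** 2 if purity * C + 2 * (1 - purity) > 0 else np.inf
            aft, bm = _af_term(het_afs[si], Pv, int(C))
            total = lrterm + cfg.af_weight * float(aft[0]) + (1e-3 if C == 0 else 0.0)
            if total < best[0] - 1e-12:  # strict: ties keep the lower C
                best = (total, int(C), int(bm[0]))
        seg.C, seg.M = best[1], best[2]
    return TumorModel(
        purity=purity, ploidy=ploidy, segments=segments, fit_score=score,
        identifiable=True,
    )


# ---------------------------------------------------------------------------
# classification


def error_logratio(var_lr: float, seg: Segment) -> float:
    """Absolute difference between variant-level and segment log-ratio."""
    return abs(var_lr - seg.observed_logratio)


def classify_variant(
    v: VariantRecord,
    seg: Segment,
    model: TumorModel,
    config: Optional[SGZConfig] = None,
    var_lr: Optional[float] = None,
    seen_in_background: Optional[bool] = None,
) -> SGZCall:
    """Label one filtered variant somatic / germline / ambiguous.

    The observed allele fraction is compared against the germline family
    (heterozygous expectations for the allele on the minor or major copies,
    plus the homozygous expectation) and the somatic family (clonal allele on
    k = 1..C copies); the nearest family within ``tau_af`` wins, with exact
    ties going to germline.  When the nearest somatic expectation puts the
    allele on two or more copies (mutation plus amplification, an a-priori
    rare event) it must additionally beat germline by ``germline_margin_z``
    binomial standard deviations of the observed allele fraction.  A variant
    whose error log ratio exceeds ``tau_lr`` is ambiguous regardless of
    allele fraction, and an observed allele fraction above
    ``high_af_germline`` is called germline outright.

    At certain parameter configurations the two families genuinely collide
    (e.g. near purity 0.5 on a one-copy segment the clonal somatic
    expectation P/(2-P) equals the lost-copy heterozygous germline
    expectation (1-P)/(2-P)); there the allele fraction carries no
    information and the optional ``seen_in_background`` flag arbitrates:
    somatic mutations are private to a tumor, so presence of the key
    anywhere in a population background library tips the collision to
    germline and verified absence tips it to somatic.
    """
    cfg = config or SGZConfig()
    if not (seg.chrom == v.chrom and seg.start <= v.pos <= seg.end):
        raise SegmentAssignmentError(f"variant {v.chrom}:{v.pos} not in segment")
    P = model.purity
    C = seg.C if seg.C is not None else 2
    M = seg.M if seg.M is not None else (1 if C >= 2 else 0)
    err_lr = 0.0 if var_lr is None else error_logratio(var_lr, seg)
    af = v.af if v.af is not None else 0.0

    D = P * C + 2.0 * (1.0 - P)
    if D <= 0:
        return SGZCall(v.key, "ambiguous", err_lr, float("nan"), float("nan"), af)
    germ = [expected_af_germline_het(P, m, C) for m in {M, C - M}]
    germ.append(expected_af_germline_hom(P, C, C))  # homozygous -> AF 1
    soma = [(expected_af_somatic(P, k, C), k) for k in range(1, max(C, 1) + 1)]
    eg = min(germ, key=lambda e: abs(af - e))
    es, ks = min(soma, key=lambda ek: abs(af - ek[0]))

    if err_lr > cfg.tau_lr:
        label = "ambiguous"
    elif af > cfg.high_af_germline:
        label = "germline"
    else:
        dg, ds = abs(af - eg), abs(af - es)
        dp0 = v.dp[0] if v.dp and v.dp[0] else None
        sd_af = math.sqrt(max(af * (1.0 - af), 1e-6) / dp0) if dp0 else 0.0
        # A somatic allele on k >= 2 copies (mutation plus amplification) is a
        # priori rare, so such an expectation must beat germline by a margin
        # of z binomial SDs; the default clonal k = 1 case competes head-on.
        margin = cfg.germline_margin_z * sd_af if ks >= 2 else 0.0
        if min(dg, ds) > cfg.tau_af:
            label = "ambiguous"
        elif abs(eg - es) <= sd_af and seen_in_background is not None:
            # family collision: AF is uninformative, the library arbitrates
            label = "germline" if seen_in_background else "somatic"
        elif ds < dg - margin:
            label = "somatic"
        else:
            label = "germline"
    return SGZCall(v.key, label, err_lr, eg, es, af)


def estimate_baseline_depth(
    records: Sequence[VariantRecord], segments: Sequence[Segment]
) -> float:
    """Median depth after dividing out each variant's segment copy-ratio.

    This is the depth a diploid-equivalent locus would have, the
    normalization constant used to put variant depths on the same log-ratio
    scale as the coverage bins.
    """
    ratios = []
    for r in records:
        dp = r.dp[0]
        if dp is None or dp <= 0:
            continue
        try:
            seg = find_segment(segments, r.chrom, r.pos)
        except SegmentAssignmentError:
            continue
        ratios.append(dp / 2.0**seg.observed_logratio)
    if not ratios:
        raise ValueError("no usable depths to estimate baseline")
    return float(np.median(ratios))


def collect_het_afs(
    records: Iterable[VariantRecord],
    segments: Sequence[Segment],
    recurrent_keys: Optional[set] = None,
    af_range: tuple[float, float] = (0.1, 0.9),
) -> list[np.ndarray]:
    """Gather candidate heterozygous-germline allele fractions per segment.

    When ``recurrent_keys`` (e.g. background-library sites seen in many
    normals) is given, only those variants are used — recurrent germline SNPs
    are the cleanest purity probes; otherwise every record in ``af_range``
    is taken as a candidate.
    """
    per_seg: list[list[float]] = [[] for _ in segments]
    index = {id(s): i for i, s in enumerate(segments)}
    for r in records:
        if r.af is None or not (af_range[0] <= r.af <= af_range[1]):
            continue
        if recurrent_keys is not None and r.key not in recurrent_keys:
            continue
        try:
            seg = find_segment(segments, r.chrom, r.pos)
        except SegmentAssignmentError:
            continue
        per_seg[index[id(seg)]].append(r.af)
    return [np.asarray(a) for a in per_seg]


def write_calls(calls: Sequence[SGZCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tlabel\terror_logratio\t"
            "expected_af_germline\texpected_af_somatic\tobserved_af\n"
        )
        for c in calls:
            fh.write(
                f"{c.key.chrom}\t{c.key.pos}\t{c.key.ref}\t{c.key.alt}\t{c.label}\t"
                f"{c.error_logratio:.6g}\t{c.expected_af_germline:.6g}\t"
                f"{c.expected_af_somatic:.6g}\t{c.observed_af:.6g}\n"
            )
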