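import numpy as np
import pytest

from tmbforge.background import build_library_from_records
from tmbforge.simdata import SimConfig, _passing_record, simulate_cohort
from tmbforge.variantio import VariantRecord


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated study: 5 tumors, 100 background normals."""
    cfg = SimConfig(seed=11, n_samples=5, n_background_normals=100)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_library(small_cohort):
    return build_library_from_records(small_cohort.background_normals)


@pytest.fixture
def make_record():
    """Factory for records whose QC tags pass every filter clause."""

    def _make(chrom="chr1", pos=100, ref="A", alt="T", af=0.3, vd=60, dp_t=200,
              effect="missense_variant", paired=False, **overrides):
        rec = _passing_record(
            chrom=chrom, pos=pos, ref=ref, alt=alt, af=af, vd=vd, dp_t=dp_t,
            effect=effect, paired=paired, dp_n=200 if paired else None,
            status="StrongSomatic" if paired else None,
        )
        for attr, value in overrides.items():
            setattr(rec, attr, value)
        return rec

    return _make


def random_filter_records(n, seed, mode="tumor_only"):
    """Records with tag values scattered across every filter threshold."""
    rng = np.random.default_rng(seed)
    ns = 2 if mode == "paired" else 1

    def num(choices, p_missing=0.1):
        return None if rng.random() < p_missing else float(rng.choice(choices))

    records = []
    for i in range(n):
        is_indel = rng.random() < 0.3
        ref_len = int(rng.choice([1, 2, 4, 49, 50, 51, 60], p=[0.5, 0.15, 0.15, 0.05, 0.05, 0.05, 0.05]))
        alt_len = 1 if not is_indel else int(rng.choice([1, 2, 3, 52]))
        if not is_indel:
            alt_len = ref_len
        records.append(
            VariantRecord(
                chrom="chr1",
                pos=int(rng.integers(1, 10_000)),
                ref="A" * ref_len,
                alt="C" * alt_len,
                status=str(rng.choice([".", "Somatic", "StrongSomatic", "LikelySomatic", "Germline", "LOH"])),
                hotspot=str(rng.choice([".", "HS1"], p=[0.7, 0.3])),
                sor=num([0.0, 1.0, 2.9, 3.0, 4.9, 5.0, 9.9, 10.0, 12.0]),
                vd=None if rng.random() < 0.1 else int(rng.choice([0, 4, 5, 9, 10, 49, 50, 80])),
                af=num([0.001, 0.006, 0.007, 0.019, 0.02, 0.04, 0.05, 0.09, 0.1, 0.19, 0.29, 0.3, 0.5, 0.91, 1.0], p_missing=0.05),
                ssf=num([0.001, 0.009, 0.011, 0.049, 0.051, 0.2]),
                fpdb=str(rng.choice([".", "0", "3"])),
                germline_tag=str(rng.choice([".", "0", "rs12"])),
                msi=num([0.0, 3.0, 4.0, 5.0, 10.0, 11.0]),
                msilen=num([0.0, 1.0, 2.0, 3.0]),
                effect="missense_variant",
                pmean=[num([10.0, 19.9, 20.0, 35.0]) for _ in range(ns)],
                mq=[num([25.0, 29.9, 30.0, 49.0, 54.0, 55.0, 59.0, 60.0, 70.0]) for _ in range(ns)],
                qual=[num([25.0, 29.0, 30.0, 40.0]) for _ in range(ns)],
                nm=[num([0.0, 2.0, 3.0, 4.0, 6.0]) for _ in range(ns)],
                dp=[None if rng.random() < 0.1 else int(rng.choice([10, 29, 30, 100, 400])) for _ in range(ns)],
                bias=[str(rng.choice([".", "2;2", "2;1", "1;2", "0;0", "2", ""])) for _ in range(ns)],
                sbf=[num([0.01, 0.049, 0.05, 0.5, 1.0]) for _ in range(ns)],
                vd_s=[None if rng.random() < 0.1 else int(rng.choice([5, 40, 49, 50, 100])) for _ in range(ns)],
            )
        )
    return records
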