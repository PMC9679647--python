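"""Independent brute-force re-evaluation of the four exclusion expressions.

Deliberately written as literal one-shot boolean transcriptions (missing
numerics become NaN, so any comparison against them is False), sharing no
code with the production filter engine; used as the oracle in equivalence
tests.
"""

import math


def _n(x):
    return math.nan if x is None else float(x)


def naive_verdict(v, mode):
    """Return dict of filter-name -> fired for one record."""
    ref, alt = v.ref, v.alt
    af, sor, ssf, vd = _n(v.af), _n(v.sor), _n(v.ssf), _n(v.vd)
    msi, msilen = _n(v.msi), _n(v.msilen)
    pm0, mq0 = _n(v.pmean[0]), _n(v.mq[0])
    q0, nm0 = _n(v.qual[0]), _n(v.nm[0])
    dp0, sbf0, vds0 = _n(v.dp[0]), _n(v.sbf[0]), _n(v.vd_s[0])
    paired = mode == "paired" and v.n_samples > 1
    dp1 = _n(v.dp[1]) if paired else math.nan
    nm1 = _n(v.nm[1]) if paired else math.nan
    bias_parts = (v.bias[0] or ".").split(";")
    b_fwd = bias_parts[0] if bias_parts and bias_parts[0] else "."
    b_rev = bias_parts[1] if len(bias_parts) > 1 and bias_parts[1] else "."
    is_snp = len(ref) == len(alt)

    basic = (len(ref) > 50 or len(alt) > 50) or (
        v.status != "." and "Somatic" not in v.status
    )
    hotspot = v.hotspot != "." and (
        (sor != 0 and sor < 3) or vd < 5 or af < 0.007 or ssf > 0.05
    )
    fpdb = v.hotspot == "." and (
        (v.fpdb != "0" and v.fpdb != ".") or (v.germline_tag != "0" and v.germline_tag != ".")
    )
    normal = v.hotspot == "." and (
        v.germline_tag != "."
        or pm0 < 20
        or ((sor != 0 and sor < 5) or af < 0.02 or ssf > 0.01)
        or (af < 0.05 and mq0 < 50)
        or mq0 < 30
        or (af < 0.05 and q0 < 30)
        or ((msi > 10 or (msilen > 1 and msi > 4)) and af < 0.3)
        or (
            not is_snp
            and msi > 3
            and (msilen == len(ref) - 1 or msilen == len(alt) - 1)
            and af < 0.1
        )
        or (nm0 > 2 and mq0 < 60 and af < 0.2)
        or (nm0 > 3 and (mq0 < 55 or nm1 > 3))
        or (dp0 < 30 or dp1 < 30)
        or vd < 10
        or (b_fwd == "2" and b_rev == "1")
        or (sbf0 < 0.05 and vds0 < 50)
        or ((sor != 0 and sor < 10) and mq0 < 60)
    )
    return {
        "basicfilter": bool(basic),
        "hotspotfilter": bool(hotspot),
        "fpdbfilter": bool(fpdb),
        "normalfilter": bool(normal),
    }


def naive_excluded(v, mode):
    return any(naive_verdict(v, mode).values())
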