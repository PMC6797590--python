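"""Handcrafted ten-variant filter-cascade fixture with known fates.

Each primary-caller call is designed to be removed by exactly one cascade
stage (or to survive); the full table with the per-stage removal trace is
documented in docs/filter_fixture.md.  The fixture is constructed
programmatically so the reference context, region tracts and calls stay
consistent by definition.
"""

from __future__ import annotations

import numpy as np

from offtarget_burden.denovo_filter import FilterConfig, FilterResources
from offtarget_burden.vario import (
    Cohort,
    GenomicInterval,
    IntervalSet,
    Sample,
    VariantCall,
    VariantKey,
)

CHROM = "chr1"
REF_LEN = 1000

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def build_reference() -> dict[str, str]:
    """A deterministic 1 kb chromosome with a planted A-homopolymer at
    positions 700-704 (context for the repeat-context indel)."""
    rng = np.random.default_rng(20190949)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = list(bases[rng.integers(0, 4, size=REF_LEN)].tobytes().decode())
    seq[699:706] = list("CAAAAAG")
    return {CHROM: "".join(seq)}


def _snv(seq: str, pos: int) -> VariantKey:
    ref = seq[pos]
    return VariantKey(CHROM, pos, ref, _TRANSITION[ref])


def _call(key: VariantKey, sample_id: str, caller_id: str,
          af: float = 0.5, depth: int = 50) -> VariantCall:
    alt = int(round(af * depth))
    fwd = alt // 2
    return VariantCall(key=key, sample_id=sample_id, caller_id=caller_id,
                       depth=depth, alt_depth=alt, af=alt / depth,
                       alt_fwd=fwd, alt_rev=alt - fwd)


def build_fixture():
    """Returns (calls_by_caller, resources, config, cohort, expected).

    ``expected`` holds the designed per-stage trace and the two survivors.
    """
    reference = build_reference()
    seq = reference[CHROM]

    v1 = _snv(seq, 100)   # s1: supported in a parent       -> parental stage
    v2 = _snv(seq, 120)   # s1: known population allele     -> dbSNP stage
    v3 = _snv(seq, 210)   # s1: inside on-target +-50 flank -> on-target stage
    v4 = _snv(seq, 420)   # s1: inside repeat tract         -> region stage
    # s1: deletion of one A inside the AAAAA homopolymer -> repeat-context
    v6 = VariantKey(CHROM, 700, seq[700:702], seq[700])
    assert seq[700:702] == "AA"
    v7 = _snv(seq, 800)   # s1+s2: same key in two samples  -> cross-noise
    v9 = _snv(seq, 840)   # s2: AF 0.2                      -> AF threshold
    v10a = _snv(seq, 900)  # s1: survivor (confirmed by 2nd caller)
    v10b = _snv(seq, 950)  # s2: survivor (confirmed by 2nd caller)

    A, B = "germline", "somatic"
    calls_by_caller = {
        A: {
            "s1": [
                _call(v1, "s1", A), _call(v2, "s1", A), _call(v3, "s1", A),
                _call(v4, "s1", A), _call(v6, "s1", A), _call(v7, "s1", A),
                _call(v10a, "s1", A),
            ],
            "s2": [
                _call(v7, "s2", A), _call(v9, "s2", A, af=0.2),
                _call(v10b, "s2", A),
            ],
        },
        B: {
            "s1": [_call(v10a, "s1", B)],
            "s2": [_call(v10b, "s2", B)],
        },
    }

    resources = FilterResources(
        parental_keys={v1},
        known_keys={v2},
        on_target=IntervalSet([GenomicInterval(CHROM, 200, 223)]),
        repeats=IntervalSet([GenomicInterval(CHROM, 400, 450)]),
        segdups=IntervalSet([GenomicInterval(CHROM, 600, 650)]),
        reference=reference,
        parental_indel_keys=set(),
        chrom_lengths={CHROM: REF_LEN},
    )
    config = FilterConfig(af_threshold=0.3, intersect_callers=True,
                          primary_caller=A)
    cohort = Cohort([
        Sample("p1", "parent", "uninjected"),
        Sample("p2", "parent", "uninjected"),
        Sample("s1", "F0", "edited", "g1", ("p1", "p2")),
        Sample("s2", "F0", "edited", "g1", ("p1", "p2")),
    ])

    expected = {
        # (stage name, total input, total surviving) over both callers
        "trace": [
            ("parental_exclusion", 12, 11),
            ("known_variant_exclusion", 11, 10),
            ("on_target_exclusion", 10, 9),
            ("region_exclusion", 9, 8),
            ("repeat_context_indels", 8, 7),
            ("cross_noise", 7, 5),
            ("af_threshold", 5, 4),
            ("caller_intersection", 4, 2),
        ],
        "survivors": {"s1": {v10a}, "s2": {v10b}},
        "keys": {
            "parental": v1, "dbsnp": v2, "on_target": v3, "repeat_region": v4,
            "repeat_context_indel": v6, "cross_noise": v7, "low_af": v9,
            "survivor_s1": v10a, "survivor_s2": v10b,
        },
    }
    return calls_by_caller, resources, config, cohort, expected
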