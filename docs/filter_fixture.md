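# The ten-variant filter-cascade fixture

`tests/fixture_cascade.py` builds a fully handcrafted cascade input whose
per-stage fate is known by design.  The reference is a deterministic 1 kb
chromosome (`chr1`) with an `AAAAA` homopolymer planted at positions
700–704.  Region resources: on-target locus `[200, 223)` (excluded with a
±50 bp flank), repeat tract `[400, 450)`, segmental-duplication tract
`[600, 650)`.  Positions are 0-based; SNV alt alleles are the transition
partner of the reference base.

## Primary-caller (germline) calls

| # | Sample | Variant            | AF  | Designed fate                              |
|---|--------|--------------------|-----|--------------------------------------------|
| 1 | s1     | SNV @ 100          | 0.5 | removed: parental exclusion (key in a parent) |
| 2 | s1     | SNV @ 120          | 0.5 | removed: known-variant (dbSNP-like) exclusion |
| 3 | s1     | SNV @ 210          | 0.5 | removed: on-target exclusion (inside ±50 bp)  |
| 4 | s1     | SNV @ 420          | 0.5 | removed: region exclusion (repeat tract)      |
| 5 | s1     | del `AA`→`A` @ 700 | 0.5 | removed: repeat-context indel (A-run ≥ 3)     |
| 6 | s1     | SNV @ 800          | 0.5 | removed: cross-noise (same key as #7)         |
| 7 | s2     | SNV @ 800          | 0.5 | removed: cross-noise (same key as #6)         |
| 8 | s2     | SNV @ 840          | 0.2 | removed: AF threshold (0.2 < 0.3)             |
| 9 | s1     | SNV @ 900          | 0.5 | **survivor** (confirmed by second caller)     |
| 10| s2     | SNV @ 950          | 0.5 | **survivor** (confirmed by second caller)     |

The second caller (somatic) carries only the two survivor keys, so the
dual-caller intersection keeps exactly those.

## Expected per-stage trace (totals over both callers)

| Stage                   | Input | Surviving |
|-------------------------|-------|-----------|
| parental_exclusion      | 12    | 11        |
| known_variant_exclusion | 11    | 10        |
| on_target_exclusion     | 10    | 9         |
| region_exclusion        | 9     | 8         |
| repeat_context_indels   | 8     | 7         |
| cross_noise             | 7     | 5         |
| af_threshold            | 5     | 4         |
| caller_intersection     | 4     | 2         |

Final surviving set: `{s1: SNV@900, s2: SNV@950}` — the two designed
survivors.
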