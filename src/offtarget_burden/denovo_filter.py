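"""The de novo filter cascade with per-stage accounting.

Raw cohort calls are reduced to candidate de novo variants by, in order:
parental exclusion, known-variant (dbSNP-like) exclusion, on-target-locus
exclusion, repeat/segmental-duplication region exclusion, a repeat-context
indel filter, cross-noise removal (keys recurring in >= 2 samples), an
allele-frequency threshold, optional dual-caller intersection, and
rule-based flagging of calls adjacent to parental indels (the stand-in for
manual review; flagged calls are marked suspect, never silently removed).

Every stage's survivors are a subset of its input and the
:class:`FilterReport` records the per-stage accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

from offtarget_burden.vario import (
    Cohort,
    IntervalSet,
    VariantCall,
    VariantKey,
)

log = logging.getLogger(__name__)

#: calls grouped per sample: sample_id -> list of calls
CallMap = dict[str, list[VariantCall]]


@dataclass
class FilterConfig:
    """Tunable thresholds of the cascade.

    ``af_threshold`` of None disables AF filtering (the "no threshold"
    analysis mode); thresholds are inclusive (AF >= threshold).
    """

    af_threshold: Optional[float] = 0.3
    use_dbsnp: bool = True
    cross_noise_min_samples: int = 2
    cross_noise_scope: str = "cohort"  # "cohort" | "within_guide"
    on_target_flank: int = 50
    indel_repeat_max_unit: int = 3
    indel_repeat_min_copies: int = 3
    indel_adjacency_flank: int = 25
    require_both_strands: bool = False
    intersect_callers: bool = True
    primary_caller: Optional[str] = None  # None -> first caller id

    def __post_init__(self) -> None:
        if self.af_threshold is not None and not (0.0 <= self.af_threshold <= 1.0):
            raise ValueError("af_threshold must be in [0,1] or None")
        if self.cross_noise_scope not in ("cohort", "within_guide"):
            raise ValueError(f"unknown cross_noise_scope {self.cross_noise_scope!r}")
        if self.on_target_flank < 0 or self.indel_adjacency_flank < 0:
            raise ValueError("flanks must be >= 0")
        if self.indel_repeat_max_unit not in (1, 2, 3):
            raise ValueError("indel_repeat_max_unit must be 1, 2 or 3")


@dataclass
class FilterResources:
    """Pre-loaded exclusion resources for :func:`run_cascade`."""

    parental_keys: set[VariantKey]
    known_keys: set[VariantKey]
    on_target: IntervalSet
    repeats: IntervalSet
    segdups: IntervalSet
    reference: Optional[Mapping[str, str]] = None
    parental_indel_keys: set[VariantKey] = field(default_factory=set)
    chrom_lengths: Optional[Mapping[str, int]] = None


@dataclass
class StageRecord:
    name: str
    n_input: int
    n_surviving: int
    removed_keys: list[tuple[str, str, VariantKey]]  # (caller, sample, key)
    per_caller: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_surviving


@dataclass
class FilterReport:
    """Ordered per-stage accounting plus the final call sets."""

    stages: list[StageRecord] = field(default_factory=list)
    final_by_caller: CallMap_by_caller = None  # type: ignore[valid-type]
    final_calls: CallMap = field(default_factory=dict)
    flagged: set[tuple[str, VariantKey]] = field(default_factory=set)
    primary_caller: str = ""
    consensus: bool = False

    def __post_init__(self) -> None:
        if self.final_by_caller is None:
            self.final_by_caller = {}

    def validate_monotone(self) -> None:
        prev = None
        for st in self.stages:
            if st.n_surviving > st.n_input:
                raise AssertionError(f"stage {st.name}: surviving > input")
            if prev is not None and st.n_input != prev.n_surviving:
                raise AssertionError(
                    f"stage {st.name}: input {st.n_input} != previous "
                    f"surviving {prev.n_surviving}"
                )
            prev = st

    def stage_counts(self) -> list[dict]:
        return [
            {
                "stage": st.name,
                "input": st.n_input,
                "surviving": st.n_surviving,
                "removed": st.n_removed,
                "per_caller": {k: {"input": v[0], "surviving": v[1]}
                               for k, v in st.per_caller.items()},
            }
            for st in self.stages
        ]

    def to_dict(self) -> dict:
        return {
            "stages": self.stage_counts(),
            "primary_caller": self.primary_caller,
            "consensus": self.consensus,
            "final_counts": {s: len(c) for s, c in sorted(self.final_calls.items())},
            "n_flagged": len(self.flagged),
        }


CallMap_by_caller = dict[str, CallMap]


def _n_calls(calls_by_caller: CallMap_by_caller) -> int:
    return sum(len(v) for by_sample in calls_by_caller.values()
               for v in by_sample.values())


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------


def exclude_matching(
    calls: Sequence[VariantCall],
    exclusion_keys: set[VariantKey],
    stage_name: str = "exclude_matching",
) -> list[VariantCall]:
    """Remove calls whose normalized key is in ``exclusion_keys``.

    Used for parental, known-variant (dbSNP-like) and control-intersection
    exclusions.  Both sides must already be left-normalized; a raw
    unnormalized duplicate on either side will (intentionally) not match.
    """
    return [c for c in calls if c.key not in exclusion_keys]


def exclude_in_regions(
    calls: Sequence[VariantCall],
    regions: IntervalSet,
    stage_name: str = "exclude_in_regions",
) -> list[VariantCall]:
    """Remove calls whose reference footprint overlaps any region
    (half-open overlap; an SNV at a region's ``end`` is retained)."""
    return [c for c in calls if not regions.overlaps_interval(c.key.interval)]


def _indel_changed_seq(key: VariantKey) -> Optional[tuple[str, int]]:
    """(inserted-or-deleted sequence, 0-based start of the event) for simple
    anchored indels; None for SNVs/complex substitutions."""
    if not key.is_indel:
        return None
    if len(key.ref) > len(key.alt) and key.ref.startswith(key.alt):
        return key.ref[len(key.alt):], key.pos + len(key.alt)
    if len(key.alt) > len(key.ref) and key.alt.startswith(key.ref):
        return key.alt[len(key.ref):], key.pos + len(key.ref)
    return None


def _tandem_copies(context: str, event_start: int, unit: str) -> int:
    """Maximal number of tandem copies of ``unit`` in the reference run
    covering position ``event_start``."""
    u = len(unit)
    # walk left to the start of the tandem run
    start = event_start
    while start - u >= 0 and context[start - u : start] == unit:
        start -= u
    # count copies rightwards from the run start
    copies = 0
    i = start
    while context[i : i + u] == unit:
        copies += 1
        i += u
    return copies


def filter_repeat_context_indels(
    calls: Sequence[VariantCall],
    reference: Optional[Mapping[str, str]],
    max_unit: int = 3,
    min_copies: int = 3,
) -> list[VariantCall]:
    """Remove indels whose changed sequence is a whole number of copies of a
    short unit (homo-, di- or trinucleotide) lying in a tandem repeat of
    >= ``min_copies`` copies in the flanking reference.  SNVs always pass;
    missing reference context retains the call with a warning (fail-open).
    """
    out = []
    for call in calls:
        changed = _indel_changed_seq(call.key)
        if changed is None:
            out.append(call)
            continue
        seq, event_start = changed
        context = reference.get(call.key.chrom) if reference else None
        if context is None:
            log.warning("no reference context for %s; indel retained", call.key)
            out.append(call)
            continue
        removed = False
        for u in range(1, max_unit + 1):
            if len(seq) % u != 0:
                continue
            unit = seq[:u]
            if unit * (len(seq) // u) != seq:
                continue
            if _tandem_copies(context, event_start, unit) >= min_copies:
                removed = True
                break
        if not removed:
            out.append(call)
    return out


def exclude_cross_noise(
    calls_by_sample: CallMap,
    min_samples: int = 2,
    scope: str = "cohort",
    guide_by_sample: Optional[Mapping[str, str]] = None,
) -> tuple[CallMap, set[VariantKey]]:
    """Remove keys observed in >= ``min_samples`` distinct samples.

    Scope "cohort" counts across all samples; "within_guide" counts only
    among samples sharing a guide assignment (samples without a guide form
    one group).  Multiplicity is judged on keys alone, never AF or caller.
    """
    if scope == "within_guide" and guide_by_sample is None:
        raise ValueError("within_guide scope requires guide_by_sample")
    carriers: dict[tuple[str, VariantKey], set[str]] = {}
    for sid, calls in calls_by_sample.items():
        group = guide_by_sample.get(sid, "") if scope == "within_guide" else ""
        for c in calls:
            carriers.setdefault((group, c.key), set()).add(sid)
    noisy: set[VariantKey] = {
        key for (_, key), sids in carriers.items() if len(sids) >= min_samples
    }
    if scope == "within_guide":
        noisy_pairs = {
            (group, key)
            for (group, key), sids in carriers.items()
            if len(sids) >= min_samples
        }
        out = {
            sid: [c for c in calls
                  if (guide_by_sample.get(sid, ""), c.key) not in noisy_pairs]
            for sid, calls in calls_by_sample.items()
        }
        removed = {key for _, key in noisy_pairs}
        return out, removed
    out = {
        sid: [c for c in calls if c.key not in noisy]
        for sid, calls in calls_by_sample.items()
    }
    return out, noisy


def apply_af_threshold(
    calls: Sequence[VariantCall], threshold: Optional[float]
) -> list[VariantCall]:
    """Retain calls with AF >= threshold (inclusive); None is the identity."""
    if threshold is None:
        return list(calls)
    return [c for c in calls if c.af >= threshold]


def intersect_callers(
    calls_a: CallMap, calls_b: CallMap
) -> CallMap:
    """Dual-caller consensus: (sample, key) pairs present in both callers.

    AF/depth are reported from the first argument (the designated primary
    caller); membership is symmetric in the two arguments.
    """
    out: CallMap = {}
    for sid, calls in calls_a.items():
        b_keys = {c.key for c in calls_b.get(sid, ())}
        out[sid] = [c for c in calls if c.key in b_keys]
    return out


def flag_indel_adjacent(
    calls: Sequence[VariantCall],
    parental_indel_keys: set[VariantKey],
    flank: int = 25,
) -> list[VariantCall]:
    """Mark calls within ``flank`` bp of any parental indel as suspect.

    Rule-based stand-in for manual inspection of alignment artifacts around
    inherited small deletions; flagged calls are retained, not removed.
    """
    indel_set = IntervalSet(k.interval for k in parental_indel_keys)
    expanded = indel_set.expand(flank)
    out = []
    for c in calls:
        if expanded.overlaps_interval(c.key.interval):
            out.append(replace(c, suspect=True))
        else:
            out.append(c)
    return out


def titv_ratio(calls: Sequence[VariantCall]) -> Optional[float]:
    """Transition/transversion ratio over SNVs; None when undefined
    (zero transversions or no SNVs)."""
    ti = tv = 0
    for c in calls:
        if not c.key.is_snv:
            continue
        if c.key.is_transition:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def _apply_per_call_stage(
    calls_by_caller: CallMap_by_caller,
    name: str,
    fn: Callable[[Sequence[VariantCall]], list[VariantCall]],
    stages: list[StageRecord],
) -> CallMap_by_caller:
    n_in = _n_calls(calls_by_caller)
    removed: list[tuple[str, str, VariantKey]] = []
    out: CallMap_by_caller = {}
    per_caller = {}
    for caller_id, by_sample in calls_by_caller.items():
        c_in = sum(len(v) for v in by_sample.values())
        new_by_sample: CallMap = {}
        for sid, calls in by_sample.items():
            survivors = fn(calls)
            surviving_ids = {id(c) for c in survivors}
            removed.extend(
                (caller_id, sid, c.key) for c in calls
                if id(c) not in surviving_ids
            )
            new_by_sample[sid] = survivors
        out[caller_id] = new_by_sample
        per_caller[caller_id] = (
            c_in, sum(len(v) for v in new_by_sample.values())
        )
    stages.append(
        StageRecord(name, n_in, _n_calls(out), removed, per_caller)
    )
    return out


def run_cascade(
    calls_by_caller: CallMap_by_caller,
    resources: FilterResources,
    config: FilterConfig,
    cohort: Optional[Cohort] = None,
) -> FilterReport:
    """Apply the full filter cascade and return the per-stage report.

    Stage order: parental exclusion -> known-variant exclusion -> on-target
    exclusion -> repeat/segdup region exclusion -> repeat-context indel
    filter -> cross-noise -> AF threshold -> (optional strand requirement)
    -> (optional) caller intersection -> suspect flagging.  Cross-noise runs
    after the region filters so systematic repeat artifacts do not consume
    the >= 2-sample budget.
    """
    if not calls_by_caller:
        raise ValueError("no call sets supplied")
    for name, res in (("parental_keys", resources.parental_keys),
                      ("on_target", resources.on_target),
                      ("repeats", resources.repeats),
                      ("segdups", resources.segdups)):
        if res is None:
            raise ValueError(f"missing resource {name}")
    primary = config.primary_caller or next(iter(calls_by_caller))
    if primary not in calls_by_caller:
        raise ValueError(f"primary caller {primary!r} not in call sets")

    stages: list[StageRecord] = []
    current = {
        caller: {sid: list(calls) for sid, calls in by_sample.items()}
        for caller, by_sample in calls_by_caller.items()
    }

    current = _apply_per_call_stage(
        current, "parental_exclusion",
        lambda calls: exclude_matching(calls, resources.parental_keys),
        stages,
    )
    if config.use_dbsnp:
        current = _apply_per_call_stage(
            current, "known_variant_exclusion",
            lambda calls: exclude_matching(calls, resources.known_keys),
            stages,
        )
    on_target = resources.on_target.expand(
        config.on_target_flank, resources.chrom_lengths
    )
    current = _apply_per_call_stage(
        current, "on_target_exclusion",
        lambda calls: exclude_in_regions(calls, on_target),
        stages,
    )
    regions = resources.repeats.union(resources.segdups)
    current = _apply_per_call_stage(
        current, "region_exclusion",
        lambda calls: exclude_in_regions(calls, regions),
        stages,
    )
    current = _apply_per_call_stage(
        current, "repeat_context_indels",
        lambda calls: filter_repeat_context_indels(
            calls, resources.reference,
            max_unit=config.indel_repeat_max_unit,
            min_copies=config.indel_repeat_min_copies,
        ),
        stages,
    )

    # cross-noise: multiplicity judged per caller across samples
    guide_by_sample = None
    if config.cross_noise_scope == "within_guide":
        if cohort is None:
            raise ValueError("within_guide cross-noise scope requires a cohort")
        guide_by_sample = {s.sample_id: s.guide_id for s in cohort}
    n_in = _n_calls(current)
    removed_cn: list[tuple[str, str, VariantKey]] = []
    per_caller = {}
    new_current: CallMap_by_caller = {}
    for caller_id, by_sample in current.items():
        c_in = sum(len(v) for v in by_sample.values())
        filtered, noisy = exclude_cross_noise(
            by_sample, config.cross_noise_min_samples,
            config.cross_noise_scope, guide_by_sample,
        )
        for sid, calls in by_sample.items():
            kept = {id(c) for c in filtered[sid]}
            removed_cn.extend(
                (caller_id, sid, c.key) for c in calls if id(c) not in kept
            )
        new_current[caller_id] = filtered
        per_caller[caller_id] = (
            c_in, sum(len(v) for v in filtered.values())
        )
    current = new_current
    stages.append(StageRecord("cross_noise", n_in, _n_calls(current),
                              removed_cn, per_caller))

    current = _apply_per_call_stage(
        current, "af_threshold",
        lambda calls: apply_af_threshold(calls, config.af_threshold),
        stages,
    )
    if config.require_both_strands:
        current = _apply_per_call_stage(
            current, "strand_support",
            lambda calls: [c for c in calls if c.both_strands is not False],
            stages,
        )

    final_by_caller: CallMap_by_caller = {
        caller: {sid: list(calls) for sid, calls in by_sample.items()}
        for caller, by_sample in current.items()
    }

    if config.intersect_callers and len(current) >= 2:
        others = [cid for cid in current if cid != primary]
        n_in = _n_calls(current)
        consensus = current[primary]
        for other in others:
            consensus = intersect_callers(consensus, current[other])
        # everything that leaves the stream is listed: the primary caller's
        # non-consensus calls plus all secondary-caller calls (their streams
        # are absorbed into the single consensus stream)
        removed = [
            (primary, sid, c.key)
            for sid, calls in current[primary].items()
            for c in calls
            if c.key not in {x.key for x in consensus.get(sid, ())}
        ]
        removed.extend(
            (other, sid, c.key)
            for other in others
            for sid, calls in current[other].items()
            for c in calls
        )
        n_out = sum(len(v) for v in consensus.values())
        stages.append(
            StageRecord("caller_intersection", n_in, n_out, removed,
                        {primary: (sum(len(v) for v in current[primary].values()),
                                   n_out)})
        )
        final: CallMap = consensus
        is_consensus = True
    else:
        final = current[primary]
        is_consensus = False

    flagged: set[tuple[str, VariantKey]] = set()
    flagged_final: CallMap = {}
    for sid, calls in final.items():
        marked = flag_indel_adjacent(
            calls, resources.parental_indel_keys, config.indel_adjacency_flank
        )
        flagged_final[sid] = marked
        flagged.update((sid, c.key) for c in marked if c.suspect)
    # flagging also annotates the per-caller finals for panel-style reporting
    final_by_caller = {
        caller: {
            sid: flag_indel_adjacent(calls, resources.parental_indel_keys,
                                     config.indel_adjacency_flank)
            for sid, calls in by_sample.items()
        }
        for caller, by_sample in final_by_caller.items()
    }

    report = FilterReport(
        stages=stages,
        final_by_caller=final_by_caller,
        final_calls=flagged_final,
        flagged=flagged,
        primary_caller=primary,
        consensus=is_consensus,
    )
    report.validate_monotone()
    return report
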