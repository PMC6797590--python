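"""Off-target proximity analysis and the expected-chance-variant null model.

The question asked here: do edited individuals carry more variant calls near
predicted Cas9 off-target cut sites than sequencing error alone would place
there?  The model treats every base of the exome capture space as a trial.
A position becomes a chance "variant" when sequencing error produces enough
alternate reads to be called (at least ``min_alt_reads`` errant reads and an
alternate allele fraction above ``min_af`` at the average depth) — a binomial
tail.  Scaling by the capture size gives the expected number of chance
variant positions K.  Observing k distinct variant positions inside the
merged off-target windows (n bp) drawn from a capture of N bp with K chance
positions is then scored with a hypergeometric upper tail.

Hits inside windows are additionally triaged by a fixed rule order that
mirrors manual review: shared across guides/conditions, single-strand
support, control-only carriers, allele fraction at the limit of detection,
and absence from the second caller all demote a hit before it is accepted
as a candidate off-target edit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy import stats

from offtarget_burden.vario import (
    Cohort,
    GenomicInterval,
    IntervalSet,
    VariantCall,
    VariantKey,
    read_bed,
)

log = logging.getLogger(__name__)

#: Triage categories, in rule-application order (first match wins).
TRIAGE_CATEGORIES = (
    "shared_across_conditions",
    "single_strand",
    "control_only",
    "low_af_limit",
    "caller_unconfirmed",
    "candidate",
)


@dataclass(frozen=True)
class OffTargetSite:
    """A predicted off-target cut locus for one guide."""

    interval: GenomicInterval
    guide_id: str
    cfd_score: float
    predicted_by: frozenset[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.cfd_score <= 1.0):
            raise ValueError(f"cfd_score must be in [0,1], got {self.cfd_score}")
        if not self.predicted_by:
            raise ValueError("predicted_by must be non-empty")


@dataclass(frozen=True)
class ErrorModel:
    """Platform error rates and calling thresholds for the chance model.

    Defaults follow the study conditions: a 74,691,693 bp exome capture,
    a high/low Illumina per-base error bracket of 0.24% / 0.1%, and a call
    requiring >= 4 errant reads with AF strictly above 0.05 at 76x depth.
    """

    capture_bp: int = 74_691_693
    error_rate: float = 0.0024
    min_alt_reads: int = 4
    min_af: float = 0.05  # strict: AF > min_af
    depth: int = 76

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError("error_rate must be in (0,1)")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")
        if self.capture_bp < 1:
            raise ValueError("capture_bp must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def read_threshold(self) -> int:
        """Minimum alt reads implied by both thresholds combined.

        ``AF > min_af`` at integer depth means at least
        ``floor(min_af * depth) + 1`` reads; the call threshold is the max of
        that and ``min_alt_reads`` (they coincide at 4 for depth 76).
        """
        af_reads = int(self.min_af * self.depth) + 1 if self.min_af > 0 else 0
        return max(self.min_alt_reads, af_reads)


@dataclass(frozen=True)
class WindowHit:
    call: VariantCall
    site: OffTargetSite


@dataclass
class WindowHits:
    """Calls overlapping flank-expanded off-target windows."""

    pairs: list[WindowHit]
    windows: IntervalSet  # merged expanded windows, clipped to capture space
    window_bp: int

    @property
    def distinct_keys(self) -> set[VariantKey]:
        return {h.call.key for h in self.pairs}

    @property
    def distinct_positions(self) -> set[tuple[str, int]]:
        return {(h.call.key.chrom, h.call.key.pos) for h in self.pairs}


@dataclass(frozen=True)
class HitTriage:
    hit: WindowHit
    category: str
    evidence: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.category!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of window hits over the chance expectation."""

    error_rate: float
    site_probability: float
    expected_sites: float
    K: int  # rounded expectation used as the success count
    window_bp: int
    observed: int
    p_value: Optional[float]  # None when window_bp == 0 (undefined)


# ---------------------------------------------------------------------------
# Window intersection
# ---------------------------------------------------------------------------


def window_hits(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    sites: Sequence[OffTargetSite],
    flank: int = 100,
    capture: Optional[IntervalSet] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> WindowHits:
    """Intersect (unfiltered) calls with flank-expanded off-target windows.

    Every (call, site) pair whose intervals overlap is returned; the merged
    window territory is clipped to the capture space when given, and its
    total bp is the hypergeometric sample size downstream.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    site_set = IntervalSet(s.interval for s in sites)
    windows = site_set.expand(flank, chrom_lengths)
    if capture is not None:
        windows = windows.intersection(capture)
    pairs: list[WindowHit] = []
    for sample_calls in calls_by_sample.values():
        for call in sample_calls:
            iv = call.key.interval
            if not windows.overlaps_interval(iv):
                continue
            for site in sites:
                window = GenomicInterval(
                    site.interval.chrom,
                    max(0, site.interval.start - flank),
                    site.interval.end + flank,
                )
                if window.overlaps(iv):
                    pairs.append(WindowHit(call, site))
    return WindowHits(pairs=pairs, windows=windows, window_bp=windows.total_bp)


# ---------------------------------------------------------------------------
# Hit triage (rule-based stand-in for manual review)
# ---------------------------------------------------------------------------


def classify_hits(
    hits: WindowHits,
    cohort: Cohort,
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    other_caller_calls: Mapping[str, Sequence[VariantCall]],
    low_af_limit: float = 0.06,
) -> list[HitTriage]:
    """Assign each window hit exactly one triage category (first rule wins).

    Rule order: (1) key carried by any sample of a different guide or a
    control condition -> shared_across_conditions; (2) alt reads on only one
    strand -> single_strand (abstains when strand counts are unknown);
    (3) the carrier itself is a control -> control_only; (4) AF below
    ``low_af_limit`` (near the callers' limit of detection) -> low_af_limit;
    (5) key absent from the second caller in the same sample ->
    caller_unconfirmed; otherwise -> candidate.
    """
    carriers: dict[VariantKey, set[str]] = {}
    for sid, sample_calls in calls_by_sample.items():
        for call in sample_calls:
            carriers.setdefault(call.key, set()).add(sid)
    other_keys: dict[str, set[VariantKey]] = {
        sid: {c.key for c in sample_calls}
        for sid, sample_calls in other_caller_calls.items()
    }
    out: list[HitTriage] = []
    for hit in hits.pairs:
        call, site = hit.call, hit.site
        sample = cohort[call.sample_id]
        shared_with = {
            sid
            for sid in carriers.get(call.key, set())
            if sid != call.sample_id
            and (
                cohort.condition_of(sid) != "edited"
                or cohort.guide_of(sid) != site.guide_id
            )
        }
        if shared_with:
            out.append(HitTriage(hit, "shared_across_conditions",
                                 {"shared_with": sorted(shared_with)}))
            continue
        if call.both_strands is False:
            out.append(HitTriage(hit, "single_strand",
                                 {"alt_fwd": call.alt_fwd, "alt_rev": call.alt_rev}))
            continue
        if sample.condition != "edited":
            out.append(HitTriage(hit, "control_only",
                                 {"condition": sample.condition}))
            continue
        if call.af < low_af_limit:
            out.append(HitTriage(hit, "low_af_limit", {"af": call.af}))
            continue
        if call.key not in other_keys.get(call.sample_id, set()):
            out.append(HitTriage(hit, "caller_unconfirmed", {}))
            continue
        out.append(HitTriage(hit, "candidate", {"cfd_score": site.cfd_score}))
    return out


def triage_counts(triage: Sequence[HitTriage]) -> dict[str, int]:
    counts = {cat: 0 for cat in TRIAGE_CATEGORIES}
    for t in triage:
        counts[t.category] += 1
    return counts


# ---------------------------------------------------------------------------
# Expected-chance-variant model
# ---------------------------------------------------------------------------


def error_site_probability(model: ErrorModel) -> float:
    """P(a single position is called a variant by sequencing error alone).

    Exact binomial upper tail: X ~ Binomial(depth, error_rate),
    P(X >= read_threshold).
    """
    thr = model.read_threshold
    if thr <= 0:
        return 1.0
    return float(stats.binom.sf(thr - 1, model.depth, model.error_rate))


def expected_chance_sites(model: ErrorModel) -> tuple[float, int]:
    """Expected number of chance-variant positions in the capture space.

    Returns the real-valued expectation and the rounded integer K used as
    the hypergeometric success count downstream.
    """
    expected = model.capture_bp * error_site_probability(model)
    return expected, int(round(expected))


def hypergeom_upper_tail(
    population_N: int, successes_K: int, sample_n: int, observed_k: int
) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable for N up to ~1e8."""
    if not (0 <= successes_K <= population_N):
        raise ValueError("need 0 <= K <= N")
    if not (0 <= sample_n <= population_N):
        raise ValueError("need 0 <= n <= N")
    if observed_k < 0:
        raise ValueError("observed_k must be >= 0")
    if observed_k == 0:
        return 1.0
    if observed_k > min(sample_n, successes_K):
        log.warning(
            "observed k=%d exceeds min(n=%d, K=%d); p = 0 by convention",
            observed_k, sample_n, successes_K,
        )
        return 0.0
    return float(
        stats.hypergeom.sf(observed_k - 1, population_N, successes_K, sample_n)
    )


def offtarget_enrichment_test(
    hits: WindowHits,
    model: ErrorModel,
) -> EnrichmentResult:
    """Score distinct window-hit positions against the chance expectation.

    p = P(X >= k), X ~ Hypergeom(N = capture_bp, K = round(expected chance
    sites), n = merged window bp, k = distinct hit positions).  Counting
    distinct positions (not per-sample calls) keeps one systematic site from
    inflating the enrichment.  ``window_bp == 0`` yields an undefined result
    (p_value None).
    """
    p_site = error_site_probability(model)
    expected, K = expected_chance_sites(model)
    k = len(hits.distinct_positions)
    if hits.window_bp == 0:
        log.warning("window_bp is 0; enrichment p-value undefined")
        p: Optional[float] = None
    else:
        p = hypergeom_upper_tail(model.capture_bp, K, hits.window_bp, k)
    return EnrichmentResult(
        error_rate=model.error_rate,
        site_probability=p_site,
        expected_sites=expected,
        K=K,
        window_bp=hits.window_bp,
        observed=k,
        p_value=p,
    )


def enrichment_by_scenario(
    hits: WindowHits,
    capture_bp: int,
    depth: int = 76,
    error_rates: Sequence[float] = (0.0024, 0.001),
    min_alt_reads: int = 4,
    min_af: float = 0.05,
) -> dict[str, EnrichmentResult]:
    """Run the enrichment test under the high/low error-rate bracket."""
    labels = ("high", "low") if len(error_rates) == 2 else [
        f"rate_{r:g}" for r in error_rates
    ]
    out = {}
    for label, rate in zip(labels, error_rates):
        model = ErrorModel(
            capture_bp=capture_bp,
            error_rate=rate,
            min_alt_reads=min_alt_reads,
            min_af=min_af,
            depth=depth,
        )
        out[label] = offtarget_enrichment_test(hits, model)
    return out


# ---------------------------------------------------------------------------
# Off-target BED dialect
# ---------------------------------------------------------------------------


def read_offtarget_bed(
    path, engines_tsv=None
) -> list[OffTargetSite]:
    """Read predicted off-target sites from BED6.

    Name column is ``guide_id:engine``; score column carries CFD x 1000.
    An optional sidecar TSV (columns chrom, start, engines) may supply
    full per-site engine sets (comma-separated).
    """
    iset = read_bed(path)
    engine_map: dict[tuple[str, int], frozenset[str]] = {}
    if engines_tsv is not None:
        import csv

        with open(engines_tsv, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                engine_map[(row["chrom"], int(row["start"]))] = frozenset(
                    row["engines"].split(",")
                )
    sites = []
    for rec in iset.records:
        if rec.name is None or ":" not in rec.name:
            raise ValueError(
                f"{path}: off-target BED requires name column 'guide_id:engine', "
                f"got {rec.name!r}"
            )
        guide_id, engine = rec.name.rsplit(":", 1)
        predicted_by = engine_map.get((rec.chrom, rec.start), frozenset({engine}))
        cfd = (rec.score or 0.0) / 1000.0
        sites.append(
            OffTargetSite(
                interval=GenomicInterval(rec.chrom, rec.start, rec.end),
                guide_id=guide_id,
                cfd_score=cfd,
                predicted_by=predicted_by,
            )
        )
    return sites


def write_offtarget_bed(sites: Sequence[OffTargetSite], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start)):
            engine = sorted(s.predicted_by)[0]
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.guide_id}:{engine}\t{s.cfd_score * 1000:g}\t+\n"
            )
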