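from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from offtarget_burden.offtarget_model import (
    ErrorModel,
    OffTargetSite,
    classify_hits,
    enrichment_by_scenario,
    error_site_probability,
    expected_chance_sites,
    hypergeom_upper_tail,
    offtarget_enrichment_test,
    read_offtarget_bed,
    triage_counts,
    window_hits,
    write_offtarget_bed,
)
from offtarget_burden.vario import (
    Cohort,
    GenomicInterval,
    IntervalSet,
    Sample,
    VariantCall,
    VariantKey,
)


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact rational upper tail by direct enumeration of draw counts."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return Fraction(hits, total)


def binom_tail_oracle(n: int, p: float, k: int) -> float:
    """Direct pmf summation of P(X >= k), X ~ Binomial(n, p)."""
    return sum(
        math.comb(n, j) * (p ** j) * ((1 - p) ** (n - j))
        for j in range(k, n + 1)
    )


def _call(chrom, pos, sample_id="s1", af=0.3, depth=76, fwd=None, rev=None,
          ref="A", alt="G"):
    alt_depth = max(1, int(round(af * depth)))
    if fwd is None and rev is None:
        fwd, rev = alt_depth // 2, alt_depth - alt_depth // 2
    elif fwd is not None and rev is not None:
        alt_depth = fwd + rev
    return VariantCall(VariantKey(chrom, pos, ref, alt), sample_id, "germline",
                       depth=depth, alt_depth=alt_depth, af=alt_depth / depth,
                       alt_fwd=fwd, alt_rev=rev)


def _site(chrom="chr1", start=1000, guide="g1", cfd=0.3,
          engines=("crispor",)):
    return OffTargetSite(GenomicInterval(chrom, start, start + 23), guide,
                         cfd, frozenset(engines))


class TestErrorModel:
    def test_read_threshold_combines_af_and_count_rules(self):
        # AF > 0.05 at depth 76 implies >= 4 reads; thresholds coincide at 4
        assert ErrorModel(depth=76).read_threshold == 4
        # deeper coverage: the AF rule dominates (floor(0.05*200)+1 = 11)
        assert ErrorModel(depth=200).read_threshold == 11

    def test_tail_matches_direct_pmf_summation_at_study_depth(self):
        for rate in (0.0024, 0.001):
            model = ErrorModel(error_rate=rate, depth=76)
            oracle = binom_tail_oracle(76, rate, 4)
            assert error_site_probability(model) == pytest.approx(
                oracle, rel=1e-10
            )
        # magnitude check for the high-rate scenario
        assert 1e-5 < error_site_probability(ErrorModel(depth=76)) < 1e-4

    def test_probability_vanishes_with_error_rate(self):
        rates = [1e-7, 1e-5, 1e-3, 1e-2]
        probs = [
            error_site_probability(ErrorModel(error_rate=r, depth=76))
            for r in rates
        ]
        assert probs == sorted(probs)
        assert probs[0] < 1e-20

    def test_zero_thresholds_make_call_certain(self):
        model = ErrorModel(min_alt_reads=0, min_af=0.0)
        assert error_site_probability(model) == 1.0

    def test_monotone_in_depth_at_fixed_read_threshold(self):
        probs = [
            error_site_probability(
                ErrorModel(depth=d, min_af=0.0, min_alt_reads=4)
            )
            for d in (40, 76, 115, 200)
        ]
        assert probs == sorted(probs)

    def test_expectation_scales_linearly_with_capture(self):
        small = expected_chance_sites(ErrorModel(capture_bp=10**6))[0]
        double = expected_chance_sites(ErrorModel(capture_bp=2 * 10**6))[0]
        assert double == pytest.approx(2 * small)
        full_expected, K = expected_chance_sites(ErrorModel())
        assert K == round(74_691_693 * binom_tail_oracle(76, 0.0024, 4))


class TestHypergeomTail:
    def test_small_case_exact_fraction(self):
        assert hypergeom_upper_tail(10, 3, 4, 2) == pytest.approx(1 / 3)

    def test_zero_observed_is_certain(self):
        assert hypergeom_upper_tail(100, 5, 10, 0) == 1.0

    def test_impossible_observation_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert hypergeom_upper_tail(10, 2, 3, 3) == 0.0
        assert "convention" in caplog.text

    def test_matches_exact_rational_oracle_small_populations(self):
        for N in range(1, 31):
            for K in range(0, N + 1, max(1, N // 5)):
                for n in range(0, N + 1, max(1, N // 5)):
                    for k in range(1, min(n, K) + 1):
                        expected = float(hypergeom_tail_oracle(N, K, n, k))
                        got = hypergeom_upper_tail(N, K, n, k)
                        assert got == pytest.approx(expected, rel=1e-9), (
                            N, K, n, k
                        )

    def test_matches_binomial_limit_for_tiny_sampling_fraction(self):
        # n/N <= 1e-3: hypergeometric ~ Binomial(n, K/N) within 1%
        N, K, n = 10**6, 2000, 800
        for k in (1, 2, 4):
            hyper = hypergeom_upper_tail(N, K, n, k)
            binom = binom_tail_oracle(n, K / N, k)
            assert hyper == pytest.approx(binom, rel=0.01)

    def test_tail_non_increasing_in_k(self):
        ps = [hypergeom_upper_tail(10**6, 500, 2000, k) for k in range(6)]
        assert ps == sorted(ps, reverse=True)


class TestWindows:
    def test_flank_window_boundaries(self):
        sites = [_site(start=1000)]
        calls = {"s1": [_call("chr1", 905), _call("chr1", 899)]}
        hits = window_hits(calls, sites, flank=100)
        assert {h.call.key.pos for h in hits.pairs} == {905}
        assert hits.window_bp == 223  # [900, 1123)

    def test_overlapping_windows_merge_and_count_once(self):
        sites = [_site(start=1000), _site(start=1100, guide="g2")]
        calls = {"s1": [_call("chr1", 1050)]}
        hits = window_hits(calls, sites, flank=100)
        assert hits.window_bp == 323  # merged [900, 1223)
        assert len(hits.pairs) == 2  # paired with both sites
        assert len(hits.distinct_positions) == 1

    def test_windows_clipped_to_capture(self):
        sites = [_site(start=1000)]
        capture = IntervalSet([GenomicInterval("chr1", 0, 1010)])
        hits = window_hits({}, sites, flank=100, capture=capture)
        assert hits.window_bp == 110  # [900, 1010)


class TestTriage:
    @pytest.fixture()
    def cohort(self):
        return Cohort([
            Sample("ctrl", "F0", "uninjected"),
            Sample("ed_g1", "F0", "edited", "g1"),
            Sample("ed_g2", "F0", "edited", "g2"),
        ])

    def _classify_one(self, cohort, call, all_calls=None, other=None):
        sites = [_site(start=1000, guide="g1")]
        calls = all_calls if all_calls is not None else {call.sample_id: [call]}
        hits = window_hits(calls, sites, flank=100)
        return classify_hits(hits, cohort, calls, other or {})

    def test_rules_apply_in_documented_order(self, cohort):
        # rule 1: same key in a sibling edited with another guide
        call = _call("chr1", 950, "ed_g1")
        sib = _call("chr1", 950, "ed_g2")
        triage = self._classify_one(
            cohort, call, all_calls={"ed_g1": [call], "ed_g2": [sib]}
        )
        by_sample = {t.hit.call.sample_id: t.category for t in triage}
        # the g1 carrier shares its key with a sibling edited by another guide
        assert by_sample["ed_g1"] == "shared_across_conditions"

        # rule 2: single-strand support
        one_strand = _call("chr1", 950, "ed_g1", fwd=5, rev=0)
        triage = self._classify_one(cohort, one_strand)
        assert triage[0].category == "single_strand"

        # rule 3: carried by a control
        ctrl_call = _call("chr1", 950, "ctrl")
        triage = self._classify_one(cohort, ctrl_call)
        assert triage[0].category == "control_only"

        # rule 4: AF at the limit of detection
        low = _call("chr1", 950, "ed_g1", af=0.05)
        triage = self._classify_one(cohort, low)
        assert triage[0].category == "low_af_limit"

        # rule 5: absent from the second caller
        solo = _call("chr1", 950, "ed_g1")
        triage = self._classify_one(cohort, solo, other={"ed_g1": []})
        assert triage[0].category == "caller_unconfirmed"

        # else: candidate
        confirmed = _call("chr1", 950, "ed_g1")
        triage = self._classify_one(
            cohort, confirmed, other={"ed_g1": [confirmed]}
        )
        assert triage[0].category == "candidate"

    def test_unknown_strand_abstains_from_rule_two(self, cohort):
        call = VariantCall(VariantKey("chr1", 950, "A", "G"), "ed_g1",
                           "germline", depth=76, alt_depth=23, af=23 / 76)
        triage = self._classify_one(cohort, call, other={"ed_g1": [call]})
        assert triage[0].category == "candidate"

    def test_categories_partition_hits(self, cohort):
        calls = {
            "ed_g1": [_call("chr1", 950, "ed_g1"),
                      _call("chr1", 1005, "ed_g1", af=0.05)],
            "ctrl": [_call("chr1", 1100, "ctrl")],
        }
        sites = [_site(start=1000, guide="g1")]
        hits = window_hits(calls, sites, flank=100)
        triage = classify_hits(hits, cohort, calls, {})
        counts = triage_counts(triage)
        assert sum(counts.values()) == len(hits.pairs)
        assert all(len([t for t in triage if t.hit is h]) == 1
                   for h in hits.pairs)


class TestEnrichment:
    def test_zero_hits_p_one(self):
        hits = window_hits({}, [_site()], flank=100)
        result = offtarget_enrichment_test(hits, ErrorModel(capture_bp=10**6))
        assert result.p_value == 1.0
        assert result.observed == 0

    def test_empty_window_undefined(self, caplog):
        hits = window_hits({}, [], flank=100)
        with caplog.at_level("WARNING"):
            result = offtarget_enrichment_test(
                hits, ErrorModel(capture_bp=10**6)
            )
        assert result.p_value is None

    def test_both_error_scenarios_reported(self):
        hits = window_hits({"s1": [_call("chr1", 990)]}, [_site()], flank=100)
        res = enrichment_by_scenario(hits, capture_bp=10**6)
        assert set(res) == {"high", "low"}
        assert res["high"].error_rate == 0.0024
        assert res["low"].error_rate == 0.001
        # fewer chance sites expected under the low error rate
        assert res["low"].expected_sites < res["high"].expected_sites


class TestNullCalibration:
    def test_enrichment_rarely_significant_under_null(self):
        """With no true off-target edits, the chance-variant model yields a
        non-significant enrichment p in >= 90% of seeded replicates (small
        F1 cohorts on a 500 kb capture stand-in)."""
        from offtarget_burden.cohortsim import SimConfig
        from offtarget_burden.report import RunConfig, run_all

        n_reps, ok = 60, 0
        for seed in range(n_reps):
            rc = RunConfig(sim=SimConfig(
                seed=3000 + seed, capture_bp=500_000, include_f0=False,
                f1_per_condition=1,
            ))
            report = run_all(rc)
            p = report["offtarget"]["enrichment"]["high"]["p_value"]
            ok += (p is None) or (p > 0.05)
        assert ok / n_reps >= 0.90, ok


class TestOfftargetBed:
    def test_round_trip_with_engine_sidecar(self, tmp_path):
        sites = [
            _site("chr1", 500, "anln_hi", 0.52, ("crispor", "casoffinder")),
            _site("chr2", 900, "kmt2d_lo", 0.2, ("crisprdirect",)),
        ]
        bed = tmp_path / "ot.bed"
        write_offtarget_bed(sites, bed)
        tsv = tmp_path / "ot_engines.tsv"
        with open(tsv, "w") as fh:
            fh.write("chrom\tstart\tengines\n")
            for s in sites:
                fh.write(f"{s.interval.chrom}\t{s.interval.start}\t"
                         f"{','.join(sorted(s.predicted_by))}\n")
        back = read_offtarget_bed(bed, tsv)
        assert {(s.interval, s.guide_id, s.cfd_score, s.predicted_by)
                for s in back} == {
            (s.interval, s.guide_id, s.cfd_score, s.predicted_by)
            for s in sites
        }
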