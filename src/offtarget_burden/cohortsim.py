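"""Synthetic multigeneration cohort simulator with known ground truth.

Emulates the study design this pipeline analyzes: a founding pair of
wild-type zebrafish, a clutch of F0 embryos split across injection arms
(uninjected, Cas9-only, sgRNA-only, and Cas9+sgRNA edited across six guides),
and an F1 generation bred from adults of the high-efficiency-guide arm.

What is simulated
-----------------
* founder-pair polymorphism (heterozygous SNVs and small indels at a
  configurable density) and a dbSNP-like known-variant set;
* Mendelian transmission of founder alleles through F0 adults to F1;
* de novo events per offspring exome, Poisson with mean 2.5 (the expected
  2-3 exonic changes per generation), heterozygous (AF 0.5) in F1 and
  mosaic (Beta-distributed AF) in F0;
* mosaic on-target allelic series in edited F0 and a fixed heterozygous
  transmitted on-target allele in edited F1;
* optional true off-target edits at the listed predicted sites;
* two pseudo-callers: binomial sequencing-error false positives, two
  indel-adjacent alignment-artifact classes placed near founder deletions
  (gap-fill and misrealignment, at an ~83:10 call ratio), and systematic
  cross-noise sites shared across samples and callers.

Every emitted call traces to exactly one :class:`TruthRecord` origin, and a
fixed seed reproduces the simulation byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from offtarget_burden.offtarget_model import OffTargetSite, write_offtarget_bed
from offtarget_burden.vario import (
    Cohort,
    GenomicInterval,
    IntervalSet,
    Sample,
    VariantCall,
    VariantKey,
    left_normalize,
    write_bed,
    write_bed_records,
    write_fasta,
    write_key_vcf,
    write_sample_sheet,
    write_vcf,
    BedRecord,
)

log = logging.getLogger(__name__)

ORIGINS = (
    "inherited",
    "denovo",
    "on_target",
    "off_target",
    "fp_error",
    "fp_indel_fill",
    "fp_realign",
    "fp_cross_noise",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_ENGINES = ("crispor", "crisprdirect", "casoffinder")


def _rng(seed: int, *labels: object) -> np.random.Generator:
    """Named substream: all randomness flows from one seed plus a label path."""
    parts = [int(seed) & 0x7FFFFFFF]
    parts.extend(zlib.crc32(str(lab).encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(parts))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GuideSpec:
    """One sgRNA: its on-target cut interval and predicted off-target sites."""

    guide_id: str
    gene: str
    efficiency: str  # "high" | "low"
    on_target: GenomicInterval
    offtargets: list[OffTargetSite] = field(default_factory=list)


@dataclass
class CallerProfile:
    """Detection and error behaviour of one pseudo-caller.

    ``mean_depth_f0``/``mean_depth_f1`` reproduce the study's sequencing
    rounds (76x for parents+F0, 115x for F1).  ``fp_indel_fill_rate`` and
    ``fp_realign_rate`` are mean artifact calls per sample for the two
    indel-adjacent false-positive classes (defaults in an ~83:10 ratio).
    Detection probability decays for true AF below ``sensitivity_floor_af``.
    """

    caller_id: str
    mean_depth_f0: float = 76.0
    mean_depth_f1: float = 115.0
    depth_dispersion: float = 50.0  # negative-binomial size parameter
    error_rate: float = 0.0024
    min_coverage: int = 30
    min_alt_reads: int = 4
    min_af: float = 0.05  # caller reports a site only when AF > min_af
    fp_indel_fill_rate: float = 2.0
    fp_realign_rate: float = 0.24
    cross_noise_sites: int = 30
    sensitivity_floor_af: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0,1)")
        if self.mean_depth_f0 <= 0 or self.mean_depth_f1 <= 0:
            raise ValueError("mean depth must be > 0")

    def mean_depth(self, generation: str) -> float:
        return self.mean_depth_f1 if generation == "F1" else self.mean_depth_f0

    @classmethod
    def noise_free(cls, caller_id: str) -> "CallerProfile":
        """A caller with perfect sensitivity and no false positives."""
        return cls(
            caller_id=caller_id,
            error_rate=0.0,
            min_coverage=0,
            min_alt_reads=1,
            min_af=0.0,
            fp_indel_fill_rate=0.0,
            fp_realign_rate=0.0,
            cross_noise_sites=0,
            sensitivity_floor_af=0.0,
        )


def default_profiles() -> list[CallerProfile]:
    """The two-caller setup: a strict germline caller and a permissive
    somatic caller with a higher effective error rate."""
    return [
        CallerProfile(caller_id="germline", error_rate=0.001, min_coverage=30),
        CallerProfile(caller_id="somatic", error_rate=0.0024, min_coverage=10),
    ]


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults reproduce the cohort design at test scale: a 1 Mb capture
    stand-in for the 74,691,693 bp exome (full size is a config value, not a
    code change), 52 F0 + 16 F1 + 2 parents, Poisson(2.5) de novo events per
    offspring exome, and zero true off-target edits (the null).
    """

    seed: int = 0
    capture_bp: int = 1_000_000
    n_chroms: int = 4
    founder_het_density: float = 1e-3
    founder_indel_fraction: float = 0.15
    founder_del_fraction: float = 0.7  # of founder indels, deletions
    dbsnp_founder_fraction: float = 0.9
    dbsnp_extra_density: float = 2e-4
    denovo_mean: float = 2.5
    denovo_indel_fraction: float = 0.10
    titv_ratio: float = 1.2  # transition bias of the substitution spectrum
    f0_control_counts: dict[str, int] = field(
        default_factory=lambda: {"uninjected": 2, "cas9_only": 2}
    )
    f0_sgrna_only_per_guide: int = 2
    f0_edited_per_guide: int = 6
    f1_per_condition: int = 4
    include_f0: bool = True
    include_f1: bool = True
    guides: Optional[list[GuideSpec]] = None  # None -> six default guides
    offtargets_per_guide: int = 2
    offtarget_rate: float = 0.0
    mosaic_af_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"high": (6.0, 4.0), "low": (1.5, 5.0)}
    )
    denovo_f0_af_beta: tuple[float, float] = (2.0, 5.0)
    edit_prob: dict[str, float] = field(
        default_factory=lambda: {"high": 1.0, "low": 0.3}
    )
    min_true_af: float = 0.05
    repeat_tracts_per_chrom: int = 8
    repeat_tract_bp: int = 300
    segdup_tracts_per_chrom: int = 2
    segdup_tract_bp: int = 2000
    fp_flank_bp: int = 10  # artifact placement flank around founder deletions
    artifact_af_beta: tuple[float, float] = (2.0, 3.0)
    cross_noise_af_range: tuple[float, float] = (0.15, 0.85)
    profiles: list[CallerProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        for name in ("founder_het_density", "denovo_mean", "offtarget_rate",
                     "dbsnp_extra_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_chroms < 1 or self.capture_bp < self.n_chroms:
            raise ValueError("need capture_bp >= n_chroms >= 1")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        base = self.capture_bp // self.n_chroms
        lengths = {f"chr{i + 1}": base for i in range(self.n_chroms)}
        lengths[f"chr{self.n_chroms}"] += self.capture_bp - base * self.n_chroms
        return lengths


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted variant in one sample.

    ``caller_id`` is empty for genomic truth (visible to both callers) and
    names a caller for caller-specific false positives.
    """

    sample_id: str
    key: VariantKey
    origin: str
    true_af: float
    caller_id: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


# ---------------------------------------------------------------------------
# Founders and reference context
# ---------------------------------------------------------------------------


@dataclass
class Founders:
    reference: dict[str, str]
    chrom_lengths: dict[str, int]
    capture: IntervalSet
    repeats: IntervalSet
    segdups: IntervalSet
    guides: list[GuideSpec]
    genotypes: dict[str, dict[VariantKey, TruthRecord]]  # founder_f / founder_m
    dbsnp_keys: set[VariantKey]
    indel_keys: list[VariantKey]  # founder indels: artifact substrate

    @property
    def founder_ids(self) -> list[str]:
        return sorted(self.genotypes)


def _synth_reference(config: SimConfig) -> dict[str, str]:
    rng = _rng(config.seed, "reference")
    ref = {}
    for chrom, length in config.chrom_lengths.items():
        idx = rng.integers(0, 4, size=length)
        ref[chrom] = _BASES[idx].tobytes().decode()
    return ref


def _plant_tracts(
    config: SimConfig, rng: np.random.Generator, per_chrom: int, tract_bp: int
) -> IntervalSet:
    out = []
    for chrom, length in config.chrom_lengths.items():
        n = min(per_chrom, max(0, (length - 2 * tract_bp) // (2 * tract_bp)))
        for _ in range(n):
            start = int(rng.integers(tract_bp, length - tract_bp))
            out.append(GenomicInterval(chrom, start, start + tract_bp))
    return IntervalSet(out)


def _random_positions(
    rng: np.random.Generator, length: int, n: int, margin: int = 60
) -> list[int]:
    if length <= 2 * margin or n <= 0:
        return []
    return sorted(int(p) for p in rng.integers(margin, length - margin, size=n))


def _random_snv(rng: np.random.Generator, seq: str, pos: int, chrom: str,
                titv_ratio: float) -> VariantKey:
    ref = seq[pos]
    p_ti = titv_ratio / (1.0 + titv_ratio)
    if rng.random() < p_ti:
        alt = _TRANSITION[ref]
    else:
        alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def _random_indel(rng: np.random.Generator, seq: str, pos: int, chrom: str,
                  del_fraction: float) -> VariantKey:
    size = int(rng.integers(1, 5))
    if rng.random() < del_fraction and pos + 1 + size < len(seq):
        ref = seq[pos : pos + 1 + size]
        alt = seq[pos]
    else:
        ins = "".join(_BASES[rng.integers(0, 4, size=size)].astype(str))
        ref = seq[pos]
        alt = ref + ins
    return left_normalize(seq, pos, ref, alt, chrom=chrom)


def _default_guides(config: SimConfig, reference: Mapping[str, str]) -> list[GuideSpec]:
    rng = _rng(config.seed, "guides")
    chroms = sorted(config.chrom_lengths)
    guides = []
    for gene in ("anln", "kmt2d", "smchd1"):
        for eff, tag in (("high", "hi"), ("low", "lo")):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = config.chrom_lengths[chrom]
            start = int(rng.integers(1000, max(1001, length - 1000)))
            on_target = GenomicInterval(chrom, start, start + 23)
            guide_id = f"{gene}_{tag}"
            offtargets = []
            for _ in range(config.offtargets_per_guide):
                oc = chroms[int(rng.integers(0, len(chroms)))]
                olen = config.chrom_lengths[oc]
                ostart = int(rng.integers(1000, max(1001, olen - 1000)))
                n_eng = int(rng.integers(1, 3))
                engines = frozenset(
                    rng.choice(_ENGINES, size=n_eng, replace=False).tolist()
                )
                offtargets.append(
                    OffTargetSite(
                        interval=GenomicInterval(oc, ostart, ostart + 23),
                        guide_id=guide_id,
                        cfd_score=float(np.round(rng.uniform(0.05, 0.75), 3)),
                        predicted_by=engines,
                    )
                )
            guides.append(
                GuideSpec(
                    guide_id=guide_id,
                    gene=gene,
                    efficiency=eff,
                    on_target=on_target,
                    offtargets=offtargets,
                )
            )
    return guides


def simulate_founders(config: SimConfig) -> Founders:
    """Synthesize the reference context, region tracts and two diploid
    founders with heterozygous sites at ``founder_het_density``."""
    reference = _synth_reference(config)
    repeats = _plant_tracts(
        config, _rng(config.seed, "repeats"),
        config.repeat_tracts_per_chrom, config.repeat_tract_bp,
    )
    segdups = _plant_tracts(
        config, _rng(config.seed, "segdups"),
        config.segdup_tracts_per_chrom, config.segdup_tract_bp,
    )
    capture = IntervalSet(
        GenomicInterval(chrom, 0, length)
        for chrom, length in config.chrom_lengths.items()
    )
    guides = config.guides if config.guides is not None else _default_guides(
        config, reference
    )

    expected_sites = config.founder_het_density * config.capture_bp
    if 0 < expected_sites < 1:
        log.warning(
            "founder_het_density x capture_bp = %.3g < 1; founders will be "
            "nearly identical to the reference", expected_sites,
        )

    genotypes: dict[str, dict[VariantKey, TruthRecord]] = {}
    indel_keys: list[VariantKey] = []
    for founder_id in ("founder_f", "founder_m"):
        rng = _rng(config.seed, "founder", founder_id)
        sites: dict[VariantKey, TruthRecord] = {}
        for chrom, length in config.chrom_lengths.items():
            seq = reference[chrom]
            n = rng.poisson(config.founder_het_density * length)
            for pos in _random_positions(rng, length, n):
                if rng.random() < config.founder_indel_fraction:
                    key = _random_indel(rng, seq, pos, chrom,
                                        config.founder_del_fraction)
                else:
                    key = _random_snv(rng, seq, pos, chrom, config.titv_ratio)
                if key in sites:
                    continue
                sites[key] = TruthRecord(founder_id, key, "inherited", 0.5)
                if key.is_indel:
                    indel_keys.append(key)
        genotypes[founder_id] = sites

    rng = _rng(config.seed, "dbsnp")
    dbsnp: set[VariantKey] = set()
    all_founder_keys = sorted(
        set(genotypes["founder_f"]) | set(genotypes["founder_m"])
    )
    for key in all_founder_keys:
        if rng.random() < config.dbsnp_founder_fraction:
            dbsnp.add(key)
    for chrom, length in config.chrom_lengths.items():
        seq = reference[chrom]
        n = rng.poisson(config.dbsnp_extra_density * length)
        for pos in _random_positions(rng, length, n):
            dbsnp.add(_random_snv(rng, seq, pos, chrom, config.titv_ratio))

    return Founders(
        reference=reference,
        chrom_lengths=dict(config.chrom_lengths),
        capture=capture,
        repeats=repeats,
        segdups=segdups,
        guides=guides,
        genotypes=genotypes,
        dbsnp_keys=dbsnp,
        indel_keys=sorted(indel_keys),
    )


# ---------------------------------------------------------------------------
# Offspring truth genotypes
# ---------------------------------------------------------------------------


def _transmit(
    rng: np.random.Generator, genotype: Mapping[VariantKey, float]
) -> set[VariantKey]:
    """One gamete: a heterozygous allele transmits with probability 1/2,
    a homozygous allele always."""
    out = set()
    for key in sorted(genotype):
        af = genotype[key]
        if af >= 1.0 or rng.random() < 0.5:
            out.add(key)
    return out


def _child_founder_alleles(
    rng: np.random.Generator,
    parent_a: Mapping[VariantKey, float],
    parent_b: Mapping[VariantKey, float],
) -> dict[VariantKey, float]:
    dosage: dict[VariantKey, int] = {}
    for key in _transmit(rng, parent_a):
        dosage[key] = dosage.get(key, 0) + 1
    for key in _transmit(rng, parent_b):
        dosage[key] = dosage.get(key, 0) + 1
    return {key: (0.5 if d == 1 else 1.0) for key, d in dosage.items()}


def _beta_trunc(rng: np.random.Generator, a: float, b: float,
                lo: float, hi: float) -> float:
    for _ in range(200):
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(rng.beta(a, b), lo), hi))


def _denovo_events(
    rng: np.random.Generator,
    config: SimConfig,
    founders: Founders,
    generation: str,
    taken: set[VariantKey],
) -> list[tuple[VariantKey, float]]:
    n = rng.poisson(config.denovo_mean)
    chroms = sorted(founders.chrom_lengths)
    weights = np.array([founders.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    events = []
    for _ in range(n):
        for _attempt in range(50):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            seq = founders.reference[chrom]
            pos = int(rng.integers(60, founders.chrom_lengths[chrom] - 60))
            if rng.random() < config.denovo_indel_fraction:
                key = _random_indel(rng, seq, pos, chrom,
                                    config.founder_del_fraction)
            else:
                key = _random_snv(rng, seq, pos, chrom, config.titv_ratio)
            if key not in taken:
                break
        taken.add(key)
        if generation == "F1":
            af = 0.5
        else:
            a, b = config.denovo_f0_af_beta
            af = _beta_trunc(rng, a, b, config.min_true_af, 1.0)
        events.append((key, af))
    return events


def _on_target_alleles(
    rng: np.random.Generator,
    config: SimConfig,
    founders: Founders,
    guide: GuideSpec,
    fixed_het: bool,
) -> list[tuple[VariantKey, float]]:
    """Allelic series of on-target edits (deletions at the cut locus)."""
    if fixed_het:
        key = _cut_site_deletion(founders, guide, del_len=4)
        return [(key, 0.5)]
    if rng.random() >= config.edit_prob[guide.efficiency]:
        return []
    n_alleles = int(rng.integers(1, 4))
    lengths = rng.choice(np.arange(1, 7), size=n_alleles, replace=False)
    a, b = config.mosaic_af_beta[guide.efficiency]
    alleles = []
    afs = []
    for del_len in lengths:
        key = _cut_site_deletion(founders, guide, del_len=int(del_len))
        afs.append(_beta_trunc(rng, a, b, config.min_true_af, 0.95))
        alleles.append(key)
    total = sum(afs)
    if total > 0.9:  # mosaic allele fractions of one locus cannot sum past 1
        afs = [af * 0.9 / total for af in afs]
    return list(zip(alleles, afs))


def _cut_site_deletion(
    founders: Founders, guide: GuideSpec, del_len: int
) -> VariantKey:
    chrom = guide.on_target.chrom
    seq = founders.reference[chrom]
    pos = guide.on_target.start + 16  # blunt cut ~3 bp upstream of the PAM
    ref = seq[pos : pos + 1 + del_len]
    alt = seq[pos]
    return left_normalize(seq, pos, ref, alt, chrom=chrom)


def _offtarget_events(
    rng: np.random.Generator,
    config: SimConfig,
    founders: Founders,
    guide: GuideSpec,
    generation: str,
    taken: set[VariantKey],
) -> list[tuple[VariantKey, float]]:
    if config.offtarget_rate <= 0 or not guide.offtargets:
        return []
    n = rng.poisson(config.offtarget_rate)
    events = []
    for _ in range(n):
        site = guide.offtargets[int(rng.integers(0, len(guide.offtargets)))]
        chrom = site.interval.chrom
        seq = founders.reference[chrom]
        pos = site.interval.start + 16
        del_len = int(rng.integers(1, 5))
        key = left_normalize(seq, pos, seq[pos : pos + 1 + del_len],
                             seq[pos], chrom=chrom)
        if key in taken:
            continue
        taken.add(key)
        if generation == "F1":
            af = 0.5
        else:
            a, b = config.mosaic_af_beta[guide.efficiency]
            af = _beta_trunc(rng, a, b, config.min_true_af, 0.95)
        events.append((key, af))
    return events


def build_cohort(config: SimConfig, guides: Sequence[GuideSpec]) -> Cohort:
    """The pedigree/sample sheet implied by the configuration."""
    samples = [
        Sample("founder_f", "parent", "uninjected"),
        Sample("founder_m", "parent", "uninjected"),
    ]
    founders = ("founder_f", "founder_m")
    if config.include_f0:
        for cond in sorted(config.f0_control_counts):
            for i in range(config.f0_control_counts[cond]):
                samples.append(
                    Sample(f"F0_{cond}_{i + 1}", "F0", cond, "", founders)
                )
        for guide in guides:
            for i in range(config.f0_sgrna_only_per_guide):
                samples.append(
                    Sample(f"F0_sgrna_{guide.guide_id}_{i + 1}", "F0",
                           "sgrna_only", guide.guide_id, founders)
                )
            for i in range(config.f0_edited_per_guide):
                samples.append(
                    Sample(f"F0_edited_{guide.guide_id}_{i + 1}", "F0",
                           "edited", guide.guide_id, founders)
                )
    if config.include_f1:
        trans_guide = _transmission_guide(guides)
        for cond in ("uninjected", "cas9_only", "sgrna_only", "edited"):
            gid = trans_guide.guide_id if cond in ("sgrna_only", "edited") else ""
            for i in range(config.f1_per_condition):
                samples.append(
                    Sample(f"F1_{cond}_{i + 1}", "F1", cond, gid, founders)
                )
    return Cohort(samples)


def _transmission_guide(guides: Sequence[GuideSpec]) -> GuideSpec:
    """The guide whose F0 arm was bred to produce F1 (a high-efficiency one)."""
    for g in guides:
        if g.efficiency == "high" and g.gene == "smchd1":
            return g
    for g in guides:
        if g.efficiency == "high":
            return g
    return guides[0]


def simulate_offspring(
    founders: Founders, config: SimConfig
) -> tuple[Cohort, dict[str, dict[VariantKey, TruthRecord]]]:
    """Generate truth genotypes for every cohort sample.

    F0 embryos inherit founder alleles directly; F1 embryos inherit through
    unsequenced F0 breeding adults of the matching condition (two adults per
    condition, themselves founder-derived).  De novo events arise in the
    generation in which they are counted; edited samples additionally carry
    on-target (and, at ``offtarget_rate``, off-target) edits.
    """
    cohort = build_cohort(config, founders.guides)
    guides_by_id = {g.guide_id: g for g in founders.guides}
    trans_guide = _transmission_guide(founders.guides)

    genotypes: dict[str, dict[VariantKey, TruthRecord]] = {
        fid: dict(sites) for fid, sites in founders.genotypes.items()
    }

    f_geno = {k: r.true_af for k, r in founders.genotypes["founder_f"].items()}
    m_geno = {k: r.true_af for k, r in founders.genotypes["founder_m"].items()}

    # unsequenced F0 adults bred per F1 condition (founder-derived genomes)
    adult_pairs: dict[str, list[dict[VariantKey, float]]] = {}
    if config.include_f1:
        for cond in ("uninjected", "cas9_only", "sgrna_only", "edited"):
            pair = []
            for j in range(2):
                rng = _rng(config.seed, "f0_adult", cond, j)
                pair.append(_child_founder_alleles(rng, f_geno, m_geno))
            adult_pairs[cond] = pair

    for sample in cohort:
        if sample.generation == "parent":
            continue
        rng = _rng(config.seed, "offspring", sample.sample_id)
        if sample.generation == "F0":
            alleles = _child_founder_alleles(rng, f_geno, m_geno)
        else:
            pa, pb = adult_pairs[sample.condition]
            alleles = _child_founder_alleles(rng, pa, pb)
        records: dict[VariantKey, TruthRecord] = {
            key: TruthRecord(sample.sample_id, key, "inherited", af)
            for key, af in alleles.items()
        }
        taken = set(records)
        for key, af in _denovo_events(rng, config, founders,
                                      sample.generation, taken):
            records[key] = TruthRecord(sample.sample_id, key, "denovo", af)
        if sample.condition == "edited":
            guide = guides_by_id[sample.guide_id]
            fixed_het = sample.generation == "F1" and guide is not None
            for key, af in _on_target_alleles(rng, config, founders, guide,
                                              fixed_het=fixed_het):
                records[key] = TruthRecord(sample.sample_id, key,
                                           "on_target", af)
            for key, af in _offtarget_events(rng, config, founders, guide,
                                             sample.generation, taken):
                records[key] = TruthRecord(sample.sample_id, key,
                                           "off_target", af)
        genotypes[sample.sample_id] = records
    return cohort, genotypes


# ---------------------------------------------------------------------------
# Pseudo-caller call sets
# ---------------------------------------------------------------------------


def _draw_depth(rng: np.random.Generator, mean: float, disp: float,
                size=None):
    """Negative-binomial depth around ``mean``; ``disp <= 0`` means a
    constant depth (useful for calibration against fixed-depth models)."""
    if disp <= 0:
        value = int(round(mean))
        return value if size is None else np.full(size, value, dtype=np.int64)
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=size)


def _detect_true_variant(
    rng: np.random.Generator, profile: CallerProfile, record: TruthRecord,
    mean_depth: float,
) -> Optional[VariantCall]:
    depth = int(_draw_depth(rng, mean_depth, profile.depth_dispersion))
    if depth < max(1, profile.min_coverage):
        return None
    alt = int(rng.binomial(depth, record.true_af))
    if alt < max(1, profile.min_alt_reads):
        return None
    if profile.min_af > 0 and alt / depth <= profile.min_af:
        return None
    if (
        profile.sensitivity_floor_af > 0
        and record.true_af < profile.sensitivity_floor_af
        and rng.random() >= record.true_af / profile.sensitivity_floor_af
    ):
        return None
    fwd = int(rng.binomial(alt, 0.5))
    return VariantCall(
        key=record.key,
        sample_id=record.sample_id,
        caller_id=profile.caller_id,
        depth=depth,
        alt_depth=alt,
        af=alt / depth,
        alt_fwd=fwd,
        alt_rev=alt - fwd,
    )


def _error_fp_calls(
    rng: np.random.Generator,
    profile: CallerProfile,
    founders: Founders,
    sample_id: str,
    mean_depth: float,
    existing: set[VariantKey],
) -> tuple[list[VariantCall], list[TruthRecord]]:
    """Sequencing-error false positives: per base, alt reads ~
    Binomial(depth, error_rate); a call is emitted when the caller's alt-read
    and AF thresholds are met."""
    if profile.error_rate <= 0:
        return [], []
    calls, truth = [], []
    thr = max(1, profile.min_alt_reads)
    for chrom in sorted(founders.chrom_lengths):
        length = founders.chrom_lengths[chrom]
        seq = founders.reference[chrom]
        depths = _draw_depth(rng, mean_depth, profile.depth_dispersion,
                             size=length)
        errs = rng.binomial(depths, profile.error_rate)
        mask = (
            (errs >= thr)
            & (depths >= profile.min_coverage)
            & (errs > depths * profile.min_af)
        )
        for pos in np.nonzero(mask)[0]:
            pos = int(pos)
            ref = seq[pos]
            alt_base = _TRANSVERSIONS[ref][int(rng.integers(0, 2))] \
                if rng.random() < 0.5 else _TRANSITION[ref]
            key = VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt_base)
            if key in existing:
                continue
            depth, alt = int(depths[pos]), int(errs[pos])
            fwd = int(rng.binomial(alt, 0.5))
            calls.append(
                VariantCall(key=key, sample_id=sample_id,
                            caller_id=profile.caller_id, depth=depth,
                            alt_depth=alt, af=alt / depth,
                            alt_fwd=fwd, alt_rev=alt - fwd)
            )
            truth.append(TruthRecord(sample_id, key, "fp_error", 0.0,
                                     caller_id=profile.caller_id))
    return calls, truth


def _artifact_call(
    rng: np.random.Generator,
    profile: CallerProfile,
    config: SimConfig,
    key: VariantKey,
    sample_id: str,
    mean_depth: float,
) -> Optional[VariantCall]:
    depth = int(_draw_depth(rng, mean_depth, profile.depth_dispersion))
    if depth < max(1, profile.min_coverage):
        return None
    a, b = config.artifact_af_beta
    af = _beta_trunc(rng, a, b, 0.08, 0.9)
    alt = max(profile.min_alt_reads, int(round(af * depth)))
    alt = min(alt, depth)
    if alt < 1:
        return None
    fwd = int(rng.binomial(alt, 0.5))
    return VariantCall(key=key, sample_id=sample_id,
                       caller_id=profile.caller_id, depth=depth,
                       alt_depth=alt, af=alt / depth,
                       alt_fwd=fwd, alt_rev=alt - fwd)


def _indel_artifact_calls(
    rng: np.random.Generator,
    profile: CallerProfile,
    config: SimConfig,
    founders: Founders,
    sample_id: str,
    mean_depth: float,
    existing: set[VariantKey],
) -> tuple[list[VariantCall], list[TruthRecord]]:
    """The two indel-adjacent artifact classes.

    Gap-fill: reads fill into a small founder deletion instead of extending
    the gap, yielding spurious SNV calls within a few bp of the deletion.
    Misrealignment: a founder deletion is re-placed in the offspring as a
    similar but non-equivalent deletion nearby.
    """
    del_keys = [k for k in founders.indel_keys if len(k.ref) > len(k.alt)]
    if not del_keys:
        return [], []
    calls, truth = [], []

    n_fill = rng.poisson(profile.fp_indel_fill_rate)
    for _ in range(n_fill):
        base = del_keys[int(rng.integers(0, len(del_keys)))]
        seq = founders.reference[base.chrom]
        offset = int(rng.integers(1, config.fp_flank_bp + 1))
        if rng.random() < 0.5:
            offset = -offset
        pos = min(max(1, base.pos + offset), len(seq) - 2)
        key = _random_snv(rng, seq, pos, base.chrom, config.titv_ratio)
        if key in existing:
            continue
        call = _artifact_call(rng, profile, config, key, sample_id, mean_depth)
        if call is not None:
            calls.append(call)
            truth.append(TruthRecord(sample_id, key, "fp_indel_fill", 0.0,
                                     caller_id=profile.caller_id))

    n_realign = rng.poisson(profile.fp_realign_rate)
    for _ in range(n_realign):
        base = del_keys[int(rng.integers(0, len(del_keys)))]
        seq = founders.reference[base.chrom]
        base_len = len(base.ref) - len(base.alt)
        for _attempt in range(10):
            shift = int(rng.integers(1, 4))
            del_len = max(1, base_len + int(rng.integers(-1, 2)))
            pos = min(base.pos + shift, len(seq) - del_len - 2)
            key = left_normalize(seq, pos, seq[pos : pos + 1 + del_len],
                                 seq[pos], chrom=base.chrom)
            if key != base and key not in existing:
                break
        else:
            continue
        call = _artifact_call(rng, profile, config, key, sample_id, mean_depth)
        if call is not None:
            calls.append(call)
            truth.append(TruthRecord(sample_id, key, "fp_realign", 0.0,
                                     caller_id=profile.caller_id))
    return calls, truth


def _cross_noise_plan(
    config: SimConfig, founders: Founders, cohort: Cohort
) -> list[tuple[VariantKey, float, list[str]]]:
    """Systematic noise sites shared across samples and callers.

    Each site is emitted in >= 2 samples; the site list is drawn once per
    simulation so both callers report the same sites (with independent depth
    draws)."""
    n_sites = max((p.cross_noise_sites for p in config.profiles), default=0)
    offspring = [s.sample_id for s in cohort if s.generation != "parent"]
    if n_sites <= 0 or len(offspring) < 2:
        return []
    rng = _rng(config.seed, "cross_noise")
    chroms = sorted(founders.chrom_lengths)
    lo, hi = config.cross_noise_af_range
    plan = []
    for _ in range(n_sites):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = founders.reference[chrom]
        pos = int(rng.integers(60, founders.chrom_lengths[chrom] - 60))
        key = _random_snv(rng, seq, pos, chrom, config.titv_ratio)
        af = float(rng.uniform(lo, hi))
        n_carriers = 2 + int(rng.binomial(len(offspring) - 2, 0.05))
        carriers = sorted(
            rng.choice(offspring, size=n_carriers, replace=False).tolist()
        )
        plan.append((key, af, carriers))
    return plan


def simulate_caller_calls(
    genotypes: Mapping[str, Mapping[VariantKey, TruthRecord]],
    profile: CallerProfile,
    founders: Founders,
    config: SimConfig,
    cohort: Cohort,
    cross_noise: Sequence[tuple[VariantKey, float, list[str]]] = (),
) -> tuple[dict[str, list[VariantCall]], list[TruthRecord]]:
    """Emit one caller's call set over the whole cohort, plus FP truth."""
    calls: dict[str, list[VariantCall]] = {}
    fp_truth: list[TruthRecord] = []
    noise_by_sample: dict[str, list[tuple[VariantKey, float]]] = {}
    for key, af, carriers in cross_noise:
        for sid in carriers:
            noise_by_sample.setdefault(sid, []).append((key, af))

    for sample in cohort:
        sid = sample.sample_id
        rng = _rng(config.seed, "caller", profile.caller_id, sid)
        mean_depth = profile.mean_depth(sample.generation)
        sample_calls: list[VariantCall] = []
        truth_here = genotypes.get(sid, {})
        for key in sorted(truth_here):
            call = _detect_true_variant(rng, profile, truth_here[key],
                                        mean_depth)
            if call is not None:
                sample_calls.append(call)
        existing = set(truth_here)
        err_calls, err_truth = _error_fp_calls(
            rng, profile, founders, sid, mean_depth, existing
        )
        sample_calls.extend(err_calls)
        fp_truth.extend(err_truth)
        existing.update(c.key for c in err_calls)
        if sample.generation != "parent":
            art_calls, art_truth = _indel_artifact_calls(
                rng, profile, config, founders, sid, mean_depth, existing
            )
            sample_calls.extend(art_calls)
            fp_truth.extend(art_truth)
            existing.update(c.key for c in art_calls)
            for key, af in noise_by_sample.get(sid, ()):
                if key in existing:
                    continue
                depth = int(_draw_depth(rng, mean_depth,
                                        profile.depth_dispersion))
                if depth < max(1, profile.min_coverage):
                    continue
                alt = int(rng.binomial(depth, af))
                if alt < max(1, profile.min_alt_reads):
                    continue
                fwd = int(rng.binomial(alt, 0.5))
                sample_calls.append(
                    VariantCall(key=key, sample_id=sid,
                                caller_id=profile.caller_id, depth=depth,
                                alt_depth=alt, af=alt / depth,
                                alt_fwd=fwd, alt_rev=alt - fwd)
                )
        calls[sid] = sample_calls
    return calls, fp_truth


# ---------------------------------------------------------------------------
# Full simulation + fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    config: SimConfig
    founders: Founders
    cohort: Cohort
    genotypes: dict[str, dict[VariantKey, TruthRecord]]
    calls: dict[str, dict[str, list[VariantCall]]]  # caller -> sample -> calls
    fp_truth: list[TruthRecord]
    cross_noise: list[tuple[VariantKey, float, list[str]]]

    @property
    def reference(self) -> dict[str, str]:
        return self.founders.reference

    @property
    def truth(self) -> list[TruthRecord]:
        out = [rec for sid in sorted(self.genotypes)
               for rec in self.genotypes[sid].values()]
        out.extend(self.fp_truth)
        # cross-noise truth: one record per carrier (shared across callers)
        for key, af, carriers in self.cross_noise:
            out.extend(
                TruthRecord(sid, key, "fp_cross_noise", af) for sid in carriers
            )
        return out

    def truth_counts(self, origin: str) -> dict[str, int]:
        counts = {s.sample_id: 0 for s in self.cohort}
        for rec in self.truth:
            if rec.origin == origin and rec.sample_id in counts:
                counts[rec.sample_id] += 1
        return counts

    @property
    def on_target_set(self) -> IntervalSet:
        return IntervalSet(g.on_target for g in self.founders.guides)

    @property
    def offtarget_sites(self) -> list[OffTargetSite]:
        return [s for g in self.founders.guides for s in g.offtargets]

    def parental_keys(self) -> set[VariantKey]:
        """Keys with call support in either parent from either caller."""
        keys = set()
        for by_sample in self.calls.values():
            for fid in ("founder_f", "founder_m"):
                keys.update(c.key for c in by_sample.get(fid, ()))
        return keys

    def parental_indel_keys(self) -> set[VariantKey]:
        return {k for k in self.founders.indel_keys}


def simulate(config: SimConfig) -> SimulatedCohort:
    """Run the full simulation: founders -> offspring -> both callers."""
    founders = simulate_founders(config)
    cohort, genotypes = simulate_offspring(founders, config)
    cross_noise = _cross_noise_plan(config, founders, cohort)
    calls: dict[str, dict[str, list[VariantCall]]] = {}
    fp_truth: list[TruthRecord] = []
    for profile in config.profiles:
        caller_calls, caller_fp = simulate_caller_calls(
            genotypes, profile, founders, config, cohort, cross_noise
        )
        calls[profile.caller_id] = caller_calls
        fp_truth.extend(caller_fp)
    return SimulatedCohort(
        config=config,
        founders=founders,
        cohort=cohort,
        genotypes=genotypes,
        calls=calls,
        fp_truth=fp_truth,
        cross_noise=cross_noise,
    )


def write_fixture_bundle(sim: SimulatedCohort, outdir: str | Path) -> Path:
    """Write the simulation as the on-disk formats the pipeline reads.

    Per-sample-per-caller VCFs, reference FASTA, region BEDs, off-target
    BED6 (+ engine sidecar), sample sheet, known-variant VCF, truth table
    TSV and the configuration used.  Re-running with the same seed produces
    a byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = sim.founders.chrom_lengths

    write_fasta(sim.reference, outdir / "reference.fa")
    write_bed(sim.founders.capture, outdir / "capture.bed")
    write_bed(sim.founders.repeats, outdir / "repeats.bed")
    write_bed(sim.founders.segdups, outdir / "segdups.bed")
    write_bed_records(
        [
            BedRecord(g.on_target.chrom, g.on_target.start, g.on_target.end,
                      name=g.guide_id)
            for g in sorted(sim.founders.guides, key=lambda g: g.guide_id)
        ],
        outdir / "on_target.bed",
    )
    write_offtarget_bed(sim.offtarget_sites, outdir / "off_target.bed")
    with open(outdir / "off_target_engines.tsv", "w") as fh:
        fh.write("chrom\tstart\tengines\n")
        for s in sorted(sim.offtarget_sites,
                        key=lambda s: (s.interval.chrom, s.interval.start)):
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t"
                     f"{','.join(sorted(s.predicted_by))}\n")
    write_sample_sheet(sim.cohort, outdir / "sample_sheet.tsv")
    write_key_vcf(sim.founders.dbsnp_keys, outdir / "known_variants.vcf",
                  contigs)

    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for caller_id in sorted(sim.calls):
        for sid in sorted(sim.calls[caller_id]):
            write_vcf(sim.calls[caller_id][sid],
                      calls_dir / f"{sid}.{caller_id}.vcf",
                      contigs, sample_id=sid)

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample_id\tcaller_id\tchrom\tpos\tref\talt\torigin\ttrue_af\n")
        rows = sorted(
            sim.truth,
            key=lambda r: (r.sample_id, r.caller_id, r.key.chrom, r.key.pos,
                           r.key.ref, r.key.alt, r.origin),
        )
        for r in rows:
            fh.write(
                f"{r.sample_id}\t{r.caller_id}\t{r.key.chrom}\t{r.key.pos}\t"
                f"{r.key.ref}\t{r.key.alt}\t{r.origin}\t{r.true_af:.6g}\n"
            )

    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(sim_config_to_dict(sim.config), fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def sim_config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["profiles"] = [dataclasses.asdict(p) for p in config.profiles]
    if config.guides is not None:
        d["guides"] = [
            {
                "guide_id": g.guide_id,
                "gene": g.gene,
                "efficiency": g.efficiency,
                "on_target": [g.on_target.chrom, g.on_target.start,
                              g.on_target.end],
                "offtargets": [
                    {
                        "interval": [s.interval.chrom, s.interval.start,
                                     s.interval.end],
                        "cfd_score": s.cfd_score,
                        "predicted_by": sorted(s.predicted_by),
                    }
                    for s in g.offtargets
                ],
            }
            for g in config.guides
        ]
    # tuples -> lists for YAML friendliness
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    d["mosaic_af_beta"] = {k: list(v) for k, v in d["mosaic_af_beta"].items()}
    return d


def sim_config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if d.get("profiles"):
        d["profiles"] = [CallerProfile(**p) for p in d["profiles"]]
    if d.get("guides"):
        guides = []
        for g in d["guides"]:
            offtargets = [
                OffTargetSite(
                    interval=GenomicInterval(*s["interval"]),
                    guide_id=g["guide_id"],
                    cfd_score=s["cfd_score"],
                    predicted_by=frozenset(s["predicted_by"]),
                )
                for s in g.get("offtargets", ())
            ]
            guides.append(
                GuideSpec(
                    guide_id=g["guide_id"],
                    gene=g["gene"],
                    efficiency=g["efficiency"],
                    on_target=GenomicInterval(*g["on_target"]),
                    offtargets=offtargets,
                )
            )
        d["guides"] = guides
    for key in ("denovo_f0_af_beta", "artifact_af_beta", "cross_noise_af_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "mosaic_af_beta" in d and d["mosaic_af_beta"] is not None:
        d["mosaic_af_beta"] = {k: tuple(v) for k, v in d["mosaic_af_beta"].items()}
    return SimConfig(**d)
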