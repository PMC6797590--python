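"""Core data types and I/O shared by every pipeline stage.

Conventions
-----------
* All coordinates are 0-based half-open internally; conversion to/from the
  1-based VCF convention happens only inside :func:`read_vcf` /
  :func:`write_vcf`.
* Variant identity across samples and callers is the left-normalized
  ``(chrom, pos, ref, alt)`` tuple (:class:`VariantKey`); position-only
  matching is deliberately not supported.
* Chromosome names are compared literally (no ``chr`` stripping).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Injection-condition tokens accepted in sample sheets.
CONDITIONS = ("uninjected", "cas9_only", "sgrna_only", "edited")
GENERATIONS = ("parent", "F0", "F1")

#: Transition substitution pairs (purine<->purine, pyrimidine<->pyrimidine).
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Left-normalized variant identity: ``(chrom, pos, ref, alt)``.

    ``pos`` is the 0-based position of the first reference base of ``ref``.
    Keys should be produced via :func:`left_normalize` so that the two
    callers' representations of the same indel compare equal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        bad = (set(self.ref) | set(self.alt)) - VALID_BASES
        if bad:
            raise ValueError(f"alleles restricted to ACGT, got {sorted(bad)}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_transition(self) -> bool:
        return self.is_snv and (self.ref, self.alt) in TRANSITIONS

    @property
    def interval(self) -> GenomicInterval:
        """Reference footprint ``[pos, pos + len(ref))``."""
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.ref))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample from one caller."""

    key: VariantKey
    sample_id: str
    caller_id: str
    depth: int
    alt_depth: int
    af: float
    alt_fwd: Optional[int] = None  # None = strand evidence unknown
    alt_rev: Optional[int] = None
    suspect: bool = False  # set by rule-based artifact flagging

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"need 0 <= alt_depth <= depth, got {self.alt_depth}/{self.depth}"
            )
        if not (0.0 < self.af <= 1.0):
            raise ValueError(f"af must be in (0, 1], got {self.af}")
        if (self.alt_fwd is None) != (self.alt_rev is None):
            raise ValueError("alt_fwd and alt_rev must be both set or both unknown")
        if self.alt_fwd is not None and self.alt_fwd + self.alt_rev != self.alt_depth:
            raise ValueError("alt_fwd + alt_rev must equal alt_depth")

    @property
    def strand_known(self) -> bool:
        return self.alt_fwd is not None

    @property
    def both_strands(self) -> Optional[bool]:
        """True/False if strand counts are known, else None (rules abstain)."""
        if not self.strand_known:
            return None
        return self.alt_fwd > 0 and self.alt_rev > 0


class BedRecord(NamedTuple):
    """A raw BED line; name/score/strand retained when columns are present."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None


class IntervalSet:
    """Merged, per-chromosome interval collection (0-based half-open).

    Overlapping or abutting intervals are merged on construction, so the
    stored representation is canonical: ``total_bp`` is the exact number of
    distinct covered bases.  Raw BED records (with name/score columns) are
    preserved on ``records`` when the set was read from a BED file.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        records: Optional[Sequence[BedRecord]] = None,
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)  # merge abutting too
        self.records: list[BedRecord] = list(records or [])

    # -- queries ----------------------------------------------------------

    @property
    def total_bp(self) -> int:
        return sum(iv.end - iv.begin for t in self._trees.values() for iv in t)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append(GenomicInterval(chrom, iv.begin, iv.end))
        return out

    def overlaps(self, chrom: str, start: int, end: Optional[int] = None) -> bool:
        """True iff ``chrom:[start, end)`` overlaps any stored interval."""
        if end is None:
            end = start + 1
        tree = self._trees.get(chrom)
        return bool(tree and tree.overlap(start, end))

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return self.overlaps(iv.chrom, iv.start, iv.end)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals() == other.intervals()

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    # -- set arithmetic ---------------------------------------------------

    def expand(
        self, flank: int, chrom_lengths: Optional[Mapping[str, int]] = None
    ) -> "IntervalSet":
        """Widen every interval by ``flank`` bp on both sides (clipped)."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        out = []
        for iv in self.intervals():
            start = max(0, iv.start - flank)
            end = iv.end + flank
            if chrom_lengths is not None and iv.chrom in chrom_lengths:
                end = min(end, chrom_lengths[iv.chrom])
            if end > start:
                out.append(GenomicInterval(iv.chrom, start, end))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for chrom, tree in self._trees.items():
            other_tree = other._trees.get(chrom)
            if not other_tree:
                continue
            for iv in sorted(tree):
                for ov in other_tree.overlap(iv.begin, iv.end):
                    out.append(
                        GenomicInterval(
                            chrom, max(iv.begin, ov.begin), min(iv.end, ov.end)
                        )
                    )
        return IntervalSet(out)


# ---------------------------------------------------------------------------
# Cohort / sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    sample_id: str
    generation: str  # parent | F0 | F1
    condition: str  # uninjected | cas9_only | sgrna_only | edited
    guide_id: str = ""  # empty for controls without a guide
    parent_ids: tuple[str, ...] = ()


@dataclass
class Cohort:
    """A validated pedigree of parents, F0 and F1 samples."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.generation not in GENERATIONS:
                raise ValueError(
                    f"{s.sample_id}: unknown generation {s.generation!r}"
                )
            if s.condition not in CONDITIONS:
                raise ValueError(
                    f"{s.sample_id}: unknown condition {s.condition!r}"
                )
            if s.condition == "edited" and not s.guide_id:
                raise ValueError(f"{s.sample_id}: condition 'edited' needs a guide_id")
        by_id = {s.sample_id: s for s in self.samples}
        for s in self.samples:
            for pid in s.parent_ids:
                parent = by_id.get(pid)
                if parent is None:
                    raise ValueError(
                        f"{s.sample_id}: dangling parent reference {pid!r}"
                    )
                if s.generation == "F0" and parent.generation != "parent":
                    raise ValueError(f"{s.sample_id}: F0 must link to founders")
                if s.generation == "F1" and parent.generation not in ("parent", "F0"):
                    raise ValueError(
                        f"{s.sample_id}: F1 must link to F0 or founder parents"
                    )
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    def generation(self, gen: str) -> list[Sample]:
        return [s for s in self.samples if s.generation == gen]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def guide_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].guide_id

    def condition_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].condition


SHEET_COLUMNS = ["sample_id", "generation", "condition", "guide_id", "parent_ids"]


def read_sample_sheet(path: str | Path) -> Cohort:
    """Read a TSV sample sheet into a validated :class:`Cohort`.

    Required columns: sample_id, generation, condition, guide_id, parent_ids
    (comma-separated; empty for founders).
    """
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing sample sheet columns {sorted(missing)}")
        for row in reader:
            parent_ids = tuple(
                p for p in (row["parent_ids"] or "").split(",") if p.strip()
            )
            samples.append(
                Sample(
                    sample_id=row["sample_id"].strip(),
                    generation=row["generation"].strip(),
                    condition=row["condition"].strip(),
                    guide_id=(row["guide_id"] or "").strip(),
                    parent_ids=parent_ids,
                )
            )
    return Cohort(samples)


def write_sample_sheet(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SHEET_COLUMNS)
        for s in cohort:
            writer.writerow(
                [s.sample_id, s.generation, s.condition, s.guide_id,
                 ",".join(s.parent_ids)]
            )


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------


def left_normalize(
    context: Optional[str],
    pos: int,
    ref: str,
    alt: str,
    chrom: str = "",
) -> VariantKey:
    """Produce the canonical left-normalized :class:`VariantKey`.

    Shared trailing then leading bases are trimmed (keeping at least one base
    per allele), and indels are shifted to the leftmost position at which the
    *same* allele strings produce an identical edited sequence.  SNVs are
    returned unchanged.  ``context`` is the chromosome sequence (0-based,
    aligned with ``pos``); when ``None``, trimming is performed but the
    left-shift step is skipped (no reference available).
    """
    ref = ref.upper()
    alt = alt.upper()
    if context is not None and context[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"ref {ref!r} does not match reference context at pos {pos} "
            f"(found {context[pos:pos + len(ref)]!r})"
        )
    # trim shared trailing bases, keeping both alleles non-empty
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if context is not None and len(ref) != len(alt):
        # shift the (fixed) allele strings to the leftmost equivalent
        # placement: p is equivalent to the current best placement iff the
        # edited sequences agree, i.e.
        #   alt + context[p+len(ref):best+len(ref)] == context[p:best] + alt.
        # Equivalent placements in a periodic context are at most
        # max(len(ref), len(alt)) apart, which bounds the scan.
        lr = len(ref)
        gap_bound = max(lr, len(alt))
        best = pos
        p = pos - 1
        misses = 0
        while p >= 0 and misses < gap_bound:
            if (
                context[p : p + lr] == ref
                and alt + context[p + lr : best + lr] == context[p:best] + alt
            ):
                best = p
                misses = 0
            else:
                misses += 1
            p -= 1
        pos = best
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# VCF I/O (single-sample dialect: FORMAT DP, AD; optional SAF/SAR)
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path,
    sample_id: Optional[str] = None,
    caller_id: str = "",
    reference: Optional[Mapping[str, str]] = None,
) -> list[VariantCall]:
    """Read a single-sample VCF into :class:`VariantCall` records.

    One record is emitted per ALT allele.  Coordinates are converted from the
    1-based VCF convention to 0-based, and alleles are left-normalized
    (against ``reference`` when given, otherwise trim-only).  Records missing
    DP/AD, with zero depth, or with non-ACGT alleles are rejected with a
    logged warning; a malformed header fails the parse.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    names = list(vf.header.samples)
    if sample_id is None:
        sample_id = names[0] if names else Path(path).stem
    calls: list[VariantCall] = []
    for rec in vf:
        if not names:
            log.warning("%s: record at %s:%s has no sample column; rejected",
                        path, rec.chrom, rec.pos)
            continue
        fmt = rec.samples[names[0]]
        depth = fmt.get("DP")
        ad = fmt.get("AD")
        if depth is None or ad is None:
            log.warning("%s: record at %s:%s missing DP/AD; rejected",
                        path, rec.chrom, rec.pos)
            continue
        if not depth:
            log.warning("%s: record at %s:%s has zero depth; rejected",
                        path, rec.chrom, rec.pos)
            continue
        alts = rec.alts or ()
        saf = fmt.get("SAF")
        sar = fmt.get("SAR")
        for i, alt in enumerate(alts):
            if alt is None:
                continue
            alleles_ok = set(rec.ref.upper()) | set(alt.upper()) <= VALID_BASES
            if not alleles_ok:
                log.warning("%s: non-ACGT alleles at %s:%s (%s>%s); rejected",
                            path, rec.chrom, rec.pos, rec.ref, alt)
                continue
            alt_depth = ad[i + 1] if len(ad) > i + 1 else None
            if not alt_depth:
                continue  # reference-only or missing support for this allele
            ctx = reference.get(rec.chrom) if reference is not None else None
            key = left_normalize(ctx, rec.pos - 1, rec.ref, alt, chrom=rec.chrom)
            fwd = rev = None
            if saf is not None and sar is not None:
                f = saf[i] if isinstance(saf, tuple) else saf
                r = sar[i] if isinstance(sar, tuple) else sar
                if f is not None and r is not None:
                    fwd, rev = int(f), int(r)
            calls.append(
                VariantCall(
                    key=key,
                    sample_id=sample_id,
                    caller_id=caller_id,
                    depth=int(depth),
                    alt_depth=int(alt_depth),
                    af=int(alt_depth) / int(depth),
                    alt_fwd=fwd,
                    alt_rev=rev,
                )
            )
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=SAF,Number=A,Type=Integer,Description="Alt reads on forward strand">
##FORMAT=<ID=SAR,Number=A,Type=Integer,Description="Alt reads on reverse strand">
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: Mapping[str, int],
    sample_id: Optional[str] = None,
) -> None:
    """Write calls as a single-sample VCF v4.2 (one record per call)."""
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "sample"
    order = {c: i for i, c in enumerate(contigs)}
    rows = sorted(calls, key=lambda c: (order.get(c.key.chrom, 1 << 30),
                                        c.key.chrom, c.key.pos, c.key.ref, c.key.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for c in rows:
            if c.strand_known:
                strand = f":{c.alt_fwd}:{c.alt_rev}"
                fmt = "DP:AD:SAF:SAR"
            else:
                strand = ""
                fmt = "DP:AD"
            ref_depth = c.depth - c.alt_depth
            fh.write(
                f"{c.key.chrom}\t{c.key.pos + 1}\t.\t{c.key.ref}\t{c.key.alt}"
                f"\t.\tPASS\t.\t{fmt}\t{c.depth}:{ref_depth},{c.alt_depth}"
                f"{strand}\n"
            )


def read_key_vcf(path: str | Path) -> set[VariantKey]:
    """Read a sites-only VCF (e.g. a dbSNP-like known-variant file) as keys."""
    vf = pysam.VariantFile(str(path))
    keys: set[VariantKey] = set()
    for rec in vf:
        for alt in rec.alts or ():
            if alt is None:
                continue
            if not (set(rec.ref.upper()) | set(alt.upper()) <= VALID_BASES):
                continue
            keys.add(left_normalize(None, rec.pos - 1, rec.ref, alt,
                                    chrom=rec.chrom))
    return keys


def write_key_vcf(
    keys: Iterable[VariantKey], path: str | Path, contigs: Mapping[str, int]
) -> None:
    order = {c: i for i, c in enumerate(contigs)}
    rows = sorted(keys, key=lambda k: (order.get(k.chrom, 1 << 30),
                                       k.chrom, k.pos, k.ref, k.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k in rows:
            fh.write(f"{k.chrom}\t{k.pos + 1}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file into a merged :class:`IntervalSet`.

    Extra columns (name, score, strand) are preserved on ``.records``.
    A line with end <= start fails with its line number.
    """
    intervals: list[GenomicInterval] = []
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path} line {lineno}: expected >= 3 columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(
                    f"{path} line {lineno}: end ({end}) <= start ({start})"
                )
            intervals.append(GenomicInterval(chrom, start, end))
            if len(cols) > 3:
                records.append(
                    BedRecord(
                        chrom,
                        start,
                        end,
                        name=cols[3] if len(cols) > 3 else None,
                        score=float(cols[4]) if len(cols) > 4 and cols[4] != "."
                        else None,
                        strand=cols[5] if len(cols) > 5 else None,
                    )
                )
    return IntervalSet(intervals, records=records)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write the merged intervals as BED3 (canonical form; round-trips)."""
    with open(path, "w") as fh:
        for iv in iset.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bed_records(records: Sequence[BedRecord], path: str | Path) -> None:
    """Write BED6 rows preserving name/score/strand columns."""
    with open(path, "w") as fh:
        for r in records:
            name = r.name if r.name is not None else "."
            score = f"{r.score:g}" if r.score is not None else "."
            strand = r.strand if r.strand is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA I/O (reference context for normalization and repeat-context rules)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
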