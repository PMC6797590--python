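"""Pipeline orchestration: simulate/load -> filter -> burden -> off-target.

One :func:`run_all` call executes the whole analysis reproducibly and
returns a consolidated report (also written as JSON when an output
directory is configured): per-stage filter accounting, burden comparisons
at AF thresholds {0.3, 0.1, none}, per-caller and dual-caller-consensus
count panels, the off-target window triage, enrichment p-values under the
high/low error-rate bracket, and (for simulations) truth-vs-called
confusion counts.  Every run records the seed and a hash of its
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from offtarget_burden import burden_stats, cohortsim, denovo_filter
from offtarget_burden import offtarget_model as otm
from offtarget_burden.cohortsim import SimConfig, SimulatedCohort
from offtarget_burden.denovo_filter import (
    FilterConfig,
    FilterReport,
    FilterResources,
    run_cascade,
)
from offtarget_burden.vario import (
    Cohort,
    IntervalSet,
    VariantCall,
    VariantKey,
    read_bed,
    read_fasta,
    read_key_vcf,
    read_sample_sheet,
    read_vcf,
)

log = logging.getLogger(__name__)

AF_THRESHOLDS: tuple[Optional[float], ...] = (0.3, 0.1, None)


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class InputPaths:
    """File inputs for a run on real (non-simulated) call sets."""

    calls_dir: str
    sample_sheet: str
    known_vcf: str
    repeats_bed: str
    segdups_bed: str
    on_target_bed: str
    offtarget_bed: str
    capture_bed: str
    reference_fasta: Optional[str] = None
    offtarget_engines_tsv: Optional[str] = None


@dataclass
class RunConfig:
    """Either a simulation block or a complete set of real-input paths."""

    sim: Optional[SimConfig] = None
    inputs: Optional[InputPaths] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha_family: float = 0.05
    offtarget_flank: int = 100
    error_rates: tuple[float, float] = (0.0024, 0.001)
    error_model_depth: int = 76
    min_alt_reads: int = 4
    min_af: float = 0.05
    seed: Optional[int] = None  # overrides sim.seed when given
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sim is None and self.inputs is None:
            raise ValueError("need either a simulation block or input paths")


@dataclass
class PipelineInputs:
    """In-memory view of one cohort's calls plus filter resources."""

    cohort: Cohort
    calls: dict[str, dict[str, list[VariantCall]]]  # caller -> sample -> calls
    resources: FilterResources
    capture: IntervalSet
    capture_bp: int
    chrom_lengths: Mapping[str, int]
    offtarget_sites: Sequence[otm.OffTargetSite]
    sim: Optional[SimulatedCohort] = None

    def offspring_calls(self) -> dict[str, dict[str, list[VariantCall]]]:
        parents = {s.sample_id for s in self.cohort if s.generation == "parent"}
        return {
            caller: {sid: calls for sid, calls in by_sample.items()
                     if sid not in parents}
            for caller, by_sample in self.calls.items()
        }


def inputs_from_simulation(sim: SimulatedCohort) -> PipelineInputs:
    resources = FilterResources(
        parental_keys=sim.parental_keys(),
        known_keys=set(sim.founders.dbsnp_keys),
        on_target=sim.on_target_set,
        repeats=sim.founders.repeats,
        segdups=sim.founders.segdups,
        reference=sim.reference,
        parental_indel_keys=sim.parental_indel_keys(),
        chrom_lengths=sim.founders.chrom_lengths,
    )
    return PipelineInputs(
        cohort=sim.cohort,
        calls=sim.calls,
        resources=resources,
        capture=sim.founders.capture,
        capture_bp=sim.founders.capture.total_bp,
        chrom_lengths=sim.founders.chrom_lengths,
        offtarget_sites=sim.offtarget_sites,
        sim=sim,
    )


def load_real_inputs(paths: InputPaths) -> PipelineInputs:
    """Assemble :class:`PipelineInputs` from on-disk files.

    Call VCFs are discovered in ``calls_dir`` as ``{sample}.{caller}.vcf``.
    Parental exclusion keys and parental indels come from the call sets of
    parent-generation samples.
    """
    cohort = read_sample_sheet(paths.sample_sheet)
    reference = (
        read_fasta(paths.reference_fasta) if paths.reference_fasta else None
    )
    calls: dict[str, dict[str, list[VariantCall]]] = {}
    for vcf in sorted(Path(paths.calls_dir).glob("*.vcf")):
        stem = vcf.name[: -len(".vcf")]
        if "." not in stem:
            log.warning("skipping %s: expected {sample}.{caller}.vcf", vcf)
            continue
        sid, caller_id = stem.rsplit(".", 1)
        calls.setdefault(caller_id, {})[sid] = read_vcf(
            vcf, sample_id=sid, caller_id=caller_id, reference=reference
        )
    parents = [s.sample_id for s in cohort if s.generation == "parent"]
    parental_keys: set[VariantKey] = set()
    parental_indels: set[VariantKey] = set()
    for by_sample in calls.values():
        for pid in parents:
            for c in by_sample.get(pid, ()):
                parental_keys.add(c.key)
                if c.key.is_indel:
                    parental_indels.add(c.key)
    capture = read_bed(paths.capture_bed)
    chrom_lengths = {iv.chrom: iv.end for iv in capture}
    resources = FilterResources(
        parental_keys=parental_keys,
        known_keys=read_key_vcf(paths.known_vcf),
        on_target=read_bed(paths.on_target_bed),
        repeats=read_bed(paths.repeats_bed),
        segdups=read_bed(paths.segdups_bed),
        reference=reference,
        parental_indel_keys=parental_indels,
        chrom_lengths=chrom_lengths,
    )
    sites = otm.read_offtarget_bed(
        paths.offtarget_bed, paths.offtarget_engines_tsv
    )
    return PipelineInputs(
        cohort=cohort,
        calls=calls,
        resources=resources,
        capture=capture,
        capture_bp=capture.total_bp,
        chrom_lengths=chrom_lengths,
        offtarget_sites=sites,
        sim=None,
    )


# ---------------------------------------------------------------------------
# Sections
# ---------------------------------------------------------------------------


def _threshold_label(threshold: Optional[float]) -> str:
    return "none" if threshold is None else f"{threshold:g}"


def _burden_section(
    report: FilterReport,
    cohort: Cohort,
    alpha_family: float,
) -> dict:
    out: dict = {}
    counts_modes = {
        "predicted": burden_stats.count_denovo_per_sample(
            _as_report(report.final_by_caller[report.primary_caller], report),
            cohort, include_suspect=True,
        ),
        "reviewed": burden_stats.count_denovo_per_sample(
            _as_report(report.final_by_caller[report.primary_caller], report),
            cohort, include_suspect=False,
        ),
    }
    if report.consensus:
        counts_modes["consensus"] = burden_stats.count_denovo_per_sample(
            report, cohort, include_suspect=True,
        )
    out["counts"] = counts_modes
    out["comparisons"] = {}
    for generation in ("F0", "F1"):
        gen_samples = [s.sample_id for s in cohort
                       if s.generation == generation]
        if len(gen_samples) < 4:
            continue
        by_condition = burden_stats.condition_assignment(cohort, generation)
        two_group = burden_stats.control_vs_edited_assignment(cohort, generation)
        gen_out = {}
        for mode, counts in counts_modes.items():
            gen_counts = {sid: counts[sid] for sid in gen_samples
                          if sid in counts}
            comps = {}
            if len(set(by_condition[sid] for sid in gen_counts)) >= 2:
                comps["by_condition"] = burden_stats.compare_groups(
                    gen_counts, by_condition, alpha_family,
                    grouping=f"{generation}_condition",
                ).to_dict()
            if len(set(two_group[sid] for sid in gen_counts)) == 2:
                comps["control_vs_edited"] = burden_stats.compare_groups(
                    gen_counts, two_group, alpha_family,
                    grouping=f"{generation}_control_vs_edited",
                ).to_dict()
            gen_out[mode] = comps
        out["comparisons"][generation] = gen_out
    return out


def _as_report(final_calls: Mapping[str, list], base: FilterReport) -> FilterReport:
    """A lightweight FilterReport view over one caller's final call map."""
    return FilterReport(
        stages=[],
        final_by_caller={},
        final_calls=dict(final_calls),
        flagged=base.flagged,
        primary_caller=base.primary_caller,
        consensus=False,
    )


def _offtarget_section(
    inputs: PipelineInputs,
    run_config: RunConfig,
    primary: str,
    other: Optional[str],
) -> dict:
    # "Unfiltered" means before the downstream cascade; the callers are
    # trio-aware, so parental-supported keys are never candidate calls and
    # are excluded here as they would be at calling time.
    parental = inputs.resources.parental_keys
    offspring = {
        caller: {
            sid: denovo_filter.exclude_matching(calls, parental)
            for sid, calls in by_sample.items()
        }
        for caller, by_sample in inputs.offspring_calls().items()
    }
    primary_calls = offspring.get(primary, {})
    hits = otm.window_hits(
        primary_calls,
        inputs.offtarget_sites,
        flank=run_config.offtarget_flank,
        capture=inputs.capture,
        chrom_lengths=inputs.chrom_lengths,
    )
    other_calls = offspring.get(other, {}) if other else {}
    triage = otm.classify_hits(hits, inputs.cohort, primary_calls, other_calls)
    enrichment = otm.enrichment_by_scenario(
        hits,
        capture_bp=inputs.capture_bp,
        depth=run_config.error_model_depth,
        error_rates=run_config.error_rates,
        min_alt_reads=run_config.min_alt_reads,
        min_af=run_config.min_af,
    )
    # per-sample enrichment (each sample's own hit positions vs chance)
    per_sample = {}
    for sid in sorted(primary_calls):
        sample_hits = otm.window_hits(
            {sid: primary_calls[sid]},
            inputs.offtarget_sites,
            flank=run_config.offtarget_flank,
            capture=inputs.capture,
            chrom_lengths=inputs.chrom_lengths,
        )
        res = otm.enrichment_by_scenario(
            sample_hits,
            capture_bp=inputs.capture_bp,
            depth=run_config.error_model_depth,
            error_rates=run_config.error_rates[:1],
            min_alt_reads=run_config.min_alt_reads,
            min_af=run_config.min_af,
        )
        first = next(iter(res.values()))
        per_sample[sid] = {"observed": first.observed, "p_value": first.p_value}
    return {
        "flank": run_config.offtarget_flank,
        "n_sites": len(inputs.offtarget_sites),
        "window_bp": hits.window_bp,
        "n_hit_calls": len(hits.pairs),
        "n_distinct_positions": len(hits.distinct_positions),
        "triage_counts": otm.triage_counts(triage),
        "triage": [
            {
                "sample_id": t.hit.call.sample_id,
                "key": str(t.hit.call.key),
                "guide_id": t.hit.site.guide_id,
                "cfd_score": t.hit.site.cfd_score,
                "af": t.hit.call.af,
                "category": t.category,
            }
            for t in triage
        ],
        "enrichment": {
            label: dataclasses.asdict(res) for label, res in enrichment.items()
        },
        "per_sample_enrichment": per_sample,
    }


def _truth_section(sim: SimulatedCohort, report: FilterReport) -> dict:
    """Confusion counts of final calls against injected truth."""
    true_origins = ("denovo", "off_target")
    per_sample = {}
    tp = fp = fn = 0
    for sample in sim.cohort:
        sid = sample.sample_id
        if sample.generation == "parent":
            continue
        truth_keys = {
            k for k, rec in sim.genotypes.get(sid, {}).items()
            if rec.origin in true_origins
        }
        called = {c.key for c in report.final_calls.get(sid, ())}
        s_tp = len(called & truth_keys)
        s_fp = len(called - truth_keys)
        s_fn = len(truth_keys - called)
        per_sample[sid] = {"tp": s_tp, "fp": s_fp, "fn": s_fn}
        tp, fp, fn = tp + s_tp, fp + s_fp, fn + s_fn
    return {"total": {"tp": tp, "fp": fp, "fn": fn}, "per_sample": per_sample}


def make_figure2_table(
    report: FilterReport, cohort: Cohort
) -> pd.DataFrame:
    """Three-panel per-sample count table grouped by condition.

    Columns: ``predicted`` (primary caller), ``reviewed`` (primary caller
    with suspect-flagged calls excluded) and ``consensus`` (dual-caller
    subset; equal to predicted when the cascade ran without intersection).
    """
    primary_final = report.final_by_caller.get(report.primary_caller, {})
    rows = []
    for sample in cohort:
        if sample.generation == "parent":
            continue
        sid = sample.sample_id
        primary_calls = primary_final.get(sid, [])
        predicted = len(primary_calls)
        reviewed = sum(1 for c in primary_calls if not c.suspect)
        if report.consensus:
            consensus = len(report.final_calls.get(sid, []))
        else:
            consensus = predicted
        rows.append(
            {
                "sample_id": sid,
                "generation": sample.generation,
                "condition": sample.condition,
                "predicted": predicted,
                "reviewed": reviewed,
                "consensus": consensus,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["generation", "condition", "sample_id"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def config_hash(run_config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    payload = json.dumps(encode(run_config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@contextmanager
def _stage(name: str, out_dir: Optional[Path]):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        if out_dir is not None:
            failed = out_dir / "failed"
            failed.mkdir(parents=True, exist_ok=True)
            (failed / name).write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageFailure(name, exc) from exc


def run_all(run_config: RunConfig) -> dict:
    """Execute the full pipeline and return the consolidated report."""
    out_dir = Path(run_config.out_dir) if run_config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    seed = run_config.seed
    with _stage("inputs", out_dir):
        if run_config.sim is not None:
            sim_config = run_config.sim
            if seed is not None:
                sim_config = replace(sim_config, seed=seed)
            sim = cohortsim.simulate(sim_config)
            inputs = inputs_from_simulation(sim)
            seed = sim_config.seed
        else:
            inputs = load_real_inputs(run_config.inputs)
            sim = None

    caller_ids = sorted(inputs.calls)
    primary = run_config.filter.primary_caller or (
        "germline" if "germline" in inputs.calls else caller_ids[0]
    )
    other = next((c for c in caller_ids if c != primary), None)
    base_filter = replace(run_config.filter, primary_caller=primary)

    report: dict = {
        "meta": {
            "seed": seed,
            "config_hash": config_hash(run_config),
            "primary_caller": primary,
            "callers": caller_ids,
            "n_samples": len(inputs.cohort),
            "capture_bp": inputs.capture_bp,
        },
        "filter": {},
        "burden": {},
    }

    offspring = inputs.offspring_calls()
    reports_by_threshold: dict[str, FilterReport] = {}
    for threshold in AF_THRESHOLDS:
        label = _threshold_label(threshold)
        with _stage(f"filter_af_{label}", out_dir):
            fconfig = replace(base_filter, af_threshold=threshold)
            freport = run_cascade(offspring, inputs.resources, fconfig,
                                  cohort=inputs.cohort)
            reports_by_threshold[label] = freport
            report["filter"][label] = freport.to_dict()
        with _stage(f"burden_af_{label}", out_dir):
            report["burden"][label] = _burden_section(
                freport, inputs.cohort, run_config.alpha_family
            )

    with _stage("offtarget", out_dir):
        report["offtarget"] = _offtarget_section(
            inputs, run_config, primary, other
        )

    with _stage("figure2", out_dir):
        fig2 = make_figure2_table(
            reports_by_threshold[_threshold_label(0.3)], inputs.cohort
        )
        report["figure2"] = fig2.to_dict(orient="records")

    if sim is not None:
        with _stage("truth_eval", out_dir):
            report["truth_eval"] = _truth_section(
                sim, reports_by_threshold[_threshold_label(0.3)]
            )

    validate_report(report)

    if out_dir is not None:
        with _stage("write_outputs", out_dir):
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            fig2.to_csv(out_dir / "figure2.tsv", sep="\t", index=False)
            stages_dir = out_dir / "stages"
            stages_dir.mkdir(exist_ok=True)
            for label, freport in reports_by_threshold.items():
                for st in freport.stages:
                    path = stages_dir / f"af_{label}.{st.name}.removed.tsv"
                    with open(path, "w") as fh:
                        fh.write("caller_id\tsample_id\tchrom\tpos\tref\talt\n")
                        for caller_id, sid, key in sorted(
                            st.removed_keys,
                            key=lambda t: (t[0], t[1], t[2].chrom, t[2].pos,
                                           t[2].ref, t[2].alt),
                        ):
                            fh.write(
                                f"{caller_id}\t{sid}\t{key.chrom}\t{key.pos}"
                                f"\t{key.ref}\t{key.alt}\n"
                            )
    return report


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

#: Minimal structural schema for the consolidated report (JSON-schema-like;
#: "required" keys and value types checked recursively).
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": {
        "meta": {
            "type": "object",
            "required": {
                "seed": {"type": "number"},
                "config_hash": {"type": "string"},
                "primary_caller": {"type": "string"},
                "capture_bp": {"type": "number"},
            },
        },
        "filter": {"type": "object"},
        "burden": {"type": "object"},
        "offtarget": {
            "type": "object",
            "required": {
                "window_bp": {"type": "number"},
                "triage_counts": {"type": "object"},
                "enrichment": {"type": "object"},
            },
        },
        "figure2": {"type": "array"},
    },
}


def validate_report(report: Mapping, schema: Optional[Mapping] = None,
                    path: str = "report") -> None:
    """Check the report against :data:`REPORT_SCHEMA`; raises ValueError."""
    schema = REPORT_SCHEMA if schema is None else schema
    kind = schema.get("type")
    if kind == "object":
        if not isinstance(report, Mapping):
            raise ValueError(f"{path}: expected object")
        for key, sub in schema.get("required", {}).items():
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
            validate_report(report[key], sub, f"{path}.{key}")
    elif kind == "array":
        if not isinstance(report, (list, tuple)):
            raise ValueError(f"{path}: expected array")
    elif kind == "number":
        if not isinstance(report, (int, float)):
            raise ValueError(f"{path}: expected number")
    elif kind == "string":
        if not isinstance(report, str):
            raise ValueError(f"{path}: expected string")
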