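"""End-to-end orchestration: simulate/ingest -> call -> QC -> filter -> segregate -> report.

Two modes:

* ``fixture`` — runs the cascade and segregation over the packaged 13-call
  table plus decoys (no marker signals, so sample QC is skipped with a
  logged note); reproduces the 7 genome-wide + 6 regional survivor report.
* ``simulation`` — generates a synthetic cohort, calls CNVs per sample,
  applies sample QC (failed samples are dropped whole, with a logged
  reason), filters against auto-generated or user-supplied tracks, and
  segregates trio cases via parental calls.

Stage outputs are written before the next stage reads them; any stage error
aborts the run with the stage name, and partial outputs from the failed run
are removed. Reports are deterministic given (config, seed).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import fixtures
from .caller import call_cnvs, sample_qc
from .calls import CnvCall
from .filters import FilterParams, regional_filter, survivors
from .hmm import HmmModel
from .intervals import AnnotationTrack, GenomicInterval
from .io import read_bed, write_calls, write_report, write_signal_table
from .simulate import SimConfig, TruthEvent, simulate_cohort
from .trio import carrier_from_calls, segregate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("cnvscreen")


@dataclass
class PipelineConfig:
    mode: str = "fixture"  # fixture | simulation
    out_dir: Path = Path("cnvscreen_out")
    seed: int = 0
    hmm_overrides: dict = field(default_factory=dict)
    filter_overrides: dict = field(default_factory=dict)
    min_markers: int = 5
    min_lbf: float = 30.0
    max_calls: int = 10
    max_lrr_sd: float = 0.3
    # simulation mode
    genome_layout: tuple[tuple[str, int], ...] = (("1", 4_000_000),)
    n_controls: int = 20
    events: tuple[dict, ...] = ()  # {sample, chrom, start, end, cn_state}
    trio_flags: tuple[tuple[str, bool, bool], ...] = ()
    # optional user tracks (BED paths); auto-generated when absent in simulation mode
    track_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "genome_layout" in raw:
            raw["genome_layout"] = tuple((str(c), int(l)) for c, l in raw["genome_layout"])
        if "events" in raw:
            raw["events"] = tuple(raw["events"])
        if "trio_flags" in raw:
            raw["trio_flags"] = tuple((str(c), bool(m), bool(f)) for c, m, f in raw["trio_flags"])
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)


@dataclass
class PipelineResult:
    report_path: Path
    n_genomewide: int
    n_regional: int
    n_calls: int
    n_samples_failed_qc: int


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    log.setLevel(logging.INFO)
    return handler


def _auto_tracks(layout) -> dict[str, AnnotationTrack]:
    """Minimal tracks for a simulated genome: dense genes, no exclusions."""
    genes = []
    for chrom, length in layout:
        start = 1
        i = 0
        while start < length:
            genes.append(GenomicInterval(chrom, start, min(start + 99_999, length), f"G{chrom}_{i}"))
            start += 150_000
            i += 1
    return {
        "genes": AnnotationTrack("genes", genes),
        "segdups": AnnotationTrack("segdups", []),
        "telomere_hla_exclusion": AnnotationTrack("telomere_hla_exclusion", []),
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    written: list[Path] = [out / "run.log"]
    stage = "setup"
    try:
        model = HmmModel.from_dict(config.hmm_overrides) if config.hmm_overrides else HmmModel()
        if config.mode == "fixture":
            result = _run_fixture(config, out, written)
        elif config.mode == "simulation":
            result = _run_simulation(config, out, written, model)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        log.info("pipeline finished: report at %s", result.report_path)
        return result
    except Exception as exc:
        stage = getattr(exc, "_stage", stage)
        for path in written:
            if path.name != "run.log" and path.exists():
                path.unlink()
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name: str):
    """Tag exceptions with the stage they arose in."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not hasattr(exc, "_stage"):
                exc._stage = name
            return False

    return _Ctx()


def _filter_params(config: PipelineConfig, n_controls: Optional[int] = None) -> FilterParams:
    kwargs = dict(config.filter_overrides)
    if n_controls is not None and "n_controls" not in kwargs:
        kwargs["n_controls"] = max(1, n_controls)
    return FilterParams(**kwargs)


def _run_fixture(config: PipelineConfig, out: Path, written: list[Path]) -> PipelineResult:
    with _stage("ingest"):
        fixture = fixtures.table2_fixture()
        bundle = fixtures.fixture_tracks(config.seed)
        calls = fixture.calls + fixtures.decoy_calls()
        calls_path = out / "calls.tsv"
        write_calls(calls, calls_path)
        written.append(calls_path)
    log.info("sample QC skipped: fixture mode carries no marker signals")
    with _stage("filter"):
        params = _filter_params(config, bundle.params.n_controls)
        verdicts = regional_filter(
            calls, bundle.beec_regions, bundle.tracks, bundle.control_calls, bundle.dgv, params
        )
        _write_verdicts(verdicts, out / "verdicts.tsv")
        written.append(out / "verdicts.tsv")
    with _stage("segregate"):
        trio_results = segregate(calls, bundle.tracks["segdups"], fixtures.fixture_trios())
    with _stage("report"):
        report_path = out / "report.tsv"
        case_info = {
            pat: {"sex": info.sex, "phenotype": info.phenotype}
            for pat, info in fixture.info.items()
        }
        write_report(verdicts, report_path, trio_results=trio_results, case_info=case_info, seed=config.seed)
        written.append(report_path)
    return PipelineResult(
        report_path=report_path,
        n_genomewide=len(survivors(verdicts, "genomewide")),
        n_regional=len(survivors(verdicts, "regional")),
        n_calls=len(calls),
        n_samples_failed_qc=0,
    )


def _run_simulation(config: PipelineConfig, out: Path, written: list[Path], model: HmmModel) -> PipelineResult:
    with _stage("simulate"):
        events = tuple(
            TruthEvent(
                str(e["sample"]),
                GenomicInterval(str(e["chrom"]), int(e["start"]), int(e["end"])),
                int(e["cn_state"]),
            )
            for e in config.events
        )
        sim_config = SimConfig(
            genome_layout=config.genome_layout,
            n_controls=config.n_controls,
            events=events,
            trio_flags=config.trio_flags,
            seed=config.seed,
        )
        sim = simulate_cohort(sim_config, model)
        write_signal_table(sim.samples.values(), out / "signals.tsv")
        written.append(out / "signals.tsv")
    with _stage("call"):
        calls_by_sample = {
            sid: call_cnvs(table, model, config.min_markers, config.min_lbf)
            for sid, table in sim.samples.items()
        }
        all_calls = [c for calls in calls_by_sample.values() for c in calls]
        write_calls(all_calls, out / "calls.tsv")
        written.append(out / "calls.tsv")
    with _stage("sample_qc"):
        failed = []
        for sid, table in sim.samples.items():
            qc = sample_qc(table, calls_by_sample[sid], config.max_calls, config.max_lrr_sd)
            if not qc.passed:
                failed.append(sid)
                log.info(
                    "sample %s excluded by QC (n_calls=%d, lrr_sd=%.3f)", sid, qc.n_calls, qc.lrr_sd
                )
        control_ids = {sid for sid in sim.samples if sid.startswith("CTRL_")}
        parent_ids = {c + s for c, _, _ in config.trio_flags for s in ("_M", "_F")}
        case_calls = [
            c
            for sid, calls in calls_by_sample.items()
            for c in calls
            if sid not in failed and sid not in control_ids and sid not in parent_ids
        ]
        control_calls = [c for sid in control_ids for c in calls_by_sample[sid] if sid not in failed]
    with _stage("filter"):
        if config.track_paths:
            tracks = {name: read_bed(path, name) for name, path in config.track_paths.items() if name != "beec_regions"}
            beec = (
                read_bed(config.track_paths["beec_regions"], "beec_regions")
                if "beec_regions" in config.track_paths
                else None
            )
        else:
            tracks, beec = _auto_tracks(config.genome_layout), None
        params = _filter_params(config, config.n_controls)
        if beec is not None:
            verdicts = regional_filter(case_calls, beec, tracks, control_calls, [], params)
        else:
            from .filters import genomewide_filter

            log.info("regional pass skipped: no disease-region track configured")
            verdicts = genomewide_filter(case_calls, tracks, control_calls, [], params)
        _write_verdicts(verdicts, out / "verdicts.tsv")
        written.append(out / "verdicts.tsv")
    with _stage("segregate"):
        parental_status = {}
        for child, _, _ in config.trio_flags:
            child_calls = calls_by_sample.get(child, [])
            if not child_calls:
                parental_status[child] = (None, None)
                continue
            mother = any(carrier_from_calls(c, calls_by_sample.get(child + "_M", [])) for c in child_calls)
            father = any(carrier_from_calls(c, calls_by_sample.get(child + "_F", [])) for c in child_calls)
            parental_status[child] = (mother, father)
        trio_results = segregate(case_calls, tracks["segdups"], parental_status)
    with _stage("report"):
        report_path = out / "report.tsv"
        write_report(verdicts, report_path, trio_results=trio_results, seed=config.seed)
        written.append(report_path)
    return PipelineResult(
        report_path=report_path,
        n_genomewide=len(survivors(verdicts, "genomewide")),
        n_regional=len(survivors(verdicts, "regional")),
        n_calls=len(all_calls),
        n_samples_failed_qc=len(failed),
    )


def _write_verdicts(verdicts, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": v.call.sample_id,
            "chrom": v.call.region.chrom,
            "start": v.call.region.start,
            "end": v.call.region.end,
            "cnv_type": v.call.cnv_type,
            "size_mb": f"{v.size_mb:.2f}",
            "excluded_telomere_hla": v.excluded_telomere_hla,
            "gene_count": v.gene_count,
            "segdup_relation": v.segdup_relation,
            "control_frequency": f"{v.control_frequency:.6f}",
            "dgv_entries": v.dgv_entries,
            "matched_region": v.matched_region or "",
            "pass_genomewide": v.pass_genomewide,
            "pass_regional": v.pass_regional,
        }
        for v in verdicts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
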