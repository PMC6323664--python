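"""End-to-end orchestration: screen -> summarize -> scan -> three-band ->
restage -> two-step Cox -> system evaluation, with a TSV report bundle.

The modified system's N3a/N3b boundary is taken from the scan result
(not hard-coded), so the pipeline generalizes to any conforming cohort;
``force_cutoff`` pins it when reproducing a published configuration.
Outputs are deterministic given the input and seed: rerunning an
identical config yields byte-identical TSVs (the run log carries wall
times and is the only non-reproducible file).
"""
from __future__ import annotations

import dataclasses
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__ as _pkg_version
from .cohort import Cohort, read_cohort, write_cohort, screen_cohort, summarize
from .cutpoint import scan, three_band_analysis
from .cox import two_step
from .evaluation import compare_systems, evaluate_system
from .simulate import SimulationConfig, generate
from .staging import EIGHTH_CUTOFF, StagingSystem, restage_cohort

__all__ = ["PipelineConfig", "PipelineStageError", "PipelineResult",
           "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serializable)."""

    input_csv: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    scan_range: tuple[int, int] = (7, 20)
    min_group: int = 20
    ties: str = "breslow"
    alpha: float = 0.05
    outdir: str = "stagecut_run"
    seed: int = 0
    force_cutoff: Optional[int] = None

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_csv / simulation must be set")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        if self.simulation is not None:
            self.simulation.validate()

    def to_yaml(self, path=None) -> str:
        data = dataclasses.asdict(self)
        data["scan_range"] = list(self.scan_range)
        text = yaml.safe_dump(data, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("simulation") is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        if data.get("scan_range") is not None:
            data["scan_range"] = tuple(data["scan_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    outdir: Path
    selected_cutoff: int
    scan_result: object
    twostep: object
    comparison: object
    screening_report: object
    files: list[str] = field(default_factory=list)


def _write_manifest(outdir: Path, files: list[str], complete: bool,
                    note: str = "") -> None:
    lines = [f"complete\t{'yes' if complete else 'no'}"]
    if note:
        lines.append(f"note\t{note}")
    lines += [f"file\t{f}" for f in files]
    (outdir / "MANIFEST.tsv").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    On a stage failure the partial outputs are retained, MANIFEST.tsv is
    marked incomplete, and :class:`PipelineStageError` is raised naming
    the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    log_lines = [f"stagecut {_pkg_version}", f"seed {config.seed}"]
    import numpy, pandas, scipy
    log_lines += [f"numpy {numpy.__version__}",
                  f"pandas {pandas.__version__}",
                  f"scipy {scipy.__version__}"]

    config.to_yaml(outdir / "config.yaml")
    files.append("config.yaml")

    state: dict = {}

    def stage(name):
        def deco(fn):
            return (name, fn)
        return deco

    def emit(fname: str, writer) -> None:
        writer(outdir / fname)
        files.append(fname)

    @stage("load")
    def _load():
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv)
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = generate(sim)
        state["raw"] = cohort
        log_lines.append(f"load: {len(cohort)} records")

    @stage("screen")
    def _screen():
        kept, report = screen_cohort(state["raw"])
        state["cohort"] = kept
        state["screening"] = report
        emit("screening_report.tsv",
             lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
        log_lines.append(
            f"screen: {report.n_eligible}/{report.n_input} eligible")

    @stage("summarize")
    def _summarize():
        cohort = state["cohort"]
        by_source = cohort.df["source"].nunique() >= 2
        summary = summarize(cohort, by_source=by_source)
        emit("table1_summary.tsv", summary.to_tsv)
        log_lines.append(f"summarize: by_source={by_source}")

    @stage("scan")
    def _scan():
        res = scan(state["cohort"], cutoff_range=config.scan_range,
                   min_group=config.min_group)
        state["scan"] = res
        emit("table2_scan.tsv", res.to_tsv)
        log_lines.append(f"scan: selected cutoff {res.selected_cutoff} "
                         f"(chi2={res.selection_chi2:.3f})")

    @stage("three_band")
    def _three_band():
        cutoff = state["cutoff"] = (config.force_cutoff
                                    if config.force_cutoff is not None
                                    else state["scan"].selected_cutoff)
        if not cutoff < EIGHTH_CUTOFF:
            log_lines.append("three_band: skipped (selected cutoff not "
                             "below the eighth-edition boundary)")
            state["bands"] = None
            return
        report = three_band_analysis(
            state["cohort"], low_band=(7, cutoff),
            mid_band=(cutoff + 1, EIGHTH_CUTOFF))
        state["bands"] = report

        def writer(p):
            with open(p, "w") as fh:
                report.to_frame().to_csv(fh, sep="\t", index=False)
                fh.write("\n")
                report.pairwise_frame().to_csv(fh, sep="\t", index=False)
        emit("three_band.tsv", writer)
        log_lines.append(
            "three_band: mid vs high p = "
            f"{report.pairwise['mid_vs_high']['p_value']:.4g}")

    @stage("staging")
    def _staging():
        cohort = state["cohort"]
        eighth = restage_cohort(cohort, StagingSystem.eighth())
        modified = restage_cohort(cohort,
                                  StagingSystem.modified(state["cutoff"]))
        state["staged"] = {"eighth": eighth, "modified": modified}

        def writer(p):
            import pandas as pd
            frames = []
            for name, rc in state["staged"].items():
                f = rc.counts_frame()
                f.insert(0, "system", name)
                frames.append(f)
            pd.concat(frames).to_csv(p, sep="\t", index=False)
        emit("staging_counts.tsv", writer)

        merged = cohort.df.copy()
        for name, rc in state["staged"].items():
            merged[f"n_{name}"] = rc.cohort.df["n_sub"].to_numpy()
            merged[f"stage_{name}"] = rc.cohort.df["stage"].to_numpy()
        staged_cohort = Cohort(merged, provenance=cohort.provenance)
        emit("staged_cohort.csv",
             lambda p: write_cohort(staged_cohort, p,
                                    extra_columns=["n_eighth", "stage_eighth",
                                                   "n_modified",
                                                   "stage_modified"]))
        log_lines.append(
            "staging: eighth counts "
            + str([eighth.counts[s] for s in eighth.system.stage_order])
            + ", modified counts "
            + str([modified.counts[s] for s in modified.system.stage_order]))

    @stage("two_step")
    def _two_step():
        if state["cutoff"] == EIGHTH_CUTOFF:
            log_lines.append("two_step: skipped (modified classification "
                             "coincides with the eighth edition)")
            state["twostep"] = None
            return
        res = two_step(state["cohort"], modified_cutoff=state["cutoff"],
                       ties=config.ties, alpha=config.alpha)
        state["twostep"] = res
        emit("table3_twostep.tsv",
             lambda p: res.to_frame().to_csv(p, sep="\t", index=False,
                                             float_format="%.6g"))
        v = res.verdict
        log_lines.append(
            "two_step: eighth N3b p = "
            f"{v['n_eighth']['p_value']:.4g} "
            f"(retained={v['n_eighth']['retained']}), "
            "modified N3b p = "
            f"{v['n_modified']['p_value']:.4g} "
            f"(retained={v['n_modified']['retained']})")

    @stage("evaluate")
    def _evaluate():
        import pandas as pd
        evals = {name: evaluate_system(rc, ties=config.ties)
                 for name, rc in state["staged"].items()}
        comp = compare_systems(evals["eighth"], evals["modified"])
        state["comparison"] = comp
        rows = pd.DataFrame([e.to_row() for e in evals.values()])
        emit("table4_systems.tsv",
             lambda p: rows.to_csv(p, sep="\t", index=False))
        emit("comparison.tsv",
             lambda p: comp.to_frame().to_csv(p, sep="\t", index=False))
        log_lines.append(f"evaluate: overall better system = {comp.overall}")

    @stage("km_export")
    def _km_export():
        import pandas as pd
        frames = []
        for name, rc in state["staged"].items():
            for s, curve in rc.km.items():
                f = curve.to_frame()
                f.insert(0, "stage", s)
                f.insert(0, "system", name)
                frames.append(f)
        def writer(p):
            pd.concat(frames).to_csv(p, sep="\t", index=False)
        emit("km_stages.tsv", writer)

    stages = [_load, _screen, _summarize, _scan, _three_band, _staging,
              _two_step, _evaluate, _km_export]
    for name, fn in stages:
        t0 = _time.perf_counter()
        try:
            fn()
        except Exception as exc:
            log_lines.append(f"FAILED at stage {name}: {exc}")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            _write_manifest(outdir, files, complete=False,
                            note=f"failed at stage {name}")
            raise PipelineStageError(name, exc) from exc
        log_lines.append(f"  [{name}] {_time.perf_counter() - t0:.2f}s")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_manifest(outdir, files, complete=True)
    return PipelineResult(outdir=outdir,
                          selected_cutoff=state["cutoff"],
                          scan_result=state["scan"],
                          twostep=state["twostep"],
                          comparison=state["comparison"],
                          screening_report=state["screening"],
                          files=files)
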