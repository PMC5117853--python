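"""End-to-end orchestration: simulate -> quantify -> classify -> report.

The pipeline runs either on rendered image stacks or, by default, on
generated traces directly (the trace-level fast path); every stochastic
stage draws from an explicit seed, and a manifest records the config
hash and a checksum per written file so identical configs produce
identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cohort_statistics import chi_square_2x2
from .imaging_io import write_protocol, write_results
from .plasticity_classification import (
    CellCall,
    CohortSummary,
    ControlReference,
    build_control_reference,
    classify_cell,
    classify_cohort,
    flag_direct_IS_response,
    flag_heat_response,
    session_records,
)
from .synthetic_cohort import (
    Cohort,
    CohortDesign,
    make_cohort,
)
from .trace_quantification import DEFAULT_QUANT, QuantConfig, quantify_traces

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a full simulated experiment.

    ``arms`` maps arm names to design keyword dicts (category counts,
    arm kind, effect size, seed); ``control_arm`` names the arm whose
    percent changes build the reference band.
    """

    arms: Mapping[str, dict]
    control_arm: str
    seed: int = 0
    band_sd: float = 2.0
    session_time_min: float = 30.0
    quant: QuantConfig = DEFAULT_QUANT

    def to_dict(self) -> dict:
        return {"arms": {k: dict(v) for k, v in self.arms.items()},
                "control_arm": self.control_arm, "seed": self.seed,
                "band_sd": self.band_sd,
                "session_time_min": self.session_time_min,
                "quant": dataclasses.asdict(self.quant)}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        quant = QuantConfig(**doc.get("quant", {}))
        return cls(arms={k: dict(v) for k, v in doc["arms"].items()},
                   control_arm=doc["control_arm"],
                   seed=int(doc.get("seed", 0)),
                   band_sd=float(doc.get("band_sd", 2.0)),
                   session_time_min=float(doc.get("session_time_min", 30.0)),
                   quant=quant)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def design_from_dict(doc: Mapping, fallback_seed: int = 0) -> CohortDesign:
    return CohortDesign(
        n_cells={k: int(v) for k, v in doc["n_cells"].items()},
        arm=doc.get("arm", "IS"),
        effect_size_sd=float(doc.get("effect_size_sd", 5.0)),
        forces_mN=tuple(doc.get("forces_mN", (50.0, 100.0, 200.0, 500.0))),
        seed=int(doc.get("seed", fallback_seed)))


# ---------------------------------------------------------------------------
# cohort-level analysis steps


@dataclass(frozen=True)
class CohortResult:
    """Quantified and classified outcome of one arm."""

    arm: str
    results: pd.DataFrame            # tidy table, both sessions
    calls: tuple[CellCall, ...]
    summary: CohortSummary

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cell_id": c.cell_id, "category": c.category,
              "heat_sensitive": c.heat_sensitive,
              "direct_IS_response": c.direct_IS_response,
              "earliest_call_min": c.earliest_call_min,
              "tie_break": c.tie_break} for c in self.calls])


def quantify_cohort(cohort: Cohort,
                    config: QuantConfig = DEFAULT_QUANT) -> pd.DataFrame:
    """Tidy result table for both sessions of a simulated cohort."""
    frames = []
    for label in ("pre", "post"):
        frames.append(quantify_traces(cohort.traces[label],
                                      cohort.protocols[label], config))
    return pd.concat(frames, ignore_index=True)


def control_changes(results: pd.DataFrame) -> list[float]:
    """Pooled per-cell-per-force percent changes from a control arm."""
    pre = session_records(results[results["session"] == "pre"])
    post = session_records(results[results["session"] == "post"])
    changes = []
    for cid, rec in pre.items():
        if cid not in post:
            continue
        for force, amp, resp, amp_post in zip(
                rec.forces_mN, rec.peak_dff_pct, rec.responded,
                post[cid].peak_dff_pct):
            if resp and amp > 0:
                changes.append((amp_post - amp) / amp)
    return changes


def classify_cohort_results(cohort: Cohort, results: pd.DataFrame,
                            ref: ControlReference,
                            config: QuantConfig = DEFAULT_QUANT,
                            session_time_min: float = 30.0) -> CohortResult:
    """Cell calls plus heat / direct-IS flags for one quantified arm."""
    pre = session_records(results[results["session"] == "pre"])
    post = session_records(results[results["session"] == "post"])
    post_events = cohort.protocols["post"].events
    heat_event = next((e for e in post_events if e.kind == "heat"), None)
    infusion = next((e for e in post_events if e.kind == "infusion_IS"), None)
    cells = {c.id: c for c in cohort.cells}
    calls = []
    for cid in sorted(pre):
        call = classify_cell(pre[cid], post[cid], ref,
                             session_time_min=session_time_min)
        trace = cohort.traces["post"].get(cid)
        heat = flag_heat_response(
            trace, heat_event,
            layer="top" if cells[cid].top_layer else "bottom", config=config)
        direct = flag_direct_IS_response(trace, infusion, config=config)
        calls.append(dataclasses.replace(
            call, heat_sensitive=heat, direct_IS_response=direct))
    summary = classify_cohort(calls, arm=cohort.design.arm)
    return CohortResult(arm=cohort.design.arm, results=results,
                        calls=tuple(calls), summary=summary)


def label_accuracy(cohort: Cohort, calls: Sequence[CellCall]) -> float:
    """Fraction of cells whose call matches the simulated ground truth.

    ``lost`` is folded into D on both sides, matching the three-way
    cohort summary; an ``excluded`` call for a cell with any ground
    truth counts as an error.
    """
    truth = {c.id: c.truth_category for c in cohort.cells}

    def fold(cat: str) -> str:
        return "D" if cat == "lost" else cat

    if not calls:
        raise ValueError("no calls to score")
    hits = sum(fold(truth[c.cell_id]) == fold(c.category) for c in calls)
    return hits / len(calls)


def compare_arms(a: CohortSummary, b: CohortSummary) -> dict:
    """Per-category 2x2 chi-square between two cohort summaries."""
    out = {}
    for cat in ("NC", "I", "D", "SA"):
        table = [[a.counts[cat], a.n_cells - a.counts[cat]],
                 [b.counts[cat], b.n_cells - b.counts[cat]]]
        out[cat] = chi_square_2x2(table)
    return out


# ---------------------------------------------------------------------------
# paper-scale recovery replicate


def paper_scale_replicate(seed: int,
                          config: QuantConfig = DEFAULT_QUANT) -> dict:
    """One full replicate of the paper-scale simulation study.

    Simulates the vehicle control arm (83 cells), the IS arm
    (23 NC / 10 I / 12 D / 2 SA), the heat+IS arm (11/6/14/8) and a
    heat-only control arm, builds the 2-SD reference from the vehicle
    arm, classifies every arm and scores label accuracy against ground
    truth.  Returns per-arm accuracies, SA counts and category counts.
    """
    from .synthetic_cohort import (
        HEAT_IS_DESIGN,
        HEAT_ONLY_DESIGN,
        IS_DESIGN,
        VEHICLE_DESIGN,
    )

    arms = {"vehicle": VEHICLE_DESIGN, "IS": IS_DESIGN,
            "heat_plus_IS": HEAT_IS_DESIGN, "heat_only": HEAT_ONLY_DESIGN}
    cohorts = {name: make_cohort(dataclasses.replace(design, seed=seed))
               for name, design in arms.items()}
    tables = {name: quantify_cohort(c, config)
              for name, c in cohorts.items()}
    ref = build_control_reference(control_changes(tables["vehicle"]))
    out: dict = {"seed": seed, "ref_sd_pc": ref.sd_pc}
    for name, cohort in cohorts.items():
        res = classify_cohort_results(cohort, tables[name], ref, config)
        out[f"accuracy_{name}"] = label_accuracy(cohort, res.calls)
        out[f"sa_count_{name}"] = res.summary.counts["SA"]
        out[f"counts_{name}"] = dict(res.summary.counts)
    return out


# ---------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute every stage and write versioned outputs plus a manifest.

    Stage order: simulate each arm, quantify, build the control
    reference, classify the experimental arms, and report cohort
    summaries with between-arm chi-square comparisons.  Any failure is
    re-raised with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    cohorts: dict[str, Cohort] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name, doc in config.arms.items():
        design = design_from_dict(doc, fallback_seed=config.seed)
        cohorts[name] = _stage(f"simulate:{name}", make_cohort, design)
        tables[name] = _stage(f"quantify:{name}", quantify_cohort,
                              cohorts[name], config.quant)
        path = out / f"results_{name}.csv"
        write_results(tables[name], path)
        written.append(path)
        truth_path = out / f"truth_{name}.csv"
        cohorts[name].truth.to_csv(truth_path, index=False)
        written.append(truth_path)
        for label in ("pre", "post"):
            ppath = out / f"protocol_{name}_{label}.yaml"
            write_protocol(cohorts[name].protocols[label], ppath)
            written.append(ppath)

    if config.control_arm not in cohorts:
        raise StageError(f"stage 'reference' failed: control arm "
                         f"{config.control_arm!r} not simulated")
    changes = _stage("reference", control_changes,
                     tables[config.control_arm])
    ref = _stage("reference", build_control_reference, changes,
                 band_sd=config.band_sd)

    summaries: dict[str, dict] = {}
    results: dict[str, CohortResult] = {}
    for name, cohort in cohorts.items():
        res = _stage(f"classify:{name}", classify_cohort_results,
                     cohort, tables[name], ref, config.quant,
                     config.session_time_min)
        results[name] = res
        cpath = out / f"calls_{name}.csv"
        res.calls_frame().to_csv(cpath, index=False)
        written.append(cpath)
        summaries[name] = res.summary.to_dict()

    comparisons = {}
    for name in cohorts:
        if name == config.control_arm:
            continue
        comparisons[f"{name}_vs_{config.control_arm}"] = compare_arms(
            results[name].summary, results[config.control_arm].summary)

    report = {
        "control_reference": {"mean_pc": ref.mean_pc, "sd_pc": ref.sd_pc,
                              "n_obs": ref.n_obs, "band": list(ref.band)},
        "summaries": summaries,
        "comparisons": comparisons,
    }
    spath = out / "summary.json"
    spath.write_text(json.dumps(report, indent=1, sort_keys=True))
    written.append(spath)

    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return out
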