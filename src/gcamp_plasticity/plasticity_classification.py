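"""Cell-level plasticity calls against a control-derived 2-SD band.

Percent changes in peak ΔF/F₀ between a pre-exposure and a
post-exposure session are compared with the distribution of changes
observed in uninjected/vehicle controls: changes outside the control
mean ± 2 SD are significant.  Cells sort into no-change (NC), increased
(I), decreased (D, including cells that lost mechanical sensitivity
entirely), and 'silent' afferents (SA) — cells with no detectable
mechanical response at any force before exposure that respond after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging_io import FluorescenceTrace, StimulusEvent
from .trace_quantification import (
    DEFAULT_QUANT,
    QuantConfig,
    compute_dff,
    detect_response,
    event_windows,
)
from .cohort_statistics import summarize_proportions

log = logging.getLogger(__name__)

#: seconds after infusion offset in which an acute chemical response to
#: the inflammatory soup is still attributed to the infusion
DIRECT_IS_WINDOW_S = 20.0


class ReferenceError_(ValueError):
    """Too few control observations to form a reference band."""


class ProtocolMismatchError(ValueError):
    """Pre and post sessions used different force series."""


class EmptyCohortError(ValueError):
    """No classifiable cells in the cohort."""


# ---------------------------------------------------------------------------
# control reference


@dataclass(frozen=True)
class ControlReference:
    """Mean ± SD of control percent changes and the 2-SD band."""

    mean_pc: float
    sd_pc: float
    n_obs: int
    band_sd: float = 2.0

    def __post_init__(self):
        if self.sd_pc < 0:
            raise ValueError("sd_pc must be non-negative")

    @property
    def band(self) -> tuple[float, float]:
        return (self.mean_pc - self.band_sd * self.sd_pc,
                self.mean_pc + self.band_sd * self.sd_pc)


def build_control_reference(control_changes: Sequence[float],
                            band_sd: float = 2.0,
                            min_obs: int = 10) -> ControlReference:
    """Pool per-cell-per-force percent changes from control animals.

    Requires at least ``min_obs`` observations; the 2-SD band of these
    pooled changes is the significance criterion for experimental cells.
    """
    changes = np.asarray(list(control_changes), dtype=float)
    changes = changes[np.isfinite(changes)]
    if len(changes) < min_obs:
        raise ReferenceError_(
            f"need >= {min_obs} control observations, got {len(changes)}")
    return ControlReference(mean_pc=float(changes.mean()),
                            sd_pc=float(changes.std()),
                            n_obs=len(changes), band_sd=band_sd)


# ---------------------------------------------------------------------------
# session records and cell calls


@dataclass(frozen=True)
class SessionRecord:
    """One cell's per-force mechanical responses in one session."""

    cell_id: str
    forces_mN: tuple[float, ...]
    peak_dff_pct: tuple[float, ...]
    responded: tuple[bool, ...]

    def __post_init__(self):
        if not (len(self.forces_mN) == len(self.peak_dff_pct)
                == len(self.responded)):
            raise ValueError("per-force fields must have equal length")

    @property
    def any_response(self) -> bool:
        return any(self.responded)


@dataclass(frozen=True)
class CellCall:
    """Classification outcome for one cell."""

    cell_id: str
    category: str                     # NC | I | D | lost | SA | excluded
    per_force_pc: Mapping[float, float] = field(default_factory=dict)
    heat_sensitive: str = "untested"  # yes | no | untested
    direct_IS_response: bool | None = None
    earliest_call_min: float | None = None
    tie_break: bool = False


def session_records(results: pd.DataFrame) -> dict[str, SessionRecord]:
    """Build per-cell mechanical session records from a result table."""
    mech = results[results["kind"] == "mechanical"]
    records = {}
    for cell_id, grp in mech.groupby("cell_id"):
        grp = grp.sort_values("param")
        records[str(cell_id)] = SessionRecord(
            cell_id=str(cell_id),
            forces_mN=tuple(float(f) for f in grp["param"]),
            peak_dff_pct=tuple(float(a) for a in grp["peak_dff_pct"]),
            responded=tuple(bool(r) for r in grp["responded"]))
    return records


def classify_cell(pre: SessionRecord, post: SessionRecord,
                  ref: ControlReference,
                  session_time_min: float = 30.0) -> CellCall:
    """Classify one cell from its paired pre/post force series.

    Mechanically insensitive cells that acquire a response are SA;
    insensitive-both-ways cells are excluded from denominators (never
    NC).  Sensitive cells that stop responding everywhere are ``lost``
    (folded into D at the cohort level).  Otherwise the per-force
    percent changes are compared against the control band: any change
    above it (and none below) is I, the mirror case D, all-inside NC.
    If changes cross both bands the excursion at the highest
    out-of-band force decides, and the tie-break is logged.
    """
    if pre.forces_mN != post.forces_mN:
        raise ProtocolMismatchError(
            f"{pre.cell_id}: force series differ between sessions")
    if not pre.any_response:
        if post.any_response:
            return CellCall(pre.cell_id, "SA",
                            earliest_call_min=session_time_min)
        return CellCall(pre.cell_id, "excluded")
    if not post.any_response:
        return CellCall(pre.cell_id, "lost",
                        earliest_call_min=session_time_min)
    lo, hi = ref.band
    pcs: dict[float, float] = {}
    for force, a_pre, r_pre, a_post in zip(
            pre.forces_mN, pre.peak_dff_pct, pre.responded,
            post.peak_dff_pct):
        if r_pre and a_pre > 0:
            pcs[force] = (a_post - a_pre) / a_pre
    above = {f for f, pc in pcs.items() if pc > hi}
    below = {f for f, pc in pcs.items() if pc < lo}
    if above and not below:
        cat, tie = "I", False
    elif below and not above:
        cat, tie = "D", False
    elif not above and not below:
        cat, tie = "NC", False
    else:
        top = max(above | below)
        cat = "I" if top in above else "D"
        tie = True
        log.info("%s: changes cross both bands; highest out-of-band "
                 "force %.0f mN decides -> %s", pre.cell_id, top, cat)
    return CellCall(pre.cell_id, cat, per_force_pc=pcs, tie_break=tie,
                    earliest_call_min=(session_time_min
                                       if cat in ("I", "D") else None))


# ---------------------------------------------------------------------------
# event-level flags


def flag_direct_IS_response(trace: FluorescenceTrace | None,
                            infusion_event: StimulusEvent | None,
                            config: QuantConfig = DEFAULT_QUANT
                            ) -> bool | None:
    """Acute chemical response during, or up to 20 s after, IS infusion.

    ``None`` means untested (no infusion event or no trace).
    """
    if trace is None or infusion_event is None:
        return None
    baseline = (max(infusion_event.onset_s - config.baseline_window_s, 0.0),
                infusion_event.onset_s)
    response = (infusion_event.onset_s,
                infusion_event.offset_s + DIRECT_IS_WINDOW_S)
    measure = compute_dff(trace, baseline, response, config)
    return detect_response(measure, config.k_sd, config.min_peak_dff_pct)


def flag_heat_response(trace: FluorescenceTrace | None,
                       heat_event: StimulusEvent | None,
                       layer: str = "top",
                       config: QuantConfig = DEFAULT_QUANT) -> str:
    """Binary heat-sensitivity call for top-layer cells.

    Only the top layer of the folded skin reaches the noxious-heat
    threshold, so bottom-layer cells are untested by construction.
    """
    if layer == "bottom" or trace is None or heat_event is None:
        return "untested"
    bwin, rwin = event_windows(heat_event, config)
    measure = compute_dff(trace, bwin, rwin, config)
    return ("yes" if detect_response(measure, config.k_sd,
                                     config.min_peak_dff_pct) else "no")


# ---------------------------------------------------------------------------
# cohort summary


@dataclass(frozen=True)
class CohortSummary:
    """Category counts and proportions for one experimental arm."""

    arm: str
    counts_detail: Mapping[str, int]       # NC, I, D, lost, SA
    counts: Mapping[str, int]              # three-way + SA (lost in D)
    percentages: Mapping[str, float]
    n_cells: int                           # denominator
    n_excluded: int

    def to_dict(self) -> dict:
        return {"arm": self.arm, "counts_detail": dict(self.counts_detail),
                "counts": dict(self.counts),
                "percentages": dict(self.percentages),
                "n_cells": self.n_cells, "n_excluded": self.n_excluded}


def classify_cohort(calls: Sequence[CellCall], arm: str = "",
                    ) -> CohortSummary:
    """Aggregate cell calls into counts and integer percentages.

    The denominator counts mechanically sensitive cells plus converted
    silent afferents; insensitive-both-sessions cells are excluded.
    ``lost`` is folded into D for the three-way summary and kept
    separate in the detail counts.
    """
    detail = {c: 0 for c in ("NC", "I", "D", "lost", "SA")}
    n_excluded = 0
    for call in calls:
        if call.category == "excluded":
            n_excluded += 1
            continue
        if call.category == "SA":
            # soundness: a silent afferent can never have had a pre response
            assert not call.per_force_pc, \
                f"{call.cell_id}: SA call with pre-session percent changes"
        detail[call.category] += 1
    counts = {"NC": detail["NC"], "I": detail["I"],
              "D": detail["D"] + detail["lost"], "SA": detail["SA"]}
    n = sum(counts.values())
    if n == 0:
        raise EmptyCohortError("no classifiable cells in cohort")
    percentages = summarize_proportions(counts, total=n)
    return CohortSummary(arm=arm, counts_detail=detail, counts=counts,
                         percentages=percentages, n_cells=n,
                         n_excluded=n_excluded)
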