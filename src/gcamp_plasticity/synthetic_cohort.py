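"""Synthetic GCaMP cohorts with known ground truth.

Forward model: spikes increment a single-compartment calcium pool that
decays mono-exponentially; fluorescence reads the pool through a Hill
saturation.  This is the simplest model that reproduces the phenomena
the analysis must handle — phase-locked transients that summate at
higher firing rates, indicator saturation, and the loss of single-spike
resolution above ~10 Hz with the default kinetics.

Trial-to-trial variability is lognormal on the calcium gain, dominated
by a session-level component (shared by all stimuli of one imaging
session, emulating slow drift of focus/expression/health) plus a small
per-stimulus component.  Plasticity effects are symmetric multiplicative
gain changes of ``effect_size_sd`` control-SDs on the log scale.

All defaults here define the simulated study conditions; they are
calibration choices of this package, frozen in code, not measured
biological constants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import (
    FluorescenceTrace,
    ImageStack,
    ROI,
    StimulusEvent,
    StimulusProtocol,
)


class DesignError(ValueError):
    """Invalid cohort design (arm/category combination and the like)."""


# ---------------------------------------------------------------------------
# kinetics


@dataclass(frozen=True)
class KineticsParams:
    """Single-compartment calcium/indicator parameters.

    ``kd_nM`` defaults to 350 (GCaMP3-like affinity); 144 approximates
    GCaMP6s.  ``tau_decay_s`` and ``ca_per_spike_nM`` were calibrated so
    that transient counting resolves electrical trains up to 10 Hz and
    not at 20 Hz, then frozen.
    """

    ca_rest_nM: float = 50.0
    ca_per_spike_nM: float = 150.0
    tau_decay_s: float = 0.25
    kd_nM: float = 350.0
    hill_n: float = 2.0
    f_min: float = 50.0
    f_max: float = 1000.0

    def __post_init__(self):
        vals = (self.ca_rest_nM, self.ca_per_spike_nM, self.tau_decay_s,
                self.kd_nM, self.hill_n, self.f_min, self.f_max)
        if any(v <= 0 for v in vals[:-2]) or self.f_min < 0:
            raise ValueError("kinetic parameters must be positive")
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")

    def fluorescence(self, calcium_nM: np.ndarray) -> np.ndarray:
        """Hill readout of calcium concentration, in a.u."""
        c = np.asarray(calcium_nM, dtype=float)
        cn = c ** self.hill_n
        return self.f_min + (self.f_max - self.f_min) * cn / (
            self.kd_nM ** self.hill_n + cn)


DEFAULT_KINETICS = KineticsParams()
GCAMP6S_KINETICS = KineticsParams(kd_nM=144.0)

#: lognormal sigma of the session-level calcium-gain drift
SIGMA_SESSION = 0.08
#: lognormal sigma of the per-stimulus gain jitter
SIGMA_TRIAL = 0.003
#: model SD of log peak-amplitude ratio between two sessions
SIGMA_PC = float(np.sqrt(2.0 * (SIGMA_SESSION ** 2 + SIGMA_TRIAL ** 2)))

def _force_response_curve(gains: np.ndarray) -> np.ndarray:
    """Peak ΔF/F₀ (fraction of baseline) per (force, gain).

    Deterministic forward curve of the mechanical response: the default
    spike counts, spread over the hold, pushed through the calcium and
    Hill kinetics.  Used by the model oracle below.
    """
    kin = DEFAULT_KINETICS
    dt = MECHANICAL_FRAME_INTERVAL_S
    t = (np.arange(int(7.0 / dt)) + 0.5) * dt
    f0 = kin.fluorescence(kin.ca_rest_nM)
    out = np.empty((len(DEFAULT_SPIKES_PER_FORCE), len(gains)))
    for i, force in enumerate(sorted(DEFAULT_SPIKES_PER_FORCE)):
        n = DEFAULT_SPIKES_PER_FORCE[force]
        sp = 2.0 + np.arange(n) * MECHANICAL_HOLD_S / n
        decay = np.zeros_like(t)
        for s in sp:
            m = t >= s
            decay[m] += np.exp(-(t[m] - s) / kin.tau_decay_s)
        for j, g in enumerate(gains):
            c = kin.ca_rest_nM + g * kin.ca_per_spike_nM * decay
            out[i, j] = (kin.fluorescence(c).max() - f0) / f0
    return out


def null_call_rate_model(band_sd: float = 2.0, n_ref_obs: int = 400,
                         n_mc: int = 4000, n_reps: int = 30,
                         seed: int = 12345,
                         with_dispersion: bool = False):
    """Expected per-cell I/D false-call rate under the control model.

    Direct Monte-Carlo of the control-variability model: lognormal
    session and per-stimulus calcium gains mapped through the forward
    response curve to percent changes, with the mean ± ``band_sd``·SD
    band re-estimated from ``n_ref_obs`` pooled control observations in
    every replication (so finite-reference noise is part of the
    expectation).  A cell is a false call when any of its four per-force
    changes leaves the band.  Independent of the imaging/classification
    code path.

    With ``with_dispersion=True`` also returns the SD of the rate across
    reference-band draws: the rate observed with one concrete control
    cohort fluctuates by this much *in addition to* binomial noise.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(np.log(0.5), np.log(2.0), 81)
    curve = _force_response_curve(np.exp(grid))
    n_forces = curve.shape[0]

    def draw_pcs(n_cells):
        g_pre = rng.normal(0.0, SIGMA_SESSION, (n_cells, 1)) \
            + rng.normal(0.0, SIGMA_TRIAL, (n_cells, n_forces))
        g_post = rng.normal(0.0, SIGMA_SESSION, (n_cells, 1)) \
            + rng.normal(0.0, SIGMA_TRIAL, (n_cells, n_forces))
        pcs = np.empty((n_cells, n_forces))
        for i in range(n_forces):
            amp_pre = np.interp(g_pre[:, i], grid, curve[i])
            amp_post = np.interp(g_post[:, i], grid, curve[i])
            pcs[:, i] = (amp_post - amp_pre) / amp_pre
        return pcs

    rates = []
    n_ref_cells = max(n_ref_obs // n_forces, 2)
    for _ in range(n_reps):
        ref = draw_pcs(n_ref_cells).ravel()
        lo = ref.mean() - band_sd * ref.std()
        hi = ref.mean() + band_sd * ref.std()
        pcs = draw_pcs(n_mc)
        outside = ((pcs > hi) | (pcs < lo)).any(axis=1)
        rates.append(outside.mean())
    if with_dispersion:
        return float(np.mean(rates)), float(np.std(rates))
    return float(np.mean(rates))


#: spikes evoked per mechanical force step (mN -> count) for a typical
#: responder; monotone in force so peak fluorescence encodes intensity
DEFAULT_SPIKES_PER_FORCE = {50.0: 3, 100.0: 4, 200.0: 5, 500.0: 6}
MECHANICAL_HOLD_S = 2.0
MECHANICAL_FRAME_INTERVAL_S = 0.05
ELECTRICAL_FRAME_INTERVAL_S = 0.02

#: relative calcium gain of narrow-spike (Abeta) cells: no detectable
#: somatic signal at any stimulation frequency, by construction
NARROW_CLASS_GAIN = 2e-4

#: additive Gaussian measurement noise on rendered traces, a.u.
TRACE_NOISE_SD_AU = 0.5

#: run-to-run amplitude decline of repeated high-K applications
#: (calibration echoing the in vitro decline, not a measured truth)
HIGH_K_DECLINE = (1.00, 0.93, 0.88)
#: fraction of dissociated cells with no depolarization-evoked signal
HIGH_K_NONRESPONDER_FRACTION = 0.025

#: fraction of converted silent afferents already responsive at the
#: lowest force tested
SA_LOW_FORCE_FRACTION = 0.88

#: per-category rates of heat sensitivity and of a direct (acute)
#: response during IS infusion, used to assign ground-truth flags
HEAT_SENSITIVE_RATE = {"NC": 0.18, "I": 0.33, "D": 0.14,
                       "lost": 0.14, "SA": 0.50}
DIRECT_IS_RATE = {"NC": 0.44, "I": 0.50, "D": 0.31,
                  "lost": 0.31, "SA": 0.20}

CATEGORIES = ("NC", "I", "D", "lost", "SA")
ARMS = ("uninjected", "vehicle", "IS", "heat_plus_IS", "heat_only")


# ---------------------------------------------------------------------------
# cells and designs


@dataclass(frozen=True)
class SimCell:
    """Ground truth for one simulated DRG neuron."""

    id: str
    truth_category: str = "NC"
    ap_class: str = "broad"           # broad = C/Adelta responder
    soma_diameter_um: float = 25.0
    baseline_f: float = 0.0           # extra per-cell baseline offset, a.u.
    force_threshold_mN: float = 50.0
    spikes_per_force: Mapping[float, int] = field(
        default_factory=lambda: dict(DEFAULT_SPIKES_PER_FORCE))
    heat_sensitive: bool = False
    direct_IS_response: bool = False
    top_layer: bool = True

    def __post_init__(self):
        if self.truth_category not in CATEGORIES:
            raise DesignError(f"unknown category {self.truth_category!r}")
        if self.ap_class not in ("broad", "narrow"):
            raise DesignError(f"unknown ap_class {self.ap_class!r}")
        counts = [self.spikes_per_force[f]
                  for f in sorted(self.spikes_per_force)]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise DesignError("spikes_per_force must be nondecreasing")

    @property
    def ca_gain(self) -> float:
        return 1.0 if self.ap_class == "broad" else NARROW_CLASS_GAIN

    def mechanical_spike_count(self, force_mN: float) -> int:
        if force_mN < self.force_threshold_mN:
            return 0
        usable = [f for f in self.spikes_per_force if f <= force_mN]
        return int(self.spikes_per_force[max(usable)]) if usable else 0


@dataclass(frozen=True)
class CohortDesign:
    """Counts per ground-truth category for one experimental arm."""

    n_cells: Mapping[str, int]
    arm: str = "IS"
    effect_size_sd: float = 5.0
    forces_mN: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0)
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ARMS:
            raise DesignError(f"unknown arm {self.arm!r}")
        for cat, n in self.n_cells.items():
            if cat not in CATEGORIES:
                raise DesignError(f"unknown category {cat!r}")
            if n < 0:
                raise DesignError("cell counts must be non-negative")
        if self.arm in ("uninjected", "vehicle", "heat_only"):
            bad = [c for c in ("I", "D", "lost", "SA")
                   if self.n_cells.get(c, 0) > 0]
            if bad:
                raise DesignError(
                    f"{self.arm} arm cannot carry plasticity categories "
                    f"{bad}; controls have no simulated effect")
        if self.effect_size_sd <= 0:
            raise DesignError("effect_size_sd must be positive")

    @property
    def total_cells(self) -> int:
        return int(sum(self.n_cells.values()))


# paper-scale designs used throughout tests and the acceptance study
IS_DESIGN = CohortDesign({"NC": 23, "I": 10, "D": 12, "SA": 2}, arm="IS")
HEAT_IS_DESIGN = CohortDesign({"NC": 11, "I": 6, "D": 14, "SA": 8},
                              arm="heat_plus_IS")
VEHICLE_DESIGN = CohortDesign({"NC": 83}, arm="vehicle")
HEAT_ONLY_DESIGN = CohortDesign({"NC": 30}, arm="heat_only")


# ---------------------------------------------------------------------------
# spikes


def _cell_rng(seed: int, cell_id: str, salt: int = 0) -> np.random.Generator:
    """Independent substream per cell, stable under cohort reordering."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(cell_id.encode()), salt]))


def simulate_spikes(cell: SimCell, event: StimulusEvent, seed: int = 0,
                    fidelity: float = 1.0,
                    post_exposure: bool = False) -> list[float]:
    """Spike times (s) evoked in ``cell`` by one stimulus event.

    Electrical trains fire one spike per pulse; ``fidelity`` is the
    per-pulse following probability at >= 100 Hz (1.0 below).  Mechanical
    holds spread the cell's force-dependent spike count uniformly over
    the hold.  Silent afferents fire no mechanical spikes before
    exposure (``post_exposure=False``).  Unknown or inapplicable kinds
    yield an empty train.
    """
    if event.kind == "electrical_train":
        freq = float(event.params["frequency_Hz"])
        n = int(event.params.get(
            "n_pulses", max(1, round(freq * event.duration_s))))
        times = event.onset_s + np.arange(n) / freq
        if freq >= 100.0 and fidelity < 1.0:
            rng = np.random.default_rng(seed)
            times = times[rng.random(n) < fidelity]
        return list(times)
    if event.kind == "mechanical":
        if cell.truth_category == "SA" and not post_exposure:
            return []
        n = cell.mechanical_spike_count(float(event.params["force_mN"]))
        if n == 0:
            return []
        return list(event.onset_s + np.arange(n) * event.duration_s / n)
    if event.kind == "high_K":
        # sustained depolarization: regular 20 Hz drive for the whole
        # application produces the plateau-like summated transient
        n = max(1, int(round(20.0 * event.duration_s)))
        return list(event.onset_s + np.arange(n) / 20.0)
    if event.kind == "infusion_IS":
        if cell.direct_IS_response:
            return list(event.onset_s + np.arange(4) * event.duration_s / 4)
        return []
    if event.kind == "heat":
        if cell.heat_sensitive and cell.top_layer:
            return list(event.onset_s + np.arange(6) * event.duration_s / 6)
        return []
    return []


# ---------------------------------------------------------------------------
# fluorescence


def spikes_to_calcium(spikes: Sequence[float], kinetics: KineticsParams,
                      times: np.ndarray, gain: float = 1.0) -> np.ndarray:
    """Calcium concentration at the given times (nM)."""
    c = np.full(times.shape, kinetics.ca_rest_nM, dtype=float)
    amp = gain * kinetics.ca_per_spike_nM
    for s in spikes:
        m = times >= s
        c[m] += amp * np.exp(-(times[m] - s) / kinetics.tau_decay_s)
    return c


def spikes_to_fluorescence(spikes: Sequence[float],
                           kinetics: KineticsParams,
                           duration_s: float,
                           frame_interval_s: float,
                           gain: float = 1.0) -> FluorescenceTrace:
    """Render a spike train into a noiseless fluorescence trace.

    Samples at frame midpoints; with no spikes the trace sits at the
    resting operating point of the Hill readout.
    """
    n = int(round(duration_s / frame_interval_s))
    t = (np.arange(n) + 0.5) * frame_interval_s
    c = spikes_to_calcium(spikes, kinetics, t, gain)
    return FluorescenceTrace(kinetics.fluorescence(c), frame_interval_s)


def high_k_trace(kinetics: KineticsParams, amplitude_factor: float = 1.0,
                 duration_s: float = 40.0, onset_s: float = 10.0,
                 application_s: float = 15.0,
                 frame_interval_s: float = 1.0,
                 tau_decay_s: float = 8.0,
                 gain: float = 1.0) -> FluorescenceTrace:
    """Depolarization-evoked plateau transient for one K+ application.

    Calcium rises quickly to a plateau during the application and decays
    slowly (``tau_decay_s``, much slower than the spike-evoked decay)
    after washout; ``amplitude_factor`` implements the run-to-run
    amplitude decline of repeated applications.
    """
    n = int(round(duration_s / frame_interval_s))
    t = (np.arange(n) + 0.5) * frame_interval_s
    # 300 nM plateau sits where the Hill readout is locally linear in
    # amplitude, so relative ΔF/F declines track the amplitude factors
    amp = 300.0 * amplitude_factor * gain
    rise_tau = 1.0
    c = np.full(n, kinetics.ca_rest_nM)
    during = (t >= onset_s) & (t < onset_s + application_s)
    c[during] += amp * (1 - np.exp(-(t[during] - onset_s) / rise_tau))
    after = t >= onset_s + application_s
    plateau = amp * (1 - np.exp(-application_s / rise_tau))
    c[after] += plateau * np.exp(-(t[after] - onset_s - application_s)
                                 / tau_decay_s)
    return FluorescenceTrace(kinetics.fluorescence(c), frame_interval_s)


def make_k_series(n_cells: int, seed: int = 0,
                  kinetics: KineticsParams = DEFAULT_KINETICS,
                  decline_factors: Sequence[float] = HIGH_K_DECLINE,
                  nonresponder_fraction: float = HIGH_K_NONRESPONDER_FRACTION,
                  noise_sd_au: float = TRACE_NOISE_SD_AU,
                  ) -> tuple[list[list[FluorescenceTrace]], np.ndarray]:
    """Repeated K+ application series for a dissociated-culture cohort.

    Returns one trace per (cell, application) plus a boolean responder
    mask; non-responders (large-diameter cells) show no transient.
    """
    rng = np.random.default_rng(seed)
    n_nonresp = int(round(nonresponder_fraction * n_cells))
    responder = np.ones(n_cells, dtype=bool)
    if n_nonresp:
        responder[rng.choice(n_cells, size=n_nonresp, replace=False)] = False
    traces = []
    for i in range(n_cells):
        cell_gain = float(np.exp(rng.normal(0.0, SIGMA_SESSION)))
        row = []
        for factor in decline_factors:
            trial = factor * float(np.exp(rng.normal(0.0, SIGMA_TRIAL)))
            tr = high_k_trace(kinetics, amplitude_factor=trial,
                              gain=cell_gain if responder[i] else 0.0)
            vals = tr.values + rng.normal(0.0, noise_sd_au, tr.values.shape)
            row.append(FluorescenceTrace(np.clip(vals, 0, None),
                                         tr.frame_interval_s))
        traces.append(row)
    return traces, responder


# ---------------------------------------------------------------------------
# stack rendering


@dataclass(frozen=True)
class Optics:
    """Rendering geometry and corruption levels for synthetic movies."""

    image_hw: tuple[int, int] = (64, 64)
    soma_radius_px: float = 4.0
    background_au: float = 20.0
    blur_fraction: float = 0.0       # emission diverted to a wide halo
    blur_sigma_px: float = 6.0
    jitter_sd_px: float = 0.0        # rigid per-frame motion
    photons_per_au: float = 0.0      # >0 enables Poisson-like shot noise


def place_cells(n_cells: int, optics: Optics = Optics(),
                margin_px: int = 10) -> list[tuple[float, float]]:
    """Deterministic grid placement with no overlap."""
    h, w = optics.image_hw
    step = max(int(3.5 * optics.soma_radius_px), 1)
    xs = np.arange(margin_px, w - margin_px + 1, step)
    ys = np.arange(margin_px, h - margin_px + 1, step)
    coords = [(float(x), float(y)) for y in ys for x in xs]
    if len(coords) < n_cells:
        raise DesignError(
            f"cannot place {n_cells} cells on a {h}x{w} image")
    return coords[:n_cells]


def make_rois(cell_ids: Sequence[str],
              positions: Sequence[tuple[float, float]],
              optics: Optics = Optics(),
              with_controls: bool = True) -> list[ROI]:
    """Cell ROIs at the rendered positions plus flanking controls."""
    rois = []
    r = optics.soma_radius_px
    for cid, (x, y) in zip(cell_ids, positions):
        rois.append(ROI(cid, (x, y), r, role="cell"))
        if with_controls:
            rois.append(ROI(f"{cid}_adj", (x + 2 * r + 1, y), r,
                            role="adjacent_control", partner_id=cid))
    return rois


def render_stack(positions: Sequence[tuple[float, float]],
                 traces: Sequence[FluorescenceTrace],
                 optics: Optics = Optics(),
                 seed: int = 0) -> ImageStack:
    """Render fluorescence traces into a synthetic movie.

    Each cell is a Gaussian disc (sigma = soma_radius/2) whose brightness
    follows its trace; a wide Gaussian halo spreads ``blur_fraction`` of
    the emission to emulate out-of-focus contamination; rigid per-frame
    jitter and Poisson-like shot noise are applied on top.  With all
    corruption at zero, the ROI-mean of a rendered cell is an affine
    function of its input trace.
    """
    if not traces:
        raise DesignError("need at least one trace to render")
    h, w = optics.image_hw
    n_frames = len(traces[0].values)
    dt = traces[0].frame_interval_s
    yy, xx = np.mgrid[:h, :w]
    sigma = optics.soma_radius_px / 2.0
    discs = [np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
             for x, y in positions]
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        img = np.full((h, w), optics.background_au, dtype=float)
        for disc, tr in zip(discs, traces):
            img += float(tr.values[t]) * disc
        if optics.blur_fraction > 0:
            halo = ndimage.gaussian_filter(img - optics.background_au,
                                           optics.blur_sigma_px)
            img = (optics.background_au
                   + (1 - optics.blur_fraction) * (img - optics.background_au)
                   + optics.blur_fraction * halo)
        if optics.jitter_sd_px > 0:
            shift = rng.normal(0.0, optics.jitter_sd_px, size=2)
            img = ndimage.shift(img, shift, order=1, mode="nearest")
        if optics.photons_per_au > 0:
            img = rng.poisson(np.clip(img, 0, None)
                              * optics.photons_per_au) / optics.photons_per_au
        frames[t] = img
    return ImageStack(frames, dt)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Cohort:
    """A paired pre/post simulated imaging experiment with ground truth."""

    design: CohortDesign
    cells: tuple[SimCell, ...]
    protocols: Mapping[str, StimulusProtocol]
    traces: Mapping[str, Mapping[str, FluorescenceTrace]]
    kinetics: KineticsParams

    @property
    def truth(self):
        import pandas as pd

        return pd.DataFrame(
            [{"cell_id": c.id, "truth_category": c.truth_category,
              "heat_sensitive": c.heat_sensitive,
              "direct_IS_response": c.direct_IS_response,
              "top_layer": c.top_layer} for c in self.cells])


def _assign_flags(cells_by_cat: Mapping[str, list[str]], rates: Mapping[str, float]) -> set[str]:
    """Deterministically flag round(rate*n) cells per category."""
    flagged: set[str] = set()
    for cat, ids in cells_by_cat.items():
        k = int(round(rates.get(cat, 0.0) * len(ids)))
        flagged.update(ids[:k])
    return flagged


def make_cells(design: CohortDesign) -> list[SimCell]:
    """Materialize the ground-truth cell roster for a design."""
    by_cat: dict[str, list[str]] = {}
    cells: list[SimCell] = []
    idx = 0
    for cat in CATEGORIES:
        n = int(design.n_cells.get(cat, 0))
        ids = [f"{design.arm}_{cat}_{i:03d}" for i in range(n)]
        by_cat[cat] = ids
        idx += n
    expose_heat = design.arm in ("heat_plus_IS", "heat_only")
    expose_is = design.arm in ("IS", "heat_plus_IS")
    heat_ids = _assign_flags(by_cat, HEAT_SENSITIVE_RATE) if expose_heat else set()
    is_ids = _assign_flags(by_cat, DIRECT_IS_RATE) if expose_is else set()
    # silent afferents responding from the lowest force after conversion
    sa_ids = by_cat["SA"]
    n_low = int(round(SA_LOW_FORCE_FRACTION * len(sa_ids)))
    for cat in CATEGORIES:
        for j, cid in enumerate(by_cat[cat]):
            threshold = 50.0
            if cat == "SA" and j >= n_low:
                threshold = 100.0   # de novo sensitivity from 100 mN only
            cells.append(SimCell(
                id=cid, truth_category=cat,
                force_threshold_mN=threshold,
                heat_sensitive=cid in heat_ids,
                direct_IS_response=cid in is_ids))
    return cells


def _session_protocol(design: CohortDesign, label: str) -> StimulusProtocol:
    events = []
    t = 5.0
    if label == "post":
        if design.arm in ("heat_plus_IS", "heat_only"):
            events.append(StimulusEvent(
                "heat", onset_s=t, duration_s=3.0,
                params={"top_temp_C": 46.7, "bottom_temp_C": 36.9}))
            t += 10.0
        if design.arm in ("IS", "heat_plus_IS", "vehicle"):
            kind = ("infusion_vehicle" if design.arm == "vehicle"
                    else "infusion_IS")
            events.append(StimulusEvent(kind, onset_s=t, duration_s=10.0))
            t += 35.0   # leaves the 20 s post-infusion window stimulus-free
    for force in design.forces_mN:
        events.append(StimulusEvent(
            "mechanical", onset_s=t, duration_s=MECHANICAL_HOLD_S,
            params={"force_mN": float(force)}))
        t += MECHANICAL_HOLD_S + 8.0
    return StimulusProtocol(tuple(events), session_label=label)


def _effect_gain(category: str, effect_size_sd: float) -> float:
    if category == "I":
        return float(np.exp(effect_size_sd * SIGMA_PC))
    if category == "D":
        return float(np.exp(-effect_size_sd * SIGMA_PC))
    return 1.0


def _session_trace(cell: SimCell, protocol: StimulusProtocol,
                   kinetics: KineticsParams, rng: np.random.Generator,
                   effect_gain: float, post: bool,
                   frame_interval_s: float,
                   noise_sd_au: float) -> FluorescenceTrace:
    duration = protocol.events[-1].offset_s + 5.0
    n = int(round(duration / frame_interval_s))
    t = (np.arange(n) + 0.5) * frame_interval_s
    session_gain = float(np.exp(rng.normal(0.0, SIGMA_SESSION)))
    c = np.full(n, kinetics.ca_rest_nM)
    for event in protocol.events:
        lost = post and cell.truth_category == "lost" \
            and event.kind == "mechanical"
        if lost:
            continue
        spikes = simulate_spikes(cell, event, post_exposure=post)
        trial_gain = float(np.exp(rng.normal(0.0, SIGMA_TRIAL)))
        gain = cell.ca_gain * session_gain * trial_gain
        if post and event.kind == "mechanical":
            gain *= effect_gain
        amp = gain * kinetics.ca_per_spike_nM
        for s in spikes:
            m = t >= s
            c[m] += amp * np.exp(-(t[m] - s) / kinetics.tau_decay_s)
    values = kinetics.fluorescence(c) + cell.baseline_f
    if noise_sd_au > 0:
        values = values + rng.normal(0.0, noise_sd_au, n)
    return FluorescenceTrace(np.clip(values, 0, None), frame_interval_s)


def make_cohort(design: CohortDesign,
                kinetics: KineticsParams = DEFAULT_KINETICS,
                frame_interval_s: float = MECHANICAL_FRAME_INTERVAL_S,
                noise_sd_au: float = TRACE_NOISE_SD_AU) -> Cohort:
    """Paired pre/post sessions plus ground truth for one arm.

    The pre session is the ascending force series; the post session
    repeats it after the arm's exposure events (heat and/or infusion),
    with each cell's truth-category effect applied to its mechanical
    responses.  Every cell draws from its own seeded substream, so the
    cohort is reproducible and stable under reordering.
    """
    cells = make_cells(design)
    protocols = {"pre": _session_protocol(design, "pre"),
                 "post": _session_protocol(design, "post")}
    traces: dict[str, dict[str, FluorescenceTrace]] = {"pre": {}, "post": {}}
    for cell in cells:
        gain = _effect_gain(cell.truth_category, design.effect_size_sd)
        for salt, label in enumerate(("pre", "post")):
            rng = _cell_rng(design.seed, cell.id, salt)
            traces[label][cell.id] = _session_trace(
                cell, protocols[label], kinetics, rng, gain,
                post=(label == "post"), frame_interval_s=frame_interval_s,
                noise_sd_au=noise_sd_au)
    return Cohort(design=design, cells=tuple(cells), protocols=protocols,
                  traces=traces, kinetics=kinetics)
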