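"""Synthetic landmark recordings of a virtual sessile Ciona.

The generator produces 18-landmark contour time series with known ground
truth so every downstream stage (morphometry, ethogram, shape space,
clustering, HMM) can be tested without video data.  A recording is built
in three layers:

1. a semi-Markov state sequence over the three postural-engagement states
   (DPE, SePE, StaPE) with gamma dwell times and transitions routed
   DPE ↔ SePE ↔ StaPE only (no direct DPE ↔ StaPE jumps, matching the
   stereotyped transition structure of spontaneously behaving animals);
2. five latent postural modes — trunk contraction, oral-siphon closure,
   atrial-siphon closure, body bend, and vertical stretch — expressed as
   landmark displacement fields.  Contraction events are raised-cosine
   pulses in the coefficients of modes 1–3: DPE bouts pulse all three
   regions near-synchronously, SePE bouts pulse a strict subset, StaPE
   frames carry only sub-threshold background drift;
3. Gaussian tracking jitter and NaN dropout runs emulating markerless
   pose-estimation noise.

Frames are rendered as ``template + Σ w_k · mode_k + jitter``; the ground
truth records per-frame state labels, the event table and the mode-weight
trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .bodyplan import BodyPlan, default_body_plan
from .io import LandmarkSeries, write_dlc_csv as _write_dlc_csv, write_manifest

__all__ = [
    "SynthConfig", "StimulusConfig", "GroundTruth", "SynthEvent",
    "body_template", "mode_fields", "sample_state_sequence",
    "harmonic_mode_fields", "orthogonal_mode_fields", "render_frames", "simulate_recording", "simulate_cohort",
    "write_dlc_csv", "write_ground_truth",
]

STATES = ("DPE", "SePE", "StaPE")

# region name -> latent mode index carrying its contraction field
REGION_MODE = {"trunk": 0, "os": 1, "as": 2}


class GenerationError(RuntimeError):
    """Raised when rendering cannot produce a simple body polygon."""


# --------------------------------------------------------------------------
# configuration

@dataclass
class StimulusConfig:
    """From ``onset_frame`` on, swap in alternative dynamics.

    Emulates an acute mechanical stimulus: the animal is forced into a
    response state at onset and post-onset dwell/transition/amplitude
    parameters replace the spontaneous ones.
    """

    onset_frame: int = 0
    force_state: str = "DPE"
    dwell_scale: dict = field(default_factory=lambda: {"DPE": 1.8, "SePE": 1.0, "StaPE": 1.3})
    p_dpe: float = 0.6            # SePE -> DPE probability after onset
    amplitude_scale: float = 1.25


@dataclass
class SynthConfig:
    """Generation parameters; defaults define the reference study conditions."""

    n_frames: int = 18000          # 15 min at 20 Hz
    fps: float = 20.0
    seed: int = 0
    # gamma dwell (shape, scale) in seconds with realistic caps: contraction bouts are
    # seconds long, quiescent bouts a minute-scale but not unbounded
    state_dwell_params: dict = field(default_factory=lambda: {
        "DPE": (40.0, 0.25),       # mean 10 s, stereotyped (full contraction)
        "SePE": (2.5, 6.0),        # mean 15 s
        "StaPE": (2.5, 24.0),      # mean 60 s
    })
    state_dwell_caps: dict = field(default_factory=lambda: {
        "DPE": (7.0, 13.0), "SePE": (8.0, 60.0), "StaPE": (5.0, 150.0),
    })
    p_dpe: float = 0.20            # SePE -> DPE branch probability
    # fractional closure / shrink amplitudes per region, by state
    event_amplitudes: dict = field(default_factory=lambda: {
        "DPE": {"trunk": 0.45, "os": 0.75, "as": 0.65},
        "SePE": {"trunk": 0.30, "os": 0.45, "as": 0.50},
    })
    amplitude_jitter: float = 0.10  # fractional sd around the state amplitude
    pulse_rise_s: float = 0.8
    pulse_decay_s: float = 4.0
    sepe_gap_s: float = 4.0        # mean gap between SePE pulses
    n_modes: int = 5
    # AR(1) background drift of mode weights: per-mode sd and time constant
    background_sd: tuple = (0.001, 0.003, 0.003, 0.10, 0.08)
    background_tau_s: float = 4.0
    noise_sd: float = 1.0          # px tracking jitter (reference level)
    dropout_rate: float = 0.002    # per frame per landmark run-start prob.
    dropout_max_run: int = 10
    pixel_scale: float = 0.254     # mm per pixel
    stimulus: StimulusConfig | None = None
    custom_mode_fields: np.ndarray | None = None  # (n_modes, 18, 2) override
    background_clip: float | None = None  # clip AR(1) weights at +/- clip*sd

    def validate(self) -> None:
        for s, (shape, scale) in self.state_dwell_params.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"non-positive dwell parameter for state {s}")
        for state, amps in self.event_amplitudes.items():
            for region, a in amps.items():
                if not 0 <= a <= 1:
                    raise ValueError(f"amplitude {a} for {state}/{region} outside [0, 1]")
        if self.dropout_max_run < 0:
            raise ValueError("dropout_max_run must be >= 0")
        if self.n_frames <= 0 or self.fps <= 0:
            raise ValueError("n_frames and fps must be positive")


@dataclass
class SynthEvent:
    region: str
    onset: int
    peak: int
    offset: int
    amplitude: float


@dataclass
class GroundTruth:
    """Per-frame state labels, scripted events and latent mode weights."""

    state_labels: np.ndarray       # (T,) of {"DPE","SePE","StaPE"}
    event_table: list              # list[SynthEvent]
    mode_weights: np.ndarray       # (T, n_modes)


# --------------------------------------------------------------------------
# template geometry and mode fields

def body_template() -> np.ndarray:
    """Template outline: 18 landmarks (px) of a vertically mounted adult.

    Oral siphon points up at the top left, atrial siphon up-right, trunk
    tapering to the holdfast at the bottom.  The outline is kept smooth so
    that a low-order elliptic Fourier fit captures nearly all of its shape
    energy.
    """
    base = np.array([
        [152.0, 112.0],   # OS_base_dorsal
        [143.0,  62.0],   # OS_rim_dorsal
        [181.0,  60.0],   # OS_rim_ventral
        [196.0, 108.0],   # OS_base_ventral
        [226.0, 126.0],   # neck_ventral
        [252.0, 138.0],   # AS_base_ventral
        [278.0,  92.0],   # AS_rim_ventral
        [313.0, 114.0],   # AS_rim_dorsal
        [291.0, 163.0],   # AS_base_dorsal
        [301.0, 221.0],   # trunk_ventral_upper
        [291.0, 289.0],   # trunk_ventral_mid
        [264.0, 351.0],   # trunk_ventral_lower
        [213.0, 399.0],   # holdfast
        [164.0, 355.0],   # trunk_dorsal_lower
        [143.0, 294.0],   # trunk_dorsal_mid
        [134.0, 231.0],   # trunk_dorsal_upper
        [131.0, 180.0],   # neck_dorsal_lower
        [136.0, 139.0],   # neck_dorsal
    ])
    # scaled so the mounted animal stands ~11 cm tall at 0.254 mm/px
    return 1.3 * base


def mode_fields(plan: BodyPlan | None = None,
                template: np.ndarray | None = None) -> np.ndarray:
    """Displacement fields (n_modes, 18, 2) of the five latent modes.

    Modes 0–2 are the contraction fields: at weight ``w`` the trunk polygon
    shrinks toward its centroid by the fraction ``w`` (mode 0) and each
    siphon's rim pair closes by the fraction ``w`` of its opening (modes
    1–2, with the siphon base points pulled partway toward the quad
    centroid).  Mode 3 bends the body laterally about the holdfast; mode 4
    stretches it vertically.  All fields are smooth along the contour so
    their shape energy stays within the first ten EFD harmonics.
    """
    plan = plan or default_body_plan()
    tpl = body_template() if template is None else template
    n = plan.n_landmarks
    fields = np.zeros((5, n, 2))

    # mode 0: trunk contraction toward the trunk centroid
    trunk = list(plan.trunk_polygon)
    centroid = tpl[trunk].mean(axis=0)
    for i in trunk:
        fields[0, i] = centroid - tpl[i]

    # modes 1-2: siphon closure (rim pair -> midpoint; bases 30% -> centroid)
    for m, (pair, quad) in enumerate(
            [(plan.os_width_pair, plan.os_quad), (plan.as_width_pair, plan.as_quad)],
            start=1):
        mid = tpl[list(pair)].mean(axis=0)
        qc = tpl[list(quad)].mean(axis=0)
        for i in pair:
            fields[m, i] = mid - tpl[i]
        for i in quad:
            if i not in pair:
                fields[m, i] = 0.3 * (qc - tpl[i])

    # mode 3: lateral bend pivoting at the holdfast, saturating above
    # mid-body so the upper body (and both siphons) translates rigidly and
    # the bend leaves siphon widths untouched
    y = tpl[:, 1]
    y_hold, y_top = y.max(), y.min()
    h = y_hold - y_top
    u = np.minimum((y_hold - y) / h, 0.72) / 0.72
    fields[3, :, 0] = 40.0 * u ** 2

    # mode 4: vertical stretch anchored at the holdfast, compensated in x
    # so it is area-preserving to first order (a postural elongation, not
    # a contraction: it must stay invisible to the area channels)
    fields[4, :, 1] = -25.0 * (y_hold - y) / h
    fields[4, :, 0] = 25.0 * (tpl[:, 0] - tpl[:, 0].mean()) / h

    # the slow postural modes translate each siphon quad rigidly (the
    # field evaluated at the quad centroid), so siphon widths and areas
    # carry no slow drift at all: quiescence must stay sub-threshold
    for m in (3, 4):
        for quad in (plan.os_quad, plan.as_quad):
            fields[m, list(quad)] = fields[m, list(quad)].mean(axis=0)
    return fields


# --------------------------------------------------------------------------
# state sequence

def _dwell_frames(rng: np.random.Generator, cfg: SynthConfig, state: str,
                  scale_mult: float = 1.0) -> int:
    shape, scale = cfg.state_dwell_params[state]
    seconds = rng.gamma(shape, scale * scale_mult)
    lo, hi = cfg.state_dwell_caps.get(state, (0.05, np.inf))
    seconds = float(np.clip(seconds, lo, hi * scale_mult))
    return max(1, int(round(seconds * cfg.fps)))


def _next_state(rng: np.random.Generator, state: str, p_dpe: float) -> str:
    # transition graph: DPE <-> SePE <-> StaPE only
    if state == "SePE":
        return "DPE" if rng.random() < p_dpe else "StaPE"
    return "SePE"


def harmonic_mode_fields(plan: BodyPlan | None = None,
                         harmonics: tuple = (2, 3, 4, 5, 6),
                         scale: float = 9.0) -> np.ndarray:
    """Radial-harmonic latent-mode basis (raw candidates).

    Mode k displaces each landmark radially from the outline centroid in
    proportion to cos(h_k * theta), where theta is the landmark's
    chord-length position along the contour.  A radius modulation at
    harmonic h maps mostly onto coordinate harmonics h±1, so these raw
    fields still overlap spectrally; :func:`orthogonal_mode_fields`
    combines such candidates into a basis whose amplitude signatures are
    actually orthogonal, which is what identifiability experiments use.
    """
    plan = plan or default_body_plan()
    tpl = body_template()
    pts = tpl[list(plan.body_polygon)]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    tcum = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    theta = 2.0 * np.pi * tcum / seg.sum()
    centroid = pts.mean(axis=0)
    radial = pts - centroid
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    fields = np.zeros((len(harmonics), plan.n_landmarks, 2))
    for k, h in enumerate(harmonics):
        prof = np.cos(h * theta)
        for j, idx in enumerate(plan.body_polygon):
            fields[k, idx] = scale * prof[j] * radial[j]
    return fields


def orthogonal_mode_fields(plan: BodyPlan | None = None,
                           n_modes: int = 5, scale: float = 7.0,
                           order: int = 30) -> np.ndarray:
    """Latent-mode basis whose EFD amplitude signatures are orthogonal.

    Radial-harmonic candidate fields (cos/sin profiles at harmonics 2-6)
    are linearized through the full EFD normalization chain and combined
    by SVD so the resulting modes perturb the 10-harmonic amplitude
    spectrum along mutually orthogonal directions.  Deterministic; used
    by the mode-recovery (identifiability) experiments.
    """
    from .efd import amplitude_spectrum, efd_coefficients, normalize_efd

    plan = plan or default_body_plan()
    tpl = body_template()
    oi = list(plan.body_polygon)
    pts = tpl[oi]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    theta = 2 * np.pi * np.concatenate([[0.0], np.cumsum(seg)])[:-1] / seg.sum()
    radial = pts - pts.mean(axis=0)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)

    cands = []
    for h in (2, 3, 4, 5, 6):
        for phase in (0.0, np.pi / 2):
            F = np.zeros((plan.n_landmarks, 2))
            for j, idx in enumerate(oi):
                F[idx] = np.cos(h * theta[j] + phase) * radial[j]
            cands.append(9.0 * F)
    cands = np.array(cands)

    def signature(F, eps=0.1):
        up = amplitude_spectrum(normalize_efd(
            efd_coefficients((tpl + eps * F)[oi], order)), 10)
        dn = amplitude_spectrum(normalize_efd(
            efd_coefficients((tpl - eps * F)[oi], order)), 10)
        return (up - dn) / (2 * eps)

    S = np.array([signature(F) for F in cands])
    U, _, _ = np.linalg.svd(S, full_matrices=False)
    fields = np.einsum("ck,cij->kij", U[:, :n_modes], cands)
    for k in range(n_modes):
        fields[k] *= scale / np.sqrt((fields[k] ** 2).sum() / plan.n_landmarks)
    return fields


def sample_state_sequence(cfg: SynthConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-frame semi-Markov state labels.

    Dwell times are gamma-distributed per state; the transition graph never
    routes DPE and StaPE into each other directly.  With an attached
    :class:`StimulusConfig`, the forced response state begins at the onset
    frame and post-onset dynamics use the stimulus parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    labels = np.empty(cfg.n_frames, dtype=object)
    stim = cfg.stimulus
    t = 0
    state = "StaPE"
    post = False
    while t < cfg.n_frames:
        if stim is not None and not post and t >= stim.onset_frame:
            state = stim.force_state
            post = True
        scale_mult = stim.dwell_scale.get(state, 1.0) if (stim and post) else 1.0
        p_dpe = stim.p_dpe if (stim and post) else cfg.p_dpe
        dur = _dwell_frames(rng, cfg, state, scale_mult)
        end = min(t + dur, cfg.n_frames)
        if stim is not None and not post and end > stim.onset_frame:
            end = stim.onset_frame  # truncate the bout straddling the onset
        labels[t:end] = state
        t = end
        state = _next_state(rng, state, p_dpe)
    return labels


def _run_lengths(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """(state, start, end_exclusive) bouts of a label sequence."""
    bouts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bouts.append((str(labels[start]), start, i))
            start = i
    return bouts


# --------------------------------------------------------------------------
# event scheduling and rendering

def _raised_cosine(n_rise: int, n_decay: int) -> np.ndarray:
    """Unit-amplitude pulse: cosine rise to 1 then cosine decay to 0."""
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise + 1) / n_rise))
    down = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_decay + 1) / n_decay))
    return np.concatenate([up, down])


def _schedule_events(bouts, cfg: SynthConfig,
                     rng: np.random.Generator) -> list[SynthEvent]:
    """Scripted contraction events for every DPE/SePE bout."""
    events: list[SynthEvent] = []
    n_rise = max(2, int(round(cfg.pulse_rise_s * cfg.fps)))
    n_decay = max(2, int(round(cfg.pulse_decay_s * cfg.fps)))
    pulse_len = n_rise + n_decay
    stim = cfg.stimulus

    def amp(state: str, region: str, post: bool) -> float:
        a = cfg.event_amplitudes[state][region]
        if post and stim is not None:
            a *= stim.amplitude_scale
        a *= 1.0 + cfg.amplitude_jitter * rng.standard_normal()
        return float(np.clip(a, 0.05, 0.9))

    for state, start, end in bouts:
        if state == "StaPE":
            continue
        post = stim is not None and start >= stim.onset_frame
        t = start + rng.integers(0, max(1, n_rise // 2))
        if state == "DPE":
            # one stereotyped full-contraction pulse spanning the bout:
            # fast rise, slow relaxation, near-synchronous in all regions
            bout = end - start
            nr = max(2, int(round(0.2 * bout)))
            nd = max(2, int(round(0.75 * bout)))
            for region in ("trunk", "os", "as"):
                jit = int(rng.integers(0, max(1, int(0.2 * cfg.fps)) + 1))
                onset = min(start + jit, end - (nr + nd) - 1)
                onset = max(onset, start)
                events.append(SynthEvent(region, onset, onset + nr,
                                         onset + nr + nd,
                                         amp("DPE", region, post)))
        else:  # SePE: strict subsets of the three regions
            subsets = [("os",), ("as",), ("os", "as"), ("trunk",)]
            probs = np.array([0.3, 0.25, 0.25, 0.2])
            gap = max(1, int(round(cfg.sepe_gap_s * cfg.fps)))
            first = True
            while t + pulse_len <= end:
                chosen = subsets[rng.choice(len(subsets), p=probs)]
                for region in chosen:
                    events.append(SynthEvent(region, t, t + n_rise,
                                             t + pulse_len,
                                             amp("SePE", region, post)))
                first = False
                t += pulse_len + int(rng.integers(gap // 2 + 1, 2 * gap))
            if first and end - start > n_rise + 2:
                # short bout: fit a compressed pulse so no SePE bout is silent
                nr = max(2, (end - start) // 3)
                nd = max(2, (end - start) - nr - 1)
                events.append(SynthEvent("os", start, start + nr,
                                         start + nr + nd, amp("SePE", "os", post)))
    return events


def _mode_weight_traces(labels: np.ndarray, events: list[SynthEvent],
                        cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    T = len(labels)
    w = np.zeros((T, cfg.n_modes))
    # AR(1) background drift
    rho = float(np.exp(-1.0 / (cfg.fps * cfg.background_tau_s)))
    innov_sd = np.asarray(cfg.background_sd[:cfg.n_modes]) * np.sqrt(1 - rho ** 2)
    eps = rng.standard_normal((T, cfg.n_modes)) * innov_sd
    for t in range(1, T):
        w[t] = rho * w[t - 1] + eps[t]
    if cfg.background_clip is not None:
        lim = cfg.background_clip * np.asarray(cfg.background_sd[:cfg.n_modes])
        np.clip(w, -lim, lim, out=w)
    # contraction pulses routed into modes 0-2
    for ev in events:
        m = REGION_MODE[ev.region]
        n_rise = ev.peak - ev.onset
        n_decay = ev.offset - ev.peak
        pulse = ev.amplitude * _raised_cosine(n_rise, n_decay)
        seg = slice(ev.onset, min(ev.offset + 1, T))
        w[seg, m] += pulse[: seg.stop - seg.start]
    np.clip(w[:, :3], None, 0.88, out=w[:, :3])
    return w


def render_frames(states: np.ndarray, cfg: SynthConfig,
                  plan: BodyPlan | None = None,
                  rng: np.random.Generator | None = None,
                  events: list[SynthEvent] | None = None,
                  ) -> tuple[LandmarkSeries, GroundTruth]:
    """Render a state sequence into landmark coordinates plus ground truth.

    Each frame is ``template + Σ w_k · mode_k + jitter``; dropout runs are
    injected as NaN with likelihood 0.  Frames whose body polygon
    self-intersects after jitter are re-jittered (up to 20 draws).
    """
    cfg.validate()
    plan = plan or default_body_plan()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    tpl = body_template()
    if cfg.custom_mode_fields is not None:
        fields = np.asarray(cfg.custom_mode_fields, dtype=float)[: cfg.n_modes]
    else:
        fields = mode_fields(plan, tpl)[: cfg.n_modes]
    T = len(states)

    bouts = _run_lengths(states)
    if events is None:
        events = _schedule_events(bouts, cfg, rng)
    weights = _mode_weight_traces(states, events, cfg, rng)

    clean = tpl[None, :, :] + np.einsum("tk,kij->tij", weights, fields)
    coords = clean + rng.standard_normal((T, plan.n_landmarks, 2)) * cfg.noise_sd

    order = list(plan.body_polygon)
    n_resampled = 0
    for t in range(T):
        tries = 0
        while not Polygon(coords[t, order]).is_valid:
            if tries >= 20:
                raise GenerationError(f"frame {t}: no simple polygon after 20 jitter draws")
            coords[t] = clean[t] + rng.standard_normal((plan.n_landmarks, 2)) * cfg.noise_sd
            tries += 1
            n_resampled += 1

    likelihood = np.clip(1.0 - np.abs(rng.standard_normal((T, plan.n_landmarks))) * 0.01,
                         0.0, 1.0)
    # dropout: NaN runs with likelihood 0, per landmark
    if cfg.dropout_rate > 0 and cfg.dropout_max_run > 0:
        starts = rng.random((T, plan.n_landmarks)) < cfg.dropout_rate
        run_len = rng.integers(1, cfg.dropout_max_run + 1, size=(T, plan.n_landmarks))
        for t, k in zip(*np.nonzero(starts)):
            seg = slice(t, min(t + run_len[t, k], T))
            coords[seg, k] = np.nan
            likelihood[seg, k] = 0.0

    series = LandmarkSeries(coords=coords, likelihood=likelihood, fps=cfg.fps,
                            pixel_scale=cfg.pixel_scale)
    truth = GroundTruth(state_labels=np.asarray(states, dtype=object),
                        event_table=events, mode_weights=weights)
    return series, truth


def simulate_recording(cfg: SynthConfig, plan: BodyPlan | None = None,
                       animal_id: str = "animal0", condition: str = "control",
                       ) -> tuple[LandmarkSeries, GroundTruth]:
    """One seeded recording: state sequence, rendering, metadata."""
    rng = np.random.default_rng(cfg.seed)
    states = sample_state_sequence(cfg, rng)
    series, truth = render_frames(states, cfg, plan, rng)
    series.animal_id = animal_id
    series.condition = condition
    if cfg.stimulus is not None:
        series.stimulus_onset = cfg.stimulus.onset_frame
    return series, truth


def simulate_cohort(n_animals: int, cfg: SynthConfig | None = None,
                    seeds: list[int] | None = None, condition: str = "control",
                    plan: BodyPlan | None = None,
                    ) -> list[tuple[LandmarkSeries, GroundTruth]]:
    """Independent recordings sharing one configuration, one seed each."""
    cfg = cfg or SynthConfig()
    if seeds is None:
        seeds = [cfg.seed + i for i in range(n_animals)]
    out = []
    for i, seed in enumerate(seeds[:n_animals]):
        c = replace(cfg, seed=int(seed))
        out.append(simulate_recording(c, plan, animal_id=f"{condition}_{i:02d}",
                                      condition=condition))
    return out


# --------------------------------------------------------------------------
# serialization

def write_dlc_csv(series: LandmarkSeries, path: str | Path,
                  plan: BodyPlan | None = None) -> Path:
    """Write a rendered recording in the DLC CSV dialect."""
    return _write_dlc_csv(series, path, plan or default_body_plan())


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Ground truth as JSON: run-length states, event records, mode weights."""
    path = Path(path)
    runs = [{"state": s, "start": int(a), "end": int(b)}
            for s, a, b in _run_lengths(truth.state_labels)]
    events = [{"region": ev.region, "onset": int(ev.onset),
               "peak": int(ev.peak), "offset": int(ev.offset),
               "amplitude": float(ev.amplitude)}
              for ev in truth.event_table]
    payload = {
        "state_runs": runs,
        "events": events,
        "mode_weights": np.asarray(truth.mode_weights).tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def write_cohort(recordings, out_dir: str | Path,
                 plan: BodyPlan | None = None) -> Path:
    """Write DLC CSVs, ground-truth JSONs and the recording manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = plan or default_body_plan()
    records = []
    for series, truth in recordings:
        csv_path = out_dir / f"{series.animal_id}.csv"
        _write_dlc_csv(series, csv_path, plan)
        write_ground_truth(truth, out_dir / f"{series.animal_id}_truth.json")
        records.append({
            "animal_id": series.animal_id, "path": csv_path.name,
            "condition": series.condition,
            "stimulus_onset_frame": series.stimulus_onset if series.stimulus_onset is not None else "",
            "pixel_scale_mm_per_px": series.pixel_scale, "fps": series.fps,
        })
    return write_manifest(records, out_dir / "manifest.csv")
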