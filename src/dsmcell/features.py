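"""Action-potential feature extraction and protocol-level experiments.

Features extracted from a voltage trace:

* **RMP** — mean voltage over the last 100 ms before stimulus onset.
* **spike detection** — a local maximum exceeding RMP + 30 mV whose
  preceding upstroke reaches at least the dV/dt onset criterion
  (5 mV/ms by default).
* **threshold voltage** — the voltage where the spike upstroke leaves
  the quiescent near-threshold crawl: from the point of maximal dV/dt
  the trace is walked backwards to the last sample below the onset
  criterion (1.8 mV/ms by default, a calibrated constant distinct from
  the 5 mV/ms detection gate), so a fast passive deflection at
  stimulus onset cannot masquerade as the AP threshold.
* **AP duration** — time from the threshold crossing until the voltage
  falls back below the threshold level, so changes in the sub-peak
  shoulder register in the duration.
* **AHP depth** — RMP minus the post-peak minimum.
* **non-physiological flag** — the post-spike voltage fails to return
  within 10 mV of the pre-stimulus RMP within 500 ms of the peak, or a
  second regenerative spike occurs after the stimulus has ended.

``threshold_search`` performs a bisection on a fixed amplitude grid and
returns the smallest grid amplitude that elicits a spike.
``conductance_sweep`` and ``knockout_experiment`` drive the sensitivity
and channel-deletion protocols.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import BracketError, ConfigurationError
from .simulator import (
    CellModel,
    SimulationResult,
    Stimulus,
    initial_state,
    run,
    scale_gmax,
    with_gmax,
)
from .stimuli import AlphaSynapse, PulseStimulus

__all__ = [
    "APFeatures",
    "SweepResult",
    "extract_features",
    "threshold_search",
    "conductance_sweep",
    "knockout_experiment",
]

DVDT_THRESHOLD_MV_MS = 5.0
ONSET_DVDT_MV_MS = 1.8
SPIKE_AMP_MV = 30.0
RETURN_WINDOW_MS = 500.0
RETURN_MARGIN_MV = 10.0
RMP_WINDOW_MS = 100.0


@dataclass
class APFeatures:
    """Features of (at most) the first action potential in a trace."""

    rmp_mv: float
    spike_detected: bool
    threshold_v_mv: float = math.nan
    peak_v_mv: float = math.nan
    peak_t_ms: float = math.nan
    ap_duration_ms: float = math.nan
    ahp_depth_mv: float = math.nan
    n_spikes: int = 0
    nonphysiological: bool = False

    def __post_init__(self) -> None:
        if self.spike_detected and not (
            self.peak_v_mv > self.threshold_v_mv >= self.rmp_mv - 1e-6
        ):
            raise ConfigurationError(
                "inconsistent AP features: expected peak > threshold > RMP, "
                f"got {self.peak_v_mv!r} / {self.threshold_v_mv!r} / {self.rmp_mv!r}"
            )


@dataclass
class SweepResult:
    """Per-factor features of a conductance sweep, plus the same table
    normalized to the factor-1.0 row."""

    channel: str
    factors: Tuple[float, ...]
    features: List[APFeatures]
    normalized: Dict[str, np.ndarray] = field(default_factory=dict)
    failed: List[float] = field(default_factory=list)


def _find_spikes(
    t: np.ndarray,
    v: np.ndarray,
    dvdt: np.ndarray,
    rmp: float,
    start_idx: int,
    dvdt_threshold: float,
    spike_amp: float,
) -> List[int]:
    """Indices of qualifying spike peaks at/after ``start_idx``."""
    peaks: List[int] = []
    lo = max(start_idx, 1)
    for i in range(lo, len(v) - 1):
        if v[i] >= v[i - 1] and v[i] > v[i + 1] and v[i] > rmp + spike_amp:
            j0 = np.searchsorted(t, t[i] - 10.0)
            if dvdt[j0 : i + 1].max() >= dvdt_threshold:
                if peaks and i - peaks[-1] < int(round(1.0 / (t[1] - t[0]))):
                    continue  # same peak plateau
                peaks.append(i)
    return peaks


def extract_features(
    trace: SimulationResult,
    stim_onset_ms: Optional[float] = None,
    stim_end_ms: Optional[float] = None,
    settle_ms: float = 500.0,
    dvdt_threshold: float = DVDT_THRESHOLD_MV_MS,
    onset_dvdt: float = ONSET_DVDT_MV_MS,
    spike_amp_mv: float = SPIKE_AMP_MV,
    return_window_ms: float = RETURN_WINDOW_MS,
    return_margin_mv: float = RETURN_MARGIN_MV,
) -> APFeatures:
    """Extract AP features from a simulated trace.

    Parameters
    ----------
    trace : SimulationResult
        Voltage trajectory; must extend beyond ``settle_ms``.
    stim_onset_ms : float, optional
        Stimulus onset; the RMP window is the 100 ms preceding it and
        spikes are searched from it onward.  Defaults to ``settle_ms``.
    stim_end_ms : float, optional
        End of the stimulus; a second spike after this time marks the
        trace non-physiological (regenerative activity without drive).
    """
    t, v = np.asarray(trace.t_ms), np.asarray(trace.v_mv)
    if t[-1] <= settle_ms:
        raise ConfigurationError(
            f"trace ends at {t[-1]:.1f} ms, shorter than the settle window "
            f"({settle_ms:.1f} ms)"
        )
    onset = settle_ms if stim_onset_ms is None else stim_onset_ms
    w_lo = np.searchsorted(t, max(onset - RMP_WINDOW_MS, 0.0))
    w_hi = max(np.searchsorted(t, onset), w_lo + 1)
    rmp = float(v[w_lo:w_hi].mean())

    dvdt = np.gradient(v, t)
    start_idx = int(np.searchsorted(t, onset))
    peaks = _find_spikes(t, v, dvdt, rmp, start_idx, dvdt_threshold, spike_amp_mv)
    if not peaks:
        return APFeatures(rmp_mv=rmp, spike_detected=False)

    p = peaks[0]
    # threshold: from the upstroke maximum (largest dV/dt before the
    # peak) walk back to the last sample below the onset criterion —
    # i.e. the exit from the quiescent near-threshold crawl into the
    # regenerative rise.  A fast passive deflection at stimulus onset
    # is separated from the upstroke by that sub-criterion crawl, so at
    # near-threshold amplitudes it cannot be mistaken for threshold.
    up = start_idx + int(np.argmax(dvdt[start_idx : p + 1]))
    j = up
    while j > start_idx and dvdt[j - 1] >= onset_dvdt:
        j -= 1
    thr_idx = j
    threshold_v = float(v[thr_idx])

    # duration at the threshold-voltage level
    after = np.nonzero(v[p:] < threshold_v)[0]
    if after.size:
        dur = float(t[p + after[0]] - t[thr_idx])
    else:
        dur = math.nan
    ahp = float(rmp - v[p:].min())

    # physiological-return check
    nonphys = False
    win_end = t[p] + return_window_ms
    seg = v[p : np.searchsorted(t, win_end) + 1]
    if t[-1] >= win_end and not np.any(seg <= rmp + return_margin_mv):
        nonphys = True
    if stim_end_ms is not None:
        for q in peaks[1:]:
            if t[q] > stim_end_ms:
                nonphys = True
                break

    return APFeatures(
        rmp_mv=rmp,
        spike_detected=True,
        threshold_v_mv=threshold_v,
        peak_v_mv=float(v[p]),
        peak_t_ms=float(t[p]),
        ap_duration_ms=dur,
        ahp_depth_mv=ahp,
        n_spikes=len(peaks),
        nonphysiological=nonphys,
    )


def _default_spike_probe(
    model: CellModel,
    stimulus: Stimulus,
    t_stop_ms: float,
    dt_ms: float,
    settle_ms: float,
) -> Callable[[float], Tuple[bool, SimulationResult]]:
    init = initial_state(model)

    def probe(amplitude: float) -> Tuple[bool, SimulationResult]:
        stim = _with_amplitude(stimulus, amplitude)
        res = run(model, initial=init, stimulus=stim, t_stop_ms=t_stop_ms,
                  dt_ms=dt_ms, record_currents=False)
        feats = extract_features(
            res,
            stim_onset_ms=_onset(stim),
            settle_ms=settle_ms,
        )
        return feats.spike_detected, res

    return probe


def _with_amplitude(stimulus: Stimulus, amplitude: float) -> Stimulus:
    if isinstance(stimulus, PulseStimulus):
        return dataclasses.replace(stimulus, amplitude=amplitude)
    if isinstance(stimulus, AlphaSynapse):
        return dataclasses.replace(stimulus, g_peak_us=amplitude)
    raise ConfigurationError(
        "threshold_search needs a pulse or alpha-synapse template"
    )


def _onset(stimulus: Stimulus) -> float:
    return stimulus.onset_ms  # type: ignore[union-attr]


def threshold_search(
    model: CellModel,
    protocol_template: Stimulus,
    lo: float,
    hi: float,
    resolution: float,
    t_stop_ms: float = 400.0,
    dt_ms: float = 0.04,
    settle_ms: Optional[float] = None,
    spike: Optional[Callable[[float], bool]] = None,
) -> float:
    """Minimal spiking amplitude on the ``resolution`` grid, by bisection.

    The searched quantity is the pulse amplitude (stimulus units) for a
    :class:`PulseStimulus` template or the peak conductance (uS) for an
    :class:`AlphaSynapse` template.  ``lo`` must not spike and ``hi``
    must; otherwise a :class:`BracketError` is raised.  A custom
    ``spike`` predicate replaces the simulation probe (used for oracle
    tests).
    """
    if not (lo < hi):
        raise BracketError(f"invalid bracket: lo = {lo!r} >= hi = {hi!r}")
    if resolution <= 0.0:
        raise ConfigurationError("resolution must be > 0")
    if spike is None:
        onset = _onset(protocol_template)
        settle = onset if settle_ms is None else settle_ms
        probe = _default_spike_probe(
            model, protocol_template, t_stop_ms, dt_ms, settle
        )
        spike = lambda a: probe(a)[0]  # noqa: E731

    # snap the bracket onto the resolution grid
    n_lo = math.floor(lo / resolution + 1e-9)
    n_hi = math.ceil(hi / resolution - 1e-9)
    if not spike(n_hi * resolution):
        raise BracketError(
            f"no spike at the upper bracket amplitude {n_hi * resolution!r}"
        )
    if spike(n_lo * resolution):
        raise BracketError(
            f"spike already at the lower bracket amplitude {n_lo * resolution!r}"
        )
    while n_hi - n_lo > 1:
        mid = (n_lo + n_hi) // 2
        if spike(mid * resolution):
            n_hi = mid
        else:
            n_lo = mid
    return n_hi * resolution


def conductance_sweep(
    model: CellModel,
    channel: str,
    factors: Sequence[float],
    protocol: Stimulus,
    t_stop_ms: float = 900.0,
    dt_ms: float = 0.04,
) -> SweepResult:
    """Rescale one channel's gmax over ``factors``, rerun the protocol
    and tabulate features normalized to the factor-1.0 run.

    Runs that fail to integrate are recorded in ``failed`` rather than
    raised.  The normalized table divides each numeric feature by its
    value at factor 1.0 (sign preserved).
    """
    factors = tuple(float(f) for f in factors)
    if not any(abs(f - 1.0) < 1e-12 for f in factors):
        raise ConfigurationError("sweep factors must include 1.0")
    feats: List[APFeatures] = []
    failed: List[float] = []
    stim_end = None
    if isinstance(protocol, PulseStimulus):
        stim_end = protocol.onset_ms + protocol.duration_ms
    elif isinstance(protocol, AlphaSynapse):
        stim_end = protocol.onset_ms + 8.0 * protocol.tau_alpha_ms
    for f in factors:
        m = scale_gmax(model, {channel: f})
        try:
            res = run(
                m,
                initial=initial_state(m),
                stimulus=protocol,
                t_stop_ms=t_stop_ms,
                dt_ms=dt_ms,
                record_currents=False,
            )
            feats.append(
                extract_features(
                    res, stim_onset_ms=_onset(protocol), stim_end_ms=stim_end,
                    settle_ms=_onset(protocol),
                )
            )
        except Exception:
            failed.append(f)
            feats.append(APFeatures(rmp_mv=math.nan, spike_detected=False,
                                    nonphysiological=True))
    base_idx = min(
        range(len(factors)), key=lambda i: abs(factors[i] - 1.0)
    )
    base = feats[base_idx]
    normalized: Dict[str, np.ndarray] = {}
    for name in ("rmp_mv", "threshold_v_mv", "peak_v_mv", "ap_duration_ms",
                 "ahp_depth_mv"):
        ref = getattr(base, name)
        vals = np.array([getattr(ft, name) for ft in feats], dtype=float)
        normalized[name] = vals / ref if ref not in (0.0,) and np.isfinite(ref) \
            else np.full(len(feats), np.nan)
    return SweepResult(
        channel=channel,
        factors=factors,
        features=feats,
        normalized=normalized,
        failed=failed,
    )


def knockout_experiment(
    model: CellModel,
    mute: str,
    compensate: Optional[Dict[str, float]] = None,
    stimulus: Stimulus = None,
    t_stop_ms: float = 600.0,
    dt_ms: float = 0.04,
) -> Tuple[Tuple[SimulationResult, APFeatures], Tuple[SimulationResult, APFeatures]]:
    """Mute one channel (gmax = 0) and rerun; then additionally apply
    the compensation conductances (absolute gmax values, S/cm2) and
    rerun under the same stimulus.

    Returns ``((muted_result, muted_features), (compensated_result,
    compensated_features))``.  The experiment is reproduced when the
    muted run is spikeless and the compensated run spikes.
    """
    muted = with_gmax(model, mute, 0.0)
    comp = muted
    for name, gmax in (compensate or {}).items():
        comp = with_gmax(comp, name, gmax)
    out = []
    stim_end = None
    if isinstance(stimulus, PulseStimulus):
        stim_end = stimulus.onset_ms + stimulus.duration_ms
    for m in (muted, comp):
        res = run(
            m,
            initial=initial_state(m),
            stimulus=stimulus,
            t_stop_ms=t_stop_ms,
            dt_ms=dt_ms,
            record_currents=False,
        )
        feats = extract_features(
            res, stim_onset_ms=_onset(stimulus) if stimulus else None,
            stim_end_ms=stim_end,
            settle_ms=_onset(stimulus) if stimulus else 100.0,
        )
        out.append((res, feats))
    return out[0], out[1]
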