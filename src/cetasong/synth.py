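"""Synthetic session generation via a pressure-controlled valve model.

The whale vocal generator and the bassoon mouthpiece share one mechanical
idealization: a mass–damper–spring valve whose aperture ``z`` obeys

    m_s z̈ + r_s ż + k_s (z − z0) = p_r − p_m

with ``p_r`` and ``p_m`` the air pressures on the two sides of the valve
(trachea vs. laryngeal-sac entrance for the whale; mouth vs. bore for the
reed). The coefficients are per-unit-area quantities, so the right-hand side
is a pressure. With the flow coupling enabled, air passes the slit following
a quasi-static orifice law (flow ∝ aperture × √pressure-drop) into a
downstream air-sac compartment with acoustic compliance and a vent
resistance; the sac pressure rises with flow and pushes back on the valve.
That lagged negative feedback is the minimal closure that lets the valve
self-oscillate: below a threshold blowing pressure perturbations decay, above
it a periodic limit cycle is sustained.

On top of the oscillator, the module renders stylized song units (tonal
harmonic stacks with fundamental below 100 Hz and formant resonances up to
8 kHz, or pulsed burst trains), shapes them with attack–sustain–release
envelopes, and assembles whole stimulus–response sessions: each scheduled
concrete sound element (CSE) is followed by a unit sequence drawn from a
phrase grammar with controllable substitution/insertion/deletion noise. A
session is a pure function of its scenario, seed included.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotations import AnnotatedEvent, EventTable, TokenSequence

__all__ = [
    "ValveParams",
    "ValveState",
    "ValveTrajectory",
    "simulate_valve",
    "EnvelopeSpec",
    "UnitSpec",
    "render_unit",
    "SessionScenario",
    "generate_session",
    "perturb_sequence",
    "default_unit_spec",
    "default_cse_spec",
    "LayoutError",
]


class LayoutError(ValueError):
    """A scheduled stimulus collides with the previous response window."""


# ---------------------------------------------------------------------------
# Valve oscillator


@dataclass(frozen=True)
class ValveParams:
    """Mechanical and aerodynamic parameters of the valve oscillator.

    ``m_s``, ``r_s``, ``k_s`` are per-unit-area surface density (kg/m²),
    damping (kg/m²/s) and stiffness (Pa/m); defaults put the natural
    frequency near 80 Hz, in the tonal-unit range. ``slit_width`` is the
    effective lateral width of the aperture (the arytenoid slit is of order
    tens of centimetres). The sac compliance and vent resistance only matter
    when ``coupling`` is on.
    """

    m_s: float = 1.0
    r_s: float = 25.0
    k_s: float = 2.5e5
    z0: float = 1e-3
    slit_width: float = 0.2
    air_density: float = 1.2
    coupling: bool = False
    sac_compliance: float = 3.6e-7   # m^3/Pa
    vent_resistance: float = 1.0e4   # Pa s/m^3

    def __post_init__(self) -> None:
        if self.m_s <= 0 or self.k_s <= 0:
            raise ValueError("mass and stiffness must be positive")
        if self.r_s < 0:
            raise ValueError("damping must be non-negative")
        if self.z0 < 0:
            raise ValueError("rest aperture must be non-negative")
        if self.slit_width <= 0 or self.air_density <= 0:
            raise ValueError("slit width and air density must be positive")
        if self.sac_compliance <= 0 or self.vent_resistance <= 0:
            raise ValueError("sac compliance and vent resistance must be positive")

    @property
    def natural_frequency_hz(self) -> float:
        return np.sqrt(self.k_s / self.m_s) / (2 * np.pi)


@dataclass
class ValveState:
    """Instantaneous valve state (aperture clamped non-negative)."""

    z: float
    z_dot: float = 0.0
    p_r: float = 0.0
    p_m: float = 0.0
    flow: float = 0.0


@dataclass(frozen=True)
class ValveTrajectory:
    """Time series produced by :func:`simulate_valve`."""

    t: np.ndarray
    aperture: np.ndarray
    flow: np.ndarray
    radiated: np.ndarray        # ∝ d(flow)/dt, the far-field pressure proxy
    sac_pressure: np.ndarray
    sample_rate: float

    def to_csv(self, path) -> None:
        header = "t,z,flow"
        data = np.column_stack([self.t, self.aperture, self.flow])
        np.savetxt(path, data, delimiter=",", header=header, comments="")


def _orifice_flow(params: ValveParams, z: float, dp: float) -> float:
    """Quasi-static orifice law: flow ∝ aperture × √(pressure drop)."""
    if z <= 0 or dp <= 0:
        return 0.0
    return params.slit_width * z * np.sqrt(2.0 * dp / params.air_density)


def simulate_valve(
    params: ValveParams,
    pressure_schedule: Callable[[float], tuple[float, float] | float] | tuple[float, float] | float,
    duration: float,
    sample_rate: float,
    initial_state: ValveState | None = None,
    oversample: int = 4,
    clamp: bool = True,
) -> ValveTrajectory:
    """Integrate the valve equation with a fixed-step 4th-order scheme.

    ``pressure_schedule`` is a callable of time ``t`` (or a constant). With
    ``coupling`` off it must return ``(p_r, p_m)`` — both pressures imposed.
    With ``coupling`` on it returns the upstream (lung/trachea) pressure
    ``p_r``; the downstream sac pressure ``p_m`` is a state variable fed by
    the slit flow and vented through a resistance.

    Integration runs at ``oversample ×`` the output rate (≥ 4 recommended for
    robustness through the aperture clamp); the aperture is clamped at zero
    on contact (a closed valve cannot have negative opening). Pass
    ``clamp=False`` to integrate the unclamped linear oscillator, e.g. for
    closed-form comparisons.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if oversample < 1:
        raise ValueError("oversample must be ≥ 1")
    sched = pressure_schedule
    if not callable(sched):
        const = sched
        sched = lambda t: const  # noqa: E731

    n_out = int(round(duration * sample_rate))
    dt = 1.0 / (sample_rate * oversample)
    n_steps = n_out * oversample

    def pressures(t: float) -> tuple[float, float]:
        val = sched(t)
        if params.coupling:
            if np.ndim(val) != 0:
                raise ValueError("with coupling on, the schedule must return the lung pressure")
            return float(val), np.nan  # p_m is a state
        if np.ndim(val) == 0:
            raise ValueError("with coupling off, the schedule must return (p_r, p_m)")
        p_r, p_m = val
        return float(p_r), float(p_m)

    # probe the schedule at both ends so a too-short schedule fails early
    pressures(0.0)
    pressures(duration)

    st = initial_state or ValveState(z=params.z0)
    y = np.array([st.z, st.z_dot, st.p_m], dtype=float)

    m, r, k, z0 = params.m_s, params.r_s, params.k_s, params.z0
    C, R = params.sac_compliance, params.vent_resistance

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        z, v, p_m_state = y
        p_r, p_m_ext = pressures(t)
        p_m = p_m_state if params.coupling else p_m_ext
        zc = max(z, 0.0)
        acc = (p_r - p_m - r * v - k * (z - z0)) / m
        if params.coupling:
            flow = _orifice_flow(params, zc, p_r - p_m)
            dpm = (flow - p_m / R) / C
        else:
            dpm = 0.0
        return np.array([v, acc, dpm])

    t_out = np.arange(n_out) / sample_rate
    aperture = np.empty(n_out)
    flow_out = np.empty(n_out)
    sac_out = np.empty(n_out)

    t = 0.0
    for i in range(n_steps):
        if i % oversample == 0:
            j = i // oversample
            p_r, p_m_ext = pressures(t)
            p_m = y[2] if params.coupling else p_m_ext
            aperture[j] = max(y[0], 0.0) if clamp else y[0]
            flow_out[j] = _orifice_flow(params, max(y[0], 0.0), p_r - p_m)
            sac_out[j] = p_m
        k1 = deriv(t, y)
        k2 = deriv(t + dt / 2, y + dt / 2 * k1)
        k3 = deriv(t + dt / 2, y + dt / 2 * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # contact: clamp closed valve, kill closing velocity (inelastic)
        if clamp and y[0] < 0.0:
            y[0] = 0.0
            if y[1] < 0.0:
                y[1] = 0.0
        t += dt

    radiated = np.gradient(flow_out, 1.0 / sample_rate)
    return ValveTrajectory(
        t=t_out,
        aperture=aperture,
        flow=flow_out,
        radiated=radiated,
        sac_pressure=sac_out,
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# Unit rendering


@dataclass(frozen=True)
class EnvelopeSpec:
    """Attack–sustain–release amplitude envelope (durations in seconds)."""

    attack_s: float = 0.05
    sustain_s: float = 0.6
    release_s: float = 0.15
    sustain_level: float = 1.0

    def __post_init__(self) -> None:
        if min(self.attack_s, self.sustain_s, self.release_s) < 0:
            raise ValueError("envelope durations must be non-negative")
        if self.total_s <= 0:
            raise ValueError("envelope must have positive total duration")
        if not (0.0 <= self.sustain_level <= 1.0):
            raise ValueError("sustain level must lie in [0, 1]")

    @property
    def total_s(self) -> float:
        return self.attack_s + self.sustain_s + self.release_s

    def samples(self, sample_rate: float) -> np.ndarray:
        na = int(round(self.attack_s * sample_rate))
        ns = int(round(self.sustain_s * sample_rate))
        nr = int(round(self.release_s * sample_rate))
        attack = np.linspace(0.0, 1.0, na, endpoint=False) if na else np.empty(0)
        sustain = np.full(ns, self.sustain_level)
        release = np.linspace(self.sustain_level, 0.0, nr) if nr else np.empty(0)
        return np.concatenate([attack, sustain, release])


@dataclass(frozen=True)
class UnitSpec:
    """Recipe for one stylized vocalization.

    Tonal units are harmonic stacks at ``f0`` (whale fundamentals sit below
    100 Hz) colored by formant resonances (≤ 8 kHz); pulsed units are burst
    trains at ``pulse_rate``. The fundamental-frequency contour follows one
    of the six annotation contour classes.
    """

    label: str
    sound_type: str = "tonal"   # tonal | pulsed
    f0: float = 80.0
    pulse_rate: float | None = None
    contour: str = "flat"
    formants: tuple[tuple[float, float], ...] = ((600.0, 200.0), (1800.0, 400.0))
    envelope: EnvelopeSpec = field(default_factory=EnvelopeSpec)

    def __post_init__(self) -> None:
        if self.sound_type not in ("tonal", "pulsed"):
            raise ValueError(f"sound_type must be tonal|pulsed, got {self.sound_type!r}")
        if (self.pulse_rate is not None) != (self.sound_type == "pulsed"):
            raise ValueError("pulse_rate must be set iff the unit is pulsed")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        for fc, bw in self.formants:
            if fc > 8000.0:
                raise ValueError(f"formant center {fc} Hz exceeds the 8 kHz bound")
            if fc <= 0 or bw <= 0:
                raise ValueError("formant centers and bandwidths must be positive")


_CONTOUR_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "flat": lambda u: np.ones_like(u),
    "upsweep": lambda u: 0.8 + 0.5 * u,
    "downsweep": lambda u: 1.3 - 0.5 * u,
    "convex": lambda u: 1.0 + 0.25 * np.sin(np.pi * u),
    "concave": lambda u: 1.0 - 0.25 * np.sin(np.pi * u),
    "modulated": lambda u: 1.0 + 0.1 * np.sin(2 * np.pi * 4.0 * u),
}


def _formant_gain(formants, freqs: np.ndarray) -> np.ndarray:
    """Lorentzian resonance magnitude, peak-normalized across the stack."""
    if not formants:
        return np.ones_like(freqs)
    g = np.zeros_like(freqs, dtype=float)
    for fc, bw in formants:
        g += 1.0 / (1.0 + ((freqs - fc) / (bw / 2.0)) ** 2)
    return g / g.max() if g.max() > 0 else np.ones_like(freqs)


def render_unit(spec: UnitSpec, sample_rate: float) -> np.ndarray:
    """Render one unit; duration equals the envelope total (± one frame).

    Tonal: additive harmonics of the contour-modulated fundamental, each
    weighted 1/n and by the formant resonance gain at its frequency. Pulsed:
    a train of decaying bursts at ``pulse_rate``. The ASR envelope shapes the
    result, which is peak-normalized to 0.9.
    """
    nyquist = sample_rate / 2.0
    if spec.f0 >= nyquist:
        raise ValueError(f"f0 {spec.f0} Hz ≥ Nyquist {nyquist} Hz")
    env = spec.envelope.samples(sample_rate)
    n = len(env)
    if n == 0:
        raise ValueError("envelope renders to zero samples at this rate")
    u = np.arange(n) / max(n - 1, 1)
    try:
        shape = _CONTOUR_SHAPES[spec.contour]
    except KeyError:
        raise ValueError(f"unknown contour {spec.contour!r}") from None
    f0_traj = spec.f0 * shape(u)

    if spec.sound_type == "tonal":
        fmax = min(8000.0, 0.45 * sample_rate)
        n_harm = max(1, int(fmax / f0_traj.max()))
        x = np.zeros(n)
        for h in range(1, n_harm + 1):
            phase = 2 * np.pi * np.cumsum(h * f0_traj) / sample_rate
            gain = _formant_gain(spec.formants, np.array([h * spec.f0]))[0]
            x += (gain / h) * np.sin(phase)
    else:
        period = int(round(sample_rate / spec.pulse_rate))
        if period < 1:
            raise ValueError("pulse_rate too high for this sample rate")
        x = np.zeros(n)
        burst_len = max(4, period // 3)
        decay = np.exp(-np.arange(burst_len) / (burst_len / 4.0))
        carrier_f = spec.formants[0][0] if spec.formants else 40.0 * spec.pulse_rate
        carrier = np.sin(2 * np.pi * carrier_f * np.arange(burst_len) / sample_rate)
        burst = decay * carrier
        for start in range(0, n, period):
            seg = min(burst_len, n - start)
            x[start : start + seg] += burst[:seg]

    x *= env
    peak = np.abs(x).max()
    return 0.9 * x / peak if peak > 0 else x


# ---------------------------------------------------------------------------
# Token-sequence noise and whole-session assembly


def perturb_sequence(
    seq: Sequence[str],
    noise_rates: tuple[float, float, float],
    alphabet: Sequence[str],
    seed: int | np.random.Generator,
) -> TokenSequence:
    """Apply independent per-position substitution/insertion/deletion noise.

    ``noise_rates`` is (substitution, insertion, deletion). Deletion is drawn
    first per token; a surviving token substitutes with the substitution rate
    (to a uniformly drawn different symbol). Insertions are drawn before each
    position and after the last. Deterministic given the seed.
    """
    p_sub, p_ins, p_del = noise_rates
    for p in (p_sub, p_ins, p_del):
        if not (0.0 <= p <= 1.0):
            raise ValueError("noise rates must lie in [0, 1]")
    if (p_sub > 0 or p_ins > 0) and not alphabet:
        raise ValueError("non-empty alphabet required for substitution/insertion noise")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = list(alphabet)
    out: list[str] = []
    for tok in seq:
        if p_ins > 0 and rng.random() < p_ins:
            out.append(alphabet[rng.integers(len(alphabet))])
        if p_del > 0 and rng.random() < p_del:
            continue
        if p_sub > 0 and rng.random() < p_sub:
            others = [t for t in alphabet if t != tok] or alphabet
            tok = others[rng.integers(len(others))]
        out.append(tok)
    if p_ins > 0 and rng.random() < p_ins:
        out.append(alphabet[rng.integers(len(alphabet))])
    return TokenSequence(out)


def _stable_hash(label: str) -> int:
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def default_unit_spec(token: str) -> UnitSpec:
    """A deterministic stylized spec for a unit token.

    Category parameters (fundamental, contour, duration, tonal vs pulsed) are
    derived from a stable hash of the label so that every session that uses
    the same alphabet renders the same unit timbres.
    """
    h = _stable_hash(token)
    f0 = 60.0 + (h % 36)                       # < 100 Hz fundamentals
    contour = list(_CONTOUR_SHAPES)[h // 7 % 6]
    pulsed = (h // 11) % 4 == 0                # ~1 in 4 categories pulsed
    env = EnvelopeSpec(
        attack_s=0.03 + (h // 13 % 5) * 0.01,
        sustain_s=0.3 + (h // 17 % 7) * 0.1,
        release_s=0.08 + (h // 19 % 4) * 0.04,
    )
    formants = (
        (400.0 + (h % 9) * 150.0, 180.0),
        (1500.0 + (h // 5 % 9) * 300.0, 350.0),
    )
    if pulsed:
        return UnitSpec(
            label=token, sound_type="pulsed", f0=f0,
            pulse_rate=15.0 + (h // 23 % 4) * 5.0,
            contour=contour, formants=formants, envelope=env,
        )
    return UnitSpec(label=token, f0=f0, contour=contour, formants=formants, envelope=env)


def default_cse_spec(label: str) -> UnitSpec:
    """A deterministic spec for a played concrete sound element.

    CSEs are bassoon-derived sound objects; the stand-in is a lower, longer,
    more formant-heavy rendering distinguished from the whale-unit specs.
    """
    h = _stable_hash("cse:" + label)
    env = EnvelopeSpec(attack_s=0.02, sustain_s=0.8 + (h % 5) * 0.3, release_s=0.2)
    if h % 3 == 0:
        return UnitSpec(
            label=label, sound_type="pulsed", f0=58.0, pulse_rate=12.0 + (h // 3 % 5) * 4.0,
            contour="flat", envelope=env,
            formants=((250.0 + (h % 7) * 100.0, 150.0), (900.0, 300.0)),
        )
    return UnitSpec(
        label=label, f0=58.0 + (h % 30), contour=list(_CONTOUR_SHAPES)[h // 4 % 6],
        envelope=env,
        formants=((250.0 + (h % 7) * 100.0, 150.0), (900.0, 300.0), (2100.0, 500.0)),
    )


@dataclass(frozen=True)
class SessionScenario:
    """Seeded generative description of one playback session.

    ``response_grammar`` maps each stimulus label to weighted phrase patterns
    (token sequences); after each scheduled stimulus one pattern is drawn,
    perturbed with the per-token noise rates, and rendered as a unit train
    with inter-unit silences drawn uniformly from ``inter_unit_silence``.
    The seed fully determines the output waveform and annotation table.
    """

    stimulus_schedule: tuple[tuple[str, float], ...]
    response_grammar: Mapping[str, Sequence[tuple[Sequence[str], float]]]
    noise_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inter_unit_silence: tuple[float, float] = (0.15, 0.45)
    sample_rate: int = 48000
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = [t for _, t in self.stimulus_schedule]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        for p in self.noise_rates:
            if not (0.0 <= p <= 1.0):
                raise ValueError("noise rates must lie in [0, 1]")
        lo, hi = self.inter_unit_silence
        if lo < 0 or hi < lo:
            raise ValueError("inter-unit silence bounds must satisfy 0 ≤ lo ≤ hi")


def generate_session(scenario: SessionScenario) -> tuple[np.ndarray, EventTable]:
    """Render a full synthetic session: waveform plus annotation table.

    For each scheduled stimulus the CSE event is emitted, then its response
    units; events never overlap. A stimulus whose onset falls inside the
    previous response window raises :class:`LayoutError` naming the onset.
    Same scenario (same seed) → bit-identical output.
    """
    sr = scenario.sample_rate
    rng = np.random.default_rng(scenario.seed)
    alphabet = sorted(
        {t for pats in scenario.response_grammar.values() for p, _ in pats for t in p}
    )
    events: list[AnnotatedEvent] = []
    chunks: list[tuple[int, np.ndarray]] = []
    cursor = 0.0  # end of the last placed event

    for label, onset in scenario.stimulus_schedule:
        if onset < cursor:
            raise LayoutError(
                f"stimulus {label!r} at {onset:.3f}s collides with the previous "
                f"response window ending at {cursor:.3f}s"
            )
        cse = default_cse_spec(label)
        wave = render_unit(cse, sr)
        events.append(
            AnnotatedEvent(
                onset_s=onset,
                offset_s=onset + len(wave) / sr,
                label=label,
                source="cse",
                sound_type=cse.sound_type,
                contour=cse.contour,
            )
        )
        chunks.append((int(round(onset * sr)), wave))
        cursor = onset + len(wave) / sr

        patterns = scenario.response_grammar.get(label, [])
        if patterns:
            weights = np.array([w for _, w in patterns], dtype=float)
            idx = rng.choice(len(patterns), p=weights / weights.sum())
            tokens = perturb_sequence(
                patterns[idx][0], scenario.noise_rates, alphabet, rng
            )
            for tok in tokens:
                gap = rng.uniform(*scenario.inter_unit_silence)
                spec = default_unit_spec(tok)
                uwave = render_unit(spec, sr)
                t0 = cursor + gap
                events.append(
                    AnnotatedEvent(
                        onset_s=t0,
                        offset_s=t0 + len(uwave) / sr,
                        label=tok,
                        source="unit",
                        sound_type=spec.sound_type,
                        contour=spec.contour,
                    )
                )
                chunks.append((int(round(t0 * sr)), uwave))
                cursor = t0 + len(uwave) / sr

    total = int(round((cursor + 1.0) * sr))
    waveform = np.zeros(total)
    for start, wave in chunks:
        waveform[start : start + len(wave)] += wave
    peak = np.abs(waveform).max()
    if peak > 1.0:
        waveform /= peak
    return waveform, EventTable(events)
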