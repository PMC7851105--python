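"""Seeded synthetic first-pass perfusion cohort.

Emulates a dual-bolus cardiac perfusion study on pigs: per subject and
physiological state (rest/stress), a left-ventricular blood-pool AIF is
measured twice — once from a diluted pre-bolus (linear signal regime) and
once from the full dose (saturation-blunted peak) — and 24 myocardial ROI
signal-intensity curves are acquired over 60 heartbeats. A configurable
fraction of tissue curves carries a dark-rim artefact: a transient signal
dip below baseline at contrast arrival. Every record carries its
ground-truth myocardial blood flow (MBF), playing the role the PET
reference plays in the real protocol.

The tissue kinetics use the Kety single-compartment residue function
h(t) = F·exp(−F·t/λ), so that h(0) equals the flow F — the property the
deconvolution baseline relies on.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ConcentrationCurve, SignalIntensityCurve
from .errors import GridError, ParameterError, WindowError

__all__ = [
    "AcquisitionDesign",
    "KineticTruth",
    "AifShapeParams",
    "SignalModelParams",
    "ArtefactParams",
    "RoiRecord",
    "SessionAifs",
    "SyntheticCohort",
    "generate_aif_concentration",
    "generate_tissue_concentration",
    "concentration_to_signal",
    "inject_dark_rim",
    "generate_cohort",
]

STATES = ("rest", "stress")


@dataclass(frozen=True)
class AcquisitionDesign:
    """Structural parameters of the acquisition: who, how often, how long.

    Defaults reproduce the study design: 5 subjects, 8 apical + 16
    mid-ventricular segments, rest and stress sessions, 60 frames at one
    heartbeat (1 s) each, a 1/21 pre-bolus dilution, one technically failed
    stress session (subject 3), and ~48% dark-rim prevalence.
    """

    n_subjects: int = 5
    apical_segments: int = 8
    mid_segments: int = 16
    states: tuple[str, ...] = STATES
    n_frames: int = 60
    frame_interval: float = 1.0
    dilution_factor: float = 21.0
    excluded_sessions: tuple[tuple[int, str], ...] = ((3, "stress"),)
    artefact_prevalence: float = 103.0 / 216.0
    ischemic_fraction: float = 0.25

    def __post_init__(self):
        if self.apical_segments + self.mid_segments != 24:
            raise ParameterError("apical_segments + mid_segments must equal 24")
        if self.n_frames < 10:
            raise ParameterError("n_frames must be >= 10")
        if self.dilution_factor <= 1:
            raise ParameterError("dilution_factor must exceed 1")
        if not 0.0 <= self.artefact_prevalence <= 1.0:
            raise ParameterError("artefact_prevalence must lie in [0, 1]")
        if not 0.0 <= self.ischemic_fraction <= 1.0:
            raise ParameterError("ischemic_fraction must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ParameterError("need at least one subject")
        for sub, state in self.excluded_sessions:
            if state not in self.states:
                raise ParameterError(f"excluded session references unknown state {state!r}")
            if not 1 <= sub <= self.n_subjects:
                raise ParameterError(f"excluded session references unknown subject {sub}")

    @property
    def segments_per_subject(self) -> int:
        return self.apical_segments + self.mid_segments

    @property
    def n_sessions(self) -> int:
        return self.n_subjects * len(self.states) - len(self.excluded_sessions)

    @property
    def n_records(self) -> int:
        return self.n_sessions * self.segments_per_subject

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def sessions(self) -> list[tuple[int, str]]:
        excluded = set(self.excluded_sessions)
        return [
            (sub, state)
            for sub in range(1, self.n_subjects + 1)
            for state in self.states
            if (sub, state) not in excluded
        ]


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth kinetics of one ROI.

    ``mbf_true`` is in mL/g/min; internally the residue function uses
    per-second flow F = mbf_true/60 (with tissue density and partition
    coefficient folded into λ, default 1 mL/g).
    """

    mbf_true: float
    partition_coefficient: float = 1.0
    bolus_arrival_delay: float = 0.0

    def __post_init__(self):
        if self.mbf_true <= 0:
            raise ParameterError("mbf_true must be positive")
        if self.partition_coefficient <= 0:
            raise ParameterError("partition_coefficient must be positive")
        if self.bolus_arrival_delay < 0:
            raise ParameterError("bolus_arrival_delay must be >= 0")

    @property
    def flow_per_second(self) -> float:
        return self.mbf_true / 60.0

    def residue_function(self, times: np.ndarray) -> np.ndarray:
        """Kety single-compartment impulse response sampled on ``times`` (1/s)."""
        f = self.flow_per_second
        t = np.asarray(times, dtype=float) - self.bolus_arrival_delay
        h = np.where(t >= 0, f * np.exp(-f * np.maximum(t, 0.0) / self.partition_coefficient), 0.0)
        return h


@dataclass(frozen=True)
class AifShapeParams:
    """Gamma-variate bolus shape: A·(t−t0)^α·exp(−(t−t0)/β) for t > t0.

    An optional recirculation tail adds a delayed, dispersed copy of the
    first pass scaled by ``recirculation_fraction``.
    """

    amplitude: float = 0.28
    alpha: float = 3.0
    beta: float = 2.0
    t0: float = 10.0
    recirculation_fraction: float = 0.1
    recirculation_delay: float = 20.0
    recirculation_dispersion: float = 2.0

    def __post_init__(self):
        if self.amplitude <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("amplitude, alpha and beta must be positive")
        if self.t0 < 0:
            raise ParameterError("t0 must be >= 0")
        if not 0.0 <= self.recirculation_fraction < 1.0:
            raise ParameterError("recirculation_fraction must lie in [0, 1)")

    @property
    def peak_time(self) -> float:
        """First-pass maximum of the gamma-variate: t0 + α·β."""
        return self.t0 + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        return self.amplitude * (self.alpha * self.beta) ** self.alpha * np.exp(-self.alpha)


@dataclass(frozen=True)
class SignalModelParams:
    """Saturation-recovery signal model SI(C) = S0·(1 − exp(−TS·(R10 + r1·C))).

    The map is strictly increasing and concave in C, approximately linear at
    low concentration and compressive (blunted) at high concentration. TS is
    the saturation-recovery time (150 ms in the protocol), R10 the native
    longitudinal relaxation rate and r1 the contrast-agent relaxivity.
    """

    S0: float = 1000.0
    TS: float = 0.150
    R10: float = 1.0
    r1: float = 4.0
    noise_sd: float = 2.0
    # The LV blood pool is a much larger ROI than one myocardial segment, so
    # its ROI-averaged noise is several-fold lower (~16x the pixel count).
    aif_noise_sd: float = 0.5

    def __post_init__(self):
        if min(self.S0, self.TS, self.R10, self.r1) <= 0:
            raise ParameterError("S0, TS, R10 and r1 must be positive")
        if self.noise_sd < 0 or self.aif_noise_sd < 0:
            raise ParameterError("noise levels must be >= 0")

    def blood_pool(self) -> "SignalModelParams":
        """The same signal model at the blood-pool ROI's noise level."""
        return dataclasses.replace(self, noise_sd=self.aif_noise_sd)

    def signal(self, conc: np.ndarray) -> np.ndarray:
        """Noise-free forward map concentration -> signal intensity."""
        c = np.asarray(conc, dtype=float)
        return self.S0 * (1.0 - np.exp(-self.TS * (self.R10 + self.r1 * c)))

    @property
    def baseline_signal(self) -> float:
        return float(self.signal(0.0))

    @property
    def linear_gain(self) -> float:
        """dSI/dC at C = 0 — the slope used by linear conversion (a.u. per mmol/L)."""
        return self.S0 * self.TS * self.r1 * np.exp(-self.TS * self.R10)


@dataclass(frozen=True)
class ArtefactParams:
    """Additive dark-rim dip: amplitude (a.u.), duration (frames), onset lag."""

    dip_amplitude: float = 60.0
    dip_duration: int = 4
    onset_lag: int = 0

    def __post_init__(self):
        if self.dip_amplitude <= 0:
            raise ParameterError("dip_amplitude must be positive")
        if self.dip_duration < 1:
            raise ParameterError("dip_duration must be >= 1")
        if self.onset_lag < 0:
            raise ParameterError("onset_lag must be >= 0")


@dataclass(frozen=True)
class RoiRecord:
    """One observation: a myocardial segment in one subject/state session."""

    subject_id: int
    slice_name: str  # "apical" or "mid"
    segment_index: int  # 1-based within the slice
    state: str
    si: SignalIntensityCurve
    artefact_flag: bool
    mbf_true: float
    ischemic: bool = False

    @property
    def key(self) -> str:
        return f"s{self.subject_id}_{self.state}_{self.slice_name}_{self.segment_index:02d}"


@dataclass(frozen=True)
class SessionAifs:
    """Blood-pool curves for one subject/state session."""

    subject_id: int
    state: str
    prebolus_si: SignalIntensityCurve
    fulldose_si: SignalIntensityCurve
    true_conc: ConcentrationCurve  # full-dose C_b(t), ground truth
    arrival_frame: int  # true LV arrival frame of the full dose


@dataclass
class SyntheticCohort:
    """A generated cohort plus everything needed to regenerate it."""

    records: list[RoiRecord]
    aifs: dict[tuple[int, str], SessionAifs]
    design: AcquisitionDesign
    seed: int
    signal_params: SignalModelParams = field(default_factory=SignalModelParams)
    artefact_params: ArtefactParams = field(default_factory=ArtefactParams)

    def session(self, subject_id: int, state: str) -> SessionAifs:
        return self.aifs[(subject_id, state)]

    def subjects(self) -> list[int]:
        return sorted({r.subject_id for r in self.records})

    # ---------------------------------------------------------------- I/O
    def records_frame(self) -> pd.DataFrame:
        n = self.design.n_frames
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "slice": r.slice_name,
                "segment_index": r.segment_index,
                "state": r.state,
                "artefact_label": int(r.artefact_flag),
                "mbf_true": r.mbf_true,
            }
            row.update({f"frame_{i:03d}": r.si.values[i] for i in range(n)})
            rows.append(row)
        return pd.DataFrame(rows)

    def aif_frame(self) -> pd.DataFrame:
        n = self.design.n_frames
        rows = []
        for (sub, state), sess in sorted(self.aifs.items()):
            for bolus, curve in (
                ("prebolus", sess.prebolus_si),
                ("full", sess.fulldose_si),
            ):
                row = {"subject_id": sub, "state": state, "bolus": bolus}
                row.update({f"frame_{i:03d}": curve.values[i] for i in range(n)})
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records_frame().to_csv(out / "records.csv", index=False)
        self.aif_frame().to_csv(out / "aifs.csv", index=False)
        sidecar = {
            "seed": self.seed,
            "design": dataclasses.asdict(self.design),
            "signal_params": dataclasses.asdict(self.signal_params),
            "artefact_params": dataclasses.asdict(self.artefact_params),
        }
        (out / "cohort.json").write_text(json.dumps(sidecar, indent=2, default=list))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticCohort":
        src = Path(in_dir)
        sidecar = json.loads((src / "cohort.json").read_text())
        design_kw = sidecar["design"]
        design_kw["states"] = tuple(design_kw["states"])
        design_kw["excluded_sessions"] = tuple(
            (int(s), st) for s, st in design_kw["excluded_sessions"]
        )
        design = AcquisitionDesign(**design_kw)
        sig = SignalModelParams(**sidecar["signal_params"])
        art = ArtefactParams(**sidecar["artefact_params"])
        times = design.times
        frame_cols = [f"frame_{i:03d}" for i in range(design.n_frames)]

        rec_df = pd.read_csv(src / "records.csv")
        records = []
        for _, row in rec_df.iterrows():
            records.append(
                RoiRecord(
                    subject_id=int(row["subject_id"]),
                    slice_name=str(row["slice"]),
                    segment_index=int(row["segment_index"]),
                    state=str(row["state"]),
                    si=SignalIntensityCurve(times, row[frame_cols].to_numpy(float)),
                    artefact_flag=bool(row["artefact_label"]),
                    mbf_true=float(row["mbf_true"]),
                )
            )
        aif_df = pd.read_csv(src / "aifs.csv")
        aifs: dict[tuple[int, str], SessionAifs] = {}
        grouped: dict[tuple[int, str], dict[str, np.ndarray]] = {}
        for _, row in aif_df.iterrows():
            key = (int(row["subject_id"]), str(row["state"]))
            grouped.setdefault(key, {})[str(row["bolus"])] = row[frame_cols].to_numpy(float)
        for (sub, state), curves in grouped.items():
            aifs[(sub, state)] = SessionAifs(
                subject_id=sub,
                state=state,
                prebolus_si=SignalIntensityCurve(times, curves["prebolus"]),
                fulldose_si=SignalIntensityCurve(times, curves["full"]),
                true_conc=ConcentrationCurve(times, np.zeros_like(times), role="arterial"),
                arrival_frame=-1,  # truth not serialized; recompute via detection
            )
        return cls(records=records, aifs=aifs, design=design, seed=int(sidecar["seed"]),
                   signal_params=sig, artefact_params=art)


# --------------------------------------------------------------------------
# Curve-level generators


def generate_aif_concentration(params: AifShapeParams, times) -> ConcentrationCurve:
    """Gamma-variate arterial input function on ``times`` (mmol/L).

    Zero before onset t0; optionally adds a recirculation tail (a delayed,
    dispersed copy of the first pass).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise GridError("times must be a vector of at least 2 samples")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise GridError("times must be strictly increasing and start at 0")

    def gamma_variate(a, alpha, beta, t0):
        dt_ = t - t0
        with np.errstate(invalid="ignore"):
            out = np.where(dt_ > 0, a * np.power(np.maximum(dt_, 0.0), alpha) * np.exp(-dt_ / beta), 0.0)
        return out

    values = gamma_variate(params.amplitude, params.alpha, params.beta, params.t0)
    if params.recirculation_fraction > 0:
        values = values + params.recirculation_fraction * gamma_variate(
            params.amplitude
            / params.recirculation_dispersion ** params.alpha,  # keep tail area comparable
            params.alpha,
            params.beta * params.recirculation_dispersion,
            params.t0 + params.recirculation_delay,
        )
    return ConcentrationCurve(t, values, role="arterial")


def generate_tissue_concentration(
    aif: ConcentrationCurve, truth: KineticTruth
) -> ConcentrationCurve:
    """Tissue concentration C_t = (C_b ⊛ h_true)·dt on the AIF's grid.

    The discrete convolution uses the same causal lower-triangular scheme the
    deconvolution stage inverts, so noise-free generation and inversion are
    exact inverses of each other.
    """
    dt = aif.dt
    h = truth.residue_function(aif.times)
    ct = np.convolve(aif.values, h)[: len(aif)] * dt
    return ConcentrationCurve(aif.times, ct, role="tissue")


def concentration_to_signal(
    curve: ConcentrationCurve, sig: SignalModelParams, rng_seed: int
) -> SignalIntensityCurve:
    """Map a concentration curve through the saturation-recovery signal model.

    Additive zero-mean Gaussian noise of sd ``sig.noise_sd`` is applied,
    deterministically for a given ``rng_seed``.
    """
    if np.any(curve.values < 0):
        raise ParameterError("concentrations must be >= 0 before signal conversion")
    clean = sig.signal(curve.values)
    if sig.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        clean = clean + rng.normal(0.0, sig.noise_sd, size=clean.shape)
    return SignalIntensityCurve(curve.times, clean)


def inject_dark_rim(
    curve: SignalIntensityCurve,
    arrival_frame: int,
    art: ArtefactParams,
    baseline_mean: float | None = None,
) -> SignalIntensityCurve:
    """Superimpose a dark-rim dip at contrast arrival.

    The dip is an additive raised-cosine trough of depth ``dip_amplitude``
    starting ``onset_lag`` frames after ``arrival_frame``. The result must
    actually cross below the pre-contrast baseline mean during the dip and
    recover above it afterwards — otherwise the injection is rejected.
    """
    n = len(curve)
    start = arrival_frame + art.onset_lag
    stop = start + art.dip_duration  # exclusive
    if start < 0 or stop >= n:
        raise WindowError(
            f"dip window [{start}, {stop}) must leave room for a subsequent rise "
            f"within the {n}-frame series"
        )
    if baseline_mean is None:
        baseline_mean = float(np.mean(curve.values[:arrival_frame])) if arrival_frame > 0 else float(
            curve.values[0]
        )
    phase = np.linspace(0.0, np.pi, art.dip_duration + 2)[1:-1]
    dip = art.dip_amplitude * np.sin(phase)
    values = curve.values.copy()
    values[start:stop] -= dip
    if values[start:stop].min() >= baseline_mean:
        raise WindowError(
            "dip_amplitude too small: curve never crosses below the baseline mean"
        )
    if values[stop:].max() <= baseline_mean:
        raise WindowError("no subsequent rise above baseline after the dip window")
    return SignalIntensityCurve(curve.times, values)


# --------------------------------------------------------------------------
# Cohort generation

_REST_RANGE = (0.4, 1.5)
_STRESS_RANGE = (1.5, 4.0)
_ISCHEMIC_REST_RANGE = (0.25, 0.8)
_ISCHEMIC_STRESS_RANGE = (0.5, 1.2)


def _draw_mbf(rng: np.random.Generator, state: str, ischemic: bool) -> float:
    if state == "stress":
        lo, hi = _ISCHEMIC_STRESS_RANGE if ischemic else _STRESS_RANGE
    else:
        lo, hi = _ISCHEMIC_REST_RANGE if ischemic else _REST_RANGE
    return float(rng.uniform(lo, hi))


def _segment_layout(design: AcquisitionDesign) -> list[tuple[str, int]]:
    return [("apical", i + 1) for i in range(design.apical_segments)] + [
        ("mid", i + 1) for i in range(design.mid_segments)
    ]


def generate_cohort(
    design: AcquisitionDesign | None = None,
    seed: int = 0,
    signal_params: SignalModelParams | None = None,
    artefact_params: ArtefactParams | None = None,
    base_aif: AifShapeParams | None = None,
) -> SyntheticCohort:
    """Generate a full seeded cohort.

    Per subject/state session: a true full-dose AIF (gamma-variate with
    per-subject shape jitter and per-session onset), its 1/21-diluted
    pre-bolus twin (injected separately, so its onset differs by a couple of
    heartbeats), and 24 tissue curves convolved from per-ROI truth MBF.
    Dark-rim dips are injected into an exact-count seeded subset of records
    so that the cohort-level prevalence matches ``artefact_prevalence``.
    Byte-for-byte reproducible for a fixed (design, seed).
    """
    design = design or AcquisitionDesign()
    sig = signal_params or SignalModelParams()
    art = artefact_params or ArtefactParams()
    base = base_aif or AifShapeParams()
    rng = np.random.default_rng(seed)
    times = design.times
    layout = _segment_layout(design)

    # Per-subject shape jitter and ischemic segment designation.
    subj_shape: dict[int, tuple[float, float, float]] = {}
    subj_ischemic: dict[int, set[int]] = {}
    n_isch = int(round(design.ischemic_fraction * design.segments_per_subject))
    for sub in range(1, design.n_subjects + 1):
        subj_shape[sub] = (
            base.amplitude * rng.uniform(0.9, 1.1),
            base.alpha * rng.uniform(0.9, 1.1),
            base.beta * rng.uniform(0.9, 1.1),
        )
        subj_ischemic[sub] = set(
            rng.choice(design.segments_per_subject, size=n_isch, replace=False)
        )

    sessions = design.sessions()
    aifs: dict[tuple[int, str], SessionAifs] = {}
    pending: list[dict] = []
    for sub, state in sessions:
        amp, alpha, beta = subj_shape[sub]
        t0_full = float(rng.uniform(8.0, 12.0))
        # Both boluses are cardiac-gated and sampled once per heartbeat, so the
        # inter-bolus arrival offset is modeled in whole frames — the regime in
        # which integer-frame alignment is identifiable.
        offset_frames = int(rng.integers(-2, 3))
        t0_pre = float(np.clip(t0_full + offset_frames * design.frame_interval, 2.0, None))
        full_params = AifShapeParams(
            amplitude=amp, alpha=alpha, beta=beta, t0=t0_full,
            recirculation_fraction=base.recirculation_fraction,
            recirculation_delay=base.recirculation_delay,
            recirculation_dispersion=base.recirculation_dispersion,
        )
        pre_params = dataclasses.replace(full_params, t0=t0_pre)
        full_conc = generate_aif_concentration(full_params, times)
        pre_conc_true = generate_aif_concentration(pre_params, times)
        pre_conc_diluted = pre_conc_true.with_values(
            pre_conc_true.values / design.dilution_factor
        )
        seed_full = int(rng.integers(0, 2**31 - 1))
        seed_pre = int(rng.integers(0, 2**31 - 1))
        arrival = int(np.ceil(t0_full / design.frame_interval))
        sig_bp = sig.blood_pool()
        aifs[(sub, state)] = SessionAifs(
            subject_id=sub,
            state=state,
            prebolus_si=concentration_to_signal(pre_conc_diluted, sig_bp, seed_pre),
            fulldose_si=concentration_to_signal(full_conc, sig_bp, seed_full),
            true_conc=full_conc,
            arrival_frame=arrival,
        )
        for slice_name, seg in layout:
            seg_global = layout.index((slice_name, seg))
            ischemic = seg_global in subj_ischemic[sub]
            mbf = _draw_mbf(rng, state, ischemic)
            truth = KineticTruth(mbf_true=mbf)
            ct = generate_tissue_concentration(full_conc, truth)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            pending.append(
                dict(
                    subject_id=sub, slice_name=slice_name, segment_index=seg,
                    state=state, conc=ct, mbf=mbf, ischemic=ischemic,
                    noise_seed=noise_seed, arrival=arrival,
                )
            )

    # Exact-count artefact assignment over the whole cohort.
    n_total = len(pending)
    n_art = int(round(design.artefact_prevalence * n_total))
    art_idx = set(rng.choice(n_total, size=n_art, replace=False)) if n_art else set()

    records: list[RoiRecord] = []
    for i, p in enumerate(pending):
        si = concentration_to_signal(p["conc"], sig, p["noise_seed"])
        flagged = i in art_idx
        if flagged:
            si = inject_dark_rim(si, p["arrival"], art, baseline_mean=sig.baseline_signal)
        records.append(
            RoiRecord(
                subject_id=p["subject_id"], slice_name=p["slice_name"],
                segment_index=p["segment_index"], state=p["state"], si=si,
                artefact_flag=flagged, mbf_true=p["mbf"], ischemic=p["ischemic"],
            )
        )
    return SyntheticCohort(
        records=records, aifs=aifs, design=design, seed=seed,
        signal_params=sig, artefact_params=art,
    )
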