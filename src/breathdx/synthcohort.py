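"""Synthetic exhalation-cohort simulator.

Generates labeled multi-channel breath records with the statistical structure
observed on real breath-sensor cohorts: composite VOC profiles that are sums
of three Gaussian components ("orders") whose class-conditional parameters
follow the published adult/pediatric deconvolution tables, square (control)
versus "shark-fin" (asthmatic) CO2 capnograms, class-shifted airflow,
temperature and humidity traces, additive Gaussian sensor noise, and
triplicate measurements per subject.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so a :class:`CohortSpec` maps to a
byte-identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .tables import TABLES_BY_AGE_GROUP

__all__ = [
    "CHANNELS",
    "VOC_RETENTION_SPAN",
    "GaussianParams",
    "ClassProfile",
    "EffectProfile",
    "CohortSpec",
    "BreathRecord",
    "table_profile",
    "scale_effect",
    "generate_voc_channel",
    "generate_capnogram",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Canonical 13-channel list (simulator convention; the device names only a
#: subset of its channels publicly).
CHANNELS: tuple[str, ...] = (
    "co2",
    "voc_total",
    "isoprene",
    "acetone",
    "ethanol",
    "nox_proxy",
    "flow",
    "temperature",
    "humidity",
    "pressure",
    "voc_aux1",
    "voc_aux2",
    "voc_aux3",
)

#: The VOC channels are expressed on a pseudo retention axis spanning
#: [0, VOC_RETENTION_SPAN] retention units regardless of record length.
VOC_RETENTION_SPAN = 40.0

# Breath-cycle timing (invented plumbing with physiologic defaults):
BREATH_PERIOD_S = 4.0
DEFAULT_SAMPLING_RATE = 25.0
DEFAULT_N_SAMPLES = 300  # 12 s = 3 full breath cycles at 25 Hz
# Phase fractions of one cycle: CO2 upstroke, expiration, downstroke, baseline.
_PHASES = (0.10, 0.50, 0.10, 0.30)

AgeGroup = Literal["adult", "pediatric"]
ClassName = Literal["asthmatic", "control"]


class GaussianParams(BaseModel):
    """One VOC component: amplitude (sensor units), mean and SD (retention units)."""

    model_config = ConfigDict(extra="forbid")

    amplitude: float = Field(ge=0)
    mean: float
    sd: float = Field(gt=0)


class ClassProfile(BaseModel):
    """Class-conditional generating parameters for one diagnostic group."""

    model_config = ConfigDict(extra="forbid")

    components: list[GaussianParams]
    #: 0 = square/trapezoid capnogram, 1 = full shark-fin.
    obstruction: float = Field(ge=0.0, le=1.0)
    end_tidal: float = Field(gt=0)  # CO2 %
    plateau_slope: float = 0.0  # CO2 %/s over the alveolar plateau
    temperature: float  # airway temperature, degC
    humidity: float  # %RH
    peak_flow: float = Field(gt=0)  # L/min

    @model_validator(mode="after")
    def _three_orders(self) -> "ClassProfile":
        if len(self.components) != 3:
            raise ValueError("a class profile carries exactly 3 component orders")
        return self


class EffectProfile(BaseModel):
    """Full generating profile: both classes plus shared noise/variability knobs.

    ``noise_scale`` is the additive Gaussian noise SD expressed as a fraction
    of each clean channel's dynamic range.  ``subject_*`` terms are the
    between-subject biological variability applied on top of the class means.
    """

    model_config = ConfigDict(extra="forbid")

    age_group: AgeGroup
    asthmatic: ClassProfile
    control: ClassProfile
    noise_scale: float = Field(default=0.05, ge=0)
    baseline: float = 0.0  # constant VOC baseline offset
    subject_amp_cv: float = Field(default=0.15, ge=0)
    subject_mean_jitter: float = Field(default=0.3, ge=0)  # retention units
    subject_sd_cv: float = Field(default=0.10, ge=0)

    def for_class(self, cls: str) -> ClassProfile:
        if cls not in ("asthmatic", "control"):
            raise ValueError(f"unknown class {cls!r}; expected 'asthmatic' or 'control'")
        return self.asthmatic if cls == "asthmatic" else self.control


class CohortSpec(BaseModel):
    """Recipe for one reproducible synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n_asthmatic: int = Field(ge=1)
    n_control: int = Field(ge=1)
    age_group: AgeGroup = "adult"
    effect_profile: EffectProfile | None = None
    #: 1 = table-derived class difference, 0 = classes identical (null cohort).
    effect_scale: float = 1.0
    n_replicates: int = Field(default=3, ge=1)
    n_samples: int = Field(default=DEFAULT_N_SAMPLES, ge=50)
    sampling_rate: float = Field(default=DEFAULT_SAMPLING_RATE, gt=0)
    seed: int = 0

    def resolved_profile(self) -> EffectProfile:
        profile = self.effect_profile or table_profile(self.age_group)
        if self.effect_scale != 1.0:
            profile = scale_effect(profile, self.effect_scale)
        return profile


@dataclass
class BreathRecord:
    """One subject-session: 13 named waveform channels plus metadata."""

    subject_id: str
    age_group: str
    label: int  # 1 = asthmatic, 0 = control
    replicate_index: int
    sampling_rate: float
    channels: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def validate(self) -> None:
        if set(self.channels) != set(CHANNELS) or len(self.channels) != 13:
            raise ValueError(
                f"record {self.subject_id} must carry exactly the 13 canonical "
                f"channels; got {sorted(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"record {self.subject_id}: channel lengths differ: {lengths}")
        if lengths.pop() < 50:
            raise ValueError(f"record {self.subject_id}: series shorter than 50 samples")
        for name, series in self.channels.items():
            if not np.all(np.isfinite(series)):
                raise ValueError(f"record {self.subject_id}: non-finite values in {name}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (control) or 1 (asthmatic)")
        if self.replicate_index < 1:
            raise ValueError("replicate_index is 1-based")


# ---------------------------------------------------------------------------
# Default profiles


def table_profile(age_group: str) -> EffectProfile:
    """Default :class:`EffectProfile` whose VOC component statistics equal the
    published adult or pediatric deconvolution table entries."""
    if age_group not in TABLES_BY_AGE_GROUP:
        raise ValueError(f"unknown age_group {age_group!r}; expected 'adult' or 'pediatric'")
    table = TABLES_BY_AGE_GROUP[age_group]
    pediatric = age_group == "pediatric"

    def components(cls: str) -> list[GaussianParams]:
        return [
            GaussianParams(amplitude=a, mean=m, sd=s) for a, m, s, _fwhm in table[cls]
        ]

    control = ClassProfile(
        components=components("control"),
        obstruction=0.0,
        end_tidal=5.0,
        plateau_slope=0.0,
        temperature=34.0,
        humidity=95.0,
        peak_flow=250.0 if pediatric else 450.0,
    )
    asthmatic = ClassProfile(
        components=components("asthmatic"),
        obstruction=1.0,
        end_tidal=5.4,
        plateau_slope=0.0,
        # airway inflammation raises temperature and lowers humidity
        temperature=34.5,
        humidity=92.0,
        peak_flow=180.0 if pediatric else 320.0,
    )
    return EffectProfile(age_group=age_group, asthmatic=asthmatic, control=control)


def scale_effect(profile: EffectProfile, effect_scale: float) -> EffectProfile:
    """Interpolate every asthmatic generating parameter toward the control
    value: scale 1 keeps the profile, scale 0 makes the classes identical."""
    s = float(effect_scale)
    c = profile.control

    def lerp(a: float, b: float) -> float:
        return b + s * (a - b)

    scaled_components = [
        GaussianParams(
            amplitude=max(lerp(pa.amplitude, pc.amplitude), 0.0),
            mean=lerp(pa.mean, pc.mean),
            sd=max(lerp(pa.sd, pc.sd), 1e-12),
        )
        for pa, pc in zip(profile.asthmatic.components, c.components)
    ]
    scaled = ClassProfile(
        components=scaled_components,
        obstruction=min(max(lerp(profile.asthmatic.obstruction, c.obstruction), 0.0), 1.0),
        end_tidal=lerp(profile.asthmatic.end_tidal, c.end_tidal),
        plateau_slope=lerp(profile.asthmatic.plateau_slope, c.plateau_slope),
        temperature=lerp(profile.asthmatic.temperature, c.temperature),
        humidity=lerp(profile.asthmatic.humidity, c.humidity),
        peak_flow=lerp(profile.asthmatic.peak_flow, c.peak_flow),
    )
    return profile.model_copy(update={"asthmatic": scaled})


# ---------------------------------------------------------------------------
# Channel generators


def gaussian_mixture(t: np.ndarray, components: list[GaussianParams]) -> np.ndarray:
    """Evaluate sum_o A_o * exp(-(t - mu_o)^2 / (2 sd_o^2))."""
    out = np.zeros_like(t, dtype=float)
    for comp in components:
        if comp.sd <= 0:
            raise ValueError("component SD must be positive")
        out += comp.amplitude * np.exp(-((t - comp.mean) ** 2) / (2.0 * comp.sd**2))
    return out


def generate_voc_channel(
    cls: str,
    profile: EffectProfile,
    n_samples: int,
    seed: int,
    *,
    noise_sd: float | None = None,
    baseline: float | None = None,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Composite VOC profile: sum of the class's Gaussian components plus a
    constant baseline and additive Gaussian noise.  Same seed, same series."""
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    class_profile = profile.for_class(cls)
    if t is None:
        t = np.linspace(0.0, VOC_RETENTION_SPAN, n_samples)
    clean = gaussian_mixture(t, class_profile.components)
    if baseline is None:
        baseline = profile.baseline
    if noise_sd is None:
        rng_range = float(np.ptp(clean)) or 1.0
        noise_sd = profile.noise_scale * rng_range
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
    return clean + baseline + noise


def _expiration_shape(u: np.ndarray, obstruction: float) -> np.ndarray:
    """Expiratory-limb shape on u in [0, 1], normalized to end at 1.

    Obstruction 0 gives a flat plateau (value 1 throughout); obstruction 1
    gives a concave, monotonically rising shark-fin that only reaches the
    end-tidal level at the very end of expiration.
    """
    flat = np.ones_like(u)
    k = 4.0
    shark = 0.35 * u + 0.65 * (1.0 - np.exp(-k * u)) / (1.0 - math.exp(-k))
    return (1.0 - obstruction) * flat + obstruction * shark


def _capnogram_cycle(n: int, class_profile: ClassProfile, fs: float) -> np.ndarray:
    """One noiseless breath cycle of n samples."""
    o = class_profile.obstruction
    etl = class_profile.end_tidal
    n_up = max(int(round(_PHASES[0] * n)), 2)
    n_exp = max(int(round(_PHASES[1] * n)), 2)
    n_down = max(int(round(_PHASES[2] * n)), 2)
    n_base = n - n_up - n_exp - n_down
    # With obstruction, the fast upstroke only reaches a fraction of end-tidal.
    h0 = ((1.0 - o) + 0.3 * o) * etl
    up = np.linspace(0.0, h0, n_up, endpoint=False)
    u = np.linspace(0.0, 1.0, n_exp)
    shape = _expiration_shape(u, o)
    # Map the shape onto [h0, etl]; for o = 0 this is the flat plateau at etl
    # (plus any configured plateau slope).
    exp_limb = h0 + (etl - h0) * shape
    exp_limb = exp_limb + class_profile.plateau_slope * (u * n_exp / fs) * (1.0 - o)
    down = np.linspace(exp_limb[-1], 0.0, n_down + 1)[1:]
    base = np.zeros(max(n_base, 0))
    return np.concatenate([up, exp_limb, down, base])[:n]


def generate_capnogram(
    cls: str,
    profile: EffectProfile,
    n_samples: int,
    seed: int,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    noise_sd: float | None = None,
) -> np.ndarray:
    """CO2 capnogram: repeated breath cycles (period 4 s), square/trapezoid
    for controls, shark-fin for asthmatics, plus additive noise.

    With zero noise the last expiratory sample of every cycle equals the
    configured end-tidal level exactly.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    class_profile = profile.for_class(cls)
    cycle_len = max(int(round(BREATH_PERIOD_S * sampling_rate)), 20)
    cycle = _capnogram_cycle(cycle_len, class_profile, sampling_rate)
    reps = int(np.ceil(n_samples / cycle_len))
    clean = np.tile(cycle, reps)[:n_samples]
    if noise_sd is None:
        noise_sd = profile.noise_scale * class_profile.end_tidal * 0.2
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
    return clean + noise


def _smooth_bump(t01: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((t01 - center) ** 2) / (2.0 * width**2))


def _aux_channels(
    class_profile: ClassProfile,
    voc_total: np.ndarray,
    components: list[GaussianParams],
    t_ret: np.ndarray,
    n: int,
    fs: float,
) -> dict[str, np.ndarray]:
    """Clean (noise-free) versions of the non-CO2, non-voc_total channels."""
    t01 = np.arange(n) / n
    cycle = (np.arange(n) % int(round(BREATH_PERIOD_S * fs))) / (BREATH_PERIOD_S * fs)
    out: dict[str, np.ndarray] = {}
    # Named VOCs follow individual orders (fixed per-channel response factors).
    for name, order, factor in (("isoprene", 0, 1.0), ("acetone", 1, 0.8), ("ethanol", 2, 0.6)):
        out[name] = factor * gaussian_mixture(t_ret, [components[order]])
    out["nox_proxy"] = (1.0 + 0.3 * class_profile.obstruction) * _smooth_bump(t01, 0.5, 0.25)
    # Expiratory flow: one bell per breath peaking early in expiration.
    out["flow"] = class_profile.peak_flow * _smooth_bump(cycle, 0.25, 0.12)
    out["temperature"] = class_profile.temperature + 0.2 * np.sin(2 * np.pi * t01)
    out["humidity"] = class_profile.humidity + 1.0 * np.sin(2 * np.pi * t01 + 1.0)
    out["pressure"] = 101.3 + (0.2 + 0.1 * class_profile.obstruction) * np.sin(
        2 * np.pi * cycle
    )
    for name, factor in (("voc_aux1", 0.5), ("voc_aux2", 0.25), ("voc_aux3", 0.1)):
        out[name] = factor * voc_total
    return out


def _jittered_components(
    components: list[GaussianParams], profile: EffectProfile, rng: np.random.Generator
) -> list[GaussianParams]:
    """Between-subject biological variability around the class means."""
    out = []
    for comp in components:
        amp = comp.amplitude * rng.lognormal(0.0, profile.subject_amp_cv)
        mean = comp.mean + rng.normal(0.0, profile.subject_mean_jitter)
        sd = comp.sd * rng.lognormal(0.0, profile.subject_sd_cv)
        out.append(GaussianParams(amplitude=amp, mean=mean, sd=max(sd, 1e-9)))
    return out


def generate_record(
    subject_id: str,
    cls: str,
    spec: CohortSpec,
    replicate_index: int,
    components: list[GaussianParams],
    class_profile: ClassProfile,
    noise_seed: int,
) -> BreathRecord:
    profile = spec.resolved_profile()
    n, fs = spec.n_samples, spec.sampling_rate
    t_ret = np.linspace(0.0, VOC_RETENTION_SPAN, n)
    rng = np.random.default_rng(noise_seed)

    voc_clean = gaussian_mixture(t_ret, components) + profile.baseline
    clean: dict[str, np.ndarray] = {
        "co2": generate_capnogram(
            cls, profile, n, seed=0, sampling_rate=fs, noise_sd=0.0
        ),
        "voc_total": voc_clean,
    }
    clean.update(_aux_channels(class_profile, voc_clean, components, t_ret, n, fs))

    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        series = clean[name]
        sd = profile.noise_scale * (float(np.ptp(series)) or 1.0)
        channels[name] = series + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    record = BreathRecord(
        subject_id=subject_id,
        age_group=spec.age_group,
        label=1 if cls == "asthmatic" else 0,
        replicate_index=replicate_index,
        sampling_rate=fs,
        channels=channels,
    )
    record.validate()
    return record


def generate_cohort(spec: CohortSpec) -> list[BreathRecord]:
    """Generate ``(n_asthmatic + n_control) * n_replicates`` breath records.

    Subject-level biological jitter and replicate-level sensor noise are both
    derived from ``spec.seed`` via ``SeedSequence``, so the cohort is fully
    reproducible.
    """
    profile = spec.resolved_profile()
    root = np.random.SeedSequence(spec.seed)
    records: list[BreathRecord] = []
    plan = [("asthmatic", i) for i in range(spec.n_asthmatic)] + [
        ("control", i) for i in range(spec.n_control)
    ]
    subject_seqs = root.spawn(len(plan))
    for (cls, idx), seq in zip(plan, subject_seqs):
        prefix = "A" if cls == "asthmatic" else "C"
        subject_id = f"{prefix}{spec.age_group[0].upper()}{idx:03d}"
        children = seq.spawn(spec.n_replicates + 1)
        subj_rng = np.random.default_rng(children[0])
        class_profile = profile.for_class(cls)
        components = _jittered_components(class_profile.components, profile, subj_rng)
        for rep in range(1, spec.n_replicates + 1):
            noise_seed = int(children[rep].generate_state(1)[0] % (2**31))
            records.append(
                generate_record(
                    subject_id, cls, spec, rep, components, class_profile, noise_seed
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cohort I/O: long-format CSV + JSON sidecar

WAVEFORM_FILE = "waveforms.csv"
SIDECAR_FILE = "cohort.json"


def write_cohort(records: list[BreathRecord], out_dir: str | Path, spec: CohortSpec | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    meta: dict[str, dict] = {}
    for rec in records:
        n = rec.n_samples
        t = np.arange(n) / rec.sampling_rate
        for channel in CHANNELS:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "replicate": rec.replicate_index,
                        "channel": channel,
                        "t_seconds": t,
                        "value": rec.channels[channel],
                    }
                )
            )
        meta[rec.subject_id] = {
            "label": rec.label,
            "age_group": rec.age_group,
            "sampling_rate": rec.sampling_rate,
        }
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / WAVEFORM_FILE, index=False, float_format="%.17g")
    sidecar = {
        "subjects": meta,
        "spec": json.loads(spec.model_dump_json()) if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
    }
    (out / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1))


def read_cohort(in_dir: str | Path) -> list[BreathRecord]:
    src = Path(in_dir)
    table = pd.read_csv(src / WAVEFORM_FILE)
    sidecar = json.loads((src / SIDECAR_FILE).read_text())
    subjects = sidecar["subjects"]
    records = []
    for (subject_id, replicate), group in table.groupby(
        ["subject_id", "replicate"], sort=True
    ):
        meta = subjects[str(subject_id)]
        channels = {}
        for channel, cg in group.groupby("channel", sort=False):
            cg = cg.sort_values("t_seconds")
            channels[str(channel)] = cg["value"].to_numpy()
        rec = BreathRecord(
            subject_id=str(subject_id),
            age_group=meta["age_group"],
            label=int(meta["label"]),
            replicate_index=int(replicate),
            sampling_rate=float(meta["sampling_rate"]),
            channels={name: channels[name] for name in CHANNELS},
        )
        rec.validate()
        records.append(rec)
    return records
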