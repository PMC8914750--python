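"""Synthetic wearable-sensor generator.

Emulates the forearm force-myography hardware so every downstream stage is
testable without the device: a sponge-coupled photoresistor array (12
channels, saturating voltage-vs-compression curve), three Hall sensors
reading a wrist-mounted magnet (cosine-of-offset dipole approximation),
a 10-bit 0-5 V ADC, Gaussian sensor noise, and ramp grip trials in which
the latent force obeys the Voigt model F = a.X + b.Xdot + c exactly.

Study conditions (true parameter bank, per-channel ramp depths) are fixed
constants drawn once from an internal seed; the user seed drives only the
stochastic parts (noise, perturbation phases).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .voigt import ANGLES, N_CHANNELS, VoigtParams, estimate_derivative

__all__ = [
    "PhotoCurve", "HallGeometry", "NoiseConfig", "AdcConfig", "SynthConfig",
    "GripTrial", "default_params_bank", "photoresistor_response",
    "quantize_adc", "hall_response", "generate_grip_trial",
    "generate_hall_stream", "make_angle_dataset", "corrupt_window",
    "corrupt_values", "write_stream_csv", "read_stream_csv",
]

# fixed internal seed for the "true subject" parameter bank — a study
# condition, deliberately decoupled from the user-facing seed
_BANK_SEED = 20220315

# per-channel maximum sponge compression at full grip (mm), within the
# 0-15 mm characterization range of the sensor
_RAMP_DEPTH_MM = 6.0 + 0.4 * np.arange(N_CHANNELS)

# fixed per-channel electronics bias (V): manufacturing spread of the
# divider offsets; also keeps the 12 channels from crossing the same ADC
# code boundary in lockstep
_DARK_OFFSET_V = np.linspace(-0.024, 0.024, N_CHANNELS)

_PHOTO_COLS = [f"p{i:02d}" for i in range(1, N_CHANNELS + 1)]
_HALL_COLS = ["h1", "h2", "h3"]
STREAM_COLUMNS = ["t", *_PHOTO_COLS, *_HALL_COLS, "force", "angle"]


@dataclass
class PhotoCurve:
    """Saturating photoresistor voltage-vs-deformation characteristic."""

    v_dark: float = 0.5   # V at zero compression
    v_sat: float = 4.5    # V asymptote at deep compression
    d_scale: float = 5.0  # mm e-folding scale of the saturation


@dataclass
class HallGeometry:
    """Cosine dipole approximation of the three wrist-magnet Hall readings."""

    amplitudes: tuple = (1.2, 1.0, 1.1)   # V
    phases_deg: tuple = (-60.0, 0.0, 60.0)  # sensor placement around the wrist
    baseline: float = 2.5                 # V mid-rail offset
    wobble_deg: float = 2.0               # slow physiological wrist jitter


@dataclass
class NoiseConfig:
    photo_sd: float = 0.02  # V
    hall_sd: float = 0.05   # V
    force_sd: float = 1.0   # N, grip-meter measurement noise
    # noise inflated at -90 deg: forceful supination is awkward, producing
    # the noisier deformation signals and force readings seen at that posture
    photo_scale_by_angle: dict = field(
        default_factory=lambda: {-90: 1.75, 0: 1.0, 90: 1.0})
    force_scale_by_angle: dict = field(
        default_factory=lambda: {-90: 1.75, 0: 1.0, 90: 1.0})


@dataclass
class AdcConfig:
    bits: int = 10
    v_ref: float = 5.0

    @property
    def lsb(self) -> float:
        """Least-significant-bit voltage step, v_ref / 2**bits."""
        return self.v_ref / 2 ** self.bits


@dataclass
class SynthConfig:
    """All generator settings; defaults are the reference study conditions."""

    sampling_rate: float = 1000.0  # samples/s
    trial_duration: float = 1.0    # s -> n = 1000 samples per ramp trial
    max_force: float = 35.0        # N, grip-meter full scale
    pert_amplitude_mm: float = 0.3
    photo_curve: PhotoCurve = field(default_factory=PhotoCurve)
    hall_geometry: HallGeometry = field(default_factory=HallGeometry)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    adc: AdcConfig = field(default_factory=AdcConfig)
    true_params: dict | None = None  # angle -> VoigtParams; None = default bank
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.max_force <= 0:
            raise ValueError("max_force must be positive")
        if self.adc.bits < 1:
            raise ValueError("adc.bits must be >= 1")
        if min(self.noise.photo_sd, self.noise.hall_sd, self.noise.force_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if self.true_params is None:
            self.true_params = default_params_bank(self.photo_curve,
                                                   self.max_force)
        if set(self.true_params) != set(ANGLES):
            raise ValueError(f"true_params must have exactly the keys {ANGLES}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["true_params"] = {str(a): p.to_dict()
                            for a, p in self.true_params.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["photo_curve"] = PhotoCurve(**d["photo_curve"])
        hg = d["hall_geometry"]
        hg["amplitudes"] = tuple(hg["amplitudes"])
        hg["phases_deg"] = tuple(hg["phases_deg"])
        d["hall_geometry"] = HallGeometry(**hg)
        nz = d["noise"]
        for key in ("photo_scale_by_angle", "force_scale_by_angle"):
            nz[key] = {int(k): v for k, v in nz[key].items()}
        d["noise"] = NoiseConfig(**nz)
        d["adc"] = AdcConfig(**d["adc"])
        if d.get("true_params"):
            d["true_params"] = {int(a): VoigtParams.from_dict(p)
                                for a, p in d["true_params"].items()}
        return cls(**d)


def default_params_bank(photo_curve: PhotoCurve | None = None,
                        max_force: float = 35.0) -> dict[int, VoigtParams]:
    """Fixed per-angle true parameters.

    Elastic coefficients are scaled so the full-grip force peaks near 96%
    of the meter range; the offset puts the resting force at 0.5 N; the
    viscous coefficients are small relative to the elastic ones, as in
    passive muscle tissue.
    """
    curve = photo_curve or PhotoCurve()
    v0 = photoresistor_response(0.0, curve) + _DARK_OFFSET_V
    dv = photoresistor_response(_RAMP_DEPTH_MM, curve) \
        - photoresistor_response(0.0, curve)
    bank = {}
    for angle, ss in zip(ANGLES, np.random.SeedSequence(_BANK_SEED).spawn(3)):
        rng = np.random.default_rng(ss)
        a_raw = rng.uniform(0.8, 1.6, N_CHANNELS)
        b = rng.uniform(0.01, 0.04, N_CHANNELS)
        a = a_raw * (0.957 * max_force - 0.5) / float(a_raw @ dv)
        c = 0.5 - float(a @ v0)
        bank[angle] = VoigtParams(a=a, b=b, c=c, angle=angle)
    return bank


def photoresistor_response(d, cfg_or_curve=None):
    """Voltage of one photoresistor channel at sponge compression ``d`` mm.

    Deterministic saturating curve v_dark + (v_sat - v_dark)(1 - e^{-d/d_scale});
    noise and quantization are applied separately.
    """
    curve = _photo_curve(cfg_or_curve)
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("deformation must be finite and non-negative")
    v = curve.v_dark + (curve.v_sat - curve.v_dark) * (1.0 - np.exp(-d / curve.d_scale))
    return float(v) if v.ndim == 0 else v


def _photo_curve(obj) -> PhotoCurve:
    if obj is None:
        return PhotoCurve()
    return obj.photo_curve if isinstance(obj, SynthConfig) else obj


def quantize_adc(v, cfg_or_adc=None):
    """Clamp to [0, v_ref] and round to the nearest LSB multiple.

    For the default 10-bit 0-5 V converter the LSB is 4.88 mV, so the
    quantization error never exceeds 2.44 mV.
    """
    adc = cfg_or_adc or AdcConfig()
    if isinstance(adc, SynthConfig):
        adc = adc.adc
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    q = np.round(np.clip(v, 0.0, adc.v_ref) / adc.lsb) * adc.lsb
    return float(q) if q.ndim == 0 else q


def hall_response(theta, sensor_index: int, cfg_or_geom=None):
    """Noise-free Hall reading of sensor 1..3 at wrist angle ``theta`` deg."""
    geom = cfg_or_geom or HallGeometry()
    if isinstance(geom, SynthConfig):
        geom = geom.hall_geometry
    if sensor_index not in (1, 2, 3):
        raise ValueError("sensor_index must be 1, 2 or 3")
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    i = sensor_index - 1
    v = geom.baseline + geom.amplitudes[i] * np.cos(
        np.deg2rad(theta - geom.phases_deg[i]))
    return float(v) if v.ndim == 0 else v


@dataclass
class GripTrial:
    """One ramp grip trial with both latent and measured signals."""

    t: np.ndarray
    deformation_mm: np.ndarray   # (n, 12) latent compression
    volts_clean: np.ndarray      # (n, 12) pre-noise, pre-ADC voltages
    volts_meas: np.ndarray       # (n, 12) noisy, quantized voltages
    hall_meas: np.ndarray        # (n, 3)
    force_true: np.ndarray       # (n,) latent Voigt force
    force_meas: np.ndarray       # (n,) noisy, clipped meter reading
    angle: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.volts_meas, columns=_PHOTO_COLS)
        df.insert(0, "t", self.t)
        df[_HALL_COLS] = self.hall_meas
        df["force"] = self.force_meas
        df["angle"] = self.angle
        return df[STREAM_COLUMNS]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _hall_block(theta_series: np.ndarray, cfg: SynthConfig,
                rng: np.random.Generator) -> np.ndarray:
    h = np.stack([hall_response(theta_series, i, cfg.hall_geometry)
                  for i in (1, 2, 3)], axis=1)
    h = h + rng.normal(0.0, cfg.noise.hall_sd, size=h.shape)
    return quantize_adc(h, cfg.adc)


def _wobble(theta0: float, t: np.ndarray, geom: HallGeometry,
            rng: np.random.Generator) -> np.ndarray:
    f = rng.uniform(0.5, 1.5)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return theta0 + geom.wobble_deg * np.sin(2.0 * np.pi * f * t + phi)


def generate_grip_trial(angle: int, cfg: SynthConfig | None = None,
                        rng_seed=None) -> GripTrial:
    """One 0-to-max ramp grip trial at a fixed wrist angle.

    The 12 latent compression channels follow a smoothstep ramp to their
    per-channel depth plus small independent sinusoidal perturbations
    (muscle tremor), keeping each channel identifiable.  The latent force
    is computed exactly from the true Voigt parameters on the clean
    voltages, so a zero-noise trial satisfies the model to machine
    precision before ADC quantization.
    """
    cfg = cfg or SynthConfig()
    if angle not in ANGLES:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)

    n = int(round(cfg.trial_duration * cfg.sampling_rate))
    dt = 1.0 / cfg.sampling_rate
    t = np.arange(n) * dt
    s = _smoothstep(t / cfg.trial_duration)

    freqs = rng.uniform(2.0, 7.0, N_CHANNELS)
    phases = rng.uniform(0.0, 2.0 * np.pi, N_CHANNELS)
    pert = cfg.pert_amplitude_mm * np.sin(
        2.0 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
    d = _RAMP_DEPTH_MM[None, :] * s[:, None] + pert * s[:, None]

    v = photoresistor_response(d, cfg.photo_curve) + _DARK_OFFSET_V[None, :]
    vdot = estimate_derivative(v, dt)
    p = cfg.true_params[angle]
    force_true = np.clip(v @ p.a + vdot @ p.b + p.c, 0.0, cfg.max_force)

    photo_sd = cfg.noise.photo_sd * cfg.noise.photo_scale_by_angle.get(angle, 1.0)
    volts_meas = quantize_adc(v + rng.normal(0.0, photo_sd, size=v.shape),
                              cfg.adc)
    theta = _wobble(angle, t, cfg.hall_geometry, rng)
    hall_meas = _hall_block(theta, cfg, rng)
    force_sd = cfg.noise.force_sd * cfg.noise.force_scale_by_angle.get(angle, 1.0)
    force_meas = np.clip(force_true + rng.normal(0.0, force_sd, n),
                         0.0, cfg.max_force)
    return GripTrial(t=t, deformation_mm=d, volts_clean=v,
                     volts_meas=volts_meas, hall_meas=hall_meas,
                     force_true=force_true, force_meas=force_meas, angle=angle)


def generate_hall_stream(angle: int, duration: float,
                         cfg: SynthConfig | None = None,
                         rng_seed=None) -> pd.DataFrame:
    """Resting-grip stream (photoresistors at dark level) at one wrist angle.

    Used to build labeled Hall-window datasets for the angle classifier.
    """
    cfg = cfg or SynthConfig()
    if angle not in ANGLES:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    n = int(round(duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate

    v0 = photoresistor_response(0.0, cfg.photo_curve) + _DARK_OFFSET_V
    photo = quantize_adc(
        v0[None, :] + rng.normal(0.0, cfg.noise.photo_sd, size=(n, N_CHANNELS)),
        cfg.adc)
    theta = _wobble(angle, t, cfg.hall_geometry, rng)
    hall = _hall_block(theta, cfg, rng)

    df = pd.DataFrame(photo, columns=_PHOTO_COLS)
    df.insert(0, "t", t)
    df[_HALL_COLS] = hall
    df["force"] = np.nan
    df["angle"] = angle
    return df[STREAM_COLUMNS]


def make_angle_dataset(cfg: SynthConfig | None = None,
                       windows_per_angle: int = 333, rng_seed=None,
                       window_s: float = 0.2) -> list:
    """Labeled HallWindow dataset, equal counts at -90, 0 and 90 degrees."""
    from .preprocess import stitch_windows

    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(cfg.seed if rng_seed is None else rng_seed)
    windows = []
    for angle, sub in zip(ANGLES, ss.spawn(3)):
        duration = (windows_per_angle + 1) * window_s
        stream = generate_hall_stream(angle, duration, cfg, rng_seed=sub)
        wins = stitch_windows(stream, window_s=window_s,
                              sampling_rate=cfg.sampling_rate)
        windows.extend(wins[:windows_per_angle])
    return windows


def corrupt_values(values: np.ndarray, mode: str, rng_seed=None,
                   n_spikes: int = 5, dropout_len: int = 100,
                   high: float = 1.0) -> np.ndarray:
    """Disturbance injection: random full-scale spikes or a zeroed run.

    ``dropout`` zero-fills a contiguous run of exactly ``dropout_len``
    samples (fixed length preserved for the classifier); ``spikes``
    replaces ``n_spikes`` random samples with the full-scale value.
    """
    rng = np.random.default_rng(rng_seed)
    out = np.array(values, dtype=float, copy=True)
    n = out.shape[-1] if out.ndim else len(out)
    if mode == "spikes":
        if n_spikes > 0:
            idx = rng.choice(n, size=min(n_spikes, n), replace=False)
            out[idx] = high
    elif mode == "dropout":
        if n < dropout_len:
            raise ValueError(
                f"dropout needs >= {dropout_len} samples, window has {n}")
        start = int(rng.integers(0, n - dropout_len + 1))
        out[start:start + dropout_len] = 0.0
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return out


def corrupt_window(window, mode: str, rng_seed=None, **kwargs):
    """corrupt_values applied to a HallWindow; label and length unchanged."""
    from .preprocess import HallWindow

    values = corrupt_values(window.values, mode, rng_seed=rng_seed, **kwargs)
    return HallWindow(values=values, label=window.label,
                      t_start=window.t_start)


def write_stream_csv(df: pd.DataFrame, path) -> None:
    """Emit the stream CSV dialect (header mandatory, empty optional fields)."""
    df.to_csv(path, index=False, na_rep="")


def read_stream_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream CSV missing columns {missing}")
    return df
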