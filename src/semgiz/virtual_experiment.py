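"""Virtual sEMG experiment: arrays, montage, noise and dataset generation.

The default configuration reproduces the study conditions of the simulated
benchmark: six motor-unit geometry sets (innervation-zone width 2 cm, radius
of a 10 cm^2 disc, junction windows 0.5 cm, total lengths 15 and 19 cm split
50:50, 70:30 and 25:75), eight motor-unit ids {400, 450, ..., 750} from the
774-unit pool, and a linear 68-electrode array 2 cm above the fiber plane
with 5 mm pitch, replicated at 20 sub-pitch x-offsets.  Each recording is one
motor-unit discharge sampled at 5 kHz; double-differential channels are
derived from the monopolar potentials, and calibrated Gaussian noise is added
at configurable SNR levels.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .motor_unit import GeometrySet, MotorUnit, PopulationModel, sample_motor_unit
from .source_model import ActionPotentialShape
from .volume_conductor import Medium, motor_unit_potentials

__all__ = [
    "ElectrodeArray",
    "Recording",
    "ExperimentConfig",
    "default_geometry_sets",
    "default_config",
    "electrode_positions",
    "dd_montage",
    "noise_sigma",
    "add_noise",
    "simulation_duration",
    "generate_dataset",
    "save_recording",
    "load_recording",
]


@dataclass(frozen=True)
class ElectrodeArray:
    """Linear monopolar array along x at fixed (y, z); lengths in metres."""

    n_electrodes: int = 68
    ied: float = 0.005
    offset: float = 0.0
    base_x: float = -0.17
    y: float = 0.0
    z: float = 0.02

    def __post_init__(self) -> None:
        if self.n_electrodes < 3 or self.ied <= 0:
            raise ValueError("need >= 3 electrodes and positive pitch")


@dataclass
class Recording:
    """One simulated discharge seen by one array placement.

    ``monopolar`` is (n_electrodes, n_samples) in volts; ``dd`` the derived
    double-differential montage, (n_electrodes - 2, n_samples).
    ``dd_positions`` are the x coordinates (m) of the DD channel centers.
    """

    monopolar: np.ndarray | None
    dd: np.ndarray
    fs: float
    dd_positions: np.ndarray
    ied: float
    snr_db: float | None = None
    noise_sigma: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.dd.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def default_geometry_sets() -> list[GeometrySet]:
    """The six benchmark geometry sets (two lengths x three left:right splits)."""
    sets = []
    for L in (0.15, 0.19):
        for gl, gr in ((0.5, 0.5), (0.7, 0.3), (0.25, 0.75)):
            sets.append(GeometrySet(l_left=L * gl, l_right=L * gr))
    return sets


@dataclass
class ExperimentConfig:
    population: PopulationModel = field(default_factory=PopulationModel)
    geometry_sets: list[GeometrySet] = field(default_factory=default_geometry_sets)
    mu_ids: list[int] = field(default_factory=lambda: list(range(400, 751, 50)))
    array: ElectrodeArray = field(default_factory=ElectrodeArray)
    n_offsets: int = 20
    fs: float = 5000.0
    duration: float | None = None  # s; None -> worst-case over geometry sets
    reference_cv: float = 4.0  # m/s, expected velocity for the duration bound
    snr_list: list[float] = field(default_factory=list)
    seed: int = 0
    scale: float = 1.0
    shape: ActionPotentialShape = field(default_factory=ActionPotentialShape)
    medium: Medium = field(default_factory=Medium)

    @property
    def offsets(self) -> np.ndarray:
        """Sub-pitch array shifts: n/n_offsets electrode pitches, n = 0..n-1."""
        return np.arange(self.n_offsets) * self.array.ied / self.n_offsets


def electrode_positions(array: ElectrodeArray) -> np.ndarray:
    """Positions (n_electrodes, 3) with x = base_x + e*ied + offset."""
    e = np.arange(array.n_electrodes)
    x = array.base_x + e * array.ied + array.offset
    return np.column_stack([x, np.full_like(x, array.y), np.full_like(x, array.z)])


def dd_montage(monopolar: np.ndarray) -> np.ndarray:
    """Double-differential montage: dd[k] = mono[k] - 2 mono[k+1] + mono[k+2].

    The second spatial difference annihilates components constant or linear
    across the array, which suppresses the common far-field and emphasizes
    traveling waves.  Channel k sits at electrode k+1.
    """
    mono = np.asarray(monopolar)
    if mono.ndim != 2 or mono.shape[0] < 3:
        raise ValueError("need a (channels >= 3, samples) array")
    return mono[:-2] - 2.0 * mono[1:-1] + mono[2:]


def noise_sigma(snr_db: float, p_signal: float) -> float:
    """Noise standard deviation realizing ``snr_db`` against power ``p_signal``."""
    if not p_signal > 0:
        raise ValueError("signal power must be > 0")
    return math.sqrt(p_signal / 10.0 ** (0.1 * snr_db))


def add_noise(recording: Recording, snr_db: float, rng: np.random.Generator) -> Recording:
    """Additive white Gaussian noise on every DD channel, calibrated by SNR.

    The per-channel signal power is the uncorrected mean of squares over all
    samples; the calibration power is the median across channels, so the SNR
    is exact for the median-power channel and approximate elsewhere.
    """
    power = np.mean(recording.dd**2, axis=1)
    p_med = float(np.median(power))
    if p_med <= 0:
        raise ValueError("all-zero recording: SNR calibration undefined")
    sigma = noise_sigma(snr_db, p_med)
    noisy = recording.dd + rng.normal(0.0, sigma, size=recording.dd.shape)
    return dataclasses.replace(
        recording,
        monopolar=None,
        dd=noisy,
        snr_db=snr_db,
        noise_sigma=sigma,
        meta={**recording.meta, "noise": "awgn"},
    )


def simulation_duration(config: ExperimentConfig) -> float:
    """Time (s) for the slowest worst-case action potential to reach a fiber end.

    The worst case over the configured geometry sets is the largest admissible
    innervation-point-to-junction distance divided by the reference conduction
    velocity, rounded up to the sampling grid.
    """
    if config.duration is not None:
        return config.duration
    dmax = max(g.max_ip_to_junction for g in config.geometry_sets)
    raw = dmax / config.reference_cv
    return math.ceil(raw * config.fs - 1e-9) / config.fs


def n_samples(config: ExperimentConfig) -> int:
    """Samples per channel including t = 0."""
    return int(math.floor(simulation_duration(config) * config.fs + 1e-9)) + 1


def _simulate_mu_recordings(
    mu: MotorUnit, config: ExperimentConfig, t: np.ndarray
) -> list[Recording]:
    """Noiseless recordings of one unit for every array offset.

    All offsets are simulated in one vectorized pass over the union of
    electrode positions, then sliced per placement.
    """
    arr = config.array
    all_pos = []
    for off in config.offsets:
        all_pos.append(electrode_positions(dataclasses.replace(arr, offset=float(off))))
    pos = np.concatenate(all_pos, axis=0)
    phi = motor_unit_potentials(t, mu, config.shape, config.medium, pos)
    recs = []
    for k, off in enumerate(config.offsets):
        mono = phi[k * arr.n_electrodes : (k + 1) * arr.n_electrodes]
        dd = dd_montage(mono)
        x = pos[k * arr.n_electrodes : (k + 1) * arr.n_electrodes, 0]
        recs.append(
            Recording(
                monopolar=mono,
                dd=dd,
                fs=config.fs,
                dd_positions=x[1:-1],
                ied=arr.ied,
                meta={
                    "mu_id": mu.mu_id,
                    "array_offset": float(off),
                    "true_center_x": mu.true_iz_center_x,
                    "n_fibers": len(mu.fibers),
                },
            )
        )
    return recs


def generate_dataset(
    config: ExperimentConfig | None = None, rng: np.random.Generator | None = None
) -> list[Recording]:
    """Simulate the full factorial dataset of the virtual experiment.

    For every geometry set and motor-unit id one unit is sampled and recorded
    at every array offset; if ``config.snr_list`` is non-empty, a noisy copy
    per SNR level follows each noiseless recording.  Every random draw derives
    from ``config.seed`` (or the supplied generator), so runs are reproducible.
    """
    config = config or default_config()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(n_samples(config)) / config.fs
    out: list[Recording] = []
    for g_id, geom in enumerate(config.geometry_sets):
        for mu_id in config.mu_ids:
            mu = sample_motor_unit(mu_id, config.population, geom, rng, scale=config.scale)
            for rec in _simulate_mu_recordings(mu, config, t):
                rec.meta["geometry_set"] = g_id
                out.append(rec)
                for snr in config.snr_list:
                    out.append(add_noise(rec, snr, rng))
    return out


def default_config(**overrides) -> ExperimentConfig:
    return ExperimentConfig(**overrides)


# ---------------------------------------------------------------------------
# file I/O: CSV of DD channels plus a JSON metadata sidecar


def save_recording(recording: Recording, csv_path: str | Path) -> None:
    """Write the DD array as CSV (header: channel x in mm; col 0: time in ms).

    A ``.json`` sidecar next to the CSV holds sampling and ground-truth
    metadata.  Numbers are written in locale-independent scientific notation.
    """
    csv_path = Path(csv_path)
    header = "time_ms," + ",".join(f"{x * 1e3:.6g}" for x in recording.dd_positions)
    data = np.column_stack([recording.times * 1e3, recording.dd.T])
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="", fmt="%.10e")
    sidecar = {
        "fs": recording.fs,
        "ied": recording.ied,
        "snr_db": recording.snr_db,
        "noise_sigma": recording.noise_sigma,
        "seed": recording.seed,
        "dd_positions_m": [float(x) for x in recording.dd_positions],
        "meta": recording.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(csv_path: str | Path, fs: float | None = None, ied: float | None = None) -> Recording:
    """Read a recording written by :func:`save_recording` (or the same layout).

    Without a sidecar, ``fs`` and ``ied`` must be given and the channel
    positions are taken from the CSV header (mm).
    """
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    with open(csv_path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    dd = data[:, 1:].T
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        fs = side["fs"]
        ied = side["ied"]
        positions = np.asarray(side["dd_positions_m"], dtype=float)
        meta = side.get("meta", {})
        snr_db, nsig, seed = side.get("snr_db"), side.get("noise_sigma"), side.get("seed")
    else:
        if fs is None or ied is None:
            raise ValueError("no sidecar: fs and ied are required")
        positions = np.array([float(h) for h in header[1:]]) * 1e-3
        meta, snr_db, nsig, seed = {}, None, None, None
    return Recording(
        monopolar=None,
        dd=dd,
        fs=float(fs),
        dd_positions=positions,
        ied=float(ied),
        snr_db=snr_db,
        noise_sigma=nsig,
        seed=seed,
        meta=meta,
    )


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    """Build a configuration from a YAML document (missing keys -> defaults)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "population" in doc:
        kwargs["population"] = PopulationModel(**doc["population"])
    if "geometry_sets" in doc:
        kwargs["geometry_sets"] = [
            GeometrySet(**{**g, "iz_center": tuple(g.get("iz_center", (0, 0, 0)))})
            for g in doc["geometry_sets"]
        ]
    if "array" in doc:
        kwargs["array"] = ElectrodeArray(**doc["array"])
    for key in ("mu_ids", "n_offsets", "fs", "duration", "reference_cv", "snr_list", "seed", "scale"):
        if key in doc:
            kwargs[key] = doc[key]
    return ExperimentConfig(**kwargs)
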