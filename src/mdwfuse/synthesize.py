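"""Synthetic two-sensor spectral datasets with known ground truth.

Emulates two vibrational-spectroscopy sensors (an NIR-like and an MIR-like
channel) measuring the same analyte in a formulation matrix. Each
spectrum is a sum of Gaussian bands on the sensor's wavenumber grid:
analyte bands whose heights scale linearly with concentration
(Beer-Lambert), interferent bands with random per-sample amplitudes, a
smooth random baseline, i.i.d. Gaussian noise — and, for a chosen fraction
of samples, a sensor-specific spurious artifact band. Artifact samples are
disjoint between sensors, so every sample has at least one clean channel:
that is the regime in which per-sample distance-based fusion weighting can
beat either single sensor, and the artifact makes the affected sensor both
less accurate and more distant (larger Mahalanobis distance) for exactly
those samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ReferenceValues, SpectraTable


@dataclass
class Band:
    """A Gaussian band: center (cm^-1), width sigma (cm^-1), peak height (AU)."""

    center: float
    width: float
    height: float


@dataclass
class SensorConfig:
    name: str
    wn_start: float
    wn_end: float
    wn_step: float
    analyte_bands: list[Band]
    interferent_bands: list[Band] = field(default_factory=list)
    baseline_amplitude: float = 0.0
    noise_sd: float = 0.0
    artifact_fraction: float = 0.0
    artifact_bands: list[Band] = field(default_factory=list)

    def grid(self) -> np.ndarray:
        if not (self.wn_end > self.wn_start and self.wn_step > 0):
            raise ValueError(f"sensor {self.name}: invalid wavenumber grid")
        return np.arange(self.wn_start, self.wn_end + 0.5 * self.wn_step, self.wn_step)


@dataclass
class SyntheticConfig:
    n_samples: int
    concentration_range: tuple[float, float]
    sensors: list[SensorConfig]
    seed: int = 1

    def validate(self) -> None:
        lo, hi = self.concentration_range
        if not (0 <= lo < hi):
            raise ValueError("concentration_range must satisfy 0 <= low < high")
        if self.n_samples < 5:
            raise ValueError("need at least 5 samples")
        if not self.sensors:
            raise ValueError("need at least one sensor")
        for s in self.sensors:
            if not 0.0 <= s.artifact_fraction <= 0.5:
                raise ValueError(f"sensor {s.name}: artifact_fraction outside [0, 0.5]")
            if s.artifact_fraction > 0 and not s.artifact_bands:
                raise ValueError(f"sensor {s.name}: artifact fraction set but no band")
            s.grid()


def _gauss(wn: np.ndarray, band: Band) -> np.ndarray:
    return band.height * np.exp(-0.5 * ((wn - band.center) / band.width) ** 2)


def generate_dataset(config: SyntheticConfig):
    """Generate one dataset: (list of SpectraTable, ReferenceValues, artifact labels).

    Reproducible from ``config.seed`` alone. Random streams are derived per
    purpose — concentrations from (seed, 0), sensor i's nuisance terms from
    (seed, i+1), artifact assignment from (seed, 999) — so adding a sensor
    never perturbs the data of existing sensors. Artifact sample sets are
    disjoint slices of one shared permutation.

    ``artifact_labels`` maps sensor name -> boolean vector over samples.
    """
    config.validate()
    n = config.n_samples
    lo, hi = config.concentration_range
    conc = np.random.default_rng([config.seed, 0]).uniform(lo, hi, size=n)
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    perm = np.random.default_rng([config.seed, 999]).permutation(n)

    tables: list[SpectraTable] = []
    labels: dict[str, np.ndarray] = {}
    offset = 0
    for i, sensor in enumerate(config.sensors):
        rng = np.random.default_rng([config.seed, i + 1])
        wn = sensor.grid()
        spectra = np.zeros((n, wn.size))
        for band in sensor.analyte_bands:
            spectra += conc[:, None] * _gauss(wn, band)[None, :]
        for band in sensor.interferent_bands:
            amp = np.clip(rng.normal(1.0, 0.3, size=n), 0.0, None)
            spectra += amp[:, None] * _gauss(wn, band)[None, :]
        if sensor.baseline_amplitude > 0:
            b0 = rng.normal(0.0, sensor.baseline_amplitude, size=n)
            b1 = rng.normal(0.0, sensor.baseline_amplitude, size=n)
            x = (wn - wn.mean()) / (wn[-1] - wn[0])
            spectra += b0[:, None] + b1[:, None] * x[None, :]
        flagged = np.zeros(n, dtype=bool)
        n_art = int(round(sensor.artifact_fraction * n))
        if n_art > 0:
            chosen = perm[offset : offset + n_art]
            offset += n_art
            flagged[chosen] = True
            # one artifact event per sample: a shared random scale applied to
            # a fixed multi-band shape, so the perturbation has a consistent
            # multi-dimensional signature in score space
            shape = np.sum([_gauss(wn, b) for b in sensor.artifact_bands], axis=0)
            scale = np.clip(rng.normal(1.0, 0.2, size=n_art), 0.3, None)
            spectra[chosen] += scale[:, None] * shape[None, :]
        if sensor.noise_sd > 0:
            spectra += rng.normal(0.0, sensor.noise_sd, size=spectra.shape)
        tables.append(
            SpectraTable(
                sample_ids=list(sample_ids),
                wavenumbers=wn,
                absorbance=spectra,
                sensor_name=sensor.name,
            )
        )
        labels[sensor.name] = flagged
    reference = ReferenceValues(list(sample_ids), conc)
    return tables, reference, labels


def default_benchmark(seed: int = 1) -> SyntheticConfig:
    """The frozen two-sensor benchmark configuration.

    78 samples over 0.1-4.98 % w/w. Sensor A is NIR-like (broad overtone
    bands, low noise); sensor B is MIR-like (sharp fundamentals, noise SD
    twice sensor A's). Both carry interferent bands, baseline drift and a
    10% artifact fraction with disjoint artifact sets, so each sensor is
    locally unreliable for a different subset of samples.
    """
    nir = SensorConfig(
        name="NIR",
        wn_start=4500.0,
        wn_end=9000.0,
        wn_step=25.0,
        analyte_bands=[Band(5200, 120, 0.080), Band(6900, 180, 0.050), Band(8400, 150, 0.030)],
        interferent_bands=[Band(6000, 200, 0.060), Band(7600, 160, 0.040)],
        baseline_amplitude=0.010,
        noise_sd=0.002,
        artifact_fraction=0.1,
        artifact_bands=[Band(5320, 120, 0.250), Band(7200, 150, 0.180)],
    )
    mir = SensorConfig(
        name="MIR",
        wn_start=600.0,
        wn_end=1800.0,
        wn_step=4.0,
        analyte_bands=[Band(1050, 15, 0.50), Band(1450, 20, 0.30), Band(1730, 12, 0.20)],
        interferent_bands=[Band(900, 25, 0.35), Band(1600, 18, 0.25)],
        baseline_amplitude=0.020,
        noise_sd=0.004,
        artifact_fraction=0.1,
        artifact_bands=[Band(1075, 25, 1.20), Band(1300, 30, 0.80)],
    )
    return SyntheticConfig(
        n_samples=78,
        concentration_range=(0.1, 4.98),
        sensors=[nir, mir],
        seed=seed,
    )
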