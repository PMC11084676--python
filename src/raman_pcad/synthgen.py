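"""Synthetic two-cohort Raman study generator.

Emulates the structure of a dried-droplet CSF Raman study: two patient
cohorts measured in different years (hence batch effects), a healthy (H)
and a preclinical-Alzheimer (PC) class in each, and a fixed number of
replicate spectra per patient acquired at the droplet ring.  Class
membership perturbs the amplitudes of a few planted marker bands;
cohort membership perturbs others.  Every spectrum additionally carries
a smooth polynomial baseline, a per-spectrum multiplicative scatter
factor and additive Gaussian noise, so that the preprocessing stages
(smoothing, baseline removal, SNV) all have real work to do.

Peaks are pseudo-Voigt profiles (50/50 Gaussian-Lorentzian), the
conventional approximation for Raman band shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakSpec",
    "SynthConfig",
    "SpectralDataset",
    "default_peaks",
    "generate_patient_spectrum",
    "generate_study",
    "write_dataset_csv",
    "read_dataset_csv",
]

# Marker bands planted as class-discriminative, in cm^-1. They sit at
# wavenumbers reported for hypotaurine/taurine (1045, 1065) and
# guanine/phosphatidylserine (727, 956) in CSF Raman work.
DISCRIMINATIVE_CENTERS = (727.0, 956.0, 1045.0, 1065.0)


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band.

    Parameters
    ----------
    center : float
        Band position in cm^-1.
    width : float
        Full width at half maximum in cm^-1.
    base_amplitude : float
        Peak height in arbitrary intensity units for a healthy cohort-1
        patient with zero patient effect.
    class_effect : float
        Fractional amplitude change in the preclinical class
        (0 = non-discriminative, 0.3 = 30% higher in PC).
    batch_effect : float
        Fractional amplitude change in cohort 2 (measurement-year batch
        effect).
    """

    center: float
    width: float
    base_amplitude: float
    class_effect: float = 0.0
    batch_effect: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"peak at {self.center} cm^-1: width must be > 0")
        if not self.base_amplitude > 0:
            raise ValueError(
                f"peak at {self.center} cm^-1: base_amplitude must be > 0"
            )
        if self.class_effect <= -1 or self.batch_effect <= -1:
            raise ValueError(
                f"peak at {self.center} cm^-1: effects must be > -1 "
                "(amplitudes must stay positive)"
            )


def default_peaks() -> tuple[PeakSpec, ...]:
    """Default band set: four class-discriminative markers, a few
    cohort-dependent (batch) bands, and neutral filler bands across the
    fingerprint region."""
    discriminative = [
        PeakSpec(727.0, 12.0, 1.0, class_effect=0.3),
        PeakSpec(956.0, 12.0, 1.0, class_effect=0.3),
        PeakSpec(1045.0, 10.0, 1.0, class_effect=0.3),
        PeakSpec(1065.0, 10.0, 1.0, class_effect=0.3),
    ]
    batch = [
        PeakSpec(890.0, 14.0, 0.8, batch_effect=0.3),
        PeakSpec(1250.0, 18.0, 0.9, batch_effect=0.3),
        PeakSpec(1450.0, 16.0, 1.1, batch_effect=-0.2),
    ]
    filler = [
        PeakSpec(640.0, 14.0, 0.6),
        PeakSpec(760.0, 12.0, 0.7),
        PeakSpec(830.0, 12.0, 0.8),
        PeakSpec(998.0, 8.0, 0.9),
        PeakSpec(1009.0, 8.0, 1.2),
        PeakSpec(1039.0, 8.0, 0.8),
        PeakSpec(1051.0, 8.0, 0.7),
        PeakSpec(1120.0, 14.0, 0.6),
        PeakSpec(1170.0, 14.0, 0.5),
        PeakSpec(1310.0, 16.0, 0.8),
        PeakSpec(1400.0, 14.0, 0.6),
        PeakSpec(1550.0, 18.0, 0.5),
        PeakSpec(1610.0, 14.0, 0.7),
        PeakSpec(1660.0, 20.0, 1.0),
        PeakSpec(1740.0, 14.0, 0.4),
    ]
    return tuple(discriminative + batch + filler)


@dataclass(frozen=True)
class SynthConfig:
    """Study design for a synthetic two-cohort Raman dataset.

    Defaults reproduce the reference design: cohort 1 with 20 healthy +
    20 preclinical patients, cohort 2 with 20 healthy + 15 preclinical
    (75 patients total), 15 replicate spectra per patient, fingerprint
    grid 600-1800 cm^-1 at 1 cm^-1.
    """

    grid_min: float = 600.0
    grid_max: float = 1800.0
    grid_step: float = 1.0
    peaks: tuple[PeakSpec, ...] = field(default_factory=default_peaks)
    n_healthy_c1: int = 20
    n_preclinical_c1: int = 20
    n_healthy_c2: int = 20
    n_preclinical_c2: int = 15
    replicates_per_patient: int = 15
    baseline_order: int = 3
    baseline_scale: float = 0.5
    scatter_sd: float = 0.1
    noise_sd: float = 0.02
    patient_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be > 0")
        for name in (
            "n_healthy_c1",
            "n_preclinical_c1",
            "n_healthy_c2",
            "n_preclinical_c2",
            "replicates_per_patient",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("baseline_scale", "scatter_sd", "noise_sd", "patient_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if not isinstance(self.peaks, tuple):
            object.__setattr__(self, "peaks", tuple(self.peaks))
        for pk in self.peaks:
            if not (self.grid_min <= pk.center <= self.grid_max):
                raise ValueError(
                    f"peak center {pk.center} cm^-1 lies outside the grid "
                    f"[{self.grid_min}, {self.grid_max}]"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(np.floor((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    @property
    def n_patients(self) -> int:
        return (
            self.n_healthy_c1
            + self.n_preclinical_c1
            + self.n_healthy_c2
            + self.n_preclinical_c2
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peaks"] = [asdict(p) for p in self.peaks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["peaks"] = tuple(PeakSpec(**p) for p in d.get("peaks", []))
        return cls(**d)


@dataclass
class SpectralDataset:
    """Spectra plus aligned per-spectrum metadata.

    ``intensities`` has one row per spectrum and one column per
    wavenumber.  All replicates of one patient share a label and cohort.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: np.ndarray
    label: np.ndarray
    cohort: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.patient_id = np.asarray(self.patient_id)
        self.label = np.asarray(self.label)
        self.cohort = np.asarray(self.cohort, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n, p = self.intensities.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError("wavenumber vector does not match spectrum width")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        for name in ("patient_id", "label", "cohort", "replicate"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"metadata vector {name} must have length {n}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        bad = set(np.unique(self.label)) - {"H", "PC"}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        for pid in np.unique(self.patient_id):
            m = self.patient_id == pid
            if len(np.unique(self.label[m])) != 1 or len(np.unique(self.cohort[m])) != 1:
                raise ValueError(
                    f"patient {pid} has conflicting label or cohort across replicates"
                )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            self.wavenumbers,
            self.intensities[mask],
            self.patient_id[mask],
            self.label[mask],
            self.cohort[mask],
            self.replicate[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "label": self.label,
                "cohort": self.cohort,
                "replicate": self.replicate,
            }
        )
        spec = pd.DataFrame(
            self.intensities, columns=[f"{w:g}" for w in self.wavenumbers]
        )
        return pd.concat([meta, spec], axis=1)


_META_COLS = ["patient_id", "label", "cohort", "replicate"]


def write_dataset_csv(
    dataset: SpectralDataset, path: str | Path, config: SynthConfig | None = None
) -> None:
    """Write a dataset in long metadata + wide spectrum layout.

    If ``config`` is given, a sidecar ``<path>.json`` records the full
    generator configuration including the seed, so the file is
    replayable.
    """
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def read_dataset_csv(path: str | Path) -> SpectralDataset:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    wn_cols = [c for c in df.columns if c not in _META_COLS]
    return SpectralDataset(
        wavenumbers=np.array([float(c) for c in wn_cols]),
        intensities=df[wn_cols].to_numpy(dtype=float),
        patient_id=df["patient_id"].to_numpy(),
        label=df["label"].to_numpy(),
        cohort=df["cohort"].to_numpy(),
        replicate=df["replicate"].to_numpy(),
    )


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height 50/50 Gaussian-Lorentzian profile."""
    d2 = (x - center) ** 2
    gauss = np.exp(-4.0 * np.log(2.0) * d2 / fwhm**2)
    lorentz = 1.0 / (1.0 + 4.0 * d2 / fwhm**2)
    return 0.5 * gauss + 0.5 * lorentz


def generate_patient_spectrum(
    config: SynthConfig,
    class_label: str,
    cohort: int,
    patient_effect: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one replicate spectrum.

    The noise model, applied in this order:

    1. peak signal: sum of pseudo-Voigt bands with amplitude
       ``base_amplitude * (1 + class_effect if PC) * (1 + batch_effect
       if cohort 2) * (1 + patient_effect)``;
    2. a smooth random polynomial baseline of degree ``baseline_order``
       scaled by ``baseline_scale`` (shifted to be non-negative);
    3. a per-spectrum multiplicative scatter factor
       ``lognormal(0, scatter_sd)`` on signal + baseline;
    4. additive Gaussian noise with sd ``noise_sd``;
    5. clipping at zero (detector counts cannot be negative).

    ``patient_effect`` must be drawn once per patient upstream so that
    replicates of the same patient share it.
    """
    if class_label not in ("H", "PC"):
        raise ValueError(f"class_label must be 'H' or 'PC', got {class_label!r}")
    if cohort not in (1, 2):
        raise ValueError(f"cohort must be 1 or 2, got {cohort!r}")
    x = config.wavenumbers
    signal = np.zeros_like(x)
    for pk in config.peaks:
        amp = pk.base_amplitude * (1.0 + patient_effect)
        if class_label == "PC":
            amp *= 1.0 + pk.class_effect
        if cohort == 2:
            amp *= 1.0 + pk.batch_effect
        signal += amp * _pseudo_voigt(x, pk.center, pk.width)

    if config.baseline_scale > 0:
        u = np.linspace(-1.0, 1.0, x.size)
        coeffs = rng.normal(size=config.baseline_order + 1)
        poly = np.polynomial.polynomial.polyval(u, coeffs)
        baseline = config.baseline_scale * (poly - poly.min())
    else:
        baseline = 0.0

    scatter = rng.lognormal(0.0, config.scatter_sd) if config.scatter_sd > 0 else 1.0
    out = (signal + baseline) * scatter
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=x.size)
    return np.clip(out, 0.0, None)


def generate_study(config: SynthConfig) -> SpectralDataset:
    """Generate the full two-cohort study.

    Patients are laid out cohort 1 (H then PC) followed by cohort 2
    (H then PC); each patient contributes ``replicates_per_patient``
    consecutive rows.  The per-patient amplitude effect is drawn once
    per patient and shared by all of that patient's replicates.
    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    blocks = [
        (1, "H", config.n_healthy_c1),
        (1, "PC", config.n_preclinical_c1),
        (2, "H", config.n_healthy_c2),
        (2, "PC", config.n_preclinical_c2),
    ]
    rows, pids, labels, cohorts, reps = [], [], [], [], []
    for cohort, label, count in blocks:
        for i in range(count):
            pid = f"D{cohort}-{label}{i + 1:02d}"
            patient_effect = rng.normal(0.0, config.patient_sd)
            for r in range(config.replicates_per_patient):
                rows.append(
                    generate_patient_spectrum(config, label, cohort, patient_effect, rng)
                )
                pids.append(pid)
                labels.append(label)
                cohorts.append(cohort)
                reps.append(r + 1)
    return SpectralDataset(
        wavenumbers=config.wavenumbers,
        intensities=np.vstack(rows),
        patient_id=np.array(pids),
        label=np.array(labels),
        cohort=np.array(cohorts),
        replicate=np.array(reps),
    )


def small_study_config(
    seed: int = 0,
    n_per_group: int = 10,
    grid_step: float = 6.0,
    **overrides,
) -> SynthConfig:
    """A reduced-scale variant of the default design used for fast
    simulations: same peaks and noise structure, coarser grid
    (~200 variables at 6 cm^-1) and fewer patients."""
    base = SynthConfig(
        grid_step=grid_step,
        n_healthy_c1=n_per_group,
        n_preclinical_c1=n_per_group,
        n_healthy_c2=n_per_group,
        n_preclinical_c2=max(1, n_per_group - 2),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
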