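"""Seeded synthetic EEG cohorts with class-dependent regional band-power effects.

Each channel is a sum of band-limited oscillations (one sinusoid per band,
uniformly random phase and center frequency within the band) plus white
noise. Oscillation amplitudes follow smooth baseline scalp profiles that
mimic the canonical topography of resting EEG — theta dominant over the
frontal midline, alpha over posterior sites, beta over central sites —
modulated by per-subject, per-electrode lognormal amplitude jitter so that
individual topographies vary realistically around the group pattern.

A cohort effect ``(region, band, class, multiplier)`` scales the
oscillation amplitude of that band for that class's subjects on the
region's electrodes — not uniformly, but through a fixed spatial profile: a
Gaussian bump centered on the region's centroid electrode, so the effect
changes both the magnitude and the within-region spatial distribution of
band power. A uniform amplitude change would survive in the raw features
but vanish from the normalized topographic images, which deliberately
discard per-region scale; disease effects in this generative model are
therefore focal, as band-power alterations on the scalp are.

Phenotypes (gender, age) are drawn independently of the EEG except for a
configurable age shift in the patient class, which gives the population
graph phenotypic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .montage import ElectrodeMontage, REGIONS, default_montage
from .popgraph import PhenotypeRecord
from .spectral import BAND_ORDER, DEFAULT_BANDS, EEGRecording

__all__ = ["CohortSpec", "Effect", "SyntheticError", "generate_cohort"]


class SyntheticError(ValueError):
    """Raised for invalid cohort specifications."""


@dataclass(frozen=True)
class Effect:
    """Relative band-power multiplier for one (region, band, class) triple."""

    region: str
    band: str
    class_label: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise SyntheticError("effect multipliers must be positive")


def _default_effects() -> tuple[Effect, ...]:
    # Two-class cohort premise: patients show elevated frontal theta power
    # and a milder parietal alpha elevation relative to controls.
    return (
        Effect("frontal", "theta", "patient", 3.0),
        Effect("parietal", "alpha", "patient", 1.5),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions for a two-class synthetic EEG cohort.

    Defaults: 40 subjects per class, 128 Hz sampling, 4 s records,
    10 uV band oscillations over 5 uV broadband noise, patient-class
    frontal-theta and parietal-alpha effects, and a +5 year patient age
    shift. ``effect_width`` is the angular width (radians) of the spatial
    effect profile on the scalp sphere; ``amplitude_jitter`` the sd of the
    per-subject, per-electrode lognormal amplitude variation.
    """

    n_per_class: int = 40
    fs: float = 128.0
    duration_s: float = 4.0
    effects: tuple[Effect, ...] = field(default_factory=_default_effects)
    noise_sd: float = 5.0
    amplitude_jitter: float = 0.15
    base_amplitude: dict[str, float] = field(
        default_factory=lambda: {"theta": 10.0, "alpha": 10.0, "beta": 5.0}
    )
    class_labels: tuple[str, str] = ("patient", "control")
    gender_p: float = 0.5
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"patient": 75.0, "control": 70.0}
    )
    age_sd: float = 5.0
    effect_width: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise SyntheticError("n_per_class must be at least 2")
        top = max(hi for _, hi in DEFAULT_BANDS.values())
        if self.fs <= 2 * top:
            raise SyntheticError(
                f"fs must exceed twice the highest band edge ({2 * top} Hz)"
            )
        for eff in self.effects:
            if eff.region not in REGIONS:
                raise SyntheticError(f"effect names unknown region {eff.region!r}")
            if eff.band not in BAND_ORDER:
                raise SyntheticError(f"effect names unknown band {eff.band!r}")
            if eff.class_label not in self.class_labels:
                raise SyntheticError(
                    f"effect names unknown class {eff.class_label!r}"
                )

    def null(self) -> "CohortSpec":
        """Copy of this spec with every effect removed (identical classes)."""
        return replace(self, effects=())


def _baseline_profiles(montage: ElectrodeMontage) -> dict[str, np.ndarray]:
    """Smooth per-band baseline amplitude profiles over the montage.

    Gaussian bumps (width 0.8 rad of great-circle angle) around the
    canonical dominance site of each rhythm: theta at the frontal midline,
    alpha at the occipital pole, beta at the vertex. Values scale the base
    amplitude by 1 + 0.5 * bump, so topographies are smooth but nowhere
    silent.
    """
    coords = montage.coords3d
    centers = {
        "theta": np.array([0.0, np.sin(0.6), np.cos(0.6)]),  # frontal midline
        "alpha": np.array([0.0, -np.sin(1.2), np.cos(1.2)]),  # occipital pole
        "beta": np.array([0.0, 0.0, 1.0]),  # vertex
    }
    width = 0.8
    out = {}
    for band, c in centers.items():
        d = np.arccos(np.clip(coords @ c, -1.0, 1.0))
        out[band] = 1.0 + 0.5 * np.exp(-(d**2) / (2.0 * width**2))
    return out


def _effect_profiles(montage: ElectrodeMontage, spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-effect gain vectors over all montage electrodes.

    gain(e) = 1 + (m - 1) * exp(-d(e)^2 / (2 w^2)) for electrodes of the
    effect's region, 1 elsewhere. The focus d is measured from the region's
    most lateral-left electrode, not its centroid: pathological band-power
    changes in this model are focal and lateralized, displaced from the
    rhythm's physiological dominance site, so they alter the *shape* of the
    normalized topography rather than only its scale.
    """
    gains: dict[str, np.ndarray] = {}
    coords = montage.coords3d
    for eff in spec.effects:
        members = montage.region_members(eff.region)
        idx = np.array([montage.index_of(l) for l in members])
        center = coords[idx[np.argmin(coords[idx, 0])]]
        g = np.ones(len(montage))
        d = np.arccos(np.clip(coords[idx] @ center, -1.0, 1.0))
        p = np.exp(-(d**2) / (2.0 * spec.effect_width**2))
        g[idx] = 1.0 + (eff.multiplier - 1.0) * p
        gains[f"{eff.region}:{eff.band}:{eff.class_label}"] = g
    return gains


def generate_cohort(
    spec: CohortSpec,
    montage: ElectrodeMontage | None = None,
) -> tuple[list[EEGRecording], list[PhenotypeRecord], list[str]]:
    """Draw a seeded cohort of recordings, phenotypes, and class labels.

    Subjects are ordered patient block first, then controls, with ids
    ``sub-000`` onward. Identical spec and seed reproduce identical arrays.
    """
    montage = montage or default_montage()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.fs * spec.duration_s))
    t = np.arange(n_samples) / spec.fs
    gains = _effect_profiles(montage, spec)
    baselines = _baseline_profiles(montage)

    recordings: list[EEGRecording] = []
    phenotypes: list[PhenotypeRecord] = []
    labels: list[str] = []
    sid = 0
    for cls in spec.class_labels:
        for _ in range(spec.n_per_class):
            subject = f"sub-{sid:03d}"
            data = np.zeros((len(montage), n_samples))
            for band in BAND_ORDER:
                lo, hi = DEFAULT_BANDS[band]
                freqs = rng.uniform(lo, hi, len(montage))
                phases = rng.uniform(0, 2 * np.pi, len(montage))
                jitter = np.exp(rng.normal(0.0, spec.amplitude_jitter, len(montage)))
                amp = spec.base_amplitude[band] * baselines[band] * jitter
                for eff in spec.effects:
                    if eff.band == band and eff.class_label == cls:
                        amp = amp * gains[f"{eff.region}:{eff.band}:{eff.class_label}"]
                data += amp[:, None] * np.sin(
                    2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
                )
            data += rng.normal(0.0, spec.noise_sd, data.shape)
            recordings.append(EEGRecording(subject, spec.fs, data, montage.labels))
            gender = "male" if rng.random() < spec.gender_p else "female"
            age = float(max(0.0, rng.normal(spec.age_mean[cls], spec.age_sd)))
            phenotypes.append(PhenotypeRecord(subject, gender, age, cls))
            labels.append(cls)
            sid += 1
    return recordings, phenotypes, labels
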