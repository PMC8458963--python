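"""Synthetic study generator: EEG recordings, MRI tables, MMSE labels.

Emulates the statistical structure the downstream analysis assumes, for a
cohort of patients in the minimal-to-mild dementia range (MMSE 21-26,
concentrated around 23.3):

* EEG: each channel is an independent sum over the five classical bands of a
  band-limited Gaussian noise carrier multiplied by a strictly positive
  envelope ``1 + m(t)``.  For planted ``(band, modulation band)`` effects the
  modulation depth is ``baseline + slope * (MMSE - midpoint)``, so subband
  amplitude-modulation energy drifts monotonically with severity; all other
  modulation structure is the carrier's intrinsic envelope fluctuation.
* MRI: planted manifest features follow ``typical + slope * (MMSE - midpoint)
  + Gaussian noise``; all remaining features are typical values plus
  proportional noise (no MMSE relation).

Everything is a deterministic function of ``CohortSpec`` including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from ._filters import bandpass
from .mri import MriFeatureRow, MriManifest, load_manifest, write_flat_tsv, write_stats_tables
from .preprocess import DEFAULT_CHANNELS, EEGRecording

MMSE_MIDPOINT = 23.5

#: Relative carrier amplitude per band (coarse 1/f-like spectral tilt).
_BAND_WEIGHTS = {"delta": 1.0, "theta": 0.8, "alpha": 0.9, "beta": 0.5, "gamma": 0.3}
_BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0),
          "beta": (12.0, 30.0), "gamma": (30.0, 45.0)}
_MOD_BANDS = {"mdelta": (0.5, 4.0), "mtheta": (4.0, 8.0), "malpha": (8.0, 12.0),
              "mbeta": (12.0, 30.0), "mgamma": (30.0, 45.0)}

#: Envelope floor: rare Gaussian excursions of the modulator are clipped here
#: so the envelope stays strictly positive (no over-modulation sign flips).
_ENVELOPE_FLOOR = 0.05


@dataclass(frozen=True)
class EegEffect:
    """Planted amplitude-modulation drift: depth = baseline + slope * (MMSE - 23.5)."""
    band: str
    mod_band: str
    baseline: float
    slope: float


@dataclass(frozen=True)
class MriEffect:
    """Planted linear MRI relation: value = typical + slope * (MMSE - 23.5) + noise."""
    name: str
    typical: float
    slope: float
    noise_sd: float


#: Default planted effects.  EEG: beta-band alpha-rate modulation strengthens
#: and beta-band theta-rate modulation weakens as MMSE drops.  The beta
#: carrier is wide (18 Hz) relative to these modulation bands, so its
#: intrinsic envelope fluctuations do not saturate the planted fraction --
#: narrow carriers (e.g. theta with mdelta) are insensitive because the
#: carrier's own envelope already fills the modulation band.  MRI:
#: atrophy-like positive slopes (smaller structures at lower MMSE) on
#: temporal/frontal regions reported as severity-sensitive, with noise_sd
#: chosen so the population feature-MMSE correlation supports selection-set
#: ranking at n ~ 22.
DEFAULT_EEG_EFFECTS = (
    EegEffect("beta", "malpha", baseline=0.28, slope=-0.045),
    EegEffect("beta", "mtheta", baseline=0.28, slope=0.045),
)

DEFAULT_MRI_EFFECTS = (
    MriEffect("Left-Hippocampus", 3600.0, 60.0, 60.0),
    MriEffect("Right-Hippocampus", 3700.0, 55.0, 55.0),
    MriEffect("lh-entorhinal-thickness", 3.2, 0.045, 0.045),
    MriEffect("lh-superiortemporal-area", 3600.0, 45.0, 45.0),
    MriEffect("rh-frontalpole-area", 270.0, 6.0, 6.0),
    MriEffect("wm-rh-fusiform", 7200.0, 90.0, 90.0),
    MriEffect("CerebralWhiteMatterVol", 440000.0, 4500.0, 4500.0),
    MriEffect("rh-supramarginal-area", 3400.0, 40.0, 40.0),
)

#: MMSE weights over 21..26 approximating a symmetric-ish unimodal mass with
#: mean ~ 23.3 (the exact study histogram is not published; configurable).
DEFAULT_MMSE_WEIGHTS = (0.14, 0.19, 0.22, 0.20, 0.15, 0.10)


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 89
    mmse_range: tuple[int, int] = (21, 26)
    mmse_weights: tuple[float, ...] = DEFAULT_MMSE_WEIGHTS
    fs: float = 125.0
    duration: float = 180.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    eeg_effects: tuple[EegEffect, ...] = DEFAULT_EEG_EFFECTS
    mri_effects: tuple[MriEffect, ...] = DEFAULT_MRI_EFFECTS
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mmse_range
        scores = self.mmse_scores
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.mmse_weights) != len(scores):
            raise ValueError(
                f"{len(self.mmse_weights)} weights for {len(scores)} MMSE scores")
        if abs(sum(self.mmse_weights) - 1.0) > 1e-12:
            raise ValueError("mmse_weights must sum to 1")
        if any(w < 0 for w in self.mmse_weights):
            raise ValueError("mmse_weights must be non-negative")
        n_samp = self.duration * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        halfwidth = (hi - lo) / 2.0
        budget: dict[str, float] = {}
        for eff in self.eeg_effects:
            if eff.band not in _BANDS or eff.mod_band not in _MOD_BANDS:
                raise ValueError(f"unknown band in EEG effect {eff}")
            worst = eff.baseline + abs(eff.slope) * halfwidth
            if eff.baseline - abs(eff.slope) * halfwidth <= 0:
                raise ValueError(
                    f"EEG effect {eff} reaches a non-positive modulation depth")
            budget[eff.band] = budget.get(eff.band, 0.0) + worst
        for band, depth in budget.items():
            if depth >= 0.9:
                raise ValueError(
                    f"total modulation depth {depth:.2f} in band {band!r} risks "
                    f"a non-positive envelope")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def mmse_scores(self) -> tuple[int, ...]:
        lo, hi = self.mmse_range
        return tuple(range(lo, hi + 1))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class SubjectRecord:
    subject_id: str
    mmse: int
    eeg: EEGRecording
    mri: dict[str, float]


def validate_against_manifest(spec: CohortSpec, manifest: MriManifest) -> None:
    unknown = [e.name for e in spec.mri_effects if e.name not in manifest.names]
    if unknown:
        raise ValueError(f"planted MRI effect name(s) not in manifest: {unknown}")


def _unit_rms_band_noise(rng: np.random.Generator, n: int, lo: float, hi: float,
                         fs: float) -> np.ndarray:
    x = bandpass(rng.standard_normal(n), lo, hi, fs)
    return x / np.sqrt(np.mean(x ** 2))


def _synthesize_eeg(rng: np.random.Generator, spec: CohortSpec, mmse: int) -> np.ndarray:
    n = spec.n_samples
    effects_by_band: dict[str, list[EegEffect]] = {}
    for eff in spec.eeg_effects:
        effects_by_band.setdefault(eff.band, []).append(eff)
    data = np.zeros((len(spec.channels), n))
    for c in range(len(spec.channels)):
        sig = np.zeros(n)
        for band, (lo, hi) in _BANDS.items():
            carrier = _unit_rms_band_noise(rng, n, lo, hi, spec.fs)
            m = np.zeros(n)
            for eff in effects_by_band.get(band, ()):
                depth = eff.baseline + eff.slope * (mmse - MMSE_MIDPOINT)
                mlo, mhi = _MOD_BANDS[eff.mod_band]
                m += depth * _unit_rms_band_noise(rng, n, mlo, mhi, spec.fs)
            envelope = np.maximum(1.0 + m, _ENVELOPE_FLOOR)
            sig += _BAND_WEIGHTS[band] * carrier * envelope
        data[c] = spec.noise_sd * sig
    return data


def _typical_values(manifest: MriManifest) -> pd.Series:
    """Deterministic per-feature typical values (independent of cohort seed).

    Scales are category-appropriate: subcortical/white-matter volumes in the
    1e3-1e4 mm^3 range (with the whole-brain summary measures far larger),
    thickness ~ 2.5 mm, areas ~ 2e3 mm^2.
    """
    rng = np.random.default_rng(20260301)
    vals = {}
    for name in manifest.names:
        u = rng.uniform(0.6, 1.4)
        if name.endswith("-thickness"):
            vals[name] = 2.5 * u
        elif name.endswith("-area"):
            vals[name] = 2300.0 * u
        elif name in manifest.aseg_measure_names:
            vals[name] = 5.0e5 * u
        else:
            vals[name] = 4500.0 * u
    return pd.Series(vals)


def _round_mri(name: str, value: float) -> float:
    # match the precision of the stats-dialect writer so both encodings agree
    return round(value, 3) if name.endswith("-thickness") else round(value, 1)


def _synthesize_mri(rng: np.random.Generator, spec: CohortSpec, mmse: int,
                    manifest: MriManifest, typical: pd.Series) -> dict[str, float]:
    planted = {e.name: e for e in spec.mri_effects}
    out: dict[str, float] = {}
    for name in manifest.names:
        if name in planted:
            eff = planted[name]
            v = eff.typical + eff.slope * (mmse - MMSE_MIDPOINT) + rng.normal(0.0, eff.noise_sd)
        else:
            base = typical[name]
            v = base + rng.normal(0.0, 0.05 * base)
        out[name] = _round_mri(name, max(v, 0.0))
    return out


def generate_cohort(spec: CohortSpec,
                    manifest: MriManifest | None = None) -> list[SubjectRecord]:
    """Generate the cohort; deterministic given ``spec`` (including seed)."""
    manifest = manifest or load_manifest()
    validate_against_manifest(spec, manifest)
    typical = _typical_values(manifest)
    root = np.random.SeedSequence(spec.seed)
    mmse_rng = np.random.default_rng(root.spawn(1)[0])
    scores = np.array(spec.mmse_scores)
    mmse = mmse_rng.choice(scores, size=spec.n_subjects, p=np.array(spec.mmse_weights))
    subjects = []
    for i, subject_seed in enumerate(root.spawn(spec.n_subjects + 1)[1:]):
        rng = np.random.default_rng(subject_seed)
        sid = f"sub-{i + 1:03d}"
        eeg = EEGRecording(_synthesize_eeg(rng, spec, int(mmse[i])), spec.fs,
                           spec.channels)
        mri = _synthesize_mri(rng, spec, int(mmse[i]), manifest, typical)
        subjects.append(SubjectRecord(sid, int(mmse[i]), eeg, mri))
    return subjects


def planted_eeg_marker(eff: EegEffect) -> str:
    """Substring identifying per-subject features carrying a planted EEG effect."""
    return f"-am-{eff.band}-{eff.mod_band}-"


def planted_markers(spec: CohortSpec) -> list[str]:
    """One marker per planted effect; a feature name 'hits' a marker if the
    marker is the full name (MRI) or a substring of it (EEG, any channel or
    functional)."""
    return [planted_eeg_marker(e) for e in spec.eeg_effects] + \
           [e.name for e in spec.mri_effects]


def recovered_markers(feature_names, spec: CohortSpec) -> list[str]:
    """Planted markers represented by at least one name in ``feature_names``."""
    names = list(feature_names)
    hits = []
    for marker in planted_markers(spec):
        if marker.startswith("-"):
            if any(marker in n for n in names):
                hits.append(marker)
        elif any(n == marker or n.endswith("-" + marker) for n in names):
            hits.append(marker)
    return hits


# ----------------------------------------------------------------- persistence

def write_cohort(cohort: list[SubjectRecord], out_dir: str | Path,
                 mri_format: str = "tsv",
                 manifest: MriManifest | None = None) -> dict:
    """Write EDF files, MRI tables and the cohort TSV; returns a path manifest.

    ``mri_format`` is ``"tsv"`` (canonical flat tables) or ``"stats"``
    (FreeSurfer-dialect file sets).
    """
    if not cohort:
        raise ValueError("refusing to write an empty cohort")
    if mri_format not in ("tsv", "stats"):
        raise ValueError(f"unknown mri_format {mri_format!r}")
    manifest = manifest or load_manifest()
    out = Path(out_dir)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    (out / "mri").mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        eeg_path = out / "eeg" / f"{rec.subject_id}.edf"
        edf.write_edf(eeg_path, rec.eeg.data, rec.eeg.fs, rec.eeg.labels)
        row = MriFeatureRow(rec.subject_id, rec.mri)
        if mri_format == "tsv":
            mri_path: Path | dict = out / "mri" / f"{rec.subject_id}.tsv"
            write_flat_tsv(row, mri_path, manifest)
        else:
            mri_path = {k: str(p) for k, p in write_stats_tables(
                row, out / "mri" / rec.subject_id, manifest).items()}
        entries.append({"subject_id": rec.subject_id, "mmse": rec.mmse,
                        "eeg": str(eeg_path), "mri": mri_path})
    table = pd.DataFrame({"subject_id": [r.subject_id for r in cohort],
                          "mmse": [r.mmse for r in cohort]})
    cohort_tsv = out / "cohort.tsv"
    table.to_csv(cohort_tsv, sep="\t", index=False)
    return {"cohort_tsv": str(cohort_tsv), "mri_format": mri_format,
            "subjects": entries}
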