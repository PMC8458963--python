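"""Frequency-band, electrode-pair and modulation-patch configuration.

The default :class:`BandScheme` encodes the conventional clinical EEG bands
(delta 0.5-4, theta 4-8, alpha 8-12 with low/high halves, beta 12-30, the
broad delta-beta and theta-beta composites, and low gamma 30-45 Hz), five
coherence bands over five fronto-parietal electrode pairs, and the 14
physically realizable (carrier band, modulation band) combinations for
amplitude-modulation analysis.  A modulation band can only be resolved when
it is narrower than the carrier band's own bandwidth, which is why e.g.
delta-mtheta is excluded while gamma supports all five modulation bands.

Modulation band edges mirror the carrier band edges (mdelta 0.5-4 ...
mgamma 30-45 Hz).

:class:`PatchScheme` holds rectangular regions of the (modulation frequency x
carrier frequency) plane plus ratio pairs.  The shipped default rectangles are
an approximation of regions reported to separate dementia severity stages;
they are configuration, not ground truth, and any analysis can supply its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _check_interval(name: str, lo: float, hi: float) -> None:
    if not (hi > lo):
        raise ValueError(f"interval {name!r} = ({lo}, {hi}) has non-positive width")


DEFAULT_POWER_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "low-alpha": (8.0, 10.0),
    "high-alpha": (10.0, 12.0),
    "beta": (12.0, 30.0),
    "delta-beta": (0.5, 30.0),
    "theta-beta": (4.0, 30.0),
    "gamma": (30.0, 45.0),
}

DEFAULT_COHERENCE_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

DEFAULT_COHERENCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fz", "Pz"), ("F3", "F4"), ("P3", "P4"), ("F3", "P3"), ("F4", "P4"),
)

DEFAULT_MOD_BANDS: dict[str, tuple[float, float]] = {
    "mdelta": (0.5, 4.0),
    "mtheta": (4.0, 8.0),
    "malpha": (8.0, 12.0),
    "mbeta": (12.0, 30.0),
    "mgamma": (30.0, 45.0),
}

#: The 14 realizable carrier-band x modulation-band combinations.
DEFAULT_AM_PAIRS: tuple[tuple[str, str], ...] = (
    ("delta", "mdelta"),
    ("theta", "mdelta"), ("theta", "mtheta"),
    ("alpha", "mdelta"), ("alpha", "mtheta"),
    ("beta", "mdelta"), ("beta", "mtheta"), ("beta", "malpha"), ("beta", "mbeta"),
    ("gamma", "mdelta"), ("gamma", "mtheta"), ("gamma", "malpha"),
    ("gamma", "mbeta"), ("gamma", "mgamma"),
)


@dataclass(frozen=True)
class BandScheme:
    power_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POWER_BANDS))
    coherence_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COHERENCE_BANDS))
    coherence_pairs: tuple[tuple[str, str], ...] = DEFAULT_COHERENCE_PAIRS
    am_pairs: tuple[tuple[str, str], ...] = DEFAULT_AM_PAIRS
    mod_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOD_BANDS))

    def __post_init__(self) -> None:
        for bands in (self.power_bands, self.coherence_bands, self.mod_bands):
            for name, (lo, hi) in bands.items():
                _check_interval(name, lo, hi)
        for carrier, mband in self.am_pairs:
            if carrier not in self.power_bands:
                raise ValueError(f"AM carrier band {carrier!r} is not a defined band")
            if mband not in self.mod_bands:
                raise ValueError(f"modulation band {mband!r} is not defined")

    @property
    def am_carriers(self) -> tuple[str, ...]:
        """Carrier bands appearing in ``am_pairs``, in first-appearance order."""
        seen: dict[str, None] = {}
        for carrier, _ in self.am_pairs:
            seen.setdefault(carrier)
        return tuple(seen)


#: Rectangles as (mod_lo, mod_hi, carrier_lo, carrier_hi) in Hz.
DEFAULT_PATCHES: dict[str, tuple[float, float, float, float]] = {
    "R1": (0.5, 4.0, 8.0, 12.0),
    "R2": (4.0, 12.0, 12.0, 30.0),
    "R3": (0.5, 4.0, 30.0, 45.0),
}

DEFAULT_PATCH_RATIOS: tuple[tuple[str, str], ...] = (
    ("R1", "R3"), ("R2", "R1"), ("R2", "R3"),
)


@dataclass(frozen=True)
class PatchScheme:
    patches: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PATCHES))
    ratios: tuple[tuple[str, str], ...] = DEFAULT_PATCH_RATIOS

    def __post_init__(self) -> None:
        for name, (mlo, mhi, clo, chi) in self.patches.items():
            _check_interval(f"{name} modulation extent", mlo, mhi)
            _check_interval(f"{name} carrier extent", clo, chi)
        for num, den in self.ratios:
            for p in (num, den):
                if p not in self.patches:
                    raise ValueError(f"ratio references unknown patch {p!r}")

    def ratio_names(self) -> tuple[str, ...]:
        return tuple(f"{a}o{b}" for a, b in self.ratios)
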