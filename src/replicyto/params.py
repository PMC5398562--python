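"""Parameter bundles for the simulator, imaging model and segmentation.

All bundles are frozen dataclasses with eager validation, and round-trip
through plain dicts (and hence YAML) via ``to_dict`` / ``from_dict``.

Units
-----
Fluorescence quantities are in arbitrary units (AU); image quantities in
pixels and camera counts; wash times in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import yaml

from .errors import ParameterError

#: Cell-cycle phases, in canonical order.
PHASES = ("G1", "S", "G2M")


def lognormal_logmean(mean: float, logsd: float) -> float:
    """Return the log-scale mean mu such that LogNormal(mu, logsd) has the
    given arithmetic mean."""
    if mean <= 0:
        raise ParameterError(f"lognormal mean must be positive, got {mean}")
    return math.log(mean) - 0.5 * logsd**2


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth population model for a labelling experiment.

    A population of ``n_cells`` nuclei with labelled fraction ``f_labelled``
    (F; 0.44 for a 30-min BrdU pulse in HeLa), cell-cycle structure
    ``phase_fractions`` = (G1, S, G2M), DNA content centred on ``dna_g1_mean``
    in G1 (2x in G2/M, in between in S) with CV broadening ``dna_cv``, and
    lognormal specific-signal and background distributions on the label
    channel.  Optional protein channels (e.g. the two FUCCI reporters) have
    per-phase mean intensities.

    With ``couple_label_to_s_phase`` (default) label and phase are made
    biologically consistent: labelled cells are S-phase and unlabelled cells
    are drawn from the renormalised (G1, G2M) mass — during a pulse only
    S-phase cells incorporate the nucleoside.  Switch it off to draw phase
    and label independently.

    Geometry fields place nuclei for rendering: ``layout="grid"`` uses a
    jittered grid guaranteeing non-overlap; ``layout="random"`` places
    uniformly (overlaps possible).
    """

    n_cells: int = 10_000
    f_labelled: float = 0.44
    phase_fractions: tuple[float, float, float] = (0.40, 0.44, 0.16)
    dna_g1_mean: float = 100.0
    dna_cv: float = 0.05
    signal_logmean_labelled: float = lognormal_logmean(500.0, 0.5)
    signal_logsd_labelled: float = 0.5
    background_logmean: float = lognormal_logmean(100.0, 0.35)
    background_logsd: float = 0.35
    protein_channel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    protein_cv: float = 0.25
    couple_label_to_s_phase: bool = True
    radius_mean: float = 12.0
    radius_sd: float = 1.0
    layout: str = "grid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0.0 < self.f_labelled < 1.0:
            raise ParameterError(
                f"f_labelled must lie in (0, 1), got {self.f_labelled}"
            )
        pf = tuple(float(p) for p in self.phase_fractions)
        object.__setattr__(self, "phase_fractions", pf)
        if len(pf) != 3 or any(p < 0 or p > 1 for p in pf):
            raise ParameterError(f"phase_fractions must be 3 fractions, got {pf}")
        if abs(sum(pf) - 1.0) > 1e-9:
            raise ParameterError(
                f"phase_fractions must sum to 1 (got sum {sum(pf)!r})"
            )
        if self.dna_cv < 0:
            raise ParameterError(f"dna_cv must be >= 0, got {self.dna_cv}")
        if self.dna_g1_mean <= 0:
            raise ParameterError("dna_g1_mean must be positive")
        for name in ("signal_logsd_labelled", "background_logsd", "protein_cv",
                     "radius_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.radius_mean < 3.0:
            raise ParameterError("radius_mean must be >= 3 pixels")
        if self.layout not in ("grid", "random"):
            raise ParameterError(f"layout must be 'grid' or 'random', got {self.layout!r}")
        prot = {
            str(ch): {str(ph): float(v) for ph, v in means.items()}
            for ch, means in self.protein_channel_means.items()
        }
        for ch, means in prot.items():
            missing = set(PHASES) - set(means)
            if missing:
                raise ParameterError(
                    f"protein channel {ch!r} missing per-phase means for {sorted(missing)}"
                )
        object.__setattr__(self, "protein_channel_means", prot)

    # -- derived quantities -------------------------------------------------

    @property
    def specific_mean(self) -> float:
        """Arithmetic mean of the labelled-cell specific signal (AU)."""
        return math.exp(self.signal_logmean_labelled + 0.5 * self.signal_logsd_labelled**2)

    @property
    def background_mean(self) -> float:
        """Arithmetic mean of the per-nucleus background signal (AU)."""
        return math.exp(self.background_logmean + 0.5 * self.background_logsd**2)

    @property
    def protein_channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.protein_channel_means))


@dataclass(frozen=True)
class ProtocolEffect:
    """Multiplicative stand-in for a wet-lab protocol variant.

    ``specific_scale``/``background_scale`` rescale the label-channel signal
    components; ``protein_retention`` rescales each protein channel (e.g. the
    fraction of FUCCI reporter fluorescence surviving acid treatment); an
    exponential wash-decay term ``exp(-wash_decay_rate * wash_time)``
    attenuates the specific signal with time spent in washing buffer.
    """

    label: str = "identity"
    specific_scale: float = 1.0
    background_scale: float = 1.0
    protein_retention: Mapping[str, float] = field(default_factory=dict)
    wash_decay_rate: float = 0.0
    wash_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("specific_scale", "background_scale", "wash_decay_rate",
                     "wash_time"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        ret = {str(k): float(v) for k, v in self.protein_retention.items()}
        for ch, v in ret.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    f"protein_retention[{ch!r}] must lie in [0, 1], got {v}"
                )
        object.__setattr__(self, "protein_retention", ret)

    @property
    def effective_specific_scale(self) -> float:
        """Net multiplier applied to the specific signal (scale x wash decay)."""
        return self.specific_scale * math.exp(-self.wash_decay_rate * self.wash_time)

    @classmethod
    def identity(cls) -> "ProtocolEffect":
        return cls()

    def compose(self, other: "ProtocolEffect") -> "ProtocolEffect":
        """Effect equivalent to applying ``self`` then ``other``.

        Scales multiply element-wise; wash terms combine through the product
        of their exponential decays.
        """
        channels = set(self.protein_retention) | set(other.protein_retention)
        ret = {
            ch: self.protein_retention.get(ch, 1.0) * other.protein_retention.get(ch, 1.0)
            for ch in channels
        }
        rt = self.wash_decay_rate * self.wash_time + other.wash_decay_rate * other.wash_time
        return ProtocolEffect(
            label=f"{self.label}+{other.label}",
            specific_scale=self.specific_scale * other.specific_scale,
            background_scale=self.background_scale * other.background_scale,
            protein_retention=ret,
            wash_decay_rate=rt,
            wash_time=1.0 if rt > 0 else 0.0,
        )


@dataclass(frozen=True)
class ImageModel:
    """Image-formation model: AU -> 16-bit camera counts.

    Each nucleus is a filled disc whose pixel intensities integrate to
    ``pixel_scale`` x its signal; the image is blurred by a Gaussian PSF of
    ``psf_sigma`` pixels, offset by ``background_offset`` counts, and
    corrupted by Poisson shot noise and Gaussian read noise when enabled.
    """

    width: int = 512
    height: int = 512
    pixel_scale: float = 50.0
    psf_sigma: float = 1.0
    background_offset: float = 100.0
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ParameterError("image dimensions must be positive")
        if self.psf_sigma < 0 or self.read_noise_sigma < 0:
            raise ParameterError("psf_sigma and read_noise_sigma must be >= 0")
        if self.background_offset < 0:
            raise ParameterError("background_offset must be >= 0")
        if self.bit_depth != 16:
            raise ParameterError("only 16-bit output is supported")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class SegmentationParams:
    """Nuclear segmentation settings (smooth -> threshold -> label -> split)."""

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_area: int = 20
    split_touching: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ParameterError("smoothing_sigma must be >= 0")
        if self.min_area < 1:
            raise ParameterError("min_area must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(
                f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}"
            )


# -- dict / YAML round-tripping ----------------------------------------------

_BUNDLES = {
    "PopulationParams": PopulationParams,
    "ProtocolEffect": ProtocolEffect,
    "ImageModel": ImageModel,
    "SegmentationParams": SegmentationParams,
}


def to_dict(obj: Any) -> dict:
    """Serialise a parameter bundle to a plain dict (YAML/JSON friendly)."""
    out: dict[str, Any] = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, Mapping):
            v = {k: dict(val) if isinstance(val, Mapping) else val for k, val in v.items()}
        out[f.name] = v
    return out


def from_dict(cls, data: Mapping[str, Any]):
    """Build a parameter bundle of type ``cls`` from a plain dict."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"unknown {cls.__name__} fields: {sorted(unknown)}"
        )
    kwargs = dict(data)
    if "phase_fractions" in kwargs and kwargs["phase_fractions"] is not None:
        kwargs["phase_fractions"] = tuple(kwargs["phase_fractions"])
    return cls(**kwargs)


def dump_yaml(obj: Any, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({type(obj).__name__: to_dict(obj)}, fh, sort_keys=True)


def load_yaml(path):
    """Load a single parameter bundle written by :func:`dump_yaml`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or len(data) != 1:
        raise ParameterError(f"{path}: expected a single top-level bundle mapping")
    (name, payload), = data.items()
    if name not in _BUNDLES:
        raise ParameterError(f"{path}: unknown bundle type {name!r}")
    return from_dict(_BUNDLES[name], payload)


__all__ = [
    "PHASES",
    "PopulationParams",
    "ProtocolEffect",
    "ImageModel",
    "SegmentationParams",
    "lognormal_logmean",
    "to_dict",
    "from_dict",
    "dump_yaml",
    "load_yaml",
    "replace",
]
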