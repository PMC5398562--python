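"""Ground-truth population simulation.

Generates per-nucleus records (phase, labelled flag, DNA content, label-channel
signal components, geometry, optional protein channels), applies multiplicative
protocol effects, and produces flow-cytometry-style event tables.

The label channel is two-component: labelled (replicating) nuclei carry a
lognormal *specific* signal on top of a lognormal *background* shared by all
nuclei; unlabelled nuclei show background only.  The separation between the
two populations is what the R/non-R statistic measures downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ParameterError, PresetLookupError
from .params import PHASES, PopulationParams, ProtocolEffect, lognormal_logmean

#: Schema of the ground-truth population table (protein channels appended as
#: ``protein_<name>`` columns).  Version bumps when columns change.
POPULATION_SCHEMA_VERSION = 1
POPULATION_COLUMNS = (
    "nucleus_id",
    "phase",
    "labelled",
    "dna_content",
    "specific_signal",
    "background_signal",
    "center_x",
    "center_y",
    "radius",
)


@dataclass(frozen=True)
class NucleusRecord:
    """One row of a population table (ground truth for a single nucleus)."""

    nucleus_id: int
    phase: str
    labelled: bool
    dna_content: float
    specific_signal: float
    background_signal: float
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.dna_content <= 0:
            raise ParameterError("dna_content must be positive")
        if self.specific_signal < 0 or self.background_signal < 0:
            raise ParameterError("signals must be non-negative")
        if not self.labelled and self.specific_signal != 0:
            raise ParameterError("unlabelled nuclei must have specific_signal == 0")


def protein_columns(pop: pd.DataFrame) -> list[str]:
    """Names of the protein channels present in a population table."""
    return [c.removeprefix("protein_") for c in pop.columns if c.startswith("protein_")]


def _grid_layout(n: int, max_radius: float, rng: np.random.Generator):
    """Jittered square grid guaranteeing non-overlapping discs.

    Spacing leaves >= 8 px clearance between worst-case discs after jitter so
    that segmentation of blurred images still separates neighbours.
    """
    jitter = 0.25 * max_radius
    spacing = math.ceil(2 * max_radius + 2 * jitter + 8)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    margin = math.ceil(max_radius + jitter) + 2
    idx = np.arange(n)
    cx = margin + (idx % ncols) * spacing + rng.uniform(-jitter, jitter, n)
    cy = margin + (idx // ncols) * spacing + rng.uniform(-jitter, jitter, n)
    width = 2 * margin + (ncols - 1) * spacing
    height = 2 * margin + (nrows - 1) * spacing
    return cx, cy, width, height


def sample_population(params: PopulationParams) -> pd.DataFrame:
    """Draw a ground-truth population table.

    Returns a DataFrame with :data:`POPULATION_COLUMNS` plus one
    ``protein_<channel>`` column per configured protein channel.  All
    randomness flows from ``params.seed``; the same params give an identical
    table.  The table's ``attrs`` carry the field extent used for layout.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    g1, s, g2m = params.phase_fractions

    labelled = rng.random(n) < params.f_labelled

    if params.couple_label_to_s_phase:
        # Labelled <-> S consistency: a pulse only marks S-phase cells.
        phase = np.empty(n, dtype=object)
        phase[labelled] = "S"
        n_un = int((~labelled).sum())
        if g1 + g2m > 0:
            p = np.array([g1, g2m]) / (g1 + g2m)
            phase[~labelled] = rng.choice(["G1", "G2M"], size=n_un, p=p)
        else:
            phase[~labelled] = "S"
    else:
        phase = rng.choice(list(PHASES), size=n, p=[g1, s, g2m])

    ploidy = np.ones(n)
    ploidy[phase == "G2M"] = 2.0
    is_s = phase == "S"
    ploidy[is_s] = rng.uniform(1.0, 2.0, int(is_s.sum()))

    dna = params.dna_g1_mean * ploidy * (1.0 + rng.normal(0.0, params.dna_cv, n))
    dna = np.maximum(dna, 1e-9)

    specific = np.zeros(n)
    specific[labelled] = rng.lognormal(
        params.signal_logmean_labelled,
        params.signal_logsd_labelled,
        int(labelled.sum()),
    )
    background = rng.lognormal(params.background_logmean, params.background_logsd, n)

    # Nuclear area scales with DNA content (G2/M nuclei are larger), keeping
    # the per-pixel DNA-stain brightness roughly constant across phases.
    base_radius = np.clip(
        rng.normal(params.radius_mean, params.radius_sd, n),
        3.0,
        params.radius_mean + 4.0 * params.radius_sd,
    )
    radius = base_radius * np.sqrt(ploidy)
    max_r = float(radius.max())
    if params.layout == "grid":
        cx, cy, width, height = _grid_layout(n, max_r, rng)
    else:
        side = math.ceil(math.sqrt(n)) * math.ceil(4 * max_r) + 2 * math.ceil(max_r + 2)
        width = height = side
        margin = max_r + 2
        cx = rng.uniform(margin, width - margin, n)
        cy = rng.uniform(margin, height - margin, n)

    pop = pd.DataFrame(
        {
            "nucleus_id": np.arange(n, dtype=np.int64),
            "phase": phase,
            "labelled": labelled,
            "dna_content": dna,
            "specific_signal": specific,
            "background_signal": background,
            "center_x": cx,
            "center_y": cy,
            "radius": radius,
        }
    )

    for ch in params.protein_channels:
        means = params.protein_channel_means[ch]
        mu = np.array([means[p] for p in phase], dtype=float)
        if params.protein_cv > 0:
            sigma = math.sqrt(math.log1p(params.protein_cv**2))
            factor = rng.lognormal(-0.5 * sigma**2, sigma, n)  # unit-mean noise
        else:
            factor = 1.0
        pop[f"protein_{ch}"] = mu * factor

    pop.attrs["field_width"] = int(width)
    pop.attrs["field_height"] = int(height)
    pop.attrs["schema_version"] = POPULATION_SCHEMA_VERSION
    return pop


def apply_protocol(pop: pd.DataFrame, effect: ProtocolEffect) -> pd.DataFrame:
    """Apply a multiplicative protocol effect to a population table.

    Specific signal is scaled by ``specific_scale * exp(-rate * wash_time)``,
    background by ``background_scale``, each protein channel by its retention.
    Ground-truth labels, phases, DNA and geometry are untouched.  Returns a
    new table; the input is not modified.
    """
    out = pop.copy()
    out.attrs = dict(pop.attrs)
    out["specific_signal"] = out["specific_signal"] * effect.effective_specific_scale
    out["background_signal"] = out["background_signal"] * effect.background_scale
    for ch, retention in effect.protein_retention.items():
        col = f"protein_{ch}"
        if col in out.columns:
            out[col] = out[col] * retention
    return out


def sample_flow_events(
    pop: pd.DataFrame, acq_cv: float, seed: int = 0
) -> pd.DataFrame:
    """Flow-cytometry-style event table: one event per nucleus.

    Measured DNA is ``dna_content`` and measured label is
    ``specific + background``, each perturbed by multiplicative Gaussian
    acquisition noise of CV ``acq_cv`` (0 reproduces ground truth exactly).
    Protein channels are carried through with the same noise model.
    """
    if acq_cv < 0:
        raise ParameterError(f"acq_cv must be >= 0, got {acq_cv}")
    rng = np.random.default_rng(seed)
    n = len(pop)
    prot = protein_columns(pop)
    cols = {"nucleus_id": pop["nucleus_id"].to_numpy(copy=True) if n else
            np.array([], dtype=np.int64)}

    def noisy(values: np.ndarray) -> np.ndarray:
        if acq_cv == 0 or n == 0:
            return values.astype(float, copy=True)
        return values * (1.0 + rng.normal(0.0, acq_cv, n))

    dna = pop["dna_content"].to_numpy() if n else np.array([])
    label = (
        (pop["specific_signal"] + pop["background_signal"]).to_numpy()
        if n
        else np.array([])
    )
    cols["dna"] = noisy(dna)
    cols["label"] = noisy(label)
    for ch in prot:
        vals = pop[f"protein_{ch}"].to_numpy() if n else np.array([])
        cols[f"protein_{ch}"] = noisy(vals)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Analytic expected R/non-R and preset calibration
# ---------------------------------------------------------------------------

def _lognorm_partial_upper(mu: float, sigma: float, t: float) -> float:
    """E[X ; X > t] for X ~ LogNormal(mu, sigma)."""
    if t <= 0:
        return math.exp(mu + 0.5 * sigma**2)
    z = (math.log(t) - mu) / sigma
    return math.exp(mu + 0.5 * sigma**2) * norm.sf(z - sigma)


def _lognorm_partial_lower(mu: float, sigma: float, t: float) -> float:
    """E[X ; X <= t] for X ~ LogNormal(mu, sigma)."""
    if t <= 0:
        return 0.0
    z = (math.log(t) - mu) / sigma
    return math.exp(mu + 0.5 * sigma**2) * norm.cdf(z - sigma)


def _fenton_wilkinson(means: Iterable[float], variances: Iterable[float]):
    """Moment-matched lognormal (mu, sigma) for a sum of independent
    positive variables with the given means and variances."""
    m = sum(means)
    v = sum(variances)
    sigma2 = math.log1p(v / m**2)
    return math.log(m) - 0.5 * sigma2, math.sqrt(sigma2)


def expected_r_non_r(
    params: PopulationParams,
    effect: ProtocolEffect | None = None,
    f: float | None = None,
) -> float:
    """Analytic expectation of the trimmed R/non-R statistic.

    Models the measured label signal as a two-component mixture: unlabelled
    nuclei ~ LogNormal(background); labelled nuclei ~ specific + background,
    approximated by a moment-matched (Fenton-Wilkinson) lognormal.  The
    statistic's trimmed means — mean of the top (f - 0.1) and bottom
    (0.9 - f) population quantiles — are then closed-form partial
    expectations of the mixture.
    """
    effect = effect or ProtocolEffect.identity()
    f = params.f_labelled if f is None else f
    if not 0.1 < f < 0.9:
        raise ParameterError(f"f must lie in (0.1, 0.9), got {f}")

    s_scale = effect.effective_specific_scale
    b_scale = effect.background_scale
    mu_b = params.background_logmean + math.log(b_scale) if b_scale > 0 else -math.inf
    sg_b = params.background_logsd
    m_b = params.background_mean * b_scale
    v_b = m_b**2 * math.expm1(sg_b**2)

    m_s = params.specific_mean * s_scale
    v_s = m_s**2 * math.expm1(params.signal_logsd_labelled**2)
    mu_l, sg_l = _fenton_wilkinson([m_s, m_b], [v_s, v_b])

    w = params.f_labelled  # mixture weight of the labelled component

    def sf(t: float) -> float:  # mixture survival
        zl = (math.log(t) - mu_l) / sg_l
        zb = (math.log(t) - mu_b) / sg_b
        return w * norm.sf(zl) + (1 - w) * norm.sf(zb)

    p_r, p_nr = f - 0.1, 0.9 - f
    lo, hi = 1e-6, 10 * math.exp(mu_l + 5 * sg_l)
    t_r = brentq(lambda t: sf(t) - p_r, lo, hi, xtol=1e-12, rtol=1e-12)
    t_nr = brentq(lambda t: sf(t) - (1 - p_nr), lo, hi, xtol=1e-12, rtol=1e-12)

    r_mean = (
        w * _lognorm_partial_upper(mu_l, sg_l, t_r)
        + (1 - w) * _lognorm_partial_upper(mu_b, sg_b, t_r)
    ) / p_r
    nonr_mean = (
        w * _lognorm_partial_lower(mu_l, sg_l, t_nr)
        + (1 - w) * _lognorm_partial_lower(mu_b, sg_b, t_nr)
    ) / p_nr
    return r_mean / nonr_mean


def params_for_ratio(
    target_ratio: float,
    f: float = 0.44,
    background_mean: float = 100.0,
    signal_logsd: float = 0.5,
    background_logsd: float = 0.35,
    **overrides,
) -> PopulationParams:
    """Population parameters whose expected trimmed R/non-R hits a target.

    Solves for the specific-signal mean (all other shape parameters fixed)
    so that :func:`expected_r_non_r` equals ``target_ratio``.
    """
    if target_ratio <= 1.0:
        raise ParameterError("target_ratio must exceed 1")

    def make(spec_mean: float) -> PopulationParams:
        return PopulationParams(
            f_labelled=f,
            signal_logmean_labelled=lognormal_logmean(spec_mean, signal_logsd),
            signal_logsd_labelled=signal_logsd,
            background_logmean=lognormal_logmean(background_mean, background_logsd),
            background_logsd=background_logsd,
            **overrides,
        )

    def gap(spec_mean: float) -> float:
        return expected_r_non_r(make(spec_mean)) - target_ratio

    spec_mean = brentq(gap, 1e-3 * background_mean, 1e4 * background_mean, rtol=1e-10)
    return make(spec_mean)


def params_for_separation(
    separation: float,
    f: float = 0.44,
    background_mean: float = 100.0,
    signal_logsd: float = 0.5,
    background_logsd: float = 0.35,
    **overrides,
) -> PopulationParams:
    """Population parameters with a given labelled/background mean ratio.

    ``separation`` is the ratio of the labelled cells' mean measured signal
    (specific + background) to the background mean, i.e. the generator's
    component-level separation (as opposed to the trimmed-statistic target of
    :func:`params_for_ratio`).
    """
    if separation <= 1.0:
        raise ParameterError("separation must exceed 1")
    spec_mean = (separation - 1.0) * background_mean
    return PopulationParams(
        f_labelled=f,
        signal_logmean_labelled=lognormal_logmean(spec_mean, signal_logsd),
        signal_logsd_labelled=signal_logsd,
        background_logmean=lognormal_logmean(background_mean, background_logsd),
        background_logsd=background_logsd,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    """A documented experimental condition: parameters + protocol effect."""

    name: str
    description: str
    target_ratio: float | None
    params: PopulationParams
    effect: ProtocolEffect


#: FUCCI reporter per-phase mean intensities (AU).  Orange marks G1, green
#: marks S/G2/M; small off-phase leak keeps the channels realistic.
_FUCCI_MEANS = {
    "green": {"G1": 50.0, "S": 800.0, "G2M": 1000.0},
    "orange": {"G1": 800.0, "S": 50.0, "G2M": 30.0},
}


def _build_presets() -> dict[str, Preset]:
    identity = ProtocolEffect.identity()

    def condition(name: str, desc: str, ratio: float, f: float = 0.44,
                  **overrides) -> Preset:
        return Preset(name, desc, ratio, params_for_ratio(ratio, f=f, **overrides),
                      identity)

    presets = [
        condition(
            "brdu_30min",
            "30-min BrdU pulse, optimised low-HCl + exonuclease III detection "
            "(ethanol fixation); F = 0.44, high signal/noise.",
            6.0,
        ),
        condition(
            "brdu_5min",
            "5-min BrdU pulse, optimised detection, ethanol fixation; "
            "separable (ratio ~ 4).",
            4.0,
        ),
        condition(
            "edu_5min",
            "5-min EdU pulse, click detection, ethanol fixation; weak "
            "separation (ratio ~ 2).",
            2.0,
        ),
        condition(
            "b44_fa_hcl20",
            "B44 antibody, formaldehyde fixation, 20 mM HCl.",
            4.4,
        ),
        condition(
            "bu20a_fa_hcl20",
            "Bu20a antibody, formaldehyde fixation, 20 mM HCl.",
            3.8,
        ),
        condition(
            "b44_etoh_hcl5",
            "B44 antibody, ethanol fixation, 5 mM HCl.",
            4.6,
        ),
        condition(
            "b44_etoh_hcl10",
            "B44 antibody, ethanol fixation, 10 mM HCl.",
            5.0,
        ),
        condition(
            "bu20a_etoh_hcl10",
            "Bu20a antibody, ethanol fixation, 10 mM HCl.",
            6.0,
        ),
    ]

    fucci_base = params_for_ratio(
        6.0, protein_channel_means=_FUCCI_MEANS
    )
    presets += [
        Preset(
            "fucci_control",
            "FUCCI-expressing cells, no acid treatment (control for "
            "protein-retention normalisation).",
            6.0,
            fucci_base,
            identity,
        ),
        Preset(
            "fucci_hcl20",
            "FUCCI-expressing cells, 20-min low-HCl treatment: green reporter "
            "retains ~60% and orange ~45% of control fluorescence.",
            6.0,
            fucci_base,
            ProtocolEffect(
                label="fucci_hcl20",
                protein_retention={"green": 0.60, "orange": 0.45},
            ),
        ),
        Preset(
            "fucci_hcl10",
            "FUCCI-expressing cells, 10-min low-HCl treatment: green retention "
            "improves, orange does not.",
            6.0,
            fucci_base,
            ProtocolEffect(
                label="fucci_hcl10",
                protein_retention={"green": 0.75, "orange": 0.45},
            ),
        ),
        Preset(
            "wash_25min",
            "Optimised detection with 25 min in washing buffer before "
            "stabilisation; specific signal decays exponentially with wash "
            "time.",
            None,
            params_for_ratio(6.0),
            ProtocolEffect(label="wash_25min", wash_decay_rate=0.02, wash_time=25.0),
        ),
    ]
    return {p.name: p for p in presets}


_PRESET_CACHE: dict[str, Preset] | None = None


def _registry() -> dict[str, Preset]:
    global _PRESET_CACHE
    if _PRESET_CACHE is None:
        _PRESET_CACHE = _build_presets()
    return _PRESET_CACHE


def preset_names() -> tuple[str, ...]:
    return tuple(_registry())


def get_preset(name: str) -> Preset:
    """Full preset record (including description and target ratio)."""
    reg = _registry()
    if name not in reg:
        raise PresetLookupError(
            f"unknown preset {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name]


def preset(name: str) -> tuple[PopulationParams, ProtocolEffect]:
    """Look up a named experimental condition.

    Returns the population parameters and protocol effect for the condition;
    raises :class:`PresetLookupError` listing the registry on unknown names.
    """
    p = get_preset(name)
    return p.params, p.effect


def with_seed(params: PopulationParams, seed: int) -> PopulationParams:
    """Convenience: same parameters, different seed."""
    return replace(params, seed=int(seed))


__all__ = [
    "POPULATION_COLUMNS",
    "POPULATION_SCHEMA_VERSION",
    "NucleusRecord",
    "Preset",
    "apply_protocol",
    "expected_r_non_r",
    "get_preset",
    "params_for_ratio",
    "params_for_separation",
    "preset",
    "preset_names",
    "protein_columns",
    "sample_flow_events",
    "sample_population",
    "with_seed",
]
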