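"""Cytometric statistics for replication-labelling experiments.

The central quantity is the **R/non-R ratio**, a signal-to-noise statistic
for a population in which a fraction F of nuclei carry specific label signal
(replicating, "R") and the rest show background only ("non-R"):

    R mean     = mean signal of the (F - 0.1) x N most-labelled nuclei
    non-R mean = mean signal of the (0.9 - F) x N least-labelled nuclei
    R/non-R    = R mean / non-R mean

The 0.1-wide guard bands on both sides exclude nuclei of ambiguous status,
so the statistic is well defined only for F in (0.1, 0.9).  Experience with
pulse-labelling data puts the threshold for reliable discrimination of
replicating cells at a ratio of about 3 (ratios >= 3-4 separate cleanly;
around 2 they do not).

The module also provides labelled-fraction estimation (two-component
Gaussian mixture or Otsu on log signal), replicating-cell classification,
protein-retention normalisation, replicate aggregation, histograms, and
bivariate (label x DNA content) cell-cycle profiling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from .errors import ParameterError, ProfileError

log = logging.getLogger(__name__)

#: R/non-R ratio above which two populations are considered clearly
#: separable.  Field experience puts the limit at "3 to 4"; the single
#: documented constant is the lower end and is configurable per call.
SEPARABLE_RATIO = 3.0


def trim_counts(n: int, f: float) -> tuple[int, int]:
    """Sizes of the R and non-R trim sets for N nuclei at labelled fraction f.

    ``n_r = max(1, floor((f - 0.1) N))`` and ``n_nonr = max(1, floor((0.9 - f) N))``.
    The floor guarantees the two index sets are disjoint for every f in
    (0.1, 0.9) since the trimmed fractions sum to 0.8.  A small epsilon guards
    against binary-float artefacts (e.g. (0.9 - 0.44) * 100 = 45.999...986,
    which must count as 46).
    """
    if not 0.1 < f < 0.9:
        raise ParameterError(
            f"f must lie strictly inside (0.1, 0.9); got {f} "
            "(outside this range the trim sets are empty or overlap)"
        )
    n_r = max(1, int(math.floor((f - 0.1) * n + 1e-9)))
    n_nonr = max(1, int(math.floor((0.9 - f) * n + 1e-9)))
    return n_r, n_nonr


@dataclass(frozen=True)
class RNonRResult:
    """R/non-R statistic with its trimmed-set bookkeeping."""

    ratio: float
    r_mean: float
    nonr_mean: float
    f_used: float
    n_r: int
    n_nonr: int
    infinite: bool = False  # non-R mean was exactly zero

    def as_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "r_mean": self.r_mean,
            "nonr_mean": self.nonr_mean,
            "f_used": self.f_used,
            "n_r": self.n_r,
            "n_nonr": self.n_nonr,
            "infinite": self.infinite,
        }


def _check_signals(signals, min_n: int) -> np.ndarray:
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError(f"signals must be a 1-D vector, got shape {x.shape}")
    if len(x) < min_n:
        raise ParameterError(f"need at least {min_n} signals, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("signals must be finite")
    if np.any(x < 0):
        raise ParameterError("signals must be non-negative")
    return x


def r_non_r_ratio(signals, f: float) -> RNonRResult:
    """The R/non-R signal-to-noise statistic.

    Sorts the per-nucleus signals in descending order (stable: ties keep
    their original order, so ties at a trim boundary are resolved by
    inclusion order) and divides the mean of the top ``n_r`` by the mean of
    the bottom ``n_nonr`` values; see :func:`trim_counts` for the set sizes.
    A zero non-R mean yields ``ratio = inf`` with the ``infinite`` flag set.
    """
    x = _check_signals(signals, 5)
    n_r, n_nonr = trim_counts(len(x), f)
    order = np.argsort(-x, kind="stable")
    r_mean = float(x[order[:n_r]].mean())
    nonr_mean = float(x[order[-n_nonr:]].mean())
    if nonr_mean == 0.0:
        return RNonRResult(math.inf, r_mean, nonr_mean, f, n_r, n_nonr, infinite=True)
    return RNonRResult(r_mean / nonr_mean, r_mean, nonr_mean, f, n_r, n_nonr)


def signal_intensity(signals, f: float) -> float:
    """Mean signal of the (f - 0.1) most-labelled nuclei (the "R mean")."""
    return r_non_r_ratio(signals, f).r_mean


@dataclass(frozen=True)
class LabelledFractionEstimate:
    """Estimated labelled fraction with its decision boundary.

    ``low_separation`` warns that the two fitted components overlap too much
    (or the input looks unimodal) for the estimate to be trusted.
    """

    fraction: float
    threshold: float  # on the original signal scale
    low_separation: bool
    method: str
    separation: float  # |mu1 - mu2| / pooled sd on the log scale

    def __float__(self) -> float:
        return self.fraction


#: Log-scale standardised distance between components below which the
#: labelled-fraction estimate is flagged unreliable.
LOW_SEPARATION_D = 2.0


def estimate_labelled_fraction(
    signals, method: str = "gmm2", random_state: int = 0
) -> LabelledFractionEstimate:
    """Estimate the fraction of labelled (replicating) nuclei.

    Works on ``log1p(signal)``: either a two-component Gaussian mixture
    (``gmm2``, deterministic quantile-based initialisation) or an Otsu
    threshold.  Returns the fraction of nuclei above the decision boundary.
    Degenerate, weakly bimodal input is not an error: the estimate is
    returned with ``low_separation`` set.
    """
    x = _check_signals(signals, 50)
    z = np.log1p(x)

    if method == "otsu":
        if z.min() == z.max():
            return LabelledFractionEstimate(0.0, float(np.expm1(z.max())), True,
                                            "otsu", 0.0)
        t = threshold_otsu(z)
        frac = float(np.mean(z > t))
        lo, hi = z[z <= t], z[z > t]
        sd = math.sqrt((lo.var() + hi.var()) / 2) if len(lo) and len(hi) else 0.0
        d = abs(hi.mean() - lo.mean()) / sd if sd > 0 else 0.0
        return LabelledFractionEstimate(
            frac, float(np.expm1(t)), d < LOW_SEPARATION_D, "otsu", d
        )
    if method != "gmm2":
        raise ParameterError(f"method must be 'gmm2' or 'otsu', got {method!r}")

    # Deterministic k-means initialisation (fixed seed); quantile-based
    # starts can split the dominant component into a bad local optimum.
    gm = GaussianMixture(
        n_components=2,
        init_params="kmeans",
        n_init=1,
        random_state=random_state,
        reg_covar=1e-6,
        max_iter=500,
    ).fit(z.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    upper = int(np.argmax(means))
    lower = 1 - upper

    d = abs(means[upper] - means[lower]) / math.sqrt(
        (sds[upper] ** 2 + sds[lower] ** 2) / 2
    )
    low_sep = d < LOW_SEPARATION_D or min(gm.weights_) < 1e-3

    def upper_posterior(t: float) -> float:
        return gm.predict_proba([[t]])[0, upper]

    lo_m, hi_m = sorted(means)
    try:
        if (upper_posterior(lo_m) - 0.5) * (upper_posterior(hi_m) - 0.5) < 0:
            t_z = brentq(lambda t: upper_posterior(t) - 0.5, lo_m, hi_m, xtol=1e-10)
        else:  # posteriors never cross between the means: fall back to midpoint
            t_z = 0.5 * (lo_m + hi_m)
            low_sep = True
    except ValueError:
        t_z = 0.5 * (lo_m + hi_m)
        low_sep = True

    frac = float(np.mean(z > t_z))
    return LabelledFractionEstimate(frac, float(np.expm1(t_z)), low_sep, "gmm2", d)


@dataclass(frozen=True)
class ClassificationReport:
    """Outcome of replicating-cell classification."""

    threshold: float
    f_estimate: float
    ratio: float
    separable: bool
    n_positive: int
    n_total: int
    low_separation: bool

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "f_estimate": self.f_estimate,
            "ratio": self.ratio,
            "separable": self.separable,
            "n_positive": self.n_positive,
            "n_total": self.n_total,
            "low_separation": self.low_separation,
        }


def classify_replicating(
    signals,
    threshold: float | None = None,
    f: float | None = None,
    separable_min: float = SEPARABLE_RATIO,
    method: str = "gmm2",
) -> tuple[np.ndarray, ClassificationReport]:
    """Classify nuclei as replicating (label-positive) or not.

    The decision threshold comes from :func:`estimate_labelled_fraction`
    unless supplied.  The report carries the achieved R/non-R ratio —
    computed at the estimated (or given) labelled fraction, clipped to the
    statistic's domain — and a ``separable`` flag: ratio >= ``separable_min``
    (default 3, the documented limit for clear separation).
    """
    x = _check_signals(signals, 50)
    low_sep = False
    if threshold is None:
        est = estimate_labelled_fraction(x, method=method)
        threshold = est.threshold
        f_est = est.fraction
        low_sep = est.low_separation
    else:
        f_est = float(np.mean(x > threshold))
    positive = x > threshold

    f_ratio = f if f is not None else min(max(f_est, 0.12), 0.88)
    ratio = r_non_r_ratio(x, f_ratio).ratio
    separable = bool(np.isfinite(ratio) and ratio >= separable_min) or math.isinf(ratio)
    report = ClassificationReport(
        threshold=float(threshold),
        f_estimate=f_est,
        ratio=ratio,
        separable=separable,
        n_positive=int(positive.sum()),
        n_total=len(x),
        low_separation=low_sep,
    )
    return positive, report


def normalize_protein_signal(treated, control) -> float:
    """Average protein signal of treated cells as a percentage of control.

    ``100 x mean(treated) / mean(control)``; used to express e.g. FUCCI
    reporter retention after acid treatment.
    """
    t = np.asarray(treated, dtype=np.float64)
    c = np.asarray(control, dtype=np.float64)
    if t.size == 0 or c.size == 0:
        raise ParameterError("treated and control must be non-empty")
    c_mean = c.mean()
    if c_mean == 0:
        raise ParameterError("control mean is zero; percentage undefined")
    return 100.0 * float(t.mean()) / float(c_mean)


@dataclass(frozen=True)
class CellCycleProfile:
    """G1/S/G2M fractions plus the gates that produced them."""

    frac_g1: float
    frac_s: float
    frac_g2m: float
    dna_g1_mode: float
    dna_g2_mode: float
    label_threshold: float
    warning: str | None = None

    def as_dict(self) -> dict:
        return {
            "frac_g1": self.frac_g1,
            "frac_s": self.frac_s,
            "frac_g2m": self.frac_g2m,
            "dna_g1_mode": self.dna_g1_mode,
            "dna_g2_mode": self.dna_g2_mode,
            "label_threshold": self.label_threshold,
            "warning": self.warning,
        }


def _dna_modes(dna: np.ndarray, n_bins: int, smooth_sigma: float):
    """Two highest peaks of a smoothed DNA histogram (ascending positions)."""
    lo, hi = float(dna.min()), float(dna.max())
    if hi <= lo:
        raise ProfileError(
            "DNA content of label-negative events is constant; cannot locate "
            "two modes",
            bin_centers=np.array([lo]),
            counts=np.array([len(dna)]),
        )
    counts, edges = np.histogram(dna, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = gaussian_filter1d(counts.astype(float), smooth_sigma)
    padded = np.concatenate([[0.0], smoothed, [0.0]])  # peaks at the ends count
    peaks, props = find_peaks(padded, height=0)
    peaks -= 1
    if len(peaks) < 2:
        raise ProfileError(
            f"found {len(peaks)} DNA mode(s) among label-negative events; "
            "two are required for G1/G2M gating",
            bin_centers=centers,
            counts=counts,
        )
    top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
    m1, m2 = sorted(centers[p] for p in top2)
    return m1, m2


def cell_cycle_profile(
    dna,
    label_signal,
    threshold: float | None = None,
    f: float | None = None,
    n_bins: int = 96,
    smooth_sigma: float = 1.5,
) -> CellCycleProfile:
    """Bivariate cell-cycle profile from label signal and DNA content.

    S phase = label-positive events (threshold from
    :func:`classify_replicating` unless given).  Among label-negative events
    the two highest peaks of a smoothed DNA histogram give the G1 and G2/M
    modes; events are gated at the midpoint between them.  Fractions are over
    all events and sum to 1 exactly.
    """
    d = np.asarray(dna, dtype=np.float64)
    x = _check_signals(label_signal, 200)
    if d.shape != x.shape:
        raise ParameterError("dna and label_signal must have equal length")
    n = len(x)

    positive, report = classify_replicating(x, threshold=threshold, f=f)
    neg = ~positive
    n_s = int(positive.sum())

    if neg.sum() == 0:
        return CellCycleProfile(
            0.0, 1.0, 0.0, math.nan, math.nan, report.threshold,
            warning="all events are label-positive; no G1/G2M gating possible",
        )

    m1, m2 = _dna_modes(d[neg], n_bins, smooth_sigma)
    cut = 0.5 * (m1 + m2)
    n_g1 = int((neg & (d < cut)).sum())
    n_g2m = n - n_s - n_g1
    warning = report.low_separation and (
        "label threshold has low separation; S fraction may be unreliable"
    ) or None
    log.info(
        "cell_cycle_profile: n=%d S=%d G1=%d G2M=%d (cut=%.3g)",
        n, n_s, n_g1, n_g2m, cut,
    )
    return CellCycleProfile(
        frac_g1=n_g1 / n,
        frac_s=n_s / n,
        frac_g2m=n_g2m / n,
        dna_g1_mode=m1,
        dna_g2_mode=m2,
        label_threshold=report.threshold,
        warning=warning,
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate-aggregated R/non-R for one experimental condition."""

    condition: str
    ratios: tuple[float, ...]
    mean: float
    sd: float  # sample SD (n - 1 denominator); NaN for a single replicate
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "ratios": list(self.ratios),
            "mean": self.mean,
            "sd": self.sd,
            "n_replicates": self.n_replicates,
        }


def compare_conditions(
    conditions: Mapping[str, Sequence],
    f: float | Mapping[str, float],
) -> list[ConditionSummary]:
    """Per-condition R/non-R across replicates, as mean +/- sample SD.

    ``conditions`` maps a condition label to its replicate signal vectors
    (order preserved in the output); ``f`` is a single labelled fraction or a
    per-condition mapping.
    """
    out = []
    for name, replicates in conditions.items():
        if len(replicates) == 0:
            raise ParameterError(f"condition {name!r} has no replicates")
        f_c = f[name] if isinstance(f, Mapping) else f
        ratios = tuple(r_non_r_ratio(rep, f_c).ratio for rep in replicates)
        arr = np.asarray(ratios)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
        out.append(
            ConditionSummary(name, ratios, float(arr.mean()), sd, len(arr))
        )
    return out


def signal_histogram(signals, n_bins: int = 50) -> pd.DataFrame:
    """Equal-width histogram of per-nucleus signals over [0, max].

    Returns a table with ``bin_left``, ``bin_right`` and ``count``; counts
    sum to the number of nuclei.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    x = _check_signals(signals, 1)
    hi = float(x.max())
    if hi == 0.0:
        hi = 1.0
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


__all__ = [
    "SEPARABLE_RATIO",
    "CellCycleProfile",
    "ClassificationReport",
    "ConditionSummary",
    "LabelledFractionEstimate",
    "RNonRResult",
    "cell_cycle_profile",
    "classify_replicating",
    "compare_conditions",
    "estimate_labelled_fraction",
    "normalize_protein_signal",
    "r_non_r_ratio",
    "signal_histogram",
    "signal_intensity",
    "trim_counts",
]
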