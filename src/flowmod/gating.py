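"""Automated gating: viability -> scatter -> singlet -> PE positivity.

Reduces a well's events to the one number the assay consumes: the fraction
of viable, singlet, neuroblast-gated events whose PE (gnACHR stain)
intensity exceeds a quadrant threshold positioned on the plate's unstained
control.  The original assay drew these gates by hand on the analyzer; here
each gate is a deterministic data-driven rule so identical input always
yields an identical result:

1. **Viability** — dead cells are bright on the APC channel (fixable
   viability stain); keep events below a threshold found at the KDE valley
   between the two main modes of log10(APC-A) (or Otsu's threshold, or a
   fixed percentile).
2. **Scatter** — keep events inside a robust covariance ellipse around the
   dominant (FSC-A, SSC-A) density mode, covering a configurable mass of
   that component.
3. **Singlet** — drop events whose FSC-A/FSC-H ratio falls outside a band
   around the singlet ratio (doublets have roughly twice the area per unit
   pulse height).
4. **Quadrant threshold** — the PE intensity above which only a small
   target fraction (0.5-1%, default 0.75%) of gated unstained-control
   events lies; test wells are scored as the fraction of gated events
   strictly above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from skimage.filters import threshold_otsu

from .simulate import EventTable

logger = logging.getLogger(__name__)

VIABILITY_METHODS = ("valley", "otsu", "fixed_percentile")


class GatingError(ValueError):
    """Raised when a gate cannot be applied to the given events."""


@dataclass(frozen=True)
class GatingParams:
    """Tunable gate settings.

    ``quadrant_target_fraction`` defaults to 0.75%, the midpoint of the
    0.5-1% positivity band the quadrant gate is constructed to achieve on
    unstained cells; values outside [0.005, 0.01] break that contract.
    """

    viability_method: str = "valley"
    fixed_viability_percentile: float = 92.0
    scatter_ellipse_coverage: float = 0.99
    doublet_ratio_band: float = 0.15
    quadrant_target_fraction: float = 0.0075
    min_events_of_interest: int = 5_000

    def __post_init__(self) -> None:
        if self.viability_method not in VIABILITY_METHODS:
            raise GatingError(
                f"viability_method must be one of {VIABILITY_METHODS}"
            )
        if not 0 < self.scatter_ellipse_coverage < 1:
            raise GatingError("scatter_ellipse_coverage must be in (0, 1)")
        if self.doublet_ratio_band <= 0:
            raise GatingError("doublet_ratio_band must be positive")


@dataclass(frozen=True)
class GateChainResult:
    """Event counts surviving each gate plus the PE-positive fraction."""

    n_acquired: int
    n_viable: int
    n_scatter: int
    n_singlet: int
    pe_threshold: float
    positive_fraction: float
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (self.n_acquired >= self.n_viable >= self.n_scatter >= self.n_singlet):
            raise GatingError("gate chain counts must be non-increasing")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise GatingError("positive_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Viability gate
# ---------------------------------------------------------------------------

_MIN_EVENTS = 100
_HIST_BINS = 256
_KDE_SIGMA_BINS = 3.0


def _log10(x: np.ndarray) -> np.ndarray:
    return np.log10(x + 1.0)


def _valley_threshold(logx: np.ndarray) -> float | None:
    """Minimum of a smoothed density between the two largest modes of
    ``logx``; None when fewer than two modes exist."""
    hist, edges = np.histogram(logx, bins=_HIST_BINS)
    dens = ndimage.gaussian_filter1d(hist.astype(float), _KDE_SIGMA_BINS)
    peaks, _ = signal.find_peaks(dens)
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(min(top2)), int(max(top2))
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[valley])


def viability_gate(table: EventTable, params: GatingParams) -> EventTable:
    """Keep events with low viability-stain (APC-A) signal.

    Dead cells take up the fixable viability stain and sit decades above
    live cells on APC; the threshold is found on log10(APC-A) by the
    configured method.  Falls back from valley to Otsu when the
    distribution has no two modes, and retains everything when there is no
    mortality signal at all (constant APC).
    """
    if table.n_events < _MIN_EVENTS:
        raise GatingError(
            f"viability gate needs >= {_MIN_EVENTS} events, got {table.n_events}"
        )
    apc = table.events["APC-A"].to_numpy(dtype=float)
    logx = _log10(apc)
    if np.ptp(logx) == 0.0:  # no mortality signal: nothing to exclude
        logger.warning("constant APC-A signal; viability gate retains all events")
        return table

    method = params.viability_method
    thr = None
    if method == "valley":
        thr = _valley_threshold(logx)
        if thr is None:
            logger.warning("no APC valley found; falling back to Otsu threshold")
            method = "otsu"
    if method == "otsu":
        thr = float(threshold_otsu(logx, nbins=_HIST_BINS))
    elif method == "fixed_percentile":
        thr = float(np.percentile(logx, params.fixed_viability_percentile))
    keep = logx <= thr
    return _subset(table, keep)


def _subset(table: EventTable, keep: np.ndarray) -> EventTable:
    return EventTable(
        events=table.events.loc[keep].reset_index(drop=True),
        labels=None if table.labels is None else table.labels[keep],
        meta=dict(table.meta),
    )


# ---------------------------------------------------------------------------
# Scatter + singlet gate
# ---------------------------------------------------------------------------

_TRIM_ITERS = 15
# singlet FSC-A/FSC-H ratios live near 1 when area and height are comparably
# scaled; used only to anchor the doublet band on singlet-consistent events
_SINGLET_RATIO_RANGE = (0.5, 1.5)


def _robust_mode_ellipse(
    xy: np.ndarray, coverage: float
) -> tuple[np.ndarray, np.ndarray]:
    """Location and scatter of the dominant density mode of 2-D points.

    Starts from the interquartile box (dominated by the main mode), then
    alternates trimming at the ``coverage`` Mahalanobis radius with a
    normal-truncation consistency correction, converging onto the central
    component of a mixture.
    """
    r2 = stats.chi2.ppf(coverage, df=2)
    consistency = coverage / stats.chi2.cdf(r2, df=4)
    lo = np.percentile(xy, 25, axis=0)
    hi = np.percentile(xy, 75, axis=0)
    keep = np.all((xy >= lo) & (xy <= hi), axis=1)
    if keep.sum() < 10:
        keep = np.ones(len(xy), dtype=bool)
    for _ in range(_TRIM_ITERS):
        mu = xy[keep].mean(axis=0)
        cov = np.cov(xy[keep], rowvar=False) * consistency
        if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
            raise GatingError("singular scatter matrix: scatter gate refused")
        d2 = _mahalanobis_sq(xy, mu, cov)
        new_keep = d2 <= r2
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    mu = xy[keep].mean(axis=0)
    cov = np.cov(xy[keep], rowvar=False) * consistency
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise GatingError("singular scatter matrix: scatter gate refused")
    return mu, cov


def _mahalanobis_sq(xy: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = xy - mu
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def _scatter_gate(table: EventTable, params: GatingParams) -> EventTable:
    xy = table.events[["FSC-A", "SSC-A"]].to_numpy(dtype=float)
    mu, cov = _robust_mode_ellipse(xy, params.scatter_ellipse_coverage)
    r2 = stats.chi2.ppf(params.scatter_ellipse_coverage, df=2)
    inside = _mahalanobis_sq(xy, mu, cov) <= r2
    return _subset(table, inside)


def _doublet_gate(gated: EventTable, params: GatingParams) -> EventTable:
    if not gated.has_fsc_h:
        logger.warning("FSC-H channel absent; doublet exclusion skipped")
        return gated
    ratio = (
        gated.events["FSC-A"].to_numpy(dtype=float)
        / np.clip(gated.events["FSC-H"].to_numpy(dtype=float), 1e-12, None)
    )
    singletish = ratio[(ratio >= _SINGLET_RATIO_RANGE[0]) & (ratio <= _SINGLET_RATIO_RANGE[1])]
    center = float(np.median(singletish)) if len(singletish) else 1.0
    keep = np.abs(ratio - center) <= params.doublet_ratio_band
    return _subset(gated, keep)


def scatter_singlet_gate(table: EventTable, params: GatingParams) -> EventTable:
    """Keep events in the neuroblast scatter mode, then drop doublets.

    The (FSC-A, SSC-A) ellipse covers ``scatter_ellipse_coverage`` of the
    dominant density component.  Doublet exclusion keeps events whose
    FSC-A/FSC-H ratio lies within ``doublet_ratio_band`` of the singlet
    ratio (the median ratio among singlet-consistent events); wells lacking
    FSC-H skip this stage with a warning.
    """
    return _doublet_gate(_scatter_gate(table, params), params)


# ---------------------------------------------------------------------------
# Quadrant threshold and full chain
# ---------------------------------------------------------------------------


def quadrant_threshold(
    unstained_gated: EventTable, target_fraction: float
) -> float:
    """PE threshold leaving at most ``target_fraction`` of gated
    unstained-control events strictly positive.

    Returns the smallest observed intensity such that the strictly-greater
    fraction is <= ``target_fraction`` (ties count negative).
    """
    if not 0.0 < target_fraction < 0.05:
        raise GatingError(
            f"target_fraction must be in (0, 0.05), got {target_fraction!r}"
        )
    pe = np.sort(unstained_gated.events["PE-A"].to_numpy(dtype=float))
    n = len(pe)
    k = int(np.floor(target_fraction * n))  # events allowed strictly above
    return float(pe[n - k - 1])


def gate_events(table: EventTable, params: GatingParams) -> EventTable:
    """Viability, scatter and singlet gates in sequence."""
    return scatter_singlet_gate(viability_gate(table, params), params)


def percent_positive(
    table: EventTable, pe_threshold: float, params: GatingParams
) -> GateChainResult:
    """Run the full gate chain and score the PE-positive fraction.

    ``pe_threshold`` must come from the same plate's unstained control
    (see :func:`quadrant_threshold`).  A quality flag is raised when fewer
    than ``min_events_of_interest`` events survive gating.
    """
    viable = viability_gate(table, params)
    ellipse = _scatter_gate(viable, params)
    scatter = _doublet_gate(ellipse, params)
    n_scatter = ellipse.n_events

    pe = scatter.events["PE-A"].to_numpy(dtype=float)
    pos = float(np.mean(pe > pe_threshold)) if len(pe) else 0.0
    flags = []
    if scatter.n_events < params.min_events_of_interest:
        flags.append("low_event_count")
        logger.warning(
            "only %d events of interest (min %d) in well %s",
            scatter.n_events,
            params.min_events_of_interest,
            table.meta.get("well", "?"),
        )
    return GateChainResult(
        n_acquired=table.n_events,
        n_viable=viable.n_events,
        n_scatter=n_scatter,
        n_singlet=scatter.n_events,
        pe_threshold=float(pe_threshold),
        positive_fraction=pos,
        flags=tuple(flags),
    )
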