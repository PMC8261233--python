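"""Synthetic event-level cytometry for the gnACHR immunomodulation assay.

Generates per-well event tables (FSC-A, FSC-H, SSC-A, APC-A, PE-A) with the
population structure the assay relies on: a dominant mode of viable IMR-32
neuroblasts, plus debris, cell doublets and dead (viability-stain-bright)
events.  Surface ganglionic-AChR staining on viable cells follows a
lognormal receptor-number model; serum antibody removes surface receptor via
a Hill-type dose-response (receptor crosslinking and internalization), so the
PE signal of a test well falls between the maximally stained and unstained
plate controls.

All randomness is driven by ``numpy.random.Generator`` objects seeded through
``SeedSequence`` keys derived from a single master seed, so each well and each
serum sample is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

#: Canonical channel order for every event table this package produces.
CHANNELS = ["FSC-A", "FSC-H", "SSC-A", "APC-A", "PE-A"]

#: Well roles.  "unstained" = secondary-antibody-only background control
#: (MIN), "max_stained" = fetal-calf-serum well with full staining (MAX),
#: "test" = patient serum at some dilution.
ROLES = ("unstained", "max_stained", "test")

#: Event-truth labels attached by the simulator (the gating oracle).
LABELS = ("viable", "debris", "doublet", "dead")

#: Reciprocal screening dilution: sera are screened at 1:20.
SCREENING_DILUTION = 20

#: Default two-fold titration ladder, starting at the screening dilution.
DEFAULT_DILUTIONS = (20, 40, 80, 160, 320, 640, 1280, 2560)

#: RIA values of antibody-positive sera span this range (pM).
RIA_RANGE_PM = (730.0, 3464.0)

#: Serum categories as enrolled (before any unblinding).
CATEGORIES = (
    "seropositive_AAG",
    "blinded",
    "probable_AAG",
    "seronegative_AAG",
    "healthy",
    "autonomic_not_AAG",
    "other_neuro",
    "SLE",
)

#: Default cohort composition: 190 sera in total, 9 of them blinded
#: (4 antibody-positive, 5 negative by the reference assay).
DEFAULT_GROUP_SIZES: Mapping[str, int] = {
    "seropositive_AAG": 4,
    "blinded": 9,
    "probable_AAG": 1,
    "seronegative_AAG": 5,
    "healthy": 39,
    "autonomic_not_AAG": 43,
    "other_neuro": 47,
    "SLE": 42,
}
DEFAULT_BLINDED_POSITIVE = 4

#: Test wells per plate (plus one unstained and one max-stained control).
PLATE_CAPACITY = 40

# Seed-stream tags (arbitrary distinct constants mixed into SeedSequence
# keys so well noise, serum effects and cohort metadata never collide).
_TAG_WELL = 101
_TAG_SERUM = 202
_TAG_COHORT = 303


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or requests."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EventTable:
    """A well's worth of cytometry events.

    Parameters
    ----------
    events
        ``n_events x channels`` DataFrame of non-negative linear intensities.
        ``FSC-H`` may be absent (some acquisitions do not record pulse
        height); every other channel in :data:`CHANNELS` is required.
    labels
        Optional per-event ground-truth population labels (simulator output
        only; real data has none).
    meta
        Free-form provenance: sample_id, role, dilution, plate, well.
    """

    events: pd.DataFrame
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = [c for c in CHANNELS if c != "FSC-H"]
        missing = [c for c in required if c not in self.events.columns]
        if missing:
            raise SimulationError(f"event table missing channels: {missing}")
        # gate outputs may be empty subsets; zero-event *inputs* are rejected
        # where they enter (FCS reader, viability gate)
        vals = self.events.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SimulationError("event intensities must be finite")
        if (vals < 0).any():
            raise SimulationError("event intensities must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.events):
            raise SimulationError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def has_fsc_h(self) -> bool:
        return "FSC-H" in self.events.columns


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one well of assay cytometry.

    The four population fractions must sum to one.  Receptor and
    autofluorescence intensities are lognormal (natural-log mean/sd of
    arbitrary linear fluorescence units).  ``modulation_max`` is the
    saturating fraction of surface receptor an antibody-positive serum can
    internalize; ``modulation_k`` is the effective antibody concentration
    (pM, on the screening-dilution scale) giving half-maximal
    internalization; ``hill`` shapes the dose-response.

    Antibody-negative sera still perturb staining through a per-sample
    nuisance internalization drawn from a truncated normal
    (``negative_serum_effect_mean`` +/- ``negative_serum_effect_sd`` x z,
    z standard normal truncated at :data:`NUISANCE_TRUNC_SD` SDs, effective
    SD ~0.88 x the scale).  The two constants are calibrated once so the
    full pipeline reproduces the healthy-control score distribution
    (mean ~3.45%, SD ~4.85%).
    """

    n_events_per_well: int = 30_000
    viable_fraction: float = 0.70
    debris_fraction: float = 0.15
    doublet_fraction: float = 0.07
    dead_fraction: float = 0.08
    receptor_mean_log: float = 5.40
    receptor_sd_log: float = 0.80
    autofluor_mean_log: float = 3.91  # ln(50)
    autofluor_sd_log: float = 0.60
    pe_per_receptor: float = 1.0
    modulation_max: float = 0.95
    modulation_k: float = 1000.0  # pM at the 1:20 screening scale
    hill: float = 1.0
    negative_serum_effect_mean: float = 0.049
    negative_serum_effect_sd: float = 0.0794
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "viable_fraction",
            "debris_fraction",
            "doublet_fraction",
            "dead_fraction",
            "modulation_max",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be a proportion in [0, 1], got {v!r}")
        total = (
            self.viable_fraction
            + self.debris_fraction
            + self.doublet_fraction
            + self.dead_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"population fractions must sum to 1 (got {total!r})"
            )
        if self.n_events_per_well <= 0:
            raise SimulationError("n_events_per_well must be positive")
        for name in (
            "receptor_mean_log",
            "receptor_sd_log",
            "autofluor_mean_log",
            "autofluor_sd_log",
            "pe_per_receptor",
            "modulation_k",
            "hill",
            "negative_serum_effect_mean",
            "negative_serum_effect_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise SimulationError(f"{name} must be finite, got {v!r}")
        if self.modulation_k <= 0:
            raise SimulationError("modulation_k must be positive")
        if self.negative_serum_effect_sd < 0:
            raise SimulationError("negative_serum_effect_sd must be >= 0")


@dataclass(frozen=True)
class SerumSample:
    """One serum, with its simulation truth and reference-assay metadata.

    ``true_conc_pM`` is the effective gnACHR-antibody concentration at the
    1:20 screening dilution (0 for antibody-negative sera).  ``ria_pM`` is
    the radioimmunoassay result when one exists; ``blinded_truth`` carries
    the reference status of blinded samples, revealed only at unblinding.
    """

    sample_id: str
    category: str
    true_conc_pM: float = 0.0
    ria_pM: float | None = None
    blinded_truth: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES and self.category != "FCS_control":
            raise SimulationError(f"unknown serum category {self.category!r}")
        if self.true_conc_pM < 0:
            raise SimulationError("true_conc_pM must be >= 0")
        if self.ria_pM is not None and self.ria_pM <= 0:
            raise SimulationError("ria_pM, when present, must be > 0")
        if self.blinded_truth not in (None, "positive", "negative"):
            raise SimulationError(f"invalid blinded_truth {self.blinded_truth!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and titration ladder."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    blinded_positive: int = DEFAULT_BLINDED_POSITIVE
    dilutions: Sequence[int] = DEFAULT_DILUTIONS
    plate_capacity: int = PLATE_CAPACITY
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.group_sizes.items():
            if cat not in CATEGORIES:
                raise SimulationError(f"unknown category {cat!r} in group_sizes")
            if n < 0:
                raise SimulationError(f"negative group size for {cat!r}")
        if self.blinded_positive > self.group_sizes.get("blinded", 0):
            raise SimulationError(
                "blinded_positive exceeds the number of blinded samples"
            )
        dil = list(self.dilutions)
        if not dil or dil[0] != SCREENING_DILUTION:
            raise SimulationError(
                f"dilution ladder must start at {SCREENING_DILUTION}"
            )
        if any(b <= a for a, b in zip(dil, dil[1:])):
            raise SimulationError("dilutions must be strictly increasing")
        if self.plate_capacity < 1:
            raise SimulationError("plate_capacity must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


# ---------------------------------------------------------------------------
# Dose-response and per-sample nuisance
# ---------------------------------------------------------------------------


def effective_concentration_pM(
    conc_pM: float, dilution: float, screening: float = SCREENING_DILUTION
) -> float:
    """Effective antibody concentration at a given reciprocal dilution.

    Concentrations are referenced to the 1:20 screening dilution, so a
    sample at 730 pM diluted a further 32-fold (to 1:640) acts at
    ``730 / 32 = 22.8`` pM.
    """
    if dilution <= 0:
        raise SimulationError(f"dilution must be positive, got {dilution!r}")
    return conc_pM * (screening / dilution)


def hill_internalized_fraction(conc_pM: float, params: SimParams) -> float:
    """Expected internalized receptor fraction at effective concentration c:
    ``M_max * c^h / (c^h + K^h)``."""
    if conc_pM <= 0:
        return 0.0
    ch = conc_pM**params.hill
    kh = params.modulation_k**params.hill
    return params.modulation_max * ch / (ch + kh)


#: Truncation bound (in SDs) of the per-serum nuisance effect.  Serum
#: matrix effects are bounded in practice — the assay's clean separation
#: (every antibody-negative serum below the decision limit) relies on the
#: nuisance distribution having no unbounded tail.
NUISANCE_TRUNC_SD = 2.0


def serum_nuisance_effect(sample: SerumSample, params: SimParams) -> float:
    """Per-sample nuisance internalization, reproducible from the sample id.

    Every serum carries a small matrix effect on staining, drawn from a
    normal distribution truncated at ``NUISANCE_TRUNC_SD`` standard
    deviations.  It is drawn once per (master seed, sample id) so all wells
    of a titration series share it.
    """
    key = zlib.crc32(sample.sample_id.encode("utf-8"))
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, _TAG_SERUM, key])
    )
    a = NUISANCE_TRUNC_SD
    lo, hi = special.ndtr(-a), special.ndtr(a)
    z = special.ndtri(lo + rng.random() * (hi - lo))
    return float(
        params.negative_serum_effect_mean + params.negative_serum_effect_sd * z
    )


# ---------------------------------------------------------------------------
# Per-well event generation
# ---------------------------------------------------------------------------

# Scatter geometry of the simulated populations (arbitrary linear units).
# The viable-neuroblast mode sits well away from the debris cloud; doublets
# have area roughly twice a singlet-consistent pulse height.
_VIABLE_FSC = (50_000.0, 6_000.0)
_VIABLE_SSC = (30_000.0, 5_000.0)
_VIABLE_CORR = 0.3
_RATIO_SD = 0.04  # FSC-A / FSC-H spread for single cells
_DEBRIS_FSC = (10_000.0, 5_000.0)
_DEBRIS_SSC_LOG = (9.9, 0.8)  # lognormal, median ~20k
_DOUBLET_RATIO = (1.9, 0.08)
_DOUBLET_SSC = (55_000.0, 9_000.0)
_DEAD_FSC = (45_000.0, 7_000.0)
_DEAD_SSC = (33_000.0, 6_000.0)
_LIVE_APC_LOG = (3.0, 0.5)  # median ~20
_DEAD_APC_LOG = (7.6, 0.5)  # ~100x the live level


def _bivariate(rng, n, mx, sx, my, sy, corr):
    z1 = rng.standard_normal(n)
    z2 = corr * z1 + np.sqrt(1 - corr**2) * rng.standard_normal(n)
    return mx + sx * z1, my + sy * z2


def _positive(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 1.0, None)


def simulate_well(
    sample: SerumSample,
    dilution: float,
    role: str,
    params: SimParams,
    seed: int,
) -> EventTable:
    """Simulate one well's acquired events.

    ``role`` is one of :data:`ROLES`.  Control wells ignore the serum: the
    max-stained well sees no antibody (c = 0); the unstained well
    additionally has the PE staining gain forced to zero, leaving pure
    autofluorescence.  Test wells act at the effective concentration of the
    serum at ``dilution``, plus the serum's nuisance effect.
    """
    if role not in ROLES:
        raise SimulationError(f"unknown well role {role!r}; expected one of {ROLES}")
    if dilution <= 0:
        raise SimulationError(f"dilution must be positive, got {dilution!r}")
    if role == "test" and dilution < SCREENING_DILUTION:
        raise SimulationError(
            f"test wells are run at reciprocal dilution >= {SCREENING_DILUTION}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, _TAG_WELL, seed]))
    n = params.n_events_per_well
    counts = rng.multinomial(
        n,
        [
            params.viable_fraction,
            params.debris_fraction,
            params.doublet_fraction,
            params.dead_fraction,
        ],
    )
    n_viable, n_debris, n_doublet, n_dead = (int(c) for c in counts)

    if role == "test":
        conc = effective_concentration_pM(sample.true_conc_pM, dilution)
        modulation = hill_internalized_fraction(conc, params) + serum_nuisance_effect(
            sample, params
        )
    else:
        modulation = 0.0
    modulation = min(modulation, 1.0)  # cannot internalize more than everything
    gain = 0.0 if role == "unstained" else params.pe_per_receptor

    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc_a = np.empty(n)
    apc = np.empty(n)
    pe = np.empty(n)
    labels = np.empty(n, dtype=object)

    def lognorm(mean_log, sd_log, size):
        return np.exp(rng.normal(mean_log, sd_log, size))

    def receptors(size, cells=1.0):
        r = cells * lognorm(params.receptor_mean_log, params.receptor_sd_log, size)
        return np.clip(r * (1.0 - modulation), 0.0, None)

    idx = 0
    # viable singlets
    s = slice(idx, idx + n_viable)
    a, c_ = _bivariate(rng, n_viable, *_VIABLE_FSC, *_VIABLE_SSC, _VIABLE_CORR)
    fsc_a[s] = _positive(a)
    fsc_h[s] = _positive(a / rng.normal(1.0, _RATIO_SD, n_viable))
    ssc_a[s] = _positive(c_)
    apc[s] = lognorm(*_LIVE_APC_LOG, n_viable)
    pe[s] = lognorm(params.autofluor_mean_log, params.autofluor_sd_log, n_viable)
    pe[s] += gain * receptors(n_viable)
    labels[s] = "viable"
    idx += n_viable

    # debris: small FSC, broad SSC, no receptor
    s = slice(idx, idx + n_debris)
    fsc_a[s] = _positive(rng.normal(*_DEBRIS_FSC, n_debris))
    fsc_h[s] = _positive(fsc_a[s] / rng.normal(1.0, 2 * _RATIO_SD, n_debris))
    ssc_a[s] = _positive(lognorm(*_DEBRIS_SSC_LOG, n_debris))
    apc[s] = lognorm(*_LIVE_APC_LOG, n_debris)
    pe[s] = lognorm(params.autofluor_mean_log, params.autofluor_sd_log, n_debris)
    labels[s] = "debris"
    idx += n_debris

    # doublets: singlet-like pulse height, area ~2x
    s = slice(idx, idx + n_doublet)
    h = _positive(rng.normal(*_VIABLE_FSC, n_doublet))
    fsc_h[s] = h
    fsc_a[s] = _positive(h * rng.normal(*_DOUBLET_RATIO, n_doublet))
    ssc_a[s] = _positive(rng.normal(*_DOUBLET_SSC, n_doublet))
    apc[s] = lognorm(*_LIVE_APC_LOG, n_doublet)
    pe[s] = lognorm(params.autofluor_mean_log, params.autofluor_sd_log, n_doublet)
    pe[s] += gain * receptors(n_doublet, cells=2.0)
    labels[s] = "doublet"
    idx += n_doublet

    # dead cells: bright viability stain
    s = slice(idx, idx + n_dead)
    fsc_a[s] = _positive(rng.normal(*_DEAD_FSC, n_dead))
    fsc_h[s] = _positive(fsc_a[s] / rng.normal(1.0, _RATIO_SD, n_dead))
    ssc_a[s] = _positive(rng.normal(*_DEAD_SSC, n_dead))
    apc[s] = lognorm(*_DEAD_APC_LOG, n_dead)
    pe[s] = lognorm(params.autofluor_mean_log, params.autofluor_sd_log, n_dead)
    pe[s] += gain * receptors(n_dead)
    labels[s] = "dead"

    # acquisition order should not encode the population label
    perm = rng.permutation(n)
    events = pd.DataFrame(
        {
            "FSC-A": fsc_a[perm],
            "FSC-H": fsc_h[perm],
            "SSC-A": ssc_a[perm],
            "APC-A": apc[perm],
            "PE-A": pe[perm],
        }
    )
    return EventTable(
        events=events,
        labels=labels[perm],
        meta={
            "sample_id": sample.sample_id,
            "role": role,
            "reciprocal_dilution": dilution,
            "seed": seed,
        },
    )


_FCS_CONTROL = SerumSample(sample_id="FCS", category="FCS_control")


def simulate_controls(params: SimParams, seed: int) -> tuple[EventTable, EventTable]:
    """The two per-plate control wells: unstained (MIN) and max-stained (MAX)."""
    unstained = simulate_well(_FCS_CONTROL, SCREENING_DILUTION, "unstained", params, seed)
    max_stained = simulate_well(
        _FCS_CONTROL, SCREENING_DILUTION, "max_stained", params, seed + 1
    )
    return unstained, max_stained


def simulate_dilution_series(
    sample: SerumSample,
    dilutions: Sequence[float],
    params: SimParams,
    seed: int,
) -> tuple[EventTable, EventTable, list[EventTable]]:
    """Simulate a two-fold titration series with its plate controls.

    Returns ``(unstained, max_stained, series)`` where ``series`` holds one
    test-role well per requested dilution; the effective antibody
    concentration halves at each two-fold step.
    """
    dil = list(dilutions)
    if not dil:
        raise SimulationError("dilution list is empty")
    if any(b <= a for a, b in zip(dil, dil[1:])):
        raise SimulationError("dilutions must be strictly increasing")
    unstained, max_stained = simulate_controls(params, seed)
    series = [
        simulate_well(sample, d, "test", params, seed + 2 + i)
        for i, d in enumerate(dil)
    ]
    return unstained, max_stained, series


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_positive_conc(rng: np.random.Generator) -> float:
    """Antibody concentration (screening scale, pM) of a positive serum:
    log-uniform over the seropositive RIA range."""
    lo, hi = np.log(RIA_RANGE_PM)
    return float(np.exp(rng.uniform(lo, hi)))


def _ria_from_conc(conc: float, rng: np.random.Generator) -> float:
    """Monotone-in-expectation RIA readout: the true concentration under 10%
    lognormal measurement noise, clipped to the published seropositive range."""
    noisy = conc * float(np.exp(rng.normal(0.0, 0.10)))
    return float(np.clip(noisy, *RIA_RANGE_PM))


def make_cohort_samples(config: CohortConfig) -> list[SerumSample]:
    """Draw the serum cohort: categories, antibody concentrations, RIA values.

    Blinded samples carry a hidden reference status (``blinded_truth``):
    ``config.blinded_positive`` of them are antibody-positive with RIA
    values, the rest negative.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _TAG_COHORT])
    )
    samples: list[SerumSample] = []
    counter = 0
    for cat in CATEGORIES:
        n_cat = config.group_sizes.get(cat, 0)
        for i in range(n_cat):
            counter += 1
            sid = f"S{counter:03d}_{cat}"
            if cat == "seropositive_AAG":
                conc = _draw_positive_conc(rng)
                samples.append(
                    SerumSample(sid, cat, true_conc_pM=conc,
                                ria_pM=_ria_from_conc(conc, rng))
                )
            elif cat == "blinded":
                if i < config.blinded_positive:
                    conc = _draw_positive_conc(rng)
                    samples.append(
                        SerumSample(sid, cat, true_conc_pM=conc,
                                    ria_pM=_ria_from_conc(conc, rng),
                                    blinded_truth="positive")
                    )
                else:
                    samples.append(SerumSample(sid, cat, blinded_truth="negative"))
            else:
                samples.append(SerumSample(sid, cat))
    return samples


def samples_metadata(samples: Iterable[SerumSample]) -> pd.DataFrame:
    """Sample-metadata table (one row per serum)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "category": [s.category for s in samples],
            "true_conc_pM": [s.true_conc_pM for s in samples],
            "ria_pM": [s.ria_pM for s in samples],
            "blinded_truth": [s.blinded_truth for s in samples],
        }
    )


def simulate_cohort(
    config: CohortConfig, params: SimParams, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, EventTable], pd.DataFrame]:
    """Simulate the full screening run: every serum at 1:20 plus per-plate
    controls.

    Returns ``(layout, wells, metadata)``:

    * ``layout`` — one row per well: plate, well, sample_id, role,
      reciprocal_dilution;
    * ``wells`` — mapping of well key (``"P1:W03"``) to its
      :class:`EventTable`;
    * ``metadata`` — per-serum table including the hidden truth of blinded
      samples and RIA values for antibody-positive sera.
    """
    if seed is not None:
        params = replace(params, seed=seed)
        config = replace(config, seed=seed)
    samples = make_cohort_samples(config)
    layout_rows = []
    wells: dict[str, EventTable] = {}
    well_seed = 0
    for p_start in range(0, len(samples), config.plate_capacity):
        plate = f"P{p_start // config.plate_capacity + 1}"
        plate_samples = samples[p_start : p_start + config.plate_capacity]
        unstained, max_stained = simulate_controls(params, well_seed)
        well_seed += 2
        for w, (role, table, sid, dil) in enumerate(
            [
                ("unstained", unstained, "FCS", ""),
                ("max_stained", max_stained, "FCS", ""),
            ]
        ):
            key = f"{plate}:W{w + 1:02d}"
            table.meta.update(plate=plate, well=key)
            wells[key] = table
            layout_rows.append((plate, key, sid, role, dil))
        for w, sample in enumerate(plate_samples):
            table = simulate_well(
                sample, SCREENING_DILUTION, "test", params, well_seed
            )
            well_seed += 1
            key = f"{plate}:W{w + 3:02d}"
            table.meta.update(plate=plate, well=key)
            wells[key] = table
            layout_rows.append(
                (plate, key, sample.sample_id, "test", SCREENING_DILUTION)
            )
    layout = pd.DataFrame(
        layout_rows,
        columns=["plate", "well", "sample_id", "role", "reciprocal_dilution"],
    )
    return layout, wells, samples_metadata(samples)
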