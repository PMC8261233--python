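"""Immunomodulation scoring, decision limit, classification, endpoint titer.

The assay quantifies antibody-induced receptor internalization as

    % Immunomodulation = [1 - (Test - MIN) / (MAX - MIN)] x 100

where Test, MIN and MAX are the gated gnACHR-positive event fractions of
the patient-serum well, the unstained control and the maximally stained
control on the same plate.  A serum scores 0% when it leaves staining at
the maximal-control level and 100% when it abolishes staining down to
background; scores outside [0, 100] can occur from sampling noise and are
deliberately retained (clamping would bias the control statistics).

Positivity is decided against a limit of mean + k*SD (default k = 3) of
the healthy-control score distribution; scores strictly above the limit
are "detected".  Detected sera are titrated by two-fold dilutions, the
endpoint titer being the last dilution of the unbroken run of
above-limit scores starting at 1:20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import SCREENING_DILUTION

NOT_DETECTED = "not_detected"
DETECTED = "detected"

#: Screening scores are reported at this many decimals (0.1%).
REPORT_DECIMALS = 1


class AssayInvalidError(ValueError):
    """Plate controls are unusable (MAX does not exceed MIN)."""


class ScoringError(ValueError):
    """Invalid scoring input."""


@dataclass(frozen=True)
class WellTriplet:
    """Gated positive fractions of a test well and its plate controls."""

    test_pp: float
    min_pp: float
    max_pp: float

    def __post_init__(self) -> None:
        for name in ("test_pp", "min_pp", "max_pp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScoringError(f"{name} must be a proportion in [0, 1], got {v!r}")
        if self.max_pp <= self.min_pp:
            raise AssayInvalidError(
                f"assay invalid: MAX ({self.max_pp}) must exceed MIN ({self.min_pp})"
            )


@dataclass(frozen=True)
class DecisionRule:
    """Mean + k*SD decision limit derived from control scores (%)."""

    control_mean: float
    control_sd: float
    limit: float
    n_controls: int
    k_sigma: float = 3.0


@dataclass(frozen=True)
class SampleResult:
    """Per-serum outcome: screening score, classification, endpoint titer."""

    sample_id: str
    screening_im: float
    status: str
    endpoint_titer: int | None = None
    category: str = ""
    quality_flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.status not in (DETECTED, NOT_DETECTED):
            raise ScoringError(f"invalid status {self.status!r}")
        if self.status == NOT_DETECTED and self.endpoint_titer is not None:
            raise ScoringError("endpoint_titer only applies to detected samples")
        if self.endpoint_titer is not None and self.endpoint_titer < SCREENING_DILUTION:
            raise ScoringError(
                f"endpoint_titer must be >= {SCREENING_DILUTION}"
            )


def immunomodulation_percent(triplet: WellTriplet) -> float:
    """% immunomodulation of one test well against its plate controls.

    Unclamped: full precision is carried internally; outputs round to
    0.1% only at serialization.
    """
    span = triplet.max_pp - triplet.min_pp
    return (1.0 - (triplet.test_pp - triplet.min_pp) / span) * 100.0


def decision_limit(control_scores: Sequence[float], k_sigma: float = 3.0) -> DecisionRule:
    """Mean + k*SD limit over healthy-control scores (sample SD, n-1)."""
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 2:
        raise ScoringError("decision limit needs at least 2 control scores")
    if not np.all(np.isfinite(scores)):
        raise ScoringError("control scores must be finite")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    return DecisionRule(
        control_mean=mean,
        control_sd=sd,
        limit=mean + k_sigma * sd,
        n_controls=int(scores.size),
        k_sigma=k_sigma,
    )


def classify(score: float, rule: DecisionRule) -> str:
    """Detected iff the score strictly exceeds the limit (ties negative)."""
    if not np.isfinite(score):
        raise ScoringError(f"score must be finite, got {score!r}")
    return DETECTED if score > rule.limit else NOT_DETECTED


def endpoint_titer(
    series: Sequence[tuple[float, float]], rule: DecisionRule
) -> int | None:
    """Endpoint titer of a two-fold titration series (first-crossing rule).

    ``series`` is (reciprocal_dilution, score) pairs sorted by increasing
    dilution, starting at 1:20.  Returns the last dilution of the initial
    unbroken run of above-limit scores, or None (not detected) when the
    1:20 score does not exceed the limit.  A score dipping below the limit
    ends the run even if later dilutions recross it.
    """
    if not series:
        raise ScoringError("titration series is empty")
    dils = [d for d, _ in series]
    if dils[0] != SCREENING_DILUTION:
        raise ScoringError(
            f"titration series must start at reciprocal dilution {SCREENING_DILUTION}"
        )
    if any(b <= a for a, b in zip(dils, dils[1:])):
        raise ScoringError("titration series must be sorted by increasing dilution")
    titer = None
    for dil, score in series:
        if classify(score, rule) == DETECTED:
            titer = int(dil)
        else:
            break
    return titer


# ---------------------------------------------------------------------------
# Results table round-trip
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "sample_id",
    "category",
    "screening_im",
    "limit",
    "status",
    "endpoint_titer",
    "flags",
]


def results_to_frame(results: Sequence[SampleResult], rule: DecisionRule) -> pd.DataFrame:
    """Results CSV layout: screening scores at 0.1% precision, titer as a
    reciprocal dilution, flags semicolon-joined."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "category": [r.category for r in results],
            "screening_im": [round(r.screening_im, REPORT_DECIMALS) for r in results],
            "limit": [round(rule.limit, REPORT_DECIMALS)] * len(results),
            "status": [r.status for r in results],
            "endpoint_titer": [
                r.endpoint_titer if r.endpoint_titer is not None else ""
                for r in results
            ],
            "flags": [";".join(r.quality_flags) for r in results],
        },
        columns=_RESULT_COLUMNS,
    )


def results_from_frame(frame: pd.DataFrame) -> list[SampleResult]:
    """Inverse of :func:`results_to_frame` (lossless at 0.1% precision)."""
    out = []
    for row in frame.itertuples(index=False):
        titer = row.endpoint_titer
        titer = None if titer in ("", None) or pd.isna(titer) else int(titer)
        flags = (
            tuple(str(row.flags).split(";"))
            if isinstance(row.flags, str) and row.flags
            else ()
        )
        out.append(
            SampleResult(
                sample_id=row.sample_id,
                screening_im=float(row.screening_im),
                status=row.status,
                endpoint_titer=titer,
                category="" if pd.isna(row.category) else str(row.category),
                quality_flags=flags,
            )
        )
    return out
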