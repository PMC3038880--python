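"""Standards-based assay validation.

Covers the three wet-lab validation computations, applied to per-CpG
percentage readouts: linearity against methylated/unmethylated DNA mixture
standards (0/25/50/75/100%), technical-replicate concordance via OLS plus
Bland-Altman limits of agreement, and input-titration sensitivity with
allelic-dropout detection on 50% standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalog import MethylationDataset
from .dmr import DmrWindow

__all__ = [
    "STANDARD_SERIES",
    "LinearityResult",
    "AgreementResult",
    "SensitivityResult",
    "build_standard_series",
    "assess_linearity",
    "replicate_agreement",
    "titration_sensitivity",
]

# Canonical mixture series: fully methylated, 3:1, 2:2, 1:3, fully
# unmethylated, expressed as expected percent methylation.
STANDARD_SERIES = (0.0, 25.0, 50.0, 75.0, 100.0)


def build_standard_series() -> list[float]:
    """Expected methylation percentages of the canonical mixture series."""
    return list(STANDARD_SERIES)


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    constant_observed: bool = False  # warning flag: flat response


@dataclass(frozen=True)
class AgreementResult:
    r_squared: float
    slope: float
    bias: float          # mean(rep1 - rep2), percent
    loa_low: float       # bias - 1.96 * SD(differences)
    loa_high: float
    n_pairs: int


@dataclass(frozen=True)
class MassReading:
    template_mass_ng: float
    mean_reading: float
    within_window: bool
    dropout: bool


@dataclass(frozen=True)
class SensitivityResult:
    per_mass: tuple[MassReading, ...]
    min_reliable_mass_ng: float | None


def _pairwise_complete(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    return a[mask], b[mask]


def assess_linearity(expected, observed) -> LinearityResult:
    """OLS of observed on expected; r^2 is the squared Pearson correlation.

    A constant expected vector is an error (no regression is possible); a
    constant observed vector yields slope 0, r^2 0 and a warning flag.
    """
    x, y = _pairwise_complete(expected, observed)
    if len(x) < 2:
        raise ValueError("need at least 2 complete (expected, observed) pairs")
    if np.ptp(x) == 0:
        raise ValueError("expected values are constant; cannot assess linearity")
    if np.ptp(y) == 0:
        warnings.warn("observed values are constant; r_squared set to 0")
        return LinearityResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            n_points=len(x), constant_observed=True,
        )
    fit = stats.linregress(x, y)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(x),
    )


def replicate_agreement(rep1, rep2) -> AgreementResult:
    """Technical-replicate concordance: OLS rep2 ~ rep1 and Bland-Altman.

    bias = mean(rep1 - rep2); limits of agreement = bias +/- 1.96 * sample
    SD of the paired differences. Pairs with a missing member are dropped.
    """
    a, b = _pairwise_complete(rep1, rep2)
    if len(a) < 3:
        raise ValueError("need at least 3 complete replicate pairs")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        slope, r2 = 0.0, 1.0 if np.allclose(a, b) else 0.0
    else:
        fit = stats.linregress(a, b)
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    return AgreementResult(
        r_squared=r2,
        slope=slope,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=len(a),
    )


def titration_sensitivity(
    dataset: MethylationDataset,
    window: DmrWindow,
    dropout_margin: float = 20.0,
) -> SensitivityResult:
    """Smallest template input that still reports a 50% standard reliably.

    All samples must be 50% standards carrying ``template_mass_ng``. Per
    mass: the mean over CpGs and replicates is tested for containment in
    the differential window; a mass is a dropout if any single replicate
    mean falls within ``dropout_margin`` points of either rail beyond the
    window (reading <= lower - margin or >= upper + margin), the signature
    of mono-allelic amplification failure. ``min_reliable_mass_ng`` is the
    smallest mass that is inside the window with no dropout.
    """
    df = dataset.data
    if df.empty:
        raise ValueError("no standard samples provided")
    if "template_mass_ng" not in df.columns or df["template_mass_ng"].isna().all():
        raise ValueError("standard samples carry no template_mass_ng metadata")

    readings: list[MassReading] = []
    for mass, sub in df.groupby("template_mass_ng"):
        rep_means = sub.groupby("sample")["percent"].mean()
        overall = float(rep_means.mean())
        within = window.lower <= overall <= window.upper
        dropout = bool(
            ((rep_means <= window.lower - dropout_margin)
             | (rep_means >= window.upper + dropout_margin)).any()
        )
        readings.append(MassReading(float(mass), overall, within, dropout))
    readings.sort(key=lambda r: r.template_mass_ng)

    reliable = [r.template_mass_ng for r in readings if r.within_window and not r.dropout]
    return SensitivityResult(
        per_mass=tuple(readings),
        min_reliable_mass_ng=min(reliable) if reliable else None,
    )
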