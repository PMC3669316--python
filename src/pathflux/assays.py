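"""Extracellular flux rates, OCR normalization, proliferation and t-tests.

Media metabolite rates are normalized to both cell number and the
fresh-media interval: a concentration change of ``d`` mM in ``V`` mL over
``dt`` hours with ``c`` cells at collection is

    rate = d * V * 1000 / ((c / 1e6) * dt)   [nmol / h per 1e6 cells].

Oxygen consumption readings (pmol/min per well) are normalized to total
protein (ug); proliferation is reported as treated cell count relative to
the vehicle-control mean.  Group comparisons against vehicle use a
two-tailed t-test (pooled-variance Student by default, Welch by flag) with
the usual star convention: ``*`` for p <= 0.05, ``**`` for p <= 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssayPlate",
    "metabolite_rate",
    "ocr_normalize",
    "proliferation_normalize",
    "two_tailed_ttest",
    "significance_tier",
    "dose_response_table",
    "WELL_COLUMNS",
]

#: required columns of the per-well assay table
WELL_COLUMNS = [
    "well", "drug", "dose_ug_ml", "replicate",
    "fresh_glucose_mM", "final_glucose_mM",
    "fresh_lactate_mM", "final_lactate_mM",
    "volume_ml", "interval_h", "cell_count",
    "o2_pmol_min", "protein_ug",
]


@dataclass
class AssayPlate:
    """Per-well assay measurements plus a growth-curve series.

    ``wells`` holds one endpoint row per well (see :data:`WELL_COLUMNS`);
    ``growth`` holds (dose, replicate, timepoint_h, cell_count) rows for the
    proliferation time course.  ``meta`` records generation/processing notes
    such as clipped negative concentrations.
    """

    wells: pd.DataFrame
    growth: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"assay plate missing columns: {missing}")
        w = self.wells
        if (w["interval_h"] <= 0).any():
            raise ValueError("interval_h must be > 0")
        if (w["volume_ml"] <= 0).any():
            raise ValueError("volume_ml must be > 0")
        if (w["cell_count"] < 0).any():
            raise ValueError("cell_count must be >= 0")
        if (w["dose_ug_ml"] < 0).any():
            raise ValueError("dose must be >= 0 (vehicle = 0)")
        if 0.0 not in set(w["dose_ug_ml"]):
            raise ValueError("plate needs a zero-dose vehicle condition")

    @property
    def doses(self) -> list[float]:
        return sorted(set(self.wells["dose_ug_ml"]))


def metabolite_rate(
    fresh_conc_mM: float,
    final_conc_mM: float,
    volume_ml: float,
    cell_count: float,
    interval_h: float,
    warn_on_negative: bool = True,
    cell_count_start: float | None = None,
) -> float:
    """Consumption rate in nmol/h per 1e6 cells (negative = net production).

    The cell-number denominator is the count at collection by default.
    Passing ``cell_count_start`` switches to the time-averaged count under
    exponential growth over the interval — the log-mean
    ``(N_end - N_start) / ln(N_end / N_start)``.

    For a secreted metabolite such as lactate, negate to report production
    as positive (and pass ``warn_on_negative=False``: net secretion is the
    expected sign, not an anomaly).  A final glucose above fresh is allowed
    and comes back as a negative consumption with a warning.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be > 0 to normalize a rate")
    if interval_h <= 0 or volume_ml <= 0:
        raise ValueError("interval_h and volume_ml must be > 0")
    denom = cell_count
    if cell_count_start is not None:
        if cell_count_start <= 0:
            raise ValueError("cell_count_start must be > 0")
        if cell_count_start != cell_count:
            denom = (cell_count - cell_count_start) / math.log(cell_count / cell_count_start)
    rate = (fresh_conc_mM - final_conc_mM) * volume_ml * 1000.0 / ((denom / 1e6) * interval_h)
    if warn_on_negative and final_conc_mM > fresh_conc_mM:
        logger.warning(
            "final concentration %.4g mM exceeds fresh %.4g mM; reporting negative consumption",
            final_conc_mM, fresh_conc_mM,
        )
    return rate


def ocr_normalize(reading_pmol_min: float, protein_ug: float) -> float:
    """Oxygen consumption per unit protein, pmol/min/ug."""
    if protein_ug <= 0:
        raise ValueError("protein_ug must be > 0")
    return reading_pmol_min / protein_ug


def proliferation_normalize(
    counts_treated: np.ndarray, counts_vehicle: np.ndarray
) -> tuple[float, float]:
    """Treated cell count as a fraction of the vehicle mean, with an SD.

    Returns ``(ratio, sd)`` where ratio = mean(treated) / mean(vehicle) and
    the SD propagates the replicate SDs of both groups to first order
    (delta method on a ratio of means).
    """
    a = np.asarray(counts_treated, dtype=float)
    b = np.asarray(counts_vehicle, dtype=float)
    mt, mv = a.mean(), b.mean()
    if mv <= 0:
        raise ValueError("vehicle mean must be > 0")
    ratio = mt / mv
    st = a.std(ddof=1) if a.size > 1 else 0.0
    sv = b.std(ddof=1) if b.size > 1 else 0.0
    sd = abs(ratio) * math.sqrt((st / mt) ** 2 + (sv / mv) ** 2) if mt != 0 else st / mv
    return float(ratio), float(sd)


def significance_tier(p: float) -> str:
    """Star annotation: ``**`` iff p <= 0.01, ``*`` iff 0.01 < p <= 0.05."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def two_tailed_ttest(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[float, float, str]:
    """Two-tailed t-test between replicate groups; returns (t, p, tier).

    ``student`` pools the variances (the default); ``welch`` does not.
    Two zero-variance groups with equal means yield t = 0, p = 1 by
    convention.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("both groups constant and equal; p = 1 by convention")
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
        return t, p, significance_tier(p)
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p), significance_tier(float(p))


_READOUTS = ("glucose", "lactate", "ocr")


def _well_rates(wells: pd.DataFrame, readout: str, denominator: str = "endpoint") -> pd.Series:
    if denominator not in ("endpoint", "time_averaged"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if denominator == "time_averaged" and "cell_count_start" not in wells.columns:
        raise ValueError("time_averaged denominator needs a cell_count_start column")

    def start(r):
        return r.cell_count_start if denominator == "time_averaged" else None

    if readout == "glucose":
        vals = [
            metabolite_rate(r.fresh_glucose_mM, r.final_glucose_mM, r.volume_ml,
                            r.cell_count, r.interval_h, cell_count_start=start(r))
            for r in wells.itertuples()
        ]
    elif readout == "lactate":
        vals = [
            -metabolite_rate(r.fresh_lactate_mM, r.final_lactate_mM, r.volume_ml,
                             r.cell_count, r.interval_h, warn_on_negative=False,
                             cell_count_start=start(r))
            for r in wells.itertuples()
        ]
    elif readout == "ocr":
        vals = [ocr_normalize(r.o2_pmol_min, r.protein_ug) for r in wells.itertuples()]
    else:
        raise ValueError(f"unknown readout {readout!r}; expected one of {_READOUTS}")
    return pd.Series(vals, index=wells.index, name=readout)


def dose_response_table(
    plate: AssayPlate, readout: str, *, ttest_variant: str = "student",
    denominator: str = "endpoint",
) -> pd.DataFrame:
    """Per-dose rate summary (mean, SD, n, t-test vs vehicle, tier).

    Rows are ordered by dose with the vehicle (dose 0) flagged; the
    ``monotone_increasing``/``monotone_decreasing`` columns report whether
    the dose-ordered means are fully ordered.  Units: nmol/h per 1e6 cells
    for glucose consumption and lactate production, pmol/min/ug protein for
    oxygen consumption.  ``denominator`` selects the cell-number convention
    for metabolite rates (``endpoint`` count or exponential
    ``time_averaged``; the latter needs a ``cell_count_start`` column).
    """
    wells = plate.wells
    rates = _well_rates(wells, readout, denominator)
    vehicle_vals = rates[wells["dose_ug_ml"] == 0.0].to_numpy()
    rows = []
    for dose, grp in rates.groupby(wells["dose_ug_ml"]):
        vals = grp.to_numpy()
        if vals.size == 1:
            logger.warning("dose %.3g has a single replicate; SD reported as 0", dose)
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        if dose == 0.0 or vals.size < 2 or vehicle_vals.size < 2:
            t = p = float("nan")
            tier = "ns" if dose != 0.0 else ""
        else:
            t, p, tier = two_tailed_ttest(vals, vehicle_vals, ttest_variant)
        rows.append(
            {"readout": readout, "dose_ug_ml": float(dose), "is_vehicle": dose == 0.0,
             "mean": float(vals.mean()), "sd": sd, "n": int(vals.size),
             "t": t, "p": p, "tier": tier}
        )
    df = pd.DataFrame(rows).sort_values("dose_ug_ml").reset_index(drop=True)
    means = df["mean"].to_numpy()
    df["monotone_increasing"] = bool(np.all(np.diff(means) >= 0))
    df["monotone_decreasing"] = bool(np.all(np.diff(means) <= 0))
    return df
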