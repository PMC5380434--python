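"""Co-culture statistics: CFU arithmetic, competitive index, reporter
fold-induction and PI-positive fractions.

The competitive index (CI) of an indicator strain competed against a
producer is the indicator/producer CFU ratio at the final time point
divided by the same ratio at t = 0; CI ~ 1 means no differential
killing.  CFU densities come from 10-fold serial dilutions spotted at
a known volume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "CfuObservation",
    "CompetitionResult",
    "cfu_per_ml",
    "competitive_index",
    "fold_induction",
    "pi_fraction",
    "read_cfu_table",
    "competition_table",
]

#: colony counts per spot regarded as reliably countable
RELIABLE_COUNT_RANGE = (3, 100)


@dataclass(frozen=True)
class CfuObservation:
    """One dilution spot: colonies counted at a 10^-k dilution."""

    strain: str
    time_hr: float
    dilution: float  # 10^-k factor in (0, 1]
    colonies: int
    plated_volume_ml: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError("dilution must be in (0, 1]")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")


@dataclass(frozen=True)
class CompetitionResult:
    ci: float
    log10_ci: float
    t0: float
    tf: float
    strains: Tuple[str, str]  # (indicator, producer)
    at_detection_limit: bool = False


def cfu_per_ml(obs: CfuObservation) -> Tuple[float, bool]:
    """CFU/mL = colonies / (dilution x plated volume).

    Returns ``(value, flagged)``; flagged is True when the count is
    outside the reliable band (including zero colonies, which returns 0
    as a lower-detection-limit value).
    """
    value = obs.colonies / (obs.dilution * obs.plated_volume_ml)
    lo, hi = RELIABLE_COUNT_RANGE
    flagged = not (lo <= obs.colonies <= hi)
    return value, flagged


def competitive_index(
    ind_t0: float,
    prod_t0: float,
    ind_tf: float,
    prod_tf: float,
    t0: float = 0.0,
    tf: float = 0.0,
    strains: Tuple[str, str] = ("indicator", "producer"),
    detection_limit: Optional[float] = None,
) -> CompetitionResult:
    """CI = (ind_tf / prod_tf) / (ind_t0 / prod_t0).

    A zero producer count at tf leaves the ratio undefined (error).  A
    zero indicator count at tf is reported as an upper bound with the
    indicator set to the detection limit (default: 1 CFU in the least
    dilute spot volume implied by ind_t0's scale, i.e. caller-supplied).
    """
    if ind_t0 <= 0 or prod_t0 <= 0:
        raise ValueError("t0 CFU values must be positive")
    if prod_tf <= 0:
        raise ValueError("producer CFU at tf is zero; CI undefined")
    limited = False
    if ind_tf <= 0:
        if detection_limit is None or detection_limit <= 0:
            raise ValueError(
                "indicator CFU at tf is zero; supply detection_limit for an upper bound"
            )
        ind_tf = detection_limit
        limited = True
    ci = (ind_tf / prod_tf) / (ind_t0 / prod_t0)
    return CompetitionResult(
        ci=ci,
        log10_ci=math.log10(ci),
        t0=t0,
        tf=tf,
        strains=strains,
        at_detection_limit=limited,
    )


def fold_induction(
    series: Sequence[Tuple[float, float]],
    baseline_od: float = 0.025,
    od_tol: float = 1e-6,
) -> List[Tuple[float, float]]:
    """Per-point fold induction of (OD, fluorescence density) pairs,
    relative to the value at the baseline OD."""
    baseline = None
    for od, val in series:
        if abs(od - baseline_od) <= od_tol:
            baseline = val
            break
    if baseline is None:
        raise ValueError(f"no point at baseline OD {baseline_od}")
    if baseline <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return [(od, val / baseline) for od, val in series]


def pi_fraction(fields: Sequence[Tuple[int, int]], min_cells: int = 250, min_fields: int = 3):
    """Mean +/- sd of the PI-positive fraction across microscopy fields.

    Each field is ``(total cells, PI-positive cells)``.  Fewer than
    ``min_fields`` fields or fields below ``min_cells`` cells are
    flagged, not fatal; a positive count above the total is an error.
    """
    fracs = []
    flags = []
    for total, pos in fields:
        if pos > total:
            raise ValueError(f"PI-positive count {pos} exceeds total {total}")
        if total <= 0:
            raise ValueError("field with zero cells")
        fracs.append(pos / total)
        if total < min_cells:
            flags.append(f"field with {total} cells (< {min_cells})")
    if len(fields) < min_fields:
        flags.append(f"only {len(fields)} fields (< {min_fields})")
    n = len(fracs)
    mean = sum(fracs) / n
    sd = math.sqrt(sum((f - mean) ** 2 for f in fracs) / (n - 1)) if n > 1 else 0.0
    return {"mean": mean, "sd": sd, "per_field": fracs, "flags": flags}


def read_cfu_table(path) -> List[CfuObservation]:
    """Read a TSV of strain, time_hr, dilution, colonies[, volume_ml]."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "time_hr", "dilution", "colonies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs = []
    for row in df.itertuples(index=False):
        obs.append(
            CfuObservation(
                strain=str(row.strain),
                time_hr=float(row.time_hr),
                dilution=float(row.dilution),
                colonies=int(row.colonies),
                plated_volume_ml=float(getattr(row, "volume_ml", 0.01)),
            )
        )
    return obs


def competition_table(
    observations: Sequence[CfuObservation],
    indicator: str,
    producer: str,
    detection_limit: Optional[float] = None,
) -> pd.DataFrame:
    """Per final-time-point CI table from a tidy CFU observation list.

    The earliest time point is t0; each later time point yields one CI
    row.  Densities are taken from :func:`cfu_per_ml`.
    """
    dens: dict = {}
    for o in observations:
        if o.strain not in (indicator, producer):
            continue
        v, _ = cfu_per_ml(o)
        dens[(o.strain, o.time_hr)] = v
    times = sorted({t for (_, t) in dens})
    if len(times) < 2:
        raise ValueError("need CFU at >= 2 time points")
    t0 = times[0]
    rows = []
    for tf in times[1:]:
        res = competitive_index(
            dens[(indicator, t0)],
            dens[(producer, t0)],
            dens[(indicator, tf)],
            dens[(producer, tf)],
            t0=t0,
            tf=tf,
            strains=(indicator, producer),
            detection_limit=detection_limit,
        )
        rows.append(
            {
                "indicator": indicator,
                "producer": producer,
                "t0_hr": t0,
                "tf_hr": tf,
                "ci": res.ci,
                "log10_ci": res.log10_ci,
                "at_detection_limit": res.at_detection_limit,
            }
        )
    return pd.DataFrame(rows)
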