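"""Semi-quantitative compartment ratios of peak heights.

Each compound's fate is summarised by peak-height ratios between
compartments, expressed as percentages:

    ACC100_DON0   acceptor at end time   / donor at t = 0
    ACC100_DON100 acceptor at end time   / donor at end time
    MEM_DON0      membrane extract       / donor at t = 0
    MEM_DON100    membrane extract       / donor at end time
    DON100_DON0   donor at end time      / donor at t = 0

Ratios against the end-time donor are paired within chamber (the chamber
is the experimental unit); time-0 denominators use the mean of the donor
t0 aliquots when present, otherwise the stock-solution analytical
replicates.  Aggregation is the mean +/- SD over chambers with the CV in
percent.  A censored numerator contributes 0 with a status flag (dropping
it would bias the mean upward); a censored denominator leaves the ratio
undefined.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .feature_tables import FeatureTable, parse_sample_name


class RatioKind(str, enum.Enum):
    ACC100_DON0 = "ACC100_DON0"
    ACC100_DON100 = "ACC100_DON100"
    MEM_DON0 = "MEM_DON0"
    MEM_DON100 = "MEM_DON100"
    DON100_DON0 = "DON100_DON0"


class RatioStatus(str, enum.Enum):
    OK = "ok"
    BELOW_LOD_NUMERATOR = "below_lod_numerator"
    BELOW_LOD_DENOMINATOR = "below_lod_denominator"


_KIND_LAYOUT = {
    RatioKind.ACC100_DON0: ("acceptor", "end", "donor", "t0"),
    RatioKind.ACC100_DON100: ("acceptor", "end", "donor", "end"),
    RatioKind.MEM_DON0: ("membrane", "end", "donor", "t0"),
    RatioKind.MEM_DON100: ("membrane", "end", "donor", "end"),
    RatioKind.DON100_DON0: ("donor", "end", "donor", "t0"),
}


@dataclass
class RatioResult:
    compound_id: str
    kind: RatioKind
    per_replicate: np.ndarray
    mean: float
    sd: float
    cv: float  # percent
    status: RatioStatus
    n_censored: int = 0
    n_detected: int = 0  # numerator replicates with a finite height

    @property
    def ok(self) -> bool:
        return self.status is RatioStatus.OK


def _end_time(table: FeatureTable, compartment: str) -> float:
    times = [parse_sample_name(s)[1] for s in table.sample_ids(compartment)]
    if not times:
        raise ValueError(f"no {compartment} samples in table")
    return max(times)


def compute_ratio(
    table: FeatureTable,
    matches: dict[str, str | None],
    compound_id: str,
    kind: RatioKind | str,
    end_time: float | None = None,
) -> RatioResult:
    """Percent peak-height ratio for one compound, replicate-aggregated."""
    kind = RatioKind(kind)
    fid = matches.get(compound_id)
    if fid is None:
        raise ValueError(f"compound {compound_id!r} is unmatched in the feature table")
    num_comp, num_when, den_comp, den_when = _KIND_LAYOUT[kind]

    if end_time is None:
        end_time = _end_time(table, num_comp)

    num_ids = table.sample_ids(num_comp, time=end_time)
    if not num_ids:
        raise ValueError(f"no {num_comp} samples at t={end_time:g}")
    n_detected = int(
        np.sum([math.isfinite(table.height(fid, s)) for s in num_ids])
    )

    if den_when == "t0":
        den_ids = table.sample_ids(den_comp, time=0.0)
        if not den_ids:
            den_ids = table.sample_ids("stock", time=0.0)
        if not den_ids:
            raise ValueError("no donor t0 or stock samples for the time-0 denominator")
        den_heights = np.array([table.height(fid, s) for s in den_ids])
        if not np.any(np.isfinite(den_heights)):
            return RatioResult(
                compound_id, kind, np.full(len(num_ids), np.nan), math.nan,
                math.nan, math.nan, RatioStatus.BELOW_LOD_DENOMINATOR,
                n_detected=n_detected,
            )
        denominators = {None: float(np.nanmean(den_heights))}
        paired = False
    else:
        den_end = _end_time(table, den_comp)
        den_ids = table.sample_ids(den_comp, time=den_end)
        denominators = {
            parse_sample_name(s)[2]: table.height(fid, s) for s in den_ids
        }
        paired = True

    values = []
    n_censored = 0
    any_den_censored = False
    for s in num_ids:
        rep = parse_sample_name(s)[2]
        den = denominators.get(rep if paired else None, math.nan)
        if not math.isfinite(den) or den <= 0:
            any_den_censored = True
            values.append(math.nan)
            continue
        num = table.height(fid, s)
        if not math.isfinite(num):
            n_censored += 1
            values.append(0.0)
        else:
            values.append(100.0 * num / den)

    arr = np.array(values)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return RatioResult(compound_id, kind, arr, math.nan, math.nan, math.nan,
                           RatioStatus.BELOW_LOD_DENOMINATOR, n_detected=n_detected)
    mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    cv = 100.0 * sd / mean if mean > 0 else math.nan
    if any_den_censored:
        status = RatioStatus.BELOW_LOD_DENOMINATOR
    elif n_censored > 0:
        status = RatioStatus.BELOW_LOD_NUMERATOR
    else:
        status = RatioStatus.OK
    return RatioResult(compound_id, kind, arr, mean, sd, cv, status,
                       n_censored, n_detected)


def compute_all_ratios(
    table: FeatureTable,
    matches: dict[str, str | None],
    end_time: float | None = None,
) -> dict[str, dict[RatioKind, RatioResult]]:
    """All five ratio kinds for every matched compound."""
    out: dict[str, dict[RatioKind, RatioResult]] = {}
    for cid, fid in matches.items():
        if fid is None:
            continue
        out[cid] = {}
        for kind in RatioKind:
            try:
                out[cid][kind] = compute_ratio(table, matches, cid, kind, end_time)
            except ValueError:
                continue
    return out


def permeant_call(ratio: RatioResult, threshold: float = 0.1) -> bool:
    """Is the compound a permeant? True when the acceptor(end)/donor(0) mean
    ratio reaches the detectability floor (default 0.1%).

    A compound reaching ~0.1% of its initial donor level in the acceptor is
    still regarded as having crossed the membrane; anything censored below
    the LOD is not called.
    """
    if ratio.kind is not RatioKind.ACC100_DON0:
        raise ValueError("permeant call requires an ACC100_DON0 ratio")
    return ratio.status is RatioStatus.OK and bool(ratio.mean >= threshold)


def fold_increase(conc_end: float, conc_start: float) -> float:
    """Fold change of a donor concentration over the run (same units)."""
    if conc_start <= 0:
        raise ValueError("starting concentration must be positive")
    return conc_end / conc_start
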