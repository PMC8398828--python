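"""Compound-fate classification and run reporting.

Each monitored compound is assigned one primary label from the
compartment-ratio evidence, mirroring how such experiments are read:

* ``interference_excluded`` - the blank membrane carries a rivalling signal.
* ``permeant``              - detected in the acceptor at the detectability
  floor (acceptor/donor-0 ratio >= 0.1%).
* ``intestinal_metabolite`` - absent at t0 but present at the end in the
  donor, or strongly increased without a +O mass relationship.
* ``hydroxylation_product`` - increased in the donor and exactly one oxygen
  (15.9949 Da) heavier than a monitored compound: a CYP-type oxidation.
* ``stable_in_donor``       - donor end/start ratio inside the stability
  band (default 80-120%).
* ``depleted_precursor``    - donor ratio below the band (e.g. O-glycosides
  hydrolysed by intestinal beta-glucosidases).
* ``membrane_retained``     - appended as secondary evidence when the
  membrane ratio clears its floor while the donor is stable.
* ``not_detected``          - no usable signal anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .permeation import PermeabilityFit, ViabilityReport
from .semiquant import RatioKind, RatioResult, RatioStatus

OXYGEN_MASS = 15.9949  # monoisotopic, Da


class Fate(str, enum.Enum):
    PERMEANT = "permeant"
    MEMBRANE_RETAINED = "membrane_retained"
    STABLE_IN_DONOR = "stable_in_donor"
    DEPLETED_PRECURSOR = "depleted_precursor"
    INTESTINAL_METABOLITE = "intestinal_metabolite"
    HYDROXYLATION_PRODUCT = "hydroxylation_product"
    INTERFERENCE_EXCLUDED = "interference_excluded"
    NOT_DETECTED = "not_detected"


@dataclass
class FateThresholds:
    permeant_threshold: float = 0.1  # percent, acceptor/donor-0
    stability_band: tuple[float, float] = (80.0, 120.0)  # percent, donor end/start
    membrane_min: float = 0.1  # percent
    oxide_ppm_tol: float = 5.0  # for the +O mass relationship


@dataclass
class FateLabel:
    compound_id: str
    label: Fate
    evidence: list[tuple[str, float, float]] = field(default_factory=list)
    # each evidence item: (quantity, value, threshold crossed)


def _membrane_evidence(
    ratios: dict[RatioKind, RatioResult], thresholds: FateThresholds
) -> list[tuple[str, float, float]]:
    out = []
    for kind in (RatioKind.MEM_DON100, RatioKind.MEM_DON0):
        r = ratios.get(kind)
        if r is not None and r.ok and r.mean >= thresholds.membrane_min:
            out.append((kind.value, r.mean, thresholds.membrane_min))
            break
    return out


def _is_oxide_of_monitored(
    mz: float, monitored_mz: dict[str, float], compound_id: str, ppm_tol: float
) -> bool:
    for other_id, other_mz in monitored_mz.items():
        if other_id == compound_id:
            continue
        if abs((mz - other_mz) - OXYGEN_MASS) <= ppm_tol * 1e-6 * mz:
            return True
    return False


def classify_fate(
    compound_id: str,
    ratios: dict[RatioKind, RatioResult],
    permeant: bool,
    interference: bool = False,
    mz: float | None = None,
    monitored_mz: dict[str, float] | None = None,
    thresholds: FateThresholds | None = None,
) -> FateLabel:
    """Assign the primary fate label for one compound.

    A pure function of its numeric inputs: the donor end/start ratio
    (DON100_DON0) drives the stable/depleted/increased split, the permeant
    call and interference flag pre-empt it, and membrane ratios are
    appended as secondary evidence.
    """
    th = thresholds or FateThresholds()
    if interference:
        return FateLabel(compound_id, Fate.INTERFERENCE_EXCLUDED,
                         [("blank_interference", 1.0, 0.0)])

    don = ratios.get(RatioKind.DON100_DON0)
    if don is None:
        return FateLabel(compound_id, Fate.NOT_DETECTED)

    detected_t0 = don.status is not RatioStatus.BELOW_LOD_DENOMINATOR
    detected_end = don.n_detected > 0 or (np.isfinite(don.mean) and don.mean > 0)

    if permeant:
        acc = ratios.get(RatioKind.ACC100_DON0)
        ev = [(RatioKind.ACC100_DON0.value, acc.mean if acc else np.nan,
               th.permeant_threshold)]
        ev += _membrane_evidence(ratios, th)
        return FateLabel(compound_id, Fate.PERMEANT, ev)

    if not detected_t0:
        if detected_end:
            # appeared only after membrane contact: formed by the tissue
            mem = ratios.get(RatioKind.MEM_DON100)
            ev = [("appeared_in_donor", don.mean if np.isfinite(don.mean) else 1.0, 0.0)]
            if mem is not None and mem.ok and mem.mean >= th.membrane_min:
                ev.append((RatioKind.MEM_DON100.value, mem.mean, th.membrane_min))
            return FateLabel(compound_id, Fate.INTESTINAL_METABOLITE, ev)
        return FateLabel(compound_id, Fate.NOT_DETECTED)
    if not detected_end and don.mean == 0.0 and don.status is RatioStatus.BELOW_LOD_NUMERATOR:
        return FateLabel(
            compound_id, Fate.DEPLETED_PRECURSOR,
            [(RatioKind.DON100_DON0.value, 0.0, th.stability_band[0])],
        )

    lo, hi = th.stability_band
    if lo <= don.mean <= hi:
        ev = [(RatioKind.DON100_DON0.value, don.mean, lo)]
        mem_ev = _membrane_evidence(ratios, th)
        if mem_ev:
            ev += mem_ev
            ev.append((Fate.MEMBRANE_RETAINED.value, mem_ev[0][1], th.membrane_min))
        return FateLabel(compound_id, Fate.STABLE_IN_DONOR, ev)
    if don.mean < lo:
        return FateLabel(
            compound_id, Fate.DEPLETED_PRECURSOR,
            [(RatioKind.DON100_DON0.value, don.mean, lo)],
        )
    # increased beyond the band
    ev = [(RatioKind.DON100_DON0.value, don.mean, hi)]
    if (
        mz is not None
        and monitored_mz
        and _is_oxide_of_monitored(mz, monitored_mz, compound_id, th.oxide_ppm_tol)
    ):
        return FateLabel(compound_id, Fate.HYDROXYLATION_PRODUCT, ev)
    ev += _membrane_evidence(ratios, th)
    return FateLabel(compound_id, Fate.INTESTINAL_METABOLITE, ev)


# ---------------------------------------------------------------------------
# reporting


def render_report(
    ratios: dict[str, dict[RatioKind, RatioResult]],
    fates: dict[str, FateLabel],
    papp_fits: dict[str, PermeabilityFit] | None = None,
    metrics: dict[str, dict[str, float]] | None = None,
    viability: list[ViabilityReport] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Assemble the long-format results table and a human-readable summary.

    Returns a ``(compound, metric, value, ...)`` DataFrame ordered by
    compound id and a plain-text summary naming permeants, metabolites and
    excluded chambers.
    """
    unknown = set(fates) - set(ratios)
    if unknown:
        raise ValueError(f"fate labels for compounds absent from ratios: {sorted(unknown)}")

    rows: list[dict] = []
    for cid in sorted(ratios):
        for kind in RatioKind:
            r = ratios[cid].get(kind)
            if r is None:
                continue
            rows.append(
                dict(compound=cid, metric=kind.value, value=r.mean, sd=r.sd,
                     cv=r.cv, status=r.status.value)
            )
        if papp_fits and cid in papp_fits:
            f = papp_fits[cid]
            rows.append(dict(compound=cid, metric="papp_cm_per_s", value=f.mean,
                             sd=f.sd, cv=f.cv, status="ok"))
        if metrics and cid in metrics:
            for name, value in sorted(metrics[cid].items()):
                rows.append(dict(compound=cid, metric=name, value=value,
                                 sd=np.nan, cv=np.nan, status="ok"))
        if cid in fates:
            rows.append(dict(compound=cid, metric="fate", value=np.nan,
                             sd=np.nan, cv=np.nan, status=fates[cid].label.value))
    table = pd.DataFrame(rows, columns=["compound", "metric", "value", "sd", "cv", "status"])

    permeants = sorted(c for c, f in fates.items() if f.label is Fate.PERMEANT)
    metabolites = sorted(
        c for c, f in fates.items()
        if f.label in (Fate.INTESTINAL_METABOLITE, Fate.HYDROXYLATION_PRODUCT)
    )
    depleted = sorted(c for c, f in fates.items() if f.label is Fate.DEPLETED_PRECURSOR)
    lines = [
        f"Compounds monitored: {len(ratios)}",
        f"Permeants ({len(permeants)}): {', '.join(permeants) or 'none'}",
        f"Intestinal metabolites ({len(metabolites)}): {', '.join(metabolites) or 'none'}",
        f"Depleted precursors ({len(depleted)}): {', '.join(depleted) or 'none'}",
    ]
    if viability is not None:
        excluded = [v for v in viability if not v.viable]
        n_ok = sum(v.viable for v in viability)
        lines.append(f"Viable chambers: {n_ok}/{len(viability)}")
        for v in excluded:
            lines.append(
                f"  chamber {v.chamber} excluded (min TEER "
                f"{v.min_teer:.1f} Ohm*cm^2 below threshold)"
            )
    return table, "\n".join(lines)
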