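"""Permeability, tissue-retention and biotransformation metrics.

Core quantities, all derived from molar amounts (nmol) per chamber:

* ``P_app = (dc/dt) * V / (A * C0)`` in cm/s, with dc/dt the slope of the
  (sampling-corrected) acceptor concentration-time curve over the 20-80 min
  window, V the donor volume (donor and acceptor volumes are equal here),
  A the exposed area and C0 the measured initial donor concentration.
* ``Q_DEP  = 100 * membrane(end) / donor(0)``  - percent of the initial
  donor amount deposited in the tissue.
* ``Q_PERM = 100 * acceptor(end) / donor(0)``  - percent permeated.
* ``TI = Q_DEP + Q_PERM``  - transport index.
* ``Q_DEP_extract = 100 * membrane(end) / (donor(end) + membrane(end))`` -
  deposition ratio referenced to what is measurable at the end of the run,
  suited to metabolites formed from several extract constituents.
* ``MFI = 100 * (metabolite donor+membrane+acceptor at end) / precursor
  donor(0)`` - metabolite formation index.

Periodic aliquot withdrawal removes analyte from the acceptor; the
cumulative-amount correction ``Q_n = c_n*V + sum_{i<n} c_i*v`` restores the
amount that would be present without sampling, and ``Q_n/V`` is the
equivalent concentration regressed for the P_app slope.  Chambers whose
TEER ever drops below the viability threshold are excluded from every
downstream metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve, quantify
from .design import ExperimentDesign, TEERTrace
from .feature_tables import FeatureTable, parse_sample_name

SECONDS_PER_MINUTE = 60.0


# ---------------------------------------------------------------------------
# sampling correction


def correct_sampling(
    times: np.ndarray,
    conc: np.ndarray,
    volume: float,
    aliquot: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-amount correction for aliquot withdrawal with replacement.

    Parameters
    ----------
    times, conc
        Measured concentration (uM) at each sampling time (the aliquot is
        withdrawn immediately after each measurement and replaced by an
        equal volume of fresh buffer).
    volume, aliquot
        Compartment and aliquot volumes in mL.

    Returns
    -------
    (cumulative_nmol, equivalent_conc_uM)
        ``Q_n = c_n * V + sum_{i<n} c_i * v`` and ``Q_n / V``.
    """
    if aliquot >= volume:
        raise ValueError("aliquot must be smaller than the compartment volume")
    conc = np.asarray(conc, dtype=float)
    removed = np.concatenate([[0.0], np.cumsum(conc[:-1] * aliquot)])
    q = conc * volume + removed
    return q, q / volume


@dataclass
class PermeabilityFit:
    compound_id: str
    per_chamber: np.ndarray  # cm/s
    mean: float
    sd: float
    slope_uM_per_s: float  # mean over chambers
    window: tuple[float, float]
    r2: np.ndarray  # per chamber

    @property
    def cv(self) -> float:
        return 100.0 * self.sd / self.mean if self.mean > 0 else math.nan


def papp_from_slope(
    slope_uM_per_s: float, design: ExperimentDesign, c0_uM: float
) -> float:
    """Eq.-of-definition conversion: P_app = slope * V / (A * C0), cm/s."""
    if c0_uM <= 0:
        raise ValueError("C0 must be positive")
    return slope_uM_per_s * design.donor_volume / (design.exposed_area * c0_uM)


def estimate_papp(
    times: np.ndarray,
    conc_by_chamber: np.ndarray,
    design: ExperimentDesign,
    c0_uM: float,
    compound_id: str = "",
    window: tuple[float, float] = (20.0, 80.0),
    correct: bool = True,
) -> PermeabilityFit:
    """Apparent permeability from acceptor concentration-time series.

    ``conc_by_chamber`` has shape (n_chambers, n_times) in uM.  Each
    chamber is fitted separately (free intercept, so any lag time is
    absorbed); results aggregate as mean +/- SD over chambers.
    """
    times = np.asarray(times, dtype=float)
    conc_by_chamber = np.atleast_2d(np.asarray(conc_by_chamber, dtype=float))
    lo, hi = window
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError("need at least 3 sampling points inside the fit window")

    papps, slopes, r2s = [], [], []
    for row in conc_by_chamber:
        row = np.where(np.isfinite(row), row, 0.0)  # censored -> below LOD -> 0
        if correct:
            _, eq = correct_sampling(
                times, row, design.acceptor_volume, design.acceptor_aliquot
            )
        else:
            eq = row
        fit = stats.linregress(times[mask], eq[mask])
        slope_s = fit.slope / SECONDS_PER_MINUTE
        slopes.append(slope_s)
        papps.append(papp_from_slope(slope_s, design, c0_uM))
        r2s.append(fit.rvalue**2)

    papps = np.array(papps)
    return PermeabilityFit(
        compound_id=compound_id,
        per_chamber=papps,
        mean=float(np.mean(papps)),
        sd=float(np.std(papps, ddof=1)) if papps.size > 1 else 0.0,
        slope_uM_per_s=float(np.mean(slopes)),
        window=(lo, hi),
        r2=np.array(r2s),
    )


# ---------------------------------------------------------------------------
# amount bookkeeping and ratio metrics


@dataclass
class CompartmentAmounts:
    """Molar bookkeeping for one compound in one chamber (nmol)."""

    compound_id: str
    chamber: int
    nmol_donor_0: float
    nmol_donor_end: float
    nmol_membrane_end: float
    nmol_acceptor_end: float  # sampling-corrected cumulative
    nmol_removed_acceptor: float = 0.0


def q_dep(amounts: CompartmentAmounts) -> float:
    """Percent of the initial donor amount deposited in the membrane."""
    if amounts.nmol_donor_0 <= 0:
        raise ValueError("initial donor amount must be positive")
    return 100.0 * amounts.nmol_membrane_end / amounts.nmol_donor_0


def q_perm(amounts: CompartmentAmounts) -> float:
    """Percent of the initial donor amount found in the acceptor at the end."""
    if amounts.nmol_donor_0 <= 0:
        raise ValueError("initial donor amount must be positive")
    return 100.0 * amounts.nmol_acceptor_end / amounts.nmol_donor_0


def transport_index(amounts: CompartmentAmounts) -> float:
    """TI = Q_DEP + Q_PERM."""
    return q_dep(amounts) + q_perm(amounts)


def q_dep_extract(amounts: CompartmentAmounts) -> float:
    """Membrane amount over (end donor + membrane) amounts, percent."""
    total = amounts.nmol_donor_end + amounts.nmol_membrane_end
    if total <= 0:
        raise ValueError("donor(end) + membrane(end) must be positive")
    # a proportion by construction; clamp float roundoff at the boundary
    return min(100.0 * amounts.nmol_membrane_end / total, 100.0)


def mfi(metabolite: CompartmentAmounts, precursor_nmol_donor_0: float) -> float:
    """Metabolite formation index: total metabolite recovered at the end
    (donor + membrane + acceptor) as percent of the precursor's initial
    donor amount."""
    if precursor_nmol_donor_0 <= 0:
        raise ValueError("precursor initial amount must be positive")
    total = (
        metabolite.nmol_donor_end
        + metabolite.nmol_membrane_end
        + metabolite.nmol_acceptor_end
    )
    return 100.0 * total / precursor_nmol_donor_0


# ---------------------------------------------------------------------------
# table -> amounts glue


def _conc_uM(table: FeatureTable, fid: str, sample: str, curve: CalibrationCurve) -> float:
    return quantify(table.height(fid, sample), curve).censored_conc_nM / 1000.0


def amounts_from_table(
    table: FeatureTable,
    matches: dict[str, str | None],
    curves: dict[str, CalibrationCurve],
    design: ExperimentDesign,
    extract_volume: float,
    chambers: list[int] | None = None,
) -> dict[str, list[CompartmentAmounts]]:
    """Quantify a feature table into per-chamber compartment amounts.

    Donor amounts are concentration x donor volume (t0 falls back to the
    stock mean when donor t0 aliquots are absent); the membrane extract
    concentration is multiplied back by the extract volume to give tissue
    nmol; the acceptor end amount is the sampling-corrected cumulative.
    """
    out: dict[str, list[CompartmentAmounts]] = {}
    acc_times = sorted({parse_sample_name(s)[1] for s in table.sample_ids("acceptor")})
    end = max(
        parse_sample_name(s)[1]
        for s in table.sample_ids("membrane") + table.sample_ids("donor")
    )
    if chambers is None:
        chambers = sorted({parse_sample_name(s)[2] for s in table.sample_ids("donor")})

    for cid, fid in matches.items():
        if fid is None or cid not in curves:
            continue
        curve = curves[cid]
        rows = []
        for ch in chambers:
            d0_ids = table.sample_ids("donor", time=0.0, replicate=ch)
            if not d0_ids:
                d0_ids = table.sample_ids("stock", time=0.0)
            d0 = float(np.mean([_conc_uM(table, fid, s, curve) for s in d0_ids]))
            dend_ids = table.sample_ids("donor", time=end, replicate=ch)
            dend = (
                float(np.mean([_conc_uM(table, fid, s, curve) for s in dend_ids]))
                if dend_ids
                else 0.0
            )
            mem_ids = table.sample_ids("membrane", time=end, replicate=ch)
            mem = (
                float(np.mean([_conc_uM(table, fid, s, curve) for s in mem_ids]))
                if mem_ids
                else 0.0
            )
            acc_series = np.array(
                [
                    np.mean(
                        [
                            _conc_uM(table, fid, s, curve)
                            for s in table.sample_ids("acceptor", time=t, replicate=ch)
                        ]
                    )
                    if table.sample_ids("acceptor", time=t, replicate=ch)
                    else 0.0
                    for t in acc_times
                ]
            )
            if acc_series.size:
                q, _ = correct_sampling(
                    np.array(acc_times), acc_series,
                    design.acceptor_volume, design.acceptor_aliquot,
                )
                acc_end = float(q[-1])
                removed = float(q[-1] - acc_series[-1] * design.acceptor_volume)
            else:
                acc_end, removed = 0.0, 0.0
            rows.append(
                CompartmentAmounts(
                    compound_id=cid,
                    chamber=ch,
                    nmol_donor_0=d0 * design.donor_volume,
                    nmol_donor_end=dend * design.donor_volume,
                    nmol_membrane_end=mem * extract_volume,
                    nmol_acceptor_end=acc_end,
                    nmol_removed_acceptor=removed,
                )
            )
        out[cid] = rows
    return out


# ---------------------------------------------------------------------------
# viability gating


@dataclass
class ViabilityReport:
    chamber: int
    min_teer: float
    viable: bool


def teer_gate(traces: list[TEERTrace], threshold: float = 15.0) -> list[ViabilityReport]:
    """Mark chambers whose TEER ever drops below the threshold as non-viable.

    The rule is strict ("below"): a chamber sitting exactly at the
    threshold remains viable; a single dip under it excludes the chamber
    from all downstream metrics.
    """
    return [
        ViabilityReport(t.chamber, t.min_teer, t.min_teer >= threshold) for t in traces
    ]
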