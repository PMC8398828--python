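"""End-to-end scenario analysis: simulate, measure, calibrate, quantify.

Glue that runs a :class:`~ussingkit.scenarios.Scenario` through the whole
analysis chain exactly as a real run would be processed: the measured
feature table is target-matched, an external calibration curve is fitted
per compound from (simulated) calibration series, heights are quantified
into molar amounts per chamber, and the transport metrics / permeability
fits are computed from those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve, fit_calibration, simulate_calibration
from .design import MeasurementModel
from .feature_tables import FeatureTable, TargetList, match_targets, parse_sample_name
from .permeation import (
    CompartmentAmounts,
    PermeabilityFit,
    amounts_from_table,
    estimate_papp,
)
from .scenarios import Scenario
from .semiquant import RatioKind, RatioResult, compute_all_ratios

DEFAULT_CALIBRATION_LEVELS = (2.0, 5.0, 10.0, 20.0, 50.0)  # nM


def fit_scenario_calibration(
    scenario: Scenario,
    model: MeasurementModel,
    levels_nM: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS,
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, CalibrationCurve]:
    """One external-calibration curve per monitored compound."""
    curves = {}
    for k, spec in enumerate(scenario.compounds):
        responses = simulate_calibration(
            np.asarray(levels_nM), model.response_factor, noise_cv,
            n_replicates, seed=seed + k,
        )
        curves[spec.id] = fit_calibration(np.asarray(levels_nM), responses, spec.id)
    return curves


@dataclass
class ScenarioAnalysis:
    scenario: Scenario
    model: MeasurementModel
    table: FeatureTable
    matches: dict[str, str | None]
    curves: dict[str, CalibrationCurve]
    amounts: dict[str, list[CompartmentAmounts]]
    ratios: dict[str, dict[RatioKind, RatioResult]]

    def mean_amounts(self, compound_id: str) -> CompartmentAmounts:
        """Chamber-averaged amounts for one compound."""
        rows = self.amounts[compound_id]
        return CompartmentAmounts(
            compound_id=compound_id,
            chamber=0,
            nmol_donor_0=float(np.mean([a.nmol_donor_0 for a in rows])),
            nmol_donor_end=float(np.mean([a.nmol_donor_end for a in rows])),
            nmol_membrane_end=float(np.mean([a.nmol_membrane_end for a in rows])),
            nmol_acceptor_end=float(np.mean([a.nmol_acceptor_end for a in rows])),
        )

    def papp(self, compound_id: str, window: tuple[float, float] = (20.0, 80.0),
             correct: bool = True) -> PermeabilityFit:
        """Apparent permeability of one compound from the measured table."""
        fid = self.matches[compound_id]
        if fid is None:
            raise ValueError(f"{compound_id!r} unmatched")
        curve = self.curves[compound_id]
        design = self.scenario.design
        times = np.asarray(design.sampling_times)
        chambers = sorted(
            {parse_sample_name(s)[2] for s in self.table.sample_ids("acceptor")}
        )
        from .calibration import quantify

        conc = np.array([
            [
                np.mean([
                    quantify(self.table.height(fid, s), curve).censored_conc_nM / 1e3
                    for s in self.table.sample_ids("acceptor", time=t, replicate=ch)
                ])
                for t in times
            ]
            for ch in chambers
        ])
        c0_vals = []
        for ch in chambers:
            ids = self.table.sample_ids("donor", time=0.0, replicate=ch)
            if not ids:
                ids = self.table.sample_ids("stock", time=0.0)
            c0_vals.append(np.mean([
                quantify(self.table.height(fid, s), curve).censored_conc_nM / 1e3
                for s in ids
            ]))
        return estimate_papp(times, conc, design, float(np.mean(c0_vals)),
                             compound_id=compound_id, window=window, correct=correct)


def analyze_scenario(
    scenario: Scenario,
    model: MeasurementModel | None = None,
    calibration_noise_cv: float = 0.0,
    seed: int = 0,
) -> ScenarioAnalysis:
    """Run the full measurement-and-analysis chain on a scenario."""
    model = model or MeasurementModel(seed=seed)
    table = scenario.measure(model)
    matches = match_targets(table, TargetList(entries=scenario.compounds))
    curves = fit_scenario_calibration(scenario, model,
                                      noise_cv=calibration_noise_cv, seed=seed)
    amounts = amounts_from_table(table, matches, curves, scenario.design,
                                 model.extract_volume)
    ratios = compute_all_ratios(table, matches)
    return ScenarioAnalysis(scenario, model, table, matches, curves, amounts, ratios)
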