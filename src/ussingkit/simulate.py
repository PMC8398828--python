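"""Forward model of an Ussing-chamber run: kinetics, sampling, measurement, TEER.

The compartment system per compound (donor concentration C_D in uM, membrane
amount M in nmol, acceptor concentration C_A in uM) is

    dC_D/dt = -(P*A/V_D)*C_D - k_dep*C_D - k_hyd*C_D - k_OH*C_D + inbound
    dM/dt   =  k_dep*C_D*V_D - k_rel*M
    dC_A/dt =  (P*A/V_A)*C_D + k_rel*M/V_A

where inbound collects mole-for-mole production from precursors hydrolysed or
hydroxylated in the donor (both compartments share the donor volume, so
concentrations add directly).  P is the generating permeability in cm/s,
converted once to cm/min.  Cumulative converted-in/out ledgers are integrated
alongside the state so mass balance closes to integrator accuracy.

Sampling events are instantaneous: the pre-withdrawal state is snapshotted
(that is what the aliquot measures), the aliquot volume is removed, and the
compartment is refilled either with fresh buffer (dilution) or with stock
solution (donor re-spiked at the initial concentrations).  No event is applied
at the final sampling time - the compartments are simply collected.

Integration is fixed-step classical 4th-order Runge-Kutta at 0.1 min.  Between
events the system is linear and autonomous, for which the classical RK4 step
equals the degree-4 Taylor polynomial of the matrix exponential; the step map
R = sum_{i<=4} (hK)^i / i!  is therefore built once and applied per step,
which is algebraically identical to stepwise RK4.
"""

from __future__ import annotations

import math

import numpy as np

from .design import (
    CompoundSpec,
    ExperimentDesign,
    KineticParams,
    MeasurementModel,
    ReplacementPolicy,
    TEERTrace,
    TrueState,
)
from .feature_tables import FeatureTable, sample_name

SECONDS_PER_MINUTE = 60.0
DEFAULT_DT = 0.1  # min


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integrator produces a negative state."""


def _build_generator(
    design: ExperimentDesign,
    compounds: list[CompoundSpec],
    kinetics: KineticParams,
) -> np.ndarray:
    """Assemble the linear generator K for the stacked state.

    State layout per compound i: [C_D, M, C_A, X_out, X_in] at indices
    5i .. 5i+4, with X_* the cumulative converted ledgers in nmol.
    """
    ids = [c.id for c in compounds]
    n = len(ids)
    vd, va, area = design.donor_volume, design.acceptor_volume, design.exposed_area
    K = np.zeros((5 * n, 5 * n))
    for i, spec in enumerate(compounds):
        k = kinetics[spec.id]
        perm = k.papp_true * SECONDS_PER_MINUTE * area  # mL/min (cm^3/min)
        loss = perm / vd + k.k_deposit + k.k_hydrolysis + k.k_hydroxylation
        K[5 * i + 0, 5 * i + 0] = -loss
        K[5 * i + 1, 5 * i + 0] = k.k_deposit * vd
        K[5 * i + 1, 5 * i + 1] = -k.k_release
        K[5 * i + 2, 5 * i + 0] = perm / va
        K[5 * i + 2, 5 * i + 1] = k.k_release / va
        K[5 * i + 3, 5 * i + 0] = (k.k_hydrolysis + k.k_hydroxylation) * vd
        for rate, product in (
            (k.k_hydrolysis, k.hydrolysis_product),
            (k.k_hydroxylation, k.hydroxylation_product),
        ):
            if product is None or rate == 0.0:
                continue
            if product not in ids:
                raise ValueError(f"unknown reaction product {product!r} for {spec.id!r}")
            j = ids.index(product)
            K[5 * j + 0, 5 * i + 0] += rate
            K[5 * j + 4, 5 * i + 0] += rate * vd
    return K


def _rk4_step_map(K: np.ndarray, dt: float) -> np.ndarray:
    """One classical RK4 step of x' = Kx as a matrix (degree-4 Taylor of expm)."""
    dim = K.shape[0]
    R = np.eye(dim)
    term = np.eye(dim)
    for i in range(1, 5):
        term = term @ (dt * K) / i
        R = R + term
    return R


def simulate_kinetics(
    design: ExperimentDesign,
    compounds: list[CompoundSpec],
    kinetics: KineticParams,
    dt: float = DEFAULT_DT,
) -> TrueState:
    """Deterministic solution of the compartment system with sampling events.

    Returns the :class:`~ussingkit.design.TrueState` holding dense
    trajectories, pre-withdrawal snapshots at each sampling time, and the
    removal/replacement/conversion ledgers.
    """
    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    n = len(ids)
    samp = np.asarray(design.sampling_times, dtype=float)
    # align the grid with sampling times
    for t in samp:
        if abs(round(t / dt) * dt - t) > 1e-9:
            raise ValueError(f"sampling time {t} min is not a multiple of dt={dt}")
    n_steps = int(round(samp[-1] / dt))
    grid = np.arange(n_steps + 1) * dt
    event_steps = {int(round(t / dt)): j for j, t in enumerate(samp)}

    K = _build_generator(design, compounds, kinetics)
    R = _rk4_step_map(K, dt)

    c0 = np.array([c.initial_donor_conc for c in compounds])
    x = np.zeros(5 * n)
    x[0::5] = c0

    vd, va = design.donor_volume, design.acceptor_volume
    v_don, v_acc = design.donor_aliquot, design.acceptor_aliquot
    stock_donor = design.donor_replacement is ReplacementPolicy.STOCK_SOLUTION

    n_samp = samp.size
    traj = np.zeros((n_steps + 1, 5 * n))
    sampled_d = np.zeros((n, n_samp))
    sampled_a = np.zeros((n, n_samp))
    sampled_m = np.zeros((n, n_samp))
    removed_d = np.zeros((n, n_samp))
    removed_a = np.zeros((n, n_samp))
    added_d = np.zeros((n, n_samp))
    conv_out = np.zeros((n, n_samp))
    conv_in = np.zeros((n, n_samp))
    cum_rd = np.zeros(n)
    cum_ra = np.zeros(n)
    cum_ad = np.zeros(n)

    for step in range(n_steps + 1):
        if np.min(x[0::5]) < -1e-9 or np.min(x[1::5]) < -1e-9 or np.min(x[2::5]) < -1e-9:
            raise IntegrationError(
                "negative compartment state: reduce the step size or the rates"
            )
        if step in event_steps:
            j = event_steps[step]
            sampled_d[:, j] = x[0::5]
            sampled_a[:, j] = x[2::5]
            sampled_m[:, j] = x[1::5]
            conv_out[:, j] = x[3::5]
            conv_in[:, j] = x[4::5]
            if step != n_steps:  # final time: collect only, no replacement
                cum_ra += x[2::5] * v_acc
                x[2::5] *= (va - v_acc) / va
                cum_rd += x[0::5] * v_don
                x[0::5] *= (vd - v_don) / vd
                if stock_donor:
                    x[0::5] += c0 * v_don / vd
                    cum_ad += c0 * v_don
            removed_d[:, j] = cum_rd
            removed_a[:, j] = cum_ra
            added_d[:, j] = cum_ad
        traj[step] = x
        if step != n_steps:
            x = R @ x

    return TrueState(
        compounds=ids,
        grid_times=grid,
        donor_conc=traj[:, 0::5].T.copy(),
        membrane_amount=traj[:, 1::5].T.copy(),
        acceptor_conc=traj[:, 2::5].T.copy(),
        sampling_times=samp,
        sampled_donor_conc=sampled_d,
        sampled_acceptor_conc=sampled_a,
        sampled_membrane_amount=sampled_m,
        removed_donor=removed_d,
        removed_acceptor=removed_a,
        added_donor=added_d,
        converted_out=conv_out,
        converted_in=conv_in,
        donor_volume=vd,
        acceptor_volume=va,
        initial_donor_nmol=c0 * vd,
    )


def apply_measurement(
    true_state: TrueState,
    design: ExperimentDesign,
    model: MeasurementModel,
    compounds: list[CompoundSpec],
) -> FeatureTable:
    """Turn the latent state into an aligned LC-MS feature table.

    One sample column per (compartment, time, replicate): stock-solution
    analytical replicates, donor and acceptor aliquots at every sampling
    time for each chamber, membrane extracts at the end time, and blank
    membranes.  Peak height = response_factor x concentration x
    lognormal(1, noise_cv); heights below the censor floor are absent.
    Reproducible under the model seed.
    """
    rng = np.random.default_rng(model.seed)
    ids = true_state.compounds
    order = {cid: k for k, cid in enumerate(ids)}
    spec_by_id = {c.id: c for c in compounds}
    end = float(true_state.sampling_times[-1])

    columns: list[str] = []
    conc_cols: list[np.ndarray] = []  # uM per compound, in table row order

    c0 = np.array([spec_by_id[cid].initial_donor_conc for cid in ids])
    for r in range(1, model.n_stock_replicates + 1):
        columns.append(sample_name("stock", 0.0, r))
        conc_cols.append(c0)
    for j, t in enumerate(true_state.sampling_times):
        for r in range(1, design.n_replicates + 1):
            columns.append(sample_name("donor", float(t), r))
            conc_cols.append(true_state.sampled_donor_conc[:, j])
            columns.append(sample_name("acceptor", float(t), r))
            conc_cols.append(true_state.sampled_acceptor_conc[:, j])
    for r in range(1, design.n_replicates + 1):
        columns.append(sample_name("membrane", end, r))
        conc_cols.append(true_state.sampled_membrane_amount[:, -1] / model.extract_volume)
    blank = np.zeros(len(ids))
    for cid, height in model.blank_interference.items():
        if cid in order:
            blank[order[cid]] = height / model.response_factor
    for r in range(1, model.n_blank_replicates + 1):
        columns.append(sample_name("blank_membrane", end, r))
        conc_cols.append(blank)

    conc = np.column_stack(conc_cols)  # (n_compounds, n_samples)
    heights = model.response_factor * conc
    if model.noise_cv > 0:
        sigma = math.sqrt(math.log1p(model.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=heights.shape)
        heights = heights * noise
    heights = np.where(heights < model.lod_height, np.nan, heights)

    features = [
        (f"F{k + 1:03d}", spec_by_id[cid].mz, spec_by_id[cid].rt)
        for k, cid in enumerate(ids)
    ]
    return FeatureTable.from_arrays(features, columns, heights)


def simulate_teer(
    design: ExperimentDesign,
    baseline: float,
    decay_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    chamber: int = 1,
) -> TEERTrace:
    """Per-minute TEER trace: baseline*exp(-decay_rate*t) + noise, floored at 0."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, design.duration + 1.0)
    r = baseline * np.exp(-decay_rate * times)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=times.size)
    return TEERTrace(chamber=chamber, times=times, resistance=np.maximum(r, 0.0))
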