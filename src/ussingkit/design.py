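"""Domain types describing one Ussing-chamber permeation experiment.

An Ussing chamber clamps a living piece of intestinal epithelium (here
porcine jejunum, 1.26 cm^2 exposed) between a *donor* and an *acceptor*
compartment, each holding 7 mL of oxygenated Krebs-Bicarbonate Ringer
buffer.  The test solution (a pure standard or a plant extract) is placed
in the donor; aliquots are withdrawn from both sides on a fixed schedule
and replaced (by stock solution on the donor side, by fresh buffer on the
acceptor side), and the tissue is extracted at the end of the run to
measure membrane-retained amounts.  Tissue viability is monitored through
the transepithelial electrical resistance (TEER).

Internal unit conventions: concentrations in uM, amounts in nmol, volumes
in mL, time in minutes.  Apparent permeability (P_app) is carried in cm/s
and converted to per-minute rate constants only inside the simulator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator


class Compartment(str, enum.Enum):
    STOCK = "stock"
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    MEMBRANE = "membrane"
    BLANK_MEMBRANE = "blank_membrane"
    BLANK_BUFFER = "blank_buffer"
    CALIBRATION = "calibration"


class ReplacementPolicy(str, enum.Enum):
    """What refills a compartment after an aliquot is withdrawn."""

    STOCK_SOLUTION = "stock_solution"
    FRESH_BUFFER = "fresh_buffer"


class CompoundClass(str, enum.Enum):
    C_GLYCOSIDE = "C_glycoside"
    O_GLYCOSIDE = "O_glycoside"
    MALONYL_O_GLYCOSIDE = "malonyl_O_glycoside"
    AGLYCONE = "aglycone"
    OTHER = "other"


class ExperimentDesign(BaseModel):
    """Geometry, volumes and sampling protocol of one chamber run.

    Defaults follow the porcine-jejunum protocol: 7 mL per compartment,
    1.26 cm^2 exposed area, sampling at 0/10/20/40/60/80/100 min with
    400 uL acceptor aliquots replaced by fresh buffer and donor aliquots
    replaced by stock solution (0.2 mL for extract runs, 0.1 mL for
    pure-standard runs), four chamber replicates, and a 15 Ohm*cm^2 TEER
    viability floor.
    """

    donor_volume: float = Field(default=7.0, gt=0, description="mL")
    acceptor_volume: float = Field(default=7.0, gt=0, description="mL")
    exposed_area: float = Field(default=1.26, gt=0, description="cm^2")
    sampling_times: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    donor_aliquot: float = Field(default=0.2, ge=0.0, description="mL")
    acceptor_aliquot: float = Field(default=0.4, ge=0.0, description="mL")
    donor_replacement: ReplacementPolicy = ReplacementPolicy.STOCK_SOLUTION
    acceptor_replacement: ReplacementPolicy = ReplacementPolicy.FRESH_BUFFER
    n_replicates: int = Field(default=4, ge=1)
    teer_threshold: float = Field(default=15.0, ge=0.0, description="Ohm*cm^2")

    @property
    def duration(self) -> float:
        """Run length in minutes (= last sampling time)."""
        return float(self.sampling_times[-1])

    @field_validator("sampling_times")
    @classmethod
    def _times_increasing_from_zero(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        t = np.asarray(v, dtype=float)
        if t.size < 2:
            raise ValueError("need at least two sampling times")
        if t[0] != 0.0:
            raise ValueError("sampling_times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        return tuple(float(x) for x in t)

    @model_validator(mode="after")
    def _aliquots_fit(self) -> "ExperimentDesign":
        if self.donor_aliquot >= self.donor_volume:
            raise ValueError("donor aliquot must be smaller than donor volume")
        if self.acceptor_aliquot >= self.acceptor_volume:
            raise ValueError("acceptor aliquot must be smaller than acceptor volume")
        return self


class CompoundSpec(BaseModel):
    """A monitored analyte: LC-MS coordinates plus its role in the run.

    ``initial_donor_conc`` is the concentration in the stock solution that
    fills the donor at t = 0 (0 for a compound formed only by the tissue,
    i.e. a pure intestinal metabolite).
    """

    id: str
    name: str = ""
    mz: float = Field(gt=0, description="m/z of [M+H]+ (Th)")
    rt: float = Field(ge=0, description="retention time, min")
    mw: float = Field(gt=0, description="g/mol")
    compound_class: CompoundClass = CompoundClass.OTHER
    initial_donor_conc: float = Field(default=0.0, ge=0.0, description="uM")


class CompoundKinetics(BaseModel):
    """First-order rate constants governing one compound's fate.

    ``papp_true`` is the generating transmembrane permeability (cm/s);
    ``k_deposit``/``k_release`` exchange material between donor and tissue;
    ``k_hydrolysis`` models intestinal beta-glucosidase cleavage of an
    O-glycoside into its aglycone (``hydrolysis_product``), observed as a
    donor-compartment loss feeding the product's donor pool;
    ``k_hydroxylation`` models CYP-type oxidation into a +O product.
    All rate constants are per minute.
    """

    papp_true: float = Field(default=0.0, ge=0.0, description="cm/s")
    k_deposit: float = Field(default=0.0, ge=0.0, description="1/min")
    k_release: float = Field(default=0.0, ge=0.0, description="1/min")
    k_hydrolysis: float = Field(default=0.0, ge=0.0, description="1/min")
    hydrolysis_product: str | None = None
    k_hydroxylation: float = Field(default=0.0, ge=0.0, description="1/min")
    hydroxylation_product: str | None = None


class KineticParams(BaseModel):
    """Rate constants per compound id, with an acyclic product graph."""

    rates: dict[str, CompoundKinetics] = Field(default_factory=dict)

    def __getitem__(self, compound_id: str) -> CompoundKinetics:
        return self.rates.get(compound_id, CompoundKinetics())

    @model_validator(mode="after")
    def _acyclic_products(self) -> "KineticParams":
        edges: dict[str, set[str]] = {}
        for cid, k in self.rates.items():
            out = set()
            if k.hydrolysis_product is not None and k.k_hydrolysis > 0:
                out.add(k.hydrolysis_product)
            if k.hydroxylation_product is not None and k.k_hydroxylation > 0:
                out.add(k.hydroxylation_product)
            edges[cid] = out
        # DFS cycle check over the reaction-product graph
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {cid: WHITE for cid in edges}

        def visit(u: str) -> None:
            colour[u] = GREY
            for v in edges.get(u, ()):
                if colour.get(v, WHITE) == GREY:
                    raise ValueError(f"reaction product graph has a cycle through {v!r}")
                if colour.get(v, WHITE) == WHITE and v in edges:
                    visit(v)
            colour[u] = BLACK

        for cid in edges:
            if colour[cid] == WHITE:
                visit(cid)
        return self


class MeasurementModel(BaseModel):
    """Proportional-response LC-MS measurement with LOD censoring.

    Peak height = response_factor x concentration x lognormal(1, noise_cv);
    heights below ``lod_height`` are censored to absent.  The default
    response factor and censor floor put the limit of detection at ~3 nM,
    matching the few-nM LODs typical of untargeted high-resolution MS of
    isoflavones.  The membrane extract is measured as (total tissue nmol /
    ``extract_volume``), so amounts are recovered by multiplying back.
    """

    response_factor: float = Field(default=5.0e6, gt=0, description="height per uM")
    noise_cv: float = Field(default=0.0, ge=0.0)
    lod_height: float = Field(default=1.5e4, ge=0.0)
    seed: int = 0
    extract_volume: float = Field(default=2.0, gt=0, description="mL")
    n_stock_replicates: int = Field(default=3, ge=1)
    n_blank_replicates: int = Field(default=3, ge=1)
    # optional endogenous interference: compound id -> blank-membrane height
    blank_interference: dict[str, float] = Field(default_factory=dict)


@dataclass
class TEERTrace:
    """Per-minute transepithelial resistance of one chamber (Ohm*cm^2)."""

    chamber: int
    times: np.ndarray
    resistance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.times.shape != self.resistance.shape:
            raise ValueError("times and resistance must have the same length")
        if np.any(self.resistance < 0):
            raise ValueError("resistance must be non-negative")

    @property
    def min_teer(self) -> float:
        return float(np.min(self.resistance))


@dataclass
class TrueState:
    """Latent state of a simulated run, the ground truth the pipeline estimates.

    Dense trajectories are stored on the integration grid (values after any
    sampling event at that instant); ``sampled_*`` arrays hold the
    pre-withdrawal snapshots at each sampling time, which is what an aliquot
    actually measures.  Ledger arrays (cumulative nmol, evaluated at the
    sampling times) close the mass balance:

        initial + added_donor + converted_in
            = donor + membrane + acceptor (nmol in system)
              + removed_donor + removed_acceptor + converted_out
    """

    compounds: list[str]
    grid_times: np.ndarray
    donor_conc: np.ndarray  # (n_compounds, n_grid) uM
    membrane_amount: np.ndarray  # nmol
    acceptor_conc: np.ndarray  # uM
    sampling_times: np.ndarray
    sampled_donor_conc: np.ndarray  # (n_compounds, n_samp) uM, pre-withdrawal
    sampled_acceptor_conc: np.ndarray
    sampled_membrane_amount: np.ndarray  # nmol
    removed_donor: np.ndarray  # (n_compounds, n_samp) cumulative nmol
    removed_acceptor: np.ndarray
    added_donor: np.ndarray  # nmol re-injected by stock replacement
    converted_out: np.ndarray  # nmol consumed by reactions
    converted_in: np.ndarray  # nmol formed by reactions
    donor_volume: float
    acceptor_volume: float
    initial_donor_nmol: np.ndarray = field(default=None)  # type: ignore[assignment]

    def index(self, compound_id: str) -> int:
        return self.compounds.index(compound_id)

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance defect per compound and sampling time.

        Normalised by the largest amount ever present in the lineage so
        compounds that start at zero (pure metabolites) are handled.
        """
        in_system = (
            self.sampled_donor_conc * self.donor_volume
            + self.sampled_membrane_amount
            + self.sampled_acceptor_conc * self.acceptor_volume
        )
        # ledgers are post-event; at snapshot k the events of time k have not
        # yet been applied, so use the ledgers from the previous event.
        rem_d = np.concatenate([np.zeros((len(self.compounds), 1)), self.removed_donor[:, :-1]], axis=1)
        rem_a = np.concatenate([np.zeros((len(self.compounds), 1)), self.removed_acceptor[:, :-1]], axis=1)
        add_d = np.concatenate([np.zeros((len(self.compounds), 1)), self.added_donor[:, :-1]], axis=1)
        supplied = self.initial_donor_nmol[:, None] + add_d + self.converted_in
        accounted = in_system + rem_d + rem_a + self.converted_out
        scale = np.maximum(np.max(supplied, axis=1, keepdims=True), 1e-12)
        return (supplied - accounted) / scale
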