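# Methods

## The experiment being modelled

A segment of porcine jejunum is mounted in an Ussing chamber between two
7 mL compartments of oxygenated Krebs-Bicarbonate Ringer buffer, exposing
1.26 cm² of epithelium. The donor side receives the test solution — a pure
isoflavone standard (100 µM) or a plant-extract solution (e.g. a kudzu-root
decoction at 200 µg/mL, in which the major constituents puerarin and daidzin
sit at 25.724 µM and 5.035 µM). Aliquots are withdrawn on a fixed schedule
(0, 10, 20, 40, 60, 80, 100 min; pure-standard runs add 120 min): 0.4 mL
from the acceptor, replaced by fresh buffer; 0.1–0.2 mL from the donor,
replaced by stock solution. At the end of the run the tissue is extracted to
measure membrane-retained amounts. Viability is tracked as transepithelial
electrical resistance (TEER); a chamber is discarded the moment its TEER
drops below 15 Ω·cm². Four chamber replicates per condition; stock solutions
are measured as analytical triplicates.

## Kinetic model

Per compound, with donor concentration `C_D` (µM), membrane amount `M`
(nmol) and acceptor concentration `C_A` (µM):

```
dC_D/dt = −(P·A/V_D)·C_D − k_dep·C_D − k_hyd·C_D − k_OH·C_D + inbound
dM/dt   =  k_dep·C_D·V_D − k_rel·M
dC_A/dt =  (P·A/V_A)·C_D + k_rel·M/V_A
```

`inbound` collects mole-for-mole production from precursors hydrolysed
(`k_hyd`, O-glycoside → aglycone) or hydroxylated (`k_OH`, +O product) in
the donor. All reactions are first order; the product graph must be acyclic.
Assumptions worth stating:

- transport is one-directional donor → acceptor (sink condition); back-flux
  is negligible at the concentration differentials of interest;
- hydrolysis is represented as a donor-compartment loss feeding the
  product's donor pool, consistent with aglycones appearing in the donor;
  whether the enzyme is brush-border or cytosolic is not resolved;
- malonyl-O-glycosides resist hydrolysis: their default rate is 10× lower
  than the plain O-glycoside default (0.0009 vs 0.009 min⁻¹; the plain
  default leaves ~40% of the glycoside after 100 min).

Units are µM / nmol / mL / min internally; the permeability `P` is carried
in cm/s and converted once (×60) where it enters the rate matrix.

### Integration and sampling events

The system between sampling events is linear and time-invariant, so the
fixed-step classical Runge-Kutta scheme (0.1 min steps) reduces to a
constant step matrix `R = Σ_{i≤4} (hK)^i/i!` applied per step — the exact
RK4 map for a linear autonomous system, built once per run. Cumulative
converted-in/out ledgers are integrated as extra state rows, so the mass
balance

```
initial + stock re-injections + converted-in
  = in-system + withdrawn + converted-out
```

closes to integrator accuracy (observed ≲ 1e-13 relative; the test suite
enforces ≤ 1e-3). At each sampling time the pre-withdrawal state is
snapshotted (that is what the aliquot measures), the aliquot volume is
removed, and the compartment is refilled — by fresh buffer (pure dilution
by `(V−v)/V`) or by stock solution (donor re-spiked at the initial
concentrations). No withdrawal is applied at the final time; the
compartments are simply collected. A negative state (possible only with
rates far outside the physiological range at this step size) raises an
integration error rather than propagating.

### Measurement model

Peak height = response factor × concentration × lognormal(1, CV). The
default response factor (5×10⁶ counts/µM) and censor floor (1.5×10⁴ counts)
put the LOD near 3 nM, matching the few-nM limits typical of untargeted
high-resolution MS of isoflavones. Heights below the floor are absent
(empty cells). The membrane extract is simulated as total tissue nmol
divided by a nominal 2 mL extract volume; the pipeline multiplies back.
Multiplicative lognormal noise was chosen because peak heights are positive
and CV-stable across the calibrated range. Blank membranes carry no study
compounds by default; an interference option injects chosen heights to
exercise blank subtraction. Identical seeds give byte-identical tables.

The measurement model applies noise per sample but shares one kinetic truth
across chambers: inter-chamber biological variability (tissue-to-tissue
permeability differences) is *not* modelled, so replicate scatter in
synthetic data reflects measurement noise only. Passing recovery tests
therefore demonstrate correctness of the estimators, not robustness to
biological heterogeneity, RT drift, matrix effects or saturation — none of
which the generator emulates.

## Analysis pipeline choices

- **Targeted matching**: |Δm/z|/mz ≤ 5 ppm and |ΔRT| ≤ 0.1 min (the RT
  tolerance is a package default — peak-picking tools rarely publish one —
  and is configurable). Greedy one-to-one assignment by ppm error, ties by
  |ΔRT|, so a single feature cannot quantify two isomers.
- **Ratios**: computed within chamber (the chamber is the experimental
  unit), then aggregated as mean ± SD with CV; time-0 denominators use the
  mean of the donor-t0 aliquots, falling back to the stock triplicates.
  Mean-of-ratios was chosen over ratio-of-means and is what the SD refers
  to. A censored numerator contributes 0 with a status flag (dropping it
  would bias means upward); a censored denominator leaves the ratio
  undefined.
- **Permeant call**: acceptor(end)/donor(0) mean ratio ≥ 0.1% with a clean
  (uncensored) numerator. The 0.1% floor is the detectability argument used
  to size donor concentrations.
- **Calibration**: per-replicate OLS lines; pooled slope = mean of slopes;
  σ = SD of replicate y-intercepts; LOD = 3.3σ/S, LOQ = 10σ/S (the
  standard multipliers of the response-SD/slope method). With a single
  series the residual SD substitutes and the curve is flagged. Below-LOD
  quantifications keep their raw value for diagnostics but count as 0 in
  amount sums; between LOD and LOQ they are flagged and used.
- **Sampling correction**: cumulative-amount method
  `Q_n = c_n·V + Σ_{i<n} c_i·v`; the equivalent concentration `Q_n/V` feeds
  the P_app regression. A naive (uncorrected) mode exists for sensitivity
  comparison and demonstrably underestimates the slope.
- **P_app**: free-intercept least squares over the 20–80 min window
  (endpoints inclusive — points at 20, 40, 60, 80 min), so lag time is
  absorbed by the intercept; V in the definition is the donor volume, as
  the quantity is conventionally defined (donor and acceptor volumes are
  equal here). C₀ is the *measured* donor-t0/stock concentration, not the
  nominal one.
- **Fate classification** decision order: blank interference → excluded;
  permeant call → permeant; absent at t0 but present at 100 min →
  intestinal metabolite; donor end/start within the stability band
  [80%, 120%] → stable (membrane retention appended as evidence when the
  membrane ratio clears 0.1%); below the band → depleted precursor; above
  the band → hydroxylation product if exactly one oxygen (15.9949 Da,
  5 ppm) heavier than a monitored compound, else intestinal metabolite.
  The stability band is a package default anchored loosely to the observed
  84–100% range of stable glycosides, not an authors' rule.

## Study scenarios and rate calibration

Published end-point values (membrane-deposited fractions, donor survival,
aglycone end concentrations) do not identify rate constants directly, so
the scenario builders calibrate them by root-finding (Brent's method) on
the noise-free simulator: e.g. `k_dep` of pure puerarin is tuned until the
*true* membrane fraction at 100 min equals 0.47% of the initial donor
amount; daidzin's `k_hyd` until true donor survival is 40%; for the
extract, (`k_hyd` of the glycoside, `k_dep` of the aglycone) are tuned
jointly — nested 1-D solves — so the aglycone's donor concentration at
100 min and its membrane/(donor+membrane) fraction hit the reported values
(1.544 µM and 5.38% for daidzein; 121 nM and 21.94% for genistein). The
recovery tests then re-derive these numbers through the full measurement
and analysis chain, which is the point: the estimators must invert the
forward model, including sampling and censoring, not merely echo inputs.

Genistin's concentration in the extract is not individually reported; the
scenario uses 0.3 µM — a realistic minor-constituent level well above the
LOD, and low enough that forming the reported 121 nM of genistein by
100 min depletes the genistin pool markedly, as observed for the
O-glucosides generally.

Problem sizes throughout (4 chambers, 7–8 sampling times, ≤ 5 compounds,
0.1 min integration steps) are the experiment's own dimensions; each
scenario simulates in milliseconds and the full acceptance recomputation
takes a few seconds.

## Numerical details and degenerate inputs

- Sampling times must lie on the integration grid (multiples of 0.1 min).
- `Q_DEP-extract` is clamped to ≤ 100% against float roundoff at the
  membrane-only boundary.
- Ratio of a sample against itself is exactly 100%; ratios are invariant
  under any positive rescaling of a compound's heights.
- A TEER exactly at 15 Ω·cm² is viable (the rule is "below").
- Calibration requires ≥ 3 levels and a positive slope; LOQ/LOD = 10/3.3
  for every fitted curve by construction.
- Root-finding brackets are wide (deposition 10⁻⁸–10⁻¹ min⁻¹, hydrolysis
  10⁻⁶–0.5 min⁻¹); the inner solve of the joint calibration saturates at
  its upper bound where the donor target is unreachable, keeping the outer
  solve bracketed.

## Known limitations

No spectral simulation (mzML, fragment spectra), no phase-2 conjugation,
no colon/microbiome compartment, no enterohepatic recirculation, no
chromatographic effects (RT drift, co-elution beyond exact-coordinate
features), no active-transport saturation — transport and reactions are
strictly first order. Compound identities are inputs: annotation,
molecular networking and structure elucidation are upstream concerns.
Whether donor stock replacement materially shifts measured donor
concentrations in real runs is not asserted; both replacement policies are
implemented.
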