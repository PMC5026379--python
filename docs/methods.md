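# Methods

This note documents the model implemented in `hepasim`, its numerical
treatment, the choices made where the design was genuinely open, and
what the synthetic data used by the tests do and do not establish.

## Whole-body scale

Ten compartments per compound hold molar amounts (mmol); flows are L/h,
time is hours. Every transfer is first order in its source amount:

| transfer | rate |
|---|---|
| gut lumen → gut | `kGutabs · A_gutlumen` |
| gut → liver | `QGut · A_gut / VGut` |
| liver → venous | `(QLiver+QGut) · A_liv · Rb2p / (Kl2p · Fup · VLiver)` |
| liver → metabolised | `CLmetab · A_liv / (Kl2p · Fup)` |
| venous → lung, lung → arterial | `QCardiac · A / V` |
| arterial → gut/liver/kidney/rest | `Q_organ · A_art / VArt` |
| kidney → venous | `QKidney · A_kid · Rb2p / (Kk2p · Fup · VKidney)` |
| kidney → tubules | `Qgfr · A_kid / (Kk2p · VKidney)` |
| rest → venous | `QRest · A_rest · Rb2p / (Kr2p · Fup · VRest)` |

The tubules and the metabolic sink are part of the state, so the total
derivative is identically zero and mass conservation is structural, not
numerical. The system is linear for first-order absorption; the
standalone simulator integrates it with LSODA (rtol 1e-8, atol 1e-10
mmol), and the coupled simulator propagates it exactly with a matrix
exponential per coupling step.

**Body weight.** The tabulated flows and volumes describe a 70 kg
reference adult. `pbpk_bw` acts allometrically: compartment volumes
scale as `bw/70`, blood flows as `(bw/70)^0.75`. In population and
sensitivity runs the prescribed dose is an absolute amount
(20 mg/kg × the *reference* weight), so a light individual concentrates
the same dose in smaller volumes and shows higher serum levels — which
is also why body weight is a top-ranked sensitivity.

**Standalone metabolite production.** The coupled model produces
conjugates mechanistically in the hepatocytes. In standalone whole-body
runs the lumped `CLmetab` flux is split 0.60 : 0.33 : 0.07 into the
glucuronide replicate's liver, the sulfate replicate's liver and an
untracked remainder (the fractions mirror typical human urinary
recovery). Only the remainder accumulates in the parent's metabolic
sink, so the three replicate systems jointly conserve moles.

**Saturable gut uptake.** Besides first-order absorption, a
`zero_order_lagged` variant models transporter-mediated uptake: zero
flux during a gastric-emptying lag (default 9 min when used), then
Michaelis–Menten flux whose `Km` is small against the lumen load, i.e.
effectively constant-rate absorption until the lumen empties.

## Tissue scale

One sinusoid: a 200 × 20 × 4 μm lumen (16 000 μm³) lined by 20
hepatocytes of 8 000 μm³ (10 axial ranks × 2 sides, ranks tile the
axis). Blood is discretised into parcels — RBCs of 400 μm³ and serum
portions of 100 μm³ — created at the periportal mouth and advected in
plug flow at 200 μm/s, giving exactly a 1 s transit. Parcel creation is
deterministic: volume credits accumulate at the inflow rate
(16 000 μm³/s) split by hematocrit (0.45), and a parcel is emitted
whenever a credit covers its volume; a second accumulator labels
parcels arterial/venous in a 1:3 volume ratio. On creation a parcel is
loaded from the blood concentration by the partition rule
`C_plasma = C_blood/Rb2p`, `C_rbc = (Rb2p − (1−hct))·C_plasma/hct`, so
volume-weighted recombination returns `C_blood`; compounds that do not
bind red cells (`Rb2p = 0.55 = 1−hct`) travel in plasma only.

Contact structure: a parcel touches its axial predecessor and successor
(within a 10 μm gap, about one RBC length) and the two hepatocytes —
one per side — whose rank spans its position. Hepatocytes touch the
parcels in their span; the fixed cells form no contact edges with each
other, so the tabulated hepatocyte-to-hepatocyte passive constant has
no active pairs in this geometry. Per ordered contact pair `(i→j)` the
moles moved in `dt` are `rate · V_i · dt` with:

- passive (APAP only): `k_PD_{T_i}2{T_j} · C_i / n_i`, where `n_i` is
  the source's neighbour count;
- active import (serum→hepatocyte only):
  `Vmax_AT · C_S / (C_S + Km_AT · Fup)`, per pair, undivided;
- conjugate export (hepatocyte→parcel): `k_AT_APAPG/S · C_H`, per pair,
  undivided — an export that scales with the number of passing parcels.

Transfers use explicit Euler at the native 16.7 ms cadence with a
conservative guard: if any entity would lose more than 20 % of a
compound in one step, the step halves recursively. Parcels crossing the
central-vein end are deleted and their content accumulates in the
outflow ledger. Each flow step performs creation (on its 33 ms
schedule), transfer, subcellular update, then advection, which gives
every axial rank identical per-parcel contact coverage.

The engine is bit-deterministic — identical inputs give identical
outputs — standing in for the observation that run-to-run stochastic
variation of an equivalent cellular-automaton realisation is far below
any quantity of interest.

## Cellular scale

Each hepatocyte holds six concentrations (mmol/L; time in seconds):
APAP, NAPQI, GSH, NAPQI-GSH, APAPG, APAPS, governed by

- `APAP → NAPQI` : `z · Vmax_2E1 · [APAP]/(Km_2E1 + [APAP])`, with the
  zonation factor `z = 0.8 + 0.2·rank/(n_ranks−1)` (a single-rank
  degenerate sinusoid uses 1.0);
- `NAPQI + GSH → NAPQI-GSH` : `k_NAPQIGSH · [NAPQI] · [GSH]`;
- `APAP → APAPG` and `APAP → APAPS` : Michaelis–Menten;
- `∅ → GSH` : `k_GSH · (GSH_max − [GSH])`.

Two printed units are reinterpreted for dimensional consistency and
documented prominently: `k_NAPQIGSH = 0.1` is used as L/mmol/s (the law
is second order) and `k_GSH = 1e-4` as 1/s (first order in the
deficit). Zonation applies to the CYP2E1 `Vmax` only; the Phase II
capacities are uniform. With no NAPQI the GSH trajectory has the closed
form `GSH_max − (GSH_max − GSH_0)·e^(−k·t)`, which the integrator must
match to 1e-8 — this is also one of the acceptance quantities.

## Scale bridge and coupling cycle

The liver contains `S = VLiver · f_lumen / V_sin` sinusoid replicates
(`f_lumen = 0.074`, giving `S ≈ 7.91e9` for the 1.71 L reference
liver). A bank of `S` sinusoids at 200 μm/s implies an effective
hepatic perfusion `S·Q_sin ≈ 456 L/h`; the arterial and portal-venous
compartments are debited at that rate, split in the `QLiver:QGut`
proportion of the compartment model, and parcels load the flow-weighted
mixed concentration (the 1:3 arterial:venous split only labels parcel
provenance). Everything reaching the central vein returns, scaled by
`S`, to the venous compartment. The effective perfusion exceeding the
nominal hepatic blood flow is a direct consequence of fixing the lumen
fraction, the sinusoid geometry and the flow speed simultaneously; the
bookkeeping conserves moles exactly either way, and this is the reading
under which the model reproduces human urinary recovery.

Each coupling step executes: (1) propagate the three PBPK replicates
(liver bypassed) with the diverted flows routed into a buffer state;
(2) form inflow blood concentrations from the arterial and gut
compartments; (3–5) create, advect and exchange parcels; (6) advance
every hepatocyte's reaction network; (7) drain the outflow, scale by
`S`, return to the venous compartment and reconcile the ledger. A
conservation check aborts the run if the global ledger drifts beyond
1e-6 relative (observed drift is ~1e-15).

**Quasi-steady mode (default).** A parcel's 1 s transit is four orders
of magnitude below whole-body dynamics, so per coupling step (default
10 s) the sinusoid is taken at the steady state for the current inflow
and frozen hepatocyte state. The steady state is computed by marching
one representative RBC/serum parcel pair down the axis at the native
16.7 ms cadence with the expected neighbour composition, accumulating
per-rank gross uptake and export rates whose ledger
(`outflow = inflow − 2·Σuptake + 2·Σexport`) is exact by construction.
The two sides of a rank are identical by symmetry, so ten ranks are
integrated and mirrored. Exchange rates enter the hepatocyte ODEs as
constant sources (LSODA over the step); the venous return enters the
PBPK propagation as a continuous source (the previous step's rate via
a precomputed `∫exp(As)ds` column) with the small step-to-step
difference reconciled as a lump, making the operator splitting second
order. **Explicit mode** runs the full parcel engine at its native
cadence (practical for sub-hour horizons); on a half-hour run the two
modes agree on every defined model output to better than 1 %, which is
the self-consistency oracle for both engines.

## Model outputs and analyses

The 15-entry output vector: RMSE of each serum curve against a
reference (linear interpolation of the simulation onto the reference
times; entries undefined without a reference), their sum, Cmax /
earliest-Tmax / trapezoidal AUC per compound, the excreted metabolic
ratio `(G+S)/(A+G+S)` over kidney-tubule amounts, and the `S`-scaled
total NAPQI-GSH over all hepatocytes. Zonal summaries average four
cells of one side in each of the periportal, midzonal and pericentral
thirds. Serum concentration is reported as `(A_ven/V_ven)/Rb2p`.

Sensitivities are one-sided (+25 %) by choice, matching the definition
`J_k = [(y(x+Δ)−y(x))/Δ]·[x/y(x)]`; an optional central-difference mode
exists but is off by default. Outputs whose base value is zero yield
undefined entries that are excluded from the `Average` row and from
matrix correlations. The default sensitivity/population subset is every
compound-dependent parameter at all three scales plus body weight and
hematocrit (44 names); the historically analysed subset (38 parameters)
is not published, so the membership is user-overridable and
cross-study comparisons of subset-dependent counts should be made with
care.

Populations multiply each subset parameter by an independent
`Normal(1, 0.25)` draw truncated to `[max(0.25, 1−3·cv), 1+3·cv]`
(bounds chosen to keep parameters positive within ±3 SD; the rejection
step discards <0.3 % of mass). Two physical caps apply after
multiplication: fraction-type parameters (unbound fractions,
hematocrit) cannot exceed 1, and initial GSH cannot exceed the
independently perturbed GSH ceiling. The outlier metric is the signed
area between an individual's serum APAP curve and the population mean
(no metric is canonical; signed area is robust to single-point noise).
Individuals are independent; results are invariant to execution order,
and failed individuals are excluded and reported, never silently
dropped.

## Synthetic reference data

No in vivo calibration points ship with the package. The reference
generator samples the model's own serum curves at chosen times and
optionally applies mean-one lognormal noise — sufficient for RMSE
plumbing, parameter-recovery exercises and sensitivity-of-fit analyses.
Passing tests therefore establish internal consistency (the model
recovers its own parameters; the fit error responds to parameters as
expected), not agreement with clinical data, except where the test pins
a quantity that is itself a published physiological figure (urinary
composition, GSH ceiling, transit time).

## Numerical choices and limitations

- Tolerances: LSODA rtol 1e-8 / atol 1e-10 mmol (whole body), rtol 1e-8
  / atol 1e-11 (hepatocytes in the coupled loop), rtol 1e-9 standalone.
- Tie-breaks: Tmax takes the earliest maximum; outlier ties take the
  lowest index.
- Degenerate inputs: zero dose short-circuits to zero output; a
  single-rank sinusoid uses the upper zonation value; an all-zero
  tubule vector makes the metabolic ratio undefined rather than zero.
- Parcel positions are quantised to the 16.7 ms grid; rank attribution
  uses a 1e-6 μm tolerance so accumulated rounding cannot flip a parcel
  sitting exactly on a span boundary.
- The sinusoid is one straight pipe representative of all sinusoids:
  no branching networks, no endothelium or space of Disse, no bile
  route, no lateral arterial/venous asymmetry (parcels contact both
  cell rows symmetrically).
- Overdose biology is out of scope: GSH never depletes enough to
  trigger necrosis pathways, and no necrosis model is included.
- Repeated dosing, enterohepatic recirculation and inhalation/IV routes
  are not modelled; dosing is a single oral bolus into the gut lumen.
- SBML export is an interchange convenience (deterministic XML with one
  reaction per rate law); the simulator integrates its own
  transcription of the equations and has no runtime SBML dependency.
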