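# Methods

## Degree-of-reduction calculus

Every species is an element→count map; the degree of reduction is
γ = Σₑ nₑ·εₑ with effective electron numbers ε(C)=+4, ε(H)=+1, ε(O)=−2.
Chlorine is assigned ε(Cl)=0: hydrogenolysis replaces one Cl with one H at
the cost of one H₂ (two electrons), so with ε(Cl)=0 each step is exactly
electron-neutral on the organic skeleton and the ledger reactions audit to
zero. This value is also the unique choice under which the published
electron recoveries of both CO-fed bottle inventories are reproduced from
their row inputs, with TCE counted as a γ=9 electron substrate; a test
solves the recovery identity for ε(Cl) and confirms 0 on both rows.
ε(N)=0 is shipped for convenience; no packaged species contains nitrogen.
All species are treated as neutral molecules (acetate is carried as acetic
acid), so charge never enters γ.

Formulas are parsed as a plain (symbol, count) sequence; repeated symbols
accumulate, so condensed spellings like `CH3COOH` parse to the same
composition as the Hill form `C2H4O2`. Unknown element symbols are errors,
never silently zero-weighted — likewise an element missing from the
electron-number scheme.

## Gibbs-energy ledger

ΔrG′° = Σ ν·ΔfG′° at 298.15 K, gases at 1 atm, solutes at 1 M, water
liquid. No pH-dependent (Legendre-transformed) correction is applied: the
ledger species are written as neutral molecules (CH₃COOH, HCl), so the
standard-state convention is the plain chemical one. The shipped constants
(CRC Handbook of Chemistry and Physics, 84th ed., one decimal) are

| species | phase | ΔfG′° (kJ/mol) |
|---|---|---|
| CO | g | −137.2 |
| CO₂ | g | −394.4 |
| H₂O | l | −237.1 |
| CH₄ | g | −50.5 |
| C₂H₄ | g | +68.4 |
| CH₃COOH | **l** | −389.9 |
| HCl | g | −95.3 |

With acetic acid as *liquid* these constants reproduce the ledger values
for the water-gas shift (−20.1), H₂/CO₂ acetogenesis (−75.3) and
hydrogenotrophic methanogenesis (−130.3) exactly at one decimal, which is
why the liquid value is the one shipped. No defensible ΔfG′° combination
reproduces the TCE hydrogenolysis row (−150.5) — the constants chosen for
aqueous TCE and HCl in that calculation are not recoverable — so that row
(and anything touching TCE energetics) is carried as a ledger constant
only; requesting its recomputation raises a `MissingFormationEnergy` error
naming TCE.

Stoichiometric coefficients are exact `Fraction`s. Hess combination
Σ mᵢ·reactionᵢ therefore cancels species exactly, and the three composite
ledger rows (acetogenesis from CO, aceticlastic methanogenesis,
methanogenesis from CO) are verified to equal linear combinations of the
elementary rows in both stoichiometry and ΔrG′° (tolerance 0.05 kJ/mol,
i.e. printed-decimal agreement).

## Recovery statistics

Carbon recovery = 100·(product µmol·C)/(substrate µmol·C); electron
recovery weights by γ instead. Defaults follow the conventions of
published bottle balances: CO₂ excluded from both sides of the carbon
balance (it exchanges with the bicarbonate buffer and is the expected
major sink, so including it would only restate conservation), residual
unconsumed substrate excluded (measured residual H₂ is nmol-scale against
µmol-scale turnover). Both exclusions are keyword-switchable, and with
everything included the electron recovery of a loss-free system is exactly
100 % — the oracle used against the simulator. Percentages are rounded
half-up to one decimal at presentation (ties away from zero, matching how
printed tables are typeset); raw in/out totals are kept at full precision
in `RecoveryResult`.

## Yield chain

Gas volumes convert at 24.5 L/mol — the ideal-gas molar volume near 25 °C
and 1 atm rounded as bench calculations do; this single value reproduces
all three published volume↔amount pairs (5 mL → 204.1, 14 mL → 571.4,
35 mL → 1428.6 µmol). The chain (1:1 H₂ from CO, 3 H₂ per TCE, 4 H₂ per
acetate, µmol/mL = mM) carries full precision between steps and rounds
only at display: pre-rounding intermediates changes the final decimal
(1428.6 − 100 gives 332.2 where the unrounded chain gives 332.1). A
caller-supplied H₂-demand override lets as-printed chains (which round the
demand to 100.0 µmol) be reproduced exactly. Henry's-law partitioning of
CO between headspace and medium is out of scope — doses are treated as a
single well-mixed pool.

## Synthetic bottle generator

The generator emulates the flux structure of a CO-fed dechlorinating
community, not any fitted kinetics: the source gives network topology,
dose schedules and H₂ thresholds but no rate laws, so the kinetic forms
are the simplest ones that produce sequential intermediates and
stage-specific H₂ accumulation:

* CO oxidation, first order in CO (`k_co`, default 0.2 /d), split by
  `co_to_acetate_fraction` (default 0.25) between the water-gas-shift
  route (→ CO₂ + H₂) and direct Wood–Ljungdahl acetogenesis
  (4 CO + 2 H₂O → 2 CO₂ + CH₃COOH);
* hydrogenolysis steps, first order in the chloroethene and Monod in H₂
  with a hard threshold: rate = kᵢ·Sᵢ·H₂/(Kᵢ+H₂) for H₂ > θᵢ, else 0.
  Defaults k = 1.0, 0.7, 0.2 /d; K = 5, 8, 150 nmol/bottle; θ = 0.05,
  0.1, 1.0 nmol/bottle for TCE, cDCE, VC. In an 80 mL medium those
  thresholds correspond to ≈0.6, 1.3 and 12.5 nM — inside the reported
  ranges (0.6–0.9 nM for TCE, 0.1–2.5 nM for cDCE, 2–24 nM for VC), with
  the VC threshold and half-saturation far above the TCE ones;
* H₂-consuming acetogenesis (4 H₂ + 2 CO₂ → acetate), first order in H₂
  above the acetogen's own threshold (`k_ac` = 20 /d, θ = 30 nmol/bottle
  ≈ 375 nM). The threshold is what lets dechlorinators win at low H₂ —
  with an ungated linear sink the H₂ pool could never show the observed
  stage structure — and matches the order-of-magnitude gap between
  acetogen and dechlorinator H₂ thresholds;
* optional aceticlastic methanogenesis (`k_me`, default 0).

Default study conditions: 38.1 µmol TCE, seven 2-mL CO doses (81.6 µmol
each) every 12 days, 80 mL medium, 90 days — a low-dose bottle run to
complete dechlorination. Bicarbonate is not modelled as an exchangeable
carbon pool (initial CO₂ = 0); the water-gas-shift route produces CO₂
ahead of acetogenic demand, so CO₂ never limits, and the closed carbon
inventory makes the with-CO₂ recovery close at exactly 100 %.

Integration is explicit fixed-step (default dt = 0.002 d) with per-pool
flux limiting: each reaction is scaled by the tightest pool it consumes so
nothing is overdrawn within a step. Conservation of carbon and of
γ-electrons then holds to float rounding at every step, by construction,
regardless of parameters — the generator's primary contract. The cost is
stiffness in the H₂ pool: when consumption capacity far exceeds
production, the limiter pins H₂ near production·dt rather than at the true
quasi-steady value, so the low-stage H₂ baseline is dt-dependent (an
artefact floor of ~10 nmol/bottle at the default dt against a genuine
VC-stage accumulation of hundreds of nmol). The qualitative contract —
H₂ accumulation above 10× the pre-VC baseline occurs only once VC is the
dominant chloroethene — is robust to this artefact and is asserted in the
tests; absolute low-stage H₂ values are not meaningful at this dt.

Measurement noise is applied only at the measurement layer: noisy =
true + N(0, noise_sd·true), truncated at 0, one seeded generator stream
(default relative SD 5 %, typical of triplicate GC/HPLC bottle data). True
trajectories, cumulative reaction extents and the final inventories stay
exactly conservative, and identical configs are bit-identical.

What passing tests on synthetic bottles do *not* show: agreement with any
measured time course (figure-derived series are not reproducible from
text and no kinetic parameters are fitted), inter-bottle variability,
biomass carbon assimilation, CO toxicity to the dechlorinator, or
gas/liquid partitioning. The generator validates the *accounting*, not
the biology's rates.

## Numerical conventions

* Exact `Fraction` arithmetic for stoichiometry and γ; floats only for
  amounts and energies.
* Half-up rounding at one decimal for all displayed percentages, kJ/mol
  and µmol; full precision retained internally and in machine-readable
  columns.
* Dose impulses are applied at the first integration step whose start
  time reaches the scheduled time; sampled rows record states at step
  ends, so a dose at exactly a sample time appears in the following row.
* Amounts are per bottle (µmol); H₂ thresholds and half-saturations are
  configured in nmol/bottle, converted internally; time is in days.
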