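# Methods

## Model and assumptions

The package implements a factorial model of the minimum metabolic demand
(MMD) for protein and each amino acid in the healthy young adult male
(reference body weight 75 kg) consuming an energy-replete diet with
protein at about the current estimated average requirement. The modelled
state is maintenance: protein synthesis balances breakdown over 24 h,
there is no net tissue gain or loss, no stress or illness, and the
digestible intake of every amino acid exactly meets its demand. Under
those assumptions the demand equals the sum of obligatory losses:
turnover-associated oxidation in the postabsorptive (PTO_PA) and
postprandial (PTO_PP) states, inevitable first-pass oxidation of absorbed
amino acids (IO), gut endogenous losses (EGL), urinary free amino acids
and peptides (UFAAP), hair/skin/nail/miscellaneous losses (HSNM), and
other losses (OL) from irreversible modification and functional
conversion.

Because IO applies to the absorbed intake, and the modelled intake equals
the demand, IO is a fixed fraction of the MMD. The model is therefore a
one-dimensional linear fixed point with the closed form

    MMD = (PTO_PP + PTO_PA + EGL + UFAAP + HSNM + OL) / (1 − io_rate),
    IO  = io_rate · MMD.

The equivalent iteration MMD ← Σ(non-IO) + io_rate·MMD converges
geometrically from any start; the test suite uses that iteration as an
independent oracle against the closed form (tolerance 1e−9).

The model works on 16 amino-acid categories (9 indispensable, 7
dispensable). SAA (Met+Cys), AAA (Phe+Tyr), Asx (Asp+Asn) and Glx
(Glu+Gln) are composites and are never decomposed, because the upstream
loss estimates exist only at that resolution; inputs keyed to individual
members are mapped to the composite before aggregation. Total protein is
defined as the sum over all amino-acid categories, not derived from
nitrogen.

## Parameters

| Constant | Default | Units | Meaning |
|---|---|---|---|
| `io_rate` | 0.29 | fraction | inevitable oxidation of absorbed amino acids |
| `pto_pa_fraction` | 0.11 | fraction | postabsorptive turnover oxidation, share of breakdown |
| `pto_pp_fraction` | 0.024 | fraction | postprandial turnover oxidation, share of breakdown |
| `n_to_protein` | 6.25 | g/g | nitrogen-to-protein conversion |
| `body_weight` | 75 | kg | reference young adult male |
| `creatinine_excretion` | 0.2 | mmol/kgBW/d | reference creatinine output for unit conversion |

The per-amino-acid PTO values are consumed directly as components (the
absolute breakdown rates behind them are not model inputs);
`LossComponentTable.scaled()` exposes scale factors for scenario analysis,
e.g. `pto_pa_scale=2.0` approximates a 22% postabsorptive oxidation rate.
`io_rate` must lie strictly below 1 or the fixed point has no solution;
this is validated, not clamped.

## Uncertainty

All totals propagate SDs by root-sum-of-squares, treating components as
independent. The published IO uncertainties are not derivable from the
component SDs plus this rule, so the parameter pack carries them as
per-amino-acid overrides (`io_sd_override`); when absent, the IO SD falls
back to io_rate/(1 − io_rate) times the root-sum-of-squares of the non-IO
SDs. SD outputs are structural (propagation-rule) results only — the
package makes no claim to reproduce externally printed MMD SDs, whose
provenance is unstated. Demand means are the quantitative surface.

## Minor-loss derivations and the synthetic fixtures

The HSNM, UFAAP and OL columns can be re-derived from primary inputs:

- **HSNM** splits 5 ± 0.9 mg N/kgBW/d into 1.8 miscellaneous and 3.2
  dermal, converts with 6.25, and apportions by the whole-body-protein and
  dermal composition tables (mg AA per g protein).
- **UFAAP** combines per-study urinary excretion (mg/d divided by body
  weight) as subject-number-weighted means per amino acid, then sums
  composite-category members. Glutamine enters via creatinine-normalised
  reference ranges: (mmol AA/mol creatinine)/1000 × 0.2 mmol
  creatinine/kgBW/d × molar mass.
- **OL** converts 24-h urinary metabolite excretion to parent-amino-acid
  loss mol-to-mol (times an optional stoichiometry) using free-amino-acid
  average molar masses, and sums pathways per amino acid.

The primary datasets behind these derivations (dermal composition, the
early urinary studies, metabolite excretion records, and the
dispensable-amino-acid body composition) are not part of the published
main tables. The packaged files marked `_synthetic` are constructed
stand-ins: their values are back-calculated so that each derivation
reproduces the published per-amino-acid loss columns, and the derivation
code is additionally tested on hand-computable synthetic cases. Passing
those tests validates the conversion and weighting arithmetic, not the
provenance of the stand-in records; the published loss columns in
`loss_components.csv` remain the authoritative model inputs.

## Sensitivity analysis

Each of the seven loss parameters is varied one at a time over −20%…+20%
in 5% steps (9 points). At each grid point the demand is recomputed as the
simple sum of the seven components with the varied parameter scaled and IO
held at its baseline numeric value; the slope b (mg/kgBW/d per 1%
variation) is fitted by ordinary least squares, which is exact for this
linear response and equals baseline/100. Holding IO fixed is the default
because the varied quantity is then purely the named loss; re-solving the
fixed point at every grid point (so IO tracks the perturbed demand, and an
IO perturbation scales io_rate itself) is available with `coupled=True`
and amplifies non-IO slopes by 1/(1 − io_rate). Aggregate targets perturb
the aggregated component value, which by linearity equals perturbing every
per-amino-acid value of that parameter simultaneously.

## Protein-quality scoring

Scoring patterns divide each indispensable amino acid demand (mg/kgBW/d)
by the total-protein demand (g/kgBW/d). The matching protein requirements
are 0.634 g/kgBW/d (model demand) and 0.66 (current FAO/WHO estimated
average requirement). A source's reference ratio per amino acid is its
digestible content (composition × true ileal digestibility, with fallback
TID resolution: per-AA → mean of available → total protein → total N)
divided by the pattern value. DIAAS is the untruncated minimum ratio
(values above 1 are reported as such); all amino acids tying at the
minimum are reported as first-limiting, and the minimum is taken before
any display rounding. Required intake is requirement/DIAAS, so
intake × DIAAS ≡ requirement. Tryptophan composition must be supplied
explicitly; there is no silent food-table fallback. The packaged protein
sources carry published reference ratios directly (their underlying
composition/TID tables are not published); raw-composition scoring is
exercised on synthetic sources in the tests.

## Numerical and display conventions

- All computation is at full double precision; rounding happens only in
  the reporting layer (1 decimal for mg/kgBW/d, integers for mg/g
  patterns, 2 decimals for ratios), using half-up rounding as in the
  source presentation.
- Demand integers are displayed via a two-stage convention (round to 1
  decimal, then half-up) so 7.465 displays as 8; pattern integers are
  computed from the integer-rounded demand columns, matching the published
  tables' construction (e.g. isoleucine 21/634 × 1000 → 33 mg/g).
- Table totals are recomputed from unrounded per-amino-acid values; the
  total-protein HSNM cell uses the aggregate nitrogen value
  (6.25 × 5 = 31.25 mg/kgBW/d) per the source convention, and both the
  aggregate and the per-amino-acid sum are available.
- Zero demands make source proportions undefined and raise an error
  rather than returning NaN.

## Known limitations

- Solving from loss components printed at 1-decimal precision cannot
  always reproduce demands printed from unrounded inputs: the AAA category
  solves to 41.41 vs a printed 41.6 mg/kgBW/d (the printed component row
  itself sums to 41.5), and the summed IAA total lands at 261.8 vs a
  printed 262.3. These ~0.2–0.5 mg/kgBW/d discrepancies are input-rounding
  artifacts, not solver error, and are left visible in the regression
  suite rather than absorbed by retuning inputs.
- A single `io_rate` is applied to every amino acid; evidence suggests
  amino-acid-specific first-pass oxidation rates (e.g. higher for
  methionine), which the constants structure can accommodate when data
  allow.
- The model describes the healthy young adult male at maintenance;
  applying it to other populations or intakes requires re-parameterising
  the loss components, not just rescaling.
- Mixed-diet (multi-source) DIAAS and digestibility prediction are out of
  scope; TID values are inputs.
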