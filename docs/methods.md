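# Methods

`cmnutricycle` implements a deterministic nutrient-cycling model comparing
cultured meat (CM) produced in stirred-tank bioreactors against swine, beef,
and broiler production, on four axes: growth/feed efficiency, cropland
footprint, spent-media nitrogen and carbon waste loads with their management
costs, and nitrogen-use efficiency (NUE). This note records the model, its
assumptions, the parameter choices, and the places where the design was
genuinely open.

## Growth and feed metrics

For every production system the package computes the specific growth rate
μ = ln(m_f/m_i)/t (day⁻¹), the average daily gain (m_f − m_i)/t, the feed
ledger (total feed = slaughter weight × feed conversion ratio; protein fed =
feed × diet protein fraction), and the protein conversion efficiency
PCE = edible protein out / protein fed. Gestation is excluded from growth
time.

Two bases are supported for the animal growth-rate fit. The default,
`mu_basis="live"`, fits birth weight → live weight; this is the basis that
reproduces the reference rates (0.025, 0.004, 0.091 day⁻¹ for swine, beef,
broilers). The alternative `"edible_output"` fits birth weight → edible
output mass. Whether the edible-mass basis was intended by the source data
is unresolved; both are implemented and neither is silently preferred beyond
the default flag.

For CM, μ is fitted on proliferation-phase cell densities over the
proliferation time only (ln(20)/4.92 d = 0.61 day⁻¹ for the default batch);
an inoculum-to-harvest mass basis over the whole batch is available
(`mu_basis="mass"`, 0.44 day⁻¹). The CM "birth weight" is not a free
constant: it is computed as initial density × reactor volume × wet mass per
cell (10.5 kg for the default batch), so the preset cannot drift out of
self-consistency.

The default batch is a 15 m³ reactor inoculated at 2×10⁵ cells ml⁻¹, grown
to 4×10⁶ cells ml⁻¹ over 118 h, matured 72 h, harvesting 345 kg wet meat
(18% protein, 70% moisture, 1.4 kcal g⁻¹) on an 11-day batch cycle with
30 m³ of media water. The harvested mass and the final cell inventory
(4×10⁶ cells ml⁻¹ × 3.5×10⁻⁹ g × 15 m³ = 210 kg) disagree by design in the
source model; the package keeps the stated 345 kg and emits a warning when a
spec with this property is constructed, rather than failing or reconciling.

Known rounding artifacts in the reference growth table are reproduced as
computed, not as printed: broiler total feed 5.32 kg (2.8 × 1.9; printed
5.40), broiler PCE 24.2% (0.46/1.9; printed 25%), beef PCE 5.24%
(52.8/1008; printed 5.0%), swine meat output 67.6 kg (130 × 0.52; printed
66). The tests pin the computed values so a regression in either direction
is caught.

## Cropland footprint and areal productivity

Protein is sourced from soybean hydrolysate and energy from corn-starch
glucose. Per kg CM: protein need = meat protein fraction / PCE
(0.18/0.24 = 0.75 kg); glucose need = meat energy / caloric conversion
efficiency / glucose energy density (1,400/0.17/4,000 = 2.06 kg).

Crop land is 10,000/(yield × 1,000) m² kg⁻¹ (2.43 for soybeans at
4.12 Mg ha⁻¹, 0.77 for corn at 13 Mg ha⁻¹). Each crop's footprint is split
among co-products by market value: share_i = m_i·p_i / Σ m_j·p_j. For
soybeans (20% oil at $0.87 kg⁻¹, 80% meal at $0.33 kg⁻¹) the meal share is
60.3%, printed as 61%; corn starch carries a 74% literature share.

The soybean chain ships in two modes. `as_printed` (default) divides the
protein need by the meal protein content (0.48) alone and applies the
rounded 61% share, reproducing the reference 2.31 m² kg⁻¹; the
component-fraction and hydrolysate-recovery factors cancel in that
arithmetic. `stated_chain` applies the full narrative chain
(0.80 meal × 0.48 protein × 0.80 recovery) with exact shares, giving
3.57 m². The corn chain computed faithfully gives 1.75 m² (allocated) to
2.36 m² (unallocated); the reference figure of 2.28 m² (and hence the
4.58 m² total) could not be reverse-engineered from the stated inputs and
is carried only as an annotation (`printed_land_reference`), never used in
computation.

Areal productivities invert land use: protein productivity =
1,000 × protein fraction / land use (g m⁻² yr⁻¹); energy productivity =
kcal kg⁻¹ × 4.184/1,000 / land use (MJ m⁻² yr⁻¹). Livestock land-use
entries use literature ranges with a midpoint rule (swine 8–15, beef
15–429, broiler 8.7 m² kg⁻¹ yr⁻¹). Lean ground beef energy density is not
given alongside the land data; the configurable default is 5.3 MJ kg⁻¹ and
the beef energy-productivity results depend on it. The CM facility's own
footprint is excluded (small against cropland).

## Spent-media mass balances

Protein ledger (exact): retained = batch mass × protein fraction
(62.1 kg); fed = retained/PCE (258.8 kg); waste = fed − retained
(196.7 kg); nitrogen = 0.16 × waste protein (31.5 kg N per batch).

Water: wastewater = media water − meat water, with the meat water computed
at the 83% moisture used by the source water balance (deliberately kept
separate from the 70% compositional moisture; the two are not reconciled).
30 − 0.286 = 29.71 m³ per batch, giving a nitrogen concentration of
1.06 kg N m⁻³ — invariant to production scale. Cleaning water (45 m³ per
batch) is a separate stream by default; `include_cleaning=True` merges it.

Oxygen and glucose: cellular uptake at 332.2 nmol O₂ h⁻¹ per 10⁶ cells,
applied to the arithmetic mean of initial and final cell counts over the
proliferation phase and the final count over maturation (a geometric-mean
rule is available by flag). This yields 85.4 kg O₂ per batch, hence
85.4 × 180/192 = 80.1 kg glucose respired by the stoichiometry of complete
aerobic oxidation. A reference value of 72 kg O₂ exists in the source
material but is mutually inconsistent with its own 80 kg respired glucose
under any standard stoichiometry; the package reports the computed 85.4 kg.
Glucose ledger (exact): fed 710.3 kg (2.06 × 345); retained = caloric
efficiency × fed (17%); respired 80.1 kg (11.3% of fed); waste 509.4 kg,
converted to COD at 0.40 kg C per kg glucose × 2.66 kg COD per kg C =
542.1 kg COD per batch. Parameter sets in which retained + respired would
exceed the feed are rejected as internally inconsistent rather than clipped.

Annual scale: a facility is assumed to require at least $10M yr⁻¹ revenue;
annual mass = revenue/price; batches round up (⌈400,000/345⌉ = 1,160 at
$25 kg⁻¹, 2,899 at $10 kg⁻¹). The reactor fleet divides the exact batch
requirement by the exact per-reactor capacity 365/batch_days before
rounding up (35 and 88 reactors); flooring the capacity first to the
integer 33 batches per reactor — which is reported separately — would give
36 rather than 35 in the high-price case. Annual loads are per-batch values
(unrounded) times the integer batch count: 36,500 / 91,200 kg N and
629,000 / 1,570,000 kg COD.

## Nutrient-management costs

Land application: the annual nitrogen load is applied at 168 kg N ha⁻¹ to
the corn share (35%) of the surrounding land, so the service territory is
area/0.35, modelled as a circle (620 ha / 1.40 km radius and 1,551 ha /
2.22 km for the two scenarios). Volume is spread uniformly, so the fraction
billed the beyond-one-mile surcharge equals the area fraction beyond the
one-mile circle: 0% (high price) and 47.5% (low price). Cost = gallons ×
$0.0125 + gallons beyond × $0.0035, one flat surcharge tier. Computed
annual costs: $113.8k (high; reference 114k) and $322.3k (low; the
reference 332k is a 3% gap of unknown provenance — the specific cost
$0.32 kg⁻¹ matches either way).

Wastewater treatment: N at $2.45 kg⁻¹ (TKN) plus COD at $0.40 kg⁻¹,
≈ $0.85 per kg CM in both scenarios ($0.22 N + $0.63 COD); annual totals
$341k / $852k against reference prints of 339k / 847k (≈0.5% rounding gap,
documented, matching at two significant figures).

Manure comparators: lifetime manure volumes (beef 9,800 L, swine 600 L,
broiler 5 L per animal) × $0.0125 gal⁻¹ ÷ edible meat output give $0.135,
$0.029, $0.013 per kg — 2–10× below the CM spent-media costs, because
spent media is far more dilute in nitrogen than manure.

A sanity check compares application cost per hectare (~$180–210) against
fertilising the same hectare at the top of the $1–3 kg⁻¹ N fertilizer price
range ($504): land-applied spent media remains worth hauling. Note that per
kg of nitrogen delivered the application cost (~$3.1–3.5) sits at or above
the fertilizer price range; the per-hectare basis is the one on which the
stream retains value, and the package makes the comparison on that basis.

## Nitrogen-use efficiency

Fed nitrogen partitions into retained (= PCE, since protein→N conversion
cancels), recoverable, and lost; the three sum to one exactly. For manure
systems, recoverable = available-N fraction × 0.98 (volatilization
retention under direct injection) × (1 − 0.20) (leaching). The two loss
factors commute, so their order does not affect the result; whether the 20%
should instead be taken on fed N is textually open and noted, not guessed.
The manure available-N source data are not part of the package: the shipped
presets back-solve the recoverable fraction from the reference lost
fractions (beef 84%, swine 47%, broiler 55%) and the preset PCEs, giving
10.8%, 36.2%, and 20.8% of fed N respectively. These are labelled derived
defaults and are overridable through `animal_partition` with user manure
data.

CM without recovery loses 1 − PCE = 76% of fed N. Recovery parity:
matching broilers requires recovering 21% of fed N (27.6% of the waste
stream); matching swine, 29% (38.2%). Beef loses more than CM, so parity
needs no recovery. Person-equivalents use 13 g N person⁻¹ day⁻¹ over a
365-day year: 7,700 and 19,200 PE for the two scenarios.

## Scenario sampler

The pipeline is deterministic; the sampler propagates published parameter
spread. Default ranges: initial density 1×10⁵–2×10⁶ and final density
4×10⁶–4×10⁷ cells ml⁻¹ (log-uniform, since the published spread exceeds an
order of magnitude), proliferation 53–240 h, maturation 24–240 h, both
conversion efficiencies 0.17–0.33 (uniform — the sources give ranges, not
distributions), meat price $10–25 kg⁻¹. Draws whose joint parameters are
internally inconsistent (oxygen demand implying more respiration than the
caloric-balance feed supplies, or final density below initial) are
resampled with a capped retry count and the rejection count is logged; at
the default ranges roughly half of raw draws are rejected, which is itself
informative about how tightly the published efficiency and density figures
constrain one another. Ensembles are bit-reproducible for a fixed integer
seed (`numpy.random.default_rng`). The one-at-a-time tornado evaluates each
parameter at its range endpoints with the rest at baseline and ranks by
absolute swing; infeasible endpoints are recorded as NaN.

## What the defaults do and do not show

All defaults are the published operating point or published ranges; passing
tests demonstrate that the arithmetic chain from those inputs to the
headline outputs is correct and stable, not that the inputs describe any
real facility. In particular the model has no bioreactor kinetics (no Monod
growth or fed-batch feeding), no amino-acid-level media formulation (the
glutamine deficit of soy hydrolysate is acknowledged, not corrected), no
vitamin/growth-factor recycling, no soil nitrogen dynamics, and no
hauling-distance optimisation. Costs are point estimates in nominal
dollars with no inflation handling. Problem sizes are small by
construction — every headline quantity is desk-scale arithmetic, and the
default test suite including the 10⁴-draw ensemble runs in seconds.
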