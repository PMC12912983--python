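# Methods

## Scope and data model

`nutriflow` performs deterministic mass-and-nutrient accounting over
bilateral aquatic-food trade flows. A flow is one record of live-weight
tonnes for a (producer, exporter, importer, taxon, production method,
commodity) key; domestic retention is encoded as a self-flow with
producer = exporter = importer. Commodities are `food_product`,
`fishmeal` and `fish_oil`; methods are `aquaculture` and `capture`. The
package consumes the *output schema* of a species-level trade
disaggregation (producers already traced); it does not re-resolve
re-export chains.

Three record-level exclusions are applied before any statistic:
fishmeal produced from aquaculture (by-products that would double-count
farmed output), fish-oil commodities and plant/algae taxa (outside the
edible-weight accounting), and flows without a producing country
(exports unexplained by production and import data). Each rule reports
the count and live-weight fraction it removed, and the filter is
idempotent.

Weights are averaged over an inclusive year range (default 2015–2019) as
a *period mean*: the divisor is the number of years in the range, so a
year with no record counts as zero production. This keeps totals
comparable across countries with intermittent records.

## Nutrient supply

Nutrient composition comes from multi-study observations of
concentration per 100 g, restricted to raw muscle tissue — the modal
stratum in composition databases and the tissue the edible-weight
conversion refers to. Mixing preparation types or body parts would
conflate retention factors, and muscle concentrations are typically
conservative relative to viscera.

Within each taxon × nutrient group, values outside
[Q1 − 3·IQR, Q3 + 3·IQR] are discarded. Quartiles use linear
interpolation (the numpy default, documented so the test oracle can
match it exactly). Groups with fewer than 4 observations are left
untouched — the IQR of 2–3 points is too unstable to screen on. The
screen is iterated to a fixed point within each group: a single pass is
not idempotent at small group sizes (removing the extreme value
collapses the quartiles, and re-screening can then remove borderline
points), whereas the fixed point is stable by construction and agrees
with the single pass on well-separated outliers.

A taxon with no species-level value for a nutrient inherits the mean
over *all* observations under the first lineage ancestor (genus, family,
order, class, phylum) that has any; the rank where the walk stopped is
recorded per nutrient. Nutrients with no data up to phylum are absent
and contribute zero supply — dropping the whole flow would corrupt the
mass accounting of the remaining nutrients. Edible fractions (muscle
share of live weight, tabulated per species group) fall back the same
way: the mean over distinct groups mapped under the nearest resolvable
ancestor.

Each nutrient carries a canonical unit (mg or µg per 100 g); inputs in
the other unit are converted on ingest and RDA units must match the
canonical unit (a mismatch is fatal rather than silently off by ×1000).
Supply per flow and nutrient is

    edible_weight [t] = live_weight × edible_fraction
    nutrient_mass     = edible_weight × concentration × 10⁴   (per-100 g → per tonne)
    person_equivalents = nutrient_mass / (daily_RDA × 365)

RDAs are for women aged 14–50 (defaults in `synthgen.RDA_DEFAULTS` are
standard reference values, e.g. iron 18 mg/d, vitamin B12 2.4 µg/d).
Supply is linear in live weight and additive over any partition of the
flows; both properties are tested.

## Fishmeal demand and allocation

Fishmeal demand of farmed production is estimated bottom-up:
FM = Σₛ ACₛ · FCRₛ · P_FMFOₛ, carried in *both* units — product tonnes
and wild-fish live-weight equivalents (× LWC_FM = 2.98) — to avoid unit
ambiguity. P_FMFO includes fish oil; no attempt is made to split the
two. Non-fed groups (bivalves) have P_FMFO = 0.

Feed parameters are tabulated for 12 feed taxa while production is
grouped by ISSCAAP statistical groups. The bridge applies three rules in
order of specificity, stopping at the first that matches: (i) the feed
taxon is mentioned in the group label (plural-tolerant token match),
(ii) the feed taxon's member species all fit inside the group,
(iii) the group's members all fit inside the feed taxon. Groups matching
several feed taxa receive mean FCR and P_FMFO; unmatched groups
contribute zero demand (inventing a global-average FCR would fabricate
feed use for unmodeled taxa) and are logged.

Demand is allocated assuming a country sources fishmeal for every farmed
taxon in proportion to its overall supply mix, by (source country, wild
species) cell. Domestic fishmeal production counts as a source alongside
imports (toggleable), so countries feeding their own fishmeal are not
flagged unsourced. Shares are computed on live-weight equivalents; with
a constant conversion factor they equal product-tonne shares. Cells with
demand but no recorded supply are reported unallocated.

The trimmings adjustment scales every fishmeal quantity by
(1 − f), f ∈ [0, 0.34]: fishmeal made from processing trimmings embodies
no additional whole wild fish. Baseline is f = 0; the 34 % upper bound is
the reported share of trimmings-derived fishmeal.

## Equity classification

Country nutritional vulnerability is the prevalence of inadequate intake
per nutrient, binned as very_low ≤ 5 < low ≤ 10 < medium ≤ 25 < high
≤ 50 < very_high (boundaries to the lower bin). "Nutritionally
vulnerable" means prevalence > 25 % by default; the threshold is a
parameter for sensitivity sweeps.

Flows are labelled per nutrient by comparing source and destination:
**inequitable** when the source is more vulnerable than the destination,
**equitable** in the opposite direction, **same** on ties. Two rules are
provided: categorical (compare bins) and absolute (|I_S − I_D| ≤ 5
percentage points → same). The absolute rule is antisymmetric by
construction. The directionality convention — inequity = flow from more
to less vulnerable — is the single most consequential interpretation in
the package and is fixed throughout; shares are reported three-way
(equitable/same/inequitable, summing to 100 %) with "same" foldable into
equitable for two-way summaries. Multi-nutrient summaries weight by
traded person-equivalents (equivalently, trade volume for uniform
profiles); the weighting basis is configurable between
person-equivalents and live weight.

Supply-chain edge lists (fishmeal source → aquaculture producer →
consumer) carry per-nutrient quantities and the equity label of each
edge, ready for Sankey rendering; no figures are drawn.

## Scenarios

Net position per country and nutrient is person-equivalents imported
minus exported (farmed-fish plus fishmeal exports); the cross-nutrient
summary is the median. Three counterfactuals are evaluated through
population-capped newly-met needs: per nutrient,
newly_met = min(supply, population × prevalence/100) — supply beyond the
people who actually lack the nutrient meets no new need. Capping is
applied per nutrient *before* averaging across the 14 nutrients (the
alternative order would let surplus in one nutrient mask deficits in
another). Scenario A (repurpose fishmeal exports) converts the wild-fish
live weight behind a country's fishmeal exports to edible supply using
the constituent species' own edible fractions and profiles, assuming
full edibility of reduction-fishery catch; trimmings scaling applies
here only. Scenario B retains farmed exports with the exporter;
scenario C evaluates actual farmed imports with the importer.
Threshold counts report countries whose newly-met fraction of total
population exceeds 3/5/10 %, and "near elimination" is operationalized
as ≥ 95 % of the vulnerable population newly met (configurable; no
canonical cut-off exists).

## Synthetic worlds

The generator emulates the structural features the analysis assumes, not
the real databases' marginals:

- **trade skew** — producers drawn from a Dirichlet(0.3)-weighted
  distribution and volumes log-normal with σ = 2.0 (default), so a
  handful of exporters dominates traded weight; importers dispersed
  (2–6 partners per species, Dirichlet shares);
- **retention** — target rates 77.7 % (farmed food) and 37.1 %
  (fishmeal) with ±10-point per-species jitter;
- **vulnerability** — per nutrient, countries are cycled through the
  five bins with uniform within-bin draws, so every bin is populated;
- **observations** — log-normal multiplicative noise (σ = 0.2) around
  family- and species-level means, 2–6 observations per species ×
  nutrient, ×8 outliers at 3 % rate, cooked/viscera strata for the
  preparation filter, and 20 % of species recorded only at genus level
  to exercise the taxonomic fallback;
- **junk rows** — aquaculture-sourced fishmeal, fish oil, algae taxa and
  producer-less exports, present only to be removed by the filters.

Yearly rows are expanded from a base (averaged) flow set so that the
range mean reproduces the base exactly; the planted-truth record
(retention fractions, per-nutrient inequitable and vulnerable-source
shares on a live-weight basis, net-position signs) is computed from the
base by independent brute-force loops at generation time. Because yearly
weights are rounded to 10⁻⁶ t on write, truth comparisons on generated
worlds use a 10⁻⁶ relative tolerance; the planted-equity construction
(`plant_equity_structure`) is single-year and unrounded, and is
recovered to 10⁻⁹.

What passing on synthetic worlds does **not** show: fidelity to real
ARTIS/AFCD marginals, species composition, or re-export structure, and
therefore none of the published global magnitudes. It does show that the
accounting is exact — conservation laws, planted-share recovery,
formula/oracle agreement — so running the same pipeline on the real
inputs is a pure data exercise.

## Numerical and engineering choices

- Percentile method: linear interpolation everywhere; ties in
  sort-based outputs broken by sorted group keys, so runs are
  deterministic and byte-identical for a fixed config.
- Degenerate inputs: empty traded sets make equity shares *undefined*
  (an error / reported as undefined, never 0); zero population and
  out-of-range prevalences or fractions are fatal.
- Country codes are validated by shape (`[A-Z]{3}`) and against the
  country table; unknown codes are retained and flagged but excluded
  from country-level statistics.
- Problem sizes used by the test suite and the acceptance script
  (default world: 40 countries, 60 species, 5 years; toy runs smaller)
  keep the full accounting exact while remaining quick to regenerate.

## Known limitations

- No subnational distribution, demographic/life-stage weighting, price
  or substitution effects; omega-3/6 fatty acids are excluded for lack
  of comparable intake-inadequacy data.
- Fish oil is excluded at the commodity level; the P_FMFO term retains
  an implicit oil share in feed demand.
- One nutrient profile per taxon (no farmed/wild split); preparation
  retention factors are not modelled.
- The equity classification compares producing and importing countries
  only; intermediary exporters are not scored.
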