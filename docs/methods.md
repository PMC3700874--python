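# Methods

## Available-energy model

For a respiratory reaction with stoichiometric coefficients vᵢ (products
positive), the energy released in situ is ∆G_r = ∆G°_T + R·T·ln Q and the
available energy is ∆G_A = −∆G_r, in kJ per mole of reaction.  Reactions
are written per mole of terminal electron acceptor (or of CH4 for the
methane reactions), i.e. as 8-electron transfers, except ferrihydrite
reduction which is written per mole of H2 (2 electrons); this makes the
kJ/mol magnitudes directly comparable across metabolisms.

∆G°_T is assembled from a registry of standard formation properties
(∆Gf°, ∆Hf° at 25 °C, taken from the SUPCRT92/CODATA lineage of
compilations and documented per constant in
`aquibiome/bioenergetics.py`) and corrected to the groundwater
temperature with the Gibbs–Helmholtz relation at constant ∆H°:
∆G°_T = ∆G°₂₉₈·(T/298.15) + ∆H°·(1 − T/298.15).  Over the 12–16 °C of
the survey wells this correction is ≲ 2 kJ/mol and the constant-∆H°
approximation contributes far less than the compositional uncertainty.

ln Q sums vᵢ·ln(yᵢ·mᵢ) over aqueous species; water and minerals
(ferrihydrite) are taken at unit activity.  Activity coefficients follow
the extended Debye–Hückel model, log₁₀ y = −A(T)·z²·√I/(1 + B(T)·å·√I),
with A and B interpolated from an embedded 0–50 °C table
(A = 0.5092, B = 0.3283 at 25 °C) and Kielland ion-size parameters å.
Neutral solutes (H2, CH4, CO2) take y = 1.  The H⁺ activity is 10^−pH
directly, since pH is itself an activity measurement.

### Inputs, assumptions and their defaults

| quantity | source | default | notes |
|---|---|---|---|
| SO4²⁻, CH4(aq), H2(aq), DIC | measured (mM, µM, nM, mM) | — | wells missing a required analyte are flagged, not imputed |
| ionic strength I | specific conductance | I = 1.6×10⁻⁵ mol/kg per µS/cm | standard dilute-water proxy; override k or supply I |
| HCO3⁻ | = DIC | — | bicarbonate dominates DIC at pH 7.1–7.9 (< 10% error) |
| HS⁻ | assumed | 10⁻⁵ mol/kg | unreported in the survey; ∆G_A shifts by RT·ln10 ≈ 5.5 kJ/mol per decade (see sensitivity sweep) |
| Fe²⁺ | assumed | 10⁻⁵ mol/kg | iron results flagged assumption-dependent |
| censored values | `< limit` entries | used at the limit | policies: limit, half-limit, exclude |
| ∆G_min | viability quantum | 10 kJ/mol reaction | minimum energy for chemiosmotic conservation |

Under these defaults the bundled survey yields ∆G_A of 33.9–82.6 kJ/mol
for H2-driven sulfate reduction (21 computable wells) and 12.6–55.1
kJ/mol for methanogenesis (20 wells) — both metabolisms exploitable
everywhere computable — while reverse-methanogenesis AOM is endergonic at
every measured bulk H2 and direct sulfate-coupled AOM is exergonic in all
23 computable wells.  Field studies of this system report somewhat higher
sulfate-reduction and methanogenesis ranges; the offset is consistent
with the unknown in situ sulfide (two decades below the default would
raise the sulfate-reduction range by ~11 kJ/mol, and sulfide scavenging
by ferrous iron argues for low values) and with thermodynamic-database
differences.  The `assumption_sensitivity` sweep quantifies this
logarithmic dependence explicitly rather than hiding it in a tuned
default.

### AOM hydrogen threshold

AOM (reverse methanogenesis) produces 4 H2 per CH4, so its ∆G_A falls
monotonically with dissolved H2 and the break-even concentration is
well-defined.  It is found by bisection on log₁₀ m(H2) within
[10⁻¹⁵, 10⁻³] mol/kg to |∆G_A| < 10⁻⁹ kJ/mol, and independently in
closed form — since H2 is neutral, ln a_H2 = (ln K − ln Q_rest)/4 —
which the solver matches to better than 10⁻⁶ relative.  The threshold is
defined at ∆G_A = 0; requiring ∆G_A ≥ ∆G_min instead lowers it by
exp(−∆G_min/(4RT)) ≈ 3×.

## Sulfate zonation and ingestion

Wells are classified from sulfate alone: HS strictly above 0.2 mM, NS at
or below 0.03 mM, LS between (inclusive of 0.2).  The boundary
assignment (0.03 → NS, 0.2 → LS) reproduces the published zone
membership of the bundled survey.  One survey well (Ver94C, 0.23 mM) was
published under LS although it exceeds the HS cutoff; the classifier
applies thresholds strictly and the published grouping ships as an
explicit per-well label file, keeping the rule pure and the exception in
data.  Censored entries (`< x`) keep their limit and a status flag;
`n/a` becomes missing; tables round-trip bit-exactly through the
reader/writer pair.

Gas-sampler readings convert to aqueous concentrations via
c = L(T)·x·P_total/(R·T_K), with the dimensionless Ostwald solubility
coefficient L interpolated linearly within an embedded 0–30 °C table for
CH4, H2 and CO2; temperatures outside the table raise rather than
extrapolate.

## OTU binning and richness

Pairwise distances are computed either on pre-aligned input ("aligned":
mismatch fraction per column, gap–gap columns ignored, gap–base columns
counted as differences — a stated convention, since tools differ here)
or by global Needleman–Wunsch alignment (match 1, mismatch −1, gap −2;
mismatch+indel fraction over alignment length).  Alignment against a
curated 16S reference database, chimera screening and taxonomy
assignment are out of scope; taxonomy labels are accepted as metadata.

OTUs form by average-linkage (UPGMA merge criterion) agglomerative
clustering cut at 0.03 dissimilarity (97% similarity).  Sequences are
sorted by id first and OTUs are labelled by their lexicographically
smallest member, so the output is deterministic and order-independent;
the implementation agrees with a brute-force average-linkage oracle on
small instances.

Collector's curves accumulate observed richness along a seeded shuffle
(or a supplied arrival order); their expectation and that of
without-replacement subsampling follow the hypergeometric rarefaction
closed form E[S(d)] = Σⱼ (1 − C(N−nⱼ, d)/C(N, d)), evaluated with
log-gamma.  Shared-richness accounting reports, per group pair, each
group's OTU richness, the shared OTU count, and the percentage of OTUs
and of sequences falling in shared OTUs.

## Community statistics

*Bray–Curtis*: d(x, y) = 1 − 2Σₖ min(xₖ, yₖ)/(Σx + Σy).

*ANOSIM*: all n(n−1)/2 distances are ranked once (mid-ranks for ties);
R = (r̄_between − r̄_within)/(M/2).  Significance is by label
permutation — exhaustive over the distinct label assignments when there
are no more of them than the requested permutation count (giving exact
p, e.g. 20 assignments for two groups of three), otherwise sampled with
the +1 correction p = (1 + #{R* ≥ R})/(1 + n_perms), so the smallest
reportable p is 1/(n_perms+1).  R is invariant under any strictly
monotone transform of the distances.  Interpretation bands follow
customary usage: R < 0.25 indistinct, 0.25–0.75 overlapping, > 0.75
distinct.

*SIMPER*: samples are converted to relative abundance (clone libraries
differ in size; `normalize=False` decomposes raw-count dissimilarity
instead).  For each cross-group pair, OTU k contributes
δₖ = |xᵢₖ − xⱼₖ|/Σₘ(xᵢₘ + xⱼₘ); contributions average over pairs and sum
per pair exactly to that pair's Bray–Curtis dissimilarity.  Identical
groups make the decomposition degenerate (zero total, NaN percentages)
and are flagged rather than silently divided.

*NMDS*: Kruskal stress-1, √(Σ(d̂ᵢⱼ − dᵢⱼ)²/Σdᵢⱼ²), is minimized by
alternating pool-adjacent-violators isotonic regression of configuration
distances on dissimilarity order (primary/weak tie treatment: tied
dissimilarities are ordered by current configuration distance, leaving
them unconstrained against each other) with Guttman/SMACOF configuration
updates.  A run stops when the stress improvement falls below the
tolerance or would increase (the recorded stress sequence is
non-increasing); the best of 20 seeded random restarts is reported with
a convergence flag.

## Synthetic data

`gen_chemistry` draws sulfate and methane log-uniformly inside per-zone
ranges chosen to match the survey (HS sulfate 0.4–11 mM with methane
≤ 20 µM; NS sulfate ≤ 0.03 mM with methane 100–1240 µM), which yields
the inverse CH4–SO4 relationship across zones by construction; H2 is
log-uniform over 3–240 nM, temperature 12–16 °C, pH 7.1–7.9, DIC 5–9 mM.
`gen_otu_table` draws each sample's composition from
Dirichlet(base × exp(effects)) and counts from a multinomial of size 192
(the survey's minimum clones per library) over 300 OTUs, with planted
log-fold enrichment of disjoint OTU blocks per fraction/zone; the
default blocks mirror the field structure (iron-reducer-like block
enriched attached, methanogen-like block in NS wells, ANME-like block in
suspended LS samples).  `fraction_contrast_effects` provides the strong
two-sided ATT/SUS contrast used for planted-effect recovery checks.
All generators are pure functions of (spec, seed).

What the generators do **not** emulate: phylogenetic correlation among
OTUs, chimeras, alignment error, spatial well-to-well correlation, and
abundance models beyond the Dirichlet-multinomial.  Passing tests
therefore demonstrate the statistics behave correctly on overdispersed
compositional counts with known structure — not that any particular
biological model fits real libraries.

## Numerical choices and degenerate inputs

Bisection tolerance 10⁻⁹ kJ/mol on |∆G_A|; Debye–Hückel and Ostwald
tables interpolated linearly and never extrapolated; zero molality of a
participating species is an error directing the caller to a floor value
rather than a silent −∞; all-zero samples and all-zero OTU columns are
rejected at table construction; ANOSIM refuses singleton groups;
NMDS requires ≥ 4 samples.  Problem sizes in the shipped checks (18
synthetic samples, 300 OTUs, 999 permutations, 100 seeded replicates,
200 rarefaction draws) were chosen to make the stochastic checks
reproducible at desk scale while keeping Monte-Carlo error well inside
the asserted margins.

## Known limitations

No aqueous speciation or charge balance (DIC ≡ HCO3⁻, sulfide fixed);
no Pitzer/b-dot activity model, so results above I ≈ 0.1 mol/kg should
not be trusted; kinetics are out of scope — ∆G_A says what respiration
can yield, not what organisms do; the iron-reduction pathway depends on
an assumed ferrihydrite phase and Fe²⁺ activity and is flagged
accordingly; NMDS is a visualization aid and no numeric claims are made
from ordination geometry beyond ANOSIM.
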