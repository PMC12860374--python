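# Methods

This note records the models, conventions and design choices behind
npannotate, and what the synthetic-data tests do and do not demonstrate.

## Mass arithmetic and the adduct convention

All masses are monoisotopic sums of IUPAC atomic masses (C 12.000000,
H 1.0078250, N 14.0030740, O 15.9949146, P 30.9737615, S 31.9720707,
Na 22.9897693).  Adduct m/z values follow the **neutral-atom convention**:
[M+H]⁺ = M + 1.00783, [M−H]⁻ = M − 1.00783, [M+HCOO]⁻ = M + 44.99765,
[M+NH₄]⁺ = M + 18.03437, [M+Na]⁺ = M + 22.98977, with the electron mass
(0.00055 Da) ignored.  This is how exact masses are tabulated in the
natural-product literature the packaged fixtures were curated from; the
test suite verifies dozens of published diagnostic-ion, neutral-loss and
calculated precursor masses to four decimals under it.  Electron-corrected
(true ion mass) arithmetic is available per call via
`electron_corrected=True` but off by default.  Internally everything is
computed in double precision; display and four-decimal comparisons use
round-half-away-from-zero, matching vendor software.

Two conventions hidden in published tables are worth noting. Oligosaccharide
"losses" named after free sugars refer to the dehydrated residues (sucrose
loss = C12H20O10 = 324.1056, raffinose = C18H30O15, stachyose = C24H40O20);
and subtracting two independently rounded masses can shift the fourth
decimal by one unit, which is why calibration anchors were chosen from
values that recompute exactly.

## Candidate libraries

* **Known compounds** expand to five adducts (positive: [M+H]⁺, [M+Na]⁺,
  [M+NH₄]⁺; negative: [M−H]⁻, [M+HCOO]⁻).  Combinatorial and metabolite
  libraries use four (no [M+NH₄]⁺).  Both sets are configurable.
* The **"A + nB" generator** enumerates multisets of group fragments with
  repetition (acyl and sugar units genuinely repeat, e.g. di-caffeoyl
  esters), capped at n ≤ 5 by default.  A class-compatibility table
  (shipped as `groups.csv`, editable) restricts which groups attach to
  which parent class: sugars and acyls on flavonols/phenolic
  acids/lignans, sugars + acyls + hydroxy-fatty-acyls on resin glycosides,
  methyl/formyl on alkaloids.  The generator's size is validated against
  the closed form p·Σ C(g+i−1, i) and against brute-force enumeration.
* The **signature library** tags each diagnostic ion and neutral loss with
  one structural class.  Diagnostic entries given as formulas resolve to
  ion m/z per polarity ([M−H]⁻ or [M+H]⁺ of the stated neutral); neutral
  losses resolve to the plain residue mass.  When both a formula and an
  exact mass are supplied they must agree within 0.5 mDa.  The packaged
  CSV holds only signatures whose values are printed in the primary
  literature — it is a curated subset, not a full production library, and
  library-size statistics are deliberately not constants of the package.
  Entries of class `other` (H₂O, CO₂) match but never score toward a
  class.

## In-source fragment exclusion

For every co-eluting ordered pair (|ΔRT| ≤ 0.02 min, configurable) the m/z
difference is compared against the neutral-loss library (±0.02 Da); a match
flags the lower-m/z feature as an in-source fragment.  Flags are
chain-safe: a flagged fragment can explain further fragments, and the
reported parent is the chain's highest unflagged member.  Flagged features
are excluded from MS1 candidate matching but retained for networking.

Three deliberate choices:

* **Loss floor 40 Da.**  In-source cleavage sheds whole residues (sugars,
  acyls, SO₃, quinic acid).  Small MS2-only eliminations (CH₂ 14.0157,
  NH₃ 17.0265, H₂O, CO) are excluded from MS1 Δmass matching; with them,
  nearly any co-eluting pair of features would be declared related.
* **Adduct-delta exemption.**  [M+HCOO]⁻ − [M−H]⁻ = 46.00548 Da coincides
  with the formic-acid loss, and [M+NH₄]⁺ − [M+H]⁺ = 17.02655 Da with the
  ammonia loss.  A pair spaced within 0.01 Da of an inter-adduct delta is
  left to adduct grouping rather than flagged.  The exemption window is a
  fixed constant (not the matching tolerance) so that enlarging the
  matching tolerance can only enlarge the flag set — flagging stays
  monotone in both tolerances.
* Δmass matching consults losses of **both** polarity tags (a neutral
  species has no charge); polarity gates only MS2 class scoring.

An optional intensity sanity check (fragment ≤ parent × factor) exists but
is off by default, as no factor is established for this data type.

## MS2 classification

Spectra are trimmed to their 20 most intense fragments (ties: lower m/z).
The neutral-loss set is built from precursor-minus-fragment differences
and, by default, fragment-pair differences (sequential eliminations appear
between fragments), deduplicated within the tolerance.  Class score =
matched diagnostics + matched class losses; the winner needs ≥1 diagnostic
or ≥2 losses, and ties return "ambiguous", which downstream code treats as
unassigned (no candidate-class filtering).  The MS2 tolerance reuses the
MS1 value of 0.02 Da.  The score is an unweighted count — no published
weighting exists for this evidence type, and counts reproduce the
narrative reasoning used in manual structure elucidation.

Classes with no signature entries (fatty acids here, which analysts accept
on precursor mass and retention behaviour alone) are outside the
classifier's domain: their features annotate at the formula-only tier.

## Dual-dimension similarity and networking

`Sim_fragment` is Σ I_A,i · I_B,i over matched pairs divided by the product
of the full L2 norms of both spectra.  Peak matching is greedy by
ascending |Δm/z| with one-to-one use, raw intensities, no square-root
scaling, and no precursor-shift alignment — the neutral-loss Jaccard
dimension plays the role a "modified cosine" plays elsewhere.
`Sim_neutral-loss` = |NL₁ ∩ NL₂| / |NL₁ ∪ NL₂| with the intersection
computed by the same one-to-one tolerance matching.  Two empty loss sets
score 0, so only shared structure is rewarded.  The combined score uses
α = 0.9, β = 0.1 and a strict edge threshold of 0.6.  `alpha_scan` reports
node/edge counts over a weight grid for choosing α on new data.  Networks
export to GraphML and edge-list CSV.

## OPLS-DA screening

Intensities are log₁₀(x + 1)-transformed, mean-centred and UV-scaled
(constant features dropped); y is ±1 class membership.  The predictive
weight vector is w ∝ Xᵀy (unit norm); each orthogonal component removes
the part of the dominant loading orthogonal to w before the predictive
score t = Xw and loading are taken.  Orthogonal scores are exactly
uncorrelated with y.  One orthogonal component is the default (the choice
is weakly identified for this screen; it is configurable).  VIP over the
single predictive component reduces to √K·|w_j| with ΣVIP² = K.
Per-feature p-values are two-sided Welch t-tests on the log scale
(Mann-Whitney is not provided; Welch on log-normal data is exact in the
simulated regime).  A feature passes with VIP ≥ 1.5 AND p < 0.05.

**Operating characteristics.**  On the default synthetic cohort
(500 features, 10 markers at 4-fold in the treated group, n = 10/group,
log₁₀ noise sd 0.3) the screen recovers 9–10/10 markers.  The null
flag rate, however, is ~5%, not lower: a calibrated 5%-level test passes
5% of nulls by construction, and under these conditions VIP ≥ 1.5
corresponds to a weaker per-feature correlation cut (|r| ≈ 0.37–0.40,
since 10 markers can contribute at most ~10 to the weight normalisation
Σr²) than p < 0.05 does (|r| ≈ 0.44 at this sample size), so the
conjunction is the p-gate.  Any claim that this screen flags materially
fewer than 5% of null features is not attainable without multiple-testing
correction, which the standard VIP/p rule does not include.

## Metabolite annotation

Reactions are signed formula deltas with per-reaction multiplicity caps
(+GluA ≤ 2, +SO₃ ≤ 2, +CH₂ ≤ 3, single-step caps on the rest) combined up
to 3 steps; transformations driving an element count negative are skipped.
Display names follow the "prototype+2GluA" convention.  Candidates for a
marker are ranked by reaction steps then |mDa|, so an exact prototype
match outranks round-trips like +2H−2H.  MS2 confirmation checks for the
prototype core ion under the matched adduct among the fragments, or a
fragment at precursor-minus-total-shift.  `best_annotations` optionally
prefers MS2-confirmed candidates: within a 0.02 Da window, chemically
distinct candidates (e.g. a methylated catechol vs. its own hydroxylated
homologue, or a [M−H]⁻ vs. a formate adduct of a lighter core) are often
indistinguishable by precursor mass, and core-fragment evidence is the
standard tiebreaker.  The default keeps the pure (steps, |mDa|) order.

Marker source (plasma/urine) is an input label, never inferred.

## Synthetic data: what it emulates and what it does not

`simulate_extract` places each library compound on an evenly spaced,
shuffled retention-time grid over 0.5–24.5 min (within a 0–25 min
acquisition window) with a small random offset.  Grid spacing stays far
above the 0.02 min co-elution tolerance, so co-elution occurs only where
the generator plants it and ground-truth identity remains decidable; real
chromatograms of complex extracts do collide, and the recovery figures
here do not bound performance on such data.  Each compound emits its
primary adduct (always) plus secondary adducts with probability 0.3; MS2
spectra are rule-generated from the class's diagnostic ions plus up to
three conjugate-loss fragments, with ~5% decoy peaks and uniform ±0.005 Da
m/z jitter (half the matching tolerance, so matching is decidable).  With
probability 0.3 a co-eluting in-source fragment is planted at the
precursor minus a class loss (≥ 40 Da, off the adduct spacings).

`simulate_cohort` draws log₁₀ intensities from N(μ_j, 0.3) with
μ_j ~ U(4, 6), multiplying markers by the fold change in the treated group
only.  `simulate_metabolized` samples prototype × reaction multisets and
emits the confirming core ion and conjugate-loss fragment.

Not emulated: chromatographic peak shapes, isotope envelopes,
intensity-dependent mass error, cross-sample RT drift, missing values,
and correlated biological variation.  Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not field accuracy.

## Numerical choices

* Rounding for display/comparison: 4 decimals, half away from zero.
* Constant-feature detection uses a relative standard-deviation floor
  (10⁻⁸ of the mean) to absorb float rounding of identical values.
* Greedy one-to-one peak matching is exact whenever peaks are separated by
  more than twice the tolerance; the tests compare it against the optimal
  assignment in that regime.
* Deduplication of neutral-loss sets clusters sorted values with gaps
  greater than the tolerance.
* All stochastic stages take an integer seed; identical seed and
  configuration give byte-identical artifacts.

## Known limitations

* Class assignment is only as good as the signature library; the packaged
  fixture covers the six signature-bearing classes plus oligosaccharides
  and is intentionally small.
* A 0.02 Da precursor window cannot separate isomers or near-isobaric
  candidates; such features annotate to the formula level only, and
  metabolite assignments without MS2 confirmation should be treated as
  tentative.
* The OPLS-DA screen controls no multiplicity; at 500 features expect
  ~25 null features through the p-gate per cohort.
* The in-source filter requires co-elution within a tight RT tolerance;
  looser upstream alignment requires raising `rt_tol`, which raises the
  chance of accidental flags.
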