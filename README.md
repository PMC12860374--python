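# npannotate

Automated annotation of untargeted LC-MS/MS data from natural-product
extracts and from plasma/urine of subjects who consumed them.  The package
targets the recurring problems of herbal/functional-food metabolomics:
candidate libraries biased toward known compounds, in-source fragmentation
and adduct interference masquerading as independent precursors, cosine-only
molecular networks that miss neutral-loss relationships, and the jump from
"significantly different feature" to "phase I/II metabolite of compound X".

It is a library plus a small CLI (`npannotate`) intended for analysts who
already run a peak picker (MZmine-style feature tables, MGF spectra) and
want a scriptable, fully inspectable annotation stage downstream of it.

## What it computes

**Candidate libraries.** Known compounds (name, formula, class) are expanded
to precursor m/z under the five singly charged adducts [M+H]⁺, [M+Na]⁺,
[M+NH₄]⁺, [M−H]⁻, [M+HCOO]⁻ using the neutral-atom mass convention
(electron mass ignored).  An "A + nB" combinatorial generator attaches 0–n
group fragments (hexosyl, caffeoyl, feruloyl, acetyl, methyl, …) to each
parent, with repetition; its size obeys

    N(p, g, n) = p · Σᵢ₌₀..n C(g+i−1, i)

which the implementation checks against brute-force enumeration.

**In-source fragment exclusion.** Co-eluting feature pairs (|ΔRT| ≤ 0.02 min)
whose m/z difference matches a neutral-loss library entry (±0.02 Da) mark
the lower feature as an in-source fragment; chains resolve to the highest
unflagged parent.  Pairs spaced by an inter-adduct delta (e.g. the 46.0055
Da between [M+HCOO]⁻ and [M−H]⁻) are left to adduct grouping instead.

**MS2 classification.** The top 20 fragments and the derived neutral-loss
set are matched against class-tagged diagnostic ions and neutral losses;
each match scores one point for its class, a winner needs ≥1 diagnostic or
≥2 losses, ties are reported as ambiguous.

**Molecular networking.** Pairwise dual-dimension similarity

    Similarity = α · Sim_fragment + β · Sim_neutral-loss   (α = 0.9, β = 0.1)

where `Sim_fragment` is the cosine over one-to-one matched fragment pairs
normalised over all valid peaks, and `Sim_neutral-loss` is the Jaccard index
of the two loss sets.  Edges are kept above 0.6 and exported to GraphML.

**Chemometric screening.** OPLS-DA (one predictive component, orthogonal
components split off first; log₁₀ + unit-variance scaling) on a
treated-vs-blank intensity matrix.  Features with VIP ≥ 1.5 and Welch
p < 0.05 are screened as exogenous markers; VIP is normalised so
mean(VIP²) = 1.

**Metabolite annotation.** Screened markers are matched against a prototype
× reaction library (+2H, −2H, +O, ±CH₂, ±H₂O, +SO₃ 79.9568 Da, +GluA
176.0321 Da, +Glc 162.0528 Da; up to 3 steps), with MS2 confirmation by the
prototype core ion or the conjugate-mass neutral loss.

A seeded `synthetic` module generates every input shape the pipeline
consumes — extract features with planted in-source fragments and
rule-generated MS2, two-group cohorts with planted markers, and
prototype-derived metabolite features — together with ground-truth
manifests, so the whole chain is testable without instrument data.

## Worked example

```python
import npannotate as npa
from npannotate import libraries, ms1, ms2, synthetic

# simulate a small extract profiled in negative mode and annotate it
cfg = synthetic.ExtractConfig(seed=7)
table, spectra, truth = synthetic.simulate_extract(cfg)
table = npa.attach_ms2(table, spectra)

sig = libraries.default_signature_library()
flags = ms1.flag_in_source_fragments(table, sig)
table = ms1.apply_flags(table, flags)
print(f"{len(table)} features, {len(flags)} flagged as in-source fragments")

index = libraries.expand_precursors(libraries.default_compound_library(),
                                    polarity="negative")
hits = ms1.match_precursors(table, index)
results = ms2.annotate(table, hits, sig)
print(ms2.annotation_table(results).head(8).to_string(index=False))
```

prints

```
49 features, 11 flagged as in-source fragments
   id         mz        rt             name   formula    adduct   mda           class               tier  n_diagnostic  n_losses
F0001 503.161357 10.522508        Raffinose C18H32O16    [M-H]-  0.15 oligosaccharide standard-confirmed             3        16
F0002 549.169988 10.522508        Raffinose C18H32O16 [M+HCOO]-  3.30                       formula-only             0         0
F0004 341.104301 12.169430          Sucrose C12H22O11    [M-H]- -4.09 oligosaccharide standard-confirmed             3        13
F0006 353.088974  4.019341 Chlorogenic acid  C16H18O9    [M-H]-  1.72   phenolic acid standard-confirmed             8        17
F0007 399.088039  4.019341 Chlorogenic acid  C16H18O9 [M+HCOO]- -4.70                       formula-only             0         0
F0008 353.090984 23.331552 Chlorogenic acid  C16H18O9    [M-H]-  3.73   phenolic acid standard-confirmed             9        14
F0009 353.091222 18.596079 Chlorogenic acid  C16H18O9    [M-H]-  3.97   phenolic acid standard-confirmed             9        23
F0010 179.031272 20.093168     Caffeic acid    C9H8O4    [M-H]- -3.16   phenolic acid standard-confirmed             4         2
```

Each row is one feature: its best candidate (name, formula, adduct), the
mass error against the calculated precursor in mDa, the class assigned
from diagnostic-ion/neutral-loss evidence, and the confidence tier.  The
eleven flagged features (in-source fragments planted by the simulator) are
excluded from candidate matching.  Formate-adduct features attach no MS2
in this simulation, hence their `formula-only` tier.

The same stages are available from the shell:

```sh
npannotate simulate --seed 7 --outdir sim/
npannotate annotate --features sim/features.csv --mgf sim/spectra.mgf \
    --polarity negative --out annotations.csv
npannotate network --features sim/features.csv --mgf sim/spectra.mgf \
    --polarity negative --out network.graphml
```

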