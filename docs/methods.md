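# Methods

This note documents the models, numerical choices and limitations
behind `fcprofiler`. Everything stated here is computed by the test
suite or `scripts/acceptance.py`; no empirical claim goes beyond what
those runs produce.

## Molecular model

A proteoform species is an allotype backbone plus site-wise glycans
plus one PTM. Masses are additive. Average masses are the working
currency: at ~25 kDa and TOF resolving power 15000, isotopes are
unresolved, so annotation and deconvolution operate on average masses;
monoisotopic masses are kept for bookkeeping only. Glycan residue
masses (Da, average): Hex 162.1406, HexNAc 203.1925, dHex 146.1412,
Neu5Ac 291.2546. PTM deltas: +K +128.1741, −GK −185.2254,
cysteinylation +119.1442, open Cₕ2 disulfide +2.0159; the N-terminally
truncated open-disulfide form (DP hydrolysis between the Cₕ2
cysteines) has an allotype-specific negative delta stored in the
reference table.

Glycan structure is read from composition under the biantennary IgG-Fc
convention: Man3 core, so galactose count = H − 3 (capped at 2) on
complex glycans; bisection = a fifth HexNAc; high-mannose = N = 2 with
H ≥ 4; N ≤ 1 is an EndoS2 chitobiose stub. This convention is what the
derived traits are defined on.

The shipped allotype table (`data/allotypes_synthetic.tsv`) is
synthetic: eight IMGT-style allotypes with realistic but constructed
backbone masses in the 23.7–24.3 kDa Fc/2 range, two per subclass,
with `IGHG3*11` carrying the second (Cₕ3) site. Users analysing real
data supply their own table (same columns); when a sequence is
available, `backbone_mass_from_sequence` computes the average mass
with the two intrachain disulfides closed (−2 × 2.0159 Da).

## Synthetic runs: what they emulate and what they do not

The generator draws, per patient, the four study fractions
(total/ACPA × plasma/SF) with shared patient-level latents so that
within-patient pairing is real. Defaults encode the emulated design:

* subclass abundances: total IgG ≈ 60/25/8/7 % (IgG1–4), ACPA shifts
  toward IgG1 and IgG4;
* complex glycoform distributions are built from target trait levels
  (per-arm Bernoulli galactosylation, conditional sialylation,
  independent fucosylation/bisection/high-mannose), so the generative
  trait values are exact by construction; base targets ≈ 42–50 %
  galactosylation, 10–12 % sialylation, 4–8 % afucosylation, 10–12 %
  bisection, 1.5–2 % high mannose, jittered per patient;
* fraction effects: ACPA afucosylation × 0.4 and bisection × 0.6
  versus total; SF galactosylation −0.10 and sialylation × 0.65 versus
  plasma within ACPA (milder in total IgG); ACPA Cₕ3 glycans richer in
  high mannose;
* Cₕ3 occupancy: patient base uniform on 0.10–0.42 with
  fraction-specific scaling, clipped to 0.07–0.45;
* PTMs: retained lysine only in SF (pool 1.6 % total / 3.2 % ACPA,
  i.e. measured levels ≈ 1.7/3.3 %), −GK on IgG4 only, cysteinylation
  2 %, open disulfide 1 % (+2 Da form) plus 1.5 % truncated form,
  non-glycosylated 0.3 % in total and lower in ACPA;
* acquisition: RT 600–1320 s (scan every 3 s, Gaussian elution σ = 6 s,
  allotypes spaced 75 s apart, open-disulfide forms +15 s), m/z
  1000–1600 on a 0.02 grid, charges 18–22 with a triangular envelope
  peaking at z = 20, peak FWHM = m/z / 15000, additive Gaussian noise
  (σ = 20 counts against a total ion area of 10⁸, leaving 0.3 %-level
  species far above the noise floor).

Not emulated: isotope envelopes (peaks are pure Gaussians of the
instrument width — real intact-protein peaks are broadened to
~0.4–1 m/z by the unresolved isotope distribution, which is why
published workflows smooth at 1 m/z; see *Preprocessing*), adduction,
in-source decay, chromatographic tailing, charge-envelope variation
between proteoforms, capture-step losses and Fab glycosylation.
Passing recovery tests therefore demonstrates the correctness of the
quantification logic under a clean, known-truth instrument model, not
robustness to every artefact of real data.

## Preprocessing

Smoothing is Gaussian with FWHM given in m/z; the tophat baseline is a
grey opening (minimum then maximum filter, odd structuring size so the
opening never exceeds the signal) subtracted from the spectrum. The
standalone functions default to the conventional 1.0 m/z width, which
matches isotope-envelope-broadened real peaks. The pipeline's own
default smoothing width is 0.1 m/z, matched to the simulator's
idealised peak width (m/z/15000 ≈ 0.085): a 1 m/z kernel on such peaks
would merge near-isobars 16 Da apart (e.g. H4N4 vs H3N4F1) and smear
the deconvolved mass peaks to ~20 Da. The width is a config knob; set
it to the actual peak width of your data.

Retention alignment fits a piecewise-linear warp through the EIC
apexes of user-chosen anchor species (constant extrapolation beyond
the anchor span); a run in which an anchor is undetected is returned
unwarped and flagged.

## Deconvolution

Direct charge-assignment summation onto a 1 Da grid. Peak picking uses
3-point local maxima (plateau ties to the lower mass) above
median + k·MAD of the combined trace, plus a charge-coherence filter:
a retained peak needs ≥ 3 charges carrying ≥ 5 % of the strongest
per-charge signal at that mass, which removes single-charge harmonic
ghosts (a species of mass M also produces ridges near M·z′/z). The
threshold default k = 8 was calibrated on the pure-noise null: the
studentised maximum over the mass grid under noise-only runs has its
95th/99th percentile near 6.6/7.2, so k = 8 keeps the family-wise
false-pick rate below ~5 % while remaining orders of magnitude below
genuine glycoform peaks. Both k and the support count are config
knobs. The `combine="median"` mode (median across charges instead of
sum) is used wherever relative intensities are read off the mass
spectrum, because single-charge ghosts of abundant species otherwise
leak into the quantified region.

## Allotype calling

An allotype is called when ≥ 2 of its expected ladder masses
(backbone + H3N4F1/H4N4F1/H5N4F1) match picked peaks within 2.0 Da; at
most the two best-supported allotypes are kept per subclass, and
ladders isobaric within tolerance are co-reported with an ambiguity
flag. Calling runs over sliding RT windows (60 s wide, 30 s step)
rather than the whole-run sum: allotypes elute apart, and windowing
prevents near-isobaric glycoforms of different allotypes from merging
into shifted peaks on the 1 Da grid. Within each window, calls with
summed evidence below 8 % of the window's strongest call are
discarded — a low-stoichiometry PTM satellite ladder (e.g. retained
lysine at a few percent of an abundant allotype, shifted by
+128.17 ≈ +162.14 − 34) can otherwise mimic another allotype's ladder,
while a genuine allotype dominates its own elution window. The 2.0 Da
(calling) and 1.5 Da (pair annotation) tolerances derive from the 1 Da
grid plus calibration slack and are declared knobs, not inferred from
data.

## Quantification

EICs use exactly three consecutive charge states, chosen once per
allotype as the triplet with maximal summed envelope weight whose
windows fit the acquisition range (computed on the G0F glycoform and
reused for all species of that allotype, keeping profiles internally
consistent). Window borders are base-peak m/z ± w·FWHM with
FWHM = m/z/15000 and w = 2 by default (w is a knob; whether published
workflows used ±1 or ±2 FWHM is not generally stated).

The allotype elution apex is located where the whole three-member
ladder co-maximises (geometric mean of the three EICs): a single
glycoform EIC can be hijacked by a larger near-isobar of another
allotype eluting elsewhere, but a coincidental co-eluting ladder of
three 162-spaced isobars is far less likely. Integration windows are
apex ± 18 s (±3 elution σ); the truncated open-disulfide form is
integrated 15 s later.

Each species' area is estimated per charge, normalised by the envelope
weight, and combined by the median across charges. This suppresses
isobaric aliasing confined to one charge window — chiefly doubly
glycosylated IgG3 species landing in singly glycosylated windows at a
different charge. Charges whose window contains a predicted peak of a
different co-eluting species are dropped beforehand when possible.
Residual interference that hits all three charges of a minor species
survives (e.g. the afucosylated H4N4 of a heavily doubly glycosylated
IgG3 allotype can be inflated by ~1–2 percentage points, propagating
a few points into its afucosylation trait); this is a genuine
isobaric limitation, not a code path that can be configured away.

Relative quantities follow fixed conventions: glycoform profiles are
percentages over the unmodified glycan-bearing species of one
allotype (PTM variants excluded from this denominator but included in
the allotype's total intensity); subclass profiles are
abundance-weighted means over the (≤ 2) allotypes; allotype and
subclass abundances are shares of the summed intensity of all
identified species; PTM levels are modified/(modified + unmodified
H3N4F1) so values are bounded percentages (the plain modified/unmodified
ratio is available via `bounded=False`); open disulfides are
quantified through the N-terminally truncated proteoform, whose large
mass shift makes it chromatographically and spectrally separable,
rather than through the +2 Da form. Occupancy uses the anchor formula
described in the README; the anchor's relative abundance among doubly
glycosylated species comes from the median-combined deconvolution of
the allotype's own elution window, with isobaric (Cₕ2, Cₕ3) pairs
merged at the mass level on both sides of the ratio so the estimate is
invariant to the pairing ambiguity.

## Traits and statistics

Arm-counted traits use the weighted-twice rule
(Σ aᵢ·nᵢ/2 over complex species). Complex-defined traits
(galactosylation, agalactosylation, sialylation, afucosylation,
bisection, and the optional mono/di sub-traits) are normalised to the
complex-type fraction; high-mannose is reported against the full
glycan profile and non-glycosylated against the full species total.
An empty profile yields NA throughout ("missing" is explicit, never
imputed at the trait level).

The statistical layer mirrors a paired four-fraction design: paired
t-tests on complete cases (identical pairs give p = 1; a zero-variance
non-zero shift is flagged degenerate rather than given a p-value),
Šídák adjustment 1 − (1 − p)^k over the k = 4 predefined fraction
comparisons, PCA after imputing missing values with the minimum
positive value 0.01 and standardising columns, and Spearman
correlations with pairwise deletion, flagging cells with fewer than
four complete pairs. Mixed-effects modelling is deliberately replaced
by complete-case paired tests + Šídák: on complete data the estimand
(within-patient contrasts) is the same, and the simpler procedure is
exactly reproducible. For the fraction PCA both readings of
"within-patient differences as input" are provided —
`per_patient_centered` (subtract each patient's mean feature vector)
and `concatenated` — with the former as default; neither is asserted
to be the historically exact choice.

## Problem sizes and determinism

The validation instrument is `recovery_study`: 20 simulated patients ×
4 fractions through the full pipeline (~1.5 s per run on one CPU),
reporting median absolute errors of glycoform percentages, Cₕ3
occupancy and allotype ratios, the retained-lysine level, and the
total-vs-ACPA PCA silhouette. Twenty patients give ~2000 glycoform
comparisons and 80 occupancy/ratio comparisons — enough for stable
medians while keeping the whole suite in minutes. Every stochastic
step is driven by an explicit seed (`numpy.random.default_rng`);
cohort seeds are spawned per patient and per run, so any single run
is reproducible in isolation.

## Known limitations

* No isotope envelopes or adducts in the simulator; no MaxEnt-style
  regularised deconvolution (the charge-assignment summation is
  adequate for mass/abundance recovery but produces harmonic ghosts
  that the support filter and median combination must remove).
* Isobaric interference that coincides across all three EIC charges is
  not correctable (see *Quantification*).
* The synthetic allotype table is a stand-in; allotype calling is only
  as complete as the user's reference, and which IGHG3 allotypes carry
  the Cₕ3 site is left to that table.
* PTM localisation is fixed to the modelled set; no scoring by isotope
  fit; no absolute quantification or cross-run normalisation beyond
  relative abundances.
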