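# Methods

`oxplid` predicts which oxidized phospholipids (oxPLs) a given native
lipidome can give rise to, simulates their negative-mode CID spectra, and
identifies them in data-dependent-acquisition (DDA) LC-MS/MS runs with a
five-score system.  This note documents the models, the defaults and the
reasoning behind choices that were genuinely open.

## Nomenclature and mass model

Species are written in the discrete LIPID MAPS style with two
modification name spaces per residue: square brackets carry the residual
double-bond count and counts of oxygen-addition groups
(`PC(18:0/18:1[1xDB,1xKETO])`), angle brackets carry an oxidative
truncation (`PE(18:0/5:0<CHO@C5>)`, where `Cn` is the number of carbons
retained and the terminal group sits on carbon *n*).  Cyclic products
use ring-class letters and a series number (`8-F2-IsoP`).

Elemental compositions are computed by atom counting: the
glycerophosphate scaffold (C3H9O6P) plus a head-group increment per
class (PC +C5H11N, PE +C2H5N, PG +C3H6O2, PS +C3H5NO2) plus each residue
as its free fatty acid minus water.  A residue `c` carbons with `k`
plain C=C, `j` keto, `a` hydroxy, `b` hydroperoxy and `e` epoxy groups
has H = 2c − 2(k+e) − 2j and O = 2 + a + 2b + j + e (an aldehyde or
carboxyl truncation terminal subtracts 2 H and adds 1 or 2 O).  A
representative SMILES structure is generated from the same description,
and the test suite parses every generated structure with RDKit and
requires formula agreement, so composition arithmetic and line notation
cannot drift apart.

m/z values use CODATA monoisotopic masses and include the electron mass
for ions.  Negative-mode adducts follow the observed class chemistry:
PC forms formate adducts `[M+HCOO]−` — except chains truncated to a
terminal carboxylic acid, which deprotonate — and PA/PE/PG/PS form
`[M−H]−`.

Double-bond positions (delta numbering) ship for the common PUFAs
(18:2 Δ9,12 through 22:6 Δ4,7,10,13,16,19; n−3 isomer is the default
where several natural isomers share c:d).  Unknown chains fall back to
methyl-end n−3 methylene-interrupted spacing with a warning.

## In-silico oxidation

Each C=C plus one neighboring (bis-)allylic carbon is one oxidizable
unit.  Enumeration is combinatorial over units, and positional isomers
with the same modification-type multiset are merged to one entry, so a
product is fully described by its type multiset:

* **OAP** (oxygen addition): multisets over {keto, hydroxy, hydroperoxy,
  epoxy}, at most one group per unit, within the level's oxygen budget.
* **OCP** (oxidative cleavage): Hock-type truncation at each double-bond
  position, both aldehyde- and carboxyl-terminated; parent double bonds
  below the cleavage site are retained, and when at least two remain the
  truncated chain is decorated by the same OAP enumeration (a lone
  residual double bond has no bis-allylic methylene and is left bare).
* **Prostanes**: ring templates (A/D/E/F/H cores) instantiated once per
  window of three consecutive methylene-interrupted double bonds;
  positional isomers are kept separate, since ring position is exactly
  what distinguishes e.g. 5- and 8-series isoprostanes.

Three severity levels gate types, budgets and cleavage variants; they
are strictly nested (raising the level never removes a product), which
the rule loader verifies.  The default level (2) allows all four OAP
types with an oxygen budget of three atoms (a hydroperoxide spends two).
This configuration is *calibrated*: it reproduces the two worked counts
that anchor the rule set — 17 distinct products for PC(18:2/18:2) and
at least 104 (here 113) for PC(16:0/20:4) — and the calibration choices
are documented in `src/oxplid/data/default_rules.yaml` itself.  Lyso
species (loss of a whole residue) are generated only on request
(`include_lyso`), because de-esterification is not an oxidation of a
double-bond unit and the worked counts exclude it.

Only one residue is oxidized per product; the partner stays native.
Products whose residue abbreviations coincide after swapping sn
positions are merged, and output order is sorted by abbreviation, so
libraries are deterministic (SDF export is byte-reproducible).

## In-silico fragmentation

The predicted spectrum holds the main structure-related ions: class
diagnostic head-group fragments (e.g. PC m/z 168.043/224.069 after
methyl loss, PE 140.012/196.038, PA/PG/PS 152.996, PS serine neutral
loss), the sn-1/sn-2 carboxylate anions at their modified masses,
residue neutral losses as ketene and as free acid, and
modification-specific losses: one water per hydroxy-bearing group,
hydrogen peroxide (34.0055) for hydroperoxides, CO2 for carboxyl
truncation terminals.  Keto and epoxy groups emit no specific loss.  PC
formate adducts fragment through the demethylated surrogate
`[M−CH3]−` (−60.0211 from the precursor), from which all residue and
head-group losses are taken.

Relative intensities come from a rank-ordered default profile (sn-2
carboxylate ≥ sn-1 carboxylate > head-group ions > losses) and are
explicitly instrument-tunable configuration; changing the profile never
changes the ion inventory.  The fingerprint list is the exhaustive
white list for intensity-independent scoring: every base ion expanded by
cumulative water losses up to the species' OH+OOH count, deduplicated
within 0.1 mDa.  The predicted spectrum is a subset of the fingerprint
by construction.

## Scoring

For a candidate/spectrum pair (peak matching is ppm-based,
nearest-peak-wins, deterministic tie-breaks):

* **Spectra Similarity** — reverse dot product over Stein-style weights
  W = I^m · (m/z)^n (defaults m = 0.6, n = 3).  Only library ions and
  their matched partners enter the sums, so impurity peaks cannot
  penalize the score; it is scale-invariant and 100 on an exact match.
* **Rank Score** — the matched fatty-acyl signals (carboxylates, residue
  neutral losses, modification losses) are ranked by observed intensity;
  rank *i* contributes (10−(i−1))/10, weighted per signal class and
  normalised by the candidate's maximum attainable sum.  Head-group ions
  are deliberately not ranked: they are shared by every candidate of a
  class and carry no residue evidence (this is also what rejects decoy
  candidates that match nothing but head-group ions).
* **Fingerprint Score** — cosine of the 0/1 match vector against the
  all-ones vector over the fingerprint list: 100·√(k/N).
* **Specificity Score** — amplified decibel ratio
  F·20·log10(specific/unspecific) of summed intensities, F = 10.4795 so
  a 3:1 ratio reaches 100; clamped to [0,100]; 100 when nothing
  unspecific matched.  Unspecific intensity is what competing candidates
  of the same spectrum matched and this candidate did not.
* **Isotope Score** — 100·(1 − Σ|r_obs,i − r_lib,i|) over the M+1/M+2
  ratios.  Predicted ratios come from per-element binomial expansion of
  the ion composition truncated at M+2 (phosphorus is monoisotopic;
  IUPAC 2013 abundances pinned in the package); the tests check it
  against an exhaustive convolution oracle to within 1%.

The overall score is the plain mean of the five, assigned only when each
sub-score clears its threshold (defaults: similarity 20, rank 20,
fingerprint 10, specificity 0, isotope 60, overall 40 — package
defaults, instrument-tunable, not literature values).  A sub-threshold
candidate is rejected, not reported with a low score.

## Identification pipeline

mzML reading handles centroided 32/64-bit, optionally zlib-compressed
arrays; each MS2 is linked to the nearest preceding survey scan (scan
numbers 1-based, retention times in minutes).  Candidates are library
entries whose default-adduct m/z falls within ms1_ppm (default 10) of
the recorded precursor; a candidate is skipped when the survey scan
shows a stronger peak one isotope spacing below the precursor (M+1
pickup).  That guard uses a fixed 0.01 Th window on purpose: tying it to
ms1_ppm would let a tighter tolerance *add* identifications, breaking
monotonicity.  The observed isotope pattern is read at the theoretical
M/M+1/M+2 positions of the linked survey scan; a missing monoisotopic
peak flags the candidate rather than scoring it.  Batch processing
isolates runs and merges results in input order, so tables are identical
for any worker count.

## Synthetic fixtures

Fixture runs plant chosen library species as Gaussian XIC profiles
(default 0.2 min FWHM) with isotope-resolved M..M+2 survey envelopes,
and trigger MS2 on the top-12 eligible survey peaks above 1000 counts
with dynamic exclusion — mirroring a negative-mode RPLC-DDA acquisition
(survey m/z 200–1200, MS2 m/z 50–1200).  MS2 events carry the predicted
spectrum scaled by the profile plus seeded impurity peaks and a noise
floor, both kept ±0.05 Th away from every fingerprint entry so they are
impurities in the scoring sense.  Decoy candidates are residue-reshuffled
isomers: identical head group and composition (hence precursor m/z) but
acyl chains whose carboxylates match nothing planted.  Everything is
driven by one integer seed; a fixed seed yields byte-identical mzML.

What these fixtures do not emulate: chromatographic co-elution and peak
shape distortions, profile-mode data, mass-calibration drift, real
fragmentation efficiency differences between instruments, and in-source
fragmentation.  Passing the closed-loop tests therefore demonstrates the
correctness of the matching/scoring machinery under its own spectral
model, not identification performance on real instrument data, which
depends on tuning the intensity profile and tolerances.

## Problem sizes and determinism

The test suite runs the full loop at deliberately modest sizes — an
eight-species lipidome (~800 predicted products), a 20-species planted
run with 10 decoys, sub-minute wall time — chosen so the whole suite
stays fast while still exercising every code path end to end.  All
randomness flows through explicit integer seeds; enumeration, SDF/MSP
export and identification tables are deterministic and byte-stable.

## Known limitations

* Ether/plasmalogen lipids, sphingolipids and positive-mode chemistry
  are out of scope; sn-positional isomerism is taken from the input, not
  inferred from MS data.
* Merged positional isomers mean the exported structure is one
  representative isomer; ring stereochemistry of prostanes is not
  modelled.
* The shipped fragmentation inventory and intensity profile are a
  documented reconstruction of common negative-mode behaviour and are
  meant to be refined per instrument via the profile configuration.
* The three oxidation levels are a curated configuration anchored to two
  published enumeration counts, not an exhaustive chemical ontology.
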