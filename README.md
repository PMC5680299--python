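# oxplid

Prediction and identification of **oxidized phospholipids (oxPLs)** from
negative-mode DDA LC-MS/MS data.

Untargeted lipidomics can in principle see the low-abundance oxidation
products of membrane phospholipids — truncated aldehydes and acids,
hydroxy/hydroperoxy/keto/epoxy chains, isoprostane-type rings — but no
spectral library exists for most of them.  `oxplid` closes that gap for
a *specific sample*: starting from the sample's native lipidome (PA, PC,
PE, PG, PS species with discrete sn-1/sn-2 fatty-acyl composition) it

1. **enumerates** all rule-permitted oxidation products per residue
   (oxygen additions, oxidative cleavages, prostane rings), merging
   positional isomers, and exports the predicted oxidized lipidome as an
   SDF structure library;
2. **simulates** the CID spectrum and an exhaustive fingerprint m/z list
   for every predicted species (MSP/NIST export);
3. **identifies** oxPLs in mzML DDA runs by precursor matching, survey
   scan isotope verification and five scores merged into one:

   * Spectra Similarity: reverse dot product
     `100 · (Σ W_lib W_obs)² / (Σ W_lib² Σ W_obs²)` with Stein weights
     `W = I^0.6 · (m/z)³`, insensitive to unmatched impurity peaks;
   * Rank Score: intensity-ranked fatty-acyl signal evidence,
     `R = (10 − (rank−1))/10`, normalised to 0–100;
   * Fingerprint Score: `100·√(k/N)` over the exhaustive m/z white list;
   * Specificity Score: `10.4795 · 20 · log₁₀(I_specific/I_unspecific)`,
     clamped to [0, 100] (a 3:1 ratio scores 100);
   * Isotope Score: `100·(1 − Σ|r_obs,i − r_lib,i|)` over M+1/M+2 ratios
     predicted by binomial expansion of the elemental composition.

   The overall score is the mean of the five and is only assigned when
   every sub-score clears its threshold.

See `docs/methods.md` for the full model description and defaults.

## Worked example

```python
>>> import oxplid as ox
>>> rules = ox.load_rules()                      # calibrated defaults, level 2
>>> sp = ox.parse_abbreviation("PC(18:2/18:2)")
>>> products = ox.predict_species_products(sp, rules)
>>> len(products)
17
>>> from collections import Counter
>>> Counter(p.lpp_class_tag for p in products)
Counter({'OAP': 13, 'OCP': 4})
```

Dilinoleoyl-PC yields 17 distinct oxidation products under the default
rules: 13 full-length oxygen-addition products (every multiset of keto/
hydroxy/hydroperoxy/epoxy over the two double-bond units within a
three-oxygen budget) and 4 truncated products (cleavage at Δ9 and Δ12,
each as aldehyde and acid).  Its isomer PC(16:0/20:4) yields 113 — the
arachidonoyl chain's four double bonds open up decorated truncations and
isoprostane rings.

Each product knows its adduct chemistry and predicted spectrum:

```python
>>> lpp = next(p for p in products if "9:0<CHO@C9>" in p.abbreviation)
>>> lpp.abbreviation                      # oxo-nonanoyl cleavage product
'PC(9:0<CHO@C9>/18:2)'
>>> ox.species_adduct_mz(lpp.species)     # PC aldehyde -> formate adduct
718.4301...
>>> from oxplid.fragmentation import generate_spectrum
>>> for ion in generate_spectrum(lpp.species).ions[:4]:
...     print(f"{ion.mz:9.4f}  {ion.relative_intensity:4d}  {ion.ion_type}")
 168.0431   400  head_fragment:phosphocholine-CH3
 171.1027   850  sn1_carboxylate
 224.0693   400  head_fragment:glycerophosphocholine-CH3-H2O
 279.2330   999  sn2_carboxylate
```

171.1027 is the oxo-nonanoate anion (C9H15O3⁻) — the diagnostic fragment
of the truncated chain — next to the intact linoleate at 279.2330 and
the PC head-group ions.

## Command line

```sh
oxplid predict  --lipidome lipidome.csv --out-sdf predicted.sdf --out-table predicted.csv
oxplid fragment --sdf predicted.sdf --out-msp predicted.msp
oxplid identify --mzml run1.mzML --sdf predicted.sdf --out results/ --workers 4
oxplid fixtures --spec fixture.yaml --library predicted.sdf --out synthetic.mzML
```

`predict` reads a CSV/XLSX with an `abbreviation` column; `identify`
writes per-run CSV/XLSX tables (one row per accepted identification
with m/z, ppm error, retention time, scan metadata and all five scores)
plus a JSON log and optional PNG review plots.  `fixtures` builds fully
synthetic, seeded DDA runs for testing.

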