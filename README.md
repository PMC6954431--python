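# sugarcdl

Conformation-dependent stereochemical restraints for the sugar
(ribose / 2′-deoxyribose) moiety of nucleic acids.

Crystallographic refinement of nucleic acids at ordinary resolution leans on
restraint dictionaries — target values and standard deviations for every bond
length and bond angle. Classical dictionaries assign one fixed target per
parameter (split at most by ribose vs deoxyribose). The furanose sugar,
however, is the flexible hinge of the nucleotide: its covalent geometry moves
with the ring pucker, with the glycosidic torsion χ and with the exocyclic
torsion γ. `sugarcdl` implements a restraint generator in which targets are
conditioned on conformation:

* **fixed targets** per conformational group — sugar type (R/D), base type
  (purine/pyrimidine), ring pucker class (C2′-endo: 144° ≤ P ≤ 190°,
  C3′-endo: 0° ≤ P ≤ 36°, Other), χ rotamer (syn: |χ| ≤ 90°, anti) and γ
  rotamer (gauche+ 60 ± 30°, gauche− −60 ± 30°, trans 180 ± 30°);
* **linear targets** for the five endocyclic ring angles,
  `angle = a·τ_m + b` with negative slope `a` — the larger the pucker
  amplitude τ_m, the smaller the ring angles;
* **periodic targets** for the glycosidic C1′–N and anomeric O4′–C1′ bond
  lengths, `d = a·cos(2χ + b) + c` (180°-periodic, extremes at χ ≈ ±90°), and
  tabulated 360°-periodic curves for the four glycosidic-link angles
  (N–C1′–C2′, N–C1′–O4′, C1′–N–C2/C4, C1′–N–C6/C8), which are periodic but
  not sinusoidal;
* **terminal overrides** for the five parameters touching a free 3′/5′
  hydroxyl (C3′–O3′, C5′–O5′, C2′–C3′–O3′, C4′–C3′–O3′, C4′–C5′–O5′).

The pseudorotation description (P, τ_m) is obtained by least squares over the
five endocyclic torsions, ν_j = τ_m·cos(P + 144°·(j−2)).

The package also reimplements the **derivation pipeline** that produces such a
dictionary from a fragment-geometry table: quality filtering (R ≤ 8.5%,
σ(C–C) < 0.01 Å), modified-Z-score outlier rejection
(M_i = 0.6745(x_i−x̃)/MAD, |M_i| > 3.5, structure-level removal), subgroup
discovery by pairwise Welch t-tests, Spearman screening of functional
relations (|ρ| > 0.5, p < 0.05), Bayesian-ridge fits for τ_m-linear relations
and Gaussian-process regression (exp-sine-squared kernel, 180°/360° period
candidates selected by log marginal likelihood) for χ-periodic ones — plus a
synthetic fragment-table generator for closed-loop testing.

> **Note on the shipped dictionaries.** The packaged target files
> (`sugarcdl/data/*_synthetic.csv`) are synthetic-labelled reference sets:
> values quoted in accompanying running text are transcribed exactly, the
> remaining groups are populated with standard nucleoside geometry, and the
> tabulated χ-curves are regenerated by the package's own GPR fit
> (`scripts/build_dictionary_data.py`). The file headers state precisely
> which entries carry which status.

## Worked example

Generate REFMAC external restraints for a DNA dinucleotide model:

```bash
sugarcdl model.pdb -o model.refmac --format refmac
```

The equivalent library call, on a synthetic fixture built at an exactly known
conformation (C3′-endo, τ_m = 38°, χ = −120° anti, γ = 60° gauche+):

```python
import sugarcdl as s

st = s.to_gemmi_structure(
    s.build_nucleotide(sugar_type="ribose", base_type="purine",
                       P=18.0, tau_m=38.0, chi=-120.0, gamma=60.0),
    "ribose", "purine")
frags = s.extract_fragments(st)          # 1 fragment, terminal at O3'/O5'
recs = s.records_from_generated(
    s.build_full_restraint_set(frags, s.RestraintDictionary.load("this-work")))
print(s.write_refmac(recs).splitlines()[1])
```

prints

```
exte angle first chain A resi 1 atom C1' second chain A resi 1 atom C2' next chain A resi 1 atom C3' value 101.30 sigma 0.60
```

— the C1′–C2′–C3′ target evaluated at this fragment's own τ_m
(−0.130·38 + 106.24 = 101.30°, σ = 0.6°). A terminal sugar in the anti /
gauche+ conformation receives the terminal C4′–C5′–O5′ target 111.5°
(110.6° when the 5′ oxygen continues into a phosphodiester), and the terminal
C5′–O5′ bond target 1.421 Å. Output formats: REFMAC `exte` keywords, PHENIX
`geometry_restraints.edits`, and SHELXL `DFIX`/`DANG` (angles converted to
1–3 distances by the law of cosines with first-order sigma propagation).
Restraints are regenerated from scratch on every invocation: group
assignments follow the model's conformation, so they should be refreshed
before each refinement cycle.

Scoring a model against a dictionary (every target evaluated at the
fragment's own P, τ_m, χ, γ):

```python
rep = s.score_model("model.pdb", s.RestraintDictionary.load("this-work"))
print(rep.rmsd_bonds, rep.rmsd_angles)
```

## Layout

| module | contents |
| --- | --- |
| `sugarcdl.geometry` | PDB/mmCIF parsing (gemmi), fragment extraction, torsions, pseudorotation |
| `sugarcdl.classify` | pucker / χ / γ window classification, `ConformationContext` |
| `sugarcdl.dictionary` | target forms, keyed lookup with fallbacks, full restraint sets |
| `sugarcdl.derivation` | filters, outlier rejection, Welch/Spearman screens, GPR/ridge fits, `DictionaryBuilder` |
| `sugarcdl.synthetic` | fragment-table generator, 3D nucleotide fixture builders |
| `sugarcdl.recovery` | closed-loop self-consistency ensemble |
| `sugarcdl.writers` | REFMAC / PHENIX / SHELXL emitters |
| `sugarcdl.validation` | model scoring, deviation reports, Wilcoxon comparison |
| `sugarcdl.cli` | `sugarcdl` command and `api_generate` |
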