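# phasemet

Rule-based phase I/II metabolite prediction and LC-HRMS annotation for
synthetic cannabinoid receptor agonists (SCRAs), with a ground-truthed
synthetic-run generator for end-to-end validation.

## The problem

Synthetic cannabinoids are so extensively metabolized that the parent drug
is often undetectable in urine; forensic and clinical toxicologists instead
screen for metabolites. Given a parent compound's elemental composition and
a moiety-level structural inventory, `phasemet` enumerates the plausible
phase I (oxidation, hydrolysis, dealkylation, defluorination) and phase II
(glucuronidation) products as composition shifts, matches them against
high-resolution MS1 features at a ppm tolerance, and uses scaffold-specific
diagnostic MS2 fragment ions to localize each modification to a moiety.
It ships the registries for six SCRAs from two scaffold classes —
indazole-3-carboxamides (ADB-BUTINACA, MDMB-4en-PINACA) and isatin acyl
hydrazones / OXIZIDs (BZO-HEXOXIZID, BZO-POXIZID, BZO-4en-POXIZID,
5F-BZO-POXIZID) — and is user-extensible through the same plain-text
tables.

## The model

* **Masses.** Monoisotopic, from integer element counts. Protonated
  molecules are scored as M + m(H⁺); even-electron fragment cations as
  Σ atoms − m(e⁻). A singly charged positive-mode acquisition is assumed
  throughout (HESI, [M+H]⁺ only).
* **Biotransformations.** A fixed catalog of 11 named composition deltas
  with structural gating and multiplicity caps, e.g. hydroxylation +O
  (≤3×), dehydrogenation −H₂ (≤2×), dihydrodiol +H₂O₂ (requires and
  consumes a C=C double bond), oxidative defluorination −F+O+H (requires
  fluorine), N-dealkylation −(chain) with the loss parameterized per
  parent, and terminal glucuronidation +C₆H₈O₆ (requires a free hydroxyl
  or carboxyl produced upstream). Candidates are the breadth-first closure
  of rule application up to a depth cap (default 4), deduplicated by
  (composition, rule multiset).
* **Matching.** A feature annotates to every candidate within the ppm
  window (default 5 ppm, as in the emulated acquisition); annotations are
  ranked by |ppm error|, then path depth. No probabilistic scoring and no
  retention-time rule — RT is carried through for reporting only.
* **Localization.** Diagnostic ions observed *shifted* by a step's mass
  delta vote for the moieties they contain; unmodified ions observed at
  their native m/z veto theirs. One surviving moiety is the call;
  anything else is reported `ambiguous`. Atom positions are never
  asserted.
* **Formula fitting.** `fit_composition` exhaustively enumerates bounded
  compositions within a ppm window with a ring-and-double-bond-equivalents
  plausibility filter (RDBE = C − (H+F)/2 + N/2 + 1 ≥ 0; integer for
  neutral molecules).

## Worked example

```python
from phasemet import get_compound, enumerate_metabolites

adb = get_compound("ADB-BUTINACA")
print(f"{adb.name}: {adb.composition.hill()}  [M+H]+ = {adb.mz:.4f}")
for c in enumerate_metabolites(adb, max_depth=1):
    print(f"  {c.mz:9.4f}  {c.composition.hill():12s}  {c.rule_path}")
```

prints

```
ADB-BUTINACA: C18H26N4O2  [M+H]+ = 331.2129
   275.1503  C14H18N4O2    N_dealkylation
   329.1972  C18H24N4O2    dehydrogenation
   332.1969  C18H25N3O3    amide_hydrolysis
   345.1921  C18H24N4O3    ketone
   347.2078  C18H26N4O3    hydroxylation
   361.1870  C18H24N4O4    carboxylation
```

i.e. the one-step metabolite space of ADB-BUTINACA: the m/z 347.2078
monohydroxylation, the m/z 332.1969 amide-hydrolysis acid and the
m/z 275.1503 N-dealkylation product, each with its elemental composition.
The same workflow from the shell, on a simulated run with known ground
truth:

```sh
phasemet simulate --parent ADB-BUTINACA --n-planted 10 --n-decoys 5 \
    --sd-ppm 1 --seed 42 --out-dir run/
phasemet annotate --features run/features.csv --mgf run/spectra.mgf \
    --parent ADB-BUTINACA --out annotations.csv --report report.txt
phasemet biomarkers --annotations annotations.csv --k 3
```

`report.txt` then summarizes the run (10/15 features annotated, the 5
decoys left unannotated) and shortlists the three largest-area metabolite
features as biomarker candidates. Other subcommands: `predict`
(candidate enumeration) and `fitformula` (accurate-mass composition
fitting).

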