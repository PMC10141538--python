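# Methods

## Scope and approach

`phasemet` treats metabolite identification as composition arithmetic plus
moiety-level structural bookkeeping. A parent drug is a molecular formula
together with a coarse inventory — scaffold class, N-alkyl side chain
(with the alkene-equivalent composition lost on dealkylation), and flags
for labile groups (terminal amide, methyl ester, fluorine, alkene,
benzoyl). Everything downstream — candidate enumeration, MS1 matching,
MS2 localization — operates at this granularity. The package deliberately
does not model atom-level regiochemistry, fragmentation mechanisms, or
metabolite abundance; hydroxyl positions within a moiety are genuinely
uncertain at this level of evidence and are reported as such.

## Mass conventions

Monoisotopic atomic masses (¹²C = 12 exactly, H 1.0078250319,
N 14.0030740052, O 15.9949146221, F 18.9984032 Da; electron
0.0005485799 Da, proton 1.0072764665 Da). Protonated molecules are
M + m(H⁺); even-electron fragment cations, written including their
charge-carrying hydrogens, are Σ atoms − m(e⁻). The electron term matters:
at m/z 105 it is 5 ppm. Reported m/z values are rounded to 4 decimals;
internal arithmetic is full double precision.

`fit_composition` enumerates all compositions within per-element bounds
whose ionic mass falls in a ppm window, filtered by ring-and-double-bond
equivalents RDBE = C − (H+F+Cl)/2 + (N+P)/2 + 1 ≥ 0. For protonated-
molecule fitting the neutral candidate must have integer RDBE. For
fragment fitting both electron bookkeepings are legitimate targets: a
half-integer-RDBE formula is an even-electron cation (scored at
Σ atoms − e⁻), while an integer-RDBE formula is interpreted as a neutral
loss and scored at its plain mass. This dual convention is what lets a
measured 56.0626 Da loss resolve to C₄H₈ while m/z 145.0398 resolves to
the C₈H₅N₂O⁺ acylium.

## The rule catalog

Eleven biotransformations, each a signed composition delta with gating:

| rule | Δ composition | Δm (Da) | gate | cap |
|---|---|---|---|---|
| hydroxylation | +O | +15.9949 | — | 3 |
| dehydrogenation | −H₂ | −2.0157 | — | 2 |
| hydrogenation | +H₂ | +2.0157 | alkene (consumed) | 1 |
| ketone formation | +O −H₂ | +13.9793 | — | 1 |
| carboxylation | +O₂ −H₂ | +29.9742 | — | 1 |
| dihydrodiol | +H₂O₂ | +34.0055 | alkene (consumed) | 1 |
| amide hydrolysis | −N −H +O | +0.9840 | terminal amide | 1 |
| ester hydrolysis | −C −H₂ | −14.0157 | methyl ester | 1 |
| N-dealkylation | −(chain) | parent-specific | side chain | 1 |
| oxidative defluorination | −F +O +H | −1.9957 | fluorine (consumed) | 1 |
| glucuronidation | +C₆H₈O₆ | +176.0321 | free OH/COOH; terminal | 1 |

Design choices made where the design was open:

* **Ketone/carboxylate as dedicated rules.** A ketone is composition-
  identical to hydroxylation + dehydrogenation; both paths are enumerated
  (deduplication is by composition *and* rule multiset, so each appears
  once) because the dedicated rule lets reports and localization say
  "ketone" explicitly, and it reaches the +14 Da product in one step.
* **Multiplicity caps** (3× hydroxylation, 2× dehydrogenation, 1×
  otherwise) mirror the deepest products observed for these scaffolds
  (trihydroxylation; doubly desaturated acids). Caps are user-overridable.
* **Glucuronidation gating.** None of the six parents carries a free
  hydroxyl or carboxyl, so a conjugate always requires an upstream
  functionalization step; the rule is terminal (nothing follows it).
  Dehydrogenation does *not* consume a hydroxyl even though ketones
  chemically form from alcohols — at composition level the dehydrogenation
  site is unknowable, so the inventory stays permissive. The cost is a
  handful of chemically optimistic glucuronidation paths; the benefit is
  that no printed conjugate is ever missed.
* **N-dealkylation after chain modification.** The dealkylation delta is
  the parent's intact-chain loss. If an earlier step has already altered
  the chain (e.g. oxidative defluorination removed the fluorine), the
  fixed delta would drive an element count negative; such applications are
  treated as inapplicable rather than recomputing a modified-chain loss.
* **Benzamide-bond hydrolysis** of the isatin acyl hydrazone linker
  (−C₇H₄O) is implemented but flagged provisional and excluded from the
  default catalog: no printed m/z confirms the product compositions.
* **Enumeration depth** defaults to 4 steps — the deepest combination with
  literature support (hydrolysis + hydroxylation + dehydrogenation +
  glucuronidation). The breadth-first closure keeps the minimal-depth path
  per (composition, multiset) state; candidate counts are monotone in
  depth by construction.

## Fragment library and localization

Each scaffold has a fixed table of diagnostic even-electron cations
(shipped as `data/fragments.tsv`, compositions locked by an accurate-mass
fitting pass so the table cannot silently drift): for the
indazole-3-carboxamides the indazole acylium C₈H₅N₂O⁺ (m/z 145.0396), the
N-alkyl indazole acylium and rearranged seven-membered ions, the α-cleavage
ion and the t-butyl iminium C₅H₁₂N⁺ (86.0964); for the isatin acyl
hydrazones the oxoindoline ion (145.0396), benzoyl C₇H₅O⁺ (105.0335),
phenyl C₆H₅⁺ (77.0386) and the hydrazone core C₉H₈N₃O⁺ (174.0662). Each
ion carries the set of moieties it contains.

A product-ion peak is explained as a library ion, a library ion shifted by
any sub-multiset of the candidate's rule deltas, or either minus one
neutral loss (H₂O 18.0106; HF 20.0062, fluorinated species only — deeper
loss chains add noise without evidential support). Localization is set
logic per step: moieties covered by shifted observations, minus moieties
covered by unshifted observations of unmodified ions. A unique survivor is
the call; survivors exactly matching one composite ion's coverage return
that composite's label (e.g. "N-butyl-indazole" when core and chain cannot
be separated); otherwise `ambiguous`. Ions that already embed a
modification (hydroxybenzoyl; the oxoindoline ketone diagnostic) never
veto, since observing them unshifted is evidence *for* the modification,
not against it.

## Annotation and biomarker ranking

Matching is deterministic tolerance gating at 5 ppm (the emulated
acquisition's acceptance window); every in-window candidate is kept,
ranked by |ppm|, then depth, then rule path — isomeric candidates sharing
an m/z are all reported rather than forced to a unique call. There is no
FDR machinery: with decoys placed ≥20 ppm away, false positives are a
structural impossibility rather than a statistical rarity, and real-data
use should treat the annotation list as a screen, not an identification.
Biomarker ranking takes the top-k (default 3) annotated features by peak
area, parent excluded (it is reported separately), ties broken by smaller
|ppm| then feature id, and flags shortlists that came up short.

## The synthetic-run generator

The generator emulates a positive-mode full-scan/data-dependent-MS2
Orbitrap acquisition: MS1 survey m/z 100–1000, product ions m/z 50–1000,
retention times uniform in the 5.10–11.67 min window where these
metabolites elute, mass error Gaussian in ppm (SD default 1 ppm, standard
Orbitrap performance) truncated at the ±5 ppm acceptance window, and
log-normal peak areas (median 10⁶, σ = 1 — the emulated study reports no
intensity distributions, so the model is deliberately simple). Planted
features take their m/z from enumerated candidates; decoys are uniform
with rejection inside 20 ppm of any candidate. All randomness flows
through one seeded `numpy` Generator.

Planted MS2 spectra are built from the unmodified fragment library: ions
containing a step's planted moiety appear shifted by that step's delta,
others at native m/z, each with a configurable completeness probability.
Hydroxylation sites are drawn only from the moieties the library can
actually resolve (`resolvable_moieties`, computed from the table, not
hard-coded): chain and t-butyl for ADB-BUTINACA; core, chain and t-butyl
for MDMB-4en-PINACA; core and benzoyl for the OXIZIDs — the OXIZID library
contains no unmodified chain-bearing ion, so a chain hydroxylation is
structurally unlocalizable with these diagnostics and planting one would
make the localization round-trip unachievable by construction rather than
by defect. Hydrolyses and glucuronidation shift no diagnostic ion (the
linker and the labile conjugate are outside every ion's coverage), which
reproduces the observed behaviour that conjugate spectra show unchanged
characteristic fragments.

What the generator does **not** emulate — and hence what passing
round-trip tests do not show about real data: chromatographic peak shape
and RT structure, isotopologue envelopes, in-source fragmentation,
co-eluting isobars closer than 20 ppm, intensity-dependent mass error, and
real fragmentation chemistry beyond the fixed diagnostic set.

## Problem sizes and numerical choices

The validation suite and the reproduction script use runs of 30 planted
candidates + 30 decoys over 20 seeds (600 planted features) for recovery,
20 single-hydroxylation features per parent for localization, and a 50-
target exhaustive cross-check of formula fitting on bounds C≤12 H≤20 N≤4
O≤4 F≤1 — sizes at which every quantity is stable to well under a percent
while the whole suite runs in seconds. Ties are broken lexicographically
everywhere (rule ids, feature ids) so identical inputs give byte-identical
outputs. Degenerate inputs fail loudly: empty formulas, non-positive
tolerances, out-of-range scan values, rule paths outside the enumerated
closure and malformed interchange files all raise with a message naming
the offending item.

## Known limitations

* Composition-level enumeration cannot distinguish positional isomers;
  the annotator reports all of them and localization resolves only to
  moiety granularity.
* The N-dealkylation delta assumes an intact side chain (see above).
* The OXIZID benzamide-hydrolysis products are provisional.
* Peak-area biomarker ranking reflects in-vitro relative response, not
  in-vivo abundance; it is a screening heuristic.
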