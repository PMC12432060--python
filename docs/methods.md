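# Methods

## Scope and model

`sulfoscreen` implements a suspect-screening workflow for sulfated and
non-sulfated phenolics in negative-mode untargeted LC–HRMS/MS data. The
chemistry model is deliberately minimal: singly deprotonated ions only
([M−H]⁻), monoisotopic masses only (no isotope envelopes), one conjugate
moiety per suspect, and 0–3 sulfate groups. These bounds match how sulfated
phenolics are actually observed in seaweed extracts under ESI-negative
acquisition; dimers, multiply charged species and positive-mode adducts are
out of scope.

## Mass conventions

Element monoisotopic masses are hard-coded to 7 decimals (IUPAC/CODATA;
C = 12 exactly). [M−H]⁻ m/z is computed as M − 1.0072765 Da by default; an
`electron_correction` flag on `IonConvention` adds 0.0005486 Da, making the
constant-choice ambiguity of vendor software explicit and testable. Against
the packaged 44-compound reference set, recomputed mass errors agree with
the curated values within ±0.31 ppm; the test suite asserts ±1 ppm because
the reference values were produced by vendor software whose internal
constants are unknown. `pyteomics.mass` is used in tests as an independent
oracle for the element-mass table (agreement ≤ 1e−5 Da per formula) but
never in the implementation path.

## Suspect database

The shipped registry encodes 32 aglycones — 6 phenols, 16 phenolic acids,
4 coumarins, 6 phlorotannins — with Hill formulas and free-hydroxyl counts
(aromatic vs aliphatic) taken from standard structures. Phloroethol
oligomers follow a −H₂-per-aryl-ether-coupling pattern from phloroglucinol
units; the eckol dimer is encoded as the dieckol-type C–C coupled dimer
(2 × eckol − H₂). Conjugation adds the free moiety minus water (hexose
+C6H10O5, pentose +C5H8O4, quinic +C7H10O5, shikimic +C7H8O4); sulfation
adds n × SO₃. Formula collisions between distinct
(aglycone, moiety, n_sulfates) triples are retained: isobaric suspects are
separated downstream by RT and MS2, not in the mass list. The default build
is exactly 640 entries (160 non-sulfated), and the export is byte-stable
with the ion-convention constants in its header.

## Screening cascade

Defaults: 5 ppm mass tolerance everywhere (the widest mass error in the
curated reference set is 4.7 ppm, so 5 ppm reproduces its acceptance
envelope), 0.1 min RT tolerance for alignment, 0.2 min RT window for
feature↔MS2 linking, and a 5-fold blank ratio. The blank ratio and the
alignment parameters are conventions of this implementation — vendor
preprocessing does not publish its internals — so they are configurable and
recorded in the filtering report. Alignment is single-linkage over the
(m/z, RT) tolerance graph with intensity-weighted consensus coordinates.
Every post-alignment stage is contractive, and the JSON report records
in/out counts per stage.

## MS2 rule engine

Fragment matching uses an absolute ±5 mDa tolerance by default (the spread
of the sulfate diagnostic ions across the curated reference spectra is
≤ 1.5 mDa; 5 mDa stays inclusive below m/z 500 without inviting false
matches) and a ≥ 0.5 % base-peak relative-intensity floor. SO₃⁻· and HSO₄⁻
reference m/z are derived from formulas under the active `IonConvention`
rather than hard-coded, so the electron-correction flag propagates.

Site localization: SO₃⁻ only → aromatic; HSO₄⁻ only → aliphatic; both →
both; neither (but an SO₃ neutral loss) → undetermined. A call that requires
a hydroxyl class the scaffold does not carry is downgraded to undetermined
with a warning. Non-sulfated candidates are always `none`.

Candidate/rule pairing: each mass-list candidate is reduced to its
aglycone-level formula (minus sulfates, minus moiety delta) and paired with
*every* library rule of that composition, including isobars of the nominal
aglycone. The winner maximizes matched diagnostics, with curated rules
preferred over generic ones and smaller |ppm error| as the final tie-break.
This mirrors manual validation practice, where the scaffold whose fragments
are present wins regardless of which isobar the mass list happened to name.
Registry aglycones without curated fragments receive generic rules ([M−H]⁻
plus −H₂O/−CO/−CO₂) so every suspect remains annotatable.

Confidence levels: level 2 requires ≥ 2 matched aglycone diagnostics *and*
sulfate evidence consistent with the candidate's sulfation level; everything
else is level 3. This numeric criterion is a declared heuristic — published
annotations assign levels case by case and do not state one — and it is not
guaranteed to reproduce every hand-assigned level (single-fragment scaffolds
such as phloroglucinol cap at level 3 here). Retention-order checks (more
free hydroxyls → earlier elution within a homolog family; sulfate no later
than its parent) emit warnings only, never rejections, because documented
exceptions exist (a coumarin sulfate eluting after its putative parents).

## Synthetic data generator

The generator emulates the study design it is meant to stress: 10 samples
(2 green / 4 brown / 4 red; 8 edible / 2 infesting) × 3 replicate
injections, 200 planted suspects and 200 decoys by default, 1.5 ppm mass
jitter, 0.02 min RT jitter, 10 % fragment dropout, and lognormal abundances
(base ln-area 13.8 ≈ 1e6, between-compound SD 0.5, replicate SD 0.2) with
group × class fold-changes: ×100 on phenol and phenolic-acid sulfates in
green algae (observed enrichments reach three orders of magnitude), ×50 on
phlorotannins in brown algae, ×5 on coumarins in red algae. Decoy m/z are
drawn uniformly and rejected within 20 ppm of any suspect (bounded retries);
a configurable fraction of decoys also appears in the blank run. Planted
compounds are separated by ≥ 0.3 min whenever their masses lie within
10 ppm, so alignment cannot merge two distinct ground-truth suspects.

Spectra are assembled from the rule library: fragment intensities follow a
Dirichlet(α = 4) over the template peaks with a lognormal absolute scale,
and fragment m/z get 0.5 mDa Gaussian jitter. **Dropout applies to the
aglycone diagnostic fragments only**; the SO₃⁻/HSO₄⁻ ions and the SO₃
neutral-loss ladder are always emitted for sulfated compounds, reflecting
that these are consistently intense, dominant ions in real spectra of
sulfated phenolics. Consequences for interpreting the tests: recovery and
site-accuracy results certify the pipeline's bookkeeping and rule logic
under mass error, dropout of minor fragments and decoy pressure — they do
not certify robustness to weak or absent sulfate diagnostics, co-eluting
chimeric spectra, or real chromatographic noise, none of which the
generator models. Peak shapes, isotope patterns and profile data are also
not simulated.

Default problem sizes (200 + 200 features × 30 runs, one MS2 spectrum per
planted compound) keep a full simulate → screen → annotate → score round
trip under a few seconds on one CPU; the seeded acceptance run uses exactly
these defaults.

## Statistics

Reporting classes follow the five-class convention (phenol sulfates,
phenolic acids, phenolic acid sulfates, coumarins, phlorotannins), with
sulfated and non-sulfated coumarins/phlorotannins pooled and a single
regrouping rule applied once: phloroglucinol sulfate joins the
phlorotannins (it is their monomer and co-varies with them). IQR filtering
defaults to fraction 0 — for matrices of a few dozen compounds, variance
filtering would discard real signals. Autoscaling uses ddof = 1 and drops
zero-variance columns with a warning; it is idempotent. PCA is full-SVD
(scikit-learn); hierarchical clustering defaults to Euclidean/Ward;
correlation heatmaps default to Pearson with average-linkage clustering on
1 − r. Class totals conserve the grand total exactly. Replicates may be
kept as separate rows or pre-averaged by the caller; both orientations are
supported by the matrix I/O helpers.

## Known limitations

* Mass-list matching cannot distinguish isobaric suspects; without an MS2
  spectrum the nominal candidate is just the lowest-|ppm| entry.
* The confidence-level rule is a fixed heuristic (see above).
* Aglycone formulas and hydroxyl counts for scaffolds not confirmed by the
  packaged reference set are encoded from standard structures and should be
  re-verified before extending the registry.
* The real-data feature cascade of a full seaweed study (tens of thousands
  of raw features) is representable but not reproducible here; synthetic
  data validate behaviour, not instrument-scale counts.
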