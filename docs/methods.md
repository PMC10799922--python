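# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Kabat numbering

Numbering is profile-based: the query VH is globally aligned (BLOSUM62,
affine gaps, open −11 / extend −1) against each bundled reference profile,
and Kabat labels are transferred from the best-scoring reference.  Ties on
score are broken by fewest indels, then lexicographically smallest
reference id, which makes the result independent of reference iteration
order.  The best alignment must reach ≥50% identity over aligned columns;
anything lower raises `NoReferenceMatch` so non-antibody input fails loudly
rather than being numbered nonsense.  If equal-scoring references imply
different CDR lengths for the query, `AmbiguousNumbering` is raised.

Framework labels come straight through the alignment; query insertions
inside a framework receive insertion letters on the preceding position.
CDR loops are renumbered from their observed length with insertions at the
Kabat-specified points (35A/B, 52A–C, 100A–K).  Two conventions had to be
fixed for loops shorter than the canonical span: CDRH3 keeps its
C-terminal anchor (101, 102) and truncates from the middle, while
CDRH1/CDRH2 are numbered consecutively from their N-terminal side.  These
cases are rare in natural VH domains; other tools may label extreme CDRH3
lengths (>17) differently, which is a documented edge, not a guarantee.

The bundled references are three **synthetic consensus-style human VH
family profiles** (VH1/VH3/VH4-like) with hand-built, self-consistent
Kabat label tracks (including the 52A and 82A–C insertions typical of
those families).  They are not germline database entries; users with real
repertoires should supply their own reference TSV.  Invertibility — the
labelled residues concatenate back to the exact input — holds by
construction and is asserted on every call.

## Graft sets and rarity

A graft set is a mapping of Kabat labels to target residues; grafting
substitutes, never inserts or deletes, so the engineered sequence has the
parent's length and differs only at set positions.  A position already
carrying its target contributes no mutation, which is why a fixed-size set
yields variable per-clone counts (4–8 across the bundled panel, mean ≈ 7).

The shipped table (`data/graft_sets_synthetic.tsv`) is a **synthetic
reconstruction**: the published residue identities are figure-encoded and
not machine-readable, so the file preserves the sets' documented
structure — eight core substitutions each; hydrophobic targets on the VH
β-strands A/B/D/E for the two affinity-interface sets, each with two
optional "strengthening" substitutions (excluded by default, enabled by
flag); and a domain-exchange set whose single CDRH2 position is the only
CDR-resident label in any set.  The file is data, not code, so an audited
transcription can replace it without touching logic.

Rarity: a mutation is flagged when the frequency of its target residue at
that Kabat position is strictly below the threshold (default 0.01, i.e.
<1% of deposited sequences).  The bundled frequency table is a toy
(deliberately rare domain-exchange targets at 0.005, borderline-common
affinity-2 targets at 0.03); real abYsis-style tables load from the same
TSV format.  Logo heights use information content IC = log₂20 − H in bits.

## Monomer–dimer self-association

Model: M + M ⇌ D with K_D = [M]²/[D] (μM, monomer-equivalents).  The mass
balance [M] + 2[M]²/K_D = c_tot has the closed form
[M] = (−K_D + √(K_D² + 8 K_D c_tot))/4, verified against bisection and
conserving mass to 1e-10 relative across six decades of concentration.
The observable is the weight-average sedimentation coefficient
s_w = ([M]s_M + 2[D]s_D)/c_tot, strictly increasing in c_tot with limits
s_M and s_D.

Fitting happens at the **isotherm level** (s_w versus loading), not by
Lamm-equation boundary modelling: the parameterization and identifiability
structure are the same, at desk scale.  The optimizer is bounded
trust-region least squares with five deterministic starts (data-driven
base estimate jittered log-normally under a fixed internal seed); a
noiseless synthetic isotherm is recovered to 1e-6 relative.  A flat
isotherm (s_M = s_D, or a fully saturated/dilute design) leaves K_D
undetermined and raises `NonConvergence` with diagnostics rather than
returning an arbitrary number.  Optional residual-bootstrap percentile
intervals are available.

Fixture constants: the simulated Fab uses MW 48 kDa, s_M = 3.5 S,
s_D = 5.5 S — typical values for a Fab monomer and dimer, fixed a priori
as study conditions.  The three standard loadings, 0.6/0.2/0.07 mg/ml,
convert to 12.5/4.17/1.46 μM (μM = mg/ml ÷ Da × 10⁶).

**Statistical caveat.**  With three observations and three floated
parameters the least-squares fit interpolates the data exactly, so a
single replicate's K_D estimate is heavy-tailed under noise (quartiles
roughly [0.5, 20] μM at 2% proportional noise around a 6.8 μM truth).
The replicate *median* is the meaningful summary: its long-run value sits
within ~8% of truth, but the median of 100 replicates still carries a
sampling spread of a few μM, so any fixed tolerance band tighter than that
spread is met or missed largely by seed.  The module's bias test therefore
runs at 0.5% noise, where 100 replicates can actually resolve a 5% bias in
log K_D.  Real sedimentation-velocity analyses fit hundreds of boundary
points per loading and do not face this degeneracy.

## Alanine-scan epitope mapping

Scan design: one variant per non-cysteine residue (Ala, or Gly where the
wild type is already Ala); cysteines are skipped to preserve disulfides, so
the variant count is length − #Cys.  A 214-residue ectodomain with 8
cysteines (the IL-2Rβ construct A27–T240 geometry) yields 206 variants.
For the IL-2Rγ-sized construct (L23–A262, 240 residues) the printed count
of 203 scan mutants is *not* reconcilable with this rule for any plausible
cysteine count; additional, unstated exclusions (e.g. failed constructs)
must exist, so that number is documented here and never asserted.

Normalization: binding = analyte response / capture level, expressed
relative to wild type (WT ≡ 1).  Mutants captured at ≤10% of the WT level
are excluded and reported separately — they report expression/capture
failure, not epitope.  A position is disruptive when relative binding
< 0.33 (configurable; the underlying judgement is inherently a plotted
threshold, so a numeric default is required for automation).

Epitope calling: single-linkage connected components of disruptive
positions under a Cα–Cα cutoff of 10 Å, discarding components smaller
than 3; equivalent by construction (and by test) to the transitive closure
of the ≤cutoff adjacency.  Unmappable flagged positions are reported, not
dropped.  Epitope–epitope distance is the Euclidean distance between Cα
centroids in nm — reproducible from Cα-only structure parsing and adequate
at the 3–5 nm scale relevant for paired-epitope geometry; it is not a
surface-to-surface distance.

## Single-particle tracks

Simulation: 2D Brownian steps per axis ~ N(0, √(2DΔt)), reported positions
add N(0, σ) localization error, frame intensity is
oligomer_size × unit + background (+ optional noise); a multimer
co-diffuses as one entity.  Defaults mirror a 20 Hz / 130 nm-pixel
acquisition.  The generator does not emulate photobleaching, blinking,
track splitting/merging, detection misses, confined or anomalous
diffusion, or cell-shaped geometry — so passing tests demonstrate the
correctness of the estimators on ideal free diffusion, not robustness to
those artefacts.

Filtering retains tracks whose every consecutive-frame step is ≤390 nm
(3 pixels) and whose lifetime is ≥3 frames (150 ms).  "Max displacement"
is read as the per-step bound (the linking parameter of upstream
trackers); an `excursion` mode bounding displacement from the first
position is provided since the phrasing is ambiguous.  MSD uses
time-and-ensemble averaging over all start frames by default (an
ensemble-only mode exists; the choice is recorded in the curve object).
D comes from an OLS line through the first 4 lags: slope = 4D, intercept
= 4σ² of localization error.  Problem sizes in tests (≈10⁵ steps) put the
Monte-Carlo error of the checks near 1–2%.

## Fixtures

`make_vh_panel` derives ten clones from the three references: every clone
gets 3–5 seeded framework substitutions away from graft positions, and a
fixed plan plants graft-target residues at 1–4 set positions in five of
the clones, emulating acceptors with varying conservation.  The resulting
per-clone graft counts span 4–8 with a panel mean ≈ 7.  `make_toy_receptor`
builds a 60-residue ectodomain whose structure is a straight chain with a
five-residue spatial blob (pairwise <8 Å) plus one spatially isolated
disruptive decoy and one low-capture variant, so the default pipeline must
recover exactly the planted epitope while exercising both exclusion paths.
The ectodomain stand-ins named `*_synthetic` are deterministic artificial
sequences with the documented construct boundaries and cysteine counts;
they are not the biological receptor sequences.

All generators are pure functions of their seed; regenerating a bundle
with the same seed reproduces byte-identical files.

## Known limitations

* Light chains are typed but not numbered; the graft sets are VH-only.
* CDR numbering conventions for extreme loop lengths may differ from other
  Kabat implementations.
* The self-association module does not model higher-order oligomers
  (e.g. hexamer equilibria) or hydrodynamic nonideality.
* Epitope calls depend on the supplied construct-to-structure residue
  offset; mismatched identities warn rather than fail.
* The tracking module consumes tracks; detection and linking from raw
  images are out of scope.
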