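# Methods

`dbdscreen` implements the desk-side computational stages of a campaign to
find small-molecule ligands that block the DNA-binding surface of a
forkhead transcription-factor DNA-binding domain (DBD): pharmacophore
perception and screening, NMR restraint mapping, restraint-gated docking
pose selection, fluorescence-polarization (FP) assay statistics and
transcriptome reversal classification. This note describes the models and
procedures, the parameters that matter, what the synthetic generators do
and do not emulate, and the known limitations.

## Structure handling

PDB structures are read through biotite; residue numbering stays exactly
as deposited (1-based), because the residue labels the field uses (Arg211,
His212, Ser215 on helix H3; Met221/Arg222 on strand S2) are deposited
numbers. When altloc records are present only the highest-occupancy
conformer is kept, so all downstream geometry is single-conformer. Polymer
classification is deterministic: residue names {DA, DT, DG, DC, A, U, G,
C} are nucleic, anything else carrying a CA atom is protein, the rest is
"other". Hydrogens are never placed by the package — protonation defaults
of commercial modelling suites are not public — so fixtures must carry
explicit hydrogens wherever hydrogen-bond geometry is evaluated; a donor
nitrogen with no attached hydrogen is skipped with a warning, never
silently.

## Contact perception and probe maps

A hydrogen bond requires donor–acceptor heavy-atom distance ≤ d_hb
(default 3.5 Å) and donor–H···acceptor angle ≥ θ_hb (130°); a hydrophobic
contact is a pair of apolar carbons within d_phob (4.5 Å), where an apolar
carbon has no bonded N/O/S (bond inference by covalent-radius distance,
1.3 Å for X–H and 1.8 Å for heavy pairs, used because toy fixtures carry
no CONECT records); an ionic contact is a pair of opposite formal-charge
group centroids within d_ion (5.5 Å), with charged groups taken from a
fixed residue/atom table (guanidinium, ammonium, imidazolium, carboxylate,
nucleic-acid phosphate). These are perception defaults in the style of
interaction-perception tools; all four are configurable because no single
published geometry defines them.

The probe interaction maps are a deliberate simplification. Energy at each
grid point is a sum of 6-12 Lennard-Jones terms over protein heavy atoms
(Lorentz–Berthelot combination of a visible per-element parameter table
with per-probe parameters) plus, for the polar probes, a hydrogen-bond
well that is Gaussian in distance (optimum 2.9 Å, width 0.35 Å) and gated
by a continuous angular ramp that suppresses approach from inside the
residue body. There is no electrostatics term and no force-field fitting;
what is preserved from the original mapping protocol is the semantics of
the three probes (sp3 NH donor "N1", carbonyl oxygen "O", hydrophobic
"DRY") and their favourability cut-offs of −4.0, −3.5 and −2.5 kcal/mol
respectively. Grid points closer than 0.5 Å to an atom are clamped to that
distance to avoid the r⁻¹² singularity. The angular gate is a continuous
function of geometry rather than a hard threshold so that maps are exactly
translation-invariant.

Consensus binding-site definition is a residue vote: a residue enters the
site when at least `min_votes` of the supplied pocket predictions contain
it, or when it belongs to the experimentally implicated set (which enters
unconditionally). The published protocol combined four pocket-prediction
algorithms but did not state the vote rule, so `min_votes` defaults to 2
and is configurable. The site centre is the centroid of included residues'
Cα/C1′ atoms and the radius the maximal centre-to-atom distance.

## Pharmacophore model and matching

Contacts are translated into ligand-side features: a protein-donated
hydrogen bond becomes an acceptor (HBA) feature at the acceptor position
with its direction along the acceptor→donor axis; a protein-accepted bond
becomes a donor (HBD) feature; hydrophobic contacts become H features;
ionic contacts the charge complement of the protein group. Same-kind
features within `merge_radius` (1.5 Å) coalesce to their centroid.
Features sourced from anchor residues — the refinement step that pinned
published models to Asn208, Ser209, Arg211, His212 and Ser215 — become
*required*: no conformer matches unless all of them are mapped.

A conformer matches when an injective, type-compatible assignment of its
feature points to model features exists such that after least-squares
rigid superposition every mapped point lies inside its feature's tolerance
sphere (default 1.5 Å for all kinds — tolerance values are never printed
in the literature this mirrors, so they are explicit and test-visible),
all required features are mapped, at least three pairs are mapped (fewer
under-determines the alignment), and any paired directions agree within
45°. Superposition is Kabsch with reflections forbidden (the smallest
singular direction is flipped when the determinant is negative), so
enantiomers cannot match through a mirror — chirality is preserved.

The assignment search is exact, not heuristic: backtracking over
type-compatible candidates with pairwise-distance pruning. The pruning
test — |d(features) − d(points)| ≤ tol_i + tol_j — is a necessary
condition under any rigid motion (triangle inequality), so it never
discards an acceptable assignment; a dedicated suite verifies equivalence
against a brute-force itertools enumeration on hundreds of randomized
instances. Among accepted assignments the best is chosen by most features
matched, then lowest RMSD, then lexicographically smallest mapping, making
screening output a deterministic function of library content (invariant
under permutation of the input).

This exhaustive search is exponential in model size and intended for the
model sizes this workflow uses (≲ 8 features); it is not a subgraph-
matching engine for large feature sets.

## NMR quantities

The chemical-shift perturbation of a backbone amide between free and
bound ¹H-¹⁵N HSQC peak lists is

    CSP = sqrt(Δδ_H² + (w·Δδ_N)²),  w = 1/5 by default,

the standard weighting that rescales the ¹⁵N axis onto the ¹H scale. The
weight is exposed as a parameter. Relative CSPs divide the absolute values
by the standard deviation of the whole set. Significance classes use
strict inequalities against mean, mean + 1σ⁰_corr and mean + 2σ⁰_corr. By
default σ⁰_corr is the plain sample standard deviation of the whole CSP
set; a trimmed variant (iterative exclusion of values above mean + 3σ
until stable) is available via the `trim` flag, since a corrected σ
computed after outlier exclusion is common practice and the superscript
notation suggests it — both are offered, and the default follows the
plainly stated definition. Peak matching across conditions is by residue
number only: the lists are assumed assigned, and no peak-tracking is
attempted. Titration series are summarized per residue as a CSP
trajectory with a monotone-non-decreasing flag (tolerance ε = 10⁻³ ppm),
the fast-exchange signature of a gradually shifting resonance.

STD epitopes: per proton, the amplification factor A_STD = (I0 − Isat)/I0;
relative percentages are scaled to the strongest proton; a proton is
"pronounced" at ≥ 50 % of the maximum (configurable), "absent" at
A_STD ≤ 0, otherwise "weak". The default synthetic pattern has four
pronounced protons (H1, H3, H5, H7), two weak (H4, H6) and one silent
(H2), mirroring the qualitative epitope of the oxalate-salt ligand the
workflow was built around.

## Pose selection under NMR restraints

Externally generated docking poses are ranked by energy; among the
`n_keep` = 20 lowest-energy solutions, the selected pose is the
lowest-energy one consistent with both restraint families:

* **CSP contacts** — each perturbed residue carries a tier weight (2 for
  the > 2σ tier, 1 for the > 1σ tier, mirroring the two-level emphasis of
  the experimental analysis); a residue is contacted when any of its heavy
  atoms lies within `contact_cutoff` (4.0 Å) of any ligand heavy atom; the
  contact fraction is the contacted weight share and must reach
  `f_min` = 0.6.
* **STD epitope** — per labelled ligand proton, burial is the count of
  protein heavy atoms within `burial_cutoff` (5.0 Å); the Spearman rank
  correlation (average ranks on ties, since burial counts are small
  integers) between burial and relative STD percentage must reach
  `ρ_min` = 0.3. With fewer than three labelled protons the correlation is
  undefined and consistency is decided on the contact fraction alone,
  flagged in the report.

The published protocol states only the qualitative rule ("lowest-energy
solution consistent with both experiments"); the four thresholds above
make it operational and are all configurable. Selection is invariant
under permutation of the pose list (energy ties break by pose id).

## Assay statistics

Millipolarization mP = 1000·(I∥ − G·I⊥)/(I∥ + G·I⊥) with grating factor
G = 1.0 by default (not stated in the source protocol). The assay window
statistic Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| uses sample standard
deviations (n − 1), the screening-statistics convention. Displacement of
the labelled oligonucleotide is 100·(μ_bound − mP)/(μ_bound − μ_free),
reported as computed with a flag when outside [−10, 110] %. On plates
generated with control means μ_p, μ_n and a common coefficient of
variation cv, Z′ converges to 1 − 3·cv·(μ_p + μ_n)/|μ_p − μ_n|; the test
suite checks this Monte-Carlo limit at 10⁴ wells per group within 0.02.

## Reversal classification

Contrast A (factor activation vs control) defines induced (padj < α and
log2FC up) and repressed probesets; among the induced, contrast B
(activation + compound vs activation) classifies significant reversals
(padj < α, log2FC < 0) and non-significant downward trends. α defaults to
0.05 and the fold-change floor to 0 — any significant up-change counts as
induced, a declared choice since no fold-change cut-off is published; with
a floor of exactly 0 the inequality is strict, so an exactly unchanged
probeset never counts. Percentages are rounded half away from zero, which
reproduces the printed arithmetic: 972/1262 → 77.02 → 77 % overall and
193/1262 → 15.29 → 15 % significant. The Venn partition of the two
up-regulated sets is reported alongside.

## Synthetic data: what it does and does not emulate

Every generator is a pure function of (seed, configuration); streams are
derived from the seed plus the generator's name, so generators are
mutually independent and byte-identical on rerun. Defaults encode the
study conditions: a 156–269 construct span (114 residues) with 99
assigned amides; a planted hot set of 8 residues {167, 211, 212, 213,
215, 216, 220, 237} at 0.08 ppm effect against 0.002 ppm noise (the
most-affected residues of the experimental CSP map); the
four-pronounced/seven-proton STD pattern; 20-pose docking decks;
DE tables with 1262/889 induced/repressed, 193 + 779 reversals and a
208-probeset second contrast sharing 35; synthetic free-state shifts
drawn in the realistic backbone-amide windows δH ∈ [6.5, 10.5] and
δN ∈ [105, 135] ppm; DNA bases in the toy complex drawn from the
insulin-responsive-element oligo CTA TCA AAA CAA CGC.

Generators emit exact truth manifests and self-check them (the toy
complex re-perceives its planted contacts; decoy conformers are verified
to produce no match; the planted pose is verified consistent), so truth
labels are guarantees, not probabilities. What the generators do *not*
emulate: real docking energetics, NMR lineshapes or peak overlap,
microarray probe-level noise, conformational averaging, or solvent
effects. Passing the recovery suites therefore demonstrates that the
*algorithms* recover planted signal under realistic magnitudes and noise;
it does not validate performance on experimental data.

## Problem sizes and numerical choices

The recovery suites and the acceptance script use 100 seeded replicates
for CSP hot-set recovery and pose selection, 55-compound screening
libraries (5 actives, 50 decoys, jitter σ = 0.3 Å under 1.5 Å
tolerances), 10⁴-probeset DE universes and 2 × 10⁴-well FP plates —
sizes at which every planted-recovery statistic is stable and the whole
suite runs in seconds. Geometric comparisons use absolute tolerances
(1e-6 Å for superposition identities, 1e-9 for translation invariance);
threshold comparisons in matching carry a 1e-9 guard so boundary cases do
not flip on rounding. Degenerate inputs are handled explicitly: empty
structures give empty (all-zero) maps, an all-identical CSP set gives
σ⁰_corr = 0 with a warning and no exceedances, a constant burial or STD
vector gives a rank correlation of 0 (no rank information), and zero
induced probesets give *undefined* percentages rather than 0/0.

## Known limitations and non-reproducible published values

* The published screening campaign reported a Z′ factor of 0.6499, six
  pharmacophore models, and 76 virtually selected compounds. None of
  these are recomputable here: the raw FP well data, the six models' full
  feature geometries and the commercial compound databases (Specs,
  Maybridge) and engines (GOLD/GoldScore, LigandScout, MOE, Autodock
  Vina) behind them are unpublished or proprietary. They are cited in
  documentation only and deliberately appear nowhere in code or tests as
  targets.
* The experimental report contains an internal discrepancy — fifteen
  residues above 1σ⁰_corr in the text versus thirteen in a figure caption
  — which cannot be resolved without the raw spectra; neither count is
  used as a target.
* The final docking pose geometry is engine-dependent and is consumed,
  not generated: this package selects among supplied poses and never
  re-implements docking search or scoring.
* Pocket-prediction algorithms are likewise external; only the consensus
  vote over their residue outputs is implemented.
* The hotspot maps are a transparent LJ + hydrogen-bond-well surrogate;
  their absolute energies are not comparable to any published force
  field, only their cut-off semantics and relative topology are
  meaningful.
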