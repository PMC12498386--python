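# Methods

This note documents the models, conventions and numerical choices behind
`gagconf`, and what its synthetic-data tests do and do not demonstrate
about real trajectory data.

## Coordinate model and conventions

Coordinates are Cartesian Å everywhere; masses amu; residues 1-indexed
with the reducing end of a chain as residue 1. Ensembles are ordered
conformers over one shared topology with a nominal frame spacing in ps
(metadata only — no analysis depends on it). Atom naming follows
carbohydrate convention: ring atoms O5, C1…C5, glycosidic oxygen O4.

Torsions use the IUPAC sign convention (eclipsed = 0°; positive =
clockwise rotation of the far bond seen along the central bond) and are
reported on (−180°, 180°]. Degenerate geometry (coincident or collinear
defining atoms) raises an error rather than returning 0 or NaN, so state
classification can never silently mislabel a broken ring.

## Ring puckering classification

A pyranose conformer is assigned to ⁴C₁, ¹C₄, ²S_O or ¹S₃ when both ring
dihedrals γ = C1–C2–C3–C4 and δ = C1–O5–C5–C4 lie within ±23° (circular
distance, boundary inclusive) of the state's reference values; otherwise
it is "other" (noncanonical). 23° is the standard window half-width for
this two-dihedral scheme and is configurable.

**Reference derivation.** Reference (γ, δ) pairs are measured from ideal
conformers, never transcribed: rings are built at canonical Cremer–Pople
(CP) coordinates — chairs at θ = 0°/180°, skew-boats on the θ = 90°
equator at the IUPAC-named positions, located programmatically by a
geometric designation routine (reference-plane fitting plus the
numbering-appears-clockwise rule for the "above" side). At the default
amplitude Q = 0.57 Å this gives

| state | θ | φ₂ | γ (°) | δ (°) |
|-------|----|-----|-------|-------|
| ⁴C₁ | 0 | – | −54.56 | +59.72 |
| ¹C₄ | 180 | – | +54.56 | −59.72 |
| ²S_O | 90 | 150 | −47.68 | −53.62 |
| ¹S₃ | 90 | 210 | −23.01 | −27.73 |

frozen in `gagconf/_pucker_refs.py` and regenerated by
`scripts/derive_pucker_references.py` (a test asserts frozen = derived).

**Window overlap.** ²S_O and ¹S₃ are *adjacent* stations on the
pseudorotation equator (Δφ₂ = 60°), and their ideal (γ, δ) differ by only
~25° — less than the 46° needed for two ±23° boxes to be disjoint. This
is a geometric fact, not a tunable: no admissible reference placement
separates them. The classifier therefore tolerates corner overlap of two
windows and resolves points inside both by the circularly nearest
reference (Chebyshev metric over γ, δ; deterministic tie-break). Window
construction still errors if one state's center falls inside another's
window, which would make classification genuinely ambiguous. In sampled
data the overlap region is a low-population saddle; assignment there is a
labelling convention, as it is in any hard-window scheme.

**Ring realization.** Rings realize the exact CP out-of-plane pattern
z_j (which has no first-order Fourier component, so the CP mean plane of
the built ring is exactly the construction plane and CP analysis
round-trips to machine precision). In-plane coordinates are fitted by
least squares to realistic alternating bonds (C–O 1.43 Å, C–C 1.52 Å) and
valence angles (110°, 112° at O5). A uniform-bond profile (all bonds
1.49 Å, regular hexagonal projection) is also available; it is the
variant in which an ideal chair has six ring torsions of exactly equal
magnitude. The realistic profile is the default because it breaks the
artificial γ = δ degeneracy of equilateral twist-boats and places the
¹S₃ reference far enough from (0, 0) that the planar ring classifies as
"other" on both coordinates.

## Glycosidic linkage analysis

For the 1→4 linkage with donor residue n+1 and acceptor n (n counted
from the reducing end — the only direction compatible with the
O5(n+1)–C1(n+1)–O4(n) atom chain):

    φ = O5(n+1)–C1(n+1)–O4(n)–C4(n)
    ψ = C1(n+1)–O4(n)–C4(n)–C3(n)

The C1–O4 bond is verified geometrically (< 1.8 Å) before measuring.
Series are pooled by linkage class (GlcNS(6S)–IdoA(2S) vs
IdoA(2S)–GlcNS(6S), donor named first); pooling terminal with interior
linkages is the caller's choice via per-linkage series.

Histograms are periodic on (−180°, 180°]² with a default 5° bin (bin
width must divide 360°); 5° resolves the ~40–60° separation between the
known minima without noise-dominated cells at ~10⁴ samples. Modes are
local maxima over the 8-neighbourhood with periodic wrap; plateaus of
equal-valued adjacent candidate bins are collapsed to one representative,
so a peak straddling the ±180° seam is reported once. Peak picking is on
raw fractions by default (deterministic); an optional 3×3 periodic mean
filter (`smooth_heatmap`) suppresses single-bin shot noise and is the
recommended setting when localizing basin centers from ≲10³ samples per
basin — the acceptance checks use it for exactly that reason.

## Shape descriptors

RMSD uses closed-form optimal superposition (Kabsch, SVD with reflection
guard; proper rotation guaranteed), mass-weighted by default to mirror
the common MD-analysis convention; selection and weighting are exposed
because published analyses rarely state them. The RMSD time series is
referenced to frame 0; the all-vs-all matrix computes one triangle and
caps its dimension at 2000 by automatic striding (desk-scale memory for
5×10⁴-frame inputs). The matrix's triangle inequality is not asserted:
entries come from independent fits. End-to-end distance is the distance
between centers of mass of the two terminal residues, hydrogens included
when present (pure mass weighting). Summary statistics default to the
sample SD (n−1); the population convention is one flag away — negligible
at trajectory scale but pinned for reproducibility. Correlation matrices
are Pearson over (RMSD, Rg, EED); constant columns raise rather than
producing NaN.

## Water models

The pair energy of two rigid waters is the Coulomb sum over charged
sites plus one oxygen–oxygen Lennard–Jones term, with Coulomb constant
k = 332.0636 kcal Å mol⁻¹ e⁻². The registry
(`gagconf/data/water_models.yaml`) carries the five models' site
geometries and charges from their original parameterizations; the LJ site
sits on the oxygen for all of them (for TIP5P the oxygen carries no
charge; σ₀ = 3.12 Å, ε₀ = 0.16 kcal mol⁻¹). Dipoles are |Σqᵢrᵢ| converted
at 1 e·Å = 4.8032 D; the registry values reproduce 2.35/2.18/2.29 D for
TIP3P/TIP4P/TIP5P within 0.02 D. Nothing here simulates water: the module
exists for dimer-level energetics and documentation of the solvent models
the analyses compare.

## Synthetic ensembles: what they emulate and what they do not

`synthetic` builds heparin-like chains: per residue, the six ring atoms
(exact CP geometry), explicit O4, and united pseudo-atoms for the
substituents (N-sulfo 95.1 amu at C2 of GlcNS, 6-O-sulfo arm 110.1 at C5,
2-O-sulfo 96.1 at C2 of IdoA, carboxylate 44.0 at C5, hydroxyls 17.0) so
that mass-weighted descriptors see realistic group masses without full
substituent geometry. Chains are assembled by internal-coordinate (NeRF)
placement: ψ positions the donor C1 on the acceptor O4, φ rotates the
donor about the glycosidic bond; prescribed torsions round-trip to
< 0.5°. The anomeric link direction is the axial exocyclic vector at C1,
mimicking the α-configuration of heparin's linkages. Inter-residue
contacts closer than 1.5 Å (outside the glycosidic 1-2/1-3 neighbourhood)
raise an error naming the offending atoms.

Ensembles draw per-residue pucker states iid from prescribed probability
vectors (defaults: GlcNS(6S) pure ⁴C₁; IdoA(2S) 0.65/0.35 over
²S_O/¹S₃ — dominant ²S_O with a substantial ¹S₃ minority, the documented
conformational equilibrium of 2-O-sulfo-iduronate), per-linkage (φ, ψ)
from wrapped normals around (−70°, 120°) for GlcNS→IdoA and (60°, 60°)
for IdoA→GlcNS (the two classes' global minima) with 12° circular SD, and
add iid Gaussian Cartesian noise (default σ = 0.05 Å, ≈6° of γ/δ jitter)
last. Same seed ⇒ bit-identical output.

What passing tests therefore show: the *analysis* stack recovers known
populations, modes and cluster structure from coordinates with realistic
local geometry and noise. What they do not show: force-field or solvent
realism. Frames are temporally iid (no kinetics or autocorrelation),
rings switch states without transition paths, substituents are
point masses, and global dimensions are compacter than real heparin
(the synthetic dp12 has EED ≈ 16 Å and Rg ≈ 6.7 Å versus ~34–36 Å and
~15 Å for the real dodecamer) because the reduced α-axial linker geometry
under-reproduces the real helical rise. Recovering a printed trajectory
statistic from real data requires the deposited trajectories; the
synthetic round trips validate the estimators, not the physics.

Noise bounds on label recovery follow from the ~115°/Å sensitivity of
γ/δ to Cartesian noise: at σ = 0.05 Å recovery of generating labels is
complete; at σ = 0.1 Å (~12° jitter) 10–30% of frames legitimately leave
every ±23° window and are labelled "other", so the tests assert dominant
recovery plus near-zero cross-state contamination rather than perfection.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately desk-scale inputs:
50-instance oracle sweeps for geometry; 300-frame dp12 ensembles for the
pipeline quantities; 1000-frame dp2/dp4 ensembles for population and mode
recovery (binomial SD ≈ 0.014 at n = 1000, comfortably inside the ±0.05
recovery bound); 20-frame two-template ensembles for the RMSD-matrix
block structure. All randomness flows from explicit seeds
(`numpy.random.default_rng`); hypothesis property tests are derandomized.
Pipeline outputs are plain CSV plus a manifest (input SHA-256, config
echo, package version) and are byte-identical across reruns.

## I/O

Multi-model PDB goes through biotite (AtomArrayStack; 10⁻³ Å coordinate
precision), with wwPDB component codes SGN/IDS for GlcNS(6S)/IdoA(2S) and
a caller-extensible mapping for other naming schemes. XYZ is written with
extra columns (atom name, residue index, residue class) after x/y/z so
round trips of this package's own files are lossless while plain
three-column XYZ still reads (masses then come from the element). Readers
fail loudly on truncated files, inconsistent per-model atom counts, and
unknown elements. Trajectory formats in nm must be converted to Å at the
boundary by any plugged-in reader.
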