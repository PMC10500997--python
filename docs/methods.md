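# Methods

## Representation

A heparin chain of dp residues is reduced to dp+1 glycosidic-oxygen anchor
points connected by virtual bonds (O1→O4 linkages).  Each residue carries
one interaction site at the midpoint of its two anchors; the site's charged
*head* and uncharged *tail* are placed at signed offsets (default +1 Å /
−1 Å) from the site center along the virtual-bond axis, so the unit bond
vector is also the site's orientation axis.  Setting both offsets to zero
collapses head = tail = site and forces every anisotropic term into its
isotropic limit — the "collapsed" mode used for isotropic testing.  Residues
alternate IdoA2S / GlcNS6S; the −4 e disaccharide charge is split −2 / −2 by
default (configurable), giving a dp12 chain a total charge of −24 e.

Internal coordinates are the bond lengths d_i, the bond angles θ_i ∈ (0°,
180°] (180° = collinear) and the dihedrals γ_i ∈ (−180°, 180°] (180° =
trans).  A collinear anchor triple leaves γ undefined; it is set to 180°
(continuous with the extended conformation) and flagged with a warning.
`rebuild_cartesian` regrows anchors from internal coordinates (NeRF chain
growth, first anchor at the origin) and inverts `internal_coordinates`
exactly up to rigid motion.  The "extended" start template is the fully
collinear chain at the equilibrium bond length, which makes the starting
end-to-end distance equal the contour length dp·d₀.

## Effective energy function

All terms are multiplied by a dimensionless weight and (for the
solvent-averaged terms) a temperature factor

f_n(T) = ln(e + e⁻¹) / ln(exp(x) + exp(−x)),  x = (T/T₀)^(n−1),  T₀ = 300 K,

which equals 1 at T₀ for every order n; bonded stretching/bending use n = 1
(f ≡ 1), the torsional and nonbonded mean-force terms n = 2.  Nonbonded
pairs with |i − j| < 3 are excluded (their geometry is governed by the
bonded terms); no distance cutoff is applied — chains of ≤ 68 sites make
all-pairs evaluation cheap and cutoffs would only add artifacts.

The exact published forms of several terms are not available in
redistributable form, so the package documents its own closed forms, chosen
to satisfy the model's defining limits and symmetries; all of them are
pluggable through the parameter file.

- **Bonded.**  U_bond = k_d (d − d₀)²; U_b = (k_θ/2)(cos θ − cos θ₀)²
  (cosine-harmonic: smooth at θ = 180°, which the collinear start visits);
  U_tor(γ, θ₋, θ₊) = sin θ₋ sin θ₊ [c₁(1 + cos γ) + c₂(1 − cos 2γ) +
  c₃(1 + cos 3γ)].  The sin θ coupling to the flanking bond angles removes
  the dihedral singularity at collinear geometry (the torsional force
  vanishes smoothly there) and vanishes at γ = 180° for the default
  coefficients, so the extended start is torsion-relaxed.
- **Tail–tail van der Waals.**  Shifted Gay–Berne potential
  E = 4ε(ω)[(σ₀/(r − σ(ω) + σ₀))¹² − (…)⁶] with the standard
  orientation-dependent contact distance σ(ω) (shape anisotropy
  χ_gb_sigma) and well depth ε(ω) = ε₀ ε₁ ε₂² (energy anisotropy
  χ_gb_eps).  Zero at r = σ(ω) for any orientation, σ₀ for the side-to-side
  approach, and exactly Lennard-Jones when both anisotropies vanish.
- **Generalized Born polarization (head–head).**
  E = C (1/ε_out − 1/ε_in) q_i q_j e^{−κr′} / f_GB(r′) with Still's
  interpolation f_GB = sqrt(r² + a_i a_j exp(−r²/4a_i a_j)): Born limit at
  contact, Coulomb limit at large r; stabilizing for like charges when
  ε_out > ε_in.
- **Head–tail polarization.**  Screened charge–induced-dipole form
  E = −C (1/ε_in − 1/ε_out) [α₂ q_i² e^{−2κ r″ᵢⱼ}/r″ᵢⱼ⁴ +
  α₁ q_j² e^{−2κ r″ⱼᵢ}/r″ⱼᵢ⁴] over the two head/tail cross distances;
  symmetric under particle exchange, zero when both solvation factors
  vanish, monotone in κ.  The e^{−2κr} factor follows from screening the
  polarizing field, which enters squared.
- **Cavity terms.**  Desolvation hump ε_cav x² e^{1−x²}, x = r/σ: finite
  everywhere, maximal (= ε_cav) at the contact scale, Gaussian decay.  The
  head (isotropic) version uses σ = σᵢ^iso + σⱼ^iso; the tail version uses a
  Gay–Berne-style anisotropic contact distance with the two cavity
  anisotropies χ″⁽¹⁾ (amplitude) and χ″⁽²⁾ (orientational coupling) and
  reduces exactly to the isotropic shape when both are zero.
- **Head–head Lennard-Jones** with (σ′, ε′).
- **Electrostatics.**  E = C q_i q_j e^{−κr′}/(ε_eel r′), its own weight
  w_eel.  ε_eel defaults to ε_in so that electrostatics + GB polarization
  with unit weights reduce to an effective ε_out-screened Coulomb
  interaction at large separation (the exact Still decomposition).

**Screening scope.**  The Debye factor is applied to *all* charge-sourced
terms (electrostatics, GB polarization, head–tail polarization), each
individually switchable.  Screening only the Coulomb term would flip the
net like-charge interaction attractive at moderate κ (the unscreened
polarization term dominates), creating deep unphysical minima and breaking
the compaction-by-loss-of-repulsion mechanism; counterion screening
physically attenuates every field sourced by the charges.

κ is the inverse screening length in Å⁻¹.  The electrolyte module evaluates
the monovalent Debye length κ⁻¹ = sqrt(ε_r ε₀ k_B T / 2 N_A e² I) from
CODATA constants (≈7.9 Å at 0.15 M, 300 K); because the solvent is
implicit, this is an orientation aid, not a calibration claim.

## Default parameters

The numeric constants are the package's documented placeholder
parameterization (the published tables are not shipped); every value loads
from a flat `key = value` text file.  Units: Å, kcal/mol, e, K, amu.

| parameter | default | rationale |
|---|---|---|
| d₀, k_d | 5.0 Å, 50 kcal/mol/Å² | disaccharide O1–O4 spacing ≈ 5 Å; stiff CG bond |
| θ₀, k_θ | 150°, 20 kcal/mol | gently bent helical backbone, persistence ~40 Å |
| c₁,c₂,c₃ | 0.5, 0.0, 0.2 kcal/mol | ~1 kcal/mol torsion barrier, trans minimum |
| σ₀, ε (tails) | 5.0 Å, 0.3 kcal/mol | ring footprint matches bond spacing |
| χ_gb_sigma, χ_gb_eps | 0.25, 0.15 | mild ellipsoidal anisotropy |
| σ′, ε′ (heads) | 4.0 Å, 0.2 kcal/mol | smaller charged group |
| Born radii | 3.0 Å | sulfate/carboxylate group scale |
| ε_in, ε_out | 2, 80 | interior vs water dielectric |
| α₁ = α₂ | 1.5 kcal·Å⁴/mol/e² | ~1 kcal/mol head–tail polarization at contact |
| σ^iso, σ_cav, ε_cav | 2.0/2.5 Å, 0.5 kcal/mol | sub-kcal desolvation humps |
| χ″⁽¹⁾, χ″⁽²⁾ | 0.2, 0.2 | mild cavity anisotropy |
| charge split | −2/−2 e | only the −4 e disaccharide sum is fixed |
| site mass | 288 amu | half of an IdoA2S–GlcNS6S disaccharide |

## Dynamics

BAOAB Langevin splitting; anchors are the dynamical particles (each carrying
the residue mass — only equilibrium distributions matter for the observables,
which are mass-independent).  With zero friction the O-step is the identity
and the scheme is symplectic velocity-Verlet; a bond-only harmonic chain
shows a relative secular energy drift of ~10⁻⁷ over 10⁵ steps at dt =
4.89 fs, and the thermostat holds the mean kinetic temperature within ~1% of
300 K over 10⁶ steps.  Center-of-mass velocity is removed at every snapshot
(unrestrained vacuum-like system); kinetic temperature therefore uses
3N − 3 degrees of freedom.  The default friction is 1/ps (CG convention).
For conformational sampling the analysis protocol passes 0.2/ps instead:
with γ = 1/ps a dp24 chain's slowest (Rouse-like) mode relaxes in ~0.6 ns,
comparable to a 200k-step run, whereas γ = 0.2/ps brings it to ~0.1 ns;
equilibrium averages are friction-independent, so this only improves
statistics.  Same seed ⇒ bitwise-identical trajectory; non-finite
coordinates or forces abort the run with the last good frame attached.
Times are nominal integration times (fs); coarse-grained effective time runs
faster by an unasserted scale factor (the production protocol corresponds to
roughly a microsecond of real time).

## Observables and analysis

EED is the distance between the terminal anchors (experimental EED refers to
chain termini); Rg is the mass-uniform RMS distance of site centers from
their centroid.  Means/SDs discard the first 10% of frames (configurable) —
the initial extended transient would otherwise bias both observables upward.
RMSD uses Kabsch superposition on anchors (cross-checked against a
quaternion-method oracle).  Conformational clustering is DBSCAN on the
pairwise anchor-RMSD matrix with the production settings (4 Å cutoff,
minimum cluster size 2); cluster representatives minimize the within-cluster
RMSD sum.  Percentage error is 100·|sim − ref|/ref with the direction
(above/below) reported separately.

## Calibration sweep

One weight family at a time takes values 1…10 (all others at 1) × the
decimal-safe κ grid 0.0…1.0 (11 values) × chain length; each cell records
mean EED/Rg and percentage errors vs. the reference table.  Ranking is
ascending by the chosen error with a deterministic tie-break (lower κ, then
lower weight).  One seed per cell by default (`reps` averages several).
The three production presets are (κ=0.2, w_eel=7), (κ=0.7, w_eel=7) and
(κ=0.7, w_bond=4).

## What the synthetic fixtures do and do not show

The helix generator produces ideal regular helices with configurable
rise/twist/radius; defaults give an anchor spacing of ≈5 Å so a fully
extended dp12 chain spans ≈60 Å, the scale of the packaged experimental
reference.  It reproduces the *periodicity and spacing* of the real helical
template, not its atomic geometry, sulfation chemistry or sequence
irregularities.  Tests passing on these fixtures validate geometry, energy
calculus, integrator statistics and the qualitative response of chain
dimensions to screening and electrostatic weight; they do not validate
quantitative agreement with experimental heparin beyond the packaged dp12
EED, since the placeholder force-field constants stand in for the
unpublished tables.

## Numerical choices

- Problem sizes: trend comparisons use dp24, 200k steps, 3 seeds (chosen so
  the slowest mode relaxes several times per run at γ = 0.2/ps); the sweep
  bookkeeping check uses 50-step runs — cardinality and ranking are
  independent of run length.
- Force-check error metric: |FD − analytic| / max(|FD|, 1 kcal/mol/Å) —
  a pure relative error is undefined on near-zero components.
- Degenerate geometry: collinear triples set γ = 180° with a warning; the
  sin θ torsion prefactor's gradient term is skipped below sin θ = 10⁻⁸
  (the term itself vanishes there).
- Gay–Berne anisotropies are restricted to [0, 1) so the orientation
  denominators cannot vanish.
- The κ grid is generated as i/10 (canonical decimal floats), never by
  accumulation, so grid values are usable as keys.

## Known limitations

- The numeric force-field constants are placeholders; quantitative EED/Rg
  agreement across all chain lengths is not claimed and reference slots
  beyond dp12 EED ship empty.
- Only the regular IdoA2S–GlcNS6S repeat: no branched topologies, mixed
  GAGs or sulfation variants.
- Implicit solvent with mean-field screening: no explicit ions, no
  polarizable electrostatics, no periodic boundary conditions.
- Protein–GAG complexes and enhanced-sampling schemes are out of scope.
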