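# Methods

## Multipole model

A molecule is a set of expansion sites, each carrying real spherical
multipole components in Stone ordering (Q00; Q10, Q11c, Q11s; Q20, Q21c,
Q21s, Q22c, Q22s; higher ranks retained but unused), in atomic units
e·a0^l. Positions are angstrom or bohr, declared per molecule; all
tensor arithmetic converts to bohr first with the fixed factor
1 Å = 1.8897261254578281 a0 (CODATA 2018), which makes the Å↔bohr round
trip exactly invertible.

The spherical↔Cartesian map for rank 2 is

    Θzz = Q20,  Θxz = (√3/2)Q21c,  Θyz = (√3/2)Q21s,
    Θxx − Θyy = √3·Q22c,  Θxy = (√3/2)Q22s,  tr Θ = 0,

fixed not by a normalization constant but by the dual-oracle consistency
tests: spherical moments of random point charges computed via the
regular solid harmonics must convert to the Cartesian tensor obtained
directly from the Buckingham charge sum Θαβ = ½Σq(3rαrβ − r²δαβ).

**Magnitude.** |Q₂| is the Euclidean norm of the five spherical
components (Stone's convention), not the Frobenius norm of Θ, which
differs by √(3/2). It is invariant under rotation, which the tests
assert via Cartesian conjugation.

**Translation.** The rank-2 moment about an arbitrary point depends only
on site ranks ≤ 2 (the origin-shifted moment of rank l needs site ranks
≤ l); with a = r_site − point,

    Θαβ(point) = Θαβ(site) + (3/2)(aαμβ + aβμα) − (a·μ)δαβ
               + (q/2)(3aαaβ − |a|²δαβ),

summed over sites. For site sets that are exactly rank-≤2 (point
charges, ±pair dipoles, charge-triple quadrupoles) this is exact, not
asymptotic, and the suite asserts equality with brute-force charge sums
at 1e-10 or better. Site ranks ≥ 3 are parsed and stored but never
contribute; rotation of ranks ≥ 3 is likewise not implemented because no
descriptor needs it.

A consequence worth stating: for a molecule with zero net charge *and*
zero net dipole the translated total quadrupole is independent of the
evaluation point, so |Q₂|(z) and Q20(z) are flat. The z-scan is
informative precisely for charged or polar systems (and for the
synthetic π-rings, whose per-site ± charge pairs carry a net dipole).

## Frame canonicalization

Descriptors are defined in the frame with the ring centroid at the
origin and the ring plane equal to the xy-plane. The plane is the
best-fit plane of the ring atoms (eigenvector of the smallest principal
moment of their centered coordinates); collinear ring atoms have no
unique plane and are rejected. The normal's sign is fixed
deterministically (largest-magnitude component positive) and the minimal
rotation carrying it to +z is applied to positions and multipoles alike.
For ring-plane-mirror-symmetric molecules the two normal choices give
identical descriptors; for molecules without that symmetry the ±z
ambiguity is inherent to "the" ring normal and the deterministic rule
simply makes runs reproducible. All six descriptors are invariant to
rigid rotation + translation of the input (asserted at 1e-8).

## Descriptors and normalization

The ring-atom descriptors sum *per-site* quantities over the designated
ring atoms only (attached hydrogens and substituents excluded): the
per-site spherical magnitude for `Q2_ring_atoms` and the per-site Q20
for `Q2zz_ring_atoms`. The reading "sum of per-site magnitudes" vs
"magnitude of the summed tensor" is genuinely open for the ring-atom
magnitude descriptor; the chosen reading is isolated in one function
(`descriptors.ring_atom_sums`) so it can be flipped. The origin and
1 Å descriptors translate *all* sites to the evaluation point and take
magnitude/Q20 of the summed tensor — the only reading under which
"|Q₂| computed at (0,0,1 Å)" is a single number per molecule.

Normalization divides each descriptor by the reference molecule's value;
the reference against itself is exactly 1.0 in IEEE arithmetic (x/x = 1
for finite nonzero x), and a zero reference component raises an error
naming the descriptor.

The z-scan grid defaults to 0.1–3.0 Å in 0.05 Å steps on the +z face
only (the −z face is redundant for Qzz under the ring-plane mirror);
argmax ties break toward smaller z.

## Reactivity indices

Adiabatic IP = E(cation) − E(neutral) and EA = E(neutral) − E(anion),
converted with 1 hartree = 27.211386245988 eV; all indices are reported
in eV (the working unit is a package choice, recorded here). χ, η, ω,
ω−, ω+ follow the standard definitions; the identities ω− − ω+ = χ and
2ηω = χ² hold algebraically and are asserted on random inputs at 1e-12
(scaled by the ω magnitudes, whose difference cancels catastrophically
as hardness → 0). IP = EA is rejected (zero hardness); negative EA is
physical.

R² between descriptor and reactivity columns is the squared Pearson
correlation (equivalently OLS-with-intercept coefficient of
determination), computed pairwise-complete with the per-cell n reported,
and is invariant under affine rescaling of either variable — so raw and
benzene-normalized descriptors give identical R².

## Chemometrics

z-scoring uses the population (divide-by-n) standard deviation; the
sample-sd alternative is a one-line change and the convention is written
into every run manifest. PCA is the eigendecomposition of the
covariance of the centered (z-scored) data, components sorted by
eigenvalue, each loading column's largest-magnitude entry made positive
for sign determinism; two components are kept for plotting, the full
set in the result object.

Ward clustering is greedy agglomeration minimizing the objective
increase ΔESS(A,B) = |A||B|/(|A|+|B|)·‖c_A − c_B‖², with the merge
height equal to ΔESS and ties broken toward the smallest lexicographic
cluster-id pair. Centroids are recomputed from member rows at each step
(n is small in this domain), so heights match exhaustive enumeration
exactly. scipy's `ward` linkage reports heights on the √(2ΔESS) scale;
the dendrogram object exposes that conversion and the tests cross-check
both the heights and the flat partitions against scipy. The flat k-cut
(k = 4 by default, configurable) undoes the last k−1 merges and labels
clusters by first leaf occurrence.

## Synthetic data

The generators are pure functions of seed and spec.

* **Rings** default to six sites at radius 1.39 Å (a benzene C–C-like
  ring) each carrying an axial site quadrupole Q20 = −0.35 e·a0²,
  a magnitude typical of the negative out-of-plane quadupole π density
  produces at a ring carbon. Options add per-site ± charge pairs at
  ±0.5 Å (a z-dipole per site, giving the translated tensor its
  z-structure) and one in-plane substituent site with net charge and/or
  dipole at a chosen distance — the minimal ingredient reproducing the
  angular-factor artifact: adding charge q at in-plane distance d shifts
  Q2zz_origin by exactly −½q·d² (bohr).
* **Cluster datasets** draw Gaussian groups in 6-descriptor space with
  means for four archetypes — neutral ≈ 1, quinoidal with depressed
  out-of-plane entries, cationic < 1, anionic > 1 (the qualitative
  ordering anionic > neutral > quinoidal ≈ cationic) — spread σ = 0.01
  by default and four molecules per group (16 rows, the size of a
  one-reference + 15-derivative study). These means are configuration,
  not measurements.
* **Energy records** draw IP ~ U(0.20, 0.40) Ha and EA ~ U(−0.05,
  0.12) Ha about a neutral energy near −230 Ha, so IP > EA (positive
  hardness) always holds.

What the generators do *not* emulate: real DFT-derived site multipoles
(anisotropic per-atom tensors, nonzero site dipoles on carbons,
hydrogens), vibrational or magnetic response, or correlated descriptor
noise. Passing tests therefore demonstrate the correctness of the
tensor algebra, the pipeline's conventions and the recovery behavior of
the chemometric stage under the stated noise model — not agreement with
any particular quantum-chemistry dataset.

## Problem sizes and determinism

Default analyses run 10–16 molecules with 6–19 sites each; the test
suite uses exhaustive clustering oracles up to n = 7 and brute-force
charge sums up to a few dozen charges, sizes at which every oracle is
exact. All randomness flows through explicit integer seeds; rerunning
any stage with the same config and seed is bit-identical.

## Known limitations

* Rotation (and hence canonicalization) of site ranks ≥ 3 is not
  implemented; such components survive I/O but a descriptor needing them
  does not exist in this package.
* One punch grammar is supported, strictly; unknown trailing content is
  an error rather than being skipped.
* The ring-atom heuristic (six mutually bonded heavy atoms with
  neighbor distances in 1.20–1.60 Å forming a single 6-cycle) is opt-in
  and never applied silently.
* Descriptors at off-axis evaluation points, other linkage criteria,
  and vertical (non-adiabatic) IP/EA are out of scope.
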