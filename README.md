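# q2arom

Aromaticity descriptors built from the quadrupole (rank-2) term of a
distributed multipole expansion, for studying how substituents perturb
the π-electron density of ring systems.

Aromaticity has no quantum-mechanical observable, so it is quantified
through descriptors. The descriptors implemented here are built from the
five real spherical components of the DMA quadrupole tensor
**Q**₂ = (Q20, Q21c, Q21s, Q22c, Q22s), the first term of the multipole
expansion that carries out-of-plane electron density. Q20 = Θzz is the
out-of-plane component; its integrand carries the angular weight
(3cos²θ − 1)/2, positive inside the cone θ < 54.7° about the ring normal
and negative near the ring plane — which is why in-plane *charged*
substituents shift Θzz by exactly −½q·d² without any change in ring
aromaticity (a sign artifact the package quantifies explicitly).

For a molecule canonicalized so the ring centroid is the origin and the
ring lies in the xy-plane, six descriptors are computed (all in e·a0²):

| descriptor        | definition                                                    |
|-------------------|---------------------------------------------------------------|
| `Q2_ring_atoms`   | Σ over ring atoms of the per-site \|Q₂\| magnitude             |
| `Q2zz_ring_atoms` | Σ over ring atoms of the per-site Q20 (= Qzz)                 |
| `Q2_origin`       | \|Q₂\| of all site moments translated to (0,0,0)              |
| `Q2zz_origin`     | Q20 of that translated tensor                                 |
| `Q2_1`            | \|Q₂\| of all site moments translated to (0,0,1 Å)            |
| `Q2_1zz`          | Q20 of that tensor, probing the π density above the ring      |

Descriptors are reported relative to a reference molecule (benzene), so
the reference scores exactly 1 on every descriptor. The package also
derives adiabatic IP/EA and the conceptual-DFT indices χ, η, ω, ω−, ω+
from neutral/cation/anion energies, correlates them (R²) against the
descriptors, and runs the chemometric stage: z-scoring, PCA to PC1/PC2,
Ward-criterion hierarchical clustering and a flat k-cluster cut.

Because quantum-chemistry inputs are not assumed, a synthetic-data
module generates ring-shaped multipole arrangements with exact
point-charge oracles, energy triples with IP > EA, and a four-group
(neutral / quinoidal / cationic / anionic) descriptor matrix for
exercising the clustering.

## Worked example

```python
from q2arom import compute_descriptors, normalize
from q2arom.synthetic import RingSpec, make_ring_molecule

benzene = make_ring_molecule(RingSpec(name="benzene"))
anionic = make_ring_molecule(RingSpec(name="phenolate-like", site_q20=-0.32,
                                      substituent_distance=2.4,
                                      substituent_charge=-0.3))
ref = compute_descriptors(benzene)
d = normalize(compute_descriptors(anionic), ref)
for k, raw in d.as_dict().items():
    print(f"{k:18s} raw {raw: .4f}   norm {d.normalized[k]: .4f}")
```

prints

```
Q2_ring_atoms      raw  1.9200   norm  0.9143
Q2zz_ring_atoms    raw -1.9200   norm  0.9143
Q2_origin          raw  5.4697   norm  2.6046
Q2zz_origin        raw  1.1654   norm -0.5550
Q2_1               raw  6.9571   norm  3.3129
Q2_1zz             raw  0.0941   norm -0.0448
```

The ring-atom sums barely move (the ring sites are only mildly
perturbed), but the translated descriptors swing wildly: the in-plane
−0.3 e substituent at 2.4 Å sits where the angular factor is negative,
so it contributes +½·0.3·d² to Θzz — the product of two negative signs —
flipping `Q2zz_origin` from negative to positive. That is the charged-
substituent artifact: translated descriptors of charged species must be
read with care.

The same workflow is available from the shell:

```bash
q2arom synth --out fixtures --n 15 --seed 0
q2arom full --reference benzene --energies fixtures/energies.csv \
    $(for f in fixtures/*.punch; do echo --input $f; done) \
    --k 4 --out results/
```

which writes `descriptors.csv`, `reactivity.csv`, `r2.csv`,
`pca_scores.csv`, `clusters.csv`, a dendrogram (JSON + PNG) and a
`manifest.json` recording every convention choice (magnitude definition,
z-score sd convention, Ward height convention, unit constants).

## Input formats

* **Multipoles** — a documented punch-style dialect: optional header
  lines (`units angstrom|bohr`, `name ...`, `charge N`, `ring i j ...`),
  then per site `label x y z rank k` followed by `(k+1)²` Stone-ordered
  component values; `!` starts a comment. Ranks above 2 are stored but
  never used (translation of rank-2 moments needs only site ranks ≤ 2).
* **Energies** — CSV/TSV with columns `name, E_neutral, E_cation,
  E_anion` in hartree.
* **Descriptor tables** — CSV, molecules × named descriptors; literature
  indices (HOMA, AIvib, BVI, Iring, MCI, NICS0, NICS1, NICS1zz) can be
  supplied this way for correlation analysis.

See `docs/methods.md` for conventions, assumptions and limitations.
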