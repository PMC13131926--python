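# cyclopept

De novo design of N-methylated macrocyclic peptide backbones by
hydrogen-bonded loop sampling and geometric-hash ring closure, with the
companion audits, filter cascades and assay calculators used to
characterise such designs.

## The problem

Head-to-tail cyclised peptides of 8–12 residues can be made passively
membrane-permeable if every backbone amide N–H is either removed by
N-methylation or buried in an internal hydrogen bond. `cyclopept` builds
closed macrocycle backbones that satisfy this constraint *by construction*:

1. **Loop sampling** — open loops `G-(NMe-G)n-G` (n = 3, 4, 5) are drawn
   from a glycine/sarcosine Ramachandran model; a draw is accepted only
   when the C-terminal glycine donates a beta-strand-like hydrogen bond to
   the N-terminal glycine's carbonyl and the conformer is clash-free.
2. **6D-transform hashing** — for each loop the rigid transform
   `T = (R, t)` between its terminal N–CA–C residue frames is computed in
   both senses and binned into an integer key (1 Å translation bins, 15°
   axis-angle bins). Two loops can close into a ring when the N-to-C key
   of one equals the C-to-N key of the other; a loop whose own forward and
   reverse keys coincide (`T ≈ T⁻¹`, a near-involution) closes on a copy
   of itself into a **C2-symmetric** ring.
3. **Fusion** — the terminal glycines of the pair are overlaid (N onto C
   and C onto N), the merged ring is re-closed exactly in torsion space by
   cyclic coordinate descent, rebuilt at ideal covalent geometry, and
   audited: junction peptide bonds, steric clashes, and **exactly two
   transannular hydrogen bonds** between the junction residues.
4. **Audits & clustering** — sequence notation (`apL*F*apL*F*`: lowercase
   = D amino acid, `*` = N-methylation, X = norleucine), cyclic symmetry
   order, unsatisfied-N–H count, cis-amide count, ABEGO/H-bond strings and
   conformer clustering.

Companion modules implement the binder-design metric filter cascade
(dock → design → prediction thresholds) and the assay closed forms:

- PAMPA apparent permeability
  `Pe = −ln(1 − C_A/C_eq) / (A·(1/V_D + 1/V_A)·t)` with
  `C_eq = (C_D V_D + C_A V_A)/(V_D+V_A)`, classified against the
  15 nm/s (1.5×10⁻⁶ cm/s) cutoff;
- monomer–dimer equilibrium, `K_D = [M]²/[D]` in chain units, as an exact
  inverse pair with the fraction-dimer observable `F_D = 2[D]/P_total`;
- LDH percent cytotoxicity and luminescence fold change.

## Worked example

`examples/02_design_c2_macrocycle.py` finds an n = 3 loop whose terminal
transform is its own inverse, fuses two copies into an 8-ring, symmetrizes
it and attaches the MC1 sequence:

```
sequence            apL*F*apL*F*
ring length         8 residues
symmetry order      2
transannular bonds  2
   0 -> 4: H...O 2.16 A, N-H...O 151.7 deg
   4 -> 0: H...O 2.16 A, N-H...O 151.7 deg
unsatisfied N-H     0
cis amides          2
ABEGO string        ABOEABOE
H-bond string       3>7,7>3
```

The two reciprocal hydrogen bonds sit at the fusion junctions (ring
positions 1 and 5, the only non-methylated amides), so the unsatisfied-
donor audit is zero — the permeability heuristic holds by construction.
The two `O` letters mark cis amides at the symmetric N-methylated
positions. `examples/05_assay_calculators.py` prints the assay side, e.g.
a half-equilibrated PAMPA well gives `Pe = 4.53e-6 cm/s (45.3 nm/s)`,
classified high-permeability, and fraction dimer 0.8644 at 9.4 nM total
protein maps to `K_D = 0.40 nM`.

A thin CLI wraps the same API:

```sh
cyclopept loops sample --outdir loops --seed 11 --n3 20 --n4 10 --n5 10
cyclopept close loops --outdir rings
cyclopept audit rings/ring_0000.pdb
cyclopept calc pampa --cd-t 8 --ca-t 3 --c0 10
cyclopept calc dimer-kd --fraction-dimer 0.8644 --p-total 9.4
cyclopept fixtures make all --outdir fixtures --seed 0
```

## Layout

- `src/cyclopept/geometry.py` — frames, rigid-transform algebra, NeRF
  chain building, Kabsch superposition, hydrogen-bond and clash geometry
- `src/cyclopept/sampling.py` — Ramachandran model and loop rejection
  sampling
- `src/cyclopept/closure.py` — transform keys, hash tables, closure
  search, CCD ring closure, C2 symmetrization
- `src/cyclopept/model.py` — sequence notation, symmetry, audits, ABEGO /
  H-bond strings, clustering
- `src/cyclopept/filters.py` — dock/design/prediction threshold cascade
- `src/cyclopept/assays.py` — PAMPA, dimer equilibrium, cytotoxicity,
  fold change
- `src/cyclopept/pdbio.py`, `config.py`, `fixtures.py`, `cli.py` — PDB
  I/O (D-residue names, N-methyl `CN` atoms, ring LINK records), YAML
  config, deterministic fixtures, CLI
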