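# Methods

This note documents the models, algorithms and numerical choices behind
`cyclopept`, and what its synthetic test conditions do and do not show
about real peptides.

## Backbone model

Backbones are built in torsion space at fixed ideal covalent geometry
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.010 Å,
N–CH₃ 1.455 Å; angles C–N–CA 121.7°, N–CA–C 111.2°, CA–C–N 116.2°,
CA–C–O 120.1°) by sequential natural-extension (NeRF) placement. Torsions
follow the IUPAC convention; ω of residue *i* is the
CA(i−1)–C(i−1)–N(i)–CA(i) dihedral and an amide is *cis* iff |ω| < 90°.
The amide substituent (H on secondary amides, the N-methyl carbon on
tertiary ones) is placed in the amide plane opposite the bisector of the
C(prev)–N and CA–N bonds; exactly one of the two is present per residue.
Residue 1 of an open chain is anchored to a canonical phantom frame, so
its φ and ω are realised but not measurable; `measure_torsions` returns
NaN for them.

A residue's coordinate frame sits on the alpha-carbon with axes built
from N, CA and the carbonyl C by Gram–Schmidt. `frame_transform(a, b)` is
expressed in `a`'s local axes, so transforms compose along frame chains
and `a.push(T)` reproduces `b` exactly. Superposition is Kabsch via
scipy's `align_vectors`, with the RMSD recomputed from the residuals
(the SVD by-product loses half its digits near zero).

## Hydrogen bonds and clashes

A backbone hydrogen bond requires H···O ≤ 2.5 Å, N–H···O ≥ 135° and
H···O=C ≥ 90°, with donor and acceptor at least two residues apart
(wrapping across the ring closure for cyclic chains). Tertiary nitrogens
(N-methyl, proline) never donate. These thresholds are a conventional
geometric stand-in for an energy-based definition; they are configurable.

The steric rule rejects heavy-atom contacts below 2.8 Å between residues
two or more positions apart, *except* the donor-N to acceptor-O/C
contacts of detected hydrogen bonds: a bonded N···O pair sits near 2.9 Å
by design and with the 2.5 Å H···O allowance can dip below the clash
radius, so a flat cutoff would reject exactly the designed interactions.

## Loop sampling

Loops are `G-(NMe-G)n-G`, n ∈ {3, 4, 5}. φ/ψ are drawn from four equal-
weight rectangular basins of the (symmetric) glycine/sarcosine map:
αR (−95±35, −40±30), its positive-φ mirror, extended β (−130±40, 135±45)
and its mirror. ω is trans for secondary amides; tertiary amides are cis
with probability 0.1 (default), reflecting the appreciable cis population
of N-alkylated amides; all ω receive 5° Gaussian jitter.

A draw is accepted iff (a) the C-terminal glycine donates a hydrogen bond
to the N-terminal glycine's carbonyl, and (b) the conformer is internally
clash-free. Two points deserve emphasis:

- **Donor direction.** Only the C-to-N terminal bond survives ring
  fusion. When two loops fuse, the N-terminal amide hydrogen of each is
  re-placed against its new ring predecessor and lands where the
  *partner's* C-terminal hydrogen sat; each loop therefore contributes
  its C-terminal-donor bond to the ring, and the two together form the
  reciprocal, antiparallel-beta-like pair at the junctions. Accepting
  N-terminal-donor loops instead yields rings whose expected bonds vanish
  on re-placement (confirmed numerically during development).
- **Clash screening at the source.** Only ~8 % of hydrogen-bonded draws
  are clash-free at 2.8 Å; rings fused from self-clashing loops can never
  pass the ring-level audit, so screening at acceptance keeps the
  pipeline self-consistent rather than discarding nearly every fusion.

Acceptance rates under these conditions are ~1×10⁻⁴ (n=3) down to
~2×10⁻⁵ (n=5) per draw. Each library slot draws from its own counter-
derived substream (order-independent, reproducible); a slot that produces
nothing within the 2×10⁵-draw cap is skipped with the cap charged to the
acceptance-rate denominator. Candidate batches are evaluated vectorised
(distance, then angles, then pairwise sterics) so a 300-loop library
takes on the order of a minute on one CPU.

## Transform hashing and closure search

The 6D key of a transform floors its translation components into 1 Å bins
and its rotation's axis-angle vector components into 15° bins (bins are
left-closed with edges at integer multiples of the width, so the identity
maps to the all-zero key). The axis-angle map is discontinuous at 180°;
since C2 self-closures live exactly there, transforms within one
orientation bin of 180° are additionally indexed under their antipodal
(θ−360°) representation.

Matching uses exact key equality by default, with an optional 3⁶
neighbor-bin expansion. Pipeline entry points (config, CLI, the seeded
end-to-end tests) enable the expansion: at desk-scale library sizes the
genuinely closable pairs (terminal-atom RMSD ≤ 0.5 Å) carry
frame-transform gaps of up to ~2 Å / 30° — atom positions are far less
sensitive to the frame rotation than the frame parameters themselves —
and exact 1 Å/15° keys capture almost none of them. The hash is audited
against a brute-force all-pairs binned scan in both modes.

## Fusion and ring closure

For a candidate pair the second loop is rigidly aligned with its terminal
glycines swapped onto the first's (6 backbone atoms; gate at RMSD
≤ 0.5 Å), the overlapped terminals are merged keeping the first loop's
coordinates, and the ring's measured torsions are then re-closed by
cyclic coordinate descent: the chain is rebuilt at ideal geometry with a
duplicated first residue, and φ/ψ torsions (ω fixed) are rotated one at a
time, each by the closed-form angle minimising the distance between the
duplicated and anchor N/CA/C atoms, until the gap RMSD falls below
0.03 Å (≤ 200 sweeps; typical cases converge in 5–50). A purely rigid
merge cannot work here: a 0.1–0.5 Å terminal-atom residual corresponds to
a 10–30° frame-rotation residual, and concentrating it at the junctions
(or distributing it rigidly) violates any reasonable peptide-bond
tolerance, while CCD absorbs it as a few degrees of torsion drift spread
around the ring. The closed ring keeps ideal bonds everywhere except the
closure bond, which inherits the (bounded) gap.

The ring is then audited: every C–N bond within 1.329 ± 0.1 Å, no steric
clash, and *exactly two* transannular hydrogen bonds — the reciprocal
pair between the junction residues. Self-fusions are projected onto exact
C2 symmetry: the best-fit rigid motion mapping the ring onto its
half-turn residue permutation is forced to an exact involution (rotation
angle exactly π about the fitted axis, screw translation removed — for a
π rotation `R = 2aaᵀ − I`, the operator with the perpendicular
translation halved is an exact involution), and coordinates are averaged
with their images. The result is exactly invariant under the operator and
idempotent.

## Audits, strings, clustering

Sequence notation: one letter per residue (uppercase L, lowercase D,
G achiral, X norleucine), `*` for N-methylation; prolines are always
N-alkylated; glycine writes back as uppercase `G`, and `x` is accepted
for D-norleucine. Cyclic symmetry order is the largest divisor k of the
ring length whose L/k-rotation fixes the ring. The satisfaction audit
counts non-alkylated, non-proline residues that donate no detected
backbone bond; rings emitted by the pipeline audit to zero by
construction, since their only donors are the two junction residues.

ABEGO letters: `O` for |ω| < 90° (overriding φ/ψ); otherwise `A` for
φ < 0 and −75 ≤ ψ < 50, `B` for other φ < 0, `G` for φ ≥ 0 and
−100 ≤ ψ < 100, `E` otherwise. The hydrogen-bond string lists
donor→acceptor ring positions. Both strings are canonicalised to the
lexicographically smallest rotation of the (ABEGO, H-bond) pair, the same
rotation applied to both and ties broken by the smallest rotation index —
rings have no privileged residue 1, and any consistent canonicalisation
preserves the clustering partition. Clusters are keyed by the string
pair; the representative minimises a configurable score (default: the
closure RMSD, i.e. the cleanest closure), ties broken by index.

## Filters and assays

All "above/greater/less" thresholds in the dock/design/prediction cascade
are strict; "at least three" hydrogen bonds is inclusive and "less than
one" buried unsatisfied donor means zero. Boundary rows are measure-zero
in continuous metrics; the integer columns are where the inclusive /
exclusive distinctions bind. The metrics themselves are consumed, not
computed.

PAMPA volumes are mL (≡ cm³), area cm², time s, so Pe is cm/s (×10⁷ for
nm/s); defaults are the 300 µL/200 µL, 17 h, 0.3 cm² plate geometry — the
membrane area is a typical value for the 96-well system, configurable,
as no standard value is universal. A well with C_A ≥ C_eq has no finite
Pe and is reported as equilibrated. Pe exactly at the cutoff classifies
as "low" (conservative). The dimer K_D uses the K_D = [M]²/[D] convention
in chain-concentration units; its inverse employs the cancellation-free
conjugate form of the quadratic root, making the K_D ↔ F_D pair close to
1e−9 relative across K_D ∈ [10⁻³, 10³] nM.

## Synthetic data and what the tests show

All test inputs are generated: seeded loop libraries, a C2 8-ring
fixture carrying the `apL*F*apL*F*` sequence (searched over substreams
with cis probability raised to 0.3 so the two symmetric cis amides are
present), metric tables scattered around the filter thresholds with
manifests computed by an independent plain-Python row scan, and assay
tables with closed-form expected values. The generator emulates torsional
diversity and the hydrogen-bond/clash geometry of real N-methylated
macrocycles, but not sidechains beyond the N-methyl carbon, solvation, or
any energetics — passing tests certify the geometry, combinatorics and
arithmetic of the method, not that a given design would fold or permeate.
Problem sizes in the seeded end-to-end checks (100 loops per length,
~300-loop hash tables) are chosen to exercise the full pipeline at desk
scale; at these sizes a run typically emits one to a few macrocycles,
each audited for the two-bond invariant.

## Known limitations

- No energy function: loops and rings are geometric objects; relative
  populations of basins and cis amides are model inputs, not predictions.
- Sequence design is out of scope: sequences are parsed, attached to
  compatible backbones and audited, never optimised.
- The CCD re-closure drifts torsions by up to ~20° from their sampled
  values for the worst accepted pairs, which can break a marginal
  terminal bond; such rings are rejected by the two-bond audit rather
  than repaired.
- D-norleucine has no universal PDB code; this package writes `DNE`.
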