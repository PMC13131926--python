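"""Parse the design notation for N-methylated D/L macrocycles.

Capital letters are L amino acids, lowercase D; '*' marks backbone
N-methylation of the preceding residue; X is norleucine; prolines are
intrinsically N-alkylated.  Cyclic symmetry order is the largest k such
that rotating the ring by length/k maps it onto itself.
"""

from cyclopept import cyclic_symmetry_order, parse_sequence, write_sequence

for name, seq in [
    ("MC1", "apL*F*apL*F*"),
    ("MC2", "apL*F*FPa*l*"),
    ("MC3", "fpL*a*APl*f*"),
    ("MC4", "XPa*l*iX*Pa*P"),
]:
    specs = parse_sequence(seq)
    donors = [i + 1 for i, s in enumerate(specs) if not s.n_alkylated]
    print(
        f"{name}  {seq:15s} {len(specs)} residues, "
        f"C{cyclic_symmetry_order(specs)} symmetry, "
        f"N-H donors at positions {donors}, "
        f"roundtrip={'ok' if write_sequence(specs) == seq else 'FAIL'}"
    )

# MC1's sequence is internally duplicated, hence symmetry order 2 (C2);
# the three asymmetric designs report order 1.  Each macrocycle keeps
# exactly two amide N-H donors - the junction residues that form the two
# transannular hydrogen bonds.
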