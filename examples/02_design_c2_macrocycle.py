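"""Design a C2-symmetric N-methylated macrocycle and audit it.

Scans n=3 loop substreams for one whose terminal N-to-C transform is (up to
binning) its own inverse, fuses two copies of it, symmetrizes the ring
exactly, and attaches the MC1 sequence to the backbone.  For larger design
campaigns use `generate_library` + `close_library`, which hash the whole
library and fuse every transform-matched pair.
"""

from cyclopept import conformer_strings, count_cis_amides, cyclic_symmetry_order, nh_satisfaction_audit
from cyclopept.fixtures import make_c2_ring

mc = make_c2_ring(seed=1)

print(f"sequence            {mc.sequence}")
print(f"ring length         {len(mc)} residues")
print(f"symmetry order      {cyclic_symmetry_order(mc.residues)}")
print(f"transannular bonds  {len(mc.transannular_hbonds)}")
for b in mc.transannular_hbonds:
    print(f"   {b.donor} -> {b.acceptor}: H...O {b.ho_distance:.2f} A, N-H...O {b.nho_angle:.1f} deg")
print(f"unsatisfied N-H     {nh_satisfaction_audit(mc)}")
print(f"cis amides          {count_cis_amides(mc)}")
cs = conformer_strings(mc)
print(f"ABEGO string        {cs.abego}")
print(f"H-bond string       {cs.hbond_string}")

# Zero unsatisfied N-H donors is the design heuristic for passive membrane
# permeability: every backbone amide proton is either methylated away or
# engaged in one of the two transannular hydrogen bonds at the fusion
# junctions.  'O' letters in the ABEGO string mark cis amides, permitted
# only at N-alkylated (tertiary) positions.
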