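"""Sample hydrogen-bonded G-(NMe-G)n-G loops.

Each accepted loop is an open backbone whose C-terminal glycine donates a
beta-strand-like hydrogen bond back to the N-terminal glycine's carbonyl —
the geometric seed that later lets two loops fuse into a fully
hydrogen-bond-satisfied macrocycle.
"""

import numpy as np

from cyclopept import generate_library

library = generate_library({3: 5, 4: 3, 5: 2}, seed=11)

print(f"{len(library)} loops accepted")
for n, rate in library.acceptance_rate.items():
    print(f"  n={n}: acceptance rate {rate:.2e} per torsion draw")

print("\nloop        len  H...O (A)  N-H...O (deg)  |rotvec| (deg)")
for loop in library:
    b = loop.terminal_hbond
    theta = np.linalg.norm(loop.forward_transform.rotvec_deg())
    print(f"{loop.loop_id}    {len(loop)}    {b.ho_distance:5.2f}      {b.nho_angle:6.1f}        {theta:6.1f}")

# The H...O distance and N-H...O angle describe the terminal hydrogen bond
# (<= 2.5 A, >= 135 deg by default).  |rotvec| is the rotation angle of the
# loop's terminal N-to-C frame transform: values near 180 deg mark loops
# that can close on a copy of themselves into a C2-symmetric ring.
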