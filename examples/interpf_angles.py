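"""Measure inter-protofilament rotation angles on a synthetic lattice.

Builds a cylindrical tubulin-dimer lattice with planted lateral rotations
between adjacent protofilaments (plus coordinate noise), rigid-body fits
every dimer to the shared reference, and reports the per-pair angles
averaged over three axial regions, as well as the 8-nm axial rise along one
protofilament.
"""

from axonarray.geometry import axial_offset, inter_pf_angle_table, principal_axis
from axonarray.synthetic import SyntheticLatticeConfig, make_lattice

cfg = SyntheticLatticeConfig(
    inter_pf_angles_deg=(30.0, 25.0, 35.0), coordinate_noise_sd_A=0.3, seed=1
)
lattice, truth = make_lattice(cfg)

table = inter_pf_angle_table(lattice)
print("planted angles:", truth["angle_deg"].tolist())
print(table.summary().to_string(index=False))

axis = principal_axis(lattice)
rise = axial_offset(lattice.dimers[(0, 0)], lattice.dimers[(0, 1)], axis)
print(f"\naxial offset between successive repeats: {rise:.3f} nm (planted 8.0)")
print("(each angle is the rotation relating rigid fits of adjacent-PF dimers,")
print(" mean ± s.d. over two edge regions and one middle region)")
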