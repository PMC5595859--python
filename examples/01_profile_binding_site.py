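"""Profile the noncovalent interactions of one protein-ligand complex.

Builds a small synthetic complex (a stacked aromatic ligand with paired
hydrogen bonds and a distal hydrophobic arm), carves the binding site
and runs the four interaction detectors.
"""

from ipscreen import (FixtureSpec, build_binding_site, build_fixture,
                      parse_structure, profile_complex, select_ligands)

# a ready-made complex; any PDB/mmCIF file path works the same way
fixture = build_fixture(FixtureSpec(patterns=frozenset("AEH")))
model = parse_structure(fixture.pdb_text, "pdb", identifier="demo")

ligand = select_ligands(model)[0]
site = build_binding_site(model, ligand, cutoff=7.5)
profile = profile_complex(site)

print(f"structure {profile.structure_id}, ligand {profile.ligand_id}")
print(f"  ligand rings:        {len(site.ligand_rings)}")
print(f"  protein atoms <=7.5: {len(site.protein_atoms)}")
print(f"  hydrogen bonds:      {len(profile.hydrogen_bonds)}")
for hb in profile.hydrogen_bonds:
    side = "ligand donates" if hb.ligand_is_donor else "protein donates"
    print(f"    D{hb.donor_serial}->A{hb.acceptor_serial}  "
          f"{hb.da_distance:.2f} A, {hb.donor_angle:.0f} deg ({side})")
print(f"  hydrophobic contacts: {len(profile.hydrophobic_contacts)}")
print(f"  pi-stacks:            {len(profile.pi_stacks)}")
for s in profile.pi_stacks:
    print(f"    {s.stack_type}, centroids {s.centroid_distance:.2f} A, "
          f"offset {s.lateral_offset:.2f} A, face {s.face_sign:+d}")
print(f"  halogen bonds:        {len(profile.halogen_bonds)}")

# Each line is one detected interaction with its geometry; distances are
# heavy-atom distances in Angstrom, angles in degrees.
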