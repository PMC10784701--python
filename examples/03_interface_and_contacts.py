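"""Buried interface area and distance-based contact typing.

Two toy chains in contact give a non-zero buried surface; a serine
hydroxyl near a backbone carbonyl is typed as a hydrogen bond; an
arginine/glutamate pair at salt-bridge range is detected; and the ligand
environment lists every polymer atom within the contact cutoff of a bound
cofactor-like hetero residue.
"""

import numpy as np

from conforma import (
    AtomRecord,
    Residue,
    ResidueKey,
    StructureModel,
    hydrogen_bonds,
    interface_area,
    ligand_environment,
    salt_bridges,
)


def res(chain, num, name, atoms, hetero=False):
    return Residue(
        ResidueKey(chain, num, "", name),
        {n: AtomRecord(n, e, np.asarray(x, float), is_hetero=hetero) for n, e, x in atoms},
    )


chains = {
    cid: [
        res(cid, i + 1, "UNK", [("C1", "C", [off, 1.5 * i, 0.0])])
        for i in range(8)
    ]
    for cid, off in (("A", 0.0), ("B", 4.0))
}
model = StructureModel("toy-dimer", chains)
iface = interface_area(model, ["A"], ["B"])
print(f"buried interface: {iface.area:.1f} A^2 "
      f"(SASA A {iface.sasa_a:.0f} + B {iface.sasa_b:.0f} - AB {iface.sasa_ab:.0f}, halved)")

site = StructureModel(
    "toy-site",
    {
        "A": [
            res("A", 1, "SER", [("CA", "C", [5, 5, 5]), ("OG", "O", [0, 0, 0])]),
            res("A", 2, "ALA", [("CA", "C", [8, 8, 8]), ("O", "O", [2.9, 0, 0])]),
            res("A", 5, "ARG", [("CA", "C", [0, 8, 0]), ("NH1", "N", [0, 5, 0])]),
            res("A", 9, "GLU", [("CA", "C", [0, 0, 8]), ("OE1", "O", [0, 5, 3.4])]),
        ]
    },
    ligands=[res("A", 101, "SAM", [("SD", "S", [2.0, 2.0, 2.0])], hetero=True)],
)
for hb in hydrogen_bonds(site):
    print(f"hbond:       {hb.key_1}.{hb.atom_1} -- {hb.key_2}.{hb.atom_2}  {hb.distance:.2f} A")
for sb in salt_bridges(site):
    print(f"salt bridge: {sb.key_1}.{sb.atom_1} -- {sb.key_2}.{sb.atom_2}  {sb.distance:.2f} A")
records, per_residue = ligand_environment(site, "SAM", cutoff=4.0)
print(f"ligand environment (4 A around SAM): {len(records)} atom contacts, "
      f"nearest residue at {min(per_residue.values()):.2f} A")
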