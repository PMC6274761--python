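"""Map couplings onto a synthetic complex: interface, bonds, contacts,
visibility and secondary structure.

The generator builds a helical IDP docked against a three-helix-bundle
decoy so that every planted pair sits in atomic-contact range; part of the
IDP is deliberately left without coordinates to demonstrate "invisible"
couplings (residues outside the resolved construct).
"""

from idpcoev.contacts import atomic_contacts
from idpcoev.interface import assign_interface
from idpcoev.scoring import EC
from idpcoev.secondary import assign_secondary_structure
from idpcoev.structure import classify_visibility, residue_min_distance
from idpcoev.synthetic import (GeometryConfig, SynthConfig, generate_complex,
                               generate_paired_msa)

cfg = SynthConfig(
    n_species=20, len_idp=20, len_partner=40,
    planted_pairs=((5, 8, 0.8), (12, 20, 0.8)), seed=2,
    geometry=GeometryConfig(idp_conformation="helix",
                            contact_distance_max=5.0,
                            unresolved_idp=(18,),       # resolved gap
                            idp_construct=(1, 19)))     # truncated construct
_, truth = generate_paired_msa(cfg)
s = generate_complex(cfg, truth)

iface = assign_interface(s)
print(f"interface: {iface.total_area:.0f} A^2 buried, "
      f"{len(iface.idp_if_residues)} IDP / {len(iface.partner_if_residues)} "
      f"partner interface residues, {len(iface.hbonds)} H-bonds, "
      f"{len(iface.salt_bridges)} salt bridges "
      f"({iface.bonds_per_1000A2:.2f} bonds per 1000 A^2)")

cmap = atomic_contacts(s)
print(f"atomic contacts: {cmap.total()} interchain heavy-atom contacts over "
      f"{len(cmap.entries)} residue pairs")

for (i, j) in truth.pairs:
    ri = s.residue_index("A", i)
    rj = s.residue_index("B", j)
    d = residue_min_distance(s, ri, rj)
    n = cmap.entries.get((i, j), 0)
    print(f"  planted (IDP {i}, partner {j}): min distance {d:.2f} A, "
          f"{n} atomic contacts")

ss = assign_secondary_structure(s)
helix_frac = sum(ss.three_class(ri) == "helix"
                 for ri in s.chain_residue_indices("A") if s.atom_indices(ri))
print(f"IDP secondary structure: {helix_frac} residues in helix class")

# couplings touching unresolved residues are invisible, with a reason
for pos, label in ((5, "resolved"), (18, "no coordinates"), (20, "not in construct")):
    ec = EC(i=pos, j=8, raw=1, apc=1, scaled=2.0, probability=0.95,
            idp_uniprot_pos=pos, partner_uniprot_pos=8)
    status, reason = classify_visibility(ec, s)
    print(f"coupling at IDP {pos:2d} ({label}): {status}"
          + (f" ({reason})" if reason else ""))
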