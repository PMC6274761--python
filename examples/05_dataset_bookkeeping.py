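"""Dataset bookkeeping: inventory exclusions, segment arithmetic and
screen-level coupling totals.

The screen starts from 42 bacterial IDP-partner complexes; redundant
structures and complexes whose IDP peptide is shorter than 5 residues are
excluded, analyzed segments shorter than 30 residues are extended along
their UniProt sequence, and families with fewer than 130 homologs are
gated out before any co-variation analysis.
"""

from idpcoev.dataset import (EC_BEARING_COMPLEXES, full_inventory,
                             select_nonredundant, tabulate_fixture)
from idpcoev.seqprep import pfam_gate, trim_or_extend

inventory = full_inventory()
kept, excluded = select_nonredundant(inventory)
print(f"inventory: {len(inventory)} complexes -> {len(kept)} kept, "
      f"{len(excluded)} excluded:")
for r in excluded:
    why = (f"redundant to {r.redundant_to}" if r.redundant_to
           else f"IDP peptide only {r.idp_length} residues")
    print(f"  {r.dibs_id} ({r.pdb_id}): {why}")

print("\nanalyzed-segment arithmetic for two IDPs:")
for gene in ("mazE", "flgM"):
    rec = next(r for r in EC_BEARING_COMPLEXES if r.idp_gene == gene)
    start, end = rec.idp_region
    region = trim_or_extend((start, end), "A" * end, uniprot_ac=rec.idp_ac)
    print(f"  {gene}: region {start}-{end} -> analyzed length {region.length}")

print("\nfamily-size gate (threshold 130):")
for n in (129, 130, 507):
    print(f"  {n} homologs -> {'include' if pfam_gate(n) else 'exclude'}")

totals = tabulate_fixture(EC_BEARING_COMPLEXES)
print(f"\nscreen totals over the {len(EC_BEARING_COMPLEXES)} EC-bearing "
      f"complexes: {totals['n_ecs_total']} couplings, "
      f"{totals['n_invisible_total']} invisible, "
      f"{totals['n_visible_total']} visible, "
      f"{totals['n_bonded_total']} in interchain bonds")
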