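"""Generate a synthetic paired alignment with planted couplings and show how
the co-variation signal (mutual information) grows with coupling strength.

A "paired alignment" concatenates, per species, the orthologs of a
disordered protein and of its folded partner. The generator plants chosen
(IDP column, partner column) pairs that co-vary with a tunable strength;
everything else varies independently on a star-tree phylogeny.
"""

from idpcoev.scoring import column_mi
from idpcoev.synthetic import SynthConfig, generate_paired_msa

for strength in (0.0, 0.3, 0.6, 0.9):
    cfg = SynthConfig(n_species=800, len_idp=12, len_partner=12,
                      planted_pairs=((4, 7, strength),), seed=1)
    aln, truth = generate_paired_msa(cfg)
    mi_planted = column_mi(aln, 3, 12 + 6)       # the planted pair
    mi_background = column_mi(aln, 0, 12 + 0)    # an uncoupled pair
    print(f"strength {strength:.1f}:  planted MI {mi_planted:5.2f} bits   "
          f"background MI {mi_background:5.2f} bits")

print()
print("The planted pair's mutual information rises with coupling strength,")
print("while background pairs stay at the small-sample estimation floor —")
print("this is the signal the Potts engine extracts and ranks.")
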