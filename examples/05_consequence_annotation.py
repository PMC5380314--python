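"""Coding-consequence annotation of SNVs, plus in-frame indel arithmetic
and a cross-species conservation score.

The worked example mirrors the package's motivating case: a C>T change at
coding position 376 hits the first base of codon 126 (CGC, arginine) and
creates TGC (cysteine) — a missense substitution written c.376C>T / p.R126C.
"""

import recessmap as rm

codons = ["ATG"] + ["GCT"] * 418 + ["TAA"]
codons[125] = "CGC"                       # codon 126 starts at c.376
cds = "".join(codons)
model = rm.GeneModel("TX1", "GENE1", "7", "+", [(5001, 5000 + len(cds))], cds)

variant = rm.VariantRecord(chrom="7", pos=5001 + 375, ref="C", alt="T")
c = rm.annotate_consequence(variant, [model])
print(f"{c.hgvs_c} -> {c.hgvs_p}: codon {c.codon_index}, offset "
      f"{c.codon_offset}, {c.ref_aa}->{c.alt_aa} ({c.consequence_class})")

# In-frame indel arithmetic: a 15 bp insertion with a 3 bp deletion inside a
# two-codon segment replaces those 2 residues with 6.
print("replacement codons for +15bp/-3bp over 2 codons:",
      rm.inframe_replacement_codons(2, 15, 3))

# Conservation: fraction of aligned sequences sharing the majority residue.
column = ["T"] * 19 + ["A"] * 10 + ["S"] * 10 + ["V"] * 8 + ["I"] * 6
alignment = [f"A{residue}G" for residue in column]
print(f"conservation at a 53-sequence column with a 19-strong majority: "
      f"{rm.conservation_score(alignment, 1):.4f}")
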