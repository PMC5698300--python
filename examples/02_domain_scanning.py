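"""Scan proteins for the three LOB-domain blocks and call Class I / II.

Generates a small labelled synthetic proteome (Class I with a complete
C-block + GAS + leucine-zipper grammar, Class II with a broken zipper,
plus decoys) and shows the classifier recovering every label.
"""

from lbdkit.lobscan import classify_protein
from lbdkit.simulate import SimConfig, generate_proteome

proteome = generate_proteome(SimConfig(seed=42, n_class1=8, n_class2=5, n_decoys=12))

confusion: dict = {}
for name, seq in proteome.sequences.items():
    ann = classify_protein(seq)
    truth = proteome.labels[name]
    confusion[(truth, ann.class_call)] = confusion.get((truth, ann.class_call), 0) + 1

print("true class -> called class (count):")
for (truth, called), n in sorted(confusion.items()):
    print(f"  {truth:>4} -> {called:<4} {n}")

example = next(n for n, c in proteome.labels.items() if c == "I")
ann = classify_protein(proteome.sequences[example])
print(f"\nexample Class-I annotation ({example}):")
print(f"  C-block  {ann.c_block_span}   zinc-finger-like CX2CX6CX3C")
print(f"  GAS      {ann.gas_span}   FX2(V/A)H ... DP(V/I)YG")
print(f"  zipper   {ann.zipper_span}   complete={ann.zipper_complete}")
print("\nA diagonal confusion table means the motif grammar separates the"
      "\ntwo classes and the decoys exactly at zero mutation.")
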