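"""Cis-element enrichment in target promoters versus a background set.

Plants a motif in every target promoter and none of the background,
scores over-representation with the one-sided hypergeometric test, and
shows the enumerative k-mer discovery recovering the planted element.
"""

from lbdkit.cispromoter import (
    MotifDef,
    PromoterSet,
    kmer_discovery,
    load_motif_dictionary,
    motif_enrichment,
)
from lbdkit.simulate import SimConfig, generate_promoters

config = SimConfig(seed=3, planted_motif="GGTTGAAT",
                   motif_freq_target=1.0, motif_freq_background=0.0)
prom = generate_promoters(config)
targets = PromoterSet(prom.targets, config.promoter_len)
background = PromoterSet(prom.background, config.promoter_len)

motifs = [MotifDef("planted", config.planted_motif)] + load_motif_dictionary()[:5]
rows = motif_enrichment(targets, background, motifs, alpha=0.01)
print(f"{'motif':<16}{'targets':>9}{'background':>12}{'p-value':>12}  enriched")
for r in sorted(rows, key=lambda r: r.p_value):
    print(f"{r.motif:<16}{r.n_target_with:>6}/{r.n_target:<3}"
          f"{r.n_background_with:>8}/{r.n_background:<3}{r.p_value:>12.3g}"
          f"  {'yes' if r.enriched else 'no'}")

table = kmer_discovery(targets, background, k_range=[8], top_n=3)
print("\ntop de-novo 8-mers (reverse-complement pairs merged):")
print(table.to_string(index=False))
print("\nThe planted element dominates both the dictionary scan (p << 0.01)"
      "\nand the exhaustive k-mer ranking; unplanted motifs stay flat.")
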