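"""Gene diversity and diversity loss on a synthetic collection.

Computes Nei gene diversity H = 2p(1-p) per marker from band-presence
frequencies, aggregates it per chromosome / genome / overall for the
whole collection and each subspecies, and reports the relative
diversity loss ΔGD = 1 - H_subsp/H_wc of each subspecies.
"""

from durmap import SimConfig, aggregate_h, generate_collection

dataset, _ = generate_collection(SimConfig(seed=1))
table = aggregate_h(dataset)

print("H (gene diversity) by scope and group:")
print(table.h.loc[["Genome A", "Genome B", "Total"]].round(2).to_string())
print("\nΔGD (diversity loss vs whole collection):")
print(table.dgd.loc[["Genome A", "Genome B", "Total"]].round(2).to_string())
# A ΔGD near 0 means the subspecies carries almost all of the
# collection's diversity; dicoccon (13 accessions) loses the most.
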