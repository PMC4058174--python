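"""Turn protein sequences into the 188-dimensional feature vector.

The vector is: 20 amino-acid composition fractions, then 21 values per
physicochemical property (3 content + 15 distribution + 3 dipeptide),
for the eight standard properties.
"""

from dnabind import ProteinRecord, extract_features, standard_groupings

record = ProteinRecord("demo", "MKRKRKSAEDLLAAGITQVWCVY")
fv = extract_features(record)

print(f"sequence length L = {record.length}")
print(f"feature dimension = {len(fv)}")

# Composition of the positively charged residues often enriched in
# DNA-binding proteins:
for name in ("comp_R", "comp_K"):
    idx = fv.names.index(name)
    print(f"{name} = {fv[idx]:.4f}")

# The charge property's content block: fraction of residues in the
# positive (K,R) / neutral / negative (D,E) groups — sums to 1.
charge_start = fv.names.index("charge_content_g1")
g1, g2, g3 = fv[charge_start : charge_start + 3]
print(f"charge content (pos, neutral, neg) = ({g1:.3f}, {g2:.3f}, {g3:.3f})")

print("groupings used:", ", ".join(g.name for g in standard_groupings()))
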