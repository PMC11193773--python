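"""Encode a small peptide set with the default 58-type descriptor registry.

Builds a toy dataset in memory, encodes it, and prints the envelope and a few
named feature values.  Each peptide becomes a row of 4335 numbers; column
names are "<TYPE>.<feature>" (e.g. AAC.C is the cysteine fraction).
"""

from antiangio import default_registry, encode_all
from antiangio.seqio import LabeledDataset, Peptide

dataset = LabeledDataset(
    "toy",
    [Peptide("aap1", "CWRSSCPRWCPSSR"),       # cysteine/tryptophan-rich
     Peptide("aap2", "SPCCRWPSWRSPCW"),
     Peptide("ctl1", "AEILVAELIVALEV"),       # aliphatic/acidic
     Peptide("ctl2", "LIVEALEAVILAEV")],
    [1, 1, 0, 0],
)

registry = default_registry()
matrix = encode_all(dataset, registry)

print(f"descriptor types : {len(registry)}")
print(f"values/peptide   : {registry.total_size}")
print(f"matrix shape     : {matrix.shape}")
print()
for col in ("AAC.C", "AAC.W", "AAC.A", "GAAC.ali", "SEP.entropy", "LEN.length"):
    print(f"{col:12s} " + "  ".join(f"{matrix.loc[pid, col]:6.3f}"
                                    for pid in dataset.ids))
print()
print("AAC.C / AAC.W are high for the first two peptides (the positive-like,"
      " Cys/Trp-rich ones); GAAC.ali is the aliphatic-group fraction and is"
      " high for the control peptides instead.")
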