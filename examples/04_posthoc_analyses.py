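"""Post-hoc analyses: class composition propensities, TPR vs predicted
probability, and accuracy stratified by residue-property ratios.

Uses the synthetic full-length preset; trains a default SVM on amino-acid
composition only, then inspects where the classifier is reliable.
"""


from antiangio import default_registry, encode_all, make_default_model
from antiangio.evaluate import (accuracy_by_residue_property,
                                composition_propensity,
                                probability_tpr_correlation,
                                tpr_by_probability_bins)
from antiangio.modeling import fit_final
from antiangio.seqio import stratified_split
from antiangio.synthdata import fulllength_config, generate_peptide_dataset

dataset = generate_peptide_dataset(fulllength_config(seed=5))
dev, test = stratified_split(dataset, 0.8, seed=5)

prop = composition_propensity(dataset)
print("largest residue-composition differences (positive - negative):")
print(prop["AAC"].head(8).round(3).to_string())
print("\n(The generator enriches C,P,R,S,W in positives and A,E,I,L,V in"
      " negatives; the signs above reflect that.)")

registry = default_registry().subset(["AAC"])
model = fit_final(encode_all(dev, registry), dev.labels,
                  make_default_model("SVM", seed=5))
m_test = encode_all(test, registry)
p = model.predict_proba(m_test)

bins = tpr_by_probability_bins(test.labels, p)
print("\nTPR by predicted-probability bin (held-out split):")
print(bins[bins["count"] > 0][["midpoint", "count", "tpr"]]
      .round(3).to_string(index=False))
print(f"rank correlation: {probability_tpr_correlation(bins):.2f} "
      "(positive = probabilities are informative)")

hard = (p >= 0.5).astype(int)
print("\nmean accuracy by residue-property ratio (held-out split):")
for name in ("hydrophobic", "hydrophilic", "charged"):
    table = accuracy_by_residue_property(test, hard, name)
    occupied = table[table["count"] > 0]
    cells = "  ".join(f"{row.midpoint:.2f}:{row.mean_accuracy:.2f}(n={int(row['count'])})"
                      for _, row in occupied.iterrows())
    print(f"  {name:12s} {cells}")
print("\nOn this strongly separated synthetic data accuracy is near 1 in every"
      " occupied bin; on real peptides these curves rise with hydrophobic"
      " ratio and fall with hydrophilic/charged ratio.")
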