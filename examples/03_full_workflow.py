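"""Run the complete workflow on a synthetic N-terminus-style benchmark.

Generates 100+100 peptides of length 15 with class-enriched residue usage
(C,P,R,S,W in positives; A,E,I,L,V in negatives), splits 80/20, encodes with
the full registry, ranks and selects features, tunes three classifier
families, cross-validates, and evaluates once on the held-out split.
Takes about a minute.
"""

from antiangio.pipeline import PipelineConfig, run_pipeline
from antiangio.synthdata import generate_peptide_dataset, nterm15_config

dataset = generate_peptide_dataset(nterm15_config(seed=7), name="nterm15")
cfg = PipelineConfig(boruta_iter=20, boruta_trees=200, search_repeats=1,
                     tune_trials=15, tune_families=("SVM", "LDA", "LightGBM"),
                     eval_repeats=2, seed=7)
res = run_pipeline(dataset, config=cfg)

print(f"selected subset     : top {res.search.best_n} of 4335 features "
      f"(search family {res.search.best_family})")
for fam, rep in res.cv_reports.items():
    print(f"{fam:9s} 10-fold CV : MCC {rep.mcc:.3f}  AUC {rep.auc:.3f}")
print(f"best family         : {res.best_family}")
t = res.test_report
print(f"independent test    : Acc {t.acc:.3f}  Pre {t.pre:.3f}  "
      f"Rec {t.rec:.3f}  Sp {t.sp:.3f}  MCC {t.mcc:.3f}  AUC {t.auc:.3f}")
print(f"TPR-vs-probability rank correlation: {res.tpr_correlation:.2f}")
print()
print("CV MCC near 1 is expected here: the generator's factor-5 residue"
      " enrichment separates the classes far more strongly than real peptide"
      " benchmarks do.  The positive rank correlation says higher predicted"
      " probability indeed means a higher fraction of true positives.")
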