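"""Genomic prediction of the breeding lines from the AMP.

RRBLUP (y = X beta + Z u + e, u ~ N(0, K sigma_u2)) is trained on each
AMP site-year dataset and used to predict the F5 and DH lines — the
standard scenario (GS1) and the GWAS-assisted scenario with the top
significant SNPs as fixed effects (GS2). Predictive ability is the
Pearson correlation between GEBV and adjusted yield, reported against
both the selection environment and the next-season validation
environment; a five-fold cross-validation inside the AMP shows the
within-panel ceiling.
"""

import pandas as pd

from common import RESULTS, SEED, get_study
from wheatsel.predict import cross_validate, predictive_ability

study = get_study()
out = RESULTS / "prediction"
out.mkdir(parents=True, exist_ok=True)

rows = []
for (pop, dataset, scenario), res in sorted(study.gebv.items()):
    res.to_tsv(out / f"gebv_{pop}_{dataset}_{scenario}.tsv")
    sel_env, val_env = (f"{pop}_SEL", f"{pop}_VAL")
    r_sel, n = predictive_ability(res, study.adjusted[sel_env])
    r_val, _ = predictive_ability(res, study.adjusted[val_env])
    rows.append({"population": pop, "training_dataset": dataset,
                 "scenario": scenario, "n": n,
                 "r_selection_env": r_sel, "r_validation_env": r_val})
tab = pd.DataFrame(rows)
tab.to_csv(out / "predictive_ability.tsv", sep="\t", index=False,
           float_format="%.4f")
print(tab.round(3).to_string(index=False))
print(f"\nmean predictive ability, selection env: "
      f"{tab['r_selection_env'].mean():.3f}; validation env: "
      f"{tab['r_validation_env'].mean():.3f} "
      "(low, as expected when training on a weakly related panel under G x E)")

oof, fold_r, mean_r = cross_validate(study.genotypes["AMP"],
                                     study.adjusted["AMP_LND"],
                                     folds=5, seed=SEED)
oof.rename("oof_gebv").to_csv(out / "amp_cv_gebv.tsv", sep="\t")
print(f"five-fold CV inside the AMP (LND dataset): mean predictive ability "
      f"{mean_r:.3f} (per fold: {[round(r, 3) for r in fold_r]})")
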