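"""Simulate the study populations: a 456-line association mapping panel
(AMP) with 2,000 GBS-style SNPs, plus F5 (200 lines) and DH (500 lines)
biparental populations derived from AMP parents, each grown in augmented
complete block design trials (replicated checks, unreplicated tests) in a
selection environment and a weakly correlated validation season.

Writes the genotype matrices and field books under results/.
"""

from common import RESULTS, SEED, get_study
from wheatsel.simulate import write_fieldbook

study = get_study()

amp = study.truths["AMP"]
print(f"seed {SEED}; config hash {study.log['config_hash']}")
for name, truth in study.truths.items():
    h2 = truth.realized_h2.round(3).to_dict()
    print(f"{name}: {truth.true_genetic_values.shape[0]} lines, "
          f"environments {list(truth.true_genetic_values.columns)}, "
          f"realized H2 {h2}")

out = RESULTS / "populations"
out.mkdir(parents=True, exist_ok=True)
for name, truth in study.truths.items():
    truth.true_genetic_values.to_csv(out / f"true_genetic_values_{name}.tsv", sep="\t")
    write_fieldbook(study.fieldbooks[name], out / f"fieldbook_{name}.csv")
    study.genotypes[name].to_csv(out / f"genotypes_{name}.csv")
print(f"wrote genotypes, field books and ground-truth genetic values to {out}")
print("Checks appear in every block; every test line is unreplicated within "
      "an environment — the structure the augmented-design adjustment assumes.")
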