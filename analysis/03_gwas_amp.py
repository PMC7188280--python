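"""Marker-trait association in the AMP and relatedness to the test lines.

A kinship-corrected single-marker mixed-model scan (P3D: null-model
variance components reused per marker) is run on each AMP site-year
dataset; markers are declared significant at a Benjamini-Hochberg FDR of
0.05. The top five significant SNPs across datasets define the
favourable-allele set used by marker selection (MS) and the fixed
effects of the GWAS-assisted prediction scenario (GS2). Per-SNP variance
explained is the drop-one R^2 from the joint OLS fit. Rogers genetic
distance quantifies AMP-to-breeding-line relatedness per chromosome.
"""

import warnings

from common import RESULTS, get_study
from wheatsel.assoc import snp_variance_explained

study = get_study()
out = RESULTS / "gwas"
out.mkdir(parents=True, exist_ok=True)

for res in study.gwas_results:
    res.to_tsv(out / f"gwas_{res.dataset}.tsv")
    sig = res.significant()
    print(f"{res.dataset}: {len(sig)} significant SNPs of {len(res.table)} "
          f"scanned (engine: {res.method_note})")
    if not sig.empty:
        pheno = study.adjusted[res.dataset]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = snp_variance_explained(study.genotypes["AMP"], pheno,
                                        list(sig["marker"]))
        r2.rename_axis("marker").to_frame().to_csv(
            out / f"r2_drop_one_{res.dataset}.tsv", sep="\t")
        print("  drop-one R^2: " + ", ".join(f"{m}={v:.3g}" for m, v in r2.items()))

if len(study.allele_set):
    study.allele_set.table.to_csv(out / "favorable_alleles.tsv", sep="\t", index=False)
    print(f"top-{len(study.allele_set)} favourable-allele set "
          f"(required homozygous dosage):")
    print(study.allele_set.table.to_string(index=False))
else:
    print("no significant SNPs: MS and GS2 are not applicable for this seed")

for pop, rep in study.rogers.items():
    rep.to_tsv(out / f"rogers_AMP_vs_{pop}.tsv")
    print(f"Rogers distance AMP vs {pop}: overall {rep.overall:.3f} "
          f"(mean over {rep.n_markers} markers)")
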