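"""Per-CpG differential methylation with annotation summaries.

Runs the Welch t-test screen on beta values (case vs control), annotates
every probe by gene region x CGI context, and prints the region/context
grid of significant sites plus the promoter-island enrichment test.
"""

import warnings

from methcoupler import annotate, diffmeth, synthdata
from methcoupler import ioformats as io

cohort = synthdata.generate_cohort(synthdata.SimConfig(seed=1))
manifest = diffmeth.drop_snp_probes(cohort.manifest)
beta = io.OmicsMatrix(
    cohort.beta.data.loc[cohort.beta.data.index.intersection(manifest.index)],
    "beta")

dmcs = diffmeth.test_dmc(beta, cohort.samples, alpha=0.05, delta_min=0.05)
sig = dmcs[dmcs["significant"]]
relevant = sig[sig["biologically_relevant"]]
print(f"significant probes (P<0.05): {len(sig)} of {len(dmcs)} "
      f"({100 * len(sig) / len(dmcs):.1f}%)")
print(f"of these, |delta beta| >= 5%: {len(relevant)}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ann = annotate.annotate_cpgs(manifest, cohort.genes, cohort.cgis)
grid = annotate.region_context_grid(sig, ann)
print("\nDMC counts by gene region (rows) x CGI context (columns):")
print(grid)

enr = annotate.promoter_cgi_enrichment(sig, ann.loc[sig.index], ann)
print(f"\npromoter-island enrichment: chi2={enr.chi2:.1f}, "
      f"P={enr.p_value:.2e}")
# A small chi-squared P means significant sites concentrate in
# promoter-associated CpG islands beyond the array's own composition —
# exactly the planted structure.
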