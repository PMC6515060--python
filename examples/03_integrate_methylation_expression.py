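"""Inverse promoter-methylation / expression pairing and the group-wise
pooled Pearson statistic.

Pairs significant promoter-island DMCs with inversely changed, filter-
passing DEGs on the same gene, then pools (beta, log2 expression) points
over pairs x samples separately per group.  With case-only coupling the
case group shows a strong negative correlation while the control group
stays null.
"""

import warnings

from methcoupler import annotate, diffexpr, diffmeth, integrate, synthdata
from methcoupler import ioformats as io

cohort = synthdata.generate_cohort(synthdata.SimConfig(seed=1))
manifest = diffmeth.drop_snp_probes(cohort.manifest)
beta = io.OmicsMatrix(
    cohort.beta.data.loc[cohort.beta.data.index.intersection(manifest.index)],
    "beta")
dmcs = diffmeth.test_dmc(beta, cohort.samples)
degs = diffexpr.test_deg(cohort.fpkm, cohort.samples)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ann = annotate.annotate_cpgs(manifest, cohort.genes, cohort.cgis)

pairs = integrate.pair_inverse(dmcs, degs, ann)
print(f"inverse pairs: {len(pairs)} probes on "
      f"{pairs['gene_id'].nunique()} genes")

summary, _ = integrate.groupwise_correlation(pairs, beta, cohort.fpkm,
                                             cohort.samples)
for group, row in summary.iterrows():
    print(f"{group:>8}: n={row['n_points']:4.0f}  r={row['pearson_r']:+.3f}"
          f"  P={row['p_value']:.2e}")

report = synthdata.truth_recovery_report(cohort.truth, pairs)
print(f"\nplanted-gene recovery: {report.sensitivity:.1%} "
      f"(false-discovery fraction {report.false_discovery_fraction:.1%})")
# A very small case-group P with a control-group P above 0.05 reproduces
# the case-specific methylation-expression coupling that was planted.
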