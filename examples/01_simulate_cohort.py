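"""Generate a synthetic case/control methylation + expression cohort.

Builds the default study conditions — 6 vs 6 samples with one case dropped
(5 ICM-like cases vs 6 NICM-like controls), 120 genes x 6 CpGs, planted
promoter-CGI hyper- and hypomethylation coupled to expression in cases
only — and writes every pipeline input plus the truth tables.
"""

from methcoupler import synthdata

cfg = synthdata.SimConfig(seed=1)
cohort = synthdata.generate_cohort(cfg)
paths = synthdata.write_cohort(cohort, "scratch/example_cohort")

truth = cohort.truth.genes["planted_direction"].value_counts()
print(f"samples: {len(cohort.samples.case_ids)} case / "
      f"{len(cohort.samples.control_ids)} control")
print(f"probes: {len(cohort.manifest)}, genes: {len(cohort.genes)}")
print("planted classes:", dict(truth))
print(f"wrote {len(paths)} files to scratch/example_cohort/")
# The planted classes are the ground truth the downstream examples try to
# recover: hyper_down genes are promoter-hypermethylated and suppressed in
# cases, hypo_up genes the reverse, the rest are null.
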