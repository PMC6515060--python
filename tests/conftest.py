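import warnings

import pytest

from methcoupler import annotate, diffexpr, diffmeth, synthdata
from methcoupler import ioformats as io


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (5 vs 6 after the outlier drop)."""
    return synthdata.generate_cohort(synthdata.SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_products(cohort):
    """DMC table, DEG table and annotation for the default cohort."""
    manifest = diffmeth.drop_snp_probes(cohort.manifest)
    beta = io.OmicsMatrix(
        cohort.beta.data.loc[cohort.beta.data.index.intersection(
            manifest.index)], "beta")
    dmcs = diffmeth.test_dmc(beta, cohort.samples)
    degs = diffexpr.test_deg(cohort.fpkm, cohort.samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        annotation = annotate.annotate_cpgs(manifest, cohort.genes,
                                            cohort.cgis)
    return {"manifest": manifest, "beta": beta, "dmcs": dmcs, "degs": degs,
            "annotation": annotation}
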