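import numpy as np
import pandas as pd
import pytest

from methcoupler import integrate, synthdata
from methcoupler import ioformats as io
from _oracles import pearson_r_p


def _dmc(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "delta_beta", "p_value"]
                      ).set_index("probe_id")
    df["fdr"] = df["p_value"]
    df["significant"] = df["p_value"] < 0.05
    df["biologically_relevant"] = df["delta_beta"].abs() >= 0.05
    return df


def _deg(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value",
                                     "passes_filter"]).set_index("gene_id")
    return df


ANN = pd.DataFrame(
    {"gene_id": ["gA", "gB", "gC", "gA"],
     "region": ["promoter", "promoter", "body", "promoter"],
     "context": ["island", "island", "island", "shore"]},
    index=["cg1", "cg2", "cg3", "cg4"])


def test_pair_inverse_sign_and_annotation_rules():
    dmcs = _dmc([("cg1", 0.1, 0.001), ("cg2", 0.1, 0.001),
                 ("cg3", 0.1, 0.001), ("cg4", 0.1, 0.001)])
    degs = _deg([("gA", -1.0, 0.01, True), ("gB", 1.0, 0.01, True),
                 ("gC", -1.0, 0.01, True)])
    pairs = integrate.pair_inverse(dmcs, degs, ANN)
    # cg1/gA: inverse, promoter-island -> kept.  cg2/gB: both up -> excluded.
    # cg3/gC: body -> excluded.  cg4/gA: shore -> excluded.
    assert list(pairs["probe_id"]) == ["cg1"]
    assert pairs.iloc[0]["gene_id"] == "gA"
    assert pairs.iloc[0]["inverse"]


def test_pair_inverse_subset_and_order_invariance():
    dmcs = _dmc([("cg1", 0.1, 0.001), ("cg2", -0.2, 0.001)])
    degs = _deg([("gA", -1.0, 0.01, True), ("gB", 1.0, 0.01, True)])
    p1 = integrate.pair_inverse(dmcs, degs, ANN)
    p2 = integrate.pair_inverse(dmcs.iloc[::-1], degs.iloc[::-1], ANN)
    assert p1.equals(p2)
    assert set(p1["probe_id"]) <= set(dmcs.index[dmcs["significant"]])
    assert set(p1["gene_id"]) <= set(degs.index[degs["passes_filter"]])


def test_pair_inverse_empty_warns():
    dmcs = _dmc([("cg1", 0.1, 0.5)])
    degs = _deg([("gA", -1.0, 0.01, True)])
    with pytest.warns(UserWarning, match="no inverse"):
        pairs = integrate.pair_inverse(dmcs, degs, ANN)
    assert pairs.empty


def _simple_setup():
    samples = io.SampleSheet(pd.DataFrame(
        {"group": ["case"] * 3 + ["control"] * 3},
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id")))
    beta = io.OmicsMatrix(pd.DataFrame(
        np.array([[0.2, 0.4, 0.6, 0.3, 0.5, 0.7],
                  [0.1, 0.3, 0.5, 0.2, 0.4, 0.8]]),
        index=["cg1", "cg2"], columns=samples.sample_ids), "beta")
    return samples, beta


def test_groupwise_correlation_exact_inverse_line():
    """Points lying exactly on y = -x give r = -1 in both groups."""
    samples, beta = _simple_setup()
    # craft FPKM so log2(FPKM+1) = -beta + 2 exactly
    y = 2 ** (2 - beta.values) - 1
    expr = io.OmicsMatrix(pd.DataFrame(y, index=["gA", "gB"],
                                       columns=beta.sample_ids), "fpkm")
    pairs = pd.DataFrame({"probe_id": ["cg1", "cg2"],
                          "gene_id": ["gA", "gB"],
                          "delta_beta": [0.1, 0.1],
                          "log2fc": [-1.0, -1.0], "inverse": True})
    summary, scatter = integrate.groupwise_correlation(pairs, beta, expr,
                                                       samples)
    assert summary.loc["case", "pearson_r"] == pytest.approx(-1.0, abs=1e-12)
    assert summary.loc["control", "pearson_r"] == pytest.approx(-1.0,
                                                                abs=1e-12)
    # pooled point-count conservation: pairs x samples, split across groups
    assert summary["n_points"].sum() == len(pairs) * 6
    assert len(scatter) == len(pairs) * 6


def test_groupwise_correlation_matches_pearson_oracle():
    rng = np.random.default_rng(17)
    samples, beta = _simple_setup()
    expr = io.OmicsMatrix(pd.DataFrame(rng.lognormal(2, 0.5, size=(2, 6)),
                                       index=["gA", "gB"],
                                       columns=beta.sample_ids), "fpkm")
    pairs = pd.DataFrame({"probe_id": ["cg1", "cg2"],
                          "gene_id": ["gA", "gB"],
                          "delta_beta": [0.1, -0.1],
                          "log2fc": [-1.0, 1.0], "inverse": True})
    summary, scatter = integrate.groupwise_correlation(pairs, beta, expr,
                                                       samples)
    for group, ids in (("case", samples.case_ids),
                       ("control", samples.control_ids)):
        pts = scatter[scatter["group"] == group]
        r, p = pearson_r_p(pts["beta"], pts["log2_expr"])
        assert summary.loc[group, "pearson_r"] == pytest.approx(r, abs=1e-10)
        assert summary.loc[group, "p_value"] == pytest.approx(p, abs=1e-10)


def test_covariation_with_seed_sign_classes():
    rng = np.random.default_rng(12)
    n = 12
    seed_expr = 2 ** rng.normal(4, 1, n)
    anti = 2 ** (8 - np.log2(seed_expr + 1)) - 1   # exact mirror on log scale
    noise = 2 ** rng.normal(3, 1, n)
    expr = io.OmicsMatrix(pd.DataFrame(
        [seed_expr, seed_expr, anti, noise],
        index=["seed", "twin", "anti", "rand"],
        columns=[f"s{i}" for i in range(n)]), "fpkm")
    res = integrate.covariation_with_seed(expr, "seed")
    assert "seed" not in res.index
    assert res.loc["twin", "pearson_r"] == pytest.approx(1.0, abs=1e-10)
    assert res.loc["twin", "sign_class"] == "positive"
    assert res.loc["anti", "pearson_r"] == pytest.approx(-1.0, abs=1e-10)
    assert res.loc["anti", "sign_class"] == "negative"


def test_covariation_constant_seed_rejected():
    expr = io.OmicsMatrix(pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]],
                                       index=["seed", "g"],
                                       columns=["a", "b", "c"]), "fpkm")
    with pytest.raises(ValueError, match="constant"):
        integrate.covariation_with_seed(expr, "seed")


def test_regulator_targets_recover_planted_sign(cohort):
    res = integrate.covariation_with_seed(cohort.fpkm,
                                          cohort.truth.regulator)
    report = synthdata.truth_recovery_report(
        cohort.truth, pd.DataFrame(columns=["gene_id", "delta_beta",
                                            "log2fc"]), covariation=res)
    assert report.regulator_sign_recovery >= 0.9


# ---------------------------------------------------------------------- #
# cross-study concordance
# ---------------------------------------------------------------------- #

def _tables_with_overlap(n_overlap, n_co, seed=0):
    """Two DEG tables sharing exactly n_overlap significant genes of which
    n_co agree in sign."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_overlap)]
    sign_a = rng.choice([-1.0, 1.0], n_overlap)
    sign_b = sign_a.copy()
    flip = rng.choice(n_overlap, n_overlap - n_co, replace=False)
    sign_b[flip] *= -1
    a = pd.DataFrame({"log2fc": sign_a, "p_value": 0.01}, index=genes)
    b = pd.DataFrame({"log2fc": sign_b, "p_value": 0.01}, index=genes)
    # padding genes significant in only one study
    a = pd.concat([a, pd.DataFrame({"log2fc": 1.0, "p_value": 0.01},
                                   index=["onlyA"])])
    b = pd.concat([b, pd.DataFrame({"log2fc": 1.0, "p_value": 0.01},
                                   index=["onlyB"])])
    return a, b


def test_concordance_printed_worked_example():
    """171 overlapping genes with 143 co-directional give 84% to the nearest
    integer."""
    a, b = _tables_with_overlap(171, 143)
    res = integrate.cross_study_concordance(a, b)
    assert res.n_overlap == 171 and res.n_codirectional == 143
    assert round(res.percent) == 84


def test_concordance_identical_tables():
    a, _ = _tables_with_overlap(50, 25)
    res = integrate.cross_study_concordance(a, a)
    assert res.percent == 100.0


def test_concordance_randomized_signs_near_half():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(1000)]
    a = pd.DataFrame({"log2fc": rng.choice([-1.0, 1.0], 1000),
                      "p_value": 0.01}, index=genes)
    b = pd.DataFrame({"log2fc": rng.choice([-1.0, 1.0], 1000),
                      "p_value": 0.01}, index=genes)
    res = integrate.cross_study_concordance(a, b)
    assert abs(res.percent - 50.0) < 5.0


def test_concordance_empty_overlap():
    a = pd.DataFrame({"log2fc": [1.0], "p_value": [0.01]}, index=["g1"])
    b = pd.DataFrame({"log2fc": [1.0], "p_value": [0.01]}, index=["g2"])
    with pytest.warns(UserWarning):
        res = integrate.cross_study_concordance(a, b)
    assert res.percent is None
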