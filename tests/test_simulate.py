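"""Generator correctness: dose table, NB moments, determinism, allele model."""

import numpy as np
import pandas as pd
import pytest

from xadose import simulate as sim
from xadose.exceptions import InputError, ParameterError

from conftest import small_params


# Closed-form dose table for u=2, e=0.3 over all (category, genotype) pairs.
DOSE_TABLE = {
    # (chrom_class, x_category, beta, eroded): {genotype: dose}
    ("autosome", "none", 0.0, False): {"XX": 2, "XY": 2, "XXY": 2, "XO": 2},
    ("autosome", "none", 1.0, False): {"XX": 2, "XY": 2, "XXY": 1, "XO": 4},
    ("autosome", "none", -1.0, False): {"XX": 2, "XY": 2, "XXY": 4, "XO": 1},
    ("X", "xci_subject", 0.0, False): {"XX": 2, "XY": 2, "XXY": 2, "XO": 2},
    ("X", "xci_subject", 0.0, True): {"XX": 4, "XY": 2, "XXY": 4, "XO": 2},
    ("X", "escapee", 0.0, False): {"XX": 2.6, "XY": 2, "XXY": 2.6, "XO": 2},
    ("X", "xist_like", 0.0, False): {"XX": 2, "XY": 0, "XXY": 2, "XO": 0},
    ("X", "xist_like", 0.0, True): {"XX": 0, "XY": 0, "XXY": 0, "XO": 0},
    ("Y", "none", 0.0, False): {"XX": 0, "XY": 1, "XXY": 1, "XO": 0},
}


def test_effective_dose_matches_closed_form_table():
    params = sim.SimulationParams(upregulation=2.0, escape_fraction=0.3)
    for (cls, cat, beta, eroded), by_geno in DOSE_TABLE.items():
        for geno, expected in by_geno.items():
            spec = sim.GenotypeSpec.from_label(geno, eroded=eroded)
            d = sim.effective_dose(cls, cat, beta, spec, params)
            assert d == pytest.approx(expected), (cls, cat, beta, eroded, geno)


def test_regulator_dose_per_genotype():
    assert {g: sim.GenotypeSpec.from_label(g).regulator_dose
            for g in sim.GENOTYPES} == {"XX": 1, "XY": 1, "XXY": 2, "XO": 0}


def test_genotype_spec_rejects_inconsistent_copy_numbers():
    with pytest.raises(InputError):
        sim.GenotypeSpec("XX", 1, 1)
    with pytest.raises(InputError):
        sim.GenotypeSpec.from_label("XXX")


def test_annotation_gene_counts_and_degenerate_classes():
    only_aut = sim.SimulationParams(n_autosomal=5, n_x_xci=0, n_x_escape=0,
                                    n_y=0, n_trans_targets=0)
    ann, _ = sim.build_annotation(only_aut)
    assert len(ann) == 6  # 5 autosomal + the XIST-like marker
    assert (ann["x_category"] == "xist_like").sum() == 1

    p = small_params(n_autosomal=100, n_trans_targets=10)
    ann, truth = sim.build_annotation(p)
    assert len(ann) == 100 + p.n_x_xci + p.n_x_escape + p.n_y + 1
    assert ann["trans_target"].sum() == 10
    assert (ann.loc[ann["trans_target"], "trans_beta"] != 0).all()
    assert (ann.loc[~ann["trans_target"], "trans_beta"] == 0).all()
    assert (ann.loc[ann["trans_target"], "chrom_class"] == "autosome").all()
    assert ann["gene_id"].is_unique
    # x_category <-> chrom_class consistency
    assert ((ann["x_category"] != "none") == (ann["chrom_class"] == "X")).all()


def test_annotation_rejects_invalid_parameters():
    with pytest.raises(ParameterError):
        sim.build_annotation(sim.SimulationParams(n_autosomal=-1))
    with pytest.raises(ParameterError):
        sim.build_annotation(sim.SimulationParams(n_autosomal=5,
                                                  n_trans_targets=6))


def test_generator_is_deterministic_given_seed():
    p = small_params()
    ann1, truth1 = sim.build_annotation(p)
    ann2, truth2 = sim.build_annotation(p)
    pd.testing.assert_frame_equal(ann1, ann2)
    pd.testing.assert_frame_equal(truth1, truth2)
    sheet = sim.build_sample_sheet(p)
    c1, t1 = sim.simulate_counts(ann1, sheet, p, truth1)
    c2, t2 = sim.simulate_counts(ann2, sheet, p, truth2)
    pd.testing.assert_frame_equal(c1, c2)
    a1 = sim.simulate_allele_counts(ann1, sheet, p, coverage_mean=20)
    a2 = sim.simulate_allele_counts(ann1, sheet, p, coverage_mean=20)
    pd.testing.assert_frame_equal(a1, a2)

    other = small_params(seed=12)
    ann3, _ = sim.build_annotation(other)
    assert not ann3["trans_beta"].equals(ann1["trans_beta"])


def test_count_matrix_shape_and_y_genes_zero_without_y(small_panel):
    params, ann, sheet, counts, truth = small_panel
    n_genes = params.n_autosomal + params.n_x_xci + params.n_x_escape \
        + params.n_y + 1
    assert counts.shape == (n_genes, 4 * params.replicates_per_genotype)
    assert (counts.to_numpy() >= 0).all()
    y_genes = ann.loc[ann["chrom_class"] == "Y", "gene_id"]
    no_y_samples = sheet.loc[sheet["genotype"].isin(["XX", "XO"]), "sample_id"]
    assert (counts.loc[y_genes, no_y_samples].to_numpy() == 0).all()


def test_sample_mean_approaches_expected_in_poisson_limit():
    # alpha -> 0: sample mean over many replicates ~ mu * d / 2 within 3 SE
    p = sim.SimulationParams(n_autosomal=5, n_x_xci=2, n_x_escape=1, n_y=1,
                             n_trans_targets=0, dispersion=1e-13,
                             baseline_log_sd=0.5,
                             replicates_per_genotype=200, seed=4)
    ann, truth = sim.build_annotation(p)
    sheet = sim.build_sample_sheet(p, genotypes=["XY"])
    counts, truth = sim.simulate_counts(ann, sheet, p, truth)
    expected = truth["mu"].to_numpy() * truth["dose_XY"].to_numpy() / 2
    observed = counts.mean(axis=1).to_numpy()
    se = np.sqrt(np.maximum(expected, 1e-12) / counts.shape[1])
    pos = expected > 0
    assert np.all(np.abs(observed[pos] - expected[pos]) <= 3 * se[pos])
    assert np.all(observed[~pos] == 0)


def test_nb_marginal_moments():
    # mean m, variance m + alpha m^2 within Monte-Carlo tolerance, n=10000
    p = sim.SimulationParams(n_autosomal=1, n_x_xci=0, n_x_escape=0, n_y=0,
                             n_trans_targets=0, dispersion=0.1,
                             baseline_log_mean=np.log(100.0),
                             baseline_log_sd=0.0,
                             replicates_per_genotype=10000, seed=8)
    ann, truth = sim.build_annotation(p)
    sheet = sim.build_sample_sheet(p, genotypes=["XX"])
    counts, truth = sim.simulate_counts(ann, sheet, p, truth)
    draws = counts.iloc[0].to_numpy(dtype=float)  # autosomal gene, m = mu
    m = truth["mu"].iloc[0]
    var_expected = m + 0.1 * m ** 2
    assert draws.mean() == pytest.approx(m, rel=0.03)
    assert draws.var(ddof=1) == pytest.approx(var_expected, rel=0.15)


def test_full_compensation_matches_autosomal_expression():
    # u=2, e=0, no erosion, equal baselines: XCI-subject X genes and
    # autosomal genes have the same expected expression (paired MC check).
    p = sim.SimulationParams(n_autosomal=400, n_x_xci=400, n_x_escape=0,
                             n_y=0, n_trans_targets=0, upregulation=2.0,
                             escape_fraction=0.0, baseline_log_sd=0.0,
                             replicates_per_genotype=6, seed=21)
    ann, truth = sim.build_annotation(p)
    sheet = sim.build_sample_sheet(p, genotypes=["XX", "XY"])
    counts, truth = sim.simulate_counts(ann, sheet, p, truth)
    aut = counts.loc[ann.loc[ann["chrom_class"] == "autosome", "gene_id"]]
    xci = counts.loc[ann.loc[ann["x_category"] == "xci_subject", "gene_id"]]
    mean_a, mean_x = aut.to_numpy().mean(), xci.to_numpy().mean()
    pooled_se = np.sqrt(aut.to_numpy().var() / aut.size
                        + xci.to_numpy().var() / xci.size)
    assert abs(mean_a - mean_x) <= 3 * pooled_se


def test_true_lfc_antisymmetric_with_infinite_sentinels(small_panel):
    _, ann, _, _, truth = small_panel
    ab = sim.true_lfc(truth, "XY", "XO")
    ba = sim.true_lfc(truth, "XO", "XY")
    finite = np.isfinite(ab)
    assert np.allclose(ab[finite], -ba[finite])
    y_rows = (truth["chrom_class"] == "Y").to_numpy()
    assert np.all(np.isneginf(ab[y_rows]))  # Y: dose 1 -> 0
    assert np.all(np.isposinf(ba[y_rows]))
    # autosomal non-targets: dose 2 everywhere -> lfc exactly 0
    null_rows = ((truth["chrom_class"] == "autosome")
                 & ~truth["trans_target"]).to_numpy()
    assert np.all(ab[null_rows] == 0)


class TestAlleleCounts:
    def test_zero_error_rate_is_strictly_monoallelic(self):
        p = small_params(escape_fraction=0.3)
        ann, _ = sim.build_annotation(p)
        sheet = sim.build_sample_sheet(p, genotypes=["XX"])
        tab = sim.simulate_allele_counts(ann, sheet, p, coverage_mean=30,
                                         error_rate=0.0)
        xci_genes = set(ann.loc[ann["x_category"] == "xci_subject", "gene_id"])
        sub = tab[tab["gene_id"].isin(xci_genes)]
        assert (sub["count_allele_B"] == 0).all()

    def test_full_escape_gives_balanced_alleles(self):
        p = sim.SimulationParams(n_autosomal=1, n_x_xci=0, n_x_escape=1000,
                                 n_y=0, n_trans_targets=0,
                                 escape_fraction=1.0, seed=5)
        ann, _ = sim.build_annotation(p)
        sheet = sim.build_sample_sheet(p, genotypes=["XX"])
        sheet = sheet.iloc[:1]
        tab = sim.simulate_allele_counts(ann, sheet, p, coverage_mean=40,
                                         error_rate=0.0)
        esc = tab[tab["gene_id"].str.startswith("ESC")]
        frac = esc["count_allele_B"].sum() / (esc["count_allele_A"].sum()
                                              + esc["count_allele_B"].sum())
        n = esc[["count_allele_A", "count_allele_B"]].to_numpy().sum()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se

    def test_eroded_xci_subject_is_biallelic(self):
        p = small_params(erosion_probability=1.0, seed=6)
        ann, _ = sim.build_annotation(p)
        sheet = sim.build_sample_sheet(p, genotypes=["XX"])
        assert sheet["eroded"].all()
        tab = sim.simulate_allele_counts(ann, sheet, p, coverage_mean=50,
                                         error_rate=0.0)
        xci_genes = set(ann.loc[ann["x_category"] == "xci_subject", "gene_id"])
        sub = tab[tab["gene_id"].isin(xci_genes)]
        tot = (sub["count_allele_A"] + sub["count_allele_B"]).sum()
        frac = sub["count_allele_B"].sum() / tot
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / tot)

    def test_invalid_error_rate_rejected(self, small_panel):
        params, ann, sheet, _, _ = small_panel
        with pytest.raises(ParameterError):
            sim.simulate_allele_counts(ann, sheet, params, error_rate=0.6)


def test_unknown_genotype_in_sample_sheet_rejected(small_panel):
    params, ann, _, _, truth = small_panel
    bad = pd.DataFrame({"sample_id": ["s1"], "genotype": ["XYY"],
                        "replicate": [1]})
    with pytest.raises(InputError, match="XYY"):
        sim.simulate_counts(ann, bad, params, truth)
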