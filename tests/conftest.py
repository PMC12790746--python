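"""Shared fixtures: small and full-scale simulated panels.

Everything is generated programmatically from fixed seeds; session scope
keeps the expensive default-scale run shared across tests.
"""

import pytest

from xadose import dosage, pipeline, simulate as sim


def small_params(**overrides) -> sim.SimulationParams:
    """Desk-scale parameter set for fast unit tests."""
    base = dict(n_autosomal=300, n_x_xci=40, n_x_escape=10, n_y=8,
                n_trans_targets=30, replicates_per_genotype=3, seed=11)
    base.update(overrides)
    return sim.SimulationParams(**base)


@pytest.fixture()
def small_panel():
    """Counts/annotation/sheet/truth for a small 4-genotype panel."""
    params = small_params()
    ann, truth = sim.build_annotation(params)
    sheet = sim.build_sample_sheet(params)
    counts, truth = sim.simulate_counts(ann, sheet, params, truth)
    return params, ann, sheet, counts, truth


@pytest.fixture(scope="session")
def default_run():
    """Full default-scale simulated panel with filtering and normalization.

    Session-scoped: the generator defaults define the reference study
    conditions used by the end-to-end pattern tests.
    """
    params = sim.SimulationParams(seed=0)
    ann, truth = sim.build_annotation(params)
    sheet = sim.build_sample_sheet(params)
    counts, truth = sim.simulate_counts(ann, sheet, params, truth)
    filtered = dosage.filter_low_expression(counts, 10)
    sf = dosage.size_factors_median_of_ratios(filtered)
    vst = dosage.transform(filtered, sf)
    return {"params": params, "annotation": ann, "sheet": sheet,
            "counts": counts, "truth": truth, "filtered": filtered,
            "size_factors": sf, "vst": vst}


@pytest.fixture(scope="session")
def default_de_results(default_run):
    """Pairwise DE tables for the five default genotype contrasts."""
    return pipeline.compare_genotypes(
        default_run["filtered"], default_run["annotation"],
        default_run["sheet"], size_factors=default_run["size_factors"])
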