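"""Bulk enzymology fits, the synthetic-assay generator and the iron assay."""

import numpy as np
import pytest

from badmotor.bulk import (
    BulkDataset,
    IronAssayConfig,
    KineticParams,
    a535_for_stoichiometry,
    bulk_profile,
    default_design,
    fit_activation,
    fit_michaelis_menten,
    fit_progress_curve,
    generate_bulk_dataset,
    iron_per_protein,
)


@pytest.mark.parametrize("kind,profile,names", [
    ("mm", "atpase_mm", ("kcat", "Km")),
    ("activation", "dna_activation", ("basal_rate", "Vmax", "K_DNA")),
    ("progress", "displacement_progress", ("amplitude", "kobs")),
])
def test_noiseless_round_trip_is_exact(kind, profile, names):
    params = bulk_profile(profile)
    d = generate_bulk_dataset(kind, params, noise_cv=0.0, seed=0)
    fit = {"mm": fit_michaelis_menten, "activation": fit_activation,
           "progress": fit_progress_curve}[kind](d)
    truth = {"kcat": params.kcat, "Km": params.Km,
             "basal_rate": params.basal_rate, "Vmax": params.Vmax,
             "K_DNA": params.K_DNA, "amplitude": params.amplitude,
             "kobs": params.kobs}
    for name in names:
        assert fit.params[name] == pytest.approx(truth[name], rel=1e-6)


def test_mm_two_point_exact_data_matches_algebraic_solve():
    # v = kcat s/(Km+s): two exact points give a closed-form solution
    kcat, km = 80.0, 150.0
    s = np.array([100.0, 1000.0, 50.0, 400.0])
    v = kcat * s / (km + s)
    d = BulkDataset("mm", table=__import__("pandas").DataFrame(
        {"x": s, "y": v, "replicate": 0}))
    fit = fit_michaelis_menten(d)
    # algebraic oracle from the first two points
    s1, s2, v1, v2 = s[0], s[1], v[0], v[1]
    km_o = (v2 - v1) * s1 * s2 / (v1 * s2 - v2 * s1)
    kcat_o = v1 * (km_o + s1) / s1
    assert fit.params["Km"] == pytest.approx(km_o, rel=1e-6)
    assert fit.params["kcat"] == pytest.approx(kcat_o, rel=1e-6)


def test_mm_agrees_with_lineweaver_burk_on_noiseless_data():
    params = KineticParams(kcat=101.0, Km=223.0)
    d = generate_bulk_dataset("mm", params, noise_cv=0.0, seed=0)
    fit = fit_michaelis_menten(d)
    inv_s, inv_v = 1.0 / d.x, 1.0 / d.y
    slope, intercept = np.polyfit(inv_s, inv_v, 1)
    assert fit.params["kcat"] == pytest.approx(1.0 / intercept, rel=1e-6)
    assert fit.params["Km"] == pytest.approx(slope / intercept, rel=1e-6)


def test_fit_invariant_under_row_permutation():
    d = generate_bulk_dataset("activation", bulk_profile("dna_activation"),
                              noise_cv=0.03, seed=5)
    shuffled = BulkDataset("activation",
                           d.table.sample(frac=1, random_state=0)
                           .reset_index(drop=True))
    a = fit_activation(d)
    b = fit_activation(shuffled)
    # identical least-squares problem; tiny differences only from summation
    # order inside the optimizer
    assert a.params == pytest.approx(b.params, rel=1e-4)


def test_activation_requires_zero_point_and_flags_degenerate():
    import pandas as pd
    t = pd.DataFrame({"x": [1.0, 2.0, 5.0, 10.0, 20.0],
                      "y": [20, 30, 60, 80, 95.0], "replicate": 0})
    with pytest.raises(ValueError):
        fit_activation(BulkDataset("activation", t))
    t0 = pd.DataFrame({"x": [0.0] * 5, "y": [1.0, 1.1, 0.9, 1.05, 0.95],
                       "replicate": 0})
    with pytest.warns(RuntimeWarning):
        res = fit_activation(BulkDataset("activation", t0))
    assert res.extras["degenerate"] == 1.0
    assert res.params["basal_rate"] == pytest.approx(1.0, rel=0.1)


def test_progress_halflife_consistency():
    # fitted kobs vs ln2 / t_half read off the interpolated noiseless curve
    params = KineticParams(kobs=0.66, amplitude=0.9)
    x = np.linspace(0, 4, 200)
    y = 0.9 * (1 - np.exp(-0.66 * x))
    t_half = np.interp(0.45, y, x)
    import pandas as pd
    d = BulkDataset("progress", pd.DataFrame(
        {"x": x, "y": y, "replicate": 0}))
    fit = fit_progress_curve(d)
    assert fit.params["kobs"] == pytest.approx(np.log(2) / t_half, rel=0.01)


def test_progress_flags_gross_outliers():
    import pandas as pd
    x = np.linspace(0, 4, 8)
    y = 0.9 * (1 - np.exp(-0.5 * x))
    y[5] = 0.1  # gross non-monotone outlier
    with pytest.warns(RuntimeWarning):
        res = fit_progress_curve(BulkDataset("progress", pd.DataFrame(
            {"x": x, "y": y, "replicate": 0})))
    assert res.extras["n_outliers"] >= 1


class TestGenerator:
    def test_zero_noise_returns_exact_model(self):
        p = bulk_profile("atpase_mm")
        d = generate_bulk_dataset("mm", p, noise_cv=0.0, seed=1)
        expect = p.kcat * d.x / (p.Km + d.x)
        assert np.allclose(d.y, expect)

    def test_deterministic_per_seed(self):
        p = bulk_profile("dna_activation")
        a = generate_bulk_dataset("activation", p, noise_cv=0.05, seed=9)
        b = generate_bulk_dataset("activation", p, noise_cv=0.05, seed=9)
        assert a.table.equals(b.table)

    def test_noise_cv_is_calibrated(self):
        # empirical CV at a single design point over many replicates
        p = KineticParams(kcat=100.0, Km=200.0)
        d = generate_bulk_dataset("mm", p, design=[500.0],
                                  replicates=10_000, noise_cv=0.05, seed=2)
        cv = d.y.std() / d.y.mean()
        assert cv == pytest.approx(0.05, rel=0.10)

    def test_unknown_kind_and_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_bulk_dataset("nope", KineticParams(), seed=0)
        with pytest.raises(ValueError):
            bulk_profile("nope")

    def test_default_designs_cover_stated_ranges(self):
        mm = default_design("mm")
        assert mm.min() == pytest.approx(50.0) and mm.max() == pytest.approx(2000.0)
        act = default_design("activation")
        assert act[0] == 0.0 and act.max() == pytest.approx(20.0)
        prog = default_design("progress")
        assert prog[0] == 0.0 and prog.max() == pytest.approx(4.0)


class TestIronAssay:
    def test_zero_absorbance_gives_zero(self):
        assert iron_per_protein(0.0) == 0.0

    def test_beer_lambert_assay_concentration(self):
        # A535 = 0.1 over 1 cm -> 0.1/22369 M = 4.47 uM in the assay
        cfg = IronAssayConfig()
        fe_assay_uM = 0.1 / (cfg.epsilon_535 * cfg.path_length) * 1e6
        assert fe_assay_uM == pytest.approx(4.47, abs=0.01)
        protein_uM = cfg.protein_stock_uM * cfg.protein_volume_ul \
            / cfg.assay_volume_ul
        assert iron_per_protein(0.1) == pytest.approx(
            fe_assay_uM / protein_uM, rel=1e-9)

    def test_three_iron_per_protein_round_trip(self):
        a = a535_for_stoichiometry(3.0)
        assert iron_per_protein(a) == pytest.approx(3.0, abs=0.01)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            iron_per_protein(-0.1)
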