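import numpy as np
import pandas as pd
import pytest

from isoniche.hier_model import (
    HierModelConfig,
    NotConvergedError,
    effect_summary_table,
    fit_hier_mvst,
    pairwise_species_contrasts,
    species_mean_summary,
)
from isoniche.synthetic_data import (
    SPECIES_MEANS,
    default_isotope_spec,
    generate_isotope_dataset,
)

# deliberately small sampling budgets: these tests check statistical
# behaviour of the model, not production-grade effective sample sizes
FAST = dict(chains=2, warmup=500, steps=700, draws=1500, target_ess=100,
            max_retries=0)


@pytest.fixture(scope="module")
def default_fit():
    """One shared fit on the default (study-sized) synthetic dataset."""
    iso = generate_isotope_dataset(default_isotope_spec(), seed=42)
    return fit_hier_mvst(iso, HierModelConfig(seed=1, **FAST)), iso


class TestFit:
    def test_species_means_recover_generative_truth(self, default_fit):
        post, _ = default_fit
        summ = species_mean_summary(post, force=True)
        for sp, (c13, n15) in SPECIES_MEANS.items():
            row_c = summ[(summ.species == sp) & (summ.isotope == "d13C")].iloc[0]
            row_n = summ[(summ.species == sp) & (summ.isotope == "d15N")].iloc[0]
            # generous MC + sampling-noise tolerance at study sample sizes
            assert row_c["mean"] == pytest.approx(c13, abs=0.5)
            assert row_n["mean"] == pytest.approx(n15, abs=0.5)

    def test_summary_sorted_descending_within_isotope(self, default_fit):
        post, _ = default_fit
        summ = species_mean_summary(post, force=True)
        for iso, g in summ.groupby("isotope"):
            assert g["mean"].is_monotonic_decreasing

    def test_posterior_scale_matrices_positive_definite(self, default_fit):
        post, _ = default_fit
        dets = np.linalg.det(post.sigma.reshape(-1, 2, 2))
        assert (dets > 0).all()
        assert (post.nu > 2).all()

    def test_single_species_requires_flag(self, default_fit):
        _, iso = default_fit
        one = iso[iso.species == "H_dipterurus"]
        with pytest.raises(ValueError, match="single_species"):
            fit_hier_mvst(one, HierModelConfig(seed=0, **FAST))

    def test_contrasts_decisive_for_separated_species(self, default_fit):
        # generative d13C means are ~1.4-3.5 permil apart: all contrasts decisive
        post, _ = default_fit
        con = pairwise_species_contrasts(post, force=True)
        c13 = con[con.isotope == "d13C"]
        assert (np.maximum(c13.p_greater, c13.p_less) > 0.99).all()

    def test_contrast_probabilities_complementary(self, default_fit):
        post, _ = default_fit
        con = pairwise_species_contrasts(post, force=True)
        assert np.allclose(con.p_greater + con.p_less, 1.0)

    def test_effect_summaries_deterministic(self, default_fit):
        post, _ = default_fit
        a = effect_summary_table(post, force=True)
        b = effect_summary_table(post, force=True)
        pd.testing.assert_frame_equal(a, b)

    def test_nonconverged_posterior_refuses_summaries(self):
        iso = generate_isotope_dataset(
            default_isotope_spec(n_override=30), seed=3
        )
        cfg = HierModelConfig(
            chains=2, warmup=20, steps=30, draws=60, target_ess=5000,
            max_retries=0, seed=4,
        )
        post = fit_hier_mvst(iso, cfg)
        assert not post.converged
        with pytest.raises(NotConvergedError):
            species_mean_summary(post)
        # force=True overrides the guard
        assert len(species_mean_summary(post, force=True)) == 6

    def test_identical_seed_identical_posterior(self):
        iso = generate_isotope_dataset(
            default_isotope_spec(n_override=30), seed=5
        )
        cfg = HierModelConfig(
            chains=2, warmup=50, steps=50, draws=100, target_ess=1,
            max_retries=0, seed=11,
        )
        a = fit_hier_mvst(iso, cfg)
        b = fit_hier_mvst(iso, cfg)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta, b.beta)


class TestModelProperties:
    def test_flipping_season_coding_flips_slope_sign(self):
        # relabelling cold <-> warm flips the design coding, so the season
        # slope posterior must flip sign (up to MC error)
        spec = default_isotope_spec(n_override=150, shifts=False)
        spec.species["H_dipterurus"].shifts = {"season": (0.8, 0.8)}
        iso = generate_isotope_dataset(spec, 21)
        flipped = iso.copy()
        flipped["season"] = flipped["season"].map({"cold": "warm", "warm": "cold"})
        cfg = HierModelConfig(seed=9, **FAST)
        eff = effect_summary_table(fit_hier_mvst(iso, cfg), force=True)
        eff_f = effect_summary_table(fit_hier_mvst(flipped, cfg), force=True)
        sel = ("H_dipterurus", "season")
        for iso_ax in ("d13C", "d15N"):
            m = eff[(eff.species == sel[0]) & (eff.factor == sel[1])
                    & (eff.isotope == iso_ax)]["mean"].iloc[0]
            mf = eff_f[(eff_f.species == sel[0]) & (eff_f.factor == sel[1])
                       & (eff_f.isotope == iso_ax)]["mean"].iloc[0]
            assert mf == pytest.approx(-m, abs=0.25)

    def test_laplace_prior_shrinks_null_slopes_more_than_wide_normal(self):
        # on null data the Bayesian-lasso posterior slope magnitudes are no
        # larger than under a wide normal prior (averaged over seeds)
        lasso, wide = [], []
        for seed in range(4):
            iso = generate_isotope_dataset(
                default_isotope_spec(n_override=60, shifts=False), 300 + seed
            )
            small = dict(chains=2, warmup=400, steps=500, draws=1000,
                         target_ess=50, max_retries=0)
            for prior, acc in (("laplace", lasso), ("normal", wide)):
                cfg = HierModelConfig(seed=31 + seed, beta_prior=prior, **small)
                eff = effect_summary_table(fit_hier_mvst(iso, cfg), force=True)
                acc.append(eff["mean"].abs().mean())
        assert np.mean(lasso) <= np.mean(wide)

    def test_large_fixed_nu_approaches_normal_sample_means(self):
        # with nu fixed large the Student-t likelihood degenerates to the
        # bivariate normal, whose species mean tracks the sample mean
        spec = default_isotope_spec(n_override=150, shifts=False)
        iso = generate_isotope_dataset(spec, 77)
        cfg = HierModelConfig(seed=13, fix_nu=1000.0, **FAST)
        summ = species_mean_summary(fit_hier_mvst(iso, cfg), force=True)
        for sp, g in iso.groupby("species"):
            got = summ[(summ.species == sp) & (summ.isotope == "d13C")]["mean"].iloc[0]
            assert got == pytest.approx(g["d13C"].mean(), abs=0.2)
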