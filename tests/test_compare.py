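"""Model-comparison statistics: subject summaries, repeated-measures
ANOVA (with a brute-force oracle), Bonferroni post-hocs, error control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mrsmm as M
from mrsmm.compare import rm_anova, summaries_to_frame


def _corpus(effects=None, n_subjects=8, noise=0.02, seed=0):
    return M.generate_pattern_corpus(
        n_subjects=n_subjects,
        methods=("full_MM", "ind_MM_AM", "con_MM_AM"),
        effects=effects if effects is not None else {},
        within_noise=noise,
        seed=seed,
    )


def brute_force_rm_anova(data: np.ndarray):
    """Within-subject one-way ANOVA from raw sums of squares."""
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    cond_means = data.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_err = np.sum((data - subj_means - cond_means + grand) ** 2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    p = stats.f.sf(F, df1, df2)
    return F, p


def _fake_fits(basis, grid, amps_by_voxel, crlb=5.0, fwhm=10.0):
    """Hand-built per-voxel results: amps_by_voxel maps (i, j) -> NAA amp."""
    from mrsmm.lcfit import LCFitResult
    from mrsmm.pipeline import GridFitResults

    m = grid.matrix
    results = [[None] * m for _ in range(m)]
    z = np.zeros(4)
    for (i, j), amp in amps_by_voxel.items():
        results[i][j] = LCFitResult(
            amplitudes={"NAA": amp, "MM1": 2 * amp},
            crlb_percent={"NAA": crlb, "MM1": crlb},
            phi0_deg=0.0, phi1_deg_per_ppm=0.0, global_shift_ppm=0.0,
            broadening_hz=0.0, baseline=z, residual=z, fit_ppm=z,
            fwhm_naa_hz=fwhm, snr_naa=50.0, converged=True,
        )
    return GridFitResults(results=results, grid=grid, basis=basis, failures={})


class TestSummaries:
    def test_single_voxel_mean_equals_voxel(self, basis_con, small_phantom):
        grid, _ = small_phantom
        fits = _fake_fits(basis_con, grid, {(8, 8): 1.25})
        qa = M.qa_filter(fits)
        s = M.summarize_subject(fits, qa, "S1", "con_MM_AM", metabolites=("NAA", "MM1"))
        assert s.means["NAA"] == pytest.approx(1.25)
        assert s.means["MM1"] == pytest.approx(2.5)

    def test_exclusion_changes_mean_on_two_level_fixture(self, basis_con, small_phantom):
        grid, _ = small_phantom
        amps = {(8, j): 1.0 for j in range(4, 8)} | {(9, j): 3.0 for j in range(4, 8)}
        fits = _fake_fits(basis_con, grid, amps)
        qa_all = M.qa_filter(fits)
        s_all = M.summarize_subject(fits, qa_all, "S1", "m", metabolites=("NAA",))
        assert s_all.means["NAA"] == pytest.approx(2.0)
        # push the high-level row past both QA limits -> only 1.0s remain
        for j in range(4, 8):
            r = fits.voxel(9, j)
            r.crlb_percent["NAA"] = 40.0
            r.fwhm_naa_hz = 25.0
        qa = M.qa_filter(fits)
        s = M.summarize_subject(fits, qa, "S1", "m", metabolites=("NAA",))
        assert s.means["NAA"] == pytest.approx(1.0)

    def test_reporting_sums_and_permutation_invariance(self, basis_con, small_phantom):
        grid, _ = small_phantom
        amps = {(8, j): float(j) for j in range(4, 10)}
        fits = _fake_fits(basis_con, grid, amps)
        qa = M.qa_filter(fits)
        a = M.summarize_subject(fits, qa, "S1", "m", metabolites=("NAA", "MM1"),
                                reporting_sums={"both": ("NAA", "MM1")})
        assert a.means["both"] == pytest.approx(a.means["NAA"] + a.means["MM1"])

    def test_zero_included_voxels_rejected(self, basis_con, small_phantom):
        grid, _ = small_phantom
        fits = _fake_fits(basis_con, grid, {(8, 8): 1.0}, crlb=50.0, fwhm=30.0)
        qa = M.qa_filter(fits)
        with pytest.raises(ValueError, match="zero included"):
            M.summarize_subject(fits, qa, "S1", "m", metabolites=("NAA",))


class TestRMAnova:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(5, 4)) + rng.normal(size=(5, 1))
        wide = pd.DataFrame(data, columns=list("ABCD"))
        wide.index.name = "subject"
        F, p = rm_anova(wide)
        F0, p0 = brute_force_rm_anova(data)
        assert F == pytest.approx(F0, abs=1e-8)
        assert p == pytest.approx(p0, abs=1e-8)

    def test_greenhouse_geisser_not_more_liberal_under_effect(self):
        """With a real condition effect (F > 1) the epsilon-adjusted
        degrees of freedom can only make the test more conservative."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 4)) * np.array([1.0, 1.0, 1.0, 4.0])
        data += np.array([0.0, 0.5, 1.0, 2.0])  # planted effect
        wide = pd.DataFrame(data, columns=list("ABCD"))
        wide.index.name = "subject"
        F, p_plain = rm_anova(wide)
        _, p_gg = rm_anova(wide, greenhouse_geisser=True)
        assert F > 1
        assert p_gg >= p_plain - 1e-12


class TestCompareMethods:
    def test_identical_methods_null_case(self):
        rng = np.random.default_rng(3)
        summaries = []
        for s in range(6):
            means = {"NAA": float(1 + rng.random()), "Glu": float(2 + rng.random())}
            for method in ("full_MM", "ind_MM_AM", "con_MM_AM"):
                summaries.append(M.SubjectSummary(f"S{s}", method, dict(means)))
        df = M.compare_methods(summaries)
        assert np.allclose(df["percent_diff"], 0.0)
        assert not df["significant"].any()

    def test_planted_20pct_effect_detected(self):
        summaries = _corpus(effects={"ind_MM_AM": {"NAA": 0.20}}, n_subjects=10,
                            noise=0.01, seed=7)
        df = M.compare_methods(summaries)
        naa = df[df["metabolite"] == "NAA"].set_index("method")
        assert naa.loc["ind_MM_AM", "percent_diff"] == pytest.approx(20.0, abs=1.0)
        assert naa.loc["ind_MM_AM", "significant"]
        assert not naa.loc["con_MM_AM", "significant"]
        others = df[df["metabolite"] != "NAA"]
        assert not others[others["method"] == "con_MM_AM"]["significant"].any()

    def test_sign_convention_positive_means_higher_than_reference(self):
        summaries = _corpus(effects={"ind_MM_AM": {"NAA": -0.15}}, n_subjects=8,
                            noise=0.005, seed=2)
        df = M.compare_methods(summaries)
        val = df[(df.metabolite == "NAA") & (df.method == "ind_MM_AM")]["percent_diff"].iloc[0]
        assert val == pytest.approx(-15.0, abs=1.0)

    def test_unbalanced_design_rejected(self):
        summaries = _corpus(n_subjects=5)[:-1]  # drop one cell
        with pytest.raises(ValueError, match="missing"):
            M.compare_methods(summaries)

    def test_reference_must_be_present(self):
        summaries = [s for s in _corpus(n_subjects=4) if s.method != "full_MM"]
        with pytest.raises(ValueError, match="reference"):
            M.compare_methods(summaries)

    def test_familywise_error_controlled_on_null(self):
        """Bonferroni post-hoc keeps the per-metabolite family-wise
        rejection rate at or below alpha on null corpora (quick 150-
        replicate version; 500 replicates in the acceptance suite)."""
        n_rej = 0
        n_rep = 150
        for rep in range(n_rep):
            summaries = _corpus(n_subjects=14, noise=0.05, seed=10_000 + rep)
            df = M.compare_methods(summaries)
            naa = df[df["metabolite"] == "NAA"]
            n_rej += int(naa["significant"].any())
        rate = n_rej / n_rep
        margin = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + margin


class TestSummaryIO:
    def test_round_trip_tsv(self, tmp_path):
        summaries = _corpus(n_subjects=3)
        path = tmp_path / "summaries.tsv"
        from mrsmm.compare import read_summaries_tsv, write_summaries_tsv

        write_summaries_tsv(path, summaries)
        back = read_summaries_tsv(path)
        assert len(back) == len(summaries)
        assert back[0].means == pytest.approx(summaries[0].means)
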