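import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqtag.gca import (
    GCAError,
    bh_adjust,
    build_design,
    fit_lmm,
    morey_sem,
    peak_latency,
    poly_basis,
    relevel_and_refit,
    statistics_grid,
)
from freqtag.spectral import SNRTimeCourse


def make_tcs(n_subjects, values=None, bins=None, rng=None):
    """SNRTimeCourse collection for n subjects x 3 conditions."""
    bins = statistics_grid() if bins is None else bins
    rng = rng or np.random.default_rng(0)
    tcs = []
    for s in range(n_subjects):
        for c in ("TS", "PS", "NS"):
            if values is None:
                y = 1.5 + 0.3 * rng.random(len(bins))
            else:
                y = values(s, c, bins)
            tcs.append(SNRTimeCourse(f"S{s:02d}", c, 18.75, bins, y))
    return tcs


class TestPolyBasis:
    def test_26_point_grid_gram_identity(self):
        pb = poly_basis(statistics_grid(), 3)
        gram = pb.basis.T @ pb.basis
        assert np.abs(gram - np.eye(3)).max() < 1e-10
        assert np.abs(pb.basis.sum(axis=0)).max() < 1e-10

    def test_symmetric_grid_linear_antisymmetry(self):
        pb = poly_basis(np.linspace(-5, 5, 11), 2)
        lin = pb.basis[:, 0]
        assert np.allclose(lin, -lin[::-1], atol=1e-12)

    def test_basis_self_recovery(self):
        pb = poly_basis(statistics_grid(), 3)
        y = pb.basis[:, 1]  # the quadratic column itself
        X = np.column_stack([np.ones(len(y)), pb.basis])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(coef, [0, 0, 1, 0], atol=1e-9)

    def test_duplicate_time_points(self):
        with pytest.raises(GCAError, match="duplicate"):
            poly_basis(np.array([1.0, 2.0, 2.0, 3.0]), 2)

    def test_too_few_points(self):
        with pytest.raises(GCAError):
            poly_basis(np.array([1.0, 2.0, 3.0]), 3)


class TestBuildDesign:
    def test_full_study_row_count(self):
        design = build_design(make_tcs(17), "TS", 3)
        assert design.n_obs == 1326
        assert design.n_subjects == 17
        assert design.X.shape == (1326, 12)

    def test_single_subject_rows(self):
        design = build_design(make_tcs(1), "TS", 2)
        assert design.n_obs == 78

    def test_reference_rows_have_zero_dummies(self):
        design = build_design(make_tcs(3), "PS", 3)
        ps_rows = design.frame["condition"] == "PS"
        dummy_cols = [design.columns.index("TS"), design.columns.index("NS")]
        assert np.all(design.X[np.asarray(ps_rows)][:, dummy_cols] == 0)
        row_sums = design.X[:, dummy_cols].sum(axis=1)
        assert set(row_sums) <= {0.0, 1.0}

    def test_missing_cell_named(self):
        tcs = [tc for tc in make_tcs(3) if not
               (tc.subject_id == "S01" and tc.condition == "NS")]
        with pytest.raises(GCAError, match="S01.*NS"):
            build_design(tcs, "TS", 3)


class TestFitLMM:
    def test_identical_subjects_degenerate_tau(self):
        """All subjects identical: tau00 -> 0 and fixed effects match OLS."""
        bins = statistics_grid()
        pb = poly_basis(bins, 3)

        def values(s, c, b):
            shift = {"TS": 0.0, "PS": 0.1, "NS": 0.3}[c]
            return 1.5 + shift + pb.basis[:, 0] * 0.5 - pb.basis[:, 2] * 0.2

        design = build_design(make_tcs(5, values), "TS", 3)
        fit = fit_lmm(design)
        assert fit.tau00 < 1e-6
        ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        assert np.allclose(fit.coefficients["estimate"], ols, atol=1e-6)

    def test_balanced_variance_components_match_anova_oracle(self):
        """Balanced random-intercept data: REML sigma2/tau00 equal the
        closed-form expected-mean-squares estimators."""
        rng = np.random.default_rng(42)
        n_sub, bins = 12, statistics_grid()
        n_per = 3 * len(bins)
        offsets = rng.normal(0, 0.4, n_sub)

        def values(s, c, b):
            return 3.0 + offsets[s] + rng.normal(0, 0.25, len(b))

        design = build_design(make_tcs(n_sub, values), "TS", 3)
        fit = fit_lmm(design)

        # Closed-form EMS oracle on OLS residuals.  GLS = OLS here because
        # every subject has an identical design block, and the non-intercept
        # columns absorb only within-subject degrees of freedom.
        X, y = design.X, design.y
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        R = (y - X @ beta).reshape(n_sub, n_per)
        rbar = R.mean(axis=1)
        p = X.shape[1]
        ssw = np.sum((R - rbar[:, None]) ** 2)
        sigma_oracle = ssw / (n_sub * n_per - n_sub - (p - 1))
        msb = n_per * np.sum((rbar - rbar.mean()) ** 2) / (n_sub - 1)
        tau_oracle = (msb - sigma_oracle) / n_per
        assert fit.sigma2 == pytest.approx(sigma_oracle, rel=1e-6)
        assert fit.tau00 == pytest.approx(tau_oracle, rel=1e-6)

    def test_noise_free_exact_recovery(self):
        bins = statistics_grid()
        pb = poly_basis(bins, 3)
        beta = {"TS": (1.8, 0.14, -0.32, 0.31),
                "PS": (1.8, -0.07, -0.24, 0.38),
                "NS": (1.81, 0.38, -0.45, 0.09)}

        def values(s, c, b):
            b0, b1, b2, b3 = beta[c]
            return b0 + pb.basis @ np.array([b1, b2, b3])

        design = build_design(make_tcs(4, values), "TS", 3)
        fit = fit_lmm(design)
        est = dict(zip(fit.coefficients["name"], fit.coefficients["estimate"]))
        assert est["Intercept"] == pytest.approx(1.8, abs=1e-8)
        assert est["Linear"] == pytest.approx(0.14, abs=1e-8)
        assert est["Linear:NS"] == pytest.approx(0.38 - 0.14, abs=1e-8)
        assert est["Cubic:NS"] == pytest.approx(0.09 - 0.31, abs=1e-8)
        pvals = dict(zip(fit.coefficients["name"], fit.coefficients["p"]))
        assert pvals["Linear"] < 1e-10

    def test_centered_intercept_is_interval_mean(self):
        """With a centered basis the intercept equals the reference
        condition's mean over the analysis interval."""
        bins = statistics_grid()
        pb = poly_basis(bins, 2)

        def values(s, c, b):
            base = {"TS": 1.7, "PS": 1.5, "NS": 1.2}[c]
            return base + 0.4 * pb.basis[:, 0] - 0.2 * pb.basis[:, 1]

        design = build_design(make_tcs(3, values), "TS", 2)
        fit = fit_lmm(design)
        assert fit.coef("Intercept")["estimate"] == pytest.approx(1.7, abs=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(GCAError, match="2 subjects"):
            fit_lmm(build_design(make_tcs(1), "TS", 2))

    def test_variance_summary_fields(self):
        design = build_design(make_tcs(6), "TS", 3)
        fit = fit_lmm(design)
        assert 0.0 <= fit.icc <= 1.0
        assert fit.r2_marginal <= fit.r2_conditional
        assert fit.n_obs == design.n_obs


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(3)
    offsets = rng.normal(0, 0.4, 8)
    pb = poly_basis(statistics_grid(), 3)

    def values(s, c, b):
        shape = {"TS": 0.3, "PS": 0.1, "NS": -0.2}[c]
        return (1.6 + offsets[s] + shape * pb.basis[:, 0]
                + rng.normal(0, 0.2, len(b)))

    design = build_design(make_tcs(8, values), "TS", 3)
    return design, fit_lmm(design)


class TestRelevel:

    def test_loglik_invariant(self, fitted):
        design, fit_ts = fitted
        fit_ps = relevel_and_refit(design, "PS")
        assert fit_ps.loglik == pytest.approx(fit_ts.loglik, abs=1e-6)

    def test_fitted_values_invariant(self, fitted):
        design, fit_ts = fitted
        fit_ps = relevel_and_refit(design, "PS")
        # rows are ordered identically (subject, condition, time)
        assert np.allclose(fit_ps.fitted, fit_ts.fitted, atol=1e-6)

    def test_contrast_algebra(self, fitted):
        """The PS-referenced NS coefficient equals the difference of the
        TS-referenced NS and PS coefficients."""
        design, fit_ts = fitted
        fit_ps = relevel_and_refit(design, "PS")
        direct = fit_ps.coef("NS")["estimate"]
        derived = fit_ts.coef("NS")["estimate"] - fit_ts.coef("PS")["estimate"]
        assert direct == pytest.approx(derived, abs=1e-6)

    def test_releveling_is_involution(self, fitted):
        design, fit_ts = fitted
        d_ps = build_design(design.frame, "PS", 3)
        fit_back = relevel_and_refit(d_ps, "TS")
        assert np.allclose(
            fit_back.coefficients["estimate"], fit_ts.coefficients["estimate"],
            atol=1e-6,
        )

    def test_unknown_level(self, fitted):
        design, _ = fitted
        with pytest.raises(GCAError, match="unknown"):
            relevel_and_refit(design, "XX")


def bh_bruteforce(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j, via the
    sorted order, then undo the sort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range(self):
        with pytest.raises(GCAError):
            bh_adjust([0.5, 1.2])

    def test_deterministic_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        q = bh_adjust(p)
        assert np.array_equal(bh_adjust(p), q)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=8))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestMoreySEM:
    def test_additive_subject_offsets_give_zero(self):
        offsets = {0: 0.0, 1: 1.0, 2: 2.5}

        def values(s, c, b):
            return 1.5 + offsets[s] + 0.1 * np.arange(len(b))

        sems = morey_sem(make_tcs(3, values))
        for c, (bins, sem) in sems.items():
            assert np.allclose(sem, 0.0, atol=1e-12)

    def test_duplicated_subject_zero(self):
        rng = np.random.default_rng(0)
        base = {c: rng.random(26) for c in ("TS", "PS", "NS")}
        sems = morey_sem(make_tcs(4, lambda s, c, b: base[c]))
        for c, (_, sem) in sems.items():
            assert np.allclose(sem, 0.0, atol=1e-12)

    def test_manual_small_table(self):
        """3 subjects x 2 bins: verify against the hand-executed
        Cousineau-Morey formula (k = 3 conditions)."""
        bins = np.array([200.0, 232.0])
        raw = {  # subject -> condition -> values
            0: {"TS": [1.0, 2.0], "PS": [2.0, 1.0], "NS": [3.0, 3.0]},
            1: {"TS": [2.0, 1.0], "PS": [1.0, 2.0], "NS": [2.0, 2.0]},
            2: {"TS": [3.0, 3.0], "PS": [2.0, 3.0], "NS": [1.0, 1.0]},
        }
        tcs = [SNRTimeCourse(f"S{s:02d}", c, 18.75, bins, np.array(v))
               for s, d in raw.items() for c, v in d.items()]
        got = morey_sem(tcs)

        cube = np.array([[raw[s][c] for c in ("TS", "PS", "NS")]
                         for s in range(3)])
        centered = cube - cube.mean(axis=1, keepdims=True) + cube.mean()
        expect = centered.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(3 / 2)
        for j, c in enumerate(("TS", "PS", "NS")):
            assert np.allclose(got[c][1], expect[j], atol=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(GCAError):
            morey_sem(make_tcs(1))


class TestPeakLatency:
    def test_unimodal_peak_bin(self):
        bins = statistics_grid()
        y = np.exp(-((np.arange(26) - 7) ** 2) / 8.0)
        assert peak_latency(y, bins) == bins[7]

    def test_monotone_series_returns_last_bin(self):
        bins = statistics_grid()
        assert peak_latency(np.linspace(0, 1, 26), bins) == bins[-1]

    def test_flat_series_warns_earliest(self):
        bins = statistics_grid()
        with pytest.warns(UserWarning, match="flat"):
            assert peak_latency(np.ones(26), bins) == bins[0]

    def test_tie_earliest(self):
        bins = statistics_grid()
        y = np.zeros(26)
        y[[5, 9]] = 1.0
        assert peak_latency(y, bins) == bins[5]

    def test_poly_method_on_smooth_curve(self):
        bins = statistics_grid()
        y = -((bins - 540.0) ** 2)
        t = peak_latency(y, bins, method="poly", order=2)
        assert abs(t - 540.0) <= 2.0

    def test_too_few_bins(self):
        with pytest.raises(GCAError):
            peak_latency(np.array([1.0, 2.0]), np.array([0.0, 32.0]))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLmerTest:
    def test_matches_lme4_satterthwaite(self, tmp_path):
        """Cross-validate estimates, SEs, Satterthwaite dfs and p-values
        against lme4 + lmerTest on a small design."""
        rng = np.random.default_rng(7)
        bins = statistics_grid()[:8]
        offsets = rng.normal(0, 0.5, 4)

        def values(s, c, b):
            eff = {"TS": 0.2, "PS": 0.0, "NS": -0.1}[c]
            return 1.5 + offsets[s] + eff * np.linspace(-1, 1, len(b)) \
                + rng.normal(0, 0.3, len(b))

        design = build_design(make_tcs(4, values, bins=bins), "TS", 2)
        fit = fit_lmm(design)

        df = pd.DataFrame(design.X, columns=[c.replace(":", "_")
                                             for c in design.columns])
        df["y"] = design.y
        df["subj"] = design.groups
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        terms = [c.replace(":", "_") for c in design.columns if c != "Intercept"]
        rscript.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(y ~ {' + '.join(terms)} + (1 | subj), data = d, REML = TRUE)
co <- summary(m)$coefficients
write.csv(co, "{tmp_path / 'coef.csv'}")
vc <- as.data.frame(VarCorr(m))
write.csv(vc, "{tmp_path / 'vc.csv'}")
""")
        subprocess.run(["Rscript", str(rscript)], check=True,
                       capture_output=True, timeout=300)
        co = pd.read_csv(tmp_path / "coef.csv", index_col=0)
        vc = pd.read_csv(tmp_path / "vc.csv")
        tau_r = float(vc.loc[vc["grp"] == "subj", "vcov"].iloc[0])
        sigma_r = float(vc.loc[vc["grp"] == "Residual", "vcov"].iloc[0])
        assert fit.tau00 == pytest.approx(tau_r, rel=1e-3, abs=1e-6)
        assert fit.sigma2 == pytest.approx(sigma_r, rel=1e-3)
        ours = fit.coefficients.set_index("name")
        for name in design.columns:
            rname = "(Intercept)" if name == "Intercept" else name.replace(":", "_")
            row = co.loc[rname]
            mine = ours.loc[name]
            assert mine["estimate"] == pytest.approx(row["Estimate"], rel=1e-3,
                                                     abs=1e-6)
            assert mine["se"] == pytest.approx(row["Std. Error"], rel=1e-2)
            assert mine["df"] == pytest.approx(row["df"], rel=0.02)
            assert mine["p"] == pytest.approx(row["Pr(>|t|)"], rel=0.05,
                                              abs=1e-4)
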