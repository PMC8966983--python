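"""RPPA differential affinity: filtering, moderated t, BH-FDR, set overlap."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import comboscreen as cs
from comboscreen.errors import EmptyAnalysisError, StratumError, ValidationError
from comboscreen.rppa import estimate_variance_prior


def _matrix(values, statuses=None, treatments=None):
    values = np.asarray(values, float)
    n_ab, n_s = values.shape
    abs_ = [f"ab{i}" for i in range(n_ab)]
    samples = [f"s{i}" for i in range(n_s)]
    statuses = statuses or ["validated"] * n_ab
    treatments = treatments or ["drug"] * (n_s // 2) + ["vehicle"] * (n_s - n_s // 2)
    meta = pd.DataFrame(
        {
            "cell_line": [f"l{i}" for i in range(n_s)],
            "sensitivity": ["sensitive"] * n_s,
            "treatment": treatments,
            "timepoint": ["72h"] * n_s,
        },
        index=samples,
    )
    return cs.RPPAMatrix(
        values=pd.DataFrame(values, index=abs_, columns=samples),
        antibody_meta=pd.DataFrame({"status": statuses}, index=abs_),
        sample_meta=meta,
    )


class TestFilterValidated:
    def test_keeps_only_validated(self):
        m = _matrix(np.zeros((5, 4)), statuses=["validated"] * 3 + ["caution", "other"])
        out = cs.filter_validated(m)
        assert out.n_antibodies == 3
        assert set(out.antibody_meta["status"]) == {"validated"}

    def test_all_validated_is_identity(self):
        m = _matrix(np.arange(12.0).reshape(3, 4))
        out = cs.filter_validated(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_caution_rows_excluded(self):
        m = _matrix(np.zeros((2, 4)), statuses=["caution", "validated"])
        out = cs.filter_validated(m)
        assert list(out.values.index) == ["ab1"]

    def test_nothing_validated_is_error(self):
        m = _matrix(np.zeros((2, 4)), statuses=["caution", "other"])
        with pytest.raises(EmptyAnalysisError):
            cs.filter_validated(m)


class TestModeratedT:
    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(40, 6))
        m = _matrix(vals)
        res = cs.moderated_t_test(m, prior_df=0)
        t, p = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p, rtol=1e-10)

    def test_identical_variances_are_a_fixed_point(self):
        """When every antibody has the same sample variance, shrinkage has
        nothing to do: the moderated t equals the ordinary t."""
        base = np.array([0.0, 1.0, 2.0, 0.5, 1.5, 2.5])
        vals = np.tile(base, (30, 1)) + np.linspace(0, 5, 30)[:, None]
        m = _matrix(vals)
        res = cs.moderated_t_test(m)
        t, _ = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t, rtol=1e-6)

    def test_small_arm_is_stratum_error(self):
        m = _matrix(np.zeros((3, 4)), treatments=["drug", "vehicle", "vehicle", "vehicle"])
        with pytest.raises(StratumError):
            cs.moderated_t_test(m)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(50, 6))
        m = _matrix(vals)
        res = cs.moderated_t_test(m)
        perm = rng.permutation(50)
        m2 = cs.RPPAMatrix(
            values=m.values.iloc[perm],
            antibody_meta=m.antibody_meta.iloc[perm],
            sample_meta=m.sample_meta,
        )
        res2 = cs.moderated_t_test(m2)
        np.testing.assert_allclose(
            res.loc[res2.index, "t_mod"], res2["t_mod"], rtol=1e-12
        )

    def test_planted_antibodies_recovered(self):
        """>= 80% of planted antibodies pass FDR < 0.05 at the study's
        simulation settings, averaged over seeds."""
        powers = []
        for seed in range(20):
            spec = cs.GeneratorSpec(seed=seed)  # 1000 antibodies, 50 planted
            m, truth = cs.gen_rppa_matrix(spec)
            res = cs.moderated_t_test(m, stratum={"timepoint": "72h"})
            sig = set(res.index[res["significant"]])
            powers.append(len(sig & set(truth["planted"])) / len(truth["planted"]))
        assert float(np.mean(powers)) >= 0.8

    def test_matches_limma_oracle(self):
        """Independent cross-check of the empirical-Bayes machinery against
        Bioconductor limma on a small simulated matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        spec = cs.GeneratorSpec(
            seed=7,
            rppa=cs.RPPASpec(
                n_antibodies=60, n_planted=8, effect_size=1.0, noise_sd=0.3, n_per_arm=3
            ),
        )
        m, _ = cs.gen_rppa_matrix(spec)
        stratum = {"timepoint": "72h", "sensitivity": "sensitive"}
        res = cs.moderated_t_test(m, stratum=stratum)
        mask = np.ones(len(m.sample_meta), dtype=bool)
        for k, v in stratum.items():
            mask &= (m.sample_meta[k] == v).values
        sub = m.select_samples(mask)
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            sub.values.to_csv(os.path.join(td, "vals.tsv"), sep="\t")
            sub.sample_meta.to_csv(os.path.join(td, "meta.tsv"), sep="\t")
            script = textwrap.dedent(
                """
                suppressMessages(library(limma))
                args <- commandArgs(trailingOnly=TRUE)
                vals <- as.matrix(read.delim(file.path(args[1], 'vals.tsv'),
                                             row.names=1, check.names=FALSE))
                meta <- read.delim(file.path(args[1], 'meta.tsv'), row.names=1)
                design <- model.matrix(~ 0 + factor(meta$treatment,
                                                    levels=c('vehicle','drug')))
                colnames(design) <- c('vehicle','drug')
                fit <- lmFit(vals, design)
                fit <- contrasts.fit(fit, makeContrasts(drug - vehicle, levels=design))
                fit <- eBayes(fit)
                out <- data.frame(t=fit$t[,1], p=fit$p.value[,1])
                write.csv(out, file.path(args[1], 'r.csv'))
                """
            )
            rpath = os.path.join(td, "check.R")
            with open(rpath, "w") as fh:
                fh.write(script)
            subprocess.run(
                ["Rscript", rpath, td], check=True, capture_output=True, timeout=300
            )
            r = pd.read_csv(os.path.join(td, "r.csv"), index_col=0)
        np.testing.assert_allclose(res["t_mod"], r["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], r["p"], rtol=1e-6)


class TestVariancePrior:
    def test_constant_variances_shrink_completely(self):
        df0, s20 = estimate_variance_prior(np.full(100, 0.25), df=4)
        assert np.isinf(df0)
        assert s20 == pytest.approx(0.25)

    def test_dispersed_variances_give_finite_prior(self):
        rng = np.random.default_rng(0)
        # true inverse-chi-square spread wider than chi^2_4 sampling noise
        s2 = 0.1 * rng.chisquare(4, 500) / 4 * np.exp(rng.normal(0, 1.0, 500))
        df0, s20 = estimate_variance_prior(s2, df=4)
        assert np.isfinite(df0) and df0 > 0
        assert s20 > 0


class TestBHAdjust:
    def _brute_force(self, p):
        """Step-up BH: adj[i] = min over j with p_(j) >= p_(i) of m p_(j) / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj_sorted = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * p[idx] / rank)
            adj_sorted[rank - 1] = min(running, 1.0)
        out = np.empty(m)
        out[order] = adj_sorted
        return out

    def test_worked_example(self):
        np.testing.assert_allclose(
            cs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert cs.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        np.testing.assert_allclose(cs.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for n in (1, 2, 7, 30, 101):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(cs.bh_adjust(p), self._brute_force(p))

    def test_matches_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(cs.bh_adjust(p), adj, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cs.bh_adjust([0.1, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_adjusted_never_below_raw_and_monotone(self, p):
        adj = cs.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSetComparison:
    def _results(self, sig_up=(), sig_down=()):
        idx = sorted(set(sig_up) | set(sig_down) | {"bg1", "bg2"})
        df = pd.DataFrame(
            {
                "significant": [a in set(sig_up) | set(sig_down) for a in idx],
                "direction": ["up" if a in set(sig_up) else "down" for a in idx],
                "log_fc": 1.0,
            },
            index=idx,
        )
        return df

    def test_overlap_and_unique(self):
        rep = cs.set_comparison(
            {"A": self._results(sig_up=("x", "y")), "B": self._results(sig_up=("y", "z"))}
        )
        assert rep["up"]["shared"] == {"y"}
        assert rep["up"]["only:A"] == {"x"}
        assert rep["up"]["only:B"] == {"z"}

    def test_identical_strata_all_shared(self):
        r = self._results(sig_up=("x",), sig_down=("w",))
        rep = cs.set_comparison({"A": r, "B": r.copy()})
        assert rep["up"]["shared"] == {"x"} and rep["down"]["shared"] == {"w"}
        assert not rep["up"]["only:A"] and not rep["down"]["only:B"]

    def test_single_stratum_rejected(self):
        with pytest.raises(ValidationError):
            cs.set_comparison({"A": self._results()})

    def test_late_only_responders_found(self):
        """Antibodies planted only at 72h surface as 72h-only in >= 80% of runs."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = cs.GeneratorSpec(
                seed=seed,
                rppa=cs.RPPASpec(
                    n_antibodies=300, n_planted=10, effect_size=1.0,
                    noise_sd=0.25, n_per_arm=3,
                ),
            )
            m, truth = cs.gen_rppa_matrix(
                spec, planted_strata=[{"timepoint": "72h"}]
            )
            rep = cs.set_comparison(
                {
                    "24h": cs.moderated_t_test(m, stratum={"timepoint": "24h"}),
                    "72h": cs.moderated_t_test(m, stratum={"timepoint": "72h"}),
                }
            )
            if set(truth["planted"]) <= rep["up"]["only:72h"]:
                hits += 1
        assert hits >= 0.8 * n_seeds


def test_global_null_false_positive_control():
    """Realized false-discovery proportion under the global null stays <= 0.10
    averaged over seeds (everything found significant is a false positive)."""
    fdps = []
    for seed in range(20):
        spec = cs.GeneratorSpec(seed=seed, rppa=cs.RPPASpec(n_planted=0))
        m, _ = cs.gen_rppa_matrix(spec)
        res = cs.moderated_t_test(m, stratum={"timepoint": "72h"})
        n_sig = int(res["significant"].sum())
        fdps.append(1.0 if n_sig > 0 else 0.0)
    assert float(np.mean(fdps)) <= 0.10
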