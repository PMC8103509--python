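import subprocess

import numpy as np
import pandas as pd
import pytest

from radstab.combat import combat_apply, combat_fit, harmonize, nzv_filter


def _table(Y, batches, prefix="f"):
    df = pd.DataFrame(Y, columns=[f"{prefix}{i}" for i in range(Y.shape[1])])
    df["batch"] = batches
    return df


class TestNzvFilter:
    def test_boundary_at_95_percent(self):
        v = np.ones(20)
        v[0] = 2.0  # 19/20 = 0.95 identical -> removed
        df = _table(np.column_stack([v, np.arange(20.0)]), ["a"] * 10 + ["b"] * 10)
        out, rep = nzv_filter(df)
        assert rep.removed == ["f0"]
        assert rep.retained == ["f1"]

    def test_90_percent_retained(self):
        v = np.ones(20)
        v[:2] = [2.0, 3.0]  # modal fraction 18/20 = 0.90
        df = _table(v[:, None], ["a"] * 10 + ["b"] * 10)
        out, rep = nzv_filter(df)
        assert rep.removed == []

    def test_all_distinct_retained(self):
        df = _table(np.arange(10.0)[:, None], ["a"] * 5 + ["b"] * 5)
        _, rep = nzv_filter(df)
        assert rep.removed == []

    def test_near_equal_values_rounded_to_12_digits(self):
        v = np.full(20, 1.0)
        v[:10] += 1e-14  # identical after 12-significant-digit rounding
        df = _table(v[:, None], ["a"] * 10 + ["b"] * 10)
        _, rep = nzv_filter(df)
        assert rep.removed == ["f0"]


class TestCombatFit:
    def test_additive_shift_recovery(self):
        rng = np.random.default_rng(42)
        n = 10
        b1 = rng.normal(0, 1, (n, 3))
        b2 = b1 + rng.normal(0, 1, (n, 3)) * 0.2
        b2[:, 0] += 5.0
        df = _table(np.vstack([b1, b2]), ["a"] * n + ["b"] * n)
        model = combat_fit(df)
        out = combat_apply(model, df)
        gap = abs(out[out.batch == "a"]["f0"].mean() - out[out.batch == "b"]["f0"].mean())
        assert gap < 0.2
        # standardized gamma gap ~ 5 / pooled sd
        g = (model.gamma_star[1, 0] - model.gamma_star[0, 0]) * model.sigma[0]
        assert g == pytest.approx(5.0, abs=1.0)

    def test_no_batch_effect_shrinks_to_null(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 1, (40, 6))
        df = _table(Y, ["a"] * 20 + ["b"] * 20)
        model = combat_fit(df)
        assert np.abs(model.gamma_star).max() < 0.6
        assert np.abs(model.delta_star - 1).max() < 0.6

    def test_zero_covariate_column_is_dropped(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (20, 4))
        df = _table(Y, ["a"] * 10 + ["b"] * 10)
        m0 = combat_fit(df)
        m1 = combat_fit(df, covariates=np.zeros(20))
        np.testing.assert_allclose(m0.gamma_star, m1.gamma_star)
        np.testing.assert_allclose(m0.delta_star, m1.delta_star)

    def test_small_batch_rejected(self):
        df = _table(np.random.default_rng(0).normal(size=(3, 2)), ["a", "a", "b"])
        with pytest.raises(ValueError):
            combat_fit(df)


class TestCombatApply:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(3)
        df = _table(rng.normal(0, 1, (8, 4)), ["only"] * 8)
        model = combat_fit(df)
        out = combat_apply(model, df)
        np.testing.assert_allclose(
            out[model.features].to_numpy(), df[model.features].to_numpy(), atol=1e-10
        )

    def test_multiplicative_effect_variance_ratio(self):
        rng = np.random.default_rng(4)
        n, F = 50, 20
        b1 = rng.normal(0, 1, (n, F))
        b2 = rng.normal(0, 2, (n, F))  # delta = 2
        df = _table(np.vstack([b1, b2]), ["a"] * n + ["b"] * n)
        out = combat_apply(combat_fit(df), df)
        X = out[[f"f{i}" for i in range(F)]].to_numpy()
        vr = X[n:].var(axis=0) / X[:n].var(axis=0)
        assert 0.8 < np.median(vr) < 1.25

    def test_unseen_batch_rejected(self):
        rng = np.random.default_rng(5)
        df = _table(rng.normal(size=(8, 2)), ["a"] * 4 + ["b"] * 4)
        model = combat_fit(df)
        bad = df.copy()
        bad["batch"] = ["c"] * 8
        with pytest.raises(ValueError):
            combat_apply(model, bad)

    def test_grand_weighted_mean_preserved(self):
        rng = np.random.default_rng(6)
        b1 = rng.normal(5, 1, (12, 5))
        b2 = rng.normal(8, 2, (20, 5))
        df = _table(np.vstack([b1, b2]), ["a"] * 12 + ["b"] * 20)
        out, _ = harmonize(df)
        feats = [c for c in out.columns if c != "batch"]
        # EB shrinkage moves batch means toward each other but leaves the
        # pooled weighted mean (the alpha-hat anchor) essentially unchanged
        np.testing.assert_allclose(
            out[feats].mean().to_numpy(), df[feats].mean().to_numpy(), rtol=0.02
        )


class TestAgainstSva:
    def test_matches_bioconductor_sva(self, tmp_path):
        """Cross-check against the independent R/Bioconductor ComBat
        implementation on a shared fixture table."""
        rng = np.random.default_rng(7)
        n, F = 12, 8
        b1 = rng.normal(0, 1, (n, F)) + rng.normal(0, 2, F)
        b2 = (
            rng.normal(0, 1, (n, F)) * rng.uniform(0.5, 2, F)
            + rng.normal(0, 2, F)
            + rng.normal(0, 1.5, F)
        )
        Y = np.vstack([b1, b2])
        df = _table(Y, ["A"] * n + ["B"] * n)
        out = combat_apply(combat_fit(df), df)

        np.savetxt(tmp_path / "dat.csv", Y.T, delimiter=",")
        script = f"""
suppressMessages(library(sva))
dat <- as.matrix(read.csv("{tmp_path}/dat.csv", header=FALSE))
batch <- rep(c("A","B"), each={n})
res <- ComBat(dat=dat, batch=batch, par.prior=TRUE)
write.table(res, "{tmp_path}/out.csv", sep=",", row.names=FALSE, col.names=FALSE)
"""
        (tmp_path / "combat.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "combat.R")], capture_output=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr.decode()
        ref = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
        mine = out[[f"f{i}" for i in range(F)]].to_numpy()
        assert np.abs(mine - ref).max() < 1e-4
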