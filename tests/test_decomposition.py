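import numpy as np
import pytest

from moca import (
    MocaOptions,
    MultiBlockData,
    SyntheticSpec,
    center_scale,
    classify_joint,
    collect_and_compress,
    consensus_and_disagreement,
    extract_unique,
    fit_moca,
    fit_pairwise_joint,
    generate,
    load_model,
    recovery_report,
    save_model,
    split_joint_unique,
    strictness_sweep,
)

from conftest import make_block


def corr(a, b):
    return np.corrcoef(a, b)[0, 1]


STRICTNESS_GRID = [-0.01, -0.03, -0.05, -0.1, -0.2, -0.5]


class TestOptions:
    @pytest.mark.parametrize("bad", [0.0, 0.5, -1.5])
    def test_strictness_range_enforced(self, bad):
        with pytest.raises(ValueError, match="strictness"):
            MocaOptions(strictness=bad)


class TestFitMoca:
    def test_planted_structure_recovered(self, planted_model):
        _, model, truth = planted_model
        kinds = [c.kind for c in model.components]
        assert kinds.count("global") == 1
        locals_ = [c for c in model.components if c.kind == "local"]
        assert len(locals_) == 1 and set(locals_[0].member_blocks) == {"b1", "b2"}
        for b in ("b1", "b2", "b3"):
            assert any(c.kind == "unique" and c.member_blocks == [b]
                       for c in model.components)
        rep = recovery_report(model, truth)
        assert rep["kind_match"].all() and rep["members_match"].all()
        assert (rep["corr"] >= 0.95).all()

    def test_component_ordering_and_indices(self, planted_model):
        _, model, _ = planted_model
        order = {"global": 0, "local": 1, "unique": 2}
        ranks = [order[c.kind] for c in model.components]
        assert ranks == sorted(ranks)
        assert [c.index for c in model.components] == list(
            range(1, len(model.components) + 1)
        )

    def test_duplicated_blocks_have_no_unique_variance(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((100, 4)) @ rng.standard_normal((4, 18))
        X += 0.05 * rng.standard_normal(X.shape)
        blocks = [
            center_scale(make_block(X.copy(), name=n)) for n in ("a", "b")
        ]
        model = fit_moca(MultiBlockData(blocks))
        for b in ("a", "b"):
            assert model.r2xu[b] <= 0.02
            assert model.r2xj[b] >= 0.9

    def test_pure_noise_yields_no_joint_components(self):
        zero = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n_obs=200, blocks=[("a", 20), ("b", 20), ("c", 20)],
                global_latents=0, local_latents=[], unique_latents=0,
                noise_sd=1.0, seed=seed,
            )
            data, _ = generate(spec)
            model = fit_moca(data.center_scale())
            zero += len(model.joint_components) == 0
        assert zero >= 18

    def test_fewer_than_two_blocks_errors(self):
        blk = center_scale(make_block(np.random.default_rng(0).normal(size=(10, 3))))
        with pytest.raises(ValueError, match="at least 2"):
            fit_moca(MultiBlockData([blk]))

    def test_variance_additivity(self, planted_model):
        _, model, _ = planted_model
        for b in model.block_names:
            total = model.r2xj[b] + model.r2xu[b] + model.r2_residual[b]
            assert total == pytest.approx(1.0, abs=1e-6)
            joint_sum = sum(
                c.r2_per_block[b] for c in model.joint_components
                if b in c.member_blocks
            )
            assert joint_sum == pytest.approx(model.r2xj[b], abs=1e-8)

    def test_joint_members_satisfy_pairwise_correlation_bound(self, planted_model):
        _, model, _ = planted_model
        thr = model.options.correlation_threshold
        for c in model.joint_components:
            for a in c.member_blocks:
                for b in c.member_blocks:
                    if a < b:
                        assert abs(corr(c.scores[a], c.scores[b])) >= thr - 1e-9

    def test_block_permutation_equivariance(self, three_block_spec):
        data, _ = generate(three_block_spec(seed=4))
        pre = data.center_scale()
        opts = MocaOptions(strictness=-0.1)
        m1 = fit_moca(pre, opts)
        permuted = MultiBlockData([pre["b3"], pre["b1"], pre["b2"]])
        m2 = fit_moca(permuted, opts)
        for b in ("b1", "b2", "b3"):
            assert m2.r2xj[b] == pytest.approx(m1.r2xj[b], abs=1e-8)
            assert m2.r2xu[b] == pytest.approx(m1.r2xu[b], abs=1e-8)

    def test_observation_permutation_equivariance(self, three_block_spec):
        data, _ = generate(three_block_spec(seed=5, n_obs=120))
        pre = data.center_scale()
        opts = MocaOptions(strictness=-0.1)
        m1 = fit_moca(pre, opts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(120)
        shuffled = MultiBlockData([
            type(b)(
                name=b.name, values=b.values[perm],
                missing_mask=b.missing_mask[perm], var_names=b.var_names,
                obs_ids=[b.obs_ids[i] for i in perm],
                col_means=b.col_means, col_scales=b.col_scales,
                preprocessing=b.preprocessing,
            )
            for b in pre
        ])
        m2 = fit_moca(shuffled, opts)
        for c1, c2 in zip(m1.components, m2.components):
            assert c1.kind == c2.kind and c1.member_blocks == c2.member_blocks
            r = corr(c1.consensus_score[perm], c2.consensus_score)
            assert abs(abs(r) - 1) < 1e-6


class TestCollectAndCompress:
    def _sets_for(self, blocks, names):
        pre = [center_scale(make_block(x, name=n)) for x, n in zip(blocks, names)]
        sets = []
        for i in range(len(pre)):
            for j in range(i + 1, len(pre)):
                sets.append(fit_pairwise_joint(pre[i], pre[j]))
        return pre, sets

    def test_redundant_copies_compress_to_one_vector(self):
        rng = np.random.default_rng(30)
        z = rng.standard_normal(150)
        mats = [
            np.outer(z, rng.standard_normal(12)) + 0.1 * rng.standard_normal((150, 12))
            for _ in range(4)
        ]
        _, sets = self._sets_for(mats, ["a", "b", "c", "d"])
        basis = collect_and_compress("a", sets)
        assert basis.shape == (150, 1)
        np.testing.assert_allclose(np.linalg.norm(basis, axis=0), 1.0, atol=1e-10)

    def test_two_independent_shared_latents_give_basis_of_two(self):
        spec = SyntheticSpec(
            n_obs=200, blocks=[("a", 20), ("b", 30), ("c", 25)],
            global_latents=2, local_latents=[], unique_latents=0,
            noise_sd=0.3, seed=31,
        )
        data, _ = generate(spec)
        pre = data.center_scale()
        sets = [
            fit_pairwise_joint(pre["a"], pre["b"]),
            fit_pairwise_joint(pre["a"], pre["c"]),
            fit_pairwise_joint(pre["b"], pre["c"]),
        ]
        assert collect_and_compress("a", sets).shape[1] == 2

    def test_empty_pairwise_sets_give_empty_basis(self):
        basis = collect_and_compress("a", [])
        assert basis.shape[1] == 0


class TestSplitJointUnique:
    def test_empty_basis_returns_block_unchanged(self):
        rng = np.random.default_rng(40)
        blk = center_scale(make_block(rng.standard_normal((30, 5))))
        joint, residual, stats = split_joint_unique(blk, np.zeros((30, 0)))
        assert stats == []
        np.testing.assert_array_equal(joint, 0.0)
        np.testing.assert_allclose(residual.filled(), blk.filled(), atol=1e-12)

    def test_full_rank_basis_leaves_no_residual(self):
        rng = np.random.default_rng(41)
        X = rng.standard_normal((20, 6))
        blk = center_scale(make_block(X))
        Q, _ = np.linalg.qr(blk.filled())
        _, residual, _ = split_joint_unique(blk, Q[:, :6])
        rel = np.linalg.norm(residual.filled()) / np.linalg.norm(blk.filled())
        assert rel <= 1e-8

    def test_residual_carries_planted_unique_structure(self):
        rng = np.random.default_rng(42)
        n = 150
        z_joint = rng.standard_normal(n)
        z_unique = rng.standard_normal(n)
        z_unique -= z_joint * (z_unique @ z_joint) / (z_joint @ z_joint)
        X = np.outer(z_joint, rng.standard_normal(10)) + np.outer(
            z_unique, rng.standard_normal(10)
        ) + 0.1 * rng.standard_normal((n, 10))
        blk = center_scale(make_block(X))
        basis = (z_joint - z_joint.mean())[:, None]
        basis /= np.linalg.norm(basis)
        _, residual, _ = split_joint_unique(blk, basis)
        comps = extract_unique(residual, original_ss=blk.total_ss())
        assert len(comps) >= 1
        assert abs(corr(comps[0][0], z_unique)) >= 0.95

    def test_residual_zero_at_missing_cells(self):
        rng = np.random.default_rng(43)
        X = rng.standard_normal((40, 8))
        X[rng.random(X.shape) < 0.2] = np.nan
        blk = center_scale(make_block(X))
        Q, _ = np.linalg.qr(rng.standard_normal((40, 3)))
        _, residual, _ = split_joint_unique(blk, Q)
        assert np.abs(residual.filled()[blk.missing_mask]).max() == 0.0


class TestExtractUnique:
    def test_pure_noise_residual_yields_nothing(self):
        zeros = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 20))
            blk = center_scale(make_block(X))
            zeros += len(extract_unique(blk)) == 0
        assert zeros >= 18

    def test_strong_structure_recovered_above_floor(self):
        rng = np.random.default_rng(50)
        z = rng.standard_normal(100)
        X = np.outer(z, rng.standard_normal(15)) + 0.3 * rng.standard_normal((100, 15))
        blk = center_scale(make_block(X))
        comps = extract_unique(blk)
        assert len(comps) >= 1
        assert comps[0][2] > 0.5  # dominant planted factor


class TestClassifyJoint:
    def _two_block_bases(self, rho, n=400, seed=60):
        # two unit basis vectors with a prescribed correlation
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        v2 = rho * a + np.sqrt(1 - rho**2) * b
        return {"x": a[:, None], "y": v2[:, None]}

    def test_threshold_arithmetic_strict_rejects(self):
        bases = self._two_block_bases(0.97)
        res = classify_joint(bases, strictness=-0.01)
        assert all(r["kind"] == "discarded" for r in res)

    def test_threshold_arithmetic_lax_accepts(self):
        bases = self._two_block_bases(0.97)
        res = classify_joint(bases, strictness=-0.5)
        kinds = [r["kind"] for r in res]
        assert "global" in kinds

    def test_r2xj_monotone_in_strictness(self, three_block_spec):
        data, _ = generate(three_block_spec(seed=6))
        sweep = strictness_sweep(data.center_scale(), STRICTNESS_GRID)
        arr = sweep.table.to_numpy()
        assert (np.diff(arr, axis=0) >= -1e-8).all()


class TestConsensus:
    def test_identical_members_have_zero_disagreement(self):
        rng = np.random.default_rng(70)
        s = rng.standard_normal(50)
        consensus, disagreement = consensus_and_disagreement({"a": s, "b": s.copy()})
        np.testing.assert_allclose(disagreement, 0.0, atol=1e-12)
        assert abs(corr(consensus, s)) > 0.999999

    def test_single_deviating_observation_flagged(self):
        rng = np.random.default_rng(71)
        s = rng.standard_normal(60)
        s2 = s.copy()
        s2[17] += 2.0
        _, disagreement = consensus_and_disagreement({"a": s, "b": s2})
        assert int(np.argmax(disagreement)) == 17

    def test_disagreement_matches_noise_level(self):
        # 3 members = common latent + independent N(0, sigma^2) noise:
        # RMS deviation from the member mean has expectation ~ sigma*sqrt(2/3)
        sigma = 0.1
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(300)
            scores = {
                f"m{k}": z + sigma * rng.standard_normal(300) for k in range(3)
            }
            _, d = consensus_and_disagreement(scores)
            vals.append(d.mean())
        expected = sigma * np.sqrt(2 / 3)
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)


class TestStrictnessSweep:
    def test_single_value_skips_pca_with_warning(self, three_block_spec):
        data, _ = generate(three_block_spec(seed=7, n_obs=100))
        with pytest.warns(UserWarning, match="skipped"):
            result = strictness_sweep(data.center_scale(), [-0.1])
        assert result.pca is None
        assert result.table.shape[0] == 1

    def test_table_values_in_unit_interval(self, three_block_spec):
        data, _ = generate(three_block_spec(seed=8, n_obs=120))
        result = strictness_sweep(data.center_scale(), STRICTNESS_GRID)
        arr = result.table.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
        assert result.pca is not None


class TestSerialization:
    def test_roundtrip_preserves_model(self, planted_model, tmp_path):
        _, model, _ = planted_model
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.block_names == model.block_names
        assert loaded.r2xj == pytest.approx(model.r2xj)
        for c1, c2 in zip(model.components, loaded.components):
            assert (c1.index, c1.kind, c1.member_blocks) == (
                c2.index, c2.kind, c2.member_blocks
            )
            for b in c1.member_blocks:
                # TSV stores %.6g floats
                np.testing.assert_allclose(c2.scores[b], c1.scores[b], rtol=1e-5)
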