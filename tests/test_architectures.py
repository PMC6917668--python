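"""The shared model contract across all four integrative architectures."""

import numpy as np
import pytest

from intvae.data import ModalitySpec
from intvae.models import (CNCVAE, HVAE, MMVAE, XVAE, LatentPosterior,
                           NetworkConfig, build_cnc_vae, build_h_vae,
                           build_mm_vae, build_x_vae, make_model,
                           reparameterize, train_hierarchical)
from intvae.objectives import ObjectiveValue

from conftest import quick_config

ARCHS = ["CNC", "X", "MM", "H"]


class TestReparameterize:
    def test_zero_noise_returns_mean(self, rng):
        post = LatentPosterior(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        np.testing.assert_array_equal(reparameterize(post, np.zeros((5, 3))),
                                      post.mu)

    def test_unit_variance_adds_noise(self, rng):
        mu = rng.normal(size=(4, 2))
        e = rng.normal(size=(4, 2))
        post = LatentPosterior(mu, np.zeros((4, 2)))
        np.testing.assert_allclose(reparameterize(post, e), mu + e)

    def test_monte_carlo_mean(self, rng):
        mu = np.array([[0.7, -1.2]])
        logvar = np.array([[0.3, -0.5]])
        post = LatentPosterior(mu, logvar)
        draws = np.stack([reparameterize(post, rng.standard_normal((1, 2)))
                          for _ in range(20000)])
        se = np.exp(logvar / 2) / np.sqrt(20000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3 * se)

    def test_shape_mismatch(self):
        post = LatentPosterior(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            reparameterize(post, np.zeros((3, 2)))


@pytest.mark.parametrize("arch", ARCHS)
class TestModelContract:
    """One suite, parameterized over all four architectures."""

    def _fit(self, dataset, arch, **kw):
        model = make_model(dataset.specs, quick_config(arch, **kw))
        res = model.fit(dataset)
        return model, res

    def test_embedding_and_reconstruction_shapes(self, small_dataset, arch):
        ds, _ = small_dataset
        model, _ = self._fit(ds, arch)
        emb = model.encode(ds)
        assert emb.shape == (ds.n_samples, 16)
        recs = model.reconstruct(ds)
        for rec, spec in zip(recs, ds.specs):
            assert rec.shape == (ds.n_samples, spec.n_features)

    def test_loss_trace_length_and_decomposition(self, small_dataset, arch):
        ds, _ = small_dataset
        _, res = self._fit(ds, arch)
        assert len(res.loss_trace) == 3
        for o in res.loss_trace:
            resum = sum(o.recon_per_modality.values()) + o.beta * o.regularizer
            assert abs(o.total - resum) < 1e-9
            assert o.regularizer >= -1e-12

    def test_fixed_seed_bitwise_reproducible(self, small_dataset, arch):
        ds, _ = small_dataset
        m1, r1 = self._fit(ds, arch)
        m2, r2 = self._fit(ds, arch)
        assert [o.total for o in r1.loss_trace] == [o.total for o in r2.loss_trace]
        np.testing.assert_array_equal(m1.encode(ds), m2.encode(ds))
        for p1, p2 in zip(m1.parameters, m2.parameters):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_encode_is_deterministic_and_ordered(self, small_dataset, arch):
        ds, _ = small_dataset
        model, _ = self._fit(ds, arch)
        e1, e2 = model.encode(ds), model.encode(ds)
        np.testing.assert_array_equal(e1, e2)
        # row order follows input row order
        sub = ds.subset(np.array([5, 3, 8]))
        np.testing.assert_allclose(model.encode(sub),
                                   model.encode(ds)[[5, 3, 8]], atol=1e-12)

    def test_generative_sampling(self, small_dataset, arch):
        ds, _ = small_dataset
        model, _ = self._fit(ds, arch)
        outs = model.sample_generative(7, seed=4)
        for out, spec in zip(outs, ds.specs):
            assert out.shape == (7, spec.n_features)
            if spec.output_activation == "sigmoid":
                assert out.min() > 0 and out.max() < 1
        outs2 = model.sample_generative(7, seed=4)
        for a, b in zip(outs, outs2):
            np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            model.sample_generative(0)

    def test_summary_mentions_architecture(self, small_dataset, arch):
        ds, _ = small_dataset
        _, res = self._fit(ds, arch)
        assert arch in res.summary()


class TestArchitectureSpecifics:
    def test_cnc_blocks_follow_modality_widths(self, small_dataset):
        ds, _ = small_dataset
        model = build_cnc_vae(ds.specs, quick_config("CNC"))
        model.fit(ds)
        recs = model.reconstruct(ds)
        assert [r.shape[1] for r in recs] == [30, 30, 20]

    def test_x_prebottleneck_width_is_m_times_ds(self, small_dataset):
        ds, _ = small_dataset
        model = build_x_vae(ds.specs, quick_config("X", dense_size=64))
        assert model.mu_head.W.data.shape[0] == 64 * 3

    def test_mm_has_one_more_encoder_layer_than_x(self, small_dataset):
        ds, _ = small_dataset
        x = build_x_vae(ds.specs, quick_config("X"))
        mm = build_mm_vae(ds.specs, quick_config("MM"))
        assert mm.n_encoder_hidden_layers == x.n_encoder_hidden_layers + 1

    def test_mm_second_layer_input_width(self, small_dataset):
        ds, _ = small_dataset
        mm = build_mm_vae(ds.specs, quick_config("MM", dense_size=64))
        for block in mm.enc_second:
            assert block.dense.W.data.shape[0] == 3 * 64

    def test_hidden_depth_within_two_to_four(self, small_dataset):
        ds, _ = small_dataset
        for arch in ARCHS:
            model = make_model(ds.specs, quick_config(arch))
            # encoder+decoder hidden stages along one path
            depth = model.n_encoder_hidden_layers + 1
            assert 2 <= depth <= 4

    def test_requires_two_modalities(self):
        spec = [ModalitySpec("only", "continuous", 10)]
        for builder in (build_cnc_vae, build_x_vae, build_mm_vae, build_h_vae):
            with pytest.raises(ValueError):
                builder(spec, quick_config("CNC"))

    def test_zero_width_modality_rejected(self):
        with pytest.raises(ValueError):
            ModalitySpec("empty", "continuous", 0)


class TestHierarchical:
    def test_trains_m_plus_one_submodels(self, small_dataset):
        ds, _ = small_dataset
        model = train_hierarchical(ds.specs, ds, quick_config("H"))
        assert len(model.sub_models) == len(ds.specs) + 1
        for sub in model.sub_models:
            assert sub.fitted
            assert len(sub.loss_trace) == 3

    def test_high_level_input_width(self, small_dataset):
        ds, _ = small_dataset
        model = train_hierarchical(ds.specs, ds, quick_config("H"))
        assert model.high_model.specs[0].n_features == 16 * len(ds.specs)
        means = model._low_means(ds.modality_list())
        assert means.shape == (ds.n_samples, 16 * len(ds.specs))

    def test_untrained_low_level_rejected_at_encode(self, small_dataset):
        ds, _ = small_dataset
        model = build_h_vae(ds.specs, quick_config("H"))
        with pytest.raises(RuntimeError):
            model._low_means(ds.modality_list())

    def test_frozen_low_levels_make_stage2_reproducible(self, small_dataset):
        ds, _ = small_dataset
        base = train_hierarchical(ds.specs, ds, quick_config("H"))
        rerun = build_h_vae(ds.specs, quick_config("H"),
                            low_level_models=base.low_models)
        rerun.fit(ds)
        np.testing.assert_array_equal(base.encode(ds), rerun.encode(ds))

    def test_low_level_spec_mismatch_rejected(self, small_dataset):
        ds, _ = small_dataset
        other_specs = [ModalitySpec(s.name, s.kind, s.n_features + 1)
                       for s in ds.specs]
        lows = train_hierarchical(ds.specs, ds, quick_config("H")).low_models
        with pytest.raises(ValueError):
            build_h_vae(other_specs, quick_config("H"), low_level_models=lows)


class TestTraining:
    def test_loss_decreases(self, medium_dataset):
        ds, _ = medium_dataset
        model = make_model(ds.specs, quick_config("X", epochs=15))
        res = model.fit(ds)
        assert res.loss_trace[-1].total < res.loss_trace[0].total

    def test_batch_size_larger_than_n_rejected(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds.specs, quick_config("X", batch_size=500))
        with pytest.raises(ValueError):
            model.fit(ds)

    def test_nonfinite_loss_abort_names_term(self, small_dataset):
        from intvae.models import IntegrativeVAE
        bad = ObjectiveValue(total=np.nan,
                             recon_per_modality={"mrna": np.nan},
                             regularizer=0.0)
        with pytest.raises(RuntimeError, match="mrna"):
            IntegrativeVAE._check_finite(bad)

    def test_modality_shape_mismatch_at_encode(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds.specs, quick_config("CNC"))
        model.fit(ds)
        bad = [m[:, :-1] for m in ds.modality_list()]
        with pytest.raises(ValueError):
            model.encode(bad)

    def test_nonlinear_capacity_beats_rank_deficient_linear(self):
        """A beta=0 autoencoder with ls >= true rank beats rank-(ls-1) PCA."""
        from intvae.objectives import RegularizerSpec
        rng = np.random.default_rng(3)
        n, k = 150, 2
        h = rng.standard_normal((n, k))
        specs = [ModalitySpec("a", "continuous", 15),
                 ModalitySpec("b", "continuous", 15)]
        mats = []
        for _ in specs:
            w = rng.standard_normal((k, 15))
            x = h @ w
            x = (x - x.min(0)) / (x.max(0) - x.min(0))
            mats.append(x)
        combined = np.concatenate(mats, axis=1)
        cfg = quick_config("CNC", latent_size=k, dense_size=32, epochs=200,
                           regularizer=RegularizerSpec("KL", 0.0),
                           dropout=0.0, batch_size=50)
        model = make_model(specs, cfg)
        model.fit(mats)
        rec = np.concatenate(model.reconstruct(mats), axis=1)
        vae_mse = np.mean((combined - rec) ** 2)
        # best rank-(k-1) linear reconstruction via SVD
        centered = combined - combined.mean(0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        trunc = (u[:, :k - 1] * s[:k - 1]) @ vt[:k - 1]
        lin_mse = np.mean((centered - trunc) ** 2)
        assert vae_mse < lin_mse
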