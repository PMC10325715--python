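"""Synthetic-circuit generator: wiring rules, distributions, determinism."""

import numpy as np
import pytest

import vlconn as vl
from vlconn.config import ConfigError
from vlconn.generate import rasterize_ellipsoid
from vlconn.tables import ALLOWED_EDGE_TYPES


class TestWiring:
    def test_wiring_rules_and_validity(self, default_connectome):
        tab = default_connectome
        tab.validate()
        assert tab.edge_type_pairs() <= ALLOWED_EDGE_TYPES

    def test_each_sam_has_exactly_one_sfl_input(self, default_connectome):
        tab = default_connectome
        types = tab.types()
        sams = types[types == "SAM"].index
        syn = tab.synapses
        pre_type = syn["pre_id"].map(types)
        for s in sams:
            inputs = syn[syn["post_id"] == s]
            sfl_inputs = inputs[pre_type.loc[inputs.index] == "SFL"]
            assert len(sfl_inputs) == 1
            assert sfl_inputs["compartment"].iloc[0] == "LB"

    def test_no_sfl_to_ln_and_ln_silent(self, default_connectome):
        pairs = default_connectome.edge_type_pairs()
        assert ("SFL", "LN") not in pairs
        assert not any(pre == "LN" for pre, _ in pairs)

    def test_cin_outputs_target_only_cams_and_afs(self, default_connectome):
        posts = {post for pre, post in default_connectome.edge_type_pairs() if pre == "CIN"}
        assert posts <= {"CAM", "AF"}

    def test_zero_reciprocal_pairs_gives_dag(self):
        cfg = vl.GenerationConfig(seed=3, n_reciprocal_af_pairs=0)
        w = vl.build_wiring_diagram(vl.generate_connectome(cfg))
        assert vl.find_feedback(w).is_dag

    def test_configured_reciprocal_pair_count(self, default_connectome):
        w = vl.build_wiring_diagram(default_connectome)
        res = vl.find_feedback(w)
        # 4 reciprocal AF pairs -> 8 cycle edges
        assert len(res.feedback_edges) == 8
        types = default_connectome.types()
        assert all(types.loc[a] == types.loc[b] == "AF" for a, b in res.feedback_edges)

    def test_cam_in_degree_within_range(self, default_connectome, default_config):
        lo, hi = default_config.cam_in_degree_range
        types = default_connectome.types()
        syn = default_connectome.synapses
        for c in types[types == "CAM"].index:
            deg = int((syn["post_id"] == c).sum())
            assert lo <= deg <= hi

    def test_seeded_determinism(self):
        t1 = vl.generate_connectome(vl.GenerationConfig(seed=11))
        t2 = vl.generate_connectome(vl.GenerationConfig(seed=11))
        t3 = vl.generate_connectome(vl.GenerationConfig(seed=12))
        assert t1.equals(t2)
        assert not t1.equals(t3)

    def test_infeasible_sam_count_raises(self):
        with pytest.raises(ConfigError, match="large boutons"):
            vl.GenerationConfig(seed=0, n_per_type={**vl.GenerationConfig().n_per_type, "SAM": 10_000})


class TestSomaPopulation:
    def test_sam_volume_mean_recovered(self, default_config):
        pop = vl.generate_soma_population(default_config, {"SAM": 1000}, seed=4)
        vols = np.array([len(m.voxels) * m.voxel_volume_um3 for m in pop])
        se = 26.1 / np.sqrt(len(vols))
        assert abs(vols.mean() - 207.7) < 3 * se

    def test_ln_volumes_inside_range(self, default_config):
        pop = vl.generate_soma_population(default_config, {"LN": 100}, seed=5)
        vols = np.array([len(m.voxels) * m.voxel_volume_um3 for m in pop])
        voxel = pop[0].voxel_volume_um3
        # rasterization error is bounded by a thin surface shell
        assert vols.min() > 464 - 464 ** (2 / 3) * voxel ** (1 / 3) * 10
        assert vols.max() < 2850 + 2850 ** (2 / 3) * voxel ** (1 / 3) * 10

    def test_zero_sd_gives_constant_volumes(self):
        cfg = vl.GenerationConfig(seed=6)
        cfg.soma_volume_params["SAM"]["sd"] = 0.0
        pop = vl.generate_soma_population(cfg, {"SAM": 20}, seed=6)
        vols = np.array([len(m.voxels) * m.voxel_volume_um3 for m in pop])
        # all equal to the mean within rasterization error (surface shell)
        shell = (207.7 ** (2 / 3)) * (pop[0].voxel_volume_um3 ** (1 / 3)) * 6
        assert np.all(np.abs(vols - 207.7) < shell)

    def test_sphericity_ordering(self, default_config):
        pop = vl.generate_soma_population(
            default_config, {"SAM": 40, "CAM": 40, "Other": 40}, seed=7
        )
        feats = vl.features_table(pop)
        by = feats.groupby("true_type")["sphericity"].mean()
        assert by["SAM"] > by["CAM"] > by["Other"]

    def test_too_coarse_voxel_raises(self):
        cfg = vl.GenerationConfig(seed=0, soma_voxel_size_nm=(5000.0, 5000.0, 5000.0))
        with pytest.raises(ConfigError, match="coarse"):
            vl.generate_soma_population(cfg, {"SAM": 1})

    def test_rasterized_ball_is_roundish(self):
        vox = rasterize_ellipsoid(np.array([5.0, 5.0, 5.0]), np.eye(3), (200, 200, 200))
        vol = len(vox) * (0.2**3)
        assert vol == pytest.approx(4 / 3 * np.pi * 125, rel=0.02)


class TestBoutonSeries:
    def test_poisson_lb_mean(self, default_config):
        counts = [
            len(
                vl.generate_bouton_series(default_config, 100.0, seed=s).boutons.query(
                    "true_class == 'LB'"
                )
            )
            for s in range(10_000)
        ]
        assert 0.98 <= np.mean(counts) <= 1.08

    def test_zero_rate_gives_no_boutons(self):
        cfg = vl.GenerationConfig(
            seed=0, lb_rate=0.0, sb_rate=0.0, n_per_type={"SFL": 1}, n_reciprocal_af_pairs=0
        )
        s = vl.generate_bouton_series(cfg, 200.0, seed=0)
        assert len(s.boutons) == 0

    def test_volume_components_bimodal(self, default_config):
        series = [vl.generate_bouton_series(default_config, 260.0, seed=s) for s in range(60)]
        vols = np.concatenate([s.volumes for s in series])
        split = vl.classify_boutons_bimodal(vols, seed=0)
        mu_lb, mu_sb = split.fit_means["LB"], split.fit_means["SB"]
        pooled_sd = np.sqrt((split.fit_sds["LB"] ** 2 + split.fit_sds["SB"] ** 2) / 2)
        assert mu_lb - mu_sb > 3 * pooled_sd

    def test_positions_within_axon(self, default_config):
        s = vl.generate_bouton_series(default_config, 50.0, seed=9)
        pos = s.boutons["position_um"]
        assert ((pos >= 0) & (pos <= 50.0)).all()

    def test_seeded_determinism(self, default_config):
        a = vl.generate_bouton_series(default_config, 100.0, seed=42)
        b = vl.generate_bouton_series(default_config, 100.0, seed=42)
        assert a.boutons.equals(b.boutons)


class TestTubeVolume:
    def test_straight_segment_length(self):
        tube = vl.generate_tube_volume(
            np.array([[0, 0, 0], [50, 0, 0]], float), 1.0, (1000, 1000, 1000)
        )
        assert tube.true_length_um == pytest.approx(50.0)
        assert not tube.has_cycle

    def test_tree_length_additive(self):
        p1 = np.array([[0, 0, 0], [30, 0, 0]], float)
        p2 = np.array([[30, 0, 0], [30, 20, 0]], float)
        p3 = np.array([[30, 0, 0], [30, 0, 20]], float)
        tube = vl.generate_tube_volume([p1, p2, p3], 1.0, (1000, 1000, 1000))
        assert tube.true_length_um == pytest.approx(70.0)
        assert not tube.has_cycle

    def test_circle_flags_cycle(self):
        th = np.linspace(0, 2 * np.pi, 200)
        r = 60 / (2 * np.pi)
        path = np.stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)], axis=1)
        tube = vl.generate_tube_volume(path, 1.0, (1000, 1000, 1000))
        assert tube.true_length_um == pytest.approx(60.0, rel=1e-3)
        assert tube.has_cycle

    def test_shape_bound_enforced(self):
        with pytest.raises(ValueError, match="exceeds shape"):
            vl.generate_tube_volume(
                np.array([[0, 0, 0], [50, 0, 0]], float), 1.0, (1000, 1000, 1000), shape=(10, 10, 10)
            )
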