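import numpy as np
import pytest

from helixcg.helix_geometry import AFormTemplate
from helixcg.model_builder import place_stem
from helixcg.proposal_stats import (
    InterhelixParams,
    LoopPlacement,
    StatsTable,
    SynthConfig,
    _make_stem,
    extract_interhelix,
    load_stats,
    sample_interhelix,
    sample_loop,
    save_stats,
    synthesize_stats,
)

TPL = AFormTemplate()


def random_params(rng):
    return InterhelixParams(
        r=rng.uniform(0.3, 12.0),
        u=np.arccos(rng.uniform(-1, 1)),
        v=rng.uniform(-np.pi, np.pi),
        u_p=np.arccos(rng.uniform(-1, 1)),
        v_p=rng.uniform(-np.pi, np.pi),
        t=rng.uniform(-np.pi, np.pi),
    )


class TestInterhelixRoundTrip:
    def test_coaxial_continuation(self):
        prev = _make_stem(TPL, 6)
        gap = 4.2
        p = InterhelixParams(gap, 0, 0, 0, 0, 0.5)
        new = place_stem(prev, (2, 1), p, (TPL.rise, TPL.twist), 5)
        got = extract_interhelix(prev, new, (2, 1))
        assert got.u == pytest.approx(0.0, abs=1e-9)
        assert got.u_p == pytest.approx(0.0, abs=1e-9)
        assert got.r == pytest.approx(gap, abs=1e-9)

    def test_offset_along_twist(self):
        """A stem displaced along the frame's twist axis has u = pi/2,
        v = 0 and r equal to the displacement."""
        prev = _make_stem(TPL, 6)
        d = 7.0
        p = InterhelixParams(d, np.pi / 2, 0.0, 0.0, 0.0, 0.0)
        new = place_stem(prev, (2, 1), p, (TPL.rise, TPL.twist), 6)
        # the new stem's start should sit at a_e + d * t_e
        assert np.allclose(new.a_s, prev.a_e + d * prev.t_e, atol=1e-9)
        got = extract_interhelix(prev, new, (2, 1))
        assert got.u == pytest.approx(np.pi / 2, abs=1e-9)
        assert got.v == pytest.approx(0.0, abs=1e-9)
        assert got.r == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("connection", [(2, 1), (4, 1), (4, 3), (1, 2)])
    def test_place_extract_identity(self, connection):
        """1,000 random draws: extract_interhelix inverts place_stem to
        1e-9 for every corner pattern."""
        rng = np.random.default_rng(99)
        prev = _make_stem(TPL, 7)
        worst = 0.0
        for _ in range(250):
            p = random_params(rng)
            n_bp = int(rng.integers(2, 12))
            stem_p = (rng.uniform(2.5, 3.1), rng.uniform(0.5, 0.65))
            new = place_stem(prev, connection, p, stem_p, n_bp)
            q = extract_interhelix(prev, new, connection)
            worst = max(worst, np.abs(p.as_array() - q.as_array()).max())
        assert worst < 1e-9

    def test_doubling_rise_doubles_length(self):
        prev = _make_stem(TPL, 6)
        p = random_params(np.random.default_rng(5))
        a = place_stem(prev, (2, 1), p, (2.8, 0.57), 9)
        b = place_stem(prev, (2, 1), p, (5.6, 0.57), 9)
        assert b.length == pytest.approx(2 * a.length, rel=1e-12)


class TestSampling:
    def test_single_entry_bucket_returned(self):
        table = StatsTable()
        row = np.array([[3.0, 0.1, 0.2, 0.3, 0.4, 0.5]])
        table.interhelix[("m", 4)] = row
        got = sample_interhelix(table, "m", 4, np.random.default_rng(0))
        assert np.allclose(got.as_array(), row[0])

    def test_fixed_seed_reproducible(self, synth_table):
        draws1 = np.random.default_rng(7)
        draws2 = np.random.default_rng(7)
        for _ in range(20):
            x = sample_interhelix(synth_table, "m", 3, draws1)
            y = sample_interhelix(synth_table, "m", 3, draws2)
            assert np.array_equal(x.as_array(), y.as_array())

    def test_nearest_bucket_fallback_ties_to_smaller(self):
        table = StatsTable()
        table.interhelix[("m", 2)] = np.array([[2.0, 0, 0, 0, 0, 0]])
        table.interhelix[("m", 6)] = np.array([[6.0, 0, 0, 0, 0, 0]])
        rng = np.random.default_rng(0)
        assert sample_interhelix(table, "m", 3, rng).r == 2.0  # nearest
        assert sample_interhelix(table, "m", 4, rng).r == 2.0  # tie -> smaller
        assert sample_interhelix(table, "m", 5, rng).r == 6.0

    def test_fallback_never_crosses_kinds(self):
        table = StatsTable()
        table.interhelix[("m", 2)] = np.array([[2.0, 0, 0, 0, 0, 0]])
        with pytest.raises(KeyError, match="'i'"):
            sample_interhelix(table, "i", (1, 1), np.random.default_rng(0))


class TestSynthesize:
    def test_zero_dispersion_is_coaxial(self):
        cfg = SynthConfig(
            count=4, angular_dispersion=0.0,
            interior_strand_max=2, multiloop_max_nt=2,
            stem_max_bp=4, hairpin_max=4,
        )
        table = synthesize_stats(cfg, np.random.default_rng(0))
        for (kind, size), rows in table.interhelix.items():
            if kind == "i":
                assert np.allclose(rows[:, 3], 0.0)  # u_p column

    def test_fixed_seed_byte_identical_file(self, tmp_path):
        cfg = SynthConfig(count=3, interior_strand_max=2, multiloop_max_nt=3,
                          stem_max_bp=4, hairpin_max=5)
        for i in (1, 2):
            table = synthesize_stats(cfg, np.random.default_rng(123))
            save_stats(table, tmp_path / f"s{i}.stats")
        assert (tmp_path / "s1.stats").read_bytes() == (
            tmp_path / "s2.stats"
        ).read_bytes()

    def test_multiloop_separation_grows_with_size(self, synth_table):
        means = [
            synth_table.interhelix[("m", n)][:, 0].mean() for n in range(9)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_single_placements_mostly_clash_free(self, synth_table):
        """>= 90% of sampled interior-loop placements leave the two stems
        without atom overlap (interface base pairs excluded)."""
        from helixcg.proposal_stats import _stems_clash

        rng = np.random.default_rng(17)
        prev = _make_stem(synth_table.template, 8)
        ok = 0
        n_trials = 100
        for _ in range(n_trials):
            p = sample_interhelix(synth_table, "i", (2, 2), rng)
            new = place_stem(prev, (2, 1), p, (2.81, 0.5707), 8)
            ok += not _stems_clash(prev, new, 1.8)
        assert ok / n_trials >= 0.9


class TestStatsFile:
    def test_round_trip(self, synth_table, tmp_path):
        path = tmp_path / "t.stats"
        save_stats(synth_table, path)
        back = load_stats(path)
        assert set(back.interhelix) == set(synth_table.interhelix)
        for key in synth_table.interhelix:
            assert np.array_equal(
                back.interhelix[key], synth_table.interhelix[key]
            )
        for key in synth_table.loops:
            assert np.array_equal(back.loops[key], synth_table.loops[key])
        for key in synth_table.stems:
            assert np.array_equal(back.stems[key], synth_table.stems[key])
        assert back.template == synth_table.template
        assert back.aminor_prior == synth_table.aminor_prior

    def test_unknown_kind_errors_with_line(self, tmp_path):
        path = tmp_path / "bad.stats"
        path.write_text(
            "[interhelix]\nq 3 1.0 0.0 0.0 0.0 0.0 0.0\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            load_stats(path)

    def test_legacy_file_without_stems_warns(self, tmp_path):
        path = tmp_path / "legacy.stats"
        path.write_text(
            "[interhelix]\nm 2 3.0 0.0 0.0 0.0 0.0 0.5\n"
            "[loops]\nh 4 1.0 0.0 0.0 5.0\n"
        )
        with pytest.warns(UserWarning, match="stems"):
            table = load_stats(path)
        assert table.stems  # defaults substituted

    def test_loop_placement_validation(self):
        with pytest.raises(ValueError, match="unit"):
            LoopPlacement((1.0, 1.0, 0.0), 3.0)
        with pytest.raises(ValueError, match="negative|length"):
            LoopPlacement((1.0, 0.0, 0.0), -1.0)


class TestExtraction:
    def test_extracted_params_rebuild_same_geometry(self, synth_table):
        """Mining a built model and rebuilding from a single-entry table
        reproduces the stem positions."""
        from helixcg.model_builder import build_model
        from helixcg.proposal_stats import extract_stats_from_model
        from helixcg.ss_graph import build_skeleton_graph, parse_dotbracket

        g = build_skeleton_graph(
            parse_dotbracket("((((....))))...((((....))))")
        )
        m = build_model(g, synth_table, np.random.default_rng(3))
        mined = extract_stats_from_model(m)
        mined.template = synth_table.template
        # single-entry buckets: rebuild must reproduce relative geometry
        m2 = build_model(g, mined, np.random.default_rng(0))
        d1 = np.linalg.norm(m.stems["s1"].a_s - m.stems["s0"].a_s)
        d2 = np.linalg.norm(m2.stems["s1"].a_s - m2.stems["s0"].a_s)
        assert d1 == pytest.approx(d2, abs=1e-6)
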