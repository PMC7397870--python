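"""Footprint normalization, metagene profiles, and window densities."""

import numpy as np
import pytest

from kozakscan.annotate import StartPair
from kozakscan.metagene import (
    ELONGATING,
    FootprintTrack,
    MetageneConfig,
    MetageneMatrix,
    apply_filters,
    build_matrix,
    compare_window_densities,
    metagene_profile,
    normalize_and_codonize,
    pooled_step_change,
    step_change,
    window_densities,
)

from conftest import make_pair, make_transcript


def long_transcript(tid="t", leader=60, cds_codons=120, utr=30, spacer=60):
    """AUG-free leader, CDS with an engineered fdAUG at `spacer`, UAA stop."""
    cds = ["GCC"] * cds_codons
    cds[-1] = "UAA"
    cds = list("".join(cds))
    cds[0:3] = "AUG"
    cds[spacer : spacer + 3] = "AUG"
    return make_transcript(tid, "g", "C" * leader, "".join(cds), "G" * utr)


def uniform_track(t, value=2):
    return FootprintTrack(t.id, np.full(len(t.seq), value), mode=ELONGATING)


CFG = MetageneConfig()


class TestApplyFilters:
    def _inputs(self, transcripts, pairs=None, counts=None):
        tmap = {t.id: t for t in transcripts}
        tracks = {
            t.id: FootprintTrack(t.id, counts.get(t.id) if counts else np.ones(len(t.seq), int))
            for t in transcripts
        }
        pmap = pairs or {
            t.id: make_pair(t.id, spacer=60, saug_pos=t.cds_start) for t in transcripts
        }
        return tmap, tracks, pmap

    def test_short_cds_excluded(self):
        ts = [long_transcript("a", cds_codons=50),  # 150 nt CDS
              long_transcript("b", cds_codons=100),
              long_transcript("c", cds_codons=200)]
        tmap, tracks, pmap = self._inputs(ts)
        included, excluded = apply_filters(tmap, tracks, pmap, CFG, "saug")
        assert sorted(included) == ["b", "c"]
        assert dict(excluded) == {"a": "short_cds"}

    def test_engineered_fixture_trips_each_filter_once(self):
        """Eight transcripts: each inclusion rule violated exactly once,
        including the strict >40 nt spacer rule at the fdAUG anchor."""
        ts = {tid: long_transcript(tid) for tid in
              ["pass1", "pass2", "cds", "fp", "leader", "sp40", "sp41", "nofd"]}
        ts["cds"] = long_transcript("cds", cds_codons=60)  # 180 nt < 200
        ts["leader"] = long_transcript("leader", leader=30)
        tmap = {t.id: t for t in ts.values()}
        tracks = {tid: uniform_track(t, 1) for tid, t in tmap.items()}
        low = np.zeros(len(tmap["fp"].seq), int)
        low[:100] = 1  # 100 footprints < 200
        tracks["fp"] = FootprintTrack("fp", low)
        pairs = {tid: make_pair(tid, spacer=60, saug_pos=t.cds_start)
                 for tid, t in tmap.items()}
        pairs["sp40"] = make_pair("sp40", spacer=40, saug_pos=tmap["sp40"].cds_start)
        pairs["sp41"] = make_pair("sp41", spacer=41, saug_pos=tmap["sp41"].cds_start)
        pairs["nofd"] = StartPair(transcript_id="nofd", gene_id="g",
                                  saug_pos=tmap["nofd"].cds_start)

        inc_s, exc_s = apply_filters(tmap, tracks, pairs, CFG, "saug")
        assert dict(exc_s) == {"cds": "short_cds", "fp": "few_footprints",
                               "leader": "short_leader"}
        assert sorted(inc_s) == ["nofd", "pass1", "pass2", "sp40", "sp41"]

        inc_f, exc_f = apply_filters(tmap, tracks, pairs, CFG, "fdaug")
        assert dict(exc_f) == {"cds": "short_cds", "fp": "few_footprints",
                               "sp40": "short_spacer", "nofd": "no_fdaug"}
        assert sorted(inc_f) == ["leader", "pass1", "pass2", "sp41"]

    def test_spacer_exactly_40_excluded_41_kept(self):
        t40, t41 = long_transcript("t40"), long_transcript("t41")
        tmap = {"t40": t40, "t41": t41}
        tracks = {tid: uniform_track(t) for tid, t in tmap.items()}
        pairs = {"t40": make_pair("t40", spacer=40, saug_pos=t40.cds_start),
                 "t41": make_pair("t41", spacer=41, saug_pos=t41.cds_start)}
        included, excluded = apply_filters(tmap, tracks, pairs, CFG, "fdaug")
        assert included == ["t41"]
        assert dict(excluded) == {"t40": "short_spacer"}

    def test_track_length_mismatch_is_hard_error(self):
        t = long_transcript("t")
        tracks = {"t": FootprintTrack("t", np.ones(10, int))}
        with pytest.raises(ValueError, match="length"):
            apply_filters({"t": t}, tracks, {"t": make_pair("t")}, CFG, "saug")

    def test_filters_order_independent(self):
        ts = [long_transcript(f"t{i}", cds_codons=50 + 20 * i) for i in range(4)]
        tmap, tracks, pmap = self._inputs(ts)
        inc1, _ = apply_filters(tmap, tracks, pmap, CFG, "saug")
        rmap = dict(reversed(list(tmap.items())))
        inc2, _ = apply_filters(rmap, tracks, pmap, CFG, "saug")
        assert sorted(inc1) == sorted(inc2)


class TestNormalizeAndCodonize:
    def test_uniform_counts_give_unit_density(self):
        t = long_transcript()
        vec = normalize_and_codonize(uniform_track(t), t, t.cds_start, CFG)
        assert np.allclose(vec[~np.isnan(vec)], 1.0)
        # normalization invariant: mean CDS codon density is exactly 1
        n_codons = t.cds_len // 3
        cds_vec = [vec[i] for i, off in enumerate(CFG.offsets) if 0 <= off < n_codons]
        assert np.nanmean(cds_vec) == pytest.approx(1.0, abs=1e-9)

    def test_step_track_density_ratio(self):
        t = long_transcript(spacer=60)
        counts = np.ones(len(t.seq), int)
        counts[t.cds_start + 60 :] = 3
        vec = normalize_and_codonize(FootprintTrack(t.id, counts), t,
                                     t.cds_start + 60, CFG)
        i0 = list(CFG.offsets).index(0)
        assert vec[i0 + 5] / vec[i0 - 5] == pytest.approx(3.0)

    def test_codon_sums_match_brute_force_binning(self):
        rng = np.random.default_rng(3)
        t = long_transcript()
        counts = rng.poisson(2.0, size=len(t.seq))
        track = FootprintTrack(t.id, counts)
        anchor = t.cds_start + 60
        vec = normalize_and_codonize(track, t, anchor, CFG)
        n_codons = t.cds_len // 3
        factor = counts[t.cds_start : t.cds_start + 3 * n_codons].sum() / n_codons
        for i, off in enumerate(CFG.offsets):
            lo = anchor + 3 * off
            if lo < 0 or lo + 3 > len(counts):
                assert np.isnan(vec[i])
            else:
                assert vec[i] == pytest.approx(counts[lo : lo + 3].sum() / factor)

    def test_scaling_invariance(self):
        t = long_transcript()
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=len(t.seq))
        v1 = normalize_and_codonize(FootprintTrack(t.id, counts), t, t.cds_start, CFG)
        v7 = normalize_and_codonize(FootprintTrack(t.id, counts * 7), t, t.cds_start, CFG)
        assert np.allclose(v1[~np.isnan(v1)], v7[~np.isnan(v7)])

    def test_normalization_idempotent(self):
        t = long_transcript()
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=len(t.seq)).astype(float)
        v1 = normalize_and_codonize(FootprintTrack(t.id, counts), t, t.cds_start, CFG)
        n_codons = t.cds_len // 3
        factor = counts[t.cds_start : t.cds_start + 3 * n_codons].sum() / n_codons
        v2 = normalize_and_codonize(FootprintTrack(t.id, counts / factor), t,
                                    t.cds_start, CFG)
        assert np.allclose(v1[~np.isnan(v1)], v2[~np.isnan(v2)])

    def test_zero_cds_counts_excluded(self):
        t = long_transcript()
        counts = np.zeros(len(t.seq), int)
        counts[:10] = 5  # leader only
        assert normalize_and_codonize(FootprintTrack(t.id, counts), t, t.cds_start, CFG) is None


class TestMetageneProfile:
    def _matrix(self, vectors):
        return MetageneMatrix(anchor="saug", offsets=CFG.offsets,
                              matrix=np.array(vectors),
                              transcript_ids=[f"t{i}" for i in range(len(vectors))])

    def test_single_transcript_profile_is_its_vector(self):
        vec = np.linspace(0, 2, len(CFG.offsets))
        prof = metagene_profile(self._matrix([vec]))
        assert np.allclose(prof, vec)

    def test_median_of_constant_vectors(self):
        n = len(CFG.offsets)
        prof = metagene_profile(self._matrix([np.full(n, 1.0), np.full(n, 1.0),
                                              np.full(n, 4.0)]))
        assert np.allclose(prof, 1.0)

    def test_median_invariant_to_adding_median_valued_rows(self):
        rng = np.random.default_rng(6)
        n = len(CFG.offsets)
        rows = [rng.uniform(0, 2, n) for _ in range(5)]
        base = metagene_profile(self._matrix(rows))
        prof = metagene_profile(self._matrix(rows + [base.copy()]))
        assert np.allclose(prof, base)

    def test_offsets_below_min_contribution_masked(self):
        n = len(CFG.offsets)
        v1 = np.full(n, 1.0)
        v2 = np.full(n, 2.0)
        v2[:5] = np.nan
        prof = metagene_profile(self._matrix([v1, v2]), min_transcripts=2)
        assert np.isnan(prof[:5]).all()
        assert np.allclose(prof[5:], 1.5)


class TestWindowDensities:
    def test_all_ones_vector(self):
        n = len(CFG.offsets)
        m = MetageneMatrix("saug", CFG.offsets, np.ones((1, n)), ["t"])
        dens, skipped = window_densities(m, CFG)
        assert dens["t"] == (pytest.approx(1.0), pytest.approx(1.0))
        assert not skipped

    def test_step_vector(self):
        vec = np.where(CFG.offsets < 0, 1.0, 2.0)
        m = MetageneMatrix("saug", CFG.offsets, vec[None, :], ["t"])
        dens, _ = window_densities(m, CFG)
        assert dens["t"] == (pytest.approx(1.0), pytest.approx(2.0))

    def test_matches_slice_mean_oracle(self):
        rng = np.random.default_rng(7)
        vec = rng.uniform(0, 3, len(CFG.offsets))
        m = MetageneMatrix("saug", CFG.offsets, vec[None, :], ["t"])
        dens, _ = window_densities(m, CFG)
        offs = list(CFG.offsets)
        up = np.mean([vec[offs.index(o)] for o in range(-15, -2)])
        down = np.mean([vec[offs.index(o)] for o in range(10, 45)])
        assert dens["t"] == (pytest.approx(up), pytest.approx(down))

    def test_window_out_of_range_skipped(self):
        vec = np.full(len(CFG.offsets), 1.0)
        vec[-1] = np.nan  # offset 50 missing does not matter
        vec[list(CFG.offsets).index(44)] = np.nan  # downstream window hole
        m = MetageneMatrix("saug", CFG.offsets, vec[None, :], ["t"])
        dens, skipped = window_densities(m, CFG)
        assert not dens and skipped == [("t", "window_out_of_range")]


class TestStepChange:
    def test_uniform_track_ratio_one(self):
        t = long_transcript(spacer=60)
        assert step_change(uniform_track(t), t, t.cds_start + 60, CFG) == pytest.approx(1.0)

    def test_constructed_step_ratio_three(self):
        t = long_transcript(spacer=60)
        counts = np.ones(len(t.seq), int)
        counts[t.cds_start + 60 :] = 3
        assert step_change(FootprintTrack(t.id, counts), t, t.cds_start + 60,
                           CFG) == pytest.approx(3.0)

    def test_zero_upstream_flagged_undefined(self):
        t = long_transcript(spacer=60)
        counts = np.zeros(len(t.seq), int)
        counts[t.cds_start + 70 :] = 2
        assert step_change(FootprintTrack(t.id, counts), t, t.cds_start + 60, CFG) is None


class TestCompareWindowDensities:
    def test_identical_matrices_p_one(self):
        n = len(CFG.offsets)
        m = MetageneMatrix("fdaug", CFG.offsets,
                           np.tile(np.linspace(0.5, 1.5, n), (5, 1)), list("abcde"))
        res = compare_window_densities(m, m, CFG)
        assert res["downstream"].p_value == pytest.approx(1.0)

    def test_small_samples_match_exact_permutation(self):
        import itertools

        n = len(CFG.offsets)
        rows_a = [np.full(n, v) for v in (1.0, 1.1, 1.2)]
        rows_b = [np.full(n, v) for v in (2.0, 2.1, 2.2)]
        ma = MetageneMatrix("fdaug", CFG.offsets, np.array(rows_a), ["a1", "a2", "a3"])
        mb = MetageneMatrix("fdaug", CFG.offsets, np.array(rows_b), ["b1", "b2", "b3"])
        res = compare_window_densities(ma, mb, CFG)["downstream"]
        assert res.p_value == pytest.approx(0.1)  # exhaustive C(6,3) permutation value


def test_leak_contrast_detected_at_depth_half():
    """Weak cohort (sAUG leak 0.5) vs strong cohort (leak 0.05): downstream
    fdAUG window densities differ at p<0.01 with 300 transcripts per side."""
    from kozakscan.annotate import annotate_catalog
    from kozakscan.context import synthetic_table
    from kozakscan.simulate import SimConfig, simulate_footprints, simulate_transcripts

    table = synthetic_table()
    mats = []
    for seed, p_init in ((101, 0.5), (102, 0.95)):
        cfg = SimConfig(n_genes=300, seed=seed, depth=0.5, min_spacer_nt=46,
                        p_init_saug_override=p_init, p_init_fd_override=1.0,
                        p_frame0_given_weak=1.0, p_frame2_given_weak=0.0,
                        p_frame0_given_strong=1.0, p_frame2_given_strong=0.0)
        trans, truth = simulate_transcripts(cfg)
        tracks = simulate_footprints(cfg, trans, truth)[ELONGATING]
        pairs, _ = annotate_catalog(trans, table)
        pmap = {p.transcript_id: p for p in pairs}
        tmap = {t.id: t for t in trans}
        matrix, _ = build_matrix(list(tmap), tmap, tracks, pmap, CFG, "fdaug")
        mats.append(matrix)
    res = compare_window_densities(mats[0], mats[1], CFG)
    assert res["downstream"].p_value < 0.01
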