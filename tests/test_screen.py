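"""Alignment building, windowing, scoring, classification, CSM/CSG calls."""

import numpy as np
import pytest

from sporescreen.annotation import GeneRecord, NcRNACatalog
from sporescreen.conservation import Family
from sporescreen.screen import (
    AlignmentWindow,
    ClassifierParams,
    MultiAlignment,
    ScoredWindow,
    ScreenConfig,
    WindowScore,
    build_alignment,
    calibrate_classifier,
    call_csms,
    classify_structural,
    default_classifier,
    filter_window,
    map_csgs,
    mean_pairwise_identity,
    run_screen,
    score_window,
    window_alignment,
)


def _family(*seqs, gene_id="gX"):
    members = [("S_pombe", seqs[0])] + [
        (f"sp{i}", s) for i, s in enumerate(seqs[1:], 1)
    ]
    return Family(gene_id=gene_id, members=members, ref_species="S_pombe")


def _aln(n_cols, gene_id="gY", rows=4):
    text = ("ACGU" * (n_cols // 4 + 1))[:n_cols]
    return MultiAlignment(gene_id=gene_id, rows=[(f"r{i}", text) for i in range(rows)])


class TestBuildAlignment:
    def test_identical_sequences_align_gap_free(self):
        aln = build_alignment(_family("ACGUACGUAA", "ACGUACGUAA"))
        assert aln.texts == ["ACGUACGUAA", "ACGUACGUAA"]

    def test_single_gap_opened_for_insertion(self):
        aln = build_alignment(_family("ACGU", "ACGGU"))
        assert aln.n_cols == 5
        ref, oth = aln.texts
        assert ref.count("-") == 1 and oth.count("-") == 0
        assert ref.replace("-", "") == "ACGU"

    def test_reference_always_first_and_ungapped_roundtrip(self):
        fam = _family("GGGAAACCCUUU", "GGGAACCCUUU", "GGGAAACCCUU")
        aln = build_alignment(fam)
        assert aln.ref_species == "S_pombe"
        assert aln.ungapped_ref() == fam.ref_sequence

    def test_external_clustal_round_trip(self, tmp_path):
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        fam = _family("ACGUACGUAA", "ACGACGUAA")
        built = build_alignment(fam)
        msa = MultipleSeqAlignment(
            [
                SeqRecord(Seq(text), id=f"{fam.gene_id}|{sp}")
                for (sp, _), text in zip(fam.members, built.texts)
            ]
        )
        path = tmp_path / "fam.aln"
        AlignIO.write(msa, path, "clustal")
        back = build_alignment(fam, mode="external", external_path=path)
        assert back.texts == built.texts

    def test_external_mismatching_row_rejected(self, tmp_path):
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        fam = _family("ACGUACGUAA", "ACGACGUAA")
        msa = MultipleSeqAlignment(
            [
                SeqRecord(Seq("ACGUACGUAA"), id="gX|S_pombe"),
                SeqRecord(Seq("AAAAAAAAA-"), id="gX|sp1"),
            ]
        )
        path = tmp_path / "bad.aln"
        AlignIO.write(msa, path, "clustal")
        with pytest.raises(ValueError, match="sp1"):
            build_alignment(fam, mode="external", external_path=path)

    def test_colmap_projects_reference_positions(self, small_catalog, small_families):
        _, families = small_families
        gid, fam = next(iter(sorted(families.items())))
        aln = build_alignment(fam, catalog=small_catalog)
        from sporescreen.annotation import transcript_coords

        coords = transcript_coords(small_catalog[gid])
        got = [c for c in aln.colmap if c >= 0]
        assert got == list(coords)


class TestWindowing:
    def test_200_columns_give_three_windows(self):
        cfg = ScreenConfig()
        wins = window_alignment(_aln(200), cfg)
        assert [(w.col_start, w.col_end) for w in wins] == [
            (0, 120), (40, 160), (80, 200)
        ]

    def test_exact_window_len_gives_one(self):
        assert len(window_alignment(_aln(120), ScreenConfig())) == 1

    def test_130_columns_add_end_anchored_tail(self):
        wins = window_alignment(_aln(130), ScreenConfig())
        assert [(w.col_start, w.col_end) for w in wins] == [(0, 120), (10, 130)]

    def test_short_alignment_single_window_or_none(self):
        assert len(window_alignment(_aln(80), ScreenConfig())) == 1
        assert window_alignment(_aln(49), ScreenConfig()) == []

    def test_every_column_covered_and_overlap_80(self):
        cfg = ScreenConfig()
        for n in (120, 137, 200, 245, 391):
            wins = window_alignment(_aln(n), cfg)
            covered = set()
            for w in wins:
                covered |= set(range(w.col_start, w.col_end))
            assert covered == set(range(n))
            regular = wins[:-1] if wins[-1].col_start % cfg.step else wins
            for a, b in zip(regular, regular[1:]):
                assert a.col_end - b.col_start == cfg.window_overlap


class TestFilterWindow:
    def test_gappy_ref_row_rejects_window(self):
        rows = [("S_pombe", "A" * 40 + "-" * 80), ("sp1", "A" * 120)]
        aln = MultiAlignment(gene_id="g", rows=rows)
        win = window_alignment(aln, ScreenConfig())[0]
        assert filter_window(win, ScreenConfig()) is None

    def test_window_reduced_below_min_rows_rejected(self):
        rows = [("S_pombe", "A" * 120), ("sp1", "-" * 60 + "A" * 60)]
        aln = MultiAlignment(gene_id="g", rows=rows)
        win = window_alignment(aln, ScreenConfig())[0]
        assert filter_window(win, ScreenConfig()) is None

    def test_clean_rows_all_kept(self):
        aln = _aln(120)
        win = window_alignment(aln, ScreenConfig())[0]
        kept = filter_window(win, ScreenConfig())
        assert kept is not None and len(kept.row_indices) == 4


class TestScoring:
    def test_identical_rows_mpi_and_sci_one(self, screen_cfg):
        aln = MultiAlignment(gene_id="g", rows=[("a", "GGGAAAACCC" * 6)] * 3)
        win = window_alignment(aln, screen_cfg)[0]
        sc = score_window(win, screen_cfg, default_classifier())
        assert sc.mpi == pytest.approx(1.0)
        assert sc.sci == pytest.approx(1.0)

    def test_hand_counted_mpi(self):
        a = "ACGU" * 15
        b = "UCGU" + "ACGU" * 13 + "AGGA"  # 3 mismatches in 60 columns
        assert mean_pairwise_identity([a, b]) == pytest.approx(57 / 60)

    def test_double_gap_columns_excluded_from_mpi(self):
        assert mean_pairwise_identity(["AC--G", "AC--G"]) == 1.0

    def test_scoring_is_deterministic(self, screen_cfg, small_alignments):
        aln = next(iter(small_alignments.values()))
        win = filter_window(window_alignment(aln, screen_cfg)[0], screen_cfg)
        s1 = score_window(win, screen_cfg, default_classifier())
        s2 = score_window(win, screen_cfg, default_classifier())
        assert s1 == s2

    def test_reverse_complement_scores_differently(self, screen_cfg, small_alignments):
        comp = str.maketrans("ACGU", "UGCA")
        aln = next(iter(small_alignments.values()))
        rc_rows = [(sp, t.translate(comp)[::-1]) for sp, t in aln.rows]
        rc = MultiAlignment(gene_id=aln.gene_id, rows=rc_rows)
        w1 = filter_window(window_alignment(aln, screen_cfg)[0], screen_cfg)
        w2 = filter_window(window_alignment(rc, screen_cfg)[0], screen_cfg)
        s1 = score_window(w1, screen_cfg, default_classifier())
        s2 = score_window(w2, screen_cfg, default_classifier())
        assert s1 != s2


class TestClassifier:
    def test_probability_in_unit_interval(self, rng):
        params = default_classifier()
        for _ in range(100):
            x = rng.normal(0, 5, 4)
            assert 0.0 <= classify_structural(x, params) <= 1.0

    def test_uncalibrated_params_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            classify_structural([0, 0, 0, 0], None)

    def test_perfectly_separable_toy_has_zero_training_error(self):
        pos = [[1.0, 1.0, 1.0, 1.0]] * 60
        neg = [[-1.0, -1.0, -1.0, -1.0]] * 60
        _, report = calibrate_classifier(pos, neg, seed=0)
        assert report["train_error"] == 0.0

    def test_label_swap_negates_weights(self, rng):
        pos = rng.normal(1, 1, size=(80, 4)).tolist()
        neg = rng.normal(-1, 1, size=(80, 4)).tolist()
        p1, _ = calibrate_classifier(pos, neg, seed=0)
        p2, _ = calibrate_classifier(neg, pos, seed=0)
        assert np.allclose(p1.weights, -np.array(p2.weights), atol=1e-4)
        assert p1.bias == pytest.approx(-p2.bias, abs=1e-4)

    def test_calibration_deterministic(self, rng):
        pos = rng.normal(1, 1, size=(60, 4)).tolist()
        neg = rng.normal(-1, 1, size=(60, 4)).tolist()
        assert calibrate_classifier(pos, neg, seed=3)[0] == calibrate_classifier(
            pos, neg, seed=3
        )[0]

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            calibrate_classifier([[0] * 4] * 10, [[1] * 4] * 60)


def _scored(gene_id, ref_start, ref_end, p, species=("sp1",), n_cols=120):
    parent = MultiAlignment(
        gene_id=gene_id,
        rows=[("S_pombe", "A" * n_cols)] + [(sp, "A" * n_cols) for sp in species],
        colmap=np.arange(ref_start, ref_start + n_cols, dtype=np.int64)[
            : n_cols
        ],
    )
    window = AlignmentWindow(parent, 0, min(n_cols, ref_end - ref_start))
    return ScoredWindow(window, WindowScore(0.0, 1.0, 1.0, 2, p))


class TestCsmCalling:
    def test_overlapping_windows_fuse_to_union(self):
        cfg = ScreenConfig()
        a = _scored("g", 0, 120, 0.9)
        b = _scored("g", 40, 160, 0.8)
        (csm,) = call_csms([a, b], cfg)
        assert csm.ref_interval == (0, 160)
        assert csm.max_p == pytest.approx(0.9)

    def test_isolated_window_becomes_its_own_csm(self):
        (csm,) = call_csms([_scored("g", 40, 160, 0.7)], ScreenConfig())
        assert csm.ref_interval == (40, 160)

    def test_p_equal_to_cutoff_not_extracted(self):
        assert call_csms([_scored("g", 0, 120, 0.5)], ScreenConfig()) == []

    def test_csms_disjoint_and_cover_significant_windows(self):
        cfg = ScreenConfig()
        wins = [
            _scored("g", 0, 120, 0.9),
            _scored("g", 40, 160, 0.6),
            _scored("g", 400, 520, 0.8),
            _scored("g", 200, 320, 0.2),   # not significant
        ]
        csms = call_csms(wins, cfg)
        intervals = sorted(c.ref_interval for c in csms)
        assert intervals == [(0, 160), (400, 520)]
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2
        union = set()
        for c in csms:
            union |= set(range(*c.ref_interval))
        expected = set()
        for w in wins:
            if w.score.p > cfg.p_cutoff:
                expected |= set(range(*w.ref_interval))
        assert union == expected

    def test_raising_cutoff_never_increases_calls(self):
        wins = [
            _scored("g1", 0, 120, p)
            for p in (0.1, 0.3, 0.55, 0.7, 0.95)
        ] + [_scored("g2", 0, 120, 0.6)]
        counts = []
        for cutoff in (0.0, 0.25, 0.5, 0.75, 0.9, 1.0):
            counts.append(len(call_csms(wins, ScreenConfig(p_cutoff=cutoff))))
        assert counts == sorted(counts, reverse=True)


class TestCsgMapping:
    def _catalog(self, *gids):
        cat = NcRNACatalog()
        for i, g in enumerate(gids):
            cat.add(GeneRecord(g, "chr1", "+", [(i * 1000, i * 1000 + 100)]))
        return cat

    def test_two_csms_two_species(self):
        cfg = ScreenConfig()
        csms = call_csms(
            [
                _scored("g1", 0, 120, 0.9, species=("S_octosporus",)),
                _scored("g1", 400, 520, 0.8, species=("S_japonicus",)),
            ],
            cfg,
        )
        (csg,) = map_csgs(csms, self._catalog("g1"))
        assert csg.n_support_species == 2

    def test_empty_input_empty_output(self):
        assert map_csgs([], self._catalog("g1")) == []

    def test_unknown_gene_raises(self):
        csms = call_csms([_scored("gZ", 0, 120, 0.9)], ScreenConfig())
        with pytest.raises(KeyError, match="gZ"):
            map_csgs(csms, self._catalog("g1"))


class TestRunScreen:
    def test_empty_catalog_empty_bundle(self):
        res = run_screen(NcRNACatalog(), [], ScreenConfig(), default_classifier())
        assert res.windows == [] and res.csms == [] and res.csgs == []

    def test_repeat_runs_identical(self, small_catalog, small_alignments, screen_cfg):
        alns = list(small_alignments.values())[:4]
        r1 = run_screen(small_catalog, alns, screen_cfg)
        r2 = run_screen(small_catalog, alns, screen_cfg)
        assert [sw.score for sw in r1.windows] == [sw.score for sw in r2.windows]
        assert r1.manifest == r2.manifest

    def test_zero_divergence_planted_genes_all_called(self, tmp_path):
        from sporescreen import annotation, pipeline, synth

        spec = synth.FamilySpec(
            species_rates={s: 0.0 for s in synth.DEFAULT_SPECIES_RATES},
            indel_rate=0.0,
        )
        ss = synth.generate_screenset(
            6, 0, 0, spec=spec, seed=5, out_dir=tmp_path / "zero"
        )
        catalog = annotation.parse_genbank_ncrnas(str(ss.genbank_path))
        _, families = pipeline.build_families(catalog, ss.maf_paths)
        alns = pipeline.build_alignments(families, catalog)
        res = run_screen(catalog, alns.values(), ScreenConfig(seed=5))
        structured = {g for g, l in ss.labels.items() if l.structured}
        assert structured <= res.csg_gene_ids
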