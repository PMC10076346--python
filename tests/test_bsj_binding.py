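"""Representative transcripts, region labels, windows, matching, enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from circseam import bsj_binding as bb
from circseam.io_junctions import Peak
from conftest import bsj, make_annotation, make_transcript
from test_isoform_classify import fisher_p_enumeration


def peak(chrom="chr1", start=0, end=100, summit=None, sample_id="rep1"):
    return Peak(chrom=chrom, start=start, end=end,
                summit=summit if summit is not None else (start + end) // 2,
                signal=1.0, sample_id=sample_id)


class TestRepresentativeTranscript:
    # gene G1 on +: exons at [1000,1200), [1500,1700), [2000,2200), [2500,2700)
    EXONS = [(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)]

    def test_boundaries_on_exon_junctions_preferred(self):
        t_exact = make_transcript("T1", "G1", self.EXONS)
        t_shifted = make_transcript("T0", "G1", [(990, 1200), (1500, 1700), (2000, 2210)])
        ann = make_annotation(t_exact, t_shifted)
        model = bb.representative_transcript(bsj(start=1000, end=2200), ann)
        assert model.transcript.transcript_id == "T1"
        assert model.boundaries_on_exons

    def test_fewest_exons_in_span_wins(self):
        t3 = make_transcript("T1", "G1", self.EXONS[:3])
        t2 = make_transcript("T2", "G1", [(1000, 1200), (2000, 2200)])  # skips middle
        ann = make_annotation(t3, t2)
        model = bb.representative_transcript(bsj(start=1000, end=2200), ann)
        assert model.transcript.transcript_id == "T2"
        assert model.exon_count == 2

    def test_single_isoform_trivial(self):
        ann = make_annotation(make_transcript("T1", "G1", self.EXONS))
        model = bb.representative_transcript(bsj(start=1500, end=2200), ann)
        assert model.transcript.transcript_id == "T1"
        assert model.exon_count == 2
        assert model.first_exon_number == 2

    def test_gene_biotype_match_outranks_everything(self):
        t_lnc = make_transcript("T1", "G1", [(1000, 1200), (2000, 2200)], biotype="lncRNA")
        t_pc = make_transcript("T2", "G1", self.EXONS[:3], biotype="protein_coding")
        ann = make_annotation(t_lnc, t_pc)  # gene biotype protein_coding
        model = bb.representative_transcript(bsj(start=1000, end=2200), ann)
        assert model.transcript.transcript_id == "T2"

    def test_unannotated_circ_rejected(self):
        ann = make_annotation(make_transcript("T1", "G1", self.EXONS))
        with pytest.raises(ValueError, match="unannotated"):
            bb.representative_transcript(bsj(chrom="chr9", gene_id=None), ann)


class TestLabelRegions:
    def _model(self, n_exons, strand="+"):
        exons = [(1000 * (i + 1), 1000 * (i + 1) + 200) for i in range(n_exons)]
        t = make_transcript("T1", "G1", exons, strand=strand)
        ann = make_annotation(t)
        start, end = exons[0][0], exons[-1][1]
        return bb.representative_transcript(
            bsj(start=start, end=end, strand=strand), ann
        )

    @pytest.mark.parametrize(
        "n,expected",
        [
            (1, ["Ex_A"]),
            (2, ["Ex_A", "Intr_A", "Ex_Z"]),
            (3, ["Ex_A", "Intr_A", "Ex_M", "Intr_Z", "Ex_Z"]),
            (5, ["Ex_A", "Intr_A", "Ex_M", "Intr_M", "Ex_M", "Intr_M", "Ex_M",
                 "Intr_Z", "Ex_Z"]),
        ],
    )
    def test_label_sequence(self, n, expected):
        model = bb.label_regions(self._model(n))
        assert [r.tag for r in model.regions] == expected

    def test_minus_strand_regions_follow_transcript_order(self):
        model = bb.label_regions(self._model(3, strand="-"))
        assert [r.tag for r in model.regions] == [
            "Ex_A", "Intr_A", "Ex_M", "Intr_Z", "Ex_Z"
        ]
        # Ex_A is the genomically rightmost exon on the minus strand
        ex_a = model.regions[0]
        assert ex_a.start == 3000

    def test_boundaries_off_junctions_not_labelable(self):
        t = make_transcript("T1", "G1", [(1000, 1200), (2000, 2200)])
        ann = make_annotation(t)
        model = bb.representative_transcript(bsj(start=1050, end=2200), ann)
        with pytest.raises(ValueError, match="not labelable"):
            bb.label_regions(model)


class TestMakeWindows:
    def _model(self, strand="+"):
        t = make_transcript("T1", "G1", [(5000, 5200), (6000, 6200)], strand=strand)
        ann = make_annotation(t)
        return bb.representative_transcript(bsj(start=5000, end=6200, strand=strand), ann)

    def test_default_window_count_and_width(self):
        wins = bb.make_windows(self._model())
        per_ext = {}
        for w in wins:
            per_ext[w.extremity] = per_ext.get(w.extremity, 0) + 1
            assert w.end - w.start == 100
        assert per_ext == {"five_prime_ss": 191, "three_prime_ss": 191}

    def test_small_span_window_count(self):
        wins = bb.make_windows(self._model(), span=100, width=100, step=10)
        assert sum(w.extremity == "five_prime_ss" for w in wins) == 11

    def test_minus_strand_upstream_is_higher_coordinate(self):
        model = self._model(strand="-")
        wins = [w for w in bb.make_windows(model)
                if w.extremity == "five_prime_ss" and w.offset == -1000]
        # 5' extremity of a minus-strand circ is the genomic end (6200);
        # upstream (offset -1000) lies at higher genomic coordinates
        assert wins[0].start == 6200 + 1000 - 100 + 0  # pos - offset - width
        assert wins[0].start > model.five_prime_pos

    def test_out_of_bounds_windows_dropped(self):
        t = make_transcript("T1", "G1", [(100, 300), (600, 800)])
        ann = make_annotation(t)
        model = bb.representative_transcript(bsj(start=100, end=800), ann)
        wins = bb.make_windows(model)
        assert all(w.start >= 0 for w in wins)
        assert sum(w.extremity == "five_prime_ss" for w in wins) < 191


class TestWindowProps:
    def _model(self):
        t = make_transcript(
            "T1", "G1", [(1000, 1200), (2000, 2200)],
            cds=[(1100, 1200), (2000, 2100)],
            utr5=[(1000, 1100)], utr3=[(2100, 2200)],
        )
        ann = make_annotation(t)
        return bb.representative_transcript(bsj(start=1000, end=2200), ann)

    def test_window_inside_cds_exon(self):
        model = self._model()
        w = bb.GenomicWindow("chr1", 2000, 2100, "+", "five_prime_ss", 0, model.circ_id)
        p = bb.window_props(w, model)
        assert (p.pct_exon, p.pct_cds, p.pct_5utr, p.pct_3utr) == (100, 100, 0, 0)

    def test_fully_intronic_window(self):
        model = self._model()
        w = bb.GenomicWindow("chr1", 1400, 1500, "+", "five_prime_ss", 0, model.circ_id)
        p = bb.window_props(w, model)
        assert (p.pct_exon, p.pct_cds, p.pct_5utr, p.pct_3utr) == (0, 0, 0, 0)

    def test_half_exon_half_intron(self):
        model = self._model()
        w = bb.GenomicWindow("chr1", 1150, 1250, "+", "five_prime_ss", 0, model.circ_id)
        p = bb.window_props(w, model)
        assert p.pct_exon == 50.0
        assert p.pct_cds == 50.0

    def test_utr_fractions_bounded_by_exon(self):
        model = self._model()
        for start in range(900, 2300, 37):
            w = bb.GenomicWindow("chr1", start, start + 100, "+", "five_prime_ss", 0,
                                 model.circ_id)
            p = bb.window_props(w, model)
            assert p.pct_5utr + p.pct_cds + p.pct_3utr <= p.pct_exon + 1e-9


def window_with_props(circ_id, pct_exon, pct_5utr, pct_cds, pct_3utr,
                      biotype="protein_coding", exon_class="2",
                      extremity="five_prime_ss", offset=0):
    return bb.GenomicWindow(
        chrom="chr1", start=0, end=100, strand="+", extremity=extremity,
        offset=offset, circ_id=circ_id,
        props=bb.WindowProps(pct_exon, pct_5utr, pct_cds, pct_3utr, biotype, exon_class),
    )


class TestMatchControls:
    def test_exact_duplicate_selected_first(self):
        target = window_with_props("t", 80, 10, 60, 10)
        dup = window_with_props("c1", 80, 10, 60, 10)
        far = window_with_props("c2", 0, 0, 0, 0)
        assert bb.match_controls(target, [far, dup], k=1) == [dup]

    def test_euclidean_ranking(self):
        target = window_with_props("t", 100, 0, 100, 0)
        c1 = window_with_props("c1", 100, 0, 100, 0)
        c2 = window_with_props("c2", 0, 0, 0, 0)
        c3 = window_with_props("c3", 50, 0, 50, 0)
        out = bb.match_controls(target, [c2, c3, c1], k=2)
        assert [w.circ_id for w in out] == ["c1", "c3"]

    def test_relaxation_path_on_scarce_pool(self):
        target = window_with_props("t", 50, 0, 50, 0, exon_class="2")
        same_class = window_with_props("c1", 40, 0, 40, 0, exon_class="2")
        other_class = window_with_props("c2", 50, 0, 50, 0, exon_class="3")
        out = bb.match_controls(target, [same_class, other_class], k=2)
        assert {w.circ_id for w in out} == {"c1", "c2"}

    def test_target_itself_never_a_control(self):
        target = window_with_props("t", 50, 0, 50, 0)
        clone = window_with_props("t", 50, 0, 50, 0)
        assert bb.match_controls(target, [clone], k=1) == []


class TestWindowEnrichment:
    @staticmethod
    def _mk(prefix, n, region_start):
        out = []
        for i in range(n):
            s = region_start + i * 1000
            out.append(
                bb.GenomicWindow("chr1", s, s + 100, "+", "five_prime_ss", 0, f"{prefix}{i}",
                                 props=bb.WindowProps(100, 0, 0, 0, "protein_coding", "2"))
            )
        return out

    def test_all_targets_hit_no_controls_hit(self):
        targets = self._mk("t", 6, 0)
        controls = self._mk("c", 12, 100_000)
        peaks = {"rep1": [peak(start=w.start, end=w.end) for w in targets]}
        bins = bb.window_enrichment(targets, controls, peaks)
        row = bins.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (6, 0, 0, 12)
        assert row.odds_ratio > 1
        assert row.pvalue == pytest.approx(fisher_p_enumeration(6, 0, 0, 12), rel=1e-8)

    def test_identical_rates_not_significant(self):
        targets = self._mk("t", 6, 0)
        controls = self._mk("c", 6, 100_000)
        peaks = {"rep1": [peak(start=w.start, end=w.end) for w in targets + controls]}
        bins = bb.window_enrichment(targets, controls, peaks)
        assert bins.iloc[0].pvalue == 1.0
        assert not bins.iloc[0].significant

    def test_no_peaks_all_nonsignificant(self):
        targets = self._mk("t", 5, 0)
        controls = self._mk("c", 10, 100_000)
        bins = bb.window_enrichment(targets, controls, {"rep1": []})
        assert (bins.a == 0).all() and (bins.c == 0).all()
        assert not bins.significant.any()

    def test_fisher_matches_enumeration_on_small_bins(self):
        rng = np.random.default_rng(4)
        targets = self._mk("t", 8, 0)
        controls = self._mk("c", 16, 100_000)
        hit_t = rng.random(8) < 0.6
        hit_c = rng.random(16) < 0.2
        peaks = {"rep1": (
            [peak(start=w.start, end=w.end) for w, h in zip(targets, hit_t) if h]
            + [peak(start=w.start, end=w.end) for w, h in zip(controls, hit_c) if h]
        )}
        bins = bb.window_enrichment(targets, controls, peaks)
        row = bins.iloc[0]
        assert row.pvalue == pytest.approx(
            fisher_p_enumeration(row.a, row.b, row.c, row.d), rel=1e-8
        )


class TestRegionEnrichment:
    def _models(self, prefix, n, base):
        models = []
        for i in range(n):
            off = base + i * 10_000
            exons = [(off, off + 200), (off + 1000, off + 1200), (off + 2000, off + 2200)]
            t = make_transcript(f"T{prefix}{i}", f"G{prefix}{i}", exons)
            ann = make_annotation(t)
            m = bb.representative_transcript(
                bsj(start=off, end=off + 2200, gene_id=f"G{prefix}{i}"), ann
            )
            models.append(bb.label_regions(m))
        return models

    def test_planted_ex_a_binding_detected(self):
        down = self._models("d", 12, 0)
        inv = self._models("i", 12, 10_000_000)
        # peaks only inside Ex_A of the down set
        peaks = [peak(start=m.regions[0].start, end=m.regions[0].start + 50) for m in down]
        res = bb.region_enrichment(down, inv, peaks).set_index("region")
        assert res.loc["Ex_A", "significant"]
        assert not res.drop("Ex_A")["significant"].any()

    def test_identical_rates_p_one(self):
        down = self._models("d", 5, 0)
        inv = self._models("i", 5, 10_000_000)
        peaks = [peak(start=m.regions[0].start, end=m.regions[0].start + 50)
                 for m in down + inv]
        res = bb.region_enrichment(down, inv, peaks).set_index("region")
        assert res.loc["Ex_A", "pvalue"] == 1.0


class TestInteractorCall:
    def test_two_of_three_replicates(self):
        rec = bsj(start=1000, end=2000)
        hit = [peak(start=1500, end=1600)]
        miss = [peak(start=9000, end=9100)]
        assert bb.interactor_call(rec, {"r1": hit, "r2": miss, "r3": hit})

    def test_single_replicate_insufficient(self):
        rec = bsj(start=1000, end=2000)
        hit = [peak(start=1500, end=1600)]
        miss = [peak(start=9000, end=9100)]
        assert not bb.interactor_call(rec, {"r1": hit, "r2": miss, "r3": miss})

    def test_min_samples_one(self):
        rec = bsj(start=1000, end=2000)
        hit = [peak(start=1500, end=1600)]
        assert bb.interactor_call(rec, {"r1": hit}, min_samples=1)


class TestBalanceCheck:
    def test_exactly_matched_controls_balanced(self):
        t = [window_with_props(f"t{i}", 50, 10, 30, 10) for i in range(8)]
        c = [window_with_props(f"c{i}", 50, 10, 30, 10) for i in range(16)]
        res = bb.balance_check(t, c)
        assert (res.pvalue == 1.0).all()

    def test_planted_imbalance_detected(self):
        t = [window_with_props(f"t{i}", 100, 0, 100, 0) for i in range(20)]
        c = [window_with_props(f"c{i}", 0, 0, 0, 0) for i in range(20)]
        res = bb.balance_check(t, c).set_index("property")
        assert res.loc["pct_exon", "significant"].any()

    def test_single_window_per_set_no_power(self):
        t = [window_with_props("t", 80, 0, 80, 0)]
        c = [window_with_props("c", 10, 0, 10, 0)]
        res = bb.balance_check(t, c)
        assert (res.pvalue == 1.0).all()


class TestRunMetaBsj:
    def test_planted_five_prime_enrichment_localizes(self, scenario, scenario_models):
        truth = scenario.truth
        down = [scenario_models[c] for c in truth.index[truth.target]]
        inv = [scenario_models[c] for c in truth.index[truth.category == "Unaltered"]]
        bins, targets, controls = bb.run_meta_bsj(
            down, inv, scenario.peaks, chrom_sizes=scenario.bundle.chrom_sizes
        )
        sig = bins[bins.significant]
        assert len(sig) > 0
        from conftest import distance_to_planted_extremity

        near, far = distance_to_planted_extremity(sig, down)
        assert all(near)
        assert not any(far)

    def test_controls_never_from_target_set(self, scenario, scenario_models):
        truth = scenario.truth
        down = [scenario_models[c] for c in truth.index[truth.target]]
        inv = [scenario_models[c] for c in truth.index[truth.category == "Unaltered"]]
        _, targets, controls = bb.run_meta_bsj(
            down, inv, scenario.peaks, chrom_sizes=scenario.bundle.chrom_sizes
        )
        target_ids = {w.circ_id for w in targets}
        assert not target_ids & {w.circ_id for w in controls}
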