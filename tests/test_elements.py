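"""Element construction, filtering and linking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epmix.elements import (
    Element,
    EPLink,
    GenomicInterval,
    assign_single_enhancer,
    build_promoters,
    count_label_sites,
    count_motif,
    filter_links,
    process_enhancers,
    subtract_intervals,
)


def _tss(chrom="chr1", pos=10_000, strand="+", gene_id="G1"):
    return {"chrom": chrom, "pos": pos, "strand": strand, "gene_id": gene_id}


class TestBuildPromoters:
    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (10_000, "+", (8_000, 10_500)),  # 2 kb upstream, 500 bp downstream
            (10_000, "-", (9_500, 12_000)),  # mirrored on the minus strand
            (1_000, "+", (0, 1_500)),  # clipped at the chromosome origin
        ],
    )
    def test_strand_aware_window(self, pos, strand, expected):
        (prom,) = build_promoters([_tss(pos=pos, strand=strand)])
        assert (prom.interval.start, prom.interval.end) == expected
        assert prom.role == "promoter"

    def test_missing_strand_rejected(self):
        out = build_promoters([_tss(strand="."), _tss(pos=50_000)])
        assert len(out) == 1

    def test_duplicate_gene_ids_stay_unique(self):
        out = build_promoters([_tss(), _tss(pos=90_000)])
        assert len({p.id for p in out}) == 2


class TestProcessEnhancers:
    def _enh(self, start, end, eid="E1"):
        return Element(eid, GenomicInterval("chr1", start, end), "enhancer")

    def test_short_enhancer_recentered_to_200bp(self):
        (out,) = process_enhancers([self._enh(100, 250)])
        assert (out.interval.start, out.interval.end) == (75, 275)

    def test_fully_excluded_enhancer_dropped(self):
        excl = [GenomicInterval("chr1", 0, 1000)]
        assert process_enhancers([self._enh(0, 1000)], excl) == []

    def test_split_enhancer_keeps_longest_fragment(self):
        excl = [GenomicInterval("chr1", 100, 200)]
        (out,) = process_enhancers([self._enh(0, 600)], excl)
        assert (out.interval.start, out.interval.end) == (200, 600)

    def test_no_output_shorter_than_200(self):
        excl = [GenomicInterval("chr1", 150, 5000)]
        outs = process_enhancers(
            [self._enh(0, 300), self._enh(6000, 6400, "E2")], excl
        )
        assert all(o.interval.length >= 200 for o in outs)

    def test_subtraction_oracle(self):
        iv = GenomicInterval("chr1", 0, 100)
        excl = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 15, 40)]
        frags = subtract_intervals(iv, excl)
        assert [(f.start, f.end) for f in frags] == [(0, 10), (40, 100)]


class TestLabelSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATCGATCGA", 2), ("AAAA", 0), ("TCGA", 1), ("", 0), ("tcgatcga", 2)],
    )
    def test_motif_count_examples(self, seq, expected):
        assert count_motif(seq) == expected

    @given(st.text(alphabet="ACGT", max_size=300))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_motif_count_matches_sliding_window(self, seq):
        naive = sum(seq[i : i + 4] == "TCGA" for i in range(len(seq)))
        assert count_motif(seq) == naive

    def test_fasta_backed_count(self, tmp_path):
        import pyfaidx

        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nAAAATCGAAATCGATCGAAA\n")
        ref = pyfaidx.Fasta(str(fa))
        el = Element("E", GenomicInterval("chr1", 0, 20), "enhancer")
        assert count_label_sites(el, ref) == 3
        bad = Element("E", GenomicInterval("chrX", 0, 10), "enhancer")
        with pytest.raises(KeyError):
            count_label_sites(bad, ref)


def _elem(eid, start, end, sites, role="enhancer", chrom="chr1"):
    return Element(eid, GenomicInterval(chrom, start, end), role, site_count=sites)


class TestFilterLinks:
    def setup_method(self):
        self.prom = {"P1": _elem("P1", 0, 2500, 4, role="promoter")}

    def _link(self, eid):
        return EPLink(f"P1|{eid}", "P1", eid, "G1")

    def test_gap_boundary_5000_retained(self):
        enh = {"E1": _elem("E1", 7500, 7700, 2)}
        out = filter_links([self._link("E1")], self.prom, enh)
        assert len(out) == 1 and out[0].gap == 5000

    def test_gap_below_threshold_dropped(self):
        enh = {"E1": _elem("E1", 7000, 7200, 2)}
        assert filter_links([self._link("E1")], self.prom, enh) == []

    def test_zero_site_enhancer_dropped(self):
        enh = {"E1": _elem("E1", 100_000, 100_200, 0)}
        assert filter_links([self._link("E1")], self.prom, enh) == []

    def test_cross_chromosome_dropped(self):
        enh = {"E1": _elem("E1", 100_000, 100_200, 2, chrom="chr2")}
        assert filter_links([self._link("E1")], self.prom, enh) == []

    def test_dangling_id_dropped(self):
        assert filter_links([self._link("nope")], self.prom, {}) == []

    def test_idempotent_and_subset(self):
        enh = {
            "E1": _elem("E1", 7500, 7700, 2),
            "E2": _elem("E2", 7000, 7200, 2),
            "E3": _elem("E3", 50_000, 50_400, 0),
        }
        links = [self._link(e) for e in enh]
        once = filter_links(links, self.prom, enh)
        twice = filter_links(once, self.prom, enh)
        assert twice == once
        assert {l.pair_id for l in once} <= {l.pair_id for l in links}


class TestAssignSingleEnhancer:
    def _setup(self, enhancers):
        links = [
            EPLink(f"P1|{eid}", "P1", eid, "G1", gap=gap)
            for eid, (_s, _e, _n, gap) in enhancers.items()
        ]
        elems = {
            eid: _elem(eid, s, e, n)
            for eid, (s, e, n, _gap) in enhancers.items()
        }
        return links, elems

    def test_highest_site_count_wins(self):
        links, elems = self._setup(
            {"E1": (10_000, 10_400, 5, 7500), "E2": (20_000, 20_400, 9, 17_500)}
        )
        (best,) = assign_single_enhancer(links, elems)
        assert best.enhancer_id == "E2"

    def test_tie_broken_by_larger_enhancer(self):
        links, elems = self._setup(
            {"E1": (10_000, 10_400, 5, 7500), "E2": (20_000, 20_200, 5, 17_500)}
        )
        (best,) = assign_single_enhancer(links, elems)
        assert best.enhancer_id == "E1"

    def test_full_tie_broken_by_proximity_then_id(self):
        links, elems = self._setup(
            {"E1": (12_000, 12_200, 5, 9000), "E2": (9_000, 9_200, 5, 6000)}
        )
        (best,) = assign_single_enhancer(links, elems)
        assert best.enhancer_id == "E2"
        # identical everything: lexicographic enhancer id decides
        links, elems = self._setup(
            {"Eb": (12_000, 12_200, 5, 9000), "Ea": (30_000, 30_200, 5, 9000)}
        )
        (best,) = assign_single_enhancer(links, elems)
        assert best.enhancer_id == "Ea"

    def test_one_link_per_promoter(self):
        links = [
            EPLink(f"P{i}|E{j}", f"P{i}", f"E{j}", "G", gap=6000 + j)
            for i in range(3)
            for j in range(4)
        ]
        elems = {f"E{j}": _elem(f"E{j}", 10_000 * (j + 1), 10_000 * (j + 1) + 300, j + 1) for j in range(4)}
        out = assign_single_enhancer(links, elems)
        assert sorted(l.promoter_id for l in out) == ["P0", "P1", "P2"]
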