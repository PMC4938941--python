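import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxbs5hmc import (
    Transcript,
    assign_cgi_status,
    assign_region,
    cpg_density,
    enlarge_sites,
    gap_distances,
    probe_cpg_density,
    probes_in_track,
    smooth_track,
)
from oxbs5hmc.annotation import REGION_LABELS, _transcript_labeled_intervals
from oxbs5hmc.errors import TrackError


def _probes(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions},
        index=[f"P{i}" for i in range(len(positions))],
    )


def brute_region_label(chrom, pos, transcripts):
    """Independent labeler: per-bp label sets from each transcript's
    definition, then precedence min."""
    pos0 = pos - 1
    rank = {lab: i for i, lab in enumerate(REGION_LABELS)}
    candidates = []
    for tx in transcripts:
        if tx.chrom != chrom:
            continue
        if tx.strand == "+":
            prom_lo, prom_hi = tx.start - 2000, tx.start
        else:
            prom_lo, prom_hi = tx.end, tx.end + 2000
        if prom_lo <= pos0 < prom_hi:
            candidates.append("Promoter")
        if not (tx.start <= pos0 < tx.end):
            continue
        in_exon = any(s <= pos0 < e for s, e in tx.exons)
        if not in_exon:
            candidates.append("Intron")
            continue
        if tx.cds is not None:
            cs, ce = tx.cds
            before_cds = pos0 < cs
            after_cds = pos0 >= ce
            if tx.strand == "+":
                if before_cds:
                    candidates.append("5UTR"); continue
                if after_cds:
                    candidates.append("3UTR"); continue
            else:
                if after_cds:
                    candidates.append("5UTR"); continue
                if before_cds:
                    candidates.append("3UTR"); continue
        first = tx.exons[0] if tx.strand == "+" else tx.exons[-1]
        if first[0] <= pos0 < first[1]:
            candidates.append("FirstExon")
        else:
            candidates.append("Exon")
    if not candidates:
        return "Intergenic"
    return min(candidates, key=rank.__getitem__)


def random_toy_transcripts(rng, n_tx=8, chrom_len=60_000):
    txs = []
    for i in range(n_tx):
        length = int(rng.integers(2_000, 12_000))
        start = int(rng.integers(2_100, chrom_len - length - 2_100))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        if n_exons == 1:
            exons = [(start, start + length)]
        else:
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = [(start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                     for k in range(n_exons)]
        if rng.random() < 0.75:
            cs = start + int(rng.integers(1, max(2, length // 2)))
            ce = cs + int(rng.integers(0, length - (cs - start)))
            cds = (cs, ce)
        else:
            cds = None
        txs.append(Transcript("chr1", start, start + length, strand, exons, cds, f"t{i}"))
    return txs


class TestAssignRegion:
    def setup_method(self):
        # plus-strand coding transcript: [10000, 20000), CDS [12000, 18000),
        # exons [10000,13000) [15000,20000)
        self.tx_a = Transcript("chr1", 10_000, 20_000, "+",
                               exons=[(10_000, 13_000), (15_000, 20_000)],
                               cds=(12_000, 18_000), name="A")

    def test_promoter_upstream_of_plus_strand_tss(self):
        labels = assign_region(_probes([10_000 - 1_500 + 1]), [self.tx_a])
        assert labels.iloc[0] == "Promoter"

    def test_promoter_window_is_strand_aware(self):
        tx_minus = Transcript("chr1", 30_000, 40_000, "-",
                              exons=[(30_000, 40_000)], cds=None, name="M")
        up = assign_region(_probes([41_000]), [tx_minus])
        down = assign_region(_probes([29_000]), [tx_minus])
        assert up.iloc[0] == "Promoter"
        assert down.iloc[0] == "Intergenic"

    def test_exon_outranks_intron_across_transcripts(self):
        # probe in the intron of A (pos0 14000) and a non-first exon of C
        tx_c = Transcript("chr1", 13_000, 15_000, "+",
                          exons=[(13_000, 13_200), (13_900, 14_500)], cds=None, name="C")
        labels = assign_region(_probes([14_001]), [self.tx_a, tx_c])
        assert labels.iloc[0] == "Exon"
        # ... and a single-exon transcript contributes a FirstExon label
        tx_b = Transcript("chr1", 13_500, 14_500, "+",
                          exons=[(13_500, 14_500)], cds=None, name="B")
        labels = assign_region(_probes([14_001]), [self.tx_a, tx_b])
        assert labels.iloc[0] == "FirstExon"

    def test_first_exon_outranked_by_3utr(self):
        # probe in the 3UTR of A (exonic, pos0 19000 >= CDS end 18000) and in
        # the first exon of another transcript: 3UTR has higher precedence
        tx_d = Transcript("chr1", 18_900, 19_800, "+",
                          exons=[(18_900, 19_400), (19_500, 19_800)],
                          cds=(18_950, 19_700), name="D")
        labels = assign_region(_probes([19_001]), [self.tx_a, tx_d])
        assert labels.iloc[0] == "3UTR"

    def test_unannotated_position_is_intergenic(self):
        labels = assign_region(_probes([500_000]), [self.tx_a])
        assert labels.iloc[0] == "Intergenic"

    def test_utr_labels_on_coding_transcript(self):
        five = assign_region(_probes([11_001]), [self.tx_a])   # exonic, before CDS
        three = assign_region(_probes([19_001]), [self.tx_a])  # exonic, after CDS
        first = assign_region(_probes([12_501]), [self.tx_a])  # first exon, inside CDS
        intron = assign_region(_probes([14_001]), [self.tx_a])
        assert five.iloc[0] == "5UTR"
        assert three.iloc[0] == "3UTR"
        assert first.iloc[0] == "FirstExon"
        assert intron.iloc[0] == "Intron"

    def test_invalid_exon_bounds_rejected(self):
        with pytest.raises(TrackError):
            Transcript("chr1", 100, 200, "+", exons=[(150, 120)], name="bad")
        with pytest.raises(TrackError):
            Transcript("chr1", 100, 200, "+", exons=[(50, 150)], name="outside")

    def test_labels_partition_probes(self, rng):
        txs = random_toy_transcripts(rng)
        probes = _probes(sorted(rng.integers(1, 60_000, size=300)))
        labels = assign_region(probes, txs)
        assert labels.notna().all()
        assert labels.value_counts().sum() == len(probes)

    def test_matches_bruteforce_labeler_on_random_annotations(self, rng):
        for _ in range(10):
            txs = random_toy_transcripts(rng)
            positions = rng.integers(1, 60_000, size=150)
            labels = assign_region(_probes(positions), txs)
            expected = [brute_region_label("chr1", int(p), txs) for p in positions]
            assert labels.astype(str).tolist() == expected

    def test_decomposition_covers_transcript_body(self):
        ivs = _transcript_labeled_intervals(self.tx_a)
        body = sorted((s, e) for s, e, lab in ivs if lab != "Promoter")
        covered = set()
        for s, e in body:
            covered.update(range(s, e))
        assert covered == set(range(10_000, 20_000))


class TestCgiStatus:
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [51_000], "name": ["cgi1"]})

    @pytest.mark.parametrize("pos,expected", [
        (50_500, "CGI"),
        (52_000, "shore"),     # 1,000 bp beyond the island edge
        (54_000, "shelf"),     # 3,000 bp beyond
        (56_001, "nonCGI"),    # 5,000 bp beyond
        (49_001, "shore"),     # upstream flank
    ])
    def test_geometry(self, pos, expected):
        status = assign_cgi_status(_probes([pos]), self.cgis)
        assert status.iloc[0] == expected

    def test_nearest_island_precedence_with_overlapping_flanks(self):
        two = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10_000, 14_500],
                            "end": [11_000, 15_000], "name": ["a", "b"]})
        # 3,200 bp right of island a (shelf) but 300 bp left of island b (shore)
        status = assign_cgi_status(_probes([14_201]), two)
        assert status.iloc[0] == "shore"
        inside = assign_cgi_status(_probes([14_600]), two)
        assert inside.iloc[0] == "CGI"

    def test_chromosome_without_islands_is_noncgi(self):
        status = assign_cgi_status(_probes([1_000], chrom="chr9"), self.cgis)
        assert status.iloc[0] == "nonCGI"


class TestCpgDensity:
    @pytest.mark.parametrize("seq,expected", [
        ("CGCGCG", 1.0),
        ("ATATAT", 0.0),
        ("ACGTTACGAA", 0.4),  # CG at offsets 1 and 6; floor(10/2) = 5
    ])
    def test_window_examples(self, seq, expected):
        assert cpg_density(seq) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=60))
    def test_reverse_complement_invariance(self, seq):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        assert cpg_density(seq) == pytest.approx(cpg_density(rc))

    def test_truncated_window_flagged(self):
        genome = {"chr1": "ACGT" * 300}
        dens, truncated = probe_cpg_density(genome, "chr1", 10, window=2000)
        assert truncated
        full, not_truncated = probe_cpg_density(genome, "chr1", 600, window=100)
        assert not not_truncated
        assert full == pytest.approx(0.5)  # CG every 4 bp, denominator len/2


class TestGapDistances:
    gaps = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [0, 4_500, 9_500],
        "end": [500, 5_500, 10_000],
        "name": ["telomere", "centromere", "telomere"],
    })

    def test_inside_centromere_is_zero(self):
        d = gap_distances(_probes([5_000]), self.gaps)
        assert d.loc["P0", "dist_centromere"] == 0

    def test_half_open_edge_arithmetic(self):
        d = gap_distances(_probes([1_000]), self.gaps)
        assert d.loc["P0", "dist_telomere"] == 500

    def test_symmetric_toy_midpoint(self):
        # chromosome length 10,000, telomeres 500 bp each: the probe at the
        # exact midpoint is 4,500 bp from either telomere's inner edge
        d = gap_distances(_probes([5_000]), self.gaps)
        assert d.loc["P0", "dist_telomere"] == 10_000 / 2 - 500

    def test_invariant_to_interval_order(self):
        shuffled = self.gaps.iloc[[2, 0, 1]].reset_index(drop=True)
        d1 = gap_distances(_probes([1_000, 7_000]), self.gaps)
        d2 = gap_distances(_probes([1_000, 7_000]), shuffled)
        pd.testing.assert_frame_equal(d1, d2)

    def test_missing_centromere_yields_nan(self):
        tel_only = self.gaps[self.gaps["name"] == "telomere"]
        d = gap_distances(_probes([1_000]), tel_only)
        assert np.isnan(d.loc["P0", "dist_centromere"])
        assert d.loc["P0", "dist_telomere"] == 500


class TestTrackUtilities:
    def test_bin_averages_scores_of_overlapping_peaks(self):
        track = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [10_000, 50_000, 250_000],
            "end": [20_000, 60_000, 260_000],
            "score": [10.0, 20.0, 7.0],
        })
        out = smooth_track(track, {"chr1": 300_000}, bin_size=100_000)
        assert out.loc[0, "score"] == pytest.approx(15.0)  # peaks 10 and 20
        assert np.isnan(out.loc[1, "score"])               # empty bin
        assert out.loc[2, "score"] == pytest.approx(7.0)

    def test_peak_spanning_two_bins_counts_in_both(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [90_000],
                              "end": [110_000], "score": [4.0]})
        out = smooth_track(track, {"chr1": 200_000}, bin_size=100_000)
        assert out["score"].tolist() == [4.0, 4.0]

    def test_enlarge_centering_and_clipping(self):
        sites = _probes([1_000_000, 30_000])
        out = enlarge_sites(sites, width=200_000, chrom_sizes={"chr1": 1_050_000})
        assert (out.loc["P0", "start"], out.loc["P0", "end"]) == (900_000, 1_050_000)
        assert (out.loc["P1", "start"], out.loc["P1", "end"]) == (0, 130_000)
        mid = enlarge_sites(_probes([1_000_000]), width=200_000,
                            chrom_sizes={"chr1": 5_000_000})
        assert (mid.loc["P0", "start"], mid.loc["P0", "end"]) == (900_000, 1_100_000)

    def test_probe_membership_in_track(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        member = probes_in_track(_probes([101, 200, 250]), track)
        # position 101 -> 0-based 100 (inside); 200 -> 199 (inside, half-open);
        # 250 -> outside
        assert member.tolist() == [True, True, False]
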