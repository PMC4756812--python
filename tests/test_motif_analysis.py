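"""Motif scanning, pair geometry, clustering, disruption and enrichment."""

import numpy as np
import pytest

from allelome.intervals import GenomicInterval
from allelome.motif_analysis import (
    DEFAULT_MOTIF_SET,
    MotifDefinition,
    MotifHit,
    cluster_density,
    cluster_enrichment,
    find_clusters,
    motif_set_from_strings,
    pair_gap,
    pair_orientation,
    peak_motif_summary,
    scan_motifs,
    snp_disruption,
)
from allelome.pseudogenome import HaplotypeGenome, SnpRecord, reverse_complement

TGCCGC = motif_set_from_strings(["TGCCGC"])


def brute_force_scan(seq, motif_set):
    """Sliding-window oracle: test every position against motif and revcomp."""
    hits = []
    seq = seq.upper()
    for m in motif_set:
        rc = reverse_complement(m.sequence)
        for i in range(len(seq) - 5):
            window = seq[i : i + 6]
            if window == m.sequence:
                hits.append((i + 1, "+", m.motif_id))
            if window == rc:
                hits.append((i + 1, "-", m.motif_id))
    return sorted(hits)


class TestScan:
    def test_single_forward_hit(self):
        hits = scan_motifs("TGCCGC", TGCCGC)
        assert [(h.start, h.strand) for h in hits] == [(1, "+")]

    def test_reverse_complement_is_minus_strand_hit(self):
        hits = scan_motifs("GCGGCA", TGCCGC)
        assert [(h.start, h.strand) for h in hits] == [(1, "-")]

    def test_overlapping_inverted_pair(self):
        """GCGGCCGC holds GGCCGC on both strands, overlapping and inverted —
        the architecture seen at the Commd1 ICR."""
        hits = scan_motifs("GCGGCCGC", motif_set_from_strings(["GGCCGC"]))
        assert [(h.start, h.strand) for h in hits] == [(1, "-"), (3, "+")]
        assert pair_orientation(hits[0], hits[1]) == "inverted"

    def test_n_never_matches(self):
        assert scan_motifs("TGCNGC" + "TGCCGC", TGCCGC)[0].start == 7

    def test_non_hexamer_motif_rejected(self):
        with pytest.raises(ValueError):
            MotifDefinition("bad", "TGCCGCA")

    def test_equals_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            hits = scan_motifs(seq, DEFAULT_MOTIF_SET)
            assert [
                (h.start, h.strand, h.motif_id) for h in hits
            ] == brute_force_scan(seq, DEFAULT_MOTIF_SET)

    def test_hit_count_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            fwd = scan_motifs(seq, DEFAULT_MOTIF_SET)
            rev = scan_motifs(reverse_complement(seq), DEFAULT_MOTIF_SET)
            assert len(fwd) == len(rev)
            # positions mirror and strands swap
            mirrored = sorted(
                (len(seq) - h.end + 1, {"+": "-", "-": "+"}[h.strand], h.motif_id)
                for h in fwd
            )
            assert mirrored == sorted((h.start, h.strand, h.motif_id) for h in rev)


class TestPairGeometry:
    def _hits(self, *starts, seq_id="s", strand="+"):
        return [MotifHit(seq_id, s, strand, "TGCCGC") for s in starts]

    @pytest.mark.parametrize("s2,gap", [(10, 3), (7, 0), (3, -4)])
    def test_gap_convention(self, s2, gap):
        h1, h2 = self._hits(1, s2)
        assert pair_gap(h1, h2) == gap

    def test_gap_symmetric_in_argument_order(self):
        h1, h2 = self._hits(1, 10)
        assert pair_gap(h2, h1) == pair_gap(h1, h2)

    def test_different_sequences_rejected(self):
        h1 = MotifHit("a", 1, "+", "TGCCGC")
        h2 = MotifHit("b", 10, "+", "TGCCGC")
        with pytest.raises(ValueError):
            pair_gap(h1, h2)
        with pytest.raises(ValueError):
            pair_orientation(h1, h2)

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [("+", "+", "direct"), ("+", "-", "inverted"), ("-", "-", "direct")],
    )
    def test_orientation(self, s1, s2, expected):
        h1 = MotifHit("s", 1, s1, "TGCCGC")
        h2 = MotifHit("s", 10, s2, "TGCCGC")
        assert pair_orientation(h1, h2) == expected


def transitive_closure_clusters(hits, gap_threshold):
    """Oracle: connected components of the pairwise gap<threshold relation."""
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hits[i].seq_id != hits[j].seq_id:
                continue
            if pair_gap(hits[i], hits[j]) < gap_threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    return sorted(
        [sorted((h.start, h.strand) for h in g) for g in groups.values() if len(g) >= 2]
    )


class TestClusters:
    def _hits(self, *starts):
        return [MotifHit("s", s, "+", "TGCCGC") for s in starts]

    def test_close_pair_forms_cluster(self):
        clusters = find_clusters(self._hits(100, 120))
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_distant_pair_does_not(self):
        assert find_clusters(self._hits(100, 200)) == []

    def test_chaining_example(self):
        clusters = find_clusters(self._hits(100, 130, 160, 300, 330))
        assert [[h.start for h in c.hits] for c in clusters] == [
            [100, 130, 160],
            [300, 330],
        ]

    def test_strict_inequality_at_threshold(self):
        # starts 1 and 45: gap = 45 - 6 - 1 = 38, not < 38
        assert find_clusters(self._hits(1, 45)) == []
        assert len(find_clusters(self._hits(1, 44))) == 1

    def test_start_to_start_convention_switch(self):
        # start-to-start distance 38 is not < 38, but the intervening gap
        # (39 - 6 - 1 = 32) is
        hits = self._hits(1, 39)
        assert len(find_clusters(hits, convention="gap")) == 1
        assert find_clusters(hits, convention="start") == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(0, 50))
            starts = sorted(int(s) for s in rng.integers(1, 2000, size=n))
            hits = [
                MotifHit("s", s, "+" if rng.random() < 0.5 else "-", "TGCCGC")
                for s in starts
            ]
            got = sorted(
                sorted((h.start, h.strand) for h in c.hits)
                for c in find_clusters(hits)
            )
            assert got == transitive_closure_clusters(hits, 38)


class TestSummaryAndEnrichment:
    def test_mean_and_sample_sd(self):
        seqs = {
            "chr1": "A" * 20 + "TGCCGC" + "A" * 74,  # 1 motif
            "chr2": ("A" * 10 + "TGCCGC") * 3 + "A" * 52,  # 3 motifs
        }
        genome = HaplotypeGenome("B6", seqs)
        peaks = [
            GenomicInterval("chr1", 1, 100, "p1"),
            GenomicInterval("chr2", 1, 100, "p2"),
        ]
        out = peak_motif_summary(peaks, genome, TGCCGC)
        assert out["mean_motifs_per_peak"] == 2.0
        assert out["sd_motifs_per_peak"] == pytest.approx(1.4142, abs=1e-4)

    def test_close_pair_fraction_counts_any_close_couple(self):
        # gaps 40 then 10: the peak still counts toward the <38 fraction
        seq = "A" * 4 + "TGCCGC" + "A" * 40 + "TGCCGC" + "A" * 10 + "TGCCGC" + "A" * 28
        genome = HaplotypeGenome("B6", {"chr1": seq})
        out = peak_motif_summary(
            [GenomicInterval("chr1", 1, len(seq), "p")], genome, TGCCGC
        )
        assert out["frac_close_pair_of_multi"] == 1.0

    def test_content_buckets(self):
        genome = HaplotypeGenome(
            "B6",
            {
                "c1": "A" * 10 + "TGCCGC" + "A" * 34,
                "c2": "A" * 10 + "GGCCGC" + "A" * 34,
                "c3": "TGCCGC" + "A" * 10 + "GGCCGC" + "A" * 28,
                "c4": "A" * 50,
            },
        )
        peaks = [GenomicInterval(c, 1, 50, c) for c in genome.sequences]
        out = peak_motif_summary(peaks, genome, DEFAULT_MOTIF_SET)
        assert out["content_counts"] == {
            "TGCCGC_only": 1,
            "GGCCGC_only": 1,
            "both": 1,
            "neither": 1,
        }

    def test_enrichment_fold(self):
        fold, report = cluster_enrichment(2276, 161914)
        assert fold == pytest.approx(71.14, abs=0.01)
        assert report == 71
        assert cluster_enrichment(1234, 1234) == (1.0, 1)

    def test_enrichment_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cluster_enrichment(0, 100)

    def test_density_pipeline_matches_brute_force(self):
        rng = np.random.default_rng(37)
        genome = {
            f"chr{i}": "".join(rng.choice(list("ACGT"), size=5000)) for i in range(3)
        }
        n_clusters, total_bp, bp_per = cluster_density(
            genome.items(), DEFAULT_MOTIF_SET
        )
        oracle = sum(
            len(find_clusters(scan_motifs(s, DEFAULT_MOTIF_SET, seq_id=c)))
            for c, s in genome.items()
        )
        assert n_clusters == oracle
        assert total_bp == 15000
        if n_clusters:
            assert bp_per == pytest.approx(15000 / n_clusters)


def _genome_pair(b6_window, jf1_window, pad=30):
    """Embed allele windows at the same locus of a padded chromosome."""
    left = "ATTATA" * (pad // 6)
    right = "TAATAT" * (pad // 6)
    b6 = HaplotypeGenome("B6", {"chr1": left + b6_window + right})
    jf1 = HaplotypeGenome("JF1", {"chr1": left + jf1_window + right})
    return b6, jf1, len(left)


class TestSnpDisruption:
    def test_cpg_snp_destroys_motif_on_jf1(self):
        b6, jf1, offset = _genome_pair("AATGCCGCTTT", "AATGCAGCTTT")
        snp = SnpRecord("chr1", offset + 6, "C", "A")  # motif position 4
        call = snp_disruption(snp, b6, jf1, TGCCGC)
        assert call is not None
        assert call.lost_in == "JF1"
        assert call.motif_position_affected == 4
        assert call.motif_id == "TGCCGC"

    def test_minus_strand_motif_position(self):
        b6, jf1, offset = _genome_pair("AAGCGGCATTT", "AAGCTGCATTT")
        # forward G>T at offset+5 breaks the minus-strand TGCCGC (position 4)
        snp = SnpRecord("chr1", offset + 5, "G", "T")
        call = snp_disruption(snp, b6, jf1, TGCCGC)
        assert call is not None
        assert call.lost_in == "JF1"
        assert call.permissive_allele_hits[0].strand == "-"
        assert call.motif_position_affected == 4

    def test_no_motif_in_either_window_gives_none(self):
        b6, jf1, offset = _genome_pair("AATTTTTTTTT", "AATTTATTTTT")
        snp = SnpRecord("chr1", offset + 6, "T", "A")
        assert snp_disruption(snp, b6, jf1, TGCCGC) is None

    def test_variant_aware_scanning_explains_strain_specific_loci(self):
        """A SNP toggling TGCCGC<->GGCCGC is a disruption under the canonical
        motif alone but not once the variant is recognized."""
        b6, jf1, offset = _genome_pair("ATGCCGCTTTT", "AGGCCGCTTTT")
        snp = SnpRecord("chr1", offset + 2, "T", "G")
        call_canonical = snp_disruption(snp, b6, jf1, TGCCGC)
        assert call_canonical is not None and call_canonical.lost_in == "JF1"
        assert call_canonical.motif_position_affected == 1
        assert snp_disruption(snp, b6, jf1, DEFAULT_MOTIF_SET) is None

    def test_disruption_reversible_by_other_allele(self):
        """Applying the permissive allele back restores the motif occurrence."""
        from allelome.pseudogenome import apply_snps

        b6, jf1, offset = _genome_pair("AATGCCGCTTT", "AATGCAGCTTT")
        snp = SnpRecord("chr1", offset + 6, "C", "A")
        call = snp_disruption(snp, b6, jf1, TGCCGC)
        restored = apply_snps(jf1, [snp], "B6", ref_haplotype="JF1")
        assert restored.sequences == b6.sequences
        assert snp_disruption(snp, restored, jf1, TGCCGC).lost_in == call.lost_in

    def test_small_flank_rejected(self):
        b6, jf1, offset = _genome_pair("AATGCCGCTTT", "AATGCAGCTTT")
        with pytest.raises(ValueError):
            snp_disruption(SnpRecord("chr1", offset + 6, "C", "A"), b6, jf1, TGCCGC, flank=3)
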