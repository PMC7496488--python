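"""Segmental duplication detection: masking, chunking, self-alignment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cnvsd.intervals import IntervalSet, merge_intervals
from cnvsd.sd import (
    HIT_COLUMNS,
    SdParams,
    chunk_genome,
    detect_sds,
    filter_hits,
    mask_genome,
    merge_sd_regions,
    read_blast_hits,
    sd_summary,
    self_align,
)
from cnvsd.simulate import SimGenomeParams, simulate_genome

from conftest import random_interval_set


@pytest.fixture(scope="module")
def sd_genome():
    """300-kb genome with 6 planted SD pairs; used by several tests."""
    return simulate_genome(
        SimGenomeParams(
            n_chroms=2,
            chrom_length=150_000,
            n_genes=12,
            n_sd_pairs=6,
            sd_length_range=(1500, 4000),
            repeat_fraction=0.15,
            seed=21,
        )
    )


class TestMask:
    def test_empty_annotation_is_identity(self):
        seqs = {"chr1": "ACGTACGT"}
        assert mask_genome(seqs, IntervalSet()) == seqs

    def test_full_chromosome_mask(self):
        seqs = {"chr1": "ACGTACGT"}
        rep = IntervalSet.from_arrays(["chr1"], [0], [8])
        assert mask_genome(seqs, rep)["chr1"] == "N" * 8

    def test_masked_base_count_equals_merged_length(self, rng):
        seqs = {"chr1": "A" * 11_000, "chr2": "C" * 11_000}
        rep = random_interval_set(rng, 60, max_pos=10_000, max_len=400)
        masked = mask_genome(seqs, rep)
        n_masked = sum(s.count("N") for s in masked.values())
        assert n_masked == merge_intervals(rep).total_length()

    def test_out_of_bounds_annotation_named(self):
        seqs = {"chr1": "ACGT"}
        rep = IntervalSet.from_arrays(["chr1"], [2], [100])
        with pytest.raises(ValueError, match="chr1"):
            mask_genome(seqs, rep)


class TestChunk:
    def test_chunk_sizes_and_short_tail(self):
        seqs = {"chr1": "A" * 600_000}
        chunks = chunk_genome(seqs, 250_000)
        assert [(c, o, len(s)) for c, o, s in chunks] == [
            ("chr1", 0, 250_000), ("chr1", 250_000, 250_000), ("chr1", 500_000, 100_000)
        ]

    def test_concatenation_reproduces_chromosome(self, sd_genome):
        chunks = chunk_genome(sd_genome.seqs, 40_000)
        for chrom, seq in sd_genome.seqs.items():
            assert "".join(s for c, o, s in chunks if c == chrom) == seq

    def test_offsets_backmap_chunk_local_hits(self):
        # chunk-local [10, 2010) in the chunk starting at 250,000
        chunks = chunk_genome({"chr1": "A" * 300_000}, 250_000)
        chrom, offset, _ = chunks[1]
        assert (offset + 10, offset + 2010) == (250_010, 252_010)


class TestSelfAlign:
    def test_planted_duplications_recovered_with_identity(self, sd_genome):
        masked = mask_genome(sd_genome.seqs, sd_genome.repeats)
        params = SdParams(chunk_size=50_000)
        hits = filter_hits(self_align(masked, params), params)
        for truth in sd_genome.sd_truth.itertuples():
            matched = False
            for h in hits.itertuples():
                for (qc, qs, qe, sc, ss, se) in (
                    (h.qchrom, h.qstart, h.qend, h.schrom, h.sstart, h.send),
                    (h.schrom, h.sstart, h.send, h.qchrom, h.qstart, h.qend),
                ):
                    cov_a = min(qe, truth.end_a) - max(qs, truth.start_a)
                    cov_b = min(se, truth.end_b) - max(ss, truth.start_b)
                    if (
                        qc == truth.chrom_a
                        and sc == truth.chrom_b
                        and cov_a >= 0.9 * (truth.end_a - truth.start_a)
                        and cov_b >= 0.9 * (truth.end_b - truth.start_b)
                    ):
                        assert abs(h.pident - truth.identity) <= 0.5
                        matched = True
            assert matched, f"planted pair {truth.Index} not recovered"

    def test_fully_masked_genome_yields_no_hits(self):
        masked = {"chr1": "N" * 60_000}
        hits = self_align(masked, SdParams(chunk_size=20_000))
        assert len(hits) == 0

    def test_sd_free_genome_yields_no_regions(self):
        g = simulate_genome(
            SimGenomeParams(
                n_chroms=1, chrom_length=200_000, n_genes=20, n_sd_pairs=0,
                repeat_fraction=0.15, seed=22,
            )
        )
        res = detect_sds(g.seqs, g.repeats, SdParams(chunk_size=100_000))
        assert len(res["regions"]) == 0


class TestFilterHits:
    def _hit(self, qc, qs, qe, sc, ss, se, pident=99.0, length=None):
        length = length or (qe - qs)
        return dict(zip(HIT_COLUMNS, (qc, qs, qe, sc, ss, se, pident, length, length)))

    def test_self_hit_removed(self):
        hits = pd.DataFrame([self._hit("chr1", 0, 2000, "chr1", 0, 2000)])
        assert len(filter_hits(hits)) == 0

    def test_short_hit_removed_at_boundary(self):
        hits = pd.DataFrame([self._hit("chr1", 0, 999, "chr2", 0, 999, pident=99.0)])
        assert len(filter_hits(hits)) == 0
        hits = pd.DataFrame([self._hit("chr1", 0, 1000, "chr2", 0, 1000, pident=99.0)])
        assert len(filter_hits(hits)) == 1

    def test_low_identity_removed(self):
        hits = pd.DataFrame([self._hit("chr1", 0, 2000, "chr2", 0, 2000, pident=94.9)])
        assert len(filter_hits(hits)) == 0

    def test_symmetric_duplicates_canonicalized(self):
        hits = pd.DataFrame(
            [
                self._hit("chr2", 500, 2500, "chr1", 0, 2000),
                self._hit("chr1", 0, 2000, "chr2", 500, 2500),
            ]
        )
        out = filter_hits(hits)
        assert len(out) == 1
        assert out.loc[0, "qchrom"] == "chr1"

    def test_matches_predicate_oracle(self, rng):
        params = SdParams()
        rows = []
        for _ in range(200):
            qc, sc = f"chr{rng.integers(1, 3)}", f"chr{rng.integers(1, 3)}"
            qs = int(rng.integers(0, 50_000))
            length = int(rng.integers(200, 4000))
            if rng.random() < 0.3 and qc == sc:
                ss = qs + int(rng.integers(0, 40))  # near-self diagonal
            else:
                ss = int(rng.integers(0, 50_000))
            rows.append(
                self._hit(qc, qs, qs + length, sc, ss, ss + length,
                          pident=float(rng.uniform(90, 100)))
            )
        hits = pd.DataFrame(rows)
        out = filter_hits(hits, params)
        for h in out.itertuples():  # survivors satisfy all three predicates
            assert h.length >= params.min_length
            assert h.pident >= params.min_identity
            ov = min(h.qend, h.send) - max(h.qstart, h.sstart)
            is_self = (
                h.qchrom == h.schrom
                and abs(h.sstart - h.qstart) <= params.band_width
                and ov > 0.5 * (h.qend - h.qstart)
                and ov > 0.5 * (h.send - h.sstart)
            )
            assert not is_self
        # no surviving predicate-passing hit was dropped (up to symmetry)
        def canon(h):
            a = (h.qchrom, h.qstart, h.qend)
            b = (h.schrom, h.sstart, h.send)
            return (min(a, b), max(a, b))

        expected = set()
        for h in hits.itertuples():
            ov = min(h.qend, h.send) - max(h.qstart, h.sstart)
            is_self = (
                h.qchrom == h.schrom
                and abs(h.sstart - h.qstart) <= params.band_width
                and ov > 0.5 * (h.qend - h.qstart)
                and ov > 0.5 * (h.send - h.sstart)
            )
            if not is_self and h.length >= params.min_length and h.pident >= params.min_identity:
                expected.add(canon(h))
        assert {canon(h) for h in out.itertuples()} == expected


class TestMergeRegions:
    def _hit(self, qc, qs, qe, sc, ss, se, pident=99.0):
        return dict(zip(HIT_COLUMNS, (qc, qs, qe, sc, ss, se, pident, qe - qs, 0)))

    def test_disjoint_hit_gives_two_regions(self):
        hits = pd.DataFrame([self._hit("chr1", 0, 2000, "chr2", 0, 2000)])
        regions = merge_sd_regions(hits)
        assert len(regions) == 2

    def test_shared_side_merges(self):
        hits = pd.DataFrame(
            [
                self._hit("chr1", 0, 2000, "chr2", 0, 2000),
                self._hit("chr1", 1000, 3000, "chr2", 10_000, 12_000),
            ]
        )
        regions = merge_sd_regions(hits)
        assert len(regions) == 3
        chr1 = regions[regions["chrom"] == "chr1"]
        assert chr1[["start", "end"]].to_numpy().tolist() == [[0, 3000]]

    def test_footprint_matches_per_base_oracle(self, rng):
        rows = []
        for _ in range(60):
            qs, ss = int(rng.integers(0, 20_000)), int(rng.integers(0, 20_000))
            l = int(rng.integers(1000, 3000))
            rows.append(self._hit("chr1", qs, qs + l, "chr1", ss, ss + l))
        hits = pd.DataFrame(rows)
        regions = merge_sd_regions(hits)
        base = np.zeros(30_000, dtype=bool)
        for h in hits.itertuples():
            base[h.qstart : h.qend] = True
            base[h.sstart : h.send] = True
        assert int((regions["end"] - regions["start"]).sum()) == int(base.sum())


class TestSummary:
    def test_identical_identities_equal_counts_across_thresholds(self):
        hits = pd.DataFrame(
            [dict(zip(HIT_COLUMNS, ("chr1", 0, 2000, "chr2", 0, 2000, 99.5, 2000, 0)))]
        )
        s = sd_summary(hits, merge_sd_regions(hits), {"chr1": 10_000, "chr2": 10_000})
        assert len(set(s["threshold_counts"].values())) == 1

    def test_threshold_counts_match_direct_filtering(self, rng):
        idents = rng.uniform(95, 100, 300)
        hits = pd.DataFrame(
            [
                dict(zip(HIT_COLUMNS, ("chr1", i * 10, i * 10 + 2000, "chr2", 0, 2000, p, 2000, 0)))
                for i, p in enumerate(idents)
            ]
        )
        s = sd_summary(hits, merge_sd_regions(hits), {"chr1": 10_000, "chr2": 10_000})
        for t in (95, 96, 97, 98, 99):
            assert s["threshold_counts"][f">{t}"] == int((idents > t).sum())
        counts = [s["threshold_counts"][f">{t}"] for t in (95, 96, 97, 98, 99)]
        assert counts == sorted(counts, reverse=True)


class TestBlastIngestion:
    def test_outfmt6_coordinates_converted(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "chr1:1000\tchr2\t97.5\t2000\t50\t0\t11\t2010\t3000\t1001\t0.0\t3000\n"
        )
        hits = read_blast_hits(path)
        h = hits.iloc[0]
        assert (h.qchrom, h.qstart, h.qend) == ("chr1", 1010, 3010)
        assert (h.schrom, h.sstart, h.send) == ("chr2", 1000, 3000)  # minus strand normalized

    @pytest.mark.skipif(shutil.which("blastn") is None, reason="blast not on PATH")
    def test_blastn_external_route_agrees_with_internal_aligner(self, sd_genome, tmp_path):
        """The ingestion path fed by real blastn recovers the same planted
        SD footprint as the internal seed-and-extend aligner."""
        from cnvsd.io import write_fasta

        masked = mask_genome(sd_genome.seqs, sd_genome.repeats)
        db = tmp_path / "genome.fa"
        write_fasta(masked, db)
        chunks = chunk_genome(masked, 50_000)
        qpath = tmp_path / "chunks.fa"
        write_fasta({f"{c}:{o}": s for c, o, s in chunks}, qpath)
        subprocess.run(
            ["makeblastdb", "-in", str(db), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = tmp_path / "blast.tsv"
        subprocess.run(
            ["blastn", "-query", str(qpath), "-db", str(db), "-outfmt", "6",
             "-evalue", "1e-20", "-out", str(out)],
            check=True, capture_output=True,
        )
        params = SdParams(chunk_size=50_000)
        external = filter_hits(read_blast_hits(out), params)
        internal = filter_hits(self_align(masked, params), params)
        reg_ext = merge_sd_regions(external)
        reg_int = merge_sd_regions(internal)

        def footprint(regions):
            base = {c: np.zeros(len(s), bool) for c, s in sd_genome.seqs.items()}
            for r in regions.itertuples():
                base[r.chrom][r.start : r.end] = True
            return base

        fe, fi = footprint(reg_ext), footprint(reg_int)
        inter = sum(int((fe[c] & fi[c]).sum()) for c in fe)
        union = sum(int((fe[c] | fi[c]).sum()) for c in fe)
        assert union > 0
        assert inter / union >= 0.8  # same SD landscape up to end jitter
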