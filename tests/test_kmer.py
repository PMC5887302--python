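import gzip
import itertools
import math

import numpy as np
import pytest

from prism import (
    KmerProfile,
    PrismError,
    ZipfianCoSpectrum,
    assemble_enriched_kmers,
    count_kmers,
    detect_turning_points,
    kmer_probability_model,
    zipfian_cospectrum,
    zipfian_from_profile,
)


def brute_force_counts(seqs, k):
    """Independent enumeration oracle: every clean window of every read."""
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                counts[w] = counts.get(w, 0) + 1
    return counts


class TestCounting:
    def test_spec_example(self):
        p = count_kmers(["ACGTACGTAC"], k=6)
        assert p.counts == {"ACGTAC": 2, "CGTACG": 1, "GTACGT": 1, "TACGTA": 1}
        assert p.total == 5

    def test_n_windows_skipped(self):
        p = count_kmers(["ACGNAC"], k=3)
        assert p.counts == {"ACG": 1}
        assert p.total == 1

    def test_matches_enumeration_oracle(self, rng):
        seqs = [
            "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                               size=rng.integers(20, 150)))
            for _ in range(80)
        ]
        for k in (1, 3, 6):
            p = count_kmers(seqs, k=k)
            assert p.counts == brute_force_counts(seqs, k)

    def test_canonical_folds_strands(self):
        p = count_kmers(["AAA", "TTT"], k=3, canonicalisation="lexmin-of-strand")
        assert p.counts == {"AAA": 2}

    def test_reads_fasta_and_gzip_fastq(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">r1\nACGTACGT\n>r2\nGGGGCCCC\n")
        fq = tmp_path / "x.fastq.gz"
        with gzip.open(fq, "wt") as fh:
            fh.write("@r1\nACGTACGT\n+\nIIIIIIII\n")
        pa = count_kmers(fa, k=4)
        pq = count_kmers(fq, k=4)
        assert pa.total == 10 and pq.total == 5

    def test_malformed_fastq(self, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\nnot-a-plus\nIIII\n")
        with pytest.raises(PrismError, match="parse-error"):
            count_kmers(bad, k=2)

    def test_subsampling_is_per_read_and_consistent(self):
        seqs = ["ACGTACGTAC"] * 400  # 5 6-mer windows each
        full = count_kmers(seqs, k=6).total
        rate = 0.25
        totals = [
            count_kmers(seqs, k=6, sample_rate=rate, seed=s).total
            for s in range(10)
        ]
        # every retained read contributes exactly 5 windows
        assert all(t % 5 == 0 for t in totals)
        exp = rate * full
        sigma = 5 * math.sqrt(400 * rate * (1 - rate))
        assert abs(np.mean(totals) - exp) < 3 * sigma

    def test_empty_sample(self):
        with pytest.raises(PrismError, match="empty-sample"):
            count_kmers(["ACGT"], k=2, sample_rate=1e-9, seed=0)

    def test_profile_tsv_roundtrip(self, tmp_path, small_profile):
        small_profile.to_tsv(tmp_path / "p.tsv")
        back = KmerProfile.from_tsv(tmp_path / "p.tsv")
        assert back.counts == small_profile.counts
        assert back.k == small_profile.k and back.total == small_profile.total


class TestProbabilityAndZipf:
    def test_probabilities_from_profile(self):
        p = count_kmers(["ACGTACGTAC"], k=6)
        m = kmer_probability_model(p, "f")
        assert m.probability("ACGTAC") == pytest.approx(0.4)
        assert -math.log(0.4) == pytest.approx(0.9163, abs=5e-5)

    def test_single_kmer_certainty(self):
        m = kmer_probability_model(KmerProfile(2, {"AA": 7}, 7), "f")
        z = zipfian_cospectrum(m)
        assert z.h[0] == 0.0

    def test_rank_order_and_tie_break(self, small_profile):
        z = zipfian_from_profile(small_profile, "m")
        assert z.bins == ["AA", "AC", "AG"]  # AC before AG on equal counts
        assert z.ranks.tolist() == [1, 2, 3]
        assert np.allclose(z.h, [-math.log(0.5), -math.log(0.25), -math.log(0.25)])

    def test_h_non_decreasing(self, rng):
        counts = {f"{a}{b}": int(c) for (a, b), c in zip(
            itertools.product("ACGT", repeat=2),
            rng.integers(1, 100, size=16))}
        z = zipfian_from_profile(KmerProfile(2, counts, sum(counts.values())), "m")
        assert (np.diff(z.h) >= -1e-12).all()

    def test_uniform_is_flat(self, uniform_model_4096):
        z = zipfian_cospectrum(uniform_model_4096)
        assert len(z.ranks) == 4096
        assert np.allclose(z.h, math.log(4096))


def power_law_cospectrum(d=400, alpha=0.8):
    ranks = np.arange(1, d + 1)
    p = ranks ** (-alpha)
    p = p / p.sum()
    bins = [f"w{r:04d}" for r in ranks]
    return ZipfianCoSpectrum("pl", k=4, total=10000, ranks=ranks,
                             h=-np.log(p), bins=bins)


class TestTurningPoints:
    def test_exact_power_law_has_none(self):
        assert detect_turning_points(power_law_cospectrum()) == []

    def test_linear_ramp_has_none(self):
        d = 300
        ranks = np.arange(1, d + 1)
        h = 2.0 + 0.5 * np.log(ranks)
        z = ZipfianCoSpectrum("lin", k=4, total=1000, ranks=ranks, h=h,
                              bins=[f"w{r}" for r in ranks])
        assert detect_turning_points(z) == []

    def test_planted_step_is_found(self):
        # low-h plateau for ranks 1..40, then a jump: an adapter-like step
        d = 1000
        ranks = np.arange(1, d + 1)
        h = np.where(ranks <= 40, 5.0, 7.0 + 0.3 * np.log(ranks / 40.0))
        z = ZipfianCoSpectrum("step", k=4, total=10**5, ranks=ranks, h=h,
                              bins=[f"w{r:05d}" for r in ranks])
        tps = detect_turning_points(z)
        assert tps, "step not detected"
        best_rank = tps[0][0]
        assert 20 <= best_rank <= 80

    def test_too_few_points(self):
        z = power_law_cospectrum(d=10)
        with pytest.raises(PrismError, match="insufficient-points"):
            detect_turning_points(z, window=9)


class TestAssembly:
    def test_tiling_reconstruction(self):
        s = "ACGTACGTTGCA"
        counts = brute_force_counts([s], 6)
        prof = KmerProfile(6, counts, sum(counts.values()))
        assert assemble_enriched_kmers(prof) == [s]

    def test_random_string_reconstruction(self, rng):
        # unique k-mers guarantee an unambiguous greedy reconstruction
        for _ in range(5):
            s = "".join(rng.choice(list("ACGT"), size=60))
            counts = brute_force_counts([s], 8)
            if len(counts) != 60 - 8 + 1:
                continue  # repeated k-mer: reconstruction not unique
            prof = KmerProfile(8, counts, sum(counts.values()))
            contigs = assemble_enriched_kmers(prof)
            assert contigs[0] == s

    def test_disjoint_sets_give_two_contigs(self):
        counts = {**brute_force_counts(["AAACAAA"], 4),
                  **brute_force_counts(["GGGTGGG"], 4)}
        prof = KmerProfile(4, counts, sum(counts.values()))
        contigs = assemble_enriched_kmers(prof)
        assert sorted(contigs) == ["AAACAAA", "GGGTGGG"]

    def test_singleton_selection(self, small_profile):
        z = zipfian_from_profile(small_profile, "m")
        assert assemble_enriched_kmers(z, rank_range=(1, 1)) == ["AA"]

    def test_empty_selection(self, small_profile):
        with pytest.raises(PrismError, match="empty-selection"):
            assemble_enriched_kmers(small_profile, rank_range=(50, 60))
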