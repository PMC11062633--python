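"""Genomic co-enrichment: overlap, ratio tracks, metagenes, calls.

The overlap sweep is validated against an all-pairs brute-force oracle
and, on file-based fixtures, against pyranges as an independent library
cross-check.
"""

import numpy as np
import pandas as pd
import pytest

from monomark import (
    GeneModel,
    GenomeTruthModel,
    PeakSet,
    SignalTrack,
    TrackSpec,
    call_coenrichment,
    coenrichment_table,
    kmeans_profiles,
    overlap_fraction,
    pairwise_overlap_spearman,
    read_genes,
    read_peaks,
    read_track,
    scaled_gene_matrix,
    signal_ratio_track,
    simulate_genomic_data,
    simulate_profile_groups,
    track_correlation,
)
from monomark.errors import CoordinateError, CorrelationError, GenomeError


def brute_force_overlap_count(a: PeakSet, b: PeakSet) -> int:
    """O(n*m) all-pairs half-open overlap check."""
    count = 0
    for chrom, arr in a.intervals.items():
        b_arr = b.intervals.get(chrom, [])
        for s, e in arr:
            if any(s < be and bs < e for bs, be in b_arr):
                count += 1
    return count


def random_peakset(rng, label, n, chrom_names=("chr1", "chr2"), span=10_000):
    intervals = {}
    for chrom in chrom_names:
        starts = rng.integers(0, span, size=n // len(chrom_names))
        lengths = rng.integers(1, 400, size=len(starts))
        intervals[chrom] = np.column_stack([starts, starts + lengths])
    return PeakSet(label, intervals)


# -- readers ----------------------------------------------------------------


def test_read_peaks_sorts_and_validates(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t50\t100\nchr1\t10\t20\nchr2\t0\t5\n")
    ps = read_peaks(bed, label="A")
    assert len(ps) == 3
    assert ps.intervals["chr1"][0].tolist() == [10, 20]

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t-5\t10\n")
    with pytest.raises(CoordinateError):
        read_peaks(bad)


def test_read_genes_strand_semantics(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t200\tgA\t0\t+\nchr1\t300\t400\tgB\t0\t-\n")
    genes = read_genes(bed)
    assert genes[0].tss == 100 and genes[0].tes == 199
    assert genes[1].tss == 399 and genes[1].tes == 300


def test_read_track_length_weighted_rebinning(tmp_path):
    # 10 bp bins: [0,10) fully covered at 4; [10,20) covered 5bp at 4 and
    # 5bp at 8 -> 6; [20,30) covered 5bp at 8, rest 0 -> 4; [30,40) value 2
    bg = tmp_path / "a.bedgraph"
    bg.write_text("chr1\t0\t15\t4\nchr1\t15\t25\t8\nchr1\t30\t40\t2\n")
    track = read_track(bg, bin_size=10)
    assert np.allclose(track.values["chr1"], [4.0, 6.0, 4.0, 2.0])


# -- overlap ----------------------------------------------------------------


def test_overlap_fraction_worked_examples():
    a = PeakSet("a", {"chr1": [[0, 10], [20, 30]]})
    b = PeakSet("b", {"chr1": [[9, 12]]})
    assert overlap_fraction(a, a) == 1.0
    assert overlap_fraction(a, b) == 0.5
    # abutting half-open intervals do not overlap
    left = PeakSet("l", {"chr1": [[0, 10]]})
    right = PeakSet("r", {"chr1": [[10, 20]]})
    assert overlap_fraction(left, right) == 0.0


def test_overlap_fraction_empty_set_rejected():
    with pytest.raises(CoordinateError):
        overlap_fraction(PeakSet("e", {}), PeakSet("b", {"chr1": [[0, 5]]}))


def test_overlap_sweep_matches_brute_force(rng):
    """Sweep equals O(n*m) enumeration exactly on random interval sets."""
    for _ in range(200):
        a = random_peakset(rng, "a", int(rng.integers(2, 40)))
        b = random_peakset(rng, "b", int(rng.integers(2, 40)))
        expected = brute_force_overlap_count(a, b) / len(a)
        assert overlap_fraction(a, b) == expected


def test_overlap_invariant_to_input_order(rng):
    a = random_peakset(rng, "a", 30)
    b = random_peakset(rng, "b", 30)
    shuffled = {c: arr[rng.permutation(len(arr))] for c, arr in a.intervals.items()}
    assert overlap_fraction(PeakSet("a", shuffled), b) == overlap_fraction(a, b)


def test_overlap_matches_pyranges(tmp_path, rng):
    """Library cross-check: count of a-peaks hit by b via pyranges."""
    pr = pytest.importorskip("pyranges")
    a = random_peakset(rng, "a", 40)
    b = random_peakset(rng, "b", 40)

    def to_pr(ps):
        rows = [
            (c, s, e) for c, arr in ps.intervals.items() for s, e in arr
        ]
        df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
        return pr.PyRanges(df)

    hits = to_pr(a).overlap(to_pr(b))
    # pyranges.overlap keeps a-intervals with >=1bp overlap (duplicates possible)
    n_hit = len(hits.df.drop_duplicates()) if len(hits) else 0
    assert overlap_fraction(a, b) == pytest.approx(n_hit / len(a))


def test_pairwise_matrix_identity_and_design():
    a = PeakSet("a", {"chr1": [[0, 10], [20, 30]]})
    F, S = pairwise_overlap_spearman([a, PeakSet("b", dict(a.intervals))])
    assert np.allclose(F.to_numpy(), 1.0)
    assert np.allclose(S.to_numpy(), 1.0)


def test_designed_overlap_recovered_within_binomial_bound():
    truth = GenomeTruthModel(
        track_specs=[
            TrackSpec("first", n_peaks=500),
            TrackSpec("second", n_peaks=500, overlap_with_first=0.6),
        ],
        seed=21,
    )
    genome = simulate_genomic_data(truth)
    realized = overlap_fraction(genome.peak_sets["second"], genome.peak_sets["first"])
    half_width = 1.96 * np.sqrt(0.6 * 0.4 / 500)
    assert abs(realized - 0.6) <= half_width


def test_designed_overlap_one_gives_overlapping_sets():
    truth = GenomeTruthModel(
        track_specs=[
            TrackSpec("first", n_peaks=50),
            TrackSpec("second", n_peaks=50, overlap_with_first=1.0),
        ],
        seed=2,
    )
    genome = simulate_genomic_data(truth)
    assert overlap_fraction(genome.peak_sets["second"], genome.peak_sets["first"]) == 1.0


# -- tracks -----------------------------------------------------------------


def test_ratio_track_identities():
    ip = SignalTrack(50, {"chr1": np.array([3.0, 1.0, 4.0])})
    same = signal_ratio_track(ip, ip, bin_size=50)
    assert np.allclose(same.values["chr1"], 0.0)

    control = SignalTrack(50, {"chr1": np.array([1.0, 1.0, 1.0])})
    fwd = signal_ratio_track(ip, control, bin_size=50, pseudocount=1.0)
    rev = signal_ratio_track(control, ip, bin_size=50, pseudocount=1.0)
    assert np.allclose(fwd.values["chr1"], -rev.values["chr1"])
    # hand-computed single bin: log2((3+1)/(1+1)) = 1
    assert fwd.values["chr1"][0] == pytest.approx(1.0)


def test_ratio_track_mismatched_chromosomes(toy_layout):
    ip = SignalTrack(50, {"chr1": np.ones(4)})
    ctrl = SignalTrack(50, {"chr2": np.ones(4)})
    with pytest.raises(GenomeError):
        signal_ratio_track(ip, ctrl)


def test_track_correlation_identity_and_sign(rng):
    v = rng.poisson(5, 4000).astype(float) + 1
    t1 = SignalTrack(1000, {"chr1": v})
    t2 = SignalTrack(1000, {"chr1": v.copy()})
    t3 = SignalTrack(1000, {"chr1": -v + 100.0})
    m = track_correlation([t1, t2, t3], bin_size=1000)
    assert m[0, 1] == pytest.approx(1.0)
    assert m[0, 2] == pytest.approx(-1.0)


def test_track_correlation_recovers_designed_correlation():
    rng = np.random.default_rng(8)
    n = 2000
    x = rng.normal(10, 3, n)
    y = 0.8 * (x - 10) / 3 * 3 + np.sqrt(1 - 0.8**2) * rng.normal(0, 3, n) + 10
    m = track_correlation(
        [SignalTrack(1000, {"c": x}), SignalTrack(1000, {"c": y})], bin_size=1000
    )
    assert abs(m[0, 1] - 0.8) < 0.05


def test_track_correlation_constant_rejected():
    t1 = SignalTrack(1000, {"c": np.arange(10.0)})
    t2 = SignalTrack(1000, {"c": np.full(10, 2.0)})
    with pytest.raises(CorrelationError):
        track_correlation([t1, t2], bin_size=1000)


# -- metagenes --------------------------------------------------------------


def make_track(values, bin_size=50):
    return SignalTrack(bin_size, {"chr1": np.asarray(values, dtype=float)})


def test_scaled_matrix_constant_field():
    track = make_track(np.full(400, 2.5))
    genes = [GeneModel("g1", "chr1", 8000, 12000, "+")]
    mat = scaled_gene_matrix(track, genes, flank_bp=2000, body_bins=10, flank_bins=4)
    assert np.allclose(mat.matrix, 2.5)


def test_scaled_matrix_body_only_enrichment():
    values = np.zeros(400)
    values[160:240] = 7.0  # body 8000-12000 at 50bp bins
    track = make_track(values)
    genes = [GeneModel("g1", "chr1", 8000, 12000, "+")]
    mat = scaled_gene_matrix(track, genes, flank_bp=2000, body_bins=10, flank_bins=4)
    row = mat.matrix[0]
    assert np.allclose(row[4:14], 7.0)
    assert np.allclose(row[:4], 0.0) and np.allclose(row[14:], 0.0)


def test_scaled_matrix_minus_strand_reversed():
    values = np.zeros(400)
    values[160:170] = 9.0  # 5' end of a minus-strand gene ending at 12000? no:
    # gene 8000-12000 on '-': TSS at 11999, so signal at 8000-8500 is the TES side
    track = make_track(values)
    gene_plus = GeneModel("g1", "chr1", 8000, 12000, "+")
    gene_minus = GeneModel("g2", "chr1", 8000, 12000, "-")
    mat = scaled_gene_matrix(track, [gene_plus, gene_minus],
                             flank_bp=2000, body_bins=10, flank_bins=4)
    plus_row, minus_row = mat.matrix
    # the same genomic signal sits TSS-proximal for + and TES-proximal for -
    assert plus_row[4] > 0 and np.allclose(minus_row[4:8], 0.0)
    assert minus_row[13] > 0
    assert np.allclose(plus_row, minus_row[::-1])


def test_scaled_matrix_translation_invariance():
    rng = np.random.default_rng(3)
    values = rng.poisson(4, 400).astype(float)
    shift_bins = 40  # 2000 bp at 50 bp bins
    track = make_track(values)
    shifted = make_track(np.concatenate([np.zeros(shift_bins), values]))
    g = GeneModel("g", "chr1", 8000, 12000, "+")
    g_shift = GeneModel("g", "chr1", 10000, 14000, "+")
    m0 = scaled_gene_matrix(track, [g], flank_bp=1000, body_bins=10, flank_bins=4)
    m1 = scaled_gene_matrix(shifted, [g_shift], flank_bp=1000, body_bins=10, flank_bins=4)
    assert np.allclose(m0.matrix, m1.matrix)


def test_kmeans_recovers_separated_groups():
    from sklearn.metrics import adjusted_rand_score

    X, labels = simulate_profile_groups(seed=5)
    assignment = kmeans_profiles(X, k=3, seed=0)
    assert adjusted_rand_score(labels, assignment.labels.to_numpy()) >= 0.99
    # cluster 1 is the highest-signal group (true group 0, mean 10)
    cluster1 = assignment.labels[assignment.labels == 1].index.astype(int)
    assert set(labels[cluster1]) == {0}


def test_kmeans_degenerate_and_deterministic():
    X, _ = simulate_profile_groups(n_per_group=10, seed=1)
    one = kmeans_profiles(X, k=1, seed=0)
    assert set(one.labels) == {1}

    dup = np.vstack([X, X[:5]])
    asn = kmeans_profiles(dup, k=3, seed=4)
    for i in range(5):
        assert asn.labels.iloc[len(X) + i] == asn.labels.iloc[i]
    again = kmeans_profiles(dup, k=3, seed=4)
    assert asn.labels.equals(again.labels)


def test_genomic_simulation_cluster_truth_recovered():
    from sklearn.metrics import adjusted_rand_score

    truth = GenomeTruthModel(
        track_specs=[TrackSpec("mark", shape="body-uniform", n_peaks=0)], seed=3
    )
    genome = simulate_genomic_data(truth)
    mat = scaled_gene_matrix(genome.ip_tracks["mark"], genome.genes)
    assignment = kmeans_profiles(mat, k=3, seed=0)
    true_groups = genome.gene_groups.loc[mat.gene_ids]
    assert adjusted_rand_score(true_groups, assignment.labels) >= 0.99


def test_promoter_shape_peaks_at_tss():
    truth = GenomeTruthModel(
        track_specs=[TrackSpec("mark", shape="promoter-peaked", n_peaks=0)], seed=3
    )
    genome = simulate_genomic_data(truth)
    mat = scaled_gene_matrix(genome.ip_tracks["mark"], genome.genes)
    strong = genome.gene_groups.loc[mat.gene_ids] == 0
    rows = mat.matrix[strong.to_numpy()]
    tss_bin = mat.flank_bins  # first body bin
    mid_body = mat.flank_bins + mat.body_bins // 2
    assert rows[:, tss_bin].mean() > 2 * rows[:, mid_body].mean()


# -- co-enrichment calls ----------------------------------------------------


def test_coenrichment_promoter_vs_body_modes():
    genes = [GeneModel("g1", "chr1", 1000, 5000, "+")]
    parp = PeakSet("PARP1", {"chr1": [[900, 1100]]})        # promoter only
    mark = PeakSet("H4K20me1", {"chr1": [[3000, 4000]]})    # body only

    (call_p,) = call_coenrichment([parp, mark], genes, 250, "promoter")
    assert call_p.promoter_flags == {"PARP1": True, "H4K20me1": False}
    assert not call_p.co_enriched

    (call_b,) = call_coenrichment([parp, mark], genes, 250, "body")
    assert not call_b.co_enriched

    both_body = PeakSet("PARP1", {"chr1": [[3100, 3200]]})
    (call_ok,) = call_coenrichment([both_body, mark], genes, 250, "body")
    assert call_ok.co_enriched


def test_coenrichment_peak_on_tss():
    genes = [GeneModel("g1", "chr1", 1000, 5000, "+")]
    ps = PeakSet("x", {"chr1": [[1000, 1001]]})
    (call,) = call_coenrichment([ps], genes, 250, "promoter")
    assert call.promoter_flags["x"]


def test_coenrichment_minus_strand_promoter():
    genes = [GeneModel("g1", "chr1", 1000, 5000, "-")]  # TSS at 4999
    ps = PeakSet("x", {"chr1": [[4990, 5010]]})
    (call,) = call_coenrichment([ps], genes, 250, "promoter")
    assert call.promoter_flags["x"]
    far = PeakSet("x", {"chr1": [[900, 1100]]})  # TES side
    (call2,) = call_coenrichment([far], genes, 250, "promoter")
    assert not call2.promoter_flags["x"]
    assert call2.body_flags["x"]


def test_coenrichment_table_shape():
    genes = [GeneModel(f"g{i}", "chr1", 1000 * i + 1000, 1000 * i + 1800, "+")
             for i in range(5)]
    ps = PeakSet("x", {"chr1": [[0, 100_000]]})
    table = coenrichment_table(call_coenrichment([ps], genes))
    assert list(table.columns) == ["gene_id", "co_enriched", "promoter_x", "body_x"]
    assert table["co_enriched"].all()
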