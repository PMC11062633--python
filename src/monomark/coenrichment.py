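"""Genomic co-enrichment engine.

Consumes called peaks (BED), binned coverage (bedGraph) and a gene model,
and computes the genomic summaries used to relate PARP-1 occupancy to
histone-mark occupancy:

* directed peak-overlap fractions and a Spearman correlation of the
  rows of the fraction matrix;
* log2 IP/input ratio tracks on a fixed bin grid (50 bp by default) and
  genome-wide track correlation on a coarser grid (10 kb by default);
* scaled-region (metagene) signal matrices — fixed-width flanks plus a
  length-normalized gene body — with seeded k-means clustering of genes,
  clusters relabeled so that cluster 1 carries the highest mean signal;
* promoter / gene-body co-enrichment calls per gene, the conjunction of
  per-factor overlap flags in the chosen region mode.

All coordinates are 0-based half-open (BED convention); abutting
intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (
    CoordinateError,
    CorrelationError,
    FormatError,
    GenomeError,
)

# ---------------------------------------------------------------------------
# interval containers


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("empty chromosome name")
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"bad interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"unknown strand {self.strand!r}")


@dataclass
class PeakSet:
    """Labelled peak intervals, per chromosome, sorted by start."""

    label: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and ((arr[:, 0] < 0).any() or (arr[:, 0] >= arr[:, 1]).any()):
                raise CoordinateError(f"{self.label}/{chrom}: start >= end or negative")
            clean[chrom] = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        self.intervals = clean

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome union of intervals (sorted, non-overlapping)."""
        out = {}
        for chrom, arr in self.intervals.items():
            if not len(arr):
                out[chrom] = arr
                continue
            merged = [list(arr[0])]
            for s, e in arr[1:]:
                if s < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.array(merged, dtype=np.int64)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS and TES (both 0-based bp)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(f"gene {self.gene_id}: bad interval")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Fixed-step binned coverage: per chromosome one value per bin."""

    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        self.values = {
            c: np.asarray(v, dtype=float) for c, v in self.values.items()
        }
        for chrom, v in self.values.items():
            if not np.isfinite(v).all():
                raise ValueError(f"track {chrom}: non-finite bin values")

    def rebin(self, new_bin_size: int) -> "SignalTrack":
        """Aggregate to a coarser grid by averaging; pads the tail with zeros."""
        if new_bin_size == self.bin_size:
            return self
        if new_bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the current one")
        factor = new_bin_size // self.bin_size
        out = {}
        for chrom, v in self.values.items():
            n = int(np.ceil(len(v) / factor))
            padded = np.zeros(n * factor)
            padded[: len(v)] = v
            out[chrom] = padded.reshape(n, factor).mean(axis=1)
        return SignalTrack(bin_size=new_bin_size, values=out)

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Per-bp mean signal over [start, end); out-of-bounds bp count as 0."""
        if end <= start:
            raise CoordinateError("empty region")
        v = self.values.get(chrom)
        if v is None:
            return 0.0
        bs = self.bin_size
        total = 0.0
        first = max(start // bs, 0)
        last = min((end - 1) // bs, len(v) - 1)
        for b in range(first, last + 1):
            ov = min(end, (b + 1) * bs) - max(start, b * bs)
            if ov > 0:
                total += v[b] * ov
        return total / (end - start)


# ---------------------------------------------------------------------------
# readers


def read_peaks(path: Union[str, Path], label: str | None = None) -> PeakSet:
    """Read a BED file (first three columns) into a :class:`PeakSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError("BED needs at least chrom/start/end columns")
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in zip(df[0], df[1], df[2]):
        try:
            s, e = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"non-integer coordinate in {chrom}") from exc
        intervals.setdefault(chrom, []).append((s, e))
    return PeakSet(
        label=label or Path(path).stem,
        intervals={c: np.array(v, dtype=np.int64) for c, v in intervals.items()},
    )


def read_genes(path: Union[str, Path]) -> list[GeneModel]:
    """Read a BED6-like gene table: chrom start end gene_id score strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise FormatError("gene BED needs 6 columns (chrom start end name score strand)")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row[3],
                chrom=row[0],
                start=int(row[1]),
                end=int(row[2]),
                strand=row[5],
            )
        )
    return genes


def read_track(path: Union[str, Path], bin_size: int) -> SignalTrack:
    """Read a bedGraph and re-bin it to ``bin_size`` by length-weighted mean.

    Regions the bedGraph does not cover contribute zero, so a bin's value
    is sum(value x overlap bp) / bin_size.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise CoordinateError("bedGraph has start >= end or negative start")
    values: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n_bins = int(np.ceil(sub["end"].max() / bin_size))
        acc = np.zeros(n_bins)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                acc[b] += v * ov
        values[chrom] = acc / bin_size
    return SignalTrack(bin_size=bin_size, values=values)


def write_track(track: SignalTrack, path: Union[str, Path]) -> None:
    """Write a track as a fixed-step bedGraph (zero bins included)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            for b, v in enumerate(track.values[chrom]):
                fh.write(
                    f"{chrom}\t{b * track.bin_size}\t{(b + 1) * track.bin_size}\t{v:g}\n"
                )


# ---------------------------------------------------------------------------
# overlap statistics


def _count_overlapping(a_arr: np.ndarray, b_merged: np.ndarray) -> int:
    """Number of a-intervals overlapping >=1 bp of the merged b intervals.

    Sorted-sweep via searchsorted on the merged, non-overlapping b starts:
    a overlaps iff the closest b interval starting before a.end extends
    past a.start (half-open on both sides).
    """
    if not len(a_arr) or not len(b_merged):
        return 0
    starts, ends = b_merged[:, 0], b_merged[:, 1]
    idx = np.searchsorted(starts, a_arr[:, 1], side="left") - 1
    valid = idx >= 0
    hits = np.zeros(len(a_arr), dtype=bool)
    hits[valid] = ends[idx[valid]] > a_arr[valid, 0]
    return int(hits.sum())


def overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of a's peaks overlapping at least 1 bp of some peak in b."""
    total = len(a)
    if total == 0:
        raise CoordinateError(f"peak set {a.label!r} is empty: fraction undefined")
    b_merged = b.merged()
    count = sum(
        _count_overlapping(arr, b_merged.get(chrom, np.empty((0, 2), dtype=np.int64)))
        for chrom, arr in a.intervals.items()
    )
    return count / total


def pairwise_overlap_spearman(
    sets: Sequence[PeakSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed overlap-fraction matrix F and Spearman correlation of its rows.

    ``F[i, j]`` is the fraction of set i's peaks overlapping set j (not
    symmetric).  ``S[i, j]`` is the Spearman rank correlation between rows
    i and j of F; identical rows score 1 even when constant.
    """
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    labels = [s.label for s in sets]
    n = len(sets)
    F = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                F[i, j] = overlap_fraction(sets[i], sets[j])
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(F[i], F[j]):
                rho = 1.0
            else:
                rho = float(stats.spearmanr(F[i], F[j]).statistic)
            S[i, j] = S[j, i] = rho
    return (
        pd.DataFrame(F, index=labels, columns=labels),
        pd.DataFrame(S, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# signal tracks


def signal_ratio_track(
    ip: SignalTrack,
    control: SignalTrack,
    bin_size: int = 50,
    pseudocount: float = 1.0,
) -> SignalTrack:
    """log2((IP + psi) / (control + psi)) per bin on a common grid."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ip = ip.rebin(bin_size) if ip.bin_size != bin_size else ip
    control = control.rebin(bin_size) if control.bin_size != bin_size else control
    if set(ip.values) != set(control.values):
        raise GenomeError(
            f"chromosome sets differ: {sorted(ip.values)} vs {sorted(control.values)}"
        )
    out = {}
    for chrom in ip.values:
        a, b = ip.values[chrom], control.values[chrom]
        n = max(len(a), len(b))
        pa, pb = np.zeros(n), np.zeros(n)
        pa[: len(a)], pb[: len(b)] = a, b
        out[chrom] = np.log2((pa + pseudocount) / (pb + pseudocount))
    return SignalTrack(bin_size=bin_size, values=out)


def track_correlation(
    tracks: Sequence[SignalTrack],
    bin_size: int = 10_000,
    method: str = "pearson",
) -> np.ndarray:
    """Genome-wide correlation matrix of tracks on a common coarse grid.

    Bins where every track is zero are dropped before correlating.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    rebinned = [t.rebin(bin_size) for t in tracks]
    chroms = set(rebinned[0].values)
    for t in rebinned[1:]:
        if set(t.values) != chroms:
            raise GenomeError("tracks cover different chromosome sets")
    columns = []
    for chrom in sorted(chroms):
        n = max(len(t.values[chrom]) for t in rebinned)
        block = np.zeros((len(tracks), n))
        for i, t in enumerate(rebinned):
            v = t.values[chrom]
            block[i, : len(v)] = v
        columns.append(block)
    data = np.concatenate(columns, axis=1)
    keep = ~(data == 0).all(axis=0)
    data = data[:, keep]
    if data.shape[1] < 3:
        raise CorrelationError("too few informative bins")
    if np.any(np.ptp(data, axis=1) == 0):
        raise CorrelationError("constant track: correlation undefined")
    if method == "pearson":
        return np.corrcoef(data)
    if method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, data)
        return np.corrcoef(ranks)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# metagene matrices and clustering


@dataclass
class ScaledProfileMatrix:
    """Genes x bins signal matrix in scaled-region (metagene) layout.

    Columns run 5' flank -> scaled body -> 3' flank; minus-strand genes
    are reversed so every row reads TSS to TES left to right.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    flank_bp: int
    body_bins: int
    flank_bins: int
    out_of_bounds: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.body_bins + 2 * self.flank_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids)


def _region_bin_means(
    track: SignalTrack, chrom: str, start: float, end: float, n_bins: int
) -> np.ndarray:
    edges = np.linspace(start, end, n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        s, e = int(round(edges[i])), int(round(edges[i + 1]))
        out[i] = track.region_mean(chrom, s, e) if e > s else 0.0
    return out


def scaled_gene_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    body_bins: int = 50,
    flank_bins: int = 20,
) -> ScaledProfileMatrix:
    """Per-gene metagene row: averaged flanks plus a rescaled gene body.

    The upstream flank is averaged into ``flank_bins`` equal windows, the
    body is linearly rescaled into ``body_bins`` windows, the downstream
    flank mirrors the upstream.  Positions outside the track contribute
    zero and the gene is flagged in ``out_of_bounds``.
    """
    rows, ids, oob = [], [], []
    for gene in genes:
        if gene.length < 1:
            warnings.warn(f"gene {gene.gene_id}: empty body, skipped", stacklevel=2)
            continue
        chrom = gene.chrom
        left = _region_bin_means(track, chrom, gene.start - flank_bp, gene.start, flank_bins)
        body = _region_bin_means(track, chrom, gene.start, gene.end, body_bins)
        right = _region_bin_means(track, chrom, gene.end, gene.end + flank_bp, flank_bins)
        row = np.concatenate([left, body, right])
        if gene.strand == "-":
            row = row[::-1]
        n_track = len(track.values.get(chrom, ())) * track.bin_size
        if gene.start - flank_bp < 0 or gene.end + flank_bp > n_track:
            oob.append(gene.gene_id)
        rows.append(row)
        ids.append(gene.gene_id)
    return ScaledProfileMatrix(
        matrix=np.array(rows),
        gene_ids=ids,
        flank_bp=flank_bp,
        body_bins=body_bins,
        flank_bins=flank_bins,
        out_of_bounds=oob,
    )


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k, cluster 1 = highest mean signal) plus
    the display row order (cluster ascending, row mean descending)."""

    labels: pd.Series
    order: list[str]
    k: int


def kmeans_profiles(
    matrix: Union[ScaledProfileMatrix, np.ndarray, pd.DataFrame],
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Seeded k-means over metagene rows with signal-ordered relabeling.

    Clusters are renumbered so cluster 1 has the highest mean row signal
    (ties broken by original label); the returned order sorts genes by
    cluster and then by descending row mean, matching heatmap display.
    """
    if isinstance(matrix, ScaledProfileMatrix):
        X, ids = matrix.matrix, matrix.gene_ids
    elif isinstance(matrix, pd.DataFrame):
        X, ids = matrix.to_numpy(float), list(matrix.index.astype(str))
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(len(X))]
    if not np.isfinite(X).all():
        raise ValueError("profile matrix contains non-finite values")
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} incompatible with {len(X)} genes")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    cluster_means = np.array([X[raw == c].mean() for c in range(k)])
    rank = {c: i + 1 for i, c in enumerate(np.argsort(-cluster_means, kind="stable"))}
    labels = pd.Series([rank[c] for c in raw], index=ids, name="cluster")

    row_means = X.mean(axis=1)
    order_idx = sorted(
        range(len(ids)), key=lambda i: (labels.iloc[i], -row_means[i], ids[i])
    )
    return ClusterAssignment(labels=labels, order=[ids[i] for i in order_idx], k=k)


# ---------------------------------------------------------------------------
# co-enrichment calls


@dataclass(frozen=True)
class CoEnrichmentCall:
    """Per-gene promoter/body overlap flags per peak set plus the conjunction."""

    gene_id: str
    promoter_flags: dict[str, bool]
    body_flags: dict[str, bool]
    region_mode: str
    co_enriched: bool


def _overlaps_region(
    merged: dict[str, np.ndarray], chrom: str, start: int, end: int
) -> bool:
    start = max(start, 0)
    if end <= start:
        return False
    arr = merged.get(chrom)
    if arr is None or not len(arr):
        return False
    idx = int(np.searchsorted(arr[:, 0], end, side="left")) - 1
    return idx >= 0 and arr[idx, 1] > start


def gene_regions(gene: GeneModel, promoter_window_bp: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Strand-aware (promoter, body) half-open intervals for one gene.

    Promoter is the +/- window around the TSS; body is the transcribed
    unit minus the promoter-proximal window, mirrored on minus strand.
    """
    w = promoter_window_bp
    tss = gene.tss
    promoter = (tss - w, tss + w)
    if gene.strand == "+":
        body = (gene.start + w, gene.end)
    else:
        body = (gene.start, gene.end - w)
    return promoter, body


def call_coenrichment(
    peak_sets: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    promoter_window_bp: int = 250,
    region_mode: str = "promoter",
) -> list[CoEnrichmentCall]:
    """Flag each gene as co-enriched when every peak set overlaps it.

    A flag is true iff >=1 bp of the region overlaps >=1 peak of the set;
    ``co_enriched`` is the conjunction over all queried sets in the chosen
    ``region_mode`` ("promoter" or "body").  Genes whose body vanishes
    after removing the promoter window get a false body flag.
    """
    if region_mode not in ("promoter", "body"):
        raise ValueError(f"unknown region mode {region_mode!r}")
    merged = {ps.label: ps.merged() for ps in peak_sets}
    calls = []
    warned_empty = False
    for gene in genes:
        promoter, body = gene_regions(gene, promoter_window_bp)
        if body[1] <= body[0] and not warned_empty:
            warnings.warn(
                f"gene {gene.gene_id}: body empty after promoter windowing",
                stacklevel=2,
            )
            warned_empty = True
        pflags = {
            ps.label: _overlaps_region(merged[ps.label], gene.chrom, *promoter)
            for ps in peak_sets
        }
        bflags = {
            ps.label: _overlaps_region(merged[ps.label], gene.chrom, *body)
            for ps in peak_sets
        }
        chosen = pflags if region_mode == "promoter" else bflags
        calls.append(
            CoEnrichmentCall(
                gene_id=gene.gene_id,
                promoter_flags=pflags,
                body_flags=bflags,
                region_mode=region_mode,
                co_enriched=all(chosen.values()),
            )
        )
    return calls


def coenrichment_table(calls: Sequence[CoEnrichmentCall]) -> pd.DataFrame:
    """Flatten calls to a frame: gene_id, per-set flags, co_enriched."""
    rows = []
    for call in calls:
        row = {"gene_id": call.gene_id, "co_enriched": call.co_enriched}
        for label, flag in call.promoter_flags.items():
            row[f"promoter_{label}"] = flag
        for label, flag in call.body_flags.items():
            row[f"body_{label}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
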