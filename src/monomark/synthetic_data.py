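"""Seeded generators with known ground truth for every pipeline input.

Each generator emulates one class of input the analysis consumes — probed
peptide arrays, film-style array rasters, genomes with genes / peaks /
coverage tracks, paired differential-expression tables, and two-channel
line profiles — and returns a machine-readable truth record alongside the
data, so every downstream statistic can be tested as a parameter-recovery
problem without downloads.

The array truth model mirrors the multiplicative picture of combinatorial
binding: a spot's expected intensity is a background term plus the product
of the per-mark base affinities of its marks, times the product of the
interaction multipliers of every ordered (target, co-mark) pair present
on the peptide (1 = neutral, <1 inhibiting, >1 enhancing).  Observed
intensities multiply the expectation by mean-one lognormal noise of a
chosen coefficient of variation, independently per (spot, subarray) —
film intensities are positive and heteroscedastic, which multiplicative
noise captures and additive noise does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_model import (
    ArrayLayout,
    ModificationTag,
    PeptideSpec,
    Position,
    as_tag,
    parse_mod_tag,
)
from .array_quantify import ArrayResult, LineProfile, normalize_intensities
from .coenrichment import GeneModel, PeakSet, SignalTrack
from .errors import DesignError, GeometryError

#: Marks of the default toy layouts: the five mono-methyl marks the assay
#: singles out, their di/tri-methyl neighbours, and nearby acetyl/phospho
#: marks that share peptides on the commercial array.
DEFAULT_MARKS = (
    "H4K20me1", "H3K4me1", "H3K36me1", "H3K9me1", "H3K27me1",
    "H3K9me2", "H3K9me3", "H3K4me3", "H3K9ac", "H3S10ph",
    "H3K27me3", "H4K16ac",
)


def _span_for(histone: str, mods: Sequence[ModificationTag]) -> tuple[int, int]:
    """A 19-residue window covering all mod positions (they must fit)."""
    if not mods:
        return (1, 19)
    lo = min(m.position for m in mods)
    hi = max(m.position for m in mods)
    if hi - lo > 18:
        raise DesignError(f"marks {list(map(str, mods))} span more than 19 residues")
    start = max(1, min(lo, hi - 18))
    return (start, start + 18)


def _compatible(mods: Sequence[ModificationTag]) -> bool:
    """One histone, one mod per residue, all within a 19-mer window."""
    if len({m.histone for m in mods}) != 1:
        return False
    if len({(m.histone, m.residue) for m in mods}) != len(mods):
        return False
    positions = [m.position for m in mods]
    return max(positions) - min(positions) <= 18


def simulate_layout(
    marks: Sequence[str] = DEFAULT_MARKS,
    n_rows: int = 6,
    n_cols: int = 8,
    n_subarrays: int = 2,
    max_mods: int = 3,
    seed: int = 0,
    include_controls: bool = True,
    ensure_pairs: Sequence[tuple[str, str]] = (),
    n_per_pair: int = 3,
) -> ArrayLayout:
    """Random combinatorial toy layout printed in identical subarrays.

    Every mark gets at least two single-mark spots; each pair listed in
    ``ensure_pairs`` gets ``n_per_pair`` guaranteed two-mark spots (so
    interaction strata are testable); remaining positions carry random
    compatible combinations of 1..max_mods marks.  The last two grid
    positions become blank and positive controls when requested.
    """
    rng = np.random.default_rng(seed)
    tags = [as_tag(m) for m in marks]
    n_spots = n_rows * n_cols
    n_controls = 2 if include_controls else 0
    n_peptides = n_spots - n_controls
    n_guaranteed = 2 * len(tags) + n_per_pair * len(ensure_pairs)
    if n_peptides < n_guaranteed:
        raise DesignError(
            f"{n_peptides} peptide spots cannot host {n_guaranteed} guaranteed spots"
        )

    mod_sets: list[frozenset[ModificationTag]] = []
    for tag in tags:  # guaranteed single-mark duplicates
        mod_sets.append(frozenset([tag]))
        mod_sets.append(frozenset([tag]))
    for a, b in ensure_pairs:
        pair = [as_tag(a), as_tag(b)]
        if not _compatible(pair):
            raise DesignError(f"{a} and {b} cannot share a 19-mer peptide")
        mod_sets.extend([frozenset(pair)] * n_per_pair)
    while len(mod_sets) < n_peptides:
        size = int(rng.integers(1, max_mods + 1))
        combo = list(rng.choice(len(tags), size=size, replace=False))
        mods = [tags[i] for i in combo]
        if _compatible(mods):
            mod_sets.append(frozenset(mods))

    spots: dict[Position, PeptideSpec | str] = {}
    flat = [(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]
    for i, (r, c) in enumerate(flat):
        if i < n_peptides:
            mods = sorted(mod_sets[i])
            histone = mods[0].histone if mods else "H3"
            entry: PeptideSpec | str = PeptideSpec(
                spot_id=f"r{r}c{c}",
                histone=histone,
                span=_span_for(histone, mods),
                mods=frozenset(mods),
            )
        else:
            entry = "blank" if i == n_peptides else "positive_control"
        for s in range(1, n_subarrays + 1):
            spots[(s, r, c)] = entry
    return ArrayLayout(shape=(n_rows, n_cols), n_subarrays=n_subarrays, spots=spots)


def interaction_layout(
    target: str = "H3K4me1",
    co: str = "H3K9me3",
    n_with: int = 6,
    n_without: int = 6,
    n_subarrays: int = 2,
) -> ArrayLayout:
    """Deterministic layout with fixed (target AND co) / (target only) strata.

    One column of width max(n_with + n_without, 2); a blank control closes
    the grid when the counts leave room.
    """
    t, c = as_tag(target), as_tag(co)
    if not _compatible([t, c]):
        raise DesignError(f"{target} and {co} cannot share a 19-mer peptide")
    n_rows = n_with + n_without + 1
    spots: dict[Position, PeptideSpec | str] = {}
    for r in range(1, n_rows + 1):
        if r <= n_with:
            mods = frozenset([t, c])
        elif r <= n_with + n_without:
            mods = frozenset([t])
        else:
            for s in range(1, n_subarrays + 1):
                spots[(s, r, 1)] = "blank"
            continue
        spec = PeptideSpec(
            spot_id=f"r{r}c1",
            histone=t.histone,
            span=_span_for(t.histone, sorted(mods)),
            mods=mods,
        )
        for s in range(1, n_subarrays + 1):
            spots[(s, r, 1)] = spec
    return ArrayLayout(shape=(n_rows, 1), n_subarrays=n_subarrays, spots=spots)


# ---------------------------------------------------------------------------
# array intensities


@dataclass
class ArrayTruthModel:
    """Generative truth for a probed array.

    ``affinities`` maps mark name -> positive base affinity (marks absent
    from the map default to 1.0); ``interactions`` maps ordered
    (target, co) name pairs -> positive multiplier applied when both marks
    share a peptide; ``noise_cv`` is the coefficient of variation of the
    mean-one lognormal spot noise; ``background`` is the intensity of a
    bare spot.
    """

    affinities: Mapping[str, float] = field(default_factory=dict)
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.15
    background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.affinities.values()):
            raise DesignError("affinities must be positive")
        if any(v <= 0 for v in self.interactions.values()):
            raise DesignError("interaction multipliers must be positive")
        if self.noise_cv < 0 or self.background < 0:
            raise DesignError("noise CV and background must be non-negative")

    def expected_intensity(self, mods: frozenset[ModificationTag]) -> float:
        names = {str(m) for m in mods}
        value = 1.0
        for name in names:
            value *= self.affinities.get(name, 1.0)
        for (t, c), mult in self.interactions.items():
            if t in names and c in names:
                value *= mult
        return self.background + value


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_array(
    truth: ArrayTruthModel,
    layout: ArrayLayout,
) -> tuple[ArrayResult, pd.DataFrame]:
    """Draw a probed-array result from the truth model over a layout.

    Expected spot intensity is background + product(base affinities) x
    product(applicable interaction multipliers); the observed value
    multiplies it by independent mean-one lognormal noise per
    (spot, subarray).  Blank controls sit at background; the positive
    control at 1.5x the strongest peptide expectation.  Returns the
    normalized :class:`ArrayResult` and a per-spot truth table.
    """
    rng = np.random.default_rng(truth.seed)
    peptides = layout.peptides()
    expected = {sid: truth.expected_intensity(spec.mods) for sid, spec in peptides.items()}
    pos_control = 1.5 * max(expected.values()) if expected else truth.background

    rows = []
    truth_rows = []
    for pos in layout.positions():
        s, r, c = pos
        entry = layout.peptide_at(pos)
        if isinstance(entry, str):
            mu = truth.background if entry == "blank" else pos_control
            sid, is_control = entry, True
        else:
            mu = expected[entry.spot_id]
            sid, is_control = entry.spot_id, False
        observed = mu * _lognormal_factors(rng, truth.noise_cv, 1)[0]
        rows.append((sid, s, observed, is_control))
        if s == 1:
            truth_rows.append((sid, mu, is_control))

    table = pd.DataFrame(rows, columns=["spot_id", "subarray", "corrected", "is_control"])
    result = normalize_intensities(
        table[["spot_id", "subarray", "corrected"]], layout, method="max"
    )
    truth_table = pd.DataFrame(truth_rows, columns=["spot_id", "expected", "is_control"])
    return result, truth_table


def expected_duplicate_correlation(expected: np.ndarray, cv: float) -> float:
    """Analytic duplicate Pearson r under mean-one multiplicative noise.

    With observed X = E x N, N independent with mean 1 and variance cv^2:
    cov(X1, X2) = var(E) and var(X) = var(E) + cv^2 E[E^2], so
    r = var(E) / (var(E) + cv^2 E[E^2]).
    """
    expected = np.asarray(expected, dtype=float)
    var_e = expected.var()
    m2 = np.mean(expected**2)
    return float(var_e / (var_e + cv * cv * m2))


def cv_for_duplicate_correlation(expected: np.ndarray, target_r: float) -> float:
    """Noise CV that yields an expected duplicate correlation ``target_r``."""
    if not 0 < target_r < 1:
        raise DesignError("target correlation must lie in (0, 1)")
    expected = np.asarray(expected, dtype=float)
    var_e = expected.var()
    m2 = np.mean(expected**2)
    if var_e == 0:
        raise DesignError("constant expectations: any noise gives r = 0")
    return math.sqrt(var_e * (1.0 - target_r) / (target_r * m2))


# ---------------------------------------------------------------------------
# array raster rendering


def render_array_image(
    result: ArrayResult,
    pitch: int = 24,
    spot_radius: int = 6,
    background: float = 30.0,
    bit_depth: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a probed array as a grayscale raster of intensity disks.

    Spot disks rise above a uniform background in proportion to the
    normalized spot value; subarrays stack vertically one blank row
    apart (the convention :func:`monomark.array_quantify.quantify_spots`
    assumes for a scalar ``grid_origin``).  Optional Gaussian pixel noise
    is added before quantization to the requested bit depth.  Returns the
    image and a geometry/truth record for round-trip checks.
    """
    if pitch <= 2 * spot_radius:
        raise GeometryError("pitch must exceed twice the spot radius (disks overlap)")
    if bit_depth not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    layout = result.layout
    n_rows, n_cols = layout.shape
    maxval = 2**bit_depth - 1
    amplitude = 0.8 * maxval - background

    height = layout.n_subarrays * (n_rows * pitch + pitch) + pitch
    width = n_cols * pitch + 2 * pitch
    img = np.full((height, width), background, dtype=float)

    values = result.data.set_index(["spot_id", "subarray"])["normalized"]
    origin = (pitch, pitch)
    yy, xx = np.mgrid[-spot_radius : spot_radius + 1, -spot_radius : spot_radius + 1]
    disk = yy**2 + xx**2 <= spot_radius**2

    truth_rows = []
    for pos in layout.positions():
        s, r, c = pos
        entry = layout.peptide_at(pos)
        sid = entry if isinstance(entry, str) else entry.spot_id
        value = float(values.loc[(sid, s)])
        cy = origin[0] + (s - 1) * (n_rows * pitch + pitch) + (r - 1) * pitch
        cx = origin[1] + (c - 1) * pitch
        img[cy - spot_radius : cy + spot_radius + 1,
            cx - spot_radius : cx + spot_radius + 1][disk] = background + value * amplitude
        truth_rows.append((sid, s, value))

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.round(img), 0, maxval)
    img = img.astype(np.uint8 if bit_depth == 8 else np.uint16)

    geometry = {
        "grid_origin": origin,
        "pitch": pitch,
        "spot_radius": spot_radius,
        "background": background,
        "amplitude": amplitude,
        "bit_depth": bit_depth,
        "truth": pd.DataFrame(truth_rows, columns=["spot_id", "subarray", "normalized"]),
    }
    return img, geometry


# ---------------------------------------------------------------------------
# genomic data


@dataclass
class TrackSpec:
    """One ChIP factor in the synthetic genome.

    ``shape`` places gene-linked enrichment at the promoter
    ("promoter-peaked"), across the body ("body-uniform") or nowhere
    ("none"); ``overlap_with_first`` is the designed fraction of this
    factor's peaks overlapping the first factor's peaks.
    """

    label: str
    shape: str = "body-uniform"
    amplitude: float = 10.0
    n_peaks: int = 200
    overlap_with_first: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("promoter-peaked", "body-uniform", "none"):
            raise DesignError(f"unknown enrichment shape {self.shape!r}")
        if self.overlap_with_first is not None and not 0 <= self.overlap_with_first <= 1:
            raise DesignError("overlap fraction must lie in [0, 1]")


@dataclass
class GenomeTruthModel:
    """Design of a synthetic genome: genes, peak sets, coverage tracks."""

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr2L": 1_000_000})
    n_genes: int = 120
    gene_length: tuple[int, int] = (2_000, 8_000)
    track_specs: Sequence[TrackSpec] = field(default_factory=list)
    peak_length: tuple[int, int] = (400, 1_500)
    bin_size: int = 50
    background_rate: float = 0.5
    group_multipliers: tuple[float, ...] = (1.0, 0.5, 0.0)
    seed: int = 0


@dataclass
class SyntheticGenome:
    """Generated genome plus its ground truth."""

    genes: list[GeneModel]
    peak_sets: dict[str, PeakSet]
    ip_tracks: dict[str, SignalTrack]
    input_track: SignalTrack
    gene_groups: pd.Series  # gene_id -> group index (0 = strongest)
    designed_overlaps: dict[str, float]


def _place_genes(truth: GenomeTruthModel, rng: np.random.Generator) -> list[GeneModel]:
    chroms = list(truth.chrom_sizes)
    per_chrom = np.array_split(np.arange(truth.n_genes), len(chroms))
    genes: list[GeneModel] = []
    lo, hi = truth.gene_length
    for chrom, idx in zip(chroms, per_chrom):
        size = truth.chrom_sizes[chrom]
        n = len(idx)
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = size - lengths.sum() - 10_000
        if slack <= n:
            raise DesignError(f"{chrom}: genes do not fit the chromosome")
        gaps = rng.multinomial(int(slack - n), np.full(n, 1.0 / n)) + 1
        cursor = 5_000
        for i, g in enumerate(idx):
            start = cursor + int(gaps[i])
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{g:04d}", chrom, start, end, strand))
            cursor = end
    return genes


def _random_intervals(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    n: int,
    length_range: tuple[int, int],
) -> dict[str, list[tuple[int, int]]]:
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        out[chrom].append((start, start + length))
    return out


def simulate_genomic_data(truth: GenomeTruthModel) -> SyntheticGenome:
    """Generate genes, peak sets with designed overlaps, and coverage tracks.

    Peaks of the first track spec are placed uniformly; each later spec
    places ``round(overlap_with_first x n_peaks)`` of its peaks on top of
    randomly chosen first-set peaks and the rest in regions free of the
    first set, so the designed fraction is hit up to rejection-sampling
    noise.  IP tracks sum a per-peak plateau, gene-linked enrichment by
    group (multipliers 1 / 0.5 / 0 for clusters I-III) at the promoter or
    body per the spec's shape, and Poisson background; the input track is
    Poisson background only.
    """
    specs = list(truth.track_specs)
    if not specs:
        specs = [TrackSpec("factor0")]
    rng = np.random.default_rng(truth.seed)
    genes = _place_genes(truth, rng)

    # gene groups (cluster truth): round-robin so groups are balanced
    groups = pd.Series(
        {g.gene_id: i % len(truth.group_multipliers) for i, g in enumerate(genes)},
        name="group",
    )

    # first peak set
    base = _random_intervals(rng, truth.chrom_sizes, specs[0].n_peaks, truth.peak_length)
    peak_sets: dict[str, PeakSet] = {
        specs[0].label: PeakSet(
            specs[0].label,
            {c: np.array(v, dtype=np.int64) for c, v in base.items() if v},
        )
    }
    first_merged = peak_sets[specs[0].label].merged()
    first_flat = [
        (chrom, s, e) for chrom, arr in first_merged.items() for s, e in arr
    ]
    designed: dict[str, float] = {}

    for spec in specs[1:]:
        frac = spec.overlap_with_first
        if frac is None:
            intervals = _random_intervals(rng, truth.chrom_sizes, spec.n_peaks, truth.peak_length)
        else:
            if frac > 0 and not first_flat:
                raise DesignError("cannot overlap an empty first peak set")
            designed[spec.label] = frac
            n_hit = int(round(frac * spec.n_peaks))
            intervals = {c: [] for c in truth.chrom_sizes}
            for _ in range(n_hit):  # anchored on a random first-set peak
                chrom, s, e = first_flat[int(rng.integers(len(first_flat)))]
                length = int(rng.integers(*truth.peak_length))
                anchor = int(rng.integers(s, e))
                start = max(0, anchor - length // 2)
                intervals[chrom].append((start, start + length))
            placed = 0
            attempts = 0
            while placed < spec.n_peaks - n_hit:
                attempts += 1
                if attempts > 50 * spec.n_peaks:
                    raise DesignError(
                        f"{spec.label}: cannot place non-overlapping peaks "
                        "(first set too dense for the designed fraction)"
                    )
                cand = _random_intervals(rng, truth.chrom_sizes, 1, truth.peak_length)
                (chrom, ivs), = ((c, v) for c, v in cand.items() if v)
                s, e = ivs[0]
                arr = first_merged.get(chrom)
                if arr is not None and len(arr):
                    idx = int(np.searchsorted(arr[:, 0], e, side="left")) - 1
                    if idx >= 0 and arr[idx, 1] > s:
                        continue
                intervals[chrom].append((s, e))
                placed += 1
        peak_sets[spec.label] = PeakSet(
            spec.label,
            {c: np.array(v, dtype=np.int64) for c, v in intervals.items() if v},
        )

    # coverage tracks
    bs = truth.bin_size
    n_bins = {c: int(np.ceil(size / bs)) for c, size in truth.chrom_sizes.items()}
    input_track = SignalTrack(
        bin_size=bs,
        values={c: rng.poisson(truth.background_rate, n).astype(float)
                for c, n in n_bins.items()},
    )
    ip_tracks: dict[str, SignalTrack] = {}
    for spec in specs:
        values = {c: rng.poisson(truth.background_rate, n).astype(float)
                  for c, n in n_bins.items()}
        for chrom, arr in peak_sets[spec.label].intervals.items():
            v = values[chrom]
            for s, e in arr:
                v[s // bs : max(s // bs + 1, -(-e // bs))] += spec.amplitude
        if spec.shape != "none":
            for gene in genes:
                mult = truth.group_multipliers[groups[gene.gene_id]]
                if mult == 0:
                    continue
                v = values[gene.chrom]
                if spec.shape == "promoter-peaked":
                    s = max(0, gene.tss - 500)
                    e = gene.tss + 500
                else:
                    s, e = gene.start, gene.end
                v[s // bs : max(s // bs + 1, -(-e // bs))] += spec.amplitude * mult
        ip_tracks[spec.label] = SignalTrack(bin_size=bs, values=values)

    return SyntheticGenome(
        genes=genes,
        peak_sets=peak_sets,
        ip_tracks=ip_tracks,
        input_track=input_track,
        gene_groups=groups,
        designed_overlaps=designed,
    )


def simulate_profile_groups(
    means: Sequence[float] = (10.0, 5.0, 0.0),
    sd: float = 0.1,
    n_per_group: int = 50,
    n_bins: int = 90,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Metagene-like rows in well-separated signal groups, plus true labels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for g, mu in enumerate(means):
        rows.append(rng.normal(mu, sd, size=(n_per_group, n_bins)))
        labels.extend([g] * n_per_group)
    return np.concatenate(rows), np.array(labels)


def _correlated_pairs(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """n x 2 standard-normal pairs with correlation rho (|rho| = 1 exact)."""
    x = rng.standard_normal(n)
    if abs(rho) == 1.0:
        return np.column_stack([x, rho * x])
    y = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DEGTruthModel:
    """Design of a paired mutant-vs-WT differential-expression experiment.

    DE genes draw correlated bivariate-normal log2 fold-change pairs with
    correlation ``rho`` at scale ``effect_sd``; null genes draw small
    independent effects with uniform adjusted p-values.
    """

    n_genes: int = 2_000
    frac_de: float = 0.3
    rho: float = 0.79
    effect_sd: float = 3.0
    null_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise DesignError("fraction DE must lie in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise DesignError("|rho| must not exceed 1")


def simulate_deg_pair(
    truth: DEGTruthModel,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two DE tables (gene, log2FoldChange, padj) plus a per-gene truth table."""
    rng = np.random.default_rng(truth.seed)
    n = truth.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    is_de = rng.random(n) < truth.frac_de

    lfc = np.empty((n, 2))
    n_de = int(is_de.sum())
    if n_de:
        lfc[is_de] = truth.effect_sd * _correlated_pairs(rng, truth.rho, n_de)
    lfc[~is_de] = rng.normal(0.0, truth.null_sd, size=(n - n_de, 2))

    padj = np.empty((n, 2))
    padj[is_de] = 10.0 ** (-rng.uniform(2.0, 10.0, size=(n_de, 2)))
    padj[~is_de] = rng.uniform(0.0, 1.0, size=(n - n_de, 2))

    table_a = pd.DataFrame({"gene": genes, "log2FoldChange": lfc[:, 0], "padj": padj[:, 0]})
    table_b = pd.DataFrame({"gene": genes, "log2FoldChange": lfc[:, 1], "padj": padj[:, 1]})
    truth_table = pd.DataFrame({"gene": genes, "is_de": is_de,
                                "lfc_a": lfc[:, 0], "lfc_b": lfc[:, 1]})
    return table_a, table_b, truth_table


# ---------------------------------------------------------------------------
# line profiles


def simulate_line_profiles(rho: float, n: int, seed: int = 0) -> LineProfile:
    """Two-channel profile with target Pearson correlation ``rho``.

    Channels are bivariate standard normal pairs shifted by +5 so that
    intensities are effectively non-negative (no clipping distortion).
    """
    if not -1 <= rho <= 1:
        raise DesignError("|rho| must not exceed 1")
    if n < 3:
        raise DesignError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    xy = _correlated_pairs(rng, rho, n) + 5.0
    return LineProfile(
        positions=np.arange(n, dtype=float),
        channels={"a": xy[:, 0], "b": xy[:, 1]},
    )
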