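"""Chromosome-landscape statistics for real or synthetic genomes.

Implements the analysis methods used to compare simulated chromosomes with
real ones: scanning for degenerate IUPAC motifs (such as the 13-bp hotspot
consensus CCNCCNTNNCCNC), converting physical coordinates to the genetic
(centimorgan) scale through a recombination map, start-to-start distance
curves with uniform-randomization envelopes, motif clustering, windowed
feature counts with Spearman correlation, GC content in fixed windows, and
physical/genetic chromosome-centre statistics.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IUPAC_CODES",
    "DegenerateMotif",
    "MotifMatch",
    "GeneticMap",
    "DistanceCurve",
    "scan_motif",
    "to_genetic_scale",
    "neighbor_distances",
    "distance_curve",
    "randomization_envelope",
    "cluster_motifs",
    "windowed_counts",
    "rank_correlation",
    "gc_windows",
    "chromosome_centres",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class DegenerateMotif:
    """A degenerate nucleotide pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty motif")
        bad = set(pat) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC letters in motif: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)

    @property
    def k(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "DegenerateMotif":
        return DegenerateMotif(self.pattern.translate(_COMPLEMENT)[::-1])

    def regex(self, allow_gap_bases: bool = False) -> str:
        """Character-class regex for the forward strand.  With
        ``allow_gap_bases`` a sequence 'N' (assembly gap) is allowed to
        satisfy a motif 'N'; by default matches never extend into gaps."""
        parts = []
        for letter in self.pattern:
            allowed = set(IUPAC_CODES[letter])
            if allow_gap_bases and letter == "N":
                allowed.add("N")
            parts.append("[" + "".join(sorted(allowed)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: 0-based half-open interval on ``chrom``;
    ``matched_text`` is always the forward-strand sequence."""

    chrom: str
    start: int
    end: int
    strand: str
    matched_text: str


def scan_motif(sequence: str, motif: DegenerateMotif,
               both_strands: bool = True, chrom: str = "chr",
               allow_gap_bases: bool = False) -> list[MotifMatch]:
    """All (overlapping) occurrences of a degenerate motif.

    The forward pattern is reported on strand '+'; when ``both_strands``,
    positions where the reverse complement of the motif matches the
    forward strand are reported on strand '−' ('-').  Case-insensitive.
    A palindromic hit is reported once per strand.
    """
    seq = sequence.upper()
    if re.search("[^ACGTN]", seq):
        raise ValueError("sequence must be over A/C/G/T/N (any case)")
    out: list[MotifMatch] = []
    k = motif.k
    patterns = [("+", motif)]
    if both_strands:
        patterns.append(("-", motif.reverse_complement()))
    for strand, m in patterns:
        rx = re.compile("(?=(" + m.regex(allow_gap_bases) + "))")
        for hit in rx.finditer(seq):
            s = hit.start()
            out.append(MotifMatch(chrom, s, s + k, strand, seq[s:s + k]))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


class GeneticMap:
    """Monotone physical (bp) -> genetic (cM) mapping.

    Rows are (position, rate in cM/Mb, cumulative cM); positions must be
    strictly increasing and cumulative cM non-decreasing (the HapMap
    ``position COMBINED_rate Genetic_Map`` layout).
    """

    def __init__(self, positions: np.ndarray, rates: np.ndarray,
                 cum_cM: np.ndarray):
        self.positions = np.asarray(positions, float)
        self.rates = np.asarray(rates, float)
        self.cum_cM = np.asarray(cum_cM, float)
        if self.positions.size == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cum_cM) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                   df[cols[2]].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions.astype(int),
                             "rate_cM_Mb": self.rates,
                             "cM": self.cum_cM})

    @property
    def total_cM(self) -> float:
        return float(self.cum_cM[-1] - self.cum_cM[0])

    def interpolate(self, positions_bp: np.ndarray) -> np.ndarray:
        """Cumulative cM at arbitrary bp positions (linear between knots,
        clamped to the terminal values outside the map)."""
        return np.interp(np.asarray(positions_bp, float),
                         self.positions, self.cum_cM)

    def invert(self, cM: float) -> float:
        """Physical position at a cumulative cM value (linear inverse)."""
        return float(np.interp(cM, self.cum_cM, self.positions))


def to_genetic_scale(positions_bp: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Convert bp positions to cumulative cM via the genetic map."""
    return gmap.interpolate(positions_bp)


def neighbor_distances(starts: np.ndarray) -> np.ndarray:
    """Start-to-start distances between consecutive features (length n-1)."""
    s = np.sort(np.asarray(starts, float))
    if s.size < 2:
        import warnings
        warnings.warn("fewer than 2 positions: no distances")
        return np.empty(0)
    return np.diff(s)


@dataclass
class DistanceCurve:
    """Sorted-cumulative neighbour-distance curve.

    Distances are expressed as fractions of the total chromosome length,
    sorted ascending and cumulated from shortest to longest; ``values[i]``
    is the cumulated fraction after the ``i+1`` shortest distances.  For a
    perfectly even spacing the curve lies on the diagonal; clustering
    pushes it below.
    """

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size

    def at_median_count(self) -> float:
        """Cumulated fraction after the smaller half of all distances
        (the value read off at the vertical median-count line)."""
        if self.n == 0:
            raise ValueError("empty curve")
        return float(self.values[(self.n + 1) // 2 - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": np.arange(1, self.n + 1),
                             "cum_fraction": self.values})


def distance_curve(distances: np.ndarray, total_length: float) -> DistanceCurve:
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    d = np.sort(np.asarray(distances, float))
    return DistanceCurve(np.cumsum(d) / total_length)


def randomization_envelope(n_points: int, total_length: float,
                           n_rep: int = 100,
                           rng: np.random.Generator | None = None
                           ) -> tuple[DistanceCurve, DistanceCurve]:
    """Min/max envelope of distance curves from ``n_rep`` uniform random
    placements of ``n_points`` positions on the chromosome."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = rng or np.random.default_rng()
    lo = np.full(n_points - 1, np.inf)
    hi = np.full(n_points - 1, -np.inf)
    for _ in range(n_rep):
        pos = rng.random(n_points) * total_length
        curve = distance_curve(neighbor_distances(pos), total_length).values
        np.minimum(lo, curve, out=lo)
        np.maximum(hi, curve, out=hi)
    return DistanceCurve(lo), DistanceCurve(hi)


def cluster_motifs(matches: list[MotifMatch], mode: str = "distance",
                   avg_distance: float | None = None,
                   chrom_length: float | None = None,
                   min_cluster_size: int = 2
                   ) -> tuple[list[list[MotifMatch]], list[MotifMatch]]:
    """Chain consecutive motifs into clusters under one of three rules.

    ``same_strand``: link consecutive motifs on the same strand;
    ``opposite_strand``: link consecutive motifs on alternating strands;
    ``distance``: link neighbours whose start-to-start gap is at most the
    average expected distance (``chrom_length / n_matches`` unless
    ``avg_distance`` is given).  Motifs in no chain of size >= 2 form the
    unclustered set; ``min_cluster_size`` additionally filters the
    reported clusters (e.g. >= 8 for strong clusters).
    """
    if mode not in ("same_strand", "opposite_strand", "distance"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    ms = sorted(matches, key=lambda m: m.start)
    if not ms:
        return [], []
    if mode == "distance" and avg_distance is None:
        if chrom_length is None:
            raise ValueError("distance mode needs avg_distance or chrom_length")
        avg_distance = chrom_length / len(ms)

    def linked(a: MotifMatch, b: MotifMatch) -> bool:
        if mode == "same_strand":
            return a.strand == b.strand
        if mode == "opposite_strand":
            return a.strand != b.strand
        return (b.start - a.start) <= avg_distance

    chains: list[list[MotifMatch]] = [[ms[0]]]
    for prev, cur in zip(ms, ms[1:]):
        if linked(prev, cur):
            chains[-1].append(cur)
        else:
            chains.append([cur])
    clusters = [c for c in chains if len(c) >= max(2, min_cluster_size)]
    unclustered = [c[0] for c in chains if len(c) < 2]
    return clusters, unclustered


def windowed_counts(positions: np.ndarray, chrom_length: float,
                    width: float) -> pd.DataFrame:
    """Feature counts in non-overlapping windows of ``width``.

    The last window may be partial; it is kept and flagged in the
    ``partial`` column.  Window counts sum to the number of features.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    pos = np.asarray(positions, float)
    n_win = int(np.ceil(chrom_length / width))
    idx = np.clip((pos // width).astype(int), 0, n_win - 1)
    counts = np.bincount(idx, minlength=n_win)
    starts = np.arange(n_win) * width
    ends = np.minimum(starts + width, chrom_length)
    return pd.DataFrame({"start": starts, "end": ends, "count": counts,
                         "partial": ends - starts < width})


def rank_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties, two-sided t-approximation
    p-value) between two equal-length count vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def gc_windows(sequence: str, width: int = 8000) -> pd.DataFrame:
    """GC fraction (G+C over A+C+G+T) in non-overlapping windows; windows
    with no called bases (all N) give NaN."""
    if width <= 0:
        raise ValueError("width must be positive")
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    n_win = int(np.ceil(seq.size / width)) if seq.size else 0
    rows = []
    for w in range(n_win):
        chunk = seq[w * width:(w + 1) * width]
        gc = np.count_nonzero((chunk == ord("G")) | (chunk == ord("C")))
        at = np.count_nonzero((chunk == ord("A")) | (chunk == ord("T")))
        denom = gc + at
        rows.append((w * width, min((w + 1) * width, seq.size),
                     gc / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["start", "end", "gc_fraction"])


def chromosome_centres(gmap: GeneticMap, length: float, centromere: float,
                       intersection: float | None = None) -> dict[str, float]:
    """Physical-centre / genetic-centre / centromere distance statistics.

    The genetic centre is the physical position splitting the chromosome
    into two halves of equal total recombination (cumulative cM).  All
    distances are reported in Mb.  ``intersection`` optionally supplies
    the x-axis crossing of a detrended walk for the corresponding
    distance statistics.
    """
    if gmap.total_cM <= 0:
        raise ValueError("genetic map has zero total cM")
    phys_centre = length / 2.0
    half_cM = gmap.cum_cM[0] + gmap.total_cM / 2.0
    gen_centre = gmap.invert(half_cM)
    mb = 1e-6
    out = {
        "physical_centre_bp": phys_centre,
        "genetic_centre_bp": gen_centre,
        "centre_to_genetic_centre_Mb": abs(phys_centre - gen_centre) * mb,
        "centre_to_centromere_Mb": abs(phys_centre - centromere) * mb,
    }
    if intersection is not None:
        out["intersection_to_centre_Mb"] = abs(intersection - phys_centre) * mb
        out["intersection_to_centromere_Mb"] = abs(intersection - centromere) * mb
    return out
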