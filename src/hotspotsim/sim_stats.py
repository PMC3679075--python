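"""Population-level statistics of simulated chromosomes.

Covers the descriptive layer used to characterise the self-organized
equilibrium: per-site hotspot classification (double / single / none),
independence expectations for those classes, detrended cumulative walks,
detection of the central low-recombination region, regional count tables,
95%-fixation sets and their overlap between ancestral and descendant
populations, and whole-genome summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim_core import Individual, Population

__all__ = [
    "ClassCounts",
    "DetrendedWalk",
    "classify_positions",
    "class_counts",
    "expected_class_counts",
    "detrended_walk",
    "central_region",
    "regional_counts",
    "fixed_positions",
    "overlap_counts",
    "genome_summary",
]

DOUBLE, SINGLE, NONE = 2, 1, 0
_CLASS_NAMES = {DOUBLE: "double", SINGLE: "single", NONE: "none"}


@dataclass(frozen=True)
class ClassCounts:
    """Mean per-genome counts of intergenic site classes.

    ``double + single + none == L - 1`` and the total number of hotspot
    bits per genome is ``2 * double + single``.
    """

    double: float
    single: float
    none: float

    @property
    def total_hotspots(self) -> float:
        return 2.0 * self.double + self.single

    @property
    def n_sites(self) -> float:
        return self.double + self.single + self.none


def classify_positions(ind: Individual) -> np.ndarray:
    """Per intergenic site: 2 if both haplotypes carry a hotspot (double,
    "allowed" for recombination), 1 if exactly one does (single,
    recombination-inert), 0 if neither."""
    h1, h2 = ind.hap1.hotspots, ind.hap2.hotspots
    return (h1.astype(np.int8) + h2.astype(np.int8)) * 1  # 0/1/2 by count


def class_counts(pop: Population) -> ClassCounts:
    """Population-mean per-genome site-class counts."""
    h0 = pop.hotspots[:, 0, :]
    h1 = pop.hotspots[:, 1, :]
    double = float((h0 & h1).sum(axis=1).mean())
    single = float((h0 ^ h1).sum(axis=1).mean())
    return ClassCounts(double, single, (pop.L - 1) - double - single)


def expected_class_counts(total_hotspots: float, n_sites: int) -> ClassCounts:
    """Expected class counts if hotspots were placed independently.

    With ``p = total_hotspots / (2 * n_sites)`` the expected numbers are
    ``p^2 * n_sites`` double, ``2 p (1-p) * n_sites`` single and
    ``(1-p)^2 * n_sites`` empty sites; they sum to ``n_sites`` exactly.
    """
    if not (0 <= total_hotspots <= 2 * n_sites):
        raise ValueError(
            f"total_hotspots must lie in [0, {2 * n_sites}], got {total_hotspots}"
        )
    p = total_hotspots / (2.0 * n_sites)
    return ClassCounts(p * p * n_sites, 2.0 * p * (1.0 - p) * n_sites,
                       (1.0 - p) ** 2 * n_sites)


@dataclass
class DetrendedWalk:
    """Cumulative count of events minus the count expected under a uniform
    density, evaluated at each event position.  Rising stretches mark
    enrichment; the walk ends at exactly zero."""

    positions: np.ndarray
    observed_cum: np.ndarray
    expected_cum: np.ndarray

    @property
    def detrended(self) -> np.ndarray:
        return self.observed_cum - self.expected_cum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "observed_cum": self.observed_cum,
            "expected_cum": self.expected_cum,
            "detrended": self.detrended,
        })


def detrended_walk(event_positions: np.ndarray, length: float,
                   weights: np.ndarray | None = None) -> DetrendedWalk:
    """Build the detrended cumulative walk of a point set on ``(0, length]``.

    ``weights`` allows population-aggregated walks (e.g. per-site double
    hotspot counts) without expanding to repeated positions.  Input is
    sorted internally; an empty input yields an empty walk.
    """
    pos = np.asarray(event_positions, dtype=float)
    if pos.size == 0:
        empty = np.empty(0)
        return DetrendedWalk(empty, empty.copy(), empty.copy())
    if weights is None:
        w = np.ones_like(pos)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != pos.shape:
            raise ValueError("weights must match event_positions in shape")
    order = np.argsort(pos, kind="stable")
    pos, w = pos[order], w[order]
    if pos[0] <= 0 or pos[-1] > length:
        raise ValueError("event positions must lie in (0, length]")
    observed = np.cumsum(w)
    if pos[-1] < length:
        # close the walk at the chromosome end so it returns to zero exactly
        pos = np.append(pos, length)
        observed = np.append(observed, observed[-1])
    expected = observed[-1] * pos / length
    return DetrendedWalk(pos, observed, expected)


def central_region(walk: DetrendedWalk, smooth_window: int | None = None
                   ) -> tuple[float, float]:
    """Boundaries of the central depleted region of a detrended walk.

    For a walk that rises near both chromosome ends and falls in between
    (the double-hotspot signature), the region is delimited by the global
    maximum of the smoothed walk over its left half and the global minimum
    over its right half.  ``smooth_window`` defaults to 1/64 of the number
    of walk points.  A monotone walk has no interior reversal; the full
    range is returned with a warning.
    """
    y = walk.detrended
    n = y.size
    if n == 0:
        raise ValueError("empty walk")
    if smooth_window is None:
        smooth_window = max(1, n // 64)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ys = np.convolve(y, kernel, mode="same")
    else:
        ys = y
    diffs = np.diff(y)
    if n < 3 or np.all(diffs >= 0) or np.all(diffs <= 0):
        warnings.warn("monotone walk: no trend reversal, returning full range")
        return float(walk.positions[0]), float(walk.positions[-1])
    mid = n // 2
    left = int(np.argmax(ys[:mid]))
    right = mid + int(np.argmin(ys[mid:]))
    if left >= right:
        warnings.warn("degenerate trend reversal, returning full range")
        return float(walk.positions[0]), float(walk.positions[-1])
    return float(walk.positions[left]), float(walk.positions[right])


def regional_counts(pop: Population, region: tuple[int, int]) -> pd.DataFrame:
    """Interior-vs-exterior table of population-mean per-genome counts.

    ``region`` is a pair of 0-based locus indices ``(start, end)``, both
    inclusive, defining the interior.  Rows: defective alleles, all
    hotspots, double hotspots, single hotspots, hotspot-free positions.
    An intergenic site is interior when its left locus is interior.
    Interior and exterior columns add up to the genome-wide totals.
    """
    start, end = region
    if not (0 <= start <= end <= pop.L - 1):
        raise ValueError(f"region must be within [0, {pop.L - 1}]")
    loci_in = np.zeros(pop.L, bool)
    loci_in[start:end + 1] = True
    sites_in = loci_in[:-1]

    genes = pop.genes
    h0, h1 = pop.hotspots[:, 0, :], pop.hotspots[:, 1, :]
    dbl = (h0 & h1)
    sng = (h0 ^ h1)
    non = 1 - (h0 | h1)

    def split(per_site, site_mask):
        inner = float(per_site[:, site_mask].sum() / pop.N)
        outer = float(per_site[:, ~site_mask].sum() / pop.N)
        return outer, inner

    rows = {}
    per_locus_def = genes.sum(axis=1)  # defective alleles per locus per ind
    rows["defective_alleles"] = split(per_locus_def, loci_in)
    all_h = (h0.astype(np.int16) + h1)
    rows["all_hotspots"] = split(all_h, sites_in)
    rows["double_hotspots"] = split(dbl, sites_in)
    rows["single_hotspots"] = split(sng, sites_in)
    rows["no_hotspot_positions"] = split(non, sites_in)
    df = pd.DataFrame(rows, index=["exterior", "interior"]).T
    df.index.name = "count_of"
    return df


def fixed_positions(pop: Population, prop: str, q: float = 0.95) -> np.ndarray:
    """0-based positions where ``prop`` holds in at least ``q`` of the
    population (inclusive threshold).

    ``prop``: ``"double"`` / ``"single"`` (hotspot classes, intergenic
    sites) or ``"heterozygous"`` (gene loci with exactly one defective
    allele).
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    h0, h1 = pop.hotspots[:, 0, :], pop.hotspots[:, 1, :]
    if prop == "double":
        frac = (h0 & h1).mean(axis=0)
    elif prop == "single":
        frac = (h0 ^ h1).mean(axis=0)
    elif prop == "heterozygous":
        frac = (pop.genes[:, 0, :] ^ pop.genes[:, 1, :]).mean(axis=0)
    else:
        raise ValueError(f"unknown property {prop!r}")
    # compare counts in integers to make the >= boundary exact
    counts = np.rint(frac * pop.N)
    return np.nonzero(counts >= q * pop.N - 1e-9)[0]


def overlap_counts(sets: list[np.ndarray] | list[set]) -> pd.DataFrame:
    """Pairwise and joint intersection sizes of position sets.

    Returns a table with one row per pair plus a ``joint`` row for the
    intersection of all sets; ``size_a``/``size_b`` report each operand's
    own cardinality.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    as_sets = [set(np.asarray(list(s)).tolist()) for s in sets]
    rows = []
    for i in range(len(as_sets)):
        for j in range(i + 1, len(as_sets)):
            rows.append((f"{i}&{j}", len(as_sets[i]), len(as_sets[j]),
                         len(as_sets[i] & as_sets[j])))
    joint = set.intersection(*as_sets)
    rows.append(("joint", len(as_sets[0]), len(as_sets[-1]), len(joint)))
    return pd.DataFrame(rows, columns=["pair", "size_a", "size_b", "common"])


def genome_summary(pop: Population) -> dict[str, float]:
    """Whole-genome summary of a population.

    ``frac_defective_bits`` is the fraction of 1-bits over all ``2 N L``
    gene bits; ``defective_alleles_per_locus`` rescales it to defective
    alleles per locus per genome (twice the per-bit value), the
    convention used when quoting the equilibrium defect load of ~0.32
    alongside heterozygous/homozygous locus fractions.
    """
    g0, g1 = pop.genes[:, 0, :], pop.genes[:, 1, :]
    frac_bits = float(pop.genes.mean())
    hom = float((g0 & g1).mean())
    het = float((g0 ^ g1).mean())
    cc = class_counts(pop)
    return {
        "frac_defective_bits": frac_bits,
        "defective_alleles_per_locus": 2.0 * frac_bits,
        "frac_homozygous_defective": hom,
        "frac_heterozygous": het,
        "mean_double": cc.double,
        "mean_single": cc.single,
        "mean_none": cc.none,
        "mean_hotspots_per_genome": cc.total_hotspots,
    }
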