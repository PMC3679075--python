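"""Synthetic chromosome fixtures with planted, known structure.

Generates FASTA/BED/genetic-map inputs that emulate the features the
landscape statistics are designed to detect — subtelomeric recombination
enrichment, end-biased hotspot placement, and motif clusters with short
equal spacers — so every analysis operation can be exercised against an
exact truth table without downloading any real assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import DegenerateMotif, GeneticMap, IUPAC_CODES, MotifMatch

__all__ = [
    "FixtureSpec",
    "PlantedCluster",
    "synth_chromosome",
    "synth_genetic_map",
    "synth_hotspot_track",
]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PlantedCluster:
    """A run of motif copies planted at ``position`` with fixed
    start-to-start ``spacer`` (bp) on one strand."""

    position: int
    n_motifs: int
    spacer: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.n_motifs < 1 or self.spacer < 0 or self.position < 0:
            raise ValueError("invalid planted cluster")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chromosome.

    ``gc_baseline`` sets the background GC fraction; ``gc_end_boost``
    raises GC additively in the terminal ``end_fraction`` of the
    chromosome (real chromosomes are GC- and hotspot-rich subtelomerically).
    ``background_motif_rate`` plants additional isolated motif copies per
    bp, uniformly.  ``map_inflation`` multiplies the recombination rate in
    the terminal regions of the genetic map.
    """

    length: int = 200_000
    gc_baseline: float = 0.40
    gc_end_boost: float = 0.10
    end_fraction: float = 0.10
    planted_clusters: tuple[PlantedCluster, ...] = field(default_factory=tuple)
    background_motif_rate: float = 0.0
    map_inflation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not (0 < self.gc_baseline < 1):
            raise ValueError("gc_baseline must be in (0,1)")
        if not (0 < self.end_fraction < 0.5):
            raise ValueError("end_fraction must be in (0, 0.5)")


def _sample_motif_instance(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    """One concrete sequence from the degenerate consensus, each ambiguous
    position drawn uniformly over its IUPAC allowance (so a planted set
    exercises consensus-vs-specific distinctions)."""
    return "".join(
        sorted(IUPAC_CODES[letter])[rng.integers(0, len(IUPAC_CODES[letter]))]
        for letter in motif.pattern
    )


def synth_chromosome(spec: FixtureSpec, motif: DegenerateMotif,
                     rng: np.random.Generator | None = None
                     ) -> tuple[str, pd.DataFrame]:
    """Background sequence with planted motif copies; returns the sequence
    and an exact truth table (chrom/start/end/strand/matched_text) of every
    planted match.  Overlapping planted clusters raise an error."""
    rng = rng or np.random.default_rng(spec.seed)
    L, k = spec.length, motif.k

    # i.i.d. background with elevated GC near both ends
    pos = np.arange(L)
    gc = np.full(L, spec.gc_baseline)
    end = int(spec.end_fraction * L)
    if end:
        gc[:end] += spec.gc_end_boost
        gc[L - end:] += spec.gc_end_boost
    u = rng.random(L)
    v = rng.random(L)
    bases = np.where(u < gc, np.where(v < 0.5, 71, 67),   # G / C
                     np.where(v < 0.5, 65, 84))           # A / T
    seq = bytearray(bases.astype(np.uint8).tobytes())

    occupied: list[tuple[int, int]] = []
    rows: list[tuple] = []

    def plant(start: int, strand: str) -> None:
        if start < 0 or start + k > L:
            raise ValueError("planted motif out of bounds")
        for s, e in occupied:
            if start < e and start + k > s:
                raise ValueError(f"planted motifs overlap near {start}")
        inst = _sample_motif_instance(motif, rng)
        fwd = inst if strand == "+" else inst.translate(_COMP)[::-1]
        seq[start:start + k] = fwd.encode()
        occupied.append((start, start + k))
        rows.append(("synth", start, start + k, strand, fwd))

    for cl in spec.planted_clusters:
        step = max(cl.spacer, k)
        for i in range(cl.n_motifs):
            plant(cl.position + i * step, cl.strand)

    n_bg = rng.poisson(spec.background_motif_rate * L)
    for _ in range(n_bg):
        for _attempt in range(100):
            start = int(rng.integers(0, L - k + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            try:
                plant(start, strand)
                break
            except ValueError:
                continue

    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                        "matched_text"])
    truth = truth.sort_values("start").reset_index(drop=True)
    return seq.decode(), truth


def synth_genetic_map(length: int, map_inflation: float = 5.0,
                      knots: int = 50, end_fraction: float = 0.10,
                      total_cM: float = 100.0,
                      rng: np.random.Generator | None = None) -> GeneticMap:
    """Piecewise-linear genetic map with terminal rate inflation.

    The local rate is 1 in the central part and ``map_inflation`` in the
    terminal ``end_fraction`` at both ends (then scaled to ``total_cM``),
    emulating elevated subtelomeric recombination.  ``rng`` jitters
    interior knot placement; the map always satisfies the monotonicity
    invariants.
    """
    if knots < 2:
        raise ValueError("need at least 2 knots")
    rng = rng or np.random.default_rng()
    interior = np.round(np.sort(rng.random(knots - 2)) * length) if knots > 2 else []
    positions = np.unique(np.concatenate([[0.0], interior, [float(length)]]))
    end = end_fraction * length

    def local_rate(p: float) -> float:
        return map_inflation if (p < end or p > length - end) else 1.0

    cum = np.zeros(positions.size)
    for i in range(1, positions.size):
        a, b = positions[i - 1], positions[i]
        # integrate the stepwise rate over [a, b]
        pts = np.unique(np.clip([a, end, length - end, b], a, b))
        seg = sum(local_rate((lo + hi) / 2) * (hi - lo)
                  for lo, hi in zip(pts, pts[1:]))
        cum[i] = cum[i - 1] + seg
    cum *= total_cM / cum[-1]
    rates = np.empty_like(cum)
    rates[:-1] = np.diff(cum) / np.maximum(np.diff(positions), 1) * 1e6
    rates[-1] = rates[-2]
    return GeneticMap(positions, rates, cum)


def synth_hotspot_track(length: int, n_hotspots: int, end_bias: float = 1.0,
                        rng: np.random.Generator | None = None,
                        end_fraction: float = 0.10) -> pd.DataFrame:
    """BED-style hotspot intervals (1-2 kb) with end-biased placement.

    Placement density is ``end_bias``-fold higher in the terminal
    ``end_fraction`` at each end than in the centre; ``end_bias=1`` is
    exactly uniform.  Returns a BED3 frame sorted by start.
    """
    if n_hotspots < 0:
        raise ValueError("n_hotspots must be >= 0")
    if end_bias <= 0:
        raise ValueError("end_bias must be positive")
    rng = rng or np.random.default_rng()
    end = end_fraction * length
    w_end = 2 * end_fraction * end_bias
    w_mid = 1 - 2 * end_fraction
    p_end = w_end / (w_end + w_mid)
    mids = np.empty(n_hotspots)
    for i in range(n_hotspots):
        if rng.random() < p_end:
            u = rng.random() * 2 * end
            mids[i] = u if u < end else length - (u - end)
        else:
            mids[i] = end + rng.random() * (length - 2 * end)
    widths = rng.integers(1000, 2001, size=n_hotspots)
    starts = np.clip((mids - widths / 2).astype(int), 0, None)
    ends = np.minimum(starts + widths, length).astype(int)
    df = pd.DataFrame({"chrom": "synth", "start": starts, "end": ends})
    return df.sort_values("start").reset_index(drop=True)
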