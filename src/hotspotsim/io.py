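"""Reading and writing the package's on-disk formats.

Population snapshots and trajectories are plain TSV; chromosome sequences
are FASTA (via Biopython), feature tracks BED, and recombination maps
HapMap-style whitespace-separated tables (position, rate cM/Mb,
cumulative cM).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import GeneticMap, MotifMatch
from .params import SimParams
from .sim_core import Population

__all__ = [
    "write_snapshot", "read_snapshot",
    "write_trajectory", "read_trajectory",
    "read_fasta", "write_fasta",
    "read_bed", "write_bed", "matches_to_bed",
    "read_genetic_map", "write_genetic_map",
]


def _bits_to_str(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in bits)


def _str_to_bits(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), np.uint8) - ord("0")


def write_snapshot(path: str | Path, pop: Population,
                   params: SimParams | None = None) -> None:
    """Snapshot TSV: '#'-prefixed metadata header, then one row per
    individual (id, genes_hap1, genes_hap2, hotspots_hap1, hotspots_hap2
    as 0/1 strings)."""
    path = Path(path)
    with path.open("w") as fh:
        meta = {"step": pop.step, "N": pop.N, "L": pop.L}
        if params is not None:
            meta["params"] = dataclasses.asdict(params)
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("id\tgenes_hap1\tgenes_hap2\thotspots_hap1\thotspots_hap2\n")
        for i in range(pop.N):
            fh.write("\t".join([
                str(i),
                _bits_to_str(pop.genes[i, 0]), _bits_to_str(pop.genes[i, 1]),
                _bits_to_str(pop.hotspots[i, 0]), _bits_to_str(pop.hotspots[i, 1]),
            ]) + "\n")


def read_snapshot(path: str | Path) -> tuple[Population, dict]:
    path = Path(path)
    meta: dict = {}
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                try:
                    meta = json.loads(line.lstrip("# "))
                except json.JSONDecodeError:
                    pass
                continue
            if line.startswith("id\t") or not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"no individuals in snapshot {path}")
    N = len(rows)
    L = len(rows[0][1])
    genes = np.empty((N, 2, L), np.uint8)
    hots = np.empty((N, 2, L - 1), np.uint8)
    for r, row in enumerate(rows):
        genes[r, 0] = _str_to_bits(row[1])
        genes[r, 1] = _str_to_bits(row[2])
        hots[r, 0] = _str_to_bits(row[3])
        hots[r, 1] = _str_to_bits(row[4])
    return Population(genes, hots, step=int(meta.get("step", 0))), meta


def write_trajectory(path: str | Path, traj: pd.DataFrame) -> None:
    traj.to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA file as {name: sequence}."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str],
                width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def matches_to_bed(matches: list[MotifMatch]) -> pd.DataFrame:
    """Motif matches as BED6 (name = matched forward-strand text)."""
    return pd.DataFrame(
        [(m.chrom, m.start, m.end, m.matched_text, 0, m.strand)
         for m in matches],
        columns=_BED_COLS,
    )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """HapMap-dialect recombination map: whitespace-separated columns
    position, rate (cM/Mb), cumulative cM; a header line is detected and
    skipped."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 3:
        raise ValueError("genetic map needs 3 columns (position rate cM)")
    try:
        float(df.columns[0])
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except ValueError:
        pass
    return GeneticMap(df.iloc[:, 0].to_numpy(float),
                      df.iloc[:, 1].to_numpy(float),
                      df.iloc[:, 2].to_numpy(float))


def write_genetic_map(path: str | Path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)
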