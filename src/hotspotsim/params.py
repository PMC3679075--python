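"""Simulation parameters and config-file parsing.

The parameter set mirrors the standard run described in the model: a
fixed-size population of ``N`` diploid individuals whose chromosomes are
bitstrings of ``L`` genes, purifying selection of strength ``x`` acting on
homozygous defective loci, and on average ``M`` gene mutations and ``C``
crossovers per gamete.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

__all__ = ["SimParams", "RunOptions", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid parameter values or malformed config files."""


_FLAG_FIELDS = (
    "hotspot_mutation",
    "gene_reversions",
    "single_hotspot_recomb",
    "neutral_mode",
    "bootstrap_hotspots",
    "viable_births",
)


@dataclass(frozen=True)
class SimParams:
    """All model constants for one simulation run.

    Parameters
    ----------
    N : int
        Population size (diploid individuals); constant over the run.
    L : int
        Genes (bits) per haplotype. There are ``L - 1`` intergenic sites
        that may carry recombination hotspots.
    x : float
        Selection base in ``(0, 1]``. An individual with ``d`` homozygous
        defective loci survives a Monte Carlo step with probability
        ``x ** (d + 1)``.
    M : float
        Mean number of gene mutations introduced per gamete.
    C : float
        Mean number of crossovers attempted per gamete.
    hotspot_mutation : bool
        Toggle one uniformly chosen hotspot bit on every transmitted
        haplotype (hotspot birth/death process).
    gene_reversions : bool
        Allow 1 -> 0 gene mutations; when off, a mutation drawn on a
        defective allele is suppressed.
    single_hotspot_recomb : bool
        Allow crossover at sites where only one of the two haplotypes
        carries a hotspot (default requires a double hotspot).
    neutral_mode : bool
        Replace the fitness rule by a flat survival probability ``x``
        independent of genotype, preserving population turnover.
    bootstrap_hotspots : bool
        When a crossover is demanded but no allowed site exists, create a
        hotspot at a uniform site on both recombining copies and cross
        over there (matters only while hotspots are still rare).
    viable_births : bool
        Replacements for eliminated individuals must themselves pass the
        survival rule at birth: each newborn is tossed against
        ``x**(d+1)`` and the parent pair is re-drawn until a viable
        offspring is obtained (bounded by an internal retry cap).  With
        the flag off a newborn is placed unconditionally and first faces
        selection at the next step; under the standard parameter set that
        regime accumulates unbalanced heterozygous load until the
        population collapses, so viable replacement is the default.
    seed : int
        Seed for the single RNG stream driving the whole trajectory.
    n_steps : int
        Number of Monte Carlo steps to run.
    """

    N: int = 500
    L: int = 2048
    x: float = 0.85
    M: float = 1.0
    C: float = 1.0
    hotspot_mutation: bool = True
    gene_reversions: bool = True
    single_hotspot_recomb: bool = False
    neutral_mode: bool = False
    bootstrap_hotspots: bool = True
    viable_births: bool = True
    seed: int = 0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigError(f"N must be >= 2, got {self.N}")
        if self.L < 2:
            raise ConfigError(f"L must be >= 2, got {self.L}")
        if not (0.0 < self.x <= 1.0):
            raise ConfigError(f"x must be in (0, 1], got {self.x}")
        if self.M < 0:
            raise ConfigError(f"M must be >= 0, got {self.M}")
        if self.C < 0:
            raise ConfigError(f"C must be >= 0, got {self.C}")
        if self.n_steps < 0:
            raise ConfigError(f"n_steps must be >= 0, got {self.n_steps}")

    @property
    def n_sites(self) -> int:
        """Number of intergenic (potential hotspot) sites per haplotype."""
        return self.L - 1

    def replace(self, **kwargs: Any) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class RunOptions:
    """Run-control options that are not model constants.

    ``variant_switch_step``/``switch_flags`` implement two-phase protocols:
    the run starts with the flags in :class:`SimParams` and switches the
    named variant flags when the step counter reaches ``variant_switch_step``
    (e.g. run 50 000 steps with reversible hotspots, then freeze them).
    """

    thinning: int = 100
    snapshot_steps: tuple[int, ...] = ()
    variant_switch_step: int | None = None
    switch_flags: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.thinning < 1:
            raise ConfigError("thinning must be >= 1")
        for name, _ in self.switch_flags:
            if name not in _FLAG_FIELDS:
                raise ConfigError(f"unknown variant flag {name!r}")


_BOOL_STRINGS = {"true": True, "1": True, "yes": True, "on": True,
                 "false": False, "0": False, "no": False, "off": False}


def _coerce(key: str, value: Any) -> Any:
    if key in _FLAG_FIELDS:
        if isinstance(value, bool):
            return value
        try:
            return _BOOL_STRINGS[str(value).strip().lower()]
        except KeyError:
            raise ConfigError(f"cannot parse boolean for {key}: {value!r}")
    if key in ("N", "L", "seed", "n_steps", "thinning", "variant_switch_step"):
        return int(value)
    if key in ("x", "M", "C"):
        return float(value)
    if key == "snapshot_steps":
        if isinstance(value, str):
            value = [v for v in value.replace(",", " ").split() if v]
        return tuple(int(v) for v in value)
    if key == "switch_flags":
        if isinstance(value, dict):
            return tuple((k, _coerce(k, v)) for k, v in value.items())
        return tuple(tuple(item) for item in value)
    raise ConfigError(f"unknown config key: {key}")


def load_config(path: str | Path) -> tuple[SimParams, RunOptions]:
    """Read a simulation config from JSON or flat ``key=value`` text.

    Keys: N, L, x, M, C, n_steps, seed, hotspot_mutation, gene_reversions,
    single_hotspot_recomb, neutral_mode, bootstrap_hotspots,
    variant_switch_step, switch_flags, snapshot_steps, thinning.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw: dict[str, Any]
    try:
        raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ConfigError("JSON config must be an object")
    except json.JSONDecodeError:
        raw = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

    parsed = {k: _coerce(k, v) for k, v in raw.items()}
    run_keys = {f.name for f in dataclasses.fields(RunOptions)}
    sim_keys = {f.name for f in dataclasses.fields(SimParams)}
    sim_kwargs = {k: v for k, v in parsed.items() if k in sim_keys}
    run_kwargs = {k: v for k, v in parsed.items() if k in run_keys}
    leftovers = set(parsed) - sim_keys - run_keys
    if leftovers:
        raise ConfigError(f"unknown config keys: {sorted(leftovers)}")
    return SimParams(**sim_kwargs), RunOptions(**run_kwargs)
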