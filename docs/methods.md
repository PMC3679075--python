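# Methods

## The model

`hotspotsim` simulates a fixed-size population of `N` diploid individuals.
Each individual carries two homologous chromosomes represented as
bit-vectors of `L` genes: bit 0 is the functional (wild) allele, bit 1 a
defective allele.  Defects are recessive — only a locus defective on both
chromosomes (a *homozygous defective locus*) affects the phenotype.  A
second bit-vector over the `L − 1` intergenic sites of each chromosome
marks *recombination hotspots*.  A site is *allowed* for crossover in a
given meiosis when both of the recombining copies carry a hotspot there
(a *double hotspot*); a hotspot present on only one copy (a *single
hotspot*) is recombination-inert.  An optional variant
(`single_hotspot_recomb`) lets single hotspots recombine too.

One Monte Carlo step is one synchronized cycle:

1. **Selection.**  Every individual survives independently with
   probability `x**(d + 1)`, where `d` is its number of homozygous
   defective loci and `x ∈ (0, 1]` is the selection base.  The `+1`
   means even a perfect genome dies with probability `1 − x`, so the
   population keeps turning over.  `x = 1` freezes the population
   entirely; the `neutral_mode` flag therefore implements "no selection"
   as a flat survival probability `x` independent of genotype.
2. **Replacement.**  Every death is replaced by a newborn whose two
   haplotypes are gametes of two distinct parents drawn uniformly from
   the survivors.  Gamete formation copies the parent's two chromosomes,
   introduces gene mutations, performs hotspot-restricted crossovers,
   returns one of the two products uniformly, and toggles one uniformly
   chosen hotspot bit on the transmitted chromosome (hotspot
   birth/death).  Event counts use the 0-to-2-mean scheme: `u ~ U(0, 2m)`
   gives `floor(u)` events plus one more with probability `frac(u)`, so
   the mean is exactly `m` (`m = M` for mutations per chromosome copy,
   `m = C` for crossovers per gamete).

Crossover sites are drawn uniformly from the allowed set, sequentially
without replacement within one gamete.  If a crossover is demanded but no
allowed site exists and `bootstrap_hotspots` is on, a uniform site is
made a double hotspot and used — this matters only in the first
generations, before hotspot counts build up.  Mutations flip gene bits in
both directions (reversions); `gene_reversions=False` suppresses the
1→0 direction.  `hotspot_mutation=False` freezes the hotspot toggle.

### Viable replacement (`viable_births`)

The replacement rule has a consequential free choice: whether a newborn
that would immediately fail selection may stand in the population.  With
unconditional placement, the standing population carries a layer of
doomed newborns: under the standard parameter set below, the unbalanced
heterozygous load this permits grows without bound and the population
reliably collapses within a few tens of thousands of steps (we verified
this across seeds and also from a hand-constructed complementary-haplotype
state).  We therefore default to *viable replacement*: each newborn is
tossed against its own survival probability at birth, and the parent pair
is re-drawn until a viable offspring is produced (capped at 1000 tries;
at the organized steady state a handful suffice).  This is equivalent to
fertility selection proportional to offspring viability, keeps the
population alive indefinitely, and is the only regime in which a
homozygous-defect fraction of order 10⁻⁴ — the signature of the organized
state — is observable in the standing population.  The literal
unconditional rule remains available as `viable_births=False` and is
exercised by the test suite.

### Standard parameter set

`N = 500`, `L = 2048`, `x = 0.85`, `M = 1` (mean gene mutations per
chromosome copy per gamete), `C = 1` (mean crossovers per gamete), all
flip processes reversible, bootstrap and hotspot toggling on.  `M = 1`
follows the one-mutation-per-genome-per-generation rule of thumb; `x`
and `C` put the system in the regime where linked complementing gene
clusters can form.

### What the model self-organizes

Run from perfect founders, the population reaches a statistically
stationary state in which (i) defective alleles accumulate far above the
random-mating mutation–selection balance, held almost exclusively in the
heterozygous state (homozygous-defect fraction of order 10⁻⁴); (ii) the
heterozygous loci concentrate in a central chromosome block in which
haplotypes complement each other and crossovers are selected against;
(iii) double hotspots are enriched toward the chromosome ends and single
hotspots in the centre, i.e. recombination is self-organized away from
the complementation cluster without any direct selection on hotspots; and
(iv) individual hotspot positions keep turning over (fixed single
positions are several-fold better conserved over 10⁵ steps than fixed
double positions).  All four features are measured by the acceptance
script.  In our runs the stationary per-bit defective-allele fraction is
~0.22–0.27 and the central concentration of heterozygosity ~92–98%,
somewhat weaker than the strongest published description of this state
(0.32 and 94%); the load discrepancy is documented rather than tuned away.

## Statistics

* **Detrended cumulative walk**: running count of events (optionally
  weighted, e.g. population double-hotspot counts per site) minus the
  count expected under a uniform density, evaluated at each event
  position and closed at the chromosome end, where it is exactly zero.
  Rising stretches mark enrichment.
* **Central region**: the walk of double-hotspot positions rises near
  both ends and falls in between; boundaries are taken as the global
  maximum of the smoothed walk (window = n/64 points) over its left half
  and the global minimum over its right half.  Degenerate or monotone
  walks fall back to the full range with a warning.
* **Class counts and independence expectations**: per-genome mean counts
  of double/single/empty intergenic sites, compared with `p²`, `2p(1−p)`,
  `(1−p)²` of `n_sites` where `p` is hotspot occupancy per slot.
* **Fixation (95% rule)**: a site property (double, single, heterozygous)
  is fixed when at least `q` (default 0.95, inclusive) of individuals
  share it; overlaps of fixed sets between an ancestral population and
  descendants branched from it quantify hotspot turnover.
* **Distance curves**: neighbour start-to-start distances sorted
  ascending, cumulated, and normalized by chromosome length.  Uniform
  spacing gives the diagonal (0.5 at the median count); uniformly random
  placement converges to `1 − (ln 2 + 1)/2 ≈ 0.153` at the median count
  (the smaller half of exponential spacings); clustering pushes the curve
  below.  A 100-replicate uniform-randomization envelope (per-index
  min/max) provides the reference band.
* **Motif scanning**: degenerate IUPAC patterns (e.g. the 13-bp hotspot
  consensus CCNCCNTNNCCNC) are matched on both strands with overlaps,
  case-insensitively; by default a sequence `N` (assembly gap) never
  matches, optionally it may satisfy a motif `N`.  Matches are reported
  in 0-based half-open coordinates with forward-strand text.
* **Genetic scale**: physical positions are converted to centimorgans by
  linear interpolation of a monotone (position, rate, cumulative cM)
  map, clamped outside the map; the *genetic centre* is the inverse image
  of half the total map length.

## Synthetic fixtures

The fixture generator produces FASTA/BED/map triples with planted truth:
i.i.d. background sequence at a configurable GC with subtelomeric GC
elevation; motif clusters planted at exact positions with fixed spacers
(38/58/134 bp are typical short spacers) and strands, each instance drawn
uniformly from the degenerate consensus; end-biased hotspot intervals of
1–2 kb; and genetic maps with terminal rate inflation.  The background is
i.i.d., so fixtures do not emulate repeat elements, mutation processes or
long-range composition structure — recovering planted structure shows the
statistics are computed correctly, not that real genomes behave this way.

## Numerical choices

* All randomness flows through one seeded `numpy.random.Generator`; the
  draw order (selection sweep in member order, then replacements in death
  order; within a gamete: mutations per copy, crossover count and sites,
  product choice, toggle) is fixed, so a seed determines the trajectory
  bit-for-bit.
* The production loop runs on a bit-packed (uint64) engine that draws the
  identical RNG sequence as the byte-per-bit reference kernels; tests pin
  the two to bit-identical trajectories.  A plain-Python mirror of the
  whole step is kept in the test suite as an independent oracle.
* Indexing is 0-based half-open internally everywhere (loci `0..L-1`,
  intergenic site `s` between loci `s` and `s+1`; crossover swaps
  everything right of the site, the site's own hotspot bits staying with
  the left segment).  1-based coordinates appear only in emitted tables.
* Fixation thresholds compare integer counts (`>= q·N` with a small
  epsilon) so the exact-boundary case is inclusive.
* Problem sizes in the acceptance script: equilibrium runs use a 40k-step
  burn-in with the final 10k steps time-averaged, three seeds; the
  turnover protocol branches one ancestral population into two descendants
  evolved 100k steps.  These are the sizes at which the reported summaries
  are stationary in our runs (the strongest published form of the state
  was reported after 3M steps).

## Known limitations

* The equilibrium defect load and the sharpness of the central
  heterozygosity cluster depend on the replacement rule; with
  unconditional replacement the regime is not sustainable at all (see
  above), and with viable replacement the load stabilizes ~20% above the
  strongest published value.
* The central-region detector assumes the two-turning-point walk shape;
  chromosomes without subtelomeric enrichment fall back to the full
  range.
* Motif scanning is exact-match over IUPAC classes; no mismatch
  tolerance.
* The genetic-map transform is piecewise linear; no smoothing of noisy
  empirical maps.
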