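# Methods

## Measurement model

The pipeline assumes the titration-SILAC design for absolute modification
occupancy. Two cell populations are isotopically distinguished by lysine
labels: the light population carries the modification (induced), the heavy
population does not (suppressed pharmacologically). The modified fraction of
each light protein is captured quantitatively on an affinity resin; the
capture is treated as complete (efficiency 1), so the light peptide signal
represents `A·s` — protein abundance `A` times occupancy `s`. The heavy
channel is a whole-lysate digest representing `A` scaled by the mixed mass.
When a mass `m_H` of heavy lysate is combined with the material enriched
from a mass `m_L` of light lysate, every peptide pair of a protein with
occupancy `s` has expected heavy/light area ratio

    E[H/L] = ρ / s,      ρ = m_H / m_L  (the mix ratio).

Inverting at the protein level:

    s(mix) = ρ / median_peptides(H/L),     s = median over mixes,

and the replicate-level result is the median across replicates. Medians are
used at every level because individual peptides can be mis-quantified by
interference, and whole mix points can lose one channel to detector
censoring; the median of the surviving values needs no imputation and
ignores minority corruption entirely (a property-tested invariant).

Occupancies are fractions everywhere inside the package; percent appears
only in summaries and reports. Estimates above 1 are flagged (`GT_ONE`) but
never truncated — truncation would hide calibration errors. Estimates from
a single mix point are flagged `SINGLE_MIX`.

## Peptide filtering

Three criteria gate every peptide pair, attributed to the first failing
rule so the audit counts are conserved:

1. **S/N > 5 in both channels (strict).** A ratio requires two reliable
   peaks; the threshold and a "either channel" mode are configurable.
2. **Reference membership.** Every protein the peptide maps to (by exact
   Lys-C-compatible occurrence in the supplied sequences, up to a
   configurable number of missed cleavages, default 2) must be in the
   user-supplied list of known modified proteins. Unmapped peptides fail
   here as well.
3. **Known-site exclusion.** Peptides containing a known modification site
   are excluded: their modified form carries a mass shift, so the observed
   unmodified peptide under-represents the light channel. The spanning
   interval is closed on both ends, positions 1-based. Peptides merely
   adjacent to a site are kept. The check is skipped (with a warning) when
   sequences or site tables are not supplied.

Peptides mapping to more than one reference protein are dropped by default
(unambiguous attribution); an `assign-to-all` policy exists for users who
prefer coverage over uniqueness.

Lys-C is modelled as cleaving after every lysine *including* K-P bonds,
which is the behaviour that makes lysine-only SILAC labels cover every
internal peptide. Ile/Leu are distinct residues (exact string matching);
no ambiguity folding is attempted.

## Non-specific binding

The control design co-enriches equal masses of light (modified) and heavy
(inhibitor-treated) lysate on the same resin. Heavy signal can then only be
non-specific carryover, so the per-protein median H/L ratio in the control
is the non-specific fraction `f_ns`. The module validates the equal-mass
assumption against the design table when given. A multiplicative correction
`s → s·(1 − f_ns)` is available but **off by default**: it is an extension
beyond quantification, and enabling it is an explicit analysis decision.
`f_ns > 1` is physically impossible for a fraction and skips the
correction with a warning.

## Enrichment and clustering

Final occupancies (percent) are binned as `<0.1`, `[0.1, 0.5)`, `[0.5, 1]`,
`>1`. The boundary convention is left-closed with the third bin closed at
1%, chosen so the top bin is strictly ">1%"; the mid-boundaries are not
otherwise constrained and the convention is documented rather than assumed.

Each bin is tested per term with the one-sided hypergeometric tail
P(X ≥ k) on the custom background of all quantified proteins (term sets are
intersected with the background first; bins must be subsets of it). The
default statistic is the standard tail; an EASE-style mode (tail at k − 1)
is available behind a flag for users comparing with DAVID-derived lists.
No multiple-testing correction is applied beyond the P < α (default 0.05)
gate, matching common practice for this clustering use; the −log10 P values
of non-significant cells enter the clustering matrix as 0, the minimal
completion of the significant profile.

Clustering is agglomerative single linkage under Euclidean distance
(scipy), with rows sorted lexicographically by term id before linkage so
the result is order-invariant and ties break deterministically. An O(n³)
naive agglomeration oracle in the test suite verifies merge heights and
memberships for small n.

## The simulator

`simulate_experiment` generates what the pipeline consumes — quantified
peptide pair tables — not spectra. Per protein: a random sequence
(length 200–600, ~7% lysine), a log-uniform occupancy and abundance, a
uniform 3–15 of its fully-cleaved Lys-C peptides (length ≥ 6), and a fixed
per-peptide lognormal ionization factor. Per (replicate, mix point,
peptide): `light = A·s·ι` and `heavy = light·(ρ/s)·η` with `η` lognormal,
unit mean, CV = `ratio_noise_cv`. S/N is proportional to area
(`sn_per_unit_area`); additionally, when the minor/major area ratio of a
pair falls below 1/D the minor peak's S/N is forced to 0 — censoring acts
through the S/N channel so the *filter* removes the pair, mirroring the
real pipeline, rather than the generator deleting rows. At zero noise the
surviving set equals the closed-form predicate `1/D ≤ ρ/s ≤ D` exactly
(tested).

Default study conditions: occupancies log-uniform over 1e-4…0.36 (the
~3.5-decade range the measurement is designed for), the four-point design
ρ = 1/2000, 1/800, 1/200, 1/50, two replicates, D = 5000, S/N threshold 5,
ratio-noise CV 0.2. Abundances are log-uniform over 1e6…1e9 arbitrary
units with `sn_per_unit_area = 1e-2`, chosen once so that the S/N floor
bites exactly where it should: the light channel of low-occupancy,
low-abundance proteins becomes the limiting factor, which is what makes
the titration series necessary. The occupancy prior is log-uniform because
no distributional form is asserted by the design and log-uniform exercises
every decade equally.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning: child 0 drives every protein-level draw, child 1 is spawned into
one stream per (replicate, mix point) for measurement noise, and child 2
drives the control's noise. Changing the number of replicates or mix
points therefore never changes the ground truth.

**What the simulator does not model** — chromatography, isotope envelopes,
MS2 identification, peptide-level interference, protein inference
ambiguity beyond exact sequence sharing, or abundance-dependent missing
values other than the S/N floor. Passing recovery tests therefore
demonstrates that the *arithmetic and filtering logic* invert the
measurement model faithfully, not that any real dataset is this well
behaved.

## Numerical and design choices

* Even-count medians are midpoint means throughout (`statistics.median`).
* A peptide with zero light area has no defined ratio and is excluded by
  the ratio step (in practice the S/N gate removes it first); a zero heavy
  area is never treated as ratio 0.
* Replicate merging takes the median of per-replicate occupancies —
  consistent with the method's use of medians at the other two levels —
  and reports replicate concordance as Pearson r on log10 occupancy over
  the overlap (undefined and reported as absent when the overlap is
  degenerate).
* Filter attribution order is S/N → reference → site → shared; the counts
  re-sum to the input size by construction and this is asserted at run
  time.
* The regression bound on recovery error (median |log2(est/true)| ≤ 0.15
  at CV 0.2, seed 0, 200 proteins) was measured once at that fixed seed
  and pinned; the observed value is ~0.04, and the bound exists to catch
  regressions, not to characterize accuracy.
* Test and acceptance problem sizes (50–300 proteins, 2 replicates) were
  chosen as the smallest sizes at which every decade of the occupancy
  range is populated well enough for stable medians.

## Known limitations

* Occupancy is protein-level: the enrichment captures whole modified
  proteins, so site-level stoichiometries are out of reach by design.
* Capture efficiency is assumed to be exactly 1; incomplete enrichment
  would bias all occupancies downward proportionally.
* The dynamic range D is a single scalar; real instruments have scan-local
  and run-global limits that differ.
* Equivalence with any specific GO/DAVID output is not claimed: term sets
  are user input and the background handling of external tools is not
  reproduced.
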