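# Methods

This note documents the models and procedures `starbind` implements, the
defaults it ships and why, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know about.
Conventions used throughout: sequences are stored in the RNA alphabet
(A/C/G/U/N, T converted to U at ingest), all coordinates are 0-based and
half-open, concentrations are µM, distances and areas are Å and Å².

## K-mer over-representation

The unit of counting is the *window*: a tag of length L contributes
max(0, L − k + 1) overlapping windows, minus any containing N.  With this
convention the counts of all 4^k k-mers sum exactly to the window total,
which makes the 2×2 table well defined:

```
            k-mer     not k-mer
CLIP    [ n_obs    N_obs − n_obs ]
control [ n_bg     N_bg  − n_bg  ]
```

Each k-mer is scored with the Pearson chi-squared statistic on this table
(1 degree of freedom, no continuity correction, closed form
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))), with the upper-tail probability from the
χ²₁ survival function.  A zero marginal (k-mer absent from, or saturating,
both sets) is reported as (χ² = 0, p = 1) and flagged degenerate.  No
multiple-testing correction is applied by default: the procedure reports raw
p-values and a p < α (default 0.05) filter, as the original analysis did;
callers can apply their own correction to the returned table.

The *enrichment ratio* is the ratio of relative window frequencies, with a
+0.5 pseudocount added to all four cells only when some cell is zero, so
ratios are always finite and positive; χ² and p are always computed on raw
counts.  "Top" k-mers are the significant, enriched ones (p < α and
ratio > 1) ranked by descending ratio, ties broken by ascending p then
lexicographically.  Tag-level counting, the ranking statistic and the logo
anchoring are all choices the original description leaves open; each is
fixed here, documented, and configurable.  One practical consequence of
ratio ranking: a rare k-mer observed a handful of times against zero control
counts can out-rank the embedded signal on ratio while the top list as a
whole remains dominated by motif-bearing k-mers; rank by p instead if that
matters for an application.

The logo count matrix anchors each tag at the leftmost occurrence of any top
k-mer (earliest-ranked k-mer breaking position ties) and accumulates base
counts over offsets [−flank, k + flank); offsets outside the tag and N
residues contribute nothing, so flank columns may sum to less than the
number of stacked tags.  The package emits counts, not rendered logos.

## Bipartite (A/U)AA sites

Core scanning matches `[AU]AA` at every position (overlapping matches all
reported; windows containing N never match).  A bound core occupies a 4-nt
*footprint* — the 3-nt core plus one 3′ flanking nucleotide, truncated at
the sequence end — reflecting the ~4 nt a KH groove accommodates.
*Separation* between two cores is the number of intervening nucleotides
between the upstream footprint end and the downstream core start.  Under
this convention the two-site construct UAAA–C(n)–UAAA has maximum separation
n + 1 (via its trailing AAA core), so separation tracks linker length
closely, and the separation of a designed pair embedded with s intervening
nucleotides is s + 1 by the same arithmetic.

A bipartite site is a core pair with separation in
[min_separation, max_separation]; the defaults are 16 ("more than 15
intervening nucleotides") and 30 (the separation around which CLIP tags are
enriched).  Both bounds are parameters: under the footprint convention the
C15 linker construct sits exactly at the 16-nt boundary, so analyses that
need an unambiguous contrast should use constructs away from the threshold
(e.g. C5 vs C25, or the (UAAA)×4 / (UAAA)×8 pair with maximum separations 9
and 25).

The spacing distribution takes each tag's *maximum* core separation,
histograms it per integer distance, and divides by the number of tags
scanned (not the number of tags with a pair), so CLIP and control sets of
different sizes are directly comparable; tags with fewer than two cores
count only in the denominator.  Negative separations (only mutually
overlapping cores) are clamped into the 0 bin; separations beyond the
histogram range land in an overflow bin.  Whether the underlying data's
distance convention was start-to-start or intervening-nucleotide is not
recorded anywhere authoritative; the intervening-nucleotide convention used
here is exposed via the footprint-length parameter (set it to the core
length 3 for start-to-footprint-free counting).

## FP binding model

Both single-site isotherms share the parameterization (K_d, f_free,
f_bound):

- hyperbolic: fraction bound = P/(K_d + P), valid when probe RNA ≪ K_d;
- quadratic (default): fraction bound =
  ((K_d + R + P) − √((K_d + R + P)² − 4RP)) / (2R), the exact 1:1 solution
  with probe concentration R (default 0.2 µM).

The quadratic model is the default because measured sites in this system
reach ~1 µM, only ~5× the probe concentration, where the hyperbolic fit is
biased.  The bias is systematic: fitted to exact depletion data from the
default design (two-fold serial dilution 200→0 µM, which includes
concentrations below the probe), the hyperbolic K_d is shifted by
≈ R/2 = 0.1 µM — 5.3% at K_d = 2 µM, 0.4% at 40 µM — so the two models
agree to within a few percent only well above K_d ≈ 10·R.

Fitting is unweighted least squares (scipy `curve_fit`, K_d bounded
positive, tolerances 1e-14 so fits are reproducible to ~1e-6 relative under
affine rescaling of the signal axis), initialized from the data: f_free from
the lowest-concentration signal, f_bound from the highest, K_d from the
concentration nearest the half-signal.  The K_d standard error comes from
the fit covariance.  Two quality flags are reported: *unfittable* when the
fitted curve's span over the measured range is below 3 residual standard
deviations (flat data), and *unreliable* when the fitted K_d falls outside
[min positive concentration/10, 10·max concentration].  No Hill coefficient
is fitted: avidity across constructs is quantified afterwards as the ratio
K_d(reference)/K_d(long linker), not as cooperativity within one curve.

## Structural measures

PDB files are read with gemmi: model 1 only, altloc blank or 'A', waters
excluded — fixed, bit-reproducible defaults.  Superposition uses the Kabsch
SVD construction with the determinant correction guaranteeing a proper
rotation; atoms are matched by (mapped chain, residue number, insertion
code, atom name) over the protein backbone (N, CA, C, O) by default, taking
only the intersection of common atoms so crystallographically disordered
residues drop out (with a logged count).  For dimer-on-dimer comparisons
both pairings of the two chains are tried and the smaller RMSD is reported
with the winning mapping logged.

SASA is a direct Shrake–Rupley implementation: each atom's sphere of radius
r_vdW + probe is sampled at deterministic golden-spiral points (default 960;
doubling changes totals by < 0.5%), points inside any neighbour's expanded
sphere are buried, and neighbours are found with a k-d tree.  The radius
table is C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å with a 1.4 Å probe;
an element without a tabulated radius is an error, never a silent default.
Buried interface area per monomer is (SASA(A) + SASA(B) − SASA(A∪B))/2 over
the two selected atom groups only.  RNA end-to-end span is the distance
from the 3′-terminal O3′ of one chain to the 5′-terminal P (else O5′, else
C5′) of the other, both orderings reported.

The deposited crystal structures of the T-STAR dimer (PDB 5EMO, 5ELT and
relatives) are experimental data and are not bundled; the structural
acceptance checks look for them under `data/pdb/` and fail with an
instruction otherwise.  For demonstrations and tests the package builds a
*synthetic* dimer (`starbind.synthetic_structures`): two ideal
poly-alanine helix backbones related by a two-fold axis and packed at a
genuine interface, plus two minimal extended RNA strands running
antiparallel on opposite faces.  It reproduces the architecture the
operations probe — not the fold, size or interface chemistry of the real
proteins — so quantities computed on it validate the *operations*, not the
crystallographic numbers.

## Synthetic tag and titration generators

The tag generator emulates the study conditions of a testis CLIP experiment:
~40 ± 4 nt tags (normal lengths, rounded, minimum 1), i.i.d. background
residues with a mouse-genome-like composition A 0.29, C 0.21, G 0.21,
U 0.29 (the real control was genomic sequence of unstated composition; this
default is documented and configurable), and, in a configurable fraction of
tags, two copies of UAAA written over the background at an intervening
spacing drawn uniformly from 20–30 nt, the window where bipartite sites are
enriched in vivo.  Overwriting rather than inserting keeps lengths exact so
controls can be length-matched, mirroring the matched-control design.  A
tag too short for its sampled pair is lengthened to exactly the pair span
(or, in strict mode, raises an error naming the tag); with the default
length distribution this touches the short tail only.  Generators are pure
functions of their spec: one root seed, per-tag substreams derived with
`SeedSequence.spawn`, so output is bit-reproducible and independent of
generation order.  Ground-truth embedding records (tag index, offset,
spacing) are available on request for validation.  The control generator
produces one i.i.d. sequence per requested length; the number of control
sequences is a free parameter since no authoritative count exists.

Not emulated: crosslink-induced deletions/truncations, non-uniform genomic
sequence structure (repeats, composition heterogeneity), transcript-aware
sampling, or PCR duplication.  Passing tests on these synthetics therefore
show that the statistics recover known signals from i.i.d. backgrounds at
realistic sizes — not that real CLIP artefacts are handled.

The titration simulator evaluates the chosen isotherm on the default plate
design (two-fold serial dilution from 200 µM, 15 points plus a protein-free
well; probe 0.2 µM) and adds Gaussian noise of configurable sd (2% of a
200-unit amplitude in the recovery tests).

## Problem sizes in tests and the acceptance script

Simulation-backed checks use 2,000 tags (enrichment, type-I calibration,
spacing), 200 titration replicates for K_d recovery, and 10,000 random
50-mers for the brute-force oracle equivalences; all complete in seconds on
one core and give comfortably stable statistics at these sizes (the type-I
fraction of nominal-0.05 tests lands at 0.04–0.06 across seeds).

## Known limitations

- Exhaustive k-mer testing only: no Markov background, no motif discovery
  beyond enumeration, windows as the sampling unit (which ignores
  within-tag dependence between overlapping windows; the type-I calibration
  shows the practical effect is small at these sizes).
- The bipartite caller reports all core pairs without clustering; poly-A
  tracts legitimately yield many registered sites, and consumers should
  deduplicate per tag if they need one site per tag (the pipeline reports
  the per-tag has-site fraction).
- The FP module fits single curves; no global multi-curve fitting, no
  anisotropy/polarization unit conversion, no thermodynamic model of the
  dimer avidity mechanism beyond the K_d ratio.
- Structure handling is deliberately minimal: no mmCIF, no symmetry
  expansion, no validation; SASA radii cover C/N/O/S/P only (extend the
  table for ions or modified residues).
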