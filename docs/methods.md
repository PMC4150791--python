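# Methods

This note documents the models, conventions and numerical choices behind
`satselseq`, and what the synthetic-data checks do and do not establish
about real sequencing data.

## Reference amplicon and coordinates

The package operates on an amplified coding window of 99 codons covering
residues 71–169 of the deaminase gene, with the hotspot-recognition loop
L113-Y114-F115-C116-E117-D118-R119-K120-A121-E122-P123 at its centre.
Because no concrete optimized gene sequence is part of the analysis — only
the loop residues and the amplicon geometry matter — the default reference
(`library.default_reference`) is a **synthetic** construction: common
*E. coli* codons fill the flanks, and the loop codons are fixed constants.
Internally all coordinates are 0-based half-open offsets into the
amplicon; the user-facing interface speaks 1-based residue numbers.

One deliberate choice shapes the fixture: the wild-type codon at every
barcode slot is the C/G-ending synonym, so its silent barcode variant can
take a third base A or T. Codons ending A/T lie outside the NNS codon
space, which means a randomized NNS codon in the *neighbouring* library
can never masquerade as a positional barcode. Without this property, a
legitimate read whose NNS codon happens to equal the adjacent library's
barcode codon would carry two apparent barcodes and be rejected, silently
deleting one specific codon from that library's distribution. With it,
decoding at zero sequencing-error rate is exact. Non-NNS codons (possible
in real data through sequencing error at the third base) can still
collide with a barcode; such reads are rejected as
`multiple_positional_barcodes`, which is the conservative behaviour the
single-barcode filter implies.

## Library panel

`build_library_panel` designs one library per loop residue plus a
duplicate at Phe115 (12 libraries). The default barcode rule picks the
synonym with maximal Hamming distance from the wild-type codon,
alphabetical tie-break. The duplicate library needs a *different* silent
barcode, but Cys116 (the slot 3′ of Phe115) has exactly one synonym;
the builder therefore applies a barcode-offset override, advancing
downstream to the first slot offering an unused, collision-safe synonym
(residue 119, CGA). Duplicates are designed after all base libraries so
that every base library keeps the slot immediately 3′ of its NNS codon.
Signature uniqueness — no two libraries share a (slot, codon) pair — is
enforced and is what makes the panel decodable.

The covariation library is the Cartesian product of per-position
amino-acid choice sets: the wild type everywhere plus the mutants that
exceeded 20% of final-generation counts (F115 F/Y, E117 E/T,
D118 D/A/R/P, R119 R/G, K120 K/R, A121 A/R/P, P123 P/R), 384 variants.
The 2:2:2:2:1:1:1:1 pooling of eight sublibraries equalizes member
representation exactly when sublibrary sizes are (64, 64, 64, 64, 32, 32,
32, 32); those sizes are an inference from the stated ratio and the
stated equality of the 384 members, and are user-overridable.

## Read model and decoding

A read is `leader (4 nt) + generational barcode (8 bp) + anchor (12 nt) +
amplicon (297 nt)`. Decoding is **anchored**: the generational barcode is
matched exactly (configurable to 1 mismatch with nearest-unique
semantics), the constant anchor must match exactly at its fixed offset,
and the payload is then compared at fixed codon slots. No alignment is
performed; the noise model is substitution-only, so indels are outside
scope and surface as anchor/length rejections. Both orientations are
tried (forward, then reverse complement); when both fail, the reject
reason comes from whichever orientation progressed furthest, and a
failure at the anchor stage is reported as `orientation`.

The off-target substitution rate is estimated over accepted reads as
(mismatches ÷ comparable bases), where comparable bases exclude the
assigned library's NNS codon, *all* libraries' barcode slots and the
constant scaffold. This makes the estimator unbiased under the
substitution model, which the tests verify against binomial sampling
(pooled estimate within 3 SE of the configured rate over 20 seeds).

## Selection simulator

The campaign model is a chain of fitness-weighted multinomial
bottlenecks: the G0 library is a multinomial draw over the 32 NNS codons
(uniform by default, optionally skewed); each selection cycle draws B
survivors with probability proportional to count × w(variant); each
sequenced sample draws R reads proportional to population frequency and
applies i.i.d. substitutions at rate ε (uniform over the three
alternative bases). Fitness lives at the amino-acid level by default
(synonymous codons share w; stop codons default to w = 0, matching the
built-in stop-codon negative selection), with codon-level overrides.
Within-culture growth dynamics and plasmid copy number are deliberately
absorbed into relative fitness: one cycle of the wet protocol is a
plate bottleneck followed by regrowth, and only relative survival enters
the next generation's composition.

Defaults: initial depth 10⁴, bottleneck B = 10⁴ (warning below 10-fold
representation of the 32-codon library), 3 selection generations,
5 000 reads per (library, generation), ε = 7 × 10⁻⁴ per base (echoing the
observed 0.07%-per-nucleobase off-target rate). Randomness flows from one
master seed through `numpy.random.SeedSequence.spawn`, one child per
library and one grandchild per stage, so runs are reproducible and
per-library streams are independent.

The simulator is the oracle for the rest of the pipeline: at ε = 0,
decoding must reproduce the drawn read counts *exactly*; neutral fitness
must leave frequencies a martingale; two-variant selection must match
p′ = p·w₁/(p·w₁ + (1−p)·w₂) in expectation; and a full
simulate→decode→correct experiment must recover the rank order of the
injected fitness map (Spearman ρ ≥ 0.9 at the defaults above, averaged
over 5 replicate seeds). Passing these checks shows the pipeline is
internally consistent under its stated noise model; it does not show
robustness to real 454 artefacts (homopolymer indels, quality decay,
chimeric PCR products), which the model intentionally excludes.

## Enrichment statistics

Codon frequencies are counts/depth per (library, generation); amino-acid
frequencies aggregate synonymous codons over the 21-symbol space (20
amino acids + stop `*`, which is retained everywhere). Logo heights are
frequencies, not information bits. The G0 correction computes
e(aa) = [(c_G3 + α)/Σ] ÷ [(c_G0 + α)/Σ] with pseudocount α = 0.5 per
symbol and renormalizes per position; symbols absent from both
generations get height 0. The correction removes the codon-multiplicity
bias of NNS: an unselected amino acid with three codons (Arg at 3/32) and
one with a single codon (1/32) receive equal corrected heights, and a
pure multinomial resample of G0 converges to a uniform corrected logo as
depth grows (verified at depth 10⁵, tolerance 0.02). Each position is
normalized independently by its own frequencies; positions are not
weighted by read depth.

Replicate concordance uses Euclidean distance (∈ [0, √2] for frequency
vectors) and cosine similarity (∈ [0, 1] for non-negative vectors).
Fixation flags fire at a configurable frequency threshold, default 0.9.

## Assays

* **XXC preference profiles.** Product fractions of the 16 substrates
  (x2, x1 ∈ {A, mC, G, T}; mC is the 2-letter serialization of
  5-methylcytosine) are averaged, unweighted, over the four substrates
  sharing a nucleotide at the −1 or −2 position, then normalized to sum
  to 1 per position. The profile is invariant to uniform rescaling of the
  panel.
* **Fluctuation frequencies.** Per-culture frequency = resistant
  colonies ÷ viable cells; the summary is the across-culture mean ±
  sample SD. This is a frequency, not a Luria–Delbrück rate estimate —
  jackpot cultures inflate it, which is why group comparison works on
  log₁₀(frequency + 10⁻⁹) with a two-sided Welch t-test (a documented
  convention; an all-zero group falls back to a Mann–Whitney test).
  A power check: 4-fold shifted lognormal groups of 5 cultures are
  detected at α = 0.05 in ≥ 80% of 500 replicates.
* **Michaelis–Menten kinetics.** v = Vmax·S/(Km+S) fitted by bounded
  trust-region nonlinear least squares (`scipy.optimize.curve_fit`),
  initial guesses Vmax₀ = max rate and Km₀ = concentration nearest
  half-max, SEs from the Jacobian covariance. Noiseless model data are
  recovered to 10⁻⁶ relative error; mean bias stays below 2% at 5%
  multiplicative Gaussian noise (200 replicates, 6 concentrations).

## Trajectory analysis

Multi-model PDB files are parsed with Biopython; atoms are classed as DNA
by residue-name whitelist (DA/DC/DG/DT), everything else protein.

* **Contacts**: per-frame minimum Euclidean distance between a residue's
  atoms and any DNA atom, averaged arithmetically over the (optionally
  restricted) frame window.
* **H-bond occupancy**: fraction of frames in which ≥ 1 donor–acceptor
  pair satisfies distance ≤ 3.5 Å and, when hydrogen positions are
  available, donor–H–acceptor angle ≥ 140°. Both thresholds are closed
  (a pair exactly at the cutoff counts) and both defaults are
  conventions, configurable via `HBondCriteria`; without hydrogens a
  distance-only criterion applies with a warning.
* **SASA**: Shrake–Rupley quadrature with Bondi radii, probe 1.4 Å, and a
  deterministic golden-spiral point set, default 960 points (an isolated
  sphere is recovered within 1%; refinement to 10⁴ points changes
  two-sphere systems by < 2%). Fraction buried = 1 − mean SASA /
  reference, clamped to [0, 1]; the default reference is the theoretical
  maximum ASA of residue X in an extended Gly-X-Gly tripeptide
  (Tien et al. 2013 values), configurable because the reference state
  behind any particular published burial percentage is rarely stated.

Published MD-derived numbers for this system (H-bond occupancies of
0.2/22.6/73.7%, burial of 44.4/61.6%) depend on the original
nanosecond-scale trajectories and are **not** reproduced here; the
package computes the same quantities on user-supplied or toy
trajectories.

## Problem sizes used in the checked experiments

The test suite and the acceptance script size their simulations to the
defaults above: the exact-decoding check uses the full 12-library panel
at ~10⁴ reads; the off-target check pools 20 seeds × 1 000 reads; the
rank-recovery experiment uses 5 seeds × 4 generations × 5 000 reads on
one library; replicate concordance uses two independent campaigns at
depth 5 000. These sizes are the package's chosen study conditions and
are recorded here so results are interpretable at face value.

## Known limitations

* Substitution-only noise; no homopolymer/indel model, no quality scores.
* Anchored decoding requires reads that start at the leader; fragmented
  or adapter-trimmed-into-payload reads are rejected rather than aligned.
* The "rare *E. coli* codon" annotation uses a configurable default list
  ({AGG, AGA, CGA, CTA, ATA, CCC}); no universally accepted cutoff for
  rarity exists, and the list is used for reporting only.
* Fitness-map recovery is rank-based; absolute selection coefficients are
  not identifiable from frequency trajectories with unknown bottleneck
  composition.
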