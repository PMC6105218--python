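# Methods

This note records the models, conventions and design choices behind
`wwprofiler`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mass and ion conventions

Monoisotopic masses are sums of lightest-isotope exact masses (IUPAC 2013
atomic masses and representative abundances, embedded as static data in
`_elements.py`; never fetched). Only singly charged `[M+H]+` / `[M−H]−`
ions are modelled — the species an electrospray Q-TOF monitors for the
polar micropollutants handled here. Na⁺/K⁺ adducts and multiple charges
are out of scope (charge-2 envelopes are *recognised* during deisotoping
but not ionised or identified).

Two ionization-mass conventions are exposed because published reference
m/z tables are not always internally consistent:

* **proton** (default): ±1.00727646 Da, physically correct for gain/loss
  of H⁺;
* **hydrogen**: ±1.00782503 Da, i.e. a neutral H atom, neglecting the
  electron.

The packaged suspect list stores, per compound, the convention that
reproduces its published precursor m/z to the printed 4 decimals
(pharmaceuticals and parabens: proton; sweeteners and ibuprofen: hydrogen;
caffeine matches neither exactly and is stored as proton, 0.5 ppm off).
Pipeline-internal arithmetic — planting ions in synthetic runs, recomputing
screening targets from formulas, neutral-mass inference — always uses one
convention (proton by default), so the choice cancels end to end and the
printed values remain reproducible through the `convention` parameter.

Signed mass error is `(theoretical − experimental) / theoretical × 1e6`
ppm; this sign convention is fixed by the published error values the test
suite reproduces.

## Isotope patterns

`simulate_isotope_pattern` aggregates isotopologues into nominal-mass bins
(M, M+1, …): per element the single-atom distribution over integer mass
shifts is raised to the atom count by binary-exponentiation convolution,
elements are convolved together, and each bin reports the
probability-weighted mean exact-mass shift alongside its abundance as % of
the monoisotopic peak. No fine structure is modelled; for the compound
classes here the monoisotopic peak is the base peak and the aggregated
bins are what a unit-resolution-binned Q-TOF ratio check compares. The
test suite validates the convolution against an independent exhaustive
isotopologue-enumeration oracle (all per-element compositions, multinomial
weights) to 0.1 % absolute abundance.

## Feature extraction

Vendor feature-extraction algorithms are proprietary; this module defines
a transparent deterministic variant and does not attempt to match vendor
output. Order of operations: (1) drop centroids below the absolute noise
floor, 1300 counts by default, applied per centroid peak; (2) sort all
surviving peaks by m/z and split into groups at gaps exceeding the ppm
tolerance (default 10 ppm — the published workflow does not state one),
then split each group at scan discontinuities, keeping traces spanning ≥ 3
consecutive scans; (3) deisotope.

Gap-splitting makes trace assignment deterministic and invariant to scan
order; the classic "peak could join two traces" tie cannot arise because a
group is partitioned, not grown greedily.

Deisotoping walks traces in ascending m/z; members of an envelope must lie
at `k·1.00336/z` (charge 2 probed before charge 1, since a z=2 envelope
also contains an integer-spaced peak), co-elute within 0.1 min of the
monoisotopic apex, and stay below 1.1× the monoisotopic abundance —
permissive enough for trichlorinated M+2 ≈ M patterns, strict enough to
keep unrelated co-eluents apart. The spacing tolerance is **per
substitution step** (`k × 0.01` Da for M+k): heavy-isotope substitutions
(³⁴S, ³⁷Cl) displace aggregated bins by up to ~0.011 Da per step relative
to pure ¹³C spacing, which a flat 0.01 Da window would misclassify.
Observed envelope abundances are ratios taken at the monoisotopic apex
scan, which is exact for co-eluting Gaussian peaks even when trace edges
are truncated by the noise floor.

## Identification gates

Candidate formulas are enumerated exhaustively over a bounded CHNOPS+Cl
lattice by depth-first search with mass-window pruning (completeness is
tested against a nested-loop oracle). Plausibility filtering applies the
standard heuristic rule set: element-count bounds by mass window, integer
RDBE ≥ 0 for even-electron neutrals, H/C ∈ [0.2, 3.1], heteroatom/C caps
(N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8, Cl/C ≤ 0.8), and joint NOPS
caps. The TMS rule of the original rule set is GC-specific and excluded;
the isotope rule is realised as the isotope gate. Parameter values are the
rule set's published defaults, stored as editable configuration. When a
formula violates several rules the reported label is the first failure in
the order bounds → ratios → NOPS → RDBE.

The three acceptance gates are conjunctive: |error| ≤ 2 ppm; isotope
deviation ≤ 5 points (max absolute difference of relative abundances over
M+1…M+3, a simulated peak > 1 % with no observed counterpart compared
against 0); composite score > 98 %. **The composite score is this
package's own construction** — instrument vendors do not publish theirs —
chosen as a weighted sum of Gaussians in the three error terms
(weights 0.4/0.4/0.2, scales 2 ppm / 5 points / 0.005 Da) so that it is
100 at zero error, monotonically decreasing in each error, and ~37 when
every error sits exactly at its gate threshold. It lives behind a single
function so an alternative can be swapped in.

## Suspect screening

MS1 matching is polarity + |Δm/z| ≤ 2 ppm + |ΔRT| ≤ 0.5 min. The RT
tolerance is a declared default (the published workflow states none); the
screening target m/z is recomputed from the suspect's formula under the
pipeline convention rather than read from the stored table, so matching is
internally consistent. Targeted-MS/MS confirmation — a product peak within
0.01 Da of the published transition (2-decimal values, hence a dalton
tolerance) at ≥ 5 % relative intensity — is recorded as a separate flag,
mirroring the full-scan vs targeted acquisition split. In `run-all` the
confirmation spectra are themselves synthesized from the suspect entries;
the flag demonstrates plumbing, not independent evidence.

## Synthetic data

The generator emulates the monitored system: stages `hall_of_separators`
(raw influent), `secondary_settlement`, `effluent`; SPE protocols A/B/C
kept as sample labels only; both ESI polarities; m/z 100–1700; RT 0–25 min.

* **Suspects** are planted where the packaged reference presence matrix
  places them, at their published (methanol-gradient) retention times, at
  a fixed 4×10⁵-count base intensity.
* **Backgrounds** are anonymous random CHNOS formulas (rejection-sampled
  to pass the plausibility rules, with H-parity forced so RDBE is
  integral), log-uniform base intensities in 2×10⁴–8×10⁵ counts, uniform
  RT. Their ion m/z are kept ≥ 20 ppm apart and ≥ 5 ppm from suspect ions
  so ground truth maps one-to-one onto extracted features; this
  deliberately removes real-data co-elution/overlap ambiguity (see
  *Limitations*).
* **Stage attrition** is an independent Bernoulli per compound and
  transition, with survival 0.2 (positive) / 0.1 (negative) raw→secondary
  — the complements of the reported ~80 % / ~90 % removals — and 0.825
  secondary→effluent, the midpoint of the reported 15–20 % further
  removal. Background sets are drawn per (seed, polarity) only, so the
  same compounds exist across stages and protocols and removal is a
  well-defined per-compound property.
* **Peak model**: Gaussian chromatographic profile, σ = 0.15 min, scan
  spacing 0.05 min (≥ 5 scans above half-height; no peak shape is
  published), full simulated isotope envelope per species, optional
  Gaussian ppm mass jitter per centroid (default 0.5 ppm, a realistic
  Q-TOF value) and RT jitter (σ = 0.05 min). Sub-threshold noise centroids
  (10 per scan, uniform in m/z, below 0.95× the noise floor) give the
  extractor something to reject.
* **Matrix-effect set**: per compound, triplicate area pairs with
  A_matrix = factor × A_solvent and optional multiplicative noise.
  Saccharin (0.8073) and paracetamol (1.1247) factors are pinned by their
  published ME%; caffeine is 1.32; parabens and the remaining sweeteners
  sit inside the reported −90…−70 % suppression band; other
  pharmaceuticals get moderate suppression consistent with "suppression
  for most analytes".

All randomness derives from the mandatory config seed via independent
`numpy` Philox/PCG streams keyed by (seed, sample), so any sample is
reproducible in isolation.

Default campaign size is 300 background compounds per polarity; the
removal-percentage estimates in `scripts/acceptance.py` use 2000 per
polarity averaged over 10 seeds, a size at which the binomial sampling
error of a survival fraction is below 1 percentage point.

## What passing tests do and do not show

The synthetic generator produces well-separated, Gaussian, single-charge
peaks with exact isotope envelopes and no drift, carryover, adduct
variety, or co-elution. Recovering the reference detection matrix in all
108 cells and the 80 %/90 % removals on such data validates the *logic*
of the pipeline (thresholds, gates, bookkeeping), not its performance on
real chromatograms — matrix complexity, isotope-ratio distortion at low
abundance, and RT drift would all erode it. The real study's >4000-feature
inventory and its seasonal composition differences are not reproducible
(no raw data were deposited) and are explicitly out of scope.

## Numerical choices and degenerate inputs

* Mass-class bins are half-open ([100, 500), [500, 1000), [1000, ∞)); the
  prose description of the classes is boundary-ambiguous, so the
  convention is fixed here.
* Matrix-effect replicates are averaged *before* the ME formula (the
  aggregation is not specified with the formula); the SD of per-replicate
  ME% is reported alongside.
* Removal with a zero reference count is reported as missing (`None`),
  not an error; an empty run extracts to an empty feature list.
* Candidate ordering: score descending, then |ppm|, then formula string —
  fully deterministic.
* Detection-matrix CSV uses `+`/`-` tokens so files diff cleanly against
  the packaged reference table; RT is minutes everywhere; report m/z are
  printed at 4–6 decimals.

## Known limitations

Single-polarity files per extraction call; no profile-mode centroiding,
cross-run alignment, quantitation, or spectral-library scoring. The mzML
reader is a minimal self-contained implementation (MS1, centroided,
uncompressed or zlib 32/64-bit float arrays) — sufficient for
instrument-export subsets, not a general PSI parser. Formula
identification enumerates CHNOPS+Cl only by default; other elements
require explicit bounds.
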