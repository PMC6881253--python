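# Methods

This note documents the models, conventions, and design choices behind
`pipflank`, and what the synthetic generators do and do not emulate.

## Motif coordinate ladder and classification

All PCNA-binding motifs are compared on one coordinate ladder: the PIP-box
glutamine is coordinate 1 and the two aromatic anchors are 7 and 8.
Residues N-terminal of the glutamine take negative coordinates with no 0,
and residues past 8 are labelled +1, +2, … (stored internally as 9, 10, …
so ordering and contiguity are plain integer arithmetic). The five-residue
APIM core is anchored at 6…+2, reflecting the overlay of APIM- and PIP-bound
crystal structures, and is extended contiguously in both directions — so an
APIM peptide that begins two residues before its core starts at coordinate 4
and has no coordinate 1 at all.

Classification is flag-based: Q at 1; an aliphatic hydrophobic {L, M, I, V}
at 4; aromatics at 7 and 8, where the accepted set is {Y, F, W} (W included
so APIM-aligned entries, whose consensus allows W at 7, are not
misclassified); a basic {K, R} at +4 plus the anchors makes a PIP-degron.
By default a coordinate absent from an entry's ladder simply fails its
feature test; `strict=True` restores a hard error when coordinates 1–8 are
not all covered. The lenient default is what the set-level census needs,
since APIM entries legitimately lack coordinate 1.

Motif spans are taken from curation and never auto-detected: the observed
degeneracy (34% of the reference set lacks Q1; 10% lack both aromatics)
makes pattern-scanning ambiguous by construction. Census percentages round
half-up to integers, the convention of the printed statistics. The sequence
logo uses raw frequencies and information `log2(20) − H` with no
small-sample correction — at n = 83 the logo is descriptive, not
inferential. Alignment gaps (`-`) occupy a coordinate but are excluded from
logo counts.

### The packaged reference table

`data/table2_synthetic.tsv` is a *synthetic stand-in* for the curated
83-motif table, which is not available in machine-readable form. It
contains every motif whose sequence is public (p21, FEN1, MSH6, the UNG2
variant, Spd1, the APIM peptide, Srs2, CAF1, the archaeal DNA ligase, and
the designed peptides) plus filler rows engineered so the set reproduces
the published aggregate census exactly (28, 10, 36 and 8 entries of 83 for
the four degeneracy classes). Set-level statistics on this table are
faithful; per-row conclusions about the filler entries are not meaningful.
The census denominator is all 83 motifs, designed peptides included.

## Charge features

Two charge conventions are exposed. Integer mode (default): K, R = +1;
D, E = −1; His neutral; everything else 0 — the convention of the common
NCPR tools, used for parity with the published figures. Fractional mode:
Henderson–Hasselbalch charges at the stated pH with the standard
biochemistry pKa set (D 3.65, E 4.25, C 8.3, Y 10.1, H 6.0, K 10.5, R 12.5;
termini 8.0/3.55), under which His carries ≈ +0.04 at pH 7.4. Free termini
contribute a basic/acidic group only when the corresponding cap flag is
false (the synthesised peptides were N-acetylated and C-amidated, so caps
default to true).

NCPR windows are the motif plus up to `flank_len` residues per side,
counted in parent-sequence residues (the coordinate ladder's 0-skip plays
no role here), truncated at chain ends with truncation flags, and
normalised by the effective window length. The flank-length profile
averages only entries with complete (untruncated) windows at each length
and reports an undefined length as NaN, never zero — partially truncated
windows would otherwise contaminate the per-length comparison.

## NMR helicity

Secondary chemical shifts are Δδ(i) = δ_obs(i) − δ_coil(i); unassigned
residues carry no Δδ and are excluded from means. The shipped coil
reference is a compact Cα table for disordered peptides near 25 °C /
pH 6.3: per-residue baselines plus a small nearest-neighbour correction
table whose dominant term is the ≈ −1.9 ppm shift of a residue preceding
proline. Chain-terminal residues take no out-of-range neighbour term.
Only Cα is shipped; other nuclei raise an unsupported-nucleus error.

Fractional helicity is `max(0, ⟨Δδ⟩Cα / 3.2) · 100`, capped at 100:
3.2 ppm of mean Cα secondary shift corresponds to a fully formed helix.
Negative means (extended/coil sampling) clamp to 0%. The averaging window
defaults to all assigned residues and is restrictable to the motif span;
published per-peptide values use the motif window. For printed-table
comparison a half-up rounding helper reproduces the tables' mixed
precision (one decimal or integer per entry); the conversion itself is
kept unrounded.

## Binding models

**SPR steady state.** `Rss = KA·c·Rmax / (KA·c·n + 1)` with stoichiometry
`n` (default 1, fixable or fittable). The fit is parameterised in log(KA)
for conditioning; errors are reported on the KD scale. A fitted KD outside
[c_min/100, 100·c_max], or responses with no concentration dependence,
raise an unreliable-fit warning rather than failing silently.

**SPR single-cycle kinetics.** dR/dt = kon·c·(Rmax − R) − koff·R solved
piecewise-analytically across sequential injections with no regeneration;
the solution is continuous at segment boundaries and each dissociation gap
is a pure exponential decay. The global fit estimates (kon, koff, Rmax)
in log-rate space plus a flat baseline offset emulating reference
subtraction; mass transport and bulk shifts are out of scope. koff > 1/s
triggers a too-fast warning (the regime where only steady-state analysis
is trustworthy), and a trace the model cannot explain (fit R² < 0.5)
raises a convergence error.

**ITC, one set of sites, reverse titration.** The titrant is the clamp
trimer carrying `n` identical sites; the cell holds the peptide. Each
injection applies the exact stepwise displaced-volume recursion
(cell totals scale by 1 − dV/V0; titrant gains c_syr·dV/V0) rather than
the exponential approximation — chosen for bit-reproducible behaviour in
the small-injection limit, where total heat is conserved under splitting
an injection (verified to 1e−6 relative at dV/V0 = 1e−4). Bound complex
solves the mass-action quadratic on its cancellation-free branch
(cross-checked against bisection to 1e−10). The per-injection heat is
ΔH·V0·(B_i − B_{i−1}·(1 − dV/V0)) — newly formed complex net of complex
expelled — plus a dilution offset proportional to moles injected. ΔH is
per mole of bound peptide (per occupied site), so the stoichiometric-limit
total heat is ΔH·V0·min(n·[trimer], [peptide]).

The fit estimates (n, KA, ΔH, q_dil), or (KA, ΔH, q_dil) with `fix_n`.
When the fitted model still releases substantial binding heat in the final
injections (tail > 10% of the largest binding heat), the titration never
saturated, n is structurally unidentifiable, and the free-n fit raises an
error recommending `fix_n` — mirroring how the weakest charge-neutralised
variants must be handled. Alternatively the dilution baseline can be
subtracted as the mean of the last k = 3 injections (only valid at
saturation). First-injection discard is available but off by default. The
cell volume defaults to 200 µL (the small-cell instrument class);
configurable. Thermodynamics: ΔG = RT·ln(KD in M), −TΔS = ΔG − ΔH with
R = 8.314 J/(mol·K). Note the identity only balances with −TΔS = +190
kJ/mol for the strongest degron peptide (−230 + 190 = −40); a printed
table carries the opposite sign for that cell and the positive value is
used.

## Regressions

Affinities enter as natural log of KD in molar. Replicate affinities per
ligand are averaged arithmetically on the KD scale by default (the
simplest reading of "an average was used"); a geometric option is exposed.
OLS comes from statsmodels; the p-value is the two-sided slope test.
Fewer than 3 points or zero variance in either variable raise a
degenerate-regression error rather than returning numbers.

## Disorder consensus

Predictors are never executed by this package — per-residue score tracks
arrive as files, keeping the build download-free and predictor versions
pinned by the user. Consensus is the per-residue mean across predictors;
disordered means mean ≥ 0.5 with the threshold inclusive. A motif
annotation averages the consensus over the motif residues only (the window
is configurable) and reports whether every predictor's own motif-average
falls on the same side of 0.5 (`consistent`). Tracks with missing residues
are rejected, not imputed.

## Synthetic generators and what passing tests show

All generators use `numpy.random.default_rng(seed)`; identical arguments
and seed give bit-identical output. Noise is Gaussian throughout — the
simplest defensible choice, with sigma configurable; real instrument
artifacts (drift, spikes, bulk refractive-index jumps, baseline curvature)
are deliberately not emulated, so parameter-recovery results bound
statistical error only, not systematic error on real data.

Default generator conditions are the measured designs: sensorgrams use
five sequential two-fold injections (90 s contact, 225 s dissociation,
lowest concentration first, top 200 nM) at kon = 1.7×10⁶ /(M·s),
koff = 0.14 /s; isotherms use a 200 µL cell of 10 µM peptide titrated
with 40 µM trimer in 19 × 2 µL injections at 25 °C with truth n = 3,
KD = 67 nM, ΔH = −230 kJ/mol; ITC noise scales the largest |heat|
(2% in the recovery studies), SPR noise is absolute in RU (2 RU ≈ 2% of
Rmax) or relative to the plateau for steady state. The charge-graded
motif generator builds flanks from an S/G backbone with K/R or E/D
substitutions hitting each target integer net charge exactly, then draws
ln KD = a + b·NCPR + N(0, σ).

Recovery envelopes computed by the test suite at these conditions:
single-cycle kinetic KD within 5% per seeded fit; steady-state KD within
10% at 1% noise; ITC median fitted n within 3 ± 0.2 and median |KD error|
< 15% over 100 seeds; regression slope within two standard errors at
n = 50. Problem sizes (100 ITC seeds, 30 SPR seeds, 1000 oracle draws)
keep the whole suite under a few seconds while giving stable medians.

## Known limitations

* Set-level conclusions from the packaged reference table are faithful to
  the published census; its filler rows are synthetic sequences.
* The coil reference is Cα-only and condition-matched to 25 °C / pH 6.3;
  shifts measured at other conditions (e.g. 4 °C) are used uncorrected.
* SPR kinetics assume 1:1 interaction without mass transport or surface
  heterogeneity; ITC supports one set of sites only — no sequential or
  multi-site models, and no global SPR+ITC co-fitting.
* NCPR is the only charge descriptor; patterning metrics (kappa, SCD) and
  electrostatic surface calculations are out of scope.
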