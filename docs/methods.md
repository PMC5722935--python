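# Methods

This note documents the models implemented in pepflux, the parameter
choices that matter, and what the bundled synthetic data can and cannot
show about real experiments.

## Substrate fixture

The bundled substrate is the mature bovine serum albumin chain (UniProt
P02769 residues 25–607; the 607-residue precursor minus the 18-residue
signal peptide and 6-residue propeptide), 583 residues and therefore 582
peptide bonds. The FASTA is a *synthetic reconstruction* assembled from
the published sequence literature rather than a verbatim database export
(see `pepflux/data/bsa_mature.fasta`). Its consistency was checked three
ways: the 582-bond arithmetic; the flanking contexts of 41 of the 43
peptides in the bundled reference annotation table occur verbatim (the two
misses, `(W)/LLL/(L)` and `(L)/GLAY/(P)`, are impossible in P02769 under
any reading — BSA carries only two tryptophans, neither followed by LLL —
and are quirks of the source table, not of the chain); and the pepsin
calibration below lands exactly on the expected site count.

## Cleavage rule engine

Enzyme specificity is a declarative document: a list of rules over the
P4..P4' window around each bond, each rule either *licensing* or
*vetoing* cleavage, with veto precedence. Constraints are residue-set
memberships (`in`) or exclusions (`not_in`). The bundled pepsin variants
transcribe the Keil/PeptideCutter two-row tables: cleavage licensed by
F/L (pH 1.3 variant) or F/L/W/Y (pH > 2 variant) at P1 or P1' (the P1'
route additionally requires P1 ≠ R), vetoed by H/K/R at P3 or proline at
P2 or P2'.

**Terminus semantics** was a genuinely open design point. We treat a
positive (`in`) constraint at a position beyond the chain as failed and a
negative (`not_in`) constraint as vacuously satisfied, matching the
PeptideCutter convention of not inventing residues beyond the termini but
also not letting an unverifiable veto fire. The alternative (blocking:
any out-of-window position forbids cleavage) yields 146 sites on the
bundled chain; the adopted semantics yields 147 — the difference is the
final L582|A583 bond — and 147 is the count the workflow's DH_max of
25.26% is built on. The calibration test pins this choice.

Peptide enumeration supports specific (fragments between cleavage
boundaries with at most `max_missed` internal sites), semi-specific (one
end on a boundary) and non-specific (all substrings, guarded by a
1000-residue parent cap because the pool grows quadratically) modes.
Coordinates are 1-based inclusive; bond *i* joins residues *i* and *i+1*.

## Masses

`peptide_mass` sums pyteomics' monoisotopic (or average) residue masses
plus water, with an explicit proton for the [M+H]+ form. All peak-list
comparisons in the workflow use singly protonated monoisotopic masses:
the reference table's MW column is reproduced within 0.006 Da under that
reading, and its tripeptide entries (IAF 350.21, FTF 414.20) are
unambiguous anchors. Mass tolerance is absolute (±0.3 Da default), not
ppm, matching low-resolution peak-list matching practice. Peaks closer
than 0.005 Da within one stream are merged (areas summed, area-weighted
mass) before matching to emulate chromatogram integration.

## Identification and exclusion rules

A mass is `unique` when exactly one *distinct sequence* lies within
tolerance (repeat occurrences of one sequence at different coordinates
count once), `ambiguous` for two or more, `unmatched` otherwise. Accepted
identifications are unique hydrolysate matches; ambiguous masses and
masses seen only in a permeate (physically impossible without a feed
counterpart; instrument artefacts) are logged with reason codes. The
exclusion *behaviour* is the contract; the counts reported for any given
instrument run depend on that run's peak lists.

## Charge, pI and grouping

Net charge is the Henderson–Hasselbalch sum: +1/(1+10^(pH−pKa)) for the
N-terminus, His, Lys, Arg; −1/(1+10^(pKa−pH)) for the C-terminus, Asp,
Glu, Cys, Tyr. It is strictly decreasing in pH, so the pI is the unique
zero crossing, found by bisection on [0, 14] to 1e-3.

Four pKa tables are bundled (EMBOSS-style, Sillero, Lehninger, and the
default `table1-calibrated`). The calibrated table was fixed analytically
from the reference annotation table's charge columns, which quantise to
+0.90/+1.90/… at pH 2 and to multiples of 0.5 at pH 10: a C-terminal pKa
of 2.98 makes a free carboxyl contribute −0.10 e at pH 2; Tyr = Lys =
10.0 contribute ∓0.5 e at pH 10; Arg = 12.0 contributes +0.99; the
N-terminus at 8.0 is discharged (+0.01) at pH 10; Cys = 8.3, Asp = 3.9,
Glu = 4.25, His = 6.0. Maximum deviation over all 86 reference entries is
≈0.03 e.

Grouping is acid pI < 5.0, basic pI > 8.0, neutral otherwise; boundary
values (exactly 5.0 or 8.0) fall to neutral because the defining
inequalities are strict and neutral is the enclosing interval. The
calibrated table reproduces 41/43 reference group labels and all 10 acid
labels. The two exceptions, HTLF and HVKLVNE (labelled basic in the
source table), compute to pI ≈ 7.0 with *any* pKa table whose N-terminal
pKa is consistent with the pH-10 charge column (pKa ≤ 8.7): a
His/Lys-dominated tetra-/heptapeptide cannot cross zero above pH 8 once
the N-terminus is that acidic. This is a documented irreducible
disagreement with the source annotation, not a tuning target.

Two further source-table misprints are documented rather than absorbed:
the printed GRAVY of ACFAVE (0.87) and VAF (2.90) differ from the
Kyte–Doolittle means (1.60 and 2.93) that exactly reproduce the other 41
rows, including the single-residue-pinned entries (LLL = 3.80 = the Leu
scale value). The corresponding acceptance test asserts the full column
and is expected to fail on exactly those two rows.

## pH-stat degree of hydrolysis

DH(%) = 100·A·N_A/((1−α)·h_TOT·M_p), with (1−α), h_TOT and M_p all in
the denominator — the standard pH-stat form; a printed one-line version
of this formula is ambiguous in grouping and we fix it this way. Defaults
mirror a peptic serum-albumin digest: α = 0.325, h_TOT = 8.8 meq/g,
M_p = 3 g, 0.1 N titrant. Non-monotone titrant series are clamped to the
running maximum with a warning (instrument jitter), never silently.
Plateau onset is the start of the earliest run of ≥ 2 consecutive
sub-threshold intervals (default < 1% relative DH per 15 min — the
sampling interval of the emulated experiment) extending to the end of
the series; two-point series are never flagged. Relative DH is
100·DH/DH_max.

## Sieving transmission model

Tr_theo = 100·(1−(λ(λ−2))²)·exp(−0.7146·λ²), λ = (MW/MWCO)^0.4. For
λ ≥ 1 the raw polynomial rebounds positive (on 1 < λ < 2), which is
unphysical for a sieving coefficient, so transmission is clamped to 0.
MW defaults to the same charge form as the peak lists ([M+H]+
monoisotopic) for internal consistency. Observed transmissions above 100%
are retained and flagged as quantitation anomalies rather than truncated.
Separation factors average over *all* group members by default
(undetected peptides contribute Tr = 0), because the factor is defined
over "the number of peptides comprised" in each group and near-zero
group means are meaningful selectivity signals; a detected-only mode is
available for sensitivity analysis.

## Synthetic-data generator

The generator emulates the study design, not the instrument: a 3 g/L
peptic digest of the bundled chain, 60 peptides sampled from the specific
digest (≤ 1 missed cleavage), lognormal abundances (log-location 4,
log-scale 1), multiplicative lognormal area noise (σ = 0.2), Gaussian
mass jitter (σ = 0.05 Da, so the default 0.3 Da matching tolerance is 6σ),
two membranes (1 and 5 kDa) at pH 2 and 10, and a first-order pH-stat
curve with k = 0.03 min⁻¹ (plateau from ~2 h, as in the emulated
experiment), A_inf = 29.5 mL (the titrant volume whose asymptotic DH is
≈65.5% of DH_max at the study constants) and additive noise σ = 0.3 mL
on a 0–180 min grid in 15-min steps.

Ground-truth permeate transmission is *invented for testability*:
sieving × a logistic charge attenuation 2/(1+exp(c·|z|)) × an
exponential hydrophobicity penalty above GRAVY 1.5. It encodes the
qualitative physics (charge effects dominate sieving; hydrophobic
peptides adsorb to polyethersulfone) but is not an experimental
separation model; with c = h = 0 it degenerates to pure sieving, which
the tests exploit. What passing tests show is therefore that the
*pipeline* recovers whatever structure generated the data at the stated
noise levels — not that the transmission model predicts real membranes.
Not emulated at all: co-elution and retention-time structure, isotope
envelopes, fouling/flux dynamics, enzyme kinetics beyond the first-order
titrant curve.

Randomness flows from one seed through documented substreams (spawn key
0: hydrolysate; 1 + condition index: filtration; 2: pH-stat), so
changing one stage's noise never perturbs another and every run is
reproducible bit-for-bit.

## Numerical and reporting choices

Internal arithmetic is unrounded; 2-decimal rounding happens only at
presentation (TSV reports), with full precision preserved in the JSON run
log. pI bisection tolerance 1e-3; peak-merge window 0.005 Da; candidate
ordering by |Δm| then start coordinate (a deterministic tie-break for
isobaric candidates). The acceptance script reports percentages on the
0–100 scale.

## Problem sizes

The test suite and acceptance script run on the bundled 583-residue
substrate (pool sizes: ~10³ specific peptides at ≤ 1 missed cleavage,
~1.7·10⁵ non-specific substrings via prefix-sum mass annotation),
100-peptide synthetic tables, and 50 pH-stat replicates — sizes chosen so
a full desk run completes in well under a minute while keeping
Monte-Carlo errors small against the stated tolerances.

## Known limitations

- The substrate FASTA is a reconstruction; downstream numbers tied to it
  (147 sites, DH_max) inherit that provenance, though three independent
  consistency checks support it.
- Reported bench quantities that depend on undeposited raw chromatograms
  or titration data (experimental relative DH, per-peptide observed
  transmissions, experimental separation factors) are out of reach at
  desk scale; the package substitutes property-based checks on synthetic
  data and documents the closed-form spot values it can verify.
- No post-translational modifications, disulfide-linked species, ppm
  tolerances by default, or structure-dependent pKa shifts.
- Bioactivity scores are consumed as data; the package never predicts
  bioactivity.
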