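# Methods

This note documents the models, heuristics, numerical choices and known
limitations of `venomkit`, module by module.

## Precursor segmentation

Toxin precursors are modeled as four contiguous regions — signal peptide,
propeptide (possibly absent), mature toxin, amidation tail (possibly
absent) — that jointly partition the translated ORF, with 1-based
inclusive coordinates.

**Signal boundary.**  A dedicated signal-peptide predictor is out of scope;
the boundary k is chosen heuristically in a window (default 15–30) to
maximize the mean Kyte–Doolittle hydropathy of the core residues 5..k−5,
subject to (a) a run of ≥ 8 consecutive core residues above +1.5 and
(b) small residues (A/G/S/C) at the −1 and −3 positions of the cleavage
site (the von Heijne rule).  All four thresholds are configurable via
`SegmentationConfig`.  This is an approximation: it recovers boundaries
exactly on the synthetic libraries (which satisfy its assumptions by
construction) but will disagree with HMM-based predictors on borderline
real sequences.

**Propeptide.**  Spider-toxin propeptides end in a processing quadruplet
motif.  It is operationalized as three residues containing at least one
Asp/Glu followed by Arg, with cleavage after the Arg; when several motifs
precede the first cysteine of the downstream region, the last one wins,
and when none exists the propeptide is empty.  The published definitions
of the motif vary; this operationalization is a documented design choice.

**Amidation.**  A C-terminal tail matching Gly + up to two Lys/Arg marks
the preceding residue for amidation; the tail (1–3 residues) is trimmed
and the amide flag set.  The mass delta is −0.9840156 Da (−O +N +H).  The
rule is idempotent unless the trimmed peptide itself ends in the motif
(e.g. a Gly-Gly terminus) — an intrinsic ambiguity of C-terminal poly-Gly
that no sequence-level rule can resolve; the trimming is additionally
suppressed when it would leave a mature peptide shorter than 10 residues.

**Families.**  Mature toxins are clustered by single linkage, where a link
requires identical cysteine counts and global-alignment identity (match 1,
mismatch 0, gap −1; identity = matches / alignment columns) at or above
the configured threshold.  Representatives and processing order are
lexicographic, making the clustering order-independent.

## Masses and isotope envelopes

All masses derive from one vendored table of isotope masses and
abundances (IUPAC/CIAAW 2021 recommended values) in `_tables.py`; the
proton mass is 1.007276466 Da.  A proteoform's composition is Σ residue
formulas + H₂O − n_disulfides·H₂ + (−O +N +H if amidated) + fixed-mod
deltas; carbamidomethylation is +57.02146 Da / +C₂H₃NO.

Isotope envelopes are exact polynomial convolutions of the per-element
distributions, computed per element by binary exponentiation and
aggregated at unit (nominal-mass) resolution — each bin's exact mass is
the abundance-weighted mean of its isotopologues, matching how the peaks
of an MS1 cluster are read.  Fine isotopic structure is deliberately not
resolved.  Convolution products below 1e-15 are dropped during
accumulation and the final envelope is pruned at a configurable floor
(default 1e-4), so abundances sum to ≤ 1.  Correctness is checked against
a combinatorial oracle that enumerates all isotopologues of ≤ 8-atom
compositions, and against the identity that the abundance-weighted
envelope mean equals the average mass.

## Digestion and fragments

Trypsin cleaves C-terminal to Lys/Arg; the "not before Pro" exception is
available behind a flag and off by default (the identified peptides of the
flagship toxin do not constrain it — its sequence has no KP/RP).  GluC in
bicarbonate buffer cleaves after Glu and Asp.  Digestion enumerates all
peptides with at most the configured number of missed cleavages (stored
count = internal sites, re-derivable by scanning).  Amidation is a
property of the parent C-terminus only: it propagates to the single
parent-C-terminal digest peptide, and within fragment series only to
y-ions.  b/y ions use the conventional definitions (b = protonated
N-terminal residue sum, y = protonated C-terminal residue sum + water),
with charges {1} by default — at a fragment tolerance of 0.02 Da,
singly charged ions dominate the interpretable signal.

## Spectral search and FDR

The search engine is intentionally simplified and is this package's own
(the false-discovery behavior is validated by simulation with known
ground truth, not by replicating any production engine).  Candidates are
digest peptidoforms within a precursor ppm tolerance (default 10 ppm);
fragments match greedily one-peak-one-fragment in ascending m/z at an
absolute tolerance (default 0.02 Da).  The score is a hyperscore variant,
`log(n_b! · n_y!) + log(I_matched/I_total + 1e-6)`, invariant to peak
order and uniform intensity scaling.  A PSM must match at least 2
fragments: a single chance peak carries no sequence evidence, and such
matches are systematically invisible to the decoy model because a
reversed protein rarely yields a digest peptide at the same precursor
mass.  Ties break toward fewer modifications, then lexicographic peptide.

Decoys are full sequence reversals, 1:1 with targets; protein-level
C-terminal amidation is a variable hypothesis for the C-terminal peptides
of mature entries, applied identically to their decoys so the null model
stays unbiased.  q-values use the classic target–decoy quotient with tied
scores counted as one threshold group, monotonized from the bottom of the
ranking.  Calibration is verified on (a) pure-noise runs (1000 spectra
whose precursors sit on candidate masses drawn from the full index) and
(b) mixed runs of 200 true + 200 noise spectra, where the empirical FDR
among accepted PSMs stays within the stated bounds.

## Intact matching

MS1 isotope clusters are detected greedily, longest run first, as peak
series spaced 1.00336/z (the ¹³C spacing, adequate below ~10 kDa) for
z = 1..8 within a spacing tolerance; the monoisotopic m/z is the first
peak of the run.  Chromatographic peak-shape fitting is out of scope:
extracted-ion-chromatogram logic reduces to per-scan detection plus
aggregation of clusters whose neutral masses agree (default 10 ppm) into
one species.  Each candidate sequence is scanned over the exhaustive
hypothesis grid n_disulfides ∈ {0..⌊nCys/2⌋} × amidated ∈ {false, true};
the best hypothesis minimizes |ppm error| against the intensity-weighted
species mass, and a sequence without a hypothesis inside tolerance
(default 5 ppm, capped at 20) is reported unmatched — a result, not an
error: an undetected propeptide is itself informative.

## Structure metrics

Disulfides are all Cys pairs with Sγ–Sγ ≤ 2.5 Å, assigned greedily
shortest-first with each cysteine used once.  β-turns require
Cα(i)–Cα(i+3) ≤ 7 Å with a non-helical center; types I/I′/II/II′/VIII
come from the canonical (φ,ψ) table at i+1/i+2 with ±30° tolerance (±45°
on one angle), type IV otherwise; γ-turns are typed from (φ,ψ) of the
central residue (classic 75°/−65°, inverse −79°/69°).  The ICK core is
the three-bond subset whose six cysteines, ranked by sequence position,
connect 1–4, 2–5, 3–6; remaining bonds are labeled "C-terminal clamp"
(one partner is the last cysteine), "hairpin staple" (both partners
strictly between the 4th- and 6th-ranked core cysteines), or "other".
Superposition is least-squares Kabsch (via scipy's rotation alignment);
the Q-score consumes precomputed alignment statistics — the graph-based
alignment search of structure-comparison servers is not reimplemented.
NOE calibration is d = d_ref · (I_ref/I)^(1/6), clipped to [2, 6] Å.
Disulfide restraints follow the standard annealing convention: per bond,
Sγ–Sγ ∈ [2.0, 2.1] Å and both Cβ–Sγ pairs ∈ [3.0, 3.1] Å, i.e. three
upper and three lower bounds per bond.  β-sheet detection (backbone
N···O ≤ 3.5 Å between residues more than two apart) is a deliberately
approximate stand-in for a full secondary-structure assignment.
Hydrophobicity profiles are sliding-window means of the Wimley–White
water→interface scale (His in its neutral form; negative = hydrophobic).

## Synthetic data: what it emulates and what it does not

Each generator is a pure function of (parameters, seed) with its own
random stream, and ships ground truth sufficient for exact scoring.

* **Precursor libraries** emulate prepropeptide architecture: signal
  peptides of 18–26 residues with an L/I/V/F core and small residues at
  the −1/−3 positions; propeptides of 5–25 residues over D/E/N/Q/T ending
  in an acidic triplet + Arg; mature regions built on a cysteine
  framework (default: the 10-cysteine pattern of the flagship toxin) with
  randomized loops; a Gly + two-basic amidation tail with probability
  0.75.  Reverse translation uses one fixed codon per residue, chosen so
  no codon ends in "A"/"AT" — this provably excludes cross-junction ATGs,
  making the embedded ORF unique.  Real transcripts are messier in every
  respect (ambiguous signals, motif variants, UTR ORFs), so exact
  boundary recovery on these libraries demonstrates internal consistency
  of generator + annotator, not real-world SignalP-level accuracy.
* **MS/MS runs** give one spectrum per peptidoform: Gaussian precursor
  ppm error (sd 3 ppm, within the 10 ppm search tolerance), all 1+ b/y
  ions minus a dropout fraction with 0.004 Da jitter (within the 0.02 Da
  tolerance), log-normal intensities, and uniform noise peaks.  No
  chimeric spectra, retention-time structure, or charge-state physics.
* **MS1 runs** place exact isotope envelopes at charges 4–7 with
  log-normal per-charge scaling plus noise peaks, in a single scan.
* **Toy structures** build an ideal-geometry backbone from randomized
  extended-region torsions (NeRF placement; bond lengths/angles standard)
  and pin the Sγ atoms of requested pairs 2.03 Å apart about their Cβ
  midpoint, rejecting conformers where unrelated Sγ atoms fall within
  3 Å.  They are labeled synthetic: locally plausible, not folded chains.

## Problem sizes and numerical choices

The test suite uses 200-record precursor libraries, 200-spectrum
closed-loop identification runs, 1000-spectrum null simulations for FDR
calibration, and 50 random scaffolds for disulfide recovery — sizes at
which the Monte-Carlo bounds quoted in the tests (e.g. α + 2 standard
errors) are meaningful while the whole suite stays fast.  Floating-point
tolerances: masses asserted at 0.01 Da against printed values and 1e-6
Da against internal identities; superposition RMSD at 1e-6 Å (SVD noise);
isotope abundances at 1e-12 against enumeration.  Degenerate inputs are
errors where silence would corrupt results (collinear point sets,
non-cysteine disulfide partners, duplicate cysteine usage, unsorted MS1
peaks) and reported outcomes where absence is informative (unmatched
intact candidates, empty digests of site-free sequences).

## Known limitations

Signal-peptide and turn assignments are heuristic approximations; the
search engine omits rescoring, isotope-error correction, protein-level
FDR and >1+ fragment charges; intact matching does not deconvolve
overlapping envelopes; the agreement of turn classification with
published per-residue turn lists depends on deposited coordinates and is
an integration-level check, not a unit property.
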