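# Methods

## Scope

`tenttail` implements the two quantitative arms of a TENT (template-
independent terminal nucleotidyltransferase) characterization study:

1. **3′-RACE-seq tail analysis** — recover the nontemplated 3′ extension
   ("tail") the enzyme added to a defined RNA substrate, and summarize tail
   lengths and nucleotide composition.
2. **Fluorescence-anisotropy binding analysis** — estimate the dissociation
   constant K_d of a fluorescent nucleotide probe (saturation) and the IC50
   of each unlabeled NTP (competition), with uncertainties.

A synthetic-data module generates both kinds of raw data with known ground
truth and exact analytic expectations; it is tested, first-class code, not a
fixture.

## Tail calling

### Read model

An amplicon read in sense orientation is assumed to be

    prefix  +  b^k  +  tail  +  adapter  +  (ignored trailing bases)

where `prefix` is the substrate's leading sequence (22 nt by convention),
`b` its terminal base (A or U, DNA-encoded as A/T) with substrate-encoded
copy number `k = terminal_count` (default 4), and `adapter` the 21-nt
oligonucleotide ligated to every 3′ end before reverse transcription.

### Selection and trimming rules

* **Prefix**: the read must *begin* with the exact prefix (zero mismatches
  by default; a mismatch-tolerance knob exists but defaults to 0 because the
  selection criterion is an entirely correct substrate sequence).
* **Adapter**: leftmost exact occurrence of the full adapter at or after the
  prefix end; bases after it are ignored. Leftmost is a deterministic
  tie-break for pathological reads carrying two adapter copies.
* **Insert length**: the sequence between prefix end and adapter start must
  be ≤ `max_insert` (default 100 nt); longer inserts are contaminants
  (`INSERT_TOO_LONG`).
* **Trimming**: remove `min(leading run of b, k)` bases from the 5′ end of
  the insert; the remainder is the tail. Anchoring the trim at the substrate
  side makes it equivalent to reversing the insert and right-trimming the
  homopolymer: ambiguous nucleotides (a tail that itself starts with `b`)
  are attributed to the *tail* once the substrate quota k is exhausted. The
  "up to k" wording also covers inserts with fewer than k leading copies of
  `b` (partial substrate degradation): these are retained and counted in a
  QC field (`n_short_substrate_run`), never rejected.
* Reads whose insert is exhausted by substrate bases are **UNTAILED** — a
  reported class, not a rejection.
* An optional low-complexity rule (reads failing the prefix match whose
  total length is shorter than prefix + threshold) exists but is **off by
  default**: its published definition ("a short stretch of ACTG") is
  ambiguous, and mis-applying it risks discarding untailed products.

Offsets are 0-based half-open throughout; the insert is
`[prefix_end, adapter_start)`.

### Invariants

For every non-rejected read, `prefix + b^trimmed + tail + adapter` is a
prefix of the original read; TAILED + UNTAILED + REJECTED = input count;
calling is idempotent. On clean synthetic reads the called tail equals the
generator's tail at 100% of reads — exactness is achievable because both
matching rules are exact and the bundled placeholder adapter is border-free
(no proper prefix equals a suffix), so an exact adapter match can never
shift left into the insert. Users supplying their own adapter sequences
should prefer border-free oligos for the same reason (true sequencing
adapters generally are).

## Composition statistics

Rejected reads never enter a denominator. The tailed fraction is
`TAILED / (TAILED + UNTAILED)`. Length statistics are reported both with
untailed products included as length 0 (the default) and restricted to
tailed reads, since either convention is defensible for "mean tail length".

The per-position matrix is **3′-anchored**: position 1 is the last added
nucleotide, and position *p* is computed over the `n_p` tails of length
≥ *p* (coverage(p) = n_p / n_tailed, non-increasing in *p*). Positions with
coverage < `min_coverage` (default 0.05) or beyond `max_positions` (default
25) are excluded from the report, but coverage itself is recorded for every
position; the thresholds are display rules, so pooled ("overall")
frequencies always use every tail nucleotide. The coverage comparison is
inclusive (exactly 5% is reported, exactly 4% is not). Row frequencies sum
to 1 by construction; a conservation identity (Σ_p coverage(p) · n_tailed =
total tail nucleotides) is tested. Everything user-facing is in the RNA
alphabet (U, not T); sequences are DNA internally.

## Binding models and fits

### Models

* Saturation (one-site specific binding):
  `A(P) = A_free + (A_max − A_free) · P / (K_d + P)`, P = protein
  concentration in nM. Ligand depletion is deliberately ignored even though
  the probe (50 nM) is not negligible against K_d ≈ 250 nM: the simple
  hyperbola is the stated analysis model, and a depletion-aware quadratic
  model is out of scope.
* Competition:
  `A([NTP]) = A_free + (A_bound − A_free) / (1 + [NTP]/IC50)`. At zero
  competitor A = A_bound; at [NTP] = IC50 the anisotropy is the midpoint.
  No Hill coefficient, no two-site variant, no Cheng–Prusoff conversion to
  K_i (the assay reports IC50).

### Fitting

Both fits are unweighted nonlinear least squares (no weighting scheme is
assumed for the raw anisotropies). The midpoint is parameterized as
log10(nM): this enforces positivity and roughly equalizes curvature across
the 4 decades of a titration. To avoid local minima, fits are multi-started
on a log10 grid spanning one decade beyond the titrated range (8 starts by
default; the residual landscape in log-midpoint is benign, and in practice
all starts converge to the same optimum on identifiable data).

The competition fit is **global**: one shared log10(IC50) plus one
(A_free, A_bound) pair per experiment, stacked into a single residual
vector. Per-experiment plateaus absorb day-to-day offsets in raw anisotropy
while every experiment informs the midpoint. With a single experiment the
global fit reduces exactly to an independent 3-parameter fit (tested to
1e-8).

Uncertainties: covariance `s²(JᵀJ)⁺` with `s² = RSS/(n − p)` (pseudo-inverse
so that degenerate data do not raise); standard errors on the nM scale by
the delta method (`SE(IC50) = ln10 · IC50 · SE(log10 IC50)`); confidence
intervals on the log scale with Student-t quantiles, then exponentiated;
pointwise confidence bands for the fitted curve by the delta method using
the analytic gradient. The ± values reported are asymptotic standard errors
(the convention of the common fitting packages).

Diagnostics: a saturation fit is `converged=False` when the optimizer
fails, the Jacobian is rank-deficient, the amplitude A_max − A_free is
negligible, or K_d sits at the search bound. A competition fit is
`identifiable=False` under the analogous conditions or when the IC50
confidence interval spans more than two orders of magnitude — flat
(no-displacement) data therefore return a flagged result rather than an
exception, while structurally underdetermined inputs (fewer than 3 distinct
saturation concentrations; any experiment with fewer than 2 distinct
concentrations) raise `UnderdeterminedError`.

## Synthetic data generator

### Reads

A `TailModel` specifies a length distribution over 0..L_max and per-position
base frequencies (5′→3′ along the tail), with overrides keyed by distance
from the 3′ end that take precedence — this is the minimal parameterization
that can express "C preferred at the last and penultimate positions"
independently of tail length. The default model emulates a C/U-adding
enzyme profiled with all four NTPs present:

* lengths 0–7 nt, P(0) = 0.25, decaying thereafter (mean 1.73 nt overall);
* interior positions A 0.63 / C 0.26 / G 0.01 / U 0.10;
* last position C 0.62, penultimate C 0.48;
* giving overall expectations of 47.3% C, 42.9% A, 9.1% U, 0.7% G — i.e.
  tails that are 40–50% cytidine with <1% guanosine and single-digit
  uridine, the signature this class of enzyme shows in RACE-seq profiling.

Contaminant classes exercise each rejection rule: `no_prefix` (prefix
replaced by a random same-length sequence guaranteed to differ in ≥ 1
position), `no_adapter`, `long_insert` (insert padded with random bases to
150 nt > the 100 nt limit), and `junk` (≤ 5 arbitrary bases plus adapter,
rejected at the prefix rule). Counts are allocated exactly as
`round(fraction · n)`; the default total is 10% split 4:3:2:1. Qualities
are constant `I` since the pipeline ignores them.

`expected_composition` computes the model's exact per-position frequencies,
coverage `P(L ≥ p)` and overall base usage by finite summation over the
length support; positions with zero coverage are reported as undefined
(NaN), not zero. Note the analytic coverage is over the full length
distribution including untailed products, while the empirical coverage is
conditional on being tailed — divide by `P(L ≥ 1)` to convert.

What the generator does **not** emulate: sequencing errors (the selection
rules are exact-match, so errors would only inflate the rejected classes),
quality-score structure, PCR duplicates/chimeras, ligation bias, or any
kinetic model of the tailing reaction. Passing the round-trip tests
therefore demonstrates correctness of the selection/trimming logic, not
robustness to real-world read noise.

### Titrations

`simulate_saturation` and `simulate_competition` evaluate the binding models
on a concentration grid and add i.i.d. Gaussian noise (SD in anisotropy
units, default 0.002 — a typical plate-reader repeatability for anisotropies
in the 0.05–0.35 range). Default designs mirror the assay conditions:
saturation 5–3000 nM protein, 12 log-spaced points, triplicate, true
K_d 250 nM; competition 50 nM–500 µM competitor, 12 log-spaced points,
3 independent experiments, plateaus 0.30 → 0.18. All generators use NumPy's
PCG64 with an explicit integer seed and are bit-reproducible.

Monte-Carlo calibration (200 replicates at the default competition design)
verifies that the median relative IC50 error is below 5% and the 95%
confidence interval covers the true IC50 between 90% and 99% of the time.

## Numerical and design choices

* Exact string matching via Python's native `str` operations; no alignment.
* Placeholder default prefix (`ACGTACGTACGTACGTACGTAC`) and adapter
  (`TACGGTCCATGCAATCGTGAG`): the real substrate and adapter oligos are
  reagent-specific and must be supplied by the user for real data; the
  defaults avoid presenting an invented sequence as a real reagent. The
  adapter placeholder was chosen border-free (see above).
* Contaminant rounding uses `round()` per class; the clean class absorbs the
  remainder.
* Problem sizes in the test suite (10,000-read round trips, 50,000-tail
  composition checks, 200-replicate fit calibration) were chosen so the full
  statistical checks resolve 4-standard-error tolerances while the whole
  suite stays interactive (~20 s).
* Stochastic tests use fixed seeds and 4·SE tolerances (≈ 1 in 16,000 false
  alarm per comparison under the model).
* TSV for tables (sequences contain no tabs; human-diffable), JSON for
  nested results; outputs embed the configuration hash and seed, and contain
  no timestamps, so equal inputs give byte-identical files.

## Known limitations

* No sequencing-error tolerance: a single mismatch in prefix or adapter
  rejects the read. This matches the stated selection criteria but means
  pass rates on real data depend strongly on run quality.
* The saturation model ignores probe depletion; K_d estimates inherit the
  corresponding (small, design-dependent) bias.
* Asymptotic (Wald-type) uncertainties can undercover for poorly designed
  titrations (few points, midpoint near the grid edge); the Monte-Carlo
  calibration covers the default design only. Bootstrap bands are not
  implemented.
* The composition module reports descriptive frequencies only; no
  statistical tests between enzyme variants and no motif/Markov analysis of
  tails.
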