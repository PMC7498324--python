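# tenttail

Analysis toolkit for **template-independent terminal nucleotidyltransferase
(TENT) tailing assays**: it extracts nontemplated 3′ tails from 3′-RACE-seq
reads, profiles their nucleotide composition position by position, and fits
fluorescence-anisotropy binding data (saturation K_d and global competition
IC50). It is aimed at groups characterizing non-canonical poly(A)/poly(U)
polymerases — e.g. fungal C/U-tailing enzymes such as CutA — where the two
standard quantitative readouts are (i) what the enzyme added to a defined RNA
substrate and (ii) how tightly it binds each NTP.

Because raw MiSeq runs and raw titration tables are rarely available at desk
scale, the package ships a first-class synthetic-data generator with exact
ground truth and analytic expectations, so the entire pipeline is testable
end to end.

## What it computes

**Tail calling.** A 3′-RACE-seq amplicon read (sense orientation) is
`prefix + terminal homopolymer + added tail + adapter`. A read is kept only
if it begins with the entirely correct substrate prefix and contains the
entirely correct 3′ adapter (leftmost exact match); inserts longer than
100 nt are discarded as contaminants. Up to `terminal_count` (default 4)
substrate-encoded terminal bases are trimmed from the substrate-proximal end
of the insert; the remainder is the added tail. Trimming is anchored at the
substrate side, so tail nucleotides identical to the substrate's terminal
base are retained once the substrate quota is exhausted.

**Composition statistics.** For a set of tail calls: tailed/untailed
fractions, tail-length mean/median/histogram, pooled base frequencies, and a
3′-anchored per-position frequency matrix (position 1 = last added
nucleotide, position *p* computed over tails of length ≥ *p*). Positions are
reported while covered by ≥ 5% of tailed reads, up to 25 positions from the
3′ end (both configurable). Output is in the RNA alphabet.

**Binding fits.** Saturation: `A(P) = A_free + (A_max − A_free)·P/(K_d + P)`
(one-site specific binding). Competition:

```
A([NTP]) = A_free + (A_bound − A_free) / (1 + [NTP]/IC50)
```

fitted **globally** across independent titrations — one shared IC50, with
A_free/A_bound optimized per experiment. Midpoints are parameterized as
log10(nM) with multi-start least squares; standard errors come from the
asymptotic covariance `s²(JᵀJ)⁻¹`, and pointwise confidence bands from the
delta method.

## Worked example

```python
from tenttail import simulate, call_batch, positional_composition, fit_competition_global

substrate = simulate.default_substrate("A")       # 22-nt prefix + AAAA
adapter = simulate.default_adapter()              # 21-nt placeholder adapter
reads, truth = simulate.simulate_reads(
    substrate, adapter, simulate.default_tail_model(),
    n_reads=10_000, contaminants=simulate.default_contaminants(), seed=7,
)
calls, summary = call_batch(reads, substrate, adapter)
print(summary.to_dict())

res = positional_composition(calls, min_coverage=0.05, max_positions=25)
print({b: round(f, 3) for b, f in res.overall.items()})
print(res.per_position.round(3))

design = simulate.competition_design(ic50=467.0, noise_sd=0.002, seed=7)
fit = fit_competition_global(simulate.simulate_competition(design))
print(f"IC50 = {fit.ic50_nm:.0f} +/- {fit.ic50_se_nm:.0f} nM "
      f"(95% CI {fit.ic50_ci_nm[0]:.0f}-{fit.ic50_ci_nm[1]:.0f} nM)")
```

prints

```
{'n_reads': 10000, 'n_tailed': 6776, 'n_untailed': 2224, 'n_rejected': 1000,
 'reject_reasons': {'ADAPTER_MISSING': 300, 'INSERT_TOO_LONG': 200, 'PREFIX_MISSING': 500},
 'n_short_substrate_run': 0}
{'A': 0.429, 'C': 0.472, 'G': 0.009, 'U': 0.09}
       A      C      G      U
1  0.283  0.626  0.007  0.084
2  0.429  0.470  0.009  0.092
3  0.628  0.261  0.015  0.096
4  0.649  0.254  0.012  0.085
5  0.609  0.278  0.009  0.104
6  0.631  0.249  0.011  0.109
IC50 = 451 +/- 15 nM (95% CI 420-484 nM)
```

Reading the numbers: of 10,000 simulated reads the contaminant classes are
rejected exactly (10% total, matching the generator's allocation); among
passing reads ~75% carry a tail. The tails are ~47% cytidine overall with
<1% guanosine, and the per-position matrix shows the cytidine preference
concentrated at the last two added positions (rows 1–2) — the signature of a
C-tailing enzyme. Position 7 is covered by fewer than 5% of tails and is
therefore not reported. The competition fit recovers an IC50 close to the
generating value of 467 nM, with its standard error and confidence interval
from the global fit.

A `tenttail` command-line interface wraps the same functionality
(`simulate-reads`, `call`, `report`, `simulate-anisotropy`, `fit-saturation`,
`fit-competition`); run `tenttail --help`.

## Documentation

See `docs/methods.md` for the statistical models, the synthetic-data
generator's assumptions, numerical choices and known limitations.
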