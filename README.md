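# proberel

Probe-level **test–retest reliability analysis for array-based DNA
methylation** (Illumina 450K/EPIC-style BeadChips), for epigenetic
epidemiologists and methods developers who need to know which of the
hundreds of thousands of CpG probe measurements on an array can be
trusted.

When the same DNA is measured twice — on two platforms or in technical
replicates — most probes do *not* reproduce their β values. `proberel`
quantifies that, probe by probe, and traces its downstream
consequences: heritability estimation in twins, probe-set enrichment,
cross-study EWAS replication, cross-tissue concordance,
methylation–expression coupling, and how many replicate pairs a
reliability screen actually needs.

## The statistics at the core

**Reliability** of probe *p* is the intraclass correlation for a
mean-rating (k = 2), absolute-agreement, two-way random-effects model
(McGraw–Wong ICC(A,k)). From the two-way ANOVA mean squares of the
n×2 table of paired measurements,

```
ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)
```

with MSR/MSC/MSE the subject, rater and residual mean squares.
Absolute agreement penalizes a systematic platform offset (MSC in the
denominator), which Pearson's r does not; both are reported, along
with the ANOVA components for auditing. Negative ICCs are reported as
computed, never clipped. Estimates are categorized poor (< 0.4), fair
(0.4–0.6), good (0.6–0.75), excellent (> 0.75).

**Twin ACE decomposition**: with trait values standardized, a twin
pair is bivariate normal with correlation r_MZ = a² + c² or
r_DZ = a²/2 + c² and a² + c² + e² = 1; `fit_ace_ml` maximizes this
likelihood under nonnegativity constraints (multi-start bounded
quasi-Newton), with the Falconer closed form
(a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ, e² = 1 − r_MZ) as fallback
and cross-check.

**Enrichment**: a probe set is tested against the descending ICC
ranking with the weighted Kolmogorov–Smirnov running-sum statistic of
preranked GSEA (default weight 1), a set-membership permutation null,
NES = ES / mean(|null ES| of matching sign), and an add-one p-value
(so p ≥ 1/(n_perm + 1)).

**Replicate planning**: subsample n pairs from the full panel,
recompute ICCs, and score the sensitivity of the reduced screen for
the full panel's reliable (ICC > 0.75) probes.

A seeded synthetic-data generator produces every input with known
ground truth — paired β matrices with a calibrated zero-skewed
true-ICC distribution (mean ≈ 0.21, median ≈ 0.09, ~6–8% above 0.75),
twin panels with chosen A/C/E shares, reliability-coupled EWAS hit
lists, external statistics, and TSS-linked expression.

## Worked example

```python
import proberel as pr

cfg = pr.GeneratorConfig(n_probes=5000, n_samples=350, seed=7)
paired, truth = pr.generate_paired(cfg)

table = pr.reliability_table(paired)          # per-probe ICC, r, category
s = table.attrs["summary"]
print(f"mean ICC {s['mean_icc']:.3f}, median {s['median_icc']:.3f}, "
      f"range [{s['min_icc']:.2f}, {s['max_icc']:.2f}]")

ranked = pr.rank_probes(table)
mqtl = pr.ProbeSet("mqtl_like", frozenset(truth.index[truth.true_icc > 0.6][:300]))
res = pr.enrichment_test(ranked, mqtl, n_permutations=1000, seed=1)
print(f"{res.set_name}: ES={res.es:.3f} NES={res.nes:.2f} p={res.p_value:.2e}")

sub = pr.subsample_sensitivity(paired, 25, threshold=0.75, n_draws=50, seed=2)
print(f"25-replicate screen: sensitivity={sub.sensitivity:.2%}")
```

prints

```
mean ICC 0.196, median 0.118, range [-0.37, 0.99]
mqtl_like: ES=0.906 NES=2.20 p=9.99e-04
25-replicate screen: sensitivity=84.43%
```

The summary shows the zero-skewed reliability distribution the
generator is calibrated to; the set drawn from high-true-ICC probes is
strongly enriched at the reliable end of the ranking (p at the
permutation floor); and a 25-pair screen recovers ~84% of the probes
the 350-pair panel flags as reliable.

The same analyses are available from the shell:

```bash
proberel simulate --n-probes 5000 --n-samples 350 --seed 7 --outdir sim/
proberel icc --first sim/beta_450K.tsv --second sim/beta_EPIC.tsv --out icc.tsv
proberel subsample --first sim/beta_450K.tsv --second sim/beta_EPIC.tsv \
    --n 25 --draws 50 --seed 2 --out sub.tsv
```

Every run writes a JSON manifest (input digests, config, seed,
version) beside its output; identical invocations give byte-identical
tables.

## Layout

- `proberel.io` — TSV/GMT readers and writers, schema validation, pairing
- `proberel.reliability` — ICC(A,k=2), Pearson, categories, M values
- `proberel.twins` — ACE maximum likelihood + Falconer closed form
- `proberel.enrichment` — running-sum statistic, permutation null, set summaries
- `proberel.replication` — consistent-direction cross-study tallies
- `proberel.association` — external statistics, concordance bins, expression links
- `proberel.subsampling` — replicate-count sensitivity curves
- `proberel.simulate` — seeded generators with ground truth
- `proberel.cli` — `proberel` command with subcommands and run manifests

See `docs/methods.md` for the model details, calibration choices and
known limitations.
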