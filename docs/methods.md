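# Methods

## Model and assumptions

`cbrcare` implements a nearest-neighbor case-based reasoning cycle over
Boolean-encoded patient records. The core assumptions are:

- Every raw attribute can be decomposed into *mutually exclusive* Boolean
  options (one-hot encoding). Numeric attributes are binned with half-open
  intervals `[lower, upper)`; half-open bins are the standard convention
  that guarantees adjacent bins ("6–7 hours", "7–8 hours") never overlap
  at an endpoint, hence at most one option per source attribute fires.
- Class labels (chronic-disease categories) are given metadata, e.g. a
  confirmed diagnosis; the package never infers them.
- Treatment-protocol indicators are Boolean per case, standardized the
  same way as the state attributes.
- Retrieval is exhaustive: similarity against every stored case. No
  approximate indexing is attempted; cost is O(D·n) per query.

## Attribute weighting

The weight of option *i* is a product of up to three factors, selected by
`WeightingConfig.mode`:

| mode  | factors |
|-------|---------|
| `idf` | log2(D / D_i) |
| `eq6` | IDF × interclass dispersion |
| `eq8` | IDF × interclass dispersion × intraclass entropy |

**IDF.** `w_i = log2(D / D_i)`; options never observed (`D_i = 0`) are
flagged inactive, weigh 0, and are excluded from retrieval. No add-one
smoothing is applied — an unobserved option carries no information about
similarity in this base.

**Interclass dispersion.** With `f_k(i)` the *relative* frequency of
option *i* within class *k* (relative, not a raw count: raw counts would
confound class size with attribute concentration, and relative frequencies
make the endpoint behavior class-size invariant), the raw dispersion is
the coefficient of variation over classes,

    D_raw(i) = sd_k(f_k(i); ddof=1) / f̄(i),     f̄(i) = (1/n) Σ_k f_k(i).

Algebraically this is 0 when the frequencies are identical across classes
and exactly `sqrt(n_classes)` when all occurrences sit in a single class
(for f = (f, 0, …, 0): sd = f/√n, mean = f/n). Because a [0, 1] range is
the natural scale for a multiplicative factor, the default normalization
divides by `sqrt(n_classes)` and clamps to [0, 1]
(`dispersion_normalization="sqrt_n"`); `"none"` keeps the raw CV and
`"clamp"` merely truncates it at 1. Options absent everywhere get
dispersion 0. Computing dispersion requires at least two nonempty classes;
fewer is an error rather than a silent 0.

**Intraclass entropy.** Within class `C_k` option *i* is a Bernoulli
variable with success probability `p = f_k(i)`; its entropy is
`-(p·lg p + (1-p)·lg(1-p))` with `0·lg 0 := 0`. The logarithm base is 10
by default (`entropy_log_base`), configurable to 2; the base only rescales
all entropies by a constant, so weight *orderings* are base-invariant.
Per-class entropies are aggregated into one per-option factor by a
class-size-weighted mean (`entropy_aggregation="weighted_mean"`, the
default because it is least sensitive to tiny classes); unweighted mean
and max are available.

**Feature selection.** `select_features` keeps the N options with the
largest combined weight, after dropping inactive and zero-weight options;
ties break toward the lower option index for determinism. A class-uniform
option has combined weight 0 under `eq6`/`eq8` — it carries no
class-discriminative signal and is droppable.

## Retrieval

Cases are compared through weighted vectors `y_i = x_i · w_i` by the
cosine `⟨a, b⟩ / (|a||b|)`. All entries are nonnegative, so similarities
lie in [0, 1]; similarity 1 means identical option support. A zero-norm
vector (a case setting no active option) is defined to have similarity 0
against everything — an all-absent case matches nothing — rather than
NaN. Results are sorted by similarity descending, then case_id ascending
(a deterministic tie-break the ranking semantics do not otherwise fix).
Similarity values are invariant to positive rescaling of the whole weight
vector. Fractions in [0, 1] are the stored representation; percentages
are display formatting only.

## Reuse and retention

Protocol *j*'s adoption rate over the retrieved set is the
similarity-weighted mean of its indicators,
`NewCT_j = Σ_i CR_i·CT_ij / Σ_i CR_i`. Retrieved cases lacking protocol
indicators are excluded with a warning; an empty or zero-similarity
retrieved set raises a no-evidence error instead of fabricating a rate.

Tier thresholds (fractions of 1): necessary for rate > 0.95, optional in
(0.75, 0.95], reference in (0.60, 0.75], none otherwise. The bands are
half-open so the mapping is total and non-overlapping at the printed
boundary values. All thresholds are configurable through `ReuseConfig`.

Retention: if the best retrieved similarity is below the retention
threshold (default 0.95) the query case is *queued for review* as a
JSON-lines entry, never auto-committed — adding a case to a clinical case
base is a human decision. An empty base counts as maximum similarity 0,
i.e. certainly novel.

## Synthetic data generator

`synthgen.generate` draws each option of a class-k case as an independent
Bernoulli with probability `p[k][i]`, and protocol j with `q[k][j]`, from
a single `numpy` PRNG stream seeded per call, so fixtures are
bit-reproducible. It emulates the structural features the method relies
on — class-partitioned cases, options with controllable per-class
concentration, protocols correlated with class membership — and nothing
else: no attribute–attribute correlation, no comorbidity structure, no
missingness patterns, no temporal drift. Passing tests therefore
demonstrate the *mechanics* (weighting recovers concentration, retrieval
matches exhaustive scans, rates are correct weighted means), not clinical
validity on real questionnaire data.

Defaults in `concentrated_uniform_spec`: 3 classes × 500 cases, a
concentrated option at frequency 0.9 in its home class and 0.1 elsewhere,
a uniform option at 0.5 everywhere, protocol 1 adopted at 0.9/0.1 with
class membership and protocol 2 at 0.5 as noise. The concentrated option
deliberately avoids the fully degenerate 1/0 pattern: a constant
within-class value has zero entropy, which would zero the `eq8` weight
entirely; 0.9/0.1 keeps all three factors informative. The degenerate
pattern is still exercised where it is exact — the dispersion endpoint
`sqrt(n_classes)`.

`make_toy_base` builds the canonical 1000-case base (option counts
489/200/50) by exact counting, not sampling, so its IDF weights
(1.03/2.32/4.32 at 2 d.p.) are deterministic and seed-independent.

## Numerical choices and degenerate inputs

- `0 · log 0 := 0` in entropies; `f̄ = 0 ⇒ dispersion := 0`;
  `D_i = 0 ⇒` option inactive.
- When all class frequencies of an option are exactly equal, the sample
  standard deviation is forced to exactly 0, suppressing the ~1e-16
  residue the mean subtraction can leave in floating point.
- Cosine values are clipped into [0, 1] against rounding overshoot.
- Missing raw values encode as all-zero for that attribute's options with
  a warning (questionnaire nonresponse is expected data, not an error); a
  numeric value falling outside *every* bin of its attribute is an error
  (the schema is wrong or the value corrupt).
- Boolean-rule literals are compared on a canonical string form, so
  `1`, `"1"` and `True` match after a CSV round-trip.

## Known limitations

- Exhaustive retrieval scales linearly in the base size; large bases need
  an index, which is out of scope here.
- Boolean encoding discards within-bin ordering information; no automatic
  bin learning is provided.
- The weighting scheme assumes labeled, reasonably balanced classes;
  `eq6`/`eq8` refuse to run with fewer than two classes.
- Recommendations are frequency summaries of similar cases' protocols —
  decision support, not clinical validation; conflicting protocols are
  reported side by side, not resolved.

## Problem sizes used in the test suite

The suite exercises random bases up to D = 2000 cases against pure-Python
brute-force oracles (frequency tallies, entropy sums, full similarity
scans, weighted means) at 1e-9 to 1e-12 tolerance, and the synthetic
calibration checks use 3 × 500 cases — comfortably past the law-of-large-
numbers tolerance `3·sqrt(p(1−p)/m)` used for frequency recovery.
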