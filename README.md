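# cbrcare

Case-based reasoning (CBR) for personalized chronic-disease intervention.

Clinicians and health-informatics teams who hold a base of solved cases —
patient lifestyle questionnaires plus the treatment protocols those
patients received — can use `cbrcare` to answer: *given a new patient,
which stored cases are most similar, and which protocols did they adopt?*
The package implements the full retrieve–reuse–retain loop:

1. **Standardized Boolean encoding.** Every raw attribute (sex, age,
   sleep, diet, family history, ...) is decomposed by a declarative JSON
   schema into mutually exclusive Boolean options, so each case becomes an
   n-dimensional 0/1 vector `X = (x_1, ..., x_n)`.
2. **Attribute weighting.** Each option *i* gets a weight that is the
   product of up to three factors:
   - inverse document frequency, `w_i = log2(D / D_i)`, where `D` is the
     case count and `D_i` the number of cases with the option set;
   - interclass dispersion `D(i)` — the coefficient of variation of the
     option's per-class relative frequencies `f_k(i)`,
     `sd_k(f_k(i)) / f̄(i)`, which is 0 for a class-uniform option and
     maximal for a single-class-concentrated one (a normalized variant on
     [0, 1] is used by default);
   - intraclass information entropy
     `E(i, C_k) = -Σ_j p_j lg p_j` of the option's {0,1} distribution
     within each class, aggregated over classes by a class-size-weighted
     mean.
3. **Weighted-cosine retrieval.** Cases are compared through their
   weighted vectors `(x_1 w_1, ..., x_n w_n)` by
   `cos θ = ⟨a, b⟩ / (|a||b|) ∈ [0, 1]`, exhaustively over the base, as
   top-k or above a similarity threshold.
4. **Protocol recommendation.** Each protocol *j* gets a
   similarity-weighted adoption rate
   `NewCT_j = Σ_i CR_i·CT_ij / Σ_i CR_i` over the retrieved neighbors,
   tiered as necessary (> 0.95), optional (0.75–0.95], reference
   (0.60–0.75], or none.
5. **Retention.** When no stored case reaches the retention threshold
   (default 0.95) the new case is queued for human review before being
   added to the base.

A seeded synthetic generator (`cbrcare.synthgen`) produces labeled case
bases with controllable class concentration and protocol–class
correlation, so the whole pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from cbrcare import (
    make_toy_base, idf_weights, concentrated_uniform_spec, generate,
    build_case_base, combined_weights, WeightingConfig,
    RetrievalQuery, retrieve, recommend, retention_decision,
)

# the canonical 1000-case base: options set in 489, 200 and 50 cases
print(idf_weights(make_toy_base()).to_frame().round(2).to_string(index=False))
```

```
        option_id  D_i  idf  dispersion_raw  dispersion_norm  entropy  combined  active
              sex  489 1.03             NaN              NaN      NaN      1.03    True
daily_sleep_lt_6h  200 2.32             NaN              NaN      NaN      2.32    True
   fruit_gt_1000g   50 4.32             NaN              NaN      NaN      4.32    True
```

An option present in 489 of 1000 cases weighs `log2(1000/489) ≈ 1.03`
bits; the rarer the option, the higher the weight (2.32 at 200/1000, 4.32
at 50/1000).

```python
# synthetic 3-class base: one class-concentrated and one class-uniform option
spec = concentrated_uniform_spec(n_classes=3, cases_per_class=500, seed=7)
raws, schema = generate(spec)
cb = build_case_base(raws, schema)
w = combined_weights(cb, WeightingConfig(mode="eq8"))
print(w.to_frame().round(4).to_string(index=False))

res = retrieve(RetrievalQuery(x=np.array([1, 1]), top_k=50), cb, w)
rec = recommend(res, cb)
print(rec.to_frame().round(4).to_string(index=False))
print("retention:", retention_decision(res).value)
```

```
   option_id  D_i    idf  dispersion_raw  dispersion_norm  entropy  combined  active
concentrated  558 1.4266          1.2199           0.7043   0.1486    0.1493    True
     uniform  758 0.9847          0.0718           0.0415   0.3002    0.0123    True

protocol_id  adoption_rate     tier  n_supporting_cases
 protocol_1           0.86 optional                  43
 protocol_2           0.50     none                  25
retention: discard
```

The concentrated option (frequency 0.9 in one class, 0.1 elsewhere) gets
a combined weight an order of magnitude above the class-uniform one, so
retrieval is driven by the discriminative attribute. The query matches a
stored case exactly (similarity 1.0, hence `discard` — nothing new to
retain), and 86% of the similarity mass among its 50 nearest neighbors
adopted protocol 1, an *optional*-tier recommendation.

The same pipeline is available from the shell:

```bash
cbrcare synth --spec gen.yaml --out cases.csv --schema schema.json --seed 42
cbrcare run --schema schema.json --cases cases.csv --query query.csv \
            --outdir out/ --mode eq8 --top-k 50
```

which writes `encoded_base.csv`, `weights.csv`, `retrieval.csv`,
`recommendation.csv` and `review_queue.jsonl`.

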