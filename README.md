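# ehrfreq

**ehrfreq** computes privacy-protected clinical concept prevalence and
co-occurrence statistics from OMOP CDM v5-shaped electronic health record
extracts, in the style of the Columbia Open Health Data (COHD) resource.
It is aimed at informatics groups who hold an OMOP database and want to
release aggregate concept statistics — and at researchers who want to
consume such releases — without exposing patient-level data.

## What it computes

For a dataset window with `N_P` unique patients (a patient qualifies only
through at least one condition, drug, or procedure event in the window):

- **EHR prevalence** of a concept *C*: `P_EHR(C) = N_C / N_P`, where
  `N_C` is the number of unique patients observed with *C*.
- **Co-occurrence frequency** of a pair: `CO_EHR(C1,C2) = N_{C1,C2} / N_P`,
  with `N_{C1,C2}` the number of unique patients observed with both.
- **Association measures** from the released counts:
  - Pearson **chi-square** on the implied 2×2 table (df = 1, no
    continuity correction),
  - **relative frequency** `FR(C1|C2) = N_{C1,C2} / N_{C2}` (an empirical
    conditional-probability analogue),
  - **observed/expected log ratio**
    `LR(C1,C2) = ln(N_{C1,C2}·N_P / (N_{C1}·N_{C2}))`.

Released counts pass a fixed disclosure-protection pipeline: iatrogenic
concept codes are purged, counts ≤ 10 are excluded, and every remaining
count is replaced by one draw from a Poisson distribution with mean λ
equal to the true count. Annual mean/SD stability statistics, a
nine-file tab-delimited release format, a JSON query service (WSGI), and
a synthetic OMOP cohort generator with controllable marginal prevalences
and pairwise odds ratios round out the toolchain. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
import ehrfreq as ef
from ehrfreq.omop_io import concat_events
from ehrfreq.privacy import PrivacyConfig
from ehrfreq.synthetic_cohort import WORKED_EXAMPLE_WINDOW, write_cohort, CohortSpec

# generate a synthetic OMOP extract: 10,000 patients, three concepts,
# a condition-drug pair with odds ratio 4
spec = CohortSpec(
    n_patients=10_000, seed=7,
    concept_catalog=((101, "Condition", 0.10), (201, "Drug", 0.15),
                     (301, "Procedure", 0.90)),
    dependence_list=((101, 201, 4.0),),
)
paths = write_cohort(spec, "scratch/omop")

events = concat_events([
    ef.read_events(paths["condition_occurrence"], "condition")[0],
    ef.read_events(paths["drug_exposure"], "drug")[0],
    ef.read_events(paths["procedure_occurrence"], "procedure")[0],
])
persons = ef.read_persons(paths["person"])
concepts = ef.read_concepts(paths["concept"])

bundle = ef.build_bundle(events, persons, concepts,
                         PrivacyConfig(min_count_threshold=10, seed=7))
tables = bundle.datasets["lifetime"]
n_p = tables.metadata.patient_count
singles = dict(zip(tables.singles.concept_id, tables.singles["count"]))
p = tables.pairs
pair = p[(p.concept_id_1 == 101) & (p.concept_id_2 == 201)].iloc[0]
print("N_P =", n_p)
print("released count, prevalence of 101:",
      singles[101], round(singles[101] / n_p, 6))
print("LR(101,201) =",
      round(ef.log_ratio(pair["count"], singles[101], singles[201], n_p), 3))
```

prints

```
N_P = 9227
released count, prevalence of 101: 1017 0.11022
LR(101,201) = 0.818
```

`N_P` is below 10,000 because patients with no clinical event never enter
a dataset. The released count 1017 is the Poisson-randomized version of
the true patient count for concept 101 (marginal prevalence 0.10; the
released prevalence 0.110 is slightly higher because the denominator is
the observed patient population, not the full cohort). The positive log
ratio reflects the injected odds ratio of 4 between condition 101 and
drug 201.

The same pipeline is available from the shell:

```sh
ehrfreq generate --n-patients 10000 --seed 7 --out scratch/omop
ehrfreq export --omop-dir scratch/omop --out scratch/bundle --min-count 10 --seed 7
ehrfreq associate --bundle scratch/bundle --concept-id 101 --metric log_ratio
ehrfreq serve --bundle scratch/bundle --port 8080
```

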