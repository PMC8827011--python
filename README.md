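# labharbor

Harmonize messy electronic-health-record (EHR) laboratory exports into
validated, de-identified, REDCap-importable registry records — then
screen baseline labs against overall survival with univariable Cox
models.

## Who this is for

Clinical-research teams that run a REDCap-based patient registry and
need to load structured lab data pulled in bulk from an EHR or an
enterprise data warehouse (EDW). Bulk pulls are messy in predictable
ways: one test arrives under many subtype spellings ("Potassium",
"Potassium-External", "Potassium(POC)", "Potassium, whole-bld", ...),
whole panels are crammed into single cells, values include
non-importable tokens such as "refused" and "canceled", units drift off
the registry standard, and the same lab may be drawn twice in a day.
`labharbor` turns those exports into clean long-format CSVs that REDCap's
import tool accepts, with every dropped value itemized and patient
identifiers replaced by registry record ids before anything leaves the
PHI boundary.

## What it does

1. **Data dictionary** (`labharbor.dictionary`) — models the REDCap data
   dictionary that defines the registry schema: a repeating `labs`
   instrument with 35 number-validated lab fields plus one shared
   collection date (M/D/Y) and time (HH:MM) per instance, and the
   `subject_status` / `patient_characteristics` instruments the survival
   stage reads. Reads/writes the standard DD-CSV dialect and implements
   the per-cell validation REDCap applies at import.
2. **Ingest** (`labharbor.ingest`) — parses the "untidy" 4-column EHR
   export (patient key, date, time, one cell holding a whole panel) and
   tabular EDW exports with a configurable column map. Unparseable
   tokens are routed to a reject list, never dropped.
3. **Harmonize** (`labharbor.harmonize`) — remaps ~200 source test
   subtypes onto the 35 registry fields via a key-value lookup table,
   enforces dictionary units, excludes non-numeric values, swaps
   MRNs for record ids through a PHI-side crosswalk, assigns repeating-
   instrument instances (one per collection event), pivots to the
   REDCap import layout, validates every cell, aggregates sites, and
   annotates one LOINC code per field. Invariant throughout:
   `|raw values| = |imported values| + |itemized exclusions|`.
4. **Survival** (`labharbor.survival`) — derives overall survival (days
   from diagnosis to death, censored at last follow-up), selects one
   baseline value per lab (nearest draw within −90/+30 days of
   diagnosis), and fits one univariable Cox proportional-hazards model
   per lab. The partial likelihood is maximized by Newton iteration with
   the Efron tie correction; HR = exp(β̂), 95% CI = exp(β̂ ± 1.96·SE),
   two-sided Wald p, no multiplicity correction (the screen is
   hypothesis-generating).
5. **Quality** (`labharbor.quality`) — manual-vs-automated agreement
   rate with a complete discrepancy listing, and abstraction-throughput
   arithmetic.
6. **Synthetic** (`labharbor.synthetic`) — a seeded generator that
   simulates a registry cohort with known lab values and a known
   proportional-hazards survival structure, renders it into the messy
   input shapes above, and records every planted corruption in a
   manifest, so the whole pipeline is testable with zero real patient
   data.

## Worked example

```python
from labharbor import dictionary as dm, harmonize as hz, synthetic as syn, survival as sv
from labharbor.ingest import parse_ehr_export, explode_panels, PanelGrammar

dd = dm.default_mcc_dictionary()
lut = hz.default_lookup(dd)

# simulate a 120-subject cohort with a real effect on creatinine
# (log HR 0.5 per mg/dL) and realistic corruption rates, then render
# it as the untidy 4-column EHR export
cfg = syn.SimulationConfig(n_subjects=120, seed=11, true_log_hr={"cre": 0.5},
                           corruption=syn.CorruptionRates(0.02, 0.01, 0.02, 0.05))
truth = syn.simulate_cohort(cfg)
text, manifest = syn.render_untidy(truth, lut, rates=cfg.corruption, seed=11)

observations, rejects = [], []
for row in parse_ehr_export(text):
    o, r = explode_panels(row, PanelGrammar())
    observations.extend(o); rejects.extend(r)
result = hz.run_pipeline(observations, lut, truth.crosswalk, dd)
print(f"raw values:      {result.n_raw}")
print(f"imported values: {result.n_imported}")
print(f"excluded:        {len(result.exclusions)}  {dict(result.exclusions.counts)}")
```

prints

```
raw values:      11515
imported values: 10938
excluded:        577  {'unit_mismatch': 244, 'nonimportable_value': 333}
```

— every one of the 11 515 parsed values is either in the import table
or in the itemized exclusion report (here, the planted "refused"/
"canceled" tokens and off-dictionary units). The survival screen on the
same cohort:

```python
results = sv.baselabs_os_table(truth.observations, truth.status, truth.chars)
print(sv.render_table(results))
```

```
Laboratory test                                 Hazard ratio (95% CI)        P value
------------------------------------------------------------------------------------
Electrolytes/renal/glucose
  Sodium (na)                                   1.0466 (0.98-1.12)             0.191
  Potassium (k)                                 1.3072 (0.79-2.15)             0.293
  Chloride (cl)                                 1.0366 (0.95-1.14)             0.444
  ...
  Creatinine (cre)                              1.3855 (0.61-3.16)             0.439
```

Each row is one univariable Cox model of overall survival on that lab's
baseline value: the hazard ratio is the multiplicative change in the
death hazard per unit of the lab (here, per mg/dL of creatinine), with
its 95% Wald interval and p-value. At n=120 the creatinine interval is
wide but brackets the simulated truth (exp(0.5) ≈ 1.65).

The same pipeline is available from the shell:

```bash
labharbor simulate  --out-dir out --phi-dir phi --seed 11 --n-subjects 120
labharbor harmonize --input out/untidy_labs.csv --crosswalk phi/crosswalk.csv --out-dir out
labharbor validate  --input out/redcap_import.csv
labharbor survival  --labs out/redcap_import.csv --status out/subject_status.csv \
                    --chars out/patient_characteristics.csv --out-dir out
```

The crosswalk is required to live outside the output directory, and no
patient key ever appears in a shareable artifact or diagnostic.

## Documentation

`docs/methods.md` describes the model, the numerical choices in the Cox
fit, what the synthetic generator does and does not emulate, and known
limitations.
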