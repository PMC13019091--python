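# wpaflow

Single-event platelet aggregation analysis for imaging flow cytometry (IFC).

Bulk platelet-function assays (light transmission aggregometry, conventional
flow cytometry) measure aggregation as a population average and miss subtle
shifts in small aggregates. IFC records every acquired object as a
multi-channel image, so platelet complexes in antibody-labelled whole blood
(CD42b as the platelet identity marker, CD62P as the activation marker) can
be classified individually as singlets, doublets, triplets or multiplets
(≥ 4 platelets) and summarised by the **weighted platelet aggregation**
score. For per-class event counts m₁..m₄ with total N = Σ mₖ:

```
WPA = ((1·m₁ + 2·m₂ + 3·m₃ + 4·m₄) / N − 1) × 100   [%]
```

WPA is 0 % for a purely singlet measurement and 300 % for exclusively
multiplets; it estimates the proportion of platelets engaged in
platelet–platelet aggregates. A typical unstimulated whole-blood
measurement (≈ 8400 singlets, 200 doublets, 10 triplets, 0–1 multiplets per
~10⁴ complexes) scores ≈ 2.5 %; ADP stimulation raises it several-fold.

The package is aimed at people building or validating IFC aggregation
pipelines. Because raw donor-level IFC data is rarely shareable, everything
here runs against a synthetic-data generator with known ground truth:

- `wpaflow.synthcyto` — event images (tangent-disk aggregates, erythrocyte
  background, platelet–erythrocyte coincidences) and full donor cohorts
  (age/sex structure, technical duplicates, acquisition-date batches, ADP
  response, plantable age/sex effects), all from one master seed;
- `wpaflow.gating` — acquisition-style conditional gating on CD42b and
  image focus, with auto thresholds and a partition-complete report;
- `wpaflow.classifier` — a small numpy CNN (two conv+pool stages → flatten
  → fully connected → 4-way softmax) with class-balanced training, plus a
  deterministic oracle for testing;
- `wpaflow.wpa` — class counts, WPA, per-measurement summaries;
- `wpaflow.qc` — two-stage prefiltering: the 70–130 % technical-replicate
  concordance band, then ROUT (Q = 1 %) on acquisition-date mean WPA;
- `wpaflow.cohortstats` — Welch / Mann–Whitney contrasts with
  normality-dependent selection, age regressions by sex stratum, ADP
  fold-change tables;
- `wpaflow.io` / `wpaflow.cli` — CSV/JSON/TIFF formats, YAML run configs,
  and an end-to-end CLI (`wpaflow run-all`).

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
>>> from wpaflow import compute_wpa
>>> round(compute_wpa((8400, 200, 10, 0)), 2)
2.56
```

A 12-donor synthetic cohort, scored from ground-truth labels, quality
filtered and summarised:

```python
from wpaflow import CohortConfig, simulate_cohort
from wpaflow.wpa import summarize_cohort
from wpaflow.qc import apply_qc, QCConfig
from wpaflow.cohortstats import condition_response

config = CohortConfig(n_donors=12, events_per_measurement=8610,
                      inter_donor_dispersion=0.02, seed=42)
events, truth, donors = simulate_cohort(config)
events = events[events["gt_class"] > 0].copy()
events["class"] = events["gt_class"].clip(upper=4)
summaries = summarize_cohort(events)
```

After `apply_qc` and `condition_response` this prints:

```
baseline mean WPA: 2.54
ADP mean WPA:      7.82
WPA fold change:   3.08
doublet fold:      2.53
triplet fold:      6.99
donors retained:   12/12
paired WPA test:   paired_t[wpa] p=6.85e-12
```

The baseline cohort sits at the ≈ 2.5 % reference level; ADP multiplies
doublets ≈ 2.5× and triplets ≈ 7× (the configured stimulation effect,
recovered through the scoring path), lifting mean WPA ≈ 3-fold, and the
paired contrast flags the response as highly significant. With clean
synthetic replicates, no donor trips the concordance band or the ROUT date
screen.

The same flow from the shell:

```
wpaflow --seed 42 --outdir out simulate
wpaflow --outdir out score --events out/events.csv
wpaflow --outdir out qc --summaries out/summaries.csv --band 0.70:1.30 --rout-q 0.01
wpaflow --outdir out stats --summaries out/summaries_qc.csv
```

or end-to-end with image rendering, gating and CNN classification:
`wpaflow --seed 42 --outdir out run-all`.

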