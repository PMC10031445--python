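# diag360

A config-driven engine for a 360-degree diagnostic and lifestyle-advice tool
for people with type 2 diabetes in primary care. One assessment combines
professional-entered clinical measurements (the *body* domain) with patient
questionnaires (*thinking and feeling*, *behavior*, *environment*). The engine

- scores questionnaire items into element-level scores (well-being index,
  stress and diabetes-distress sums, alcohol frequency-quantity, activity
  minutes, sitting time, and more);
- classifies all 40 elements into traffic-light statuses (green / orange /
  red, gray when unanswered) via declarative cutoff bands, and combines them
  into 21 parameter statuses with decision rules (default: worst-of);
- renders the **profile wheel**: an SVG with 4 equal quadrants, one colored
  icon per parameter, plus click-through detail panels showing each element's
  cutoff bar, score, and position marker;
- matches orange/red parameters to an intervention catalog (7 categories,
  3 availability classes; a 27-entry example catalog is packaged);
- ships the 15-card motivational-interviewing consultation deck as structured
  data with a printable markdown rendering;
- compares two assessments of the same patient into per-parameter transitions
  (improved / worsened / unchanged / newly measured / ...);
- generates seeded synthetic patients by inverse sampling, with exact
  per-parameter status prevalence control and configurable missingness.

All clinical knowledge (cutoffs, bands, decision rules, instruments) lives in
`src/diag360/data/reference_config.yaml`, not in code; guideline updates are
config edits. Published rules (blood-pressure bands and their combination
table; the well-being <=50 red cutoff) are encoded exactly; all other cutoffs
are documented defaults.

## CLI

```sh
# generate 5 synthetic patients
diag360 simulate --n 5 --seed 42 --out patients/

# classify one assessment into a diagnosis profile (+ optional CSV export)
diag360 score --in patients/assessment-sim-0001.json --out profile.json --csv profile.csv

# render the profile wheel, 21 detail panels, and an HTML index
diag360 render --profile profile.json --out report/

# match interventions for the flagged parameters
diag360 advise --profile profile.json --availability nationwide_web

# printable consultation card deck with the agenda filled from the profile
diag360 protocol --profile profile.json --out consult.md

# per-parameter transitions between baseline and follow-up
diag360 compare --baseline profile-t0.json --followup profile-t1.json --out transitions.json
```

Every subcommand accepts `--config rules.yaml` to swap in a different rule
configuration and the group-level `--log-level` flag. See `diag360 --help`.

## Layout

```
src/diag360/
  core_model.py            domain/parameter/element hierarchy, statuses, records
  instrument_scoring.py    questionnaire scorers (pure, explicit-unavailable)
  classification.py        cutoff banding + decision rules -> DiagnosisProfile
  wheel_render.py          profile wheel + detail panels (SVG), HTML report
  advice.py                intervention catalog + matching
  consultation_protocol.py 15-card MI deck + markdown rendering
  followup.py              two-timepoint transition reports
  synthetic_patients.py    seeded inverse-sampling patient generator
  io_cli.py                canonical JSON/YAML/CSV I/O + click CLI
  data/                    reference config, example catalog, card deck
```
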