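# Reference data notes

`reference_fame_profiles.csv` is a transcription of a published
steady-state FAME composition table for four microalgal isolates
(Chlorella, Scenedesmus, Nitzschia, Tetraselmis) grown semi-continuously at
several dilution rates: 22 strain x dilution-rate conditions over 15
fatty-acid species, as mass percent of total fatty acids.  "–" means the
species was not detected and counts as exactly 0.  Column totals legally
fall below 100 % (the remainder is unidentified fatty acids) and are never
renormalized.

`reference_class_sums.csv` holds the SFA/MUFA/PUFA class sums as printed in
the source table; `reference_fuel_properties.csv` holds the published
biodiesel-property values for the same conditions.  Both are
**expected-output assets for validation only** — the package always
recomputes class sums and properties from the profiles.

## Known inconsistencies of the source table

Recomputing class sums from the profile entries exposes columns where the
source table is internally inconsistent (entries evidently dropped or
mis-printed at publication):

* **Chlorella@0.30** — entries total 39.8 % while the printed class sums
  total 80.4 %; the 18:3n3 / 18:4n3 entries are evidently missing.  The
  printed properties imply an average unsaturation of ~2.10 versus 0.73
  from the entries.
* **Chlorella@0.50** — printed MUFA 3.20 versus 6.00 from the entries.
* **Nitzschia@0.10/0.20/0.30** — printed PUFA 11.00/12.50/22.40 versus
  19.10/20.30/41.30 from the entries, and the printed properties imply an
  average unsaturation of ~0.66 (D=0.10) versus 1.20 from the profile.
  The published property values for these columns are therefore **not**
  reproducible from the published profiles.

These columns are excluded from reproduction tests; they are *not*
special-cased anywhere in the analysis code, which treats every column
identically.

Additionally, because the profile entries are printed to 0.1 % and the
iodine-value regression has the steepest slope in the average unsaturation
(74.373), recomputed iodine values can differ from the published ones by up
to ~0.4 g I2/100 g purely from input rounding; all other properties
reproduce to ~0.1 of the printed values on the internally consistent
columns.
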