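# File formats

All text tables are tab-separated with a header row (`.csv` extension
switches to comma). Machine-facing JSON carries explicit `units` keys;
fractions in JSON, percentages only in human-facing console output.

## End-tidal trace (TSV/CSV)

| column        | units | meaning                          |
|---------------|-------|----------------------------------|
| `time_s`      | s     | time from paradigm start, strictly increasing |
| `peto2_mmHg`  | mm Hg | end-tidal O2 partial pressure    |
| `petco2_mmHg` | mm Hg | end-tidal CO2 partial pressure   |

## ROI timecourse (TSV/CSV)

| column   | units     | meaning                                  |
|----------|-----------|------------------------------------------|
| `time_s` | s         | sample time                              |
| `signal` | arbitrary | ROI-mean magnitude signal (raw, positive) |

## Paradigm (JSON)

```json
{
  "variant": "A",
  "tr_s": 2.4,
  "blocks": [{"label": "normoxia", "start_s": 0.0, "end_s": 180.0}, ...],
  "trials": [{"onset_s": 60.0, "duration_s": 30.0, "off_end_s": 120.0,
              "usable": true}, ...]
}
```

`label` is `normoxia` or `hyperoxia`; blocks must not overlap. A trial's
ON window is `[onset_s, onset_s + duration_s)` and its rest window runs to
`off_end_s`; `usable: false` excludes a trial from all averaging (e.g.
trials straddling a gas transition).

## Phase profile (TSV)

Columns `position_mm`, `phase_norm_rad`, `phase_hyper_rad`, `magnitude`,
`excluded` (0/1). Excluded samples (e.g. intravascular) are dropped from
the ratio fit.

## Volumes, masks and maps (NIfTI)

4-D float volumes (time last), 3-D masks (nonzero = include); output maps
are float32 NIfTI with failed voxels NaN, accompanied by a
`provenance.json` sidecar (software version, TE, Q0, per-block q_h, kept
trials).

## Result bundles (JSON)

`calibrate` writes the fit (`m`, `m_prime` in percent; `rvcbv`, `q_act` as
fractions; slopes/intercepts in s⁻¹; standard errors; point count), the QC
decisions, per-block gas values, the full run configuration including
constants and software version, and optionally a `cmro2` block.
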