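# Data dictionary

CSV dialect everywhere: UTF-8, comma-delimited, header row, empty field
= missing.

## participants.csv (wide; one row per participant)

| column | type | meaning |
| --- | --- | --- |
| participant_id | str | unique id (`mbid_001`, `td_001`, ...) |
| group | str | `MBID` or `TD` |
| sex | str | `male` / `female` |
| ca_months | float | chronological age in months |
| cog_raw | float | cognitive-capacity raw score (missing outside the measurement subsample) |
| voc_raw | float | vocabulary raw score (likewise) |
| lexicality_order | str | `real_first` / `pseudo_first` (metadata) |
| span_short_real | float | span score, short real words |
| span_long_real | float | span score, long real words |
| span_short_pseudo | float | span score, short pseudowords |
| span_long_pseudo | float | span score, long pseudowords |

## trials.csv (one row per presented sequence)

| column | type | meaning |
| --- | --- | --- |
| participant_id | str | as above |
| condition_length | str | `short` / `long` |
| condition_lexicality | str | `real` / `pseudo` |
| phase | str | `calibration` / `test` |
| trial_index | int | 0-based position within the administration |
| sequence_length | int | words in the presented sequence (2–8) |
| correct | bool | repetition correct in strict serial order |
| points | int | `sequence_length` if correct else `sequence_length - 1` |

## Long analysis format (`to_long_format`)

Four rows per participant: the id/group/indicator columns above plus
`word_length`, `lexicality`, the centred contrasts `length_c`,
`lexicality_c` (+0.5 = short / real; sum to 0 within participant) and
`span`.

## fitted_values.csv (per trajectory)

`participant_id`, `outcome` (capacity / rehearsal / redintegration),
`di` (CA / COG / VOC), `di_value` (original scale), `observed_effect`
and `fitted_effect` (span units on the effect scale; the data behind
trajectory scatterplots).
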