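# Trial-table column dictionary

Comma-separated UTF-8 text with a header row; one row per trial; missing
values are empty fields.  Produced by `confbound simulate` /
`confbound.write_trials`, consumed by `confbound.read_trials`.

| column | type | meaning |
|---|---|---|
| `session` | int | session index (0-based) |
| `block` | int | block within session (0–3) |
| `trial_index` | int | presentation order within block |
| `trial_type` | str | `double`, `D1star`, `D2star`, or `D1catch` |
| `coh1` | float | signed coherence of the first stimulus (empty on `D2star`) |
| `coh2` | float | signed coherence of the second stimulus (empty on `D1star`/`D1catch`) |
| `rewarded_dir1` | ±1 | rewarded direction, first decision (fair coin at 0% coherence) |
| `rewarded_dir2` | ±1 | rewarded direction, second decision |
| `choice1` | ±1 | first choice (empty where no first decision) |
| `rt1_s` | float | first reaction time, seconds (decision + non-decision time) |
| `correct1` | 0/1 | first choice matched `rewarded_dir1` |
| `choice2` | ±1 | second choice (only `double`/`D2star`) |
| `rt2_s` | float | second reaction time, seconds |
| `correct2` | 0/1 | second choice matched `rewarded_dir2` |
| `confidence` | [0, 1] | recorded rating (noisy; on `double` trials it rates the conjunction of both decisions) |
| `conf_true` | [0, 1] | agent's internal first-decision confidence (ground truth; absent on `D2star`) |

`read_trials(path, confidence_scale="percent")` accepts ratings on a 0–100
scale and divides by 100.

The k-NN stage (`confbound knn` / `annotate_conf_hat`) appends a
`conf_hat` column: interpolated first-decision confidence, present on
`double` trials only.
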