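# serj — emotion-trend recognition and judgment from EDA and pulse-wave signals

`serj` implements a streaming, rule-based classifier of a player's emotional
trend in the valence–arousal (V–A) plane, driven by two finger-worn sensor
channels: electrodermal activity (EDA, "skin electricity") and the
photoplethysmographic pulse wave (PPG).  It targets affective-computing
applications — in particular emotion-adaptive games, where sustained emotional
states trigger game events (rewards, difficulty spikes, scene changes) without
the player consciously steering the system.

The package covers the full chain: signal conditioning, 10-s calculation
segments, feature extraction with pulse-wave fiducial delineation, an
optimal-feature selection procedure (PCA weights + Pearson screening), the
adaptive-threshold rule tree, an SVM baseline for head-to-head comparison, the
quadrant→game-event adaptation policy, and a synthetic-session generator that
provides ground-truth-labeled EDA/PPG streams so every stage is testable.

## The model

Emotional trend is one of the four V–A quadrants: HAPV (high arousal,
positive valence), HANV, LANV, LAPV.  Per 10-s segment the judge evaluates
five features:

* `BpNN50` — fraction of successive inter-beat-interval differences with
  |Δ| > 50 ms (a pNN50-style statistic over main-wave intervals),
* `range = max(x) − min(x)` and `1dmean = (1/(N−1)) Σ (x_{i+1} − x_i)` on
  each channel's segment samples,
* the order of the EDA extremum indices `n_max`, `n_min`.

Each feature stream carries an adaptive normalized threshold

    x_th = (1/n) Σ_i (x_i − x_min) / (x_max − x_min),

the mean of the min–max-normalized stream over a calibration span (default:
the first four windows; parameters are then frozen and later values clipped
into [0, 1]).  The rule tree is:

* **EDA branch** — if normalized EDA `range` > x_th: if `n_max ≤ n_min` →
  **LAPV**; else if normalized EDA `1dmean` > x_th → **HANV**.
* **Pulse branch** — if normalized `BpNN50` > x_th: if normalized pulse
  `range` > x_th → **LANV**; else if normalized pulse `1dmean` > x_th →
  **HAPV**.

If neither branch fires the window is UNDECIDED; if both fire, priority
HANV > LANV > LAPV > HAPV resolves the conflict.  Decisions map to game
events (HANV → reward bricks, LAPV → spawn monsters, LANV → new scene,
HAPV → no action) once a quadrant persists, with a refractory period.

Preprocessing follows the acquisition chain: optional hardware de-biasing
`f = r − ((2014 + 2r)·10000)/(512 − r)` for raw EDA counts, 3-level db4
wavelet shrinkage (EDA), zero-phase Butterworth low-pass at 10 Hz (PPG,
magnitude `H(D) = 1/(1 + (D/D0)^{2n})`), and 0–100 min–max scaling per trace.

## Worked example

Generate a labeled synthetic session (one LANV→HANV→LAPV→HAPV cycle, three
10-s windows per segment), judge it, and run the feature selection:

```bash
$ serj simulate --seed 7 --out demo
wrote session (12 windows) to demo

$ serj judge demo --out demo/decisions.jsonl
UNDECIDED    4
LAPV         3
HAPV         3
HANV         2
```

The first four windows seed the thresholds (UNDECIDED); the remaining eight
are all judged correctly — two HANV windows survive past calibration, and the
LAPV/HAPV segments are recovered in full.  Each line of `decisions.jsonl`
carries an auditable rule trace, e.g.

```json
{"window": 6, "quadrant": "LAPV", "branch": "eda",
 "rule_trace": [["eda_range>x_th", 0.99, 0.25, true], ["n_max<=n_min", 0.0, 999.0, true]], ...}
```

```bash
$ serj features demo --out demo/features.csv
$ serj select demo/features.csv demo/labels.csv --out demo/selection.json
optimal subset: ['eda_mean', 'eda_std', ..., 'eda_range', ..., 'eda_1dmean', ..., 'bpnn50', ...]
```

The selected subset always contains the three named optimal features —
`bpnn50`, `eda_range`, `eda_1dmean` — the ones the rule tree is built on.
`serj compare` trains the SVM baseline on one synthetic subject and evaluates
both approaches on another; `serj verify-tables` re-sums the packaged
reference activation tables; `serj run` chains the whole pipeline.

## Layout

| module | role |
|---|---|
| `serj.synth` | labeled synthetic EDA/PPG session generator |
| `serj.signal_io` | trace containers, CSV I/O, 10-s windowing |
| `serj.preprocess` | calibration, wavelet denoising, Butterworth, 0–100 scaling |
| `serj.features` | pulse fiducials, BpNN50/range/1dmean, full feature catalog |
| `serj.selection` | PCA-weight + Pearson-significance optimal-feature selection |
| `serj.judge` | adaptive thresholds (x_th) and the quadrant rule tree |
| `serj.baseline` | SVM baseline and the two-approach comparison |
| `serj.adaptation` | quadrant→game-event policy and activation tables |
| `serj.reference` | packaged reference activation tables + verification |
| `serj.cli` | `serj` command-line interface |

See `docs/methods.md` for modeling assumptions, parameter defaults, and known
limitations.
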