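# aditrack

Accumulative-difference-image (ADI) particle tracking for low-SNR fluorescence
time series: size-sensitive filter segmentation, passage-time trajectory
linking (including looping/entangled tracks via multi-start restarts and
crossing analysis), time-color-coded trajectory rendering, and Brownian
diffusion statistics. A ground-truth scene simulator makes the whole pipeline
testable without experimental data.

## How it works

1. **Segmentation** — each frame passes a minimum filter (suppresses
   high-frequency background), a value-preserving threshold (one value for the
   whole stack, found iteratively on a user-chosen region of frame 0 until the
   expected target count is reached), then a mean filter and maximum-based
   peak picking that reduce every target to a single marked pixel.
2. **Passage map** — frame-to-frame differences of the binary maps record,
   per pixel, the frames at which a target newly arrives ("passage times").
3. **Linking** — from each seed, the tracker repeatedly jumps to the
   neighboring pixel (Chebyshev shells up to `shell_radius`) holding the
   smallest later passage time. Restarting every `incrementostep` frames
   recovers loop/crossing segments a single pass misses.
4. **Entanglement** — trajectories sharing a Δx·Δy·Δt window are grouped; each
   group's samples merge into a time-ordered *paragon* table with per-row step
   differences, split into continuous segments wherever a step exceeds
   `threshold_paragon`. Merging segments back into one track is an explicit,
   validated user action.
5. **Statistics** — displacements between consecutive detections are
   normalized by √τ of their actual lag; x/y histograms are globally fit with
   `G(u) = A·exp(−u²/4D)` (per-axis amplitudes, shared D, Poisson weights).

## CLI

```sh
# simulate a scene with ground truth
aditrack simulate --scenario brownian --n 40 --n-frames 100 --size 256 \
    --d-coeff 0.022 --seed 1 --out stack.tif --truth truth.csv

# full pipeline (segment -> ADI -> track -> render)
aditrack run stack.tif --config config.yaml --outdir out/

# or stage by stage
aditrack segment stack.tif --threshold 0.3 --out detections.csv
aditrack track stack.tif --detections detections.csv --incrementostep 20 \
    --out trajectories.csv
aditrack crossings trajectories.csv --out crossings.csv
aditrack paragon trajectories.csv --group-id 0 --threshold 3 --out paragon.csv
aditrack merge paragon.csv --segments 0,2 --out merged.csv
aditrack render stack.tif trajectories.csv --colormap green-levels --out traj.png
aditrack fit-d trajectories.csv --pixel-size 0.1 --frame-interval 0.85
```

Config is YAML (`key: value`); every key has the module default when omitted
(`m_m: 1`, `m_b: 1`, `threshold: auto|float`, `roi`, `expected_count`,
`shell_radius: 3`, `incrementostep: 0`, `min_length: 3`, `dx/dy/dt`,
`threshold_paragon: 3`, `pixel_size_um`, `frame_interval_s`, `seed`).

## Layout

- `src/aditrack/io_stack.py` — TIFF stacks, trajectory CSVs, normalization
- `src/aditrack/segmentation.py` — phase-A filter chain
- `src/aditrack/adi.py` — passage map (the V matrix)
- `src/aditrack/linking.py` — shell-search linking, multi-start restarts
- `src/aditrack/entanglement.py` — crossings, paragon build/split/merge
- `src/aditrack/diffusion_stats.py` — normalized displacements, global fit
- `src/aditrack/viz.py` — time-color-coded renders, overlay frame export
- `src/aditrack/synthetic.py` — scene simulators, renderer, truth matching
- `src/aditrack/benchmarks.py` — reproducible benchmark scenarios
- `src/aditrack/cli.py` — click front end
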