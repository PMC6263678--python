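# barkline

Resource-efficient classification of dog vocalizations from a wearable
**noise sensor's** intensity output, instead of full audio from a sound
sensor.

Collar-mounted sensors that stream raw audio (uncompressed WAV) drain a
small wearable battery in about two hours. A cheap noise sensor that
reports only a per-frame **intensity level** — the peak-to-peak range of
the 10-bit quantized microphone voltage (0–5 V), 138 frames per second —
produces ~74× less data and runs for ~20 h on the same battery. The catch
is that the intensity envelope discards most acoustic information, so
classifying the four behaviorally meaningful vocalization classes
(**barking, growling, howling, whining** — alerting, threat, loneliness,
separation anxiety) becomes a univariate time-series problem. `barkline`
implements the full pipeline that makes this workable:

1. **Sensor simulation** — frame audio at 138 Hz, quantize to a 10-bit
   0–5 V ADC, emit per-frame peak-to-peak volts; RMSE similarity analysis
   between sound-derived intensity and the simulated intensity level.
2. **Preprocessing** — per-event 0–1 normalization
   `x' = (x − min x)/(max x − min x)`, then 1-D cubic-convolution
   interpolation (Keys kernel, `a = −0.5`) that lengthens each sequence by
   a factor (default 3) without reshaping its envelope, then zero-padding
   to a fixed model width.
3. **LSTM-FCN classifier** — two parallel branches over the same length-L
   input: three temporal-convolution blocks (128/256/128 filters, kernels
   8/5/3, each with batch normalization + ReLU) pooled by global average,
   and an LSTM (8 units, dropout 0.8) fed via a dimension shuffle (the
   series becomes one time step of L features); concatenated features feed
   a softmax over the 4 classes. Implemented in pure NumPy (seeded,
   bit-reproducible), trained with Adam on cross-entropy.
4. **Energy model** — per second of sensing,
   `E_total = E_sense + (data/link speed)·E_radio`; battery life =
   battery joules / `E_total` / 3600.
5. **Synthetic data** — class-conditional generators for intensity
   events and paired audio whose length statistics and envelope shapes
   (burst-decay barks, jagged sustained growls, long-decay howls, quiet
   jagged whines) emulate the published per-class statistics, so the whole
   pipeline is testable without any recordings.

## Worked example

```python
import barkline as bl
from barkline.preprocess import PreprocessConfig
from barkline.classifier import LSTMFCNConfig, train_evaluate_split
from barkline.synth import SynthConfig, generate_dataset
from barkline import energy

# energy budget: why the noise sensor at all?
for row in energy.energy_table():
    if row["link_speed_KB_s"] == 300.0:
        print(row["device"], row["total_J_printed"], "J/s ->",
              row["battery_hours_display"], "h")
# sound 1.011 J/s -> 1.9 h
# noise 0.102 J/s -> 19.6 h

# classify synthetic vocalizations (desk-scale sizing)
ds = generate_dataset(SynthConfig(events_per_class=75, seed=17))
pc = PreprocessConfig(interpolation_factor=3.0,
                      max_dim=max(len(s) for s in ds))
cfg = LSTMFCNConfig(conv_filters=(16, 32, 16), epochs=60, seed=17,
                    input_length=pc.model_input_length)
report = train_evaluate_split(ds, pc, cfg, split_seed=17)
print(round(report.accuracy, 3))
# 0.859
```

The energy lines say a sound sensor spends 1.011 J per second (0.9 J
sensing + 0.111 J radioing 66.4 KB at 300 KB/s) and flattens a 400 mAh/5 V
battery (7200 J) in 1.9 h, while the noise sensor lasts 19.6 h — a ≥10×
battery-life gain. The final number is the held-out accuracy of the
LSTM-FCN on a 70/30 stratified split of 300 synthetic events after
threefold cubic interpolation: 0.859, well above the 0.25 chance level of
the four balanced classes.

A CLI mirrors the pipeline stages:

```bash
barkline synth --n-per-class 300 --seed 17 --out intensity.csv
barkline simulate --wav-dir clips/ --out sensed.csv
barkline preprocess --in intensity.csv --factor 3 --out tensors.npz
barkline train --in tensors.npz --epochs 200 --seed 17 --model m.npz
barkline eval --model m.npz --in tensors.npz --report report.json
barkline energy --json
barkline run --seed 17 --out-dir results/
```

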