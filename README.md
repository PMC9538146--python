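# lagfuse

Lag-compensated EEG/sEMG fusion for decoding lower-limb movement
intention.

Cortical activity leads muscular activity: the scalp EEG of a motor
act precedes the surface EMG of the responding muscle by a
response-time difference ΔT of a few tens of milliseconds (nerve
conduction plus neuromuscular-junction delay).  Multimodal
movement-intention decoders that pair EEG and sEMG samples by wall
clock therefore mix information from different stages of the same act.
`lagfuse` is a toolkit for researchers in corticomuscular interfacing
and exoskeleton control that

1. **bounds ΔT physiologically** — ΔT = −t1 + t2 + t3 + t4 with
   t2 = D_n/v the nerve-conduction time; adult lower-limb defaults
   give ΔT ≈ 24–26 ms;
2. **estimates ΔT from data** — both signals are amplitude-quantized
   (Ps + 1 uniform bins, Ps = 30) and the symbolic transfer entropy
   TE<sub>x→y</sub>(u) = Σ p(y<sub>i+u</sub>, y<sub>i</sub>, x<sub>i</sub>)
   log₂[p(y<sub>i+u</sub>, y<sub>i</sub>, x<sub>i</sub>)p(y<sub>i</sub>) /
   (p(y<sub>i+u</sub>, y<sub>i</sub>)p(y<sub>i</sub>, x<sub>i</sub>))]
   is profiled over time steps u; the profile's peak is the lag;
3. **eliminates ΔT** by lag-compensated window alignment (offline:
   sEMG window delayed by ΔT; online: EEG window advanced), building
   data-fusion matrices or cascaded feature vectors (wavelet-packet
   band variance/energy for EEG; VAR, SSC, ZC, RMS, MPF, cepstrum
   coefficients for sEMG);
4. **decodes movement classes** with a hybrid CNN-LSTM (four
   conv/ELU/average-pool blocks, two LSTM/dropout blocks, softmax),
   evaluated by stratified, group-aware 5-fold cross-validation.

Because raw corticomuscular recordings are rarely shareable, the
package ships a synthetic-signal generator producing coupled EEG/sEMG
trials with a *known* conduction delay and class structure, so every
stage is testable end to end.  See `docs/methods.md` for the models,
assumptions and limitations.

## Worked example

```python
import lagfuse as lf
from lagfuse.coupling import TEProfile, SymbolizerConfig, te_profile

# physiological bound
est = lf.physio_delta_t(lf.PhysioParams())     # 1.4-1.5 m, 60 m/s, 0.5-1 ms
print(est.summary())

# data-driven estimate on 20 synthetic coupled trials (35-sample lag)
profiles = []
for seed in range(1, 21):
    rec = lf.simulate_coupled_pair(lf.SimConfig(seed=seed, lag=35, snr_db=5.0))
    profiles.append(te_profile(rec.data[0], rec.data[9],
                               SymbolizerConfig(Ps=30), 50, rec.fs))
print(TEProfile.average(profiles).summary())
```

prints

```
nerve conduction t2 = 23.33..25.00 ms; response-time difference dT = 23.83..26.00 ms (rounds to 24~26 ms)
TE profile over u = 1..50 (20 trial(s), fs = 1024 Hz)
  peak TE = 0.6763 bits at u = 35 samples = 34.18 ms
```

The physiological bound brackets ΔT at 24–26 ms; the transfer-entropy
profile, averaged over trials, peaks at u = 35 samples = 34.18 ms —
recovering the generator's imposed conduction delay exactly.

Decoding, end to end:

```python
from lagfuse.pipeline import filter_epochs

ep = filter_epochs(lf.simulate_movement_dataset(
    lf.SimConfig(seed=3, snr_db=10.0), 10))          # 8 classes x 10 trials
ds = lf.build_dataset(ep, lf.WindowConfig(200, 100, 35.0), mode="data")
res = lf.MovementDecoder.from_dataset(ds).fit_kfold(k=5, seed=0)
print(res.summary())
```

```
5-fold CV accuracy 0.713 +/- 0.041 [0.644, 0.715, 0.760, 0.699, 0.747]
```

(3,120 lag-compensated 13 × 200 fusion windows; chance level for 8
classes is 0.125; windows of one trial never split across folds).

## Command line

```sh
lagfuse simulate --seed 1 --trials-per-class 10 --out epochs.npz
lagfuse lag epochs.npz --ps 30 --u-max 50       # TE profile + peak lag
lagfuse physio-lag                               # physiological bound
lagfuse fuse epochs.npz -L 200 --delta-t 35 --out dataset.npz
lagfuse train dataset.npz --k 5 --report report.json
lagfuse run --report report.json                 # whole pipeline
```

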