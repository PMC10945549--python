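# kirscreen

Kinase-inhibitor regression (KiR) for cytokine secretion screens.

Macrophages stimulated with LPS release a broad panel of cytokines and
chemokines. Which kinases control the release of each factor? Single-drug
experiments cannot say, because every kinase inhibitor hits many kinases at
once. `kirscreen` turns that polypharmacology into signal: given a screen
of n drugs with known kinase-inhibition fingerprints (residual kinase
activity, percent of control) and the measured secretion response of m
factors to each drug, it deconvolves the kinase→cytokine regulation map,
predicts the efficacy of large unscreened inhibitor panels, and builds
prunable cytokine-centric kinase networks. It is aimed at systems
biologists running (or reanalyzing) kinase-inhibitor secretome screens.

## The model

For each secreted factor c, the response across drugs is modeled as linear
in the drugs' kinase-inhibition fingerprints,

    y_i = β₀ + Σ_j x_ij β_jc + ε_i,

fit with the elastic net,

    min (1/2n) Σ_i (y_i − β₀ − x_i·β)² + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],

for 11 values of α from 0 to 1 inclusive, with λ selected per α by
leave-one-out cross-validation over drugs. A model is accepted when its
LOOCV predictions reach nRMSE < 0.1 and Pearson r > 0.85. Kinases with a
positive coefficient in any selected α > 0 model are called *informative*
for that factor (β_j > 0 means inhibiting kinase j lowers secretion).
Accepted models then predict responses for any profiled-but-unscreened
inhibitor via ŷ = β₀ + x·β, and per-drug efficacy is 100·(1 − ŷ) on the
fraction-of-control scale.

A synthetic-screen generator with planted sparse ground truth
(`kirscreen.synthetic_data`) makes every stage testable without any
download. See `docs/methods.md` for the full protocol, numerical choices
and known limitations.

## Worked example

```python
import kirscreen as ks

# a synthetic screen: 34 drugs x 50 kinases, 10 cytokines with 5 planted
# regulator kinases each, responses as fraction of the LPS-only control
sim = ks.simulate_screen(ks.SimulationConfig(seed=7))
X, Y = sim["X_screen"], sim["Y_screen"]

models = ks.fit_kir_models(X, Y)
m = models["CYT01"]
print(m.quality)
print(sorted(m.informative_kinases))
print(sorted(sim["ground_truth"].support["CYT01"]))
```

prints (numbers from this exact seed):

```
ModelQuality(nrmse=0.0949..., pearson_r=0.9592..., accepted=True, reason='')
['KIN003', 'KIN007', 'KIN008', 'KIN014', 'KIN015', 'KIN016', 'KIN023',
 'KIN030', 'KIN034', 'KIN037', 'KIN039', 'KIN043', 'KIN046', 'KIN047']
['KIN003', 'KIN008', 'KIN016', 'KIN023', 'KIN047']
```

The model is accepted (LOOCV nRMSE 0.095, r 0.959) and its informative set
contains all five planted kinases — plus spurious small-coefficient hits,
which is characteristic of the sign-based hit rule (see
`docs/methods.md`). Predicting a 100-drug unscreened panel and ranking:

```python
pred = ks.predict_out_of_panel(models, sim["X_panel"])
eff = ks.compute_efficacy(pred)
chart, table = ks.rank_drugs(eff, selection=list(pred.columns), k=3)
print(chart[["avg_efficacy", "pct_selection_affected"]].round(1))
```

```
          avg_efficacy  pct_selection_affected
drug
panel014          20.4                    11.1
panel001          20.3                     0.0
panel031          16.4                     0.0
```

i.e. the best panel drug is predicted to suppress the selected factors by
20% on average at the profiled dose. The same stages run from the shell:

```
kirscreen simulate --seed 7 --out screen/
kirscreen fit --x-screen screen/X_screen.tsv --y-screen screen/Y_screen.tsv --out models/
kirscreen predict --models models/ --x-panel screen/X_panel.tsv --out pred.tsv
kirscreen rank-drugs --models models/ --x-panel screen/X_panel.tsv --out rank/
kirscreen network --network kegg_edges.tsv --models models/ --cytokine CYT01 --threshold 1.5 --out net/
kirscreen run --config pipeline.yaml          # the whole chain, manifested
```

Real screen data drop into the same entry points: TSV matrices (drugs ×
kinases residual activity; drugs × factors response relative to the
LPS-only control), a long-format replicate table for differential
secretion, and a weighted edge list for the reference network.

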