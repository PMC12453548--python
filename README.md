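# ifcdose

Radiation biodosimetry from imaging-flow-cytometry (IFC) γ-H2AX endpoints.

After ionizing-radiation exposure, γ-H2AX foci form at DNA double-strand
breaks within minutes, making them a rapid biological dosimeter. IFC images
every cell in flow, so one acquisition of a blood sample yields three
per-sample dose-response endpoints over the gated lymphocyte population:
mean fluorescence intensity (MFI), mean focus ("spot") count per cell, and
mean spot area. `ifcdose` is for radiation-protection and emergency-response
researchers who need to turn those endpoints into dose estimates, and to
test estimation strategies without access to donor blood or a cytometer.

The package implements, end to end:

* **Synthetic data** (`ifcdose.synthdata`) — an image-level generator
  (nuclei with Poisson-distributed Gaussian foci, apoptotic/debris
  contaminants) and a feature-level generator for the standard 10-donor
  calibration design at {0, 0.5, 1, 2, 4, 6, 8, 10} Gy plus blinded
  validation sets.
* **Feature extraction** (`ifcdose.imaging`) — gating (focus, singlet,
  marker-positive), a healthy-lymphocyte classifier on circularity and
  internal texture, nucleus/spot masks, and the three endpoints per cell.
* **Calibration curves** (`ifcdose.calibration`) — the linear MFI response
  `MFI = αD + β` and the saturating spot-feature response
  `Y = v(1 − e^(−ξD))`, both with 95% bands, plus calibration-curve (CC)
  dose inversion with Fieller-style interval inversion.
* **K-NN dose estimation** (`ifcdose.knn`) — the non-parametric estimator
  `D̂ = (1/k) Σ Dᵢ` over the k calibration samples nearest to the query in
  standardized (MFI, spot count, spot area) space, with 70:30 k-tuning and
  percentile-bootstrap confidence intervals.
* **Evaluation and triage** (`ifcdose.evaluate`) — RMSE
  `√((1/n) Σ (D̂ᵢ − Dᵢ)²)` overall and per dose bin, ±0.5/±1 Gy coverage,
  and 2 Gy triage classification with a full confusion report.
* **Pipeline and CLI** (`ifcdose.pipeline`, `ifcdose` command) — a seeded,
  manifest-checksummed end-to-end run.

## Worked example

Simulate a 10-donor calibration study and 75 blinded validation samples,
then estimate one query dose both ways:

```python
import numpy as np
from ifcdose.io import PipelineConfig
from ifcdose.pipeline import run_study
from ifcdose.calibration import invert_linear
from ifcdose.knn import CalibrationDataset, KnnConfig, estimate_batch

res = run_study(PipelineConfig(seed=1))
lin = res["linear_fit"]
print(f"MFI fit: alpha = {lin.alpha:.2f} a.u./Gy, beta = {lin.beta:.1f} a.u.")

q = res["query_table"].iloc[0]          # one blinded sample (truth: 2.0 Gy)
cc = invert_linear(q.mfi, lin, max_dose=10.0)
cal = CalibrationDataset.from_frame(res["calibration_table"])
knn = estimate_batch(q.to_frame().T, cal, KnnConfig(k=7, seed=1),
                     np.random.default_rng(1))[0]
print(f"CC  : {cc.dose_hat:.2f} Gy (95% CI {cc.ci_low:.2f}-{cc.ci_high:.2f})")
print(f"K-NN: {knn.dose_hat:.2f} Gy (95% CI {knn.ci_low:.2f}-{knn.ci_high:.2f})")
```

prints

```
MFI fit: alpha = 32.12 a.u./Gy, beta = 102.1 a.u.
CC  : 1.95 Gy (95% CI 0.25-3.64)
K-NN: 2.00 Gy (95% CI 1.86-2.29)
```

The fitted slope and background recover the generative values (30 a.u./Gy,
100 a.u.) up to donor noise. For this 2 Gy sample both estimators are
accurate, but the K-NN interval is far tighter: it exploits the spot count
and spot area alongside MFI, and its estimate snaps to the mean dose of the
seven nearest calibration samples. Across the whole validation set of the
same run (`res["report_cc"]`, `res["report_knn"]`):

```
CC  : RMSE 0.93 Gy | within ±0.5 Gy 56% | ±1 Gy 76% | triage acc 88%
K-NN: RMSE 0.63 Gy | within ±0.5 Gy 75% | ±1 Gy 89% | triage acc 99%
```

The K-NN advantage is concentrated above ~6 Gy, where spot endpoints
saturate but donor-to-donor MFI scatter grows in proportion to the signal,
degrading curve inversion.

The same study runs from the shell:

```sh
ifcdose run --seed 1 --out run1        # writes tables, fits, manifest.json
ifcdose simulate --seed 3 --out cal.tsv
ifcdose estimate --calibration cal.tsv --queries cal.tsv --method knn --out est.tsv
ifcdose evaluate --estimates est.tsv --out report.json
```

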