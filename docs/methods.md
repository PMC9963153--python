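# Methods

## Overview

`metaldecoder` implements the analysis chain for decoding bacterial-lysate
SERS spectra into heavy-metal contamination calls:

    spectra → baseline correction → smoothing → Si normalization
            → PCA (22 scores) → {SVM classification | 1-D CNN regression
                                 | transfer-learned binary verdict}
            → detection limits / verdicts

plus the dose arithmetic that connects salt masses, ion molarities and
per-cell doses. Every stage is driven by a synthetic-data generator so the
full pipeline is testable without the experimental archive.

## Synthetic campaigns

The generator reproduces the statistical structure the models assume of
real lysate campaigns.

**Layout.** Each exposure class is a concentration on a decade ladder
(Cr⁶⁺: 0.68 pM–68 µM, nine decades; As³⁺: 5 fM–5 mM, thirteen decades).
A class is acquired as `n_maps` Raman maps of `rows × cols` points on one
SERS surface; the paper layout (3 maps of 20×20) gives 1,200 spectra per
class. The unexposed control pools eight surfaces, maps alternating between
two biological replicates, giving 9,600 spectra. Exposure classes cycle
through the same surface pool, mirroring shared-surface acquisition.

**Spectrum model.** A spectrum on the canonical 300–1,800 cm⁻¹ grid
(1 cm⁻¹ spacing, covering both the Si line and the dominant metabolite band)
is

    gain × [ baseline(ν) + Σ_k A_k(c) · L(ν; center_k, width_k) + A_Si · L(ν; 520, w) ] + ε

with Lorentzian line shapes `L` (standard for Raman), additive Gaussian
noise `ε` (sd 0.05 a.u., a desk-scale stand-in for shot noise), and
multiplicative log-normal gains per surface (log-sd 0.15) and biological
replicate (log-sd 0.05). The gains are applied **before** noise, so Si
normalization genuinely has something to cancel — preprocessing is tested,
not decorated.

**Dose–response.** Band amplitudes follow a Hill curve in the exposure
concentration `c`:

    A(c) = A₀ · (1 + s · F · cʰ / (Kʰ + cʰ)),   s ∈ {+1, −1}

monotone in `c`, equal to `A₀` at `c = 0`, saturating at `A₀(1 ± F)`.
Defaults: the dominant responsive band sits at 725 (Cr) / 732 (As) cm⁻¹
(the 700–750 cm⁻¹ region carries the largest PC1 loading in real lysate
data); eight further bands at generic nucleotide/protein-region centers
carry half-effect points `K` spread across the decade ladder with shallow
slopes (h ≈ 0.3–0.4). The spread is deliberate: a stress response graded
over eight-plus orders of magnitude must recruit different metabolites at
different doses for *every* neighbouring decade pair to be separable, which
is the regime the real campaigns demonstrate. Cr and As get distinct
direction/center signatures (their toxicity mechanisms differ), which is
what makes metal-type classification non-trivial. Centers beyond the
dominant band are placeholders and fully configurable.

**Matrix shift.** Tap water and wastewater configs add inert background
bands (e.g. 980/1048 cm⁻¹) and a baseline offset while leaving the
dose-responsive bands and the Si line untouched — a purely additive
background shift that a frozen DI-trained model should partially survive
and fine-tuning should absorb.

**What the generator does not emulate:** real metabolite assignments and
kinetics, SERS enhancement physics, cosmic-ray spikes, wavenumber
calibration drift, heteroscedastic shot noise, or correlated
surface-chemistry drift. Passing recovery tests therefore shows the
*pipeline* is correct and sensitive under its stated assumptions, not that
the real instrument achieves the published figures; those live in
`metaldecoder.replication` as replication targets for the deposited data.

## Preprocessing

Fixed order: AsLS baseline → Savitzky–Golay smoothing → Si normalization
(normalizing last keeps the Si-window maximum exactly 1).

- **AsLS** minimises `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²zᵢ)²` with `wᵢ = p` above /
  `1−p` below the current baseline, iterated 10 times from unit weights;
  the pentadiagonal system is solved by banded Cholesky. Defaults λ = 1e5,
  p = 0.01 — standard chemometric values; no universal setting exists, so
  all knobs are exposed. The unit tests pin the solver to a dense
  brute-force oracle to 1e-8.
- **Savitzky–Golay** uses window 11, order 3, with polynomial edge-fit
  extrapolation at the boundaries.
- **Si normalization** divides by the *maximum* within 520 ± 15 cm⁻¹ rather
  than the value at a fixed index, tolerating small calibration shifts; at
  zero noise this cancels multiplicative gains exactly.

The chain is not idempotent (a second baseline pass eats real signal);
re-application triggers a provenance warning, not an error.

## Features

PCA (22 components, mean-centred, full SVD) is fit on the **training
partition only** and applied to the holdout — fitting on all data would
leak; a whole-dataset fit remains available for comparing variance fractions
against published values. Component signs are normalised so each loading's
largest-magnitude entry is positive. SMOTE synthesises minority rows as
`x + u(x_nn − x)`, `u ~ U(0,1)`, with `x_nn` among the k = 5 same-class
nearest neighbours (the canonical default; the protocol fixes no value);
synthetic rows carry a provenance flag so cross-validation can audit that
none reaches a validation fold. t-SNE (perplexity 30) is diagnostic only.

## SVM stage

RBF kernel, C = 1, γ = "scale" — the study's fixed hyperparameters; no
search is performed. Splits are per-class with `round(frac·n)` holdout rows,
so 1,200 → 960/240 and 9,600 → 7,680/1,920 exactly. Concentration labels
are log-scale class indices (control = 0, decades 1…n). The
classification LOD takes the >98% criterion symmetrically: class c separates
from control when < 2% of its holdout spectra are predicted control **and**
< 2% of control spectra are predicted as c, and the LOD is the smallest
concentration for which this holds at every concentration above as well
(making detection monotone — the criterion leaves this implicit). The
row-only reading is available via `rule="row"`.

## CNN regression

Architecture (input = 22 PCA scores as a length-22, 1-channel sequence):
four conv layers of (22, 22, 44, 44) filters, width 7, stride 1, "same"
padding on all four (specified for the first; extended to all so the filter
counts compose at constant length), each conv followed by ReLU → batch
normalization → 20% dropout; then flatten → dropout → dense(22, L2 0.001,
ReLU) → dense(1, linear). Conv-1 has 7·1·22+22 = 176 parameters. Training:
Adam, MSE on the class index, batch 44, up to 35 epochs, early stop after
`max(1, patience)` consecutive validation-loss increases (patience 10);
a fixed-epoch run is `early_stopping=False`. Predictions are not clipped
to the label range. The engine is a small NumPy implementation with exact
gradients (finite-difference-checked in the tests) and fully seeded
initialisation, dropout and shuffling, so single-threaded runs are
bit-reproducible. The Adam step size (3e-3) is the one tuned knob, chosen —
as in the original protocol — by monitoring loss convergence within the
35-epoch budget; the transfer stage uses 1e-3 as specified there.

**Detection limits.** Per class, the central 99% interval of holdout
predictions ([P0.5, P99.5], linear interpolation between order statistics).
LOB = the control's interval. "Overlap" is operationalised as the fraction
of a class's predictions falling inside a neighbour's interval. LOD =
smallest concentration with < 0.5% of predictions inside the LOB, holding
at all larger concentrations; LOQ additionally requires < 0.5% inside both
neighbouring classes' intervals (class 1's lower neighbour is the control),
and its search starts at the LOD so LOQ ≥ LOD by construction. Dynamic
range = [LOQ, c_max]. Box-plot summaries share the same percentile
definitions, so whiskers and detection intervals coincide. For the
interval views the over-represented control holdout is down-sampled
(seeded, uniform, without replacement) to the exposure-class holdout size.
With the default generator the top As³⁺ decades run near Hill saturation,
so their neighbour overlap can exceed 0.5% and the LOQ is then reported as
not quantifiable — an honest outcome of the rule, not a failure mode.

**Learning curve.** Per requested size: draw that many rows per class from
the training partition (SMOTE-augment smaller classes up to 8× their real
count, the augmentation factor used for the 960 → 7,680 balance), train a
fresh model, evaluate on the fixed holdout; report mean ± SD over repeats.

## Transfer learning

The binary safety model reuses the conv stack with a one-node sigmoid head
(binary cross-entropy, Adam lr 0.001). Pretraining uses DI classes at
0.05/0.5/5 nM (below WHO) and 5/50/500 µM (above). Fine-tuning on a new
matrix uses exactly 80 spectra per spiked class, freezes conv layers 3–4
(restored bit-identically afterwards, so the freeze audit is exact) and
retrains the rest; the epoch budget mirrors the regression protocol since
the original is unstated. Verdict: each spectrum votes at probability 0.5;
the majority decides, and an exact tie resolves to "above" — the fail-safe
direction for water safety (the protocol never encounters a tie).

## Dosimetry

Exact linear conversions with NaAsO₂ = 129.91 g/mol (1 As), K₂Cr₂O₇ =
294.18 g/mol (2 Cr — the stoichiometry doubles ion molarity relative to
salt molarity), As = 74.92, Cr = 52.00 g/mol. WHO limits quoted as µg/L of
the element convert via the elemental mass. Ions per bacterium =
(molarity · N_A / 1000 mL) / (OD · cells/mL/OD) with the calibration
1×10⁹ cells mL⁻¹ OD⁻¹ — an inferred round-number factor (5×10⁸ cells/mL at
OD 0.5), the unique such value consistent with the printed per-cell doses
of 0.6 (As) and 8.2 (Cr) at the respective LODs; it is exposed in
`CultureSpec`, documented as inferred rather than measured.

## Problem sizes and seeding

The test suite and `scripts/acceptance.py` run the model stages at 100
synthetic spectra per class (400/class for the learning-curve study so that
size 1,000 stays inside the 8× augmentation budget), the layout-arithmetic
checks at the full 1,200/9,600 layout, and the oracle checks at n ≤ 50
instances — sizes chosen so a desk run completes in minutes while every
contract is still exercised at full fidelity. One top-level seed fans out
to per-stage child seeds via `numpy.random.SeedSequence`, so stages are
independently reproducible and identical configs yield byte-identical
reports.

## Known limitations

- The NumPy engine is single-threaded and CPU-bound; it is sized for
  22-point inputs, not raw spectra.
- Stochastic recovery checks (SVM/CNN/transfer) are majority-over-seeds
  properties, not guarantees for every seed.
- SMOTE interpolates in score space only; no borderline/ADASYN variants.
- The generator's band library beyond the dominant 700–750 cm⁻¹ feature is
  synthetic placeholder chemistry; real metabolite assignments require the
  deposited data.
- Detection limits are empirical percentile rules; no parametric
  uncertainty is attached to LOB/LOD/LOQ.
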