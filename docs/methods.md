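# Methods

## Problem and model

Metalloproteins bind metal ions (Zn²⁺, Cu²⁺, Fe²⁺/Fe³⁺, Co²⁺, Mn²⁺, Ca²⁺,
Mg²⁺, Na⁺, K⁺) through a handful of residues; identifying those binding
residues from sequence is a heavily imbalanced per-residue classification
problem (typically 0.5–3% positives). `metalbind` classifies each residue
from a sliding window of length L (odd, 5–17) centred on it, padded at the
chain ends with the pseudo-residue X so that every residue gets a window.

Each window is described by seven feature blocks:

1. **amino-acid block** — 21-dim window composition plus 2L position
   conservation scores from a dual position weight matrix (PWM);
2. **secondary-structure block** — 4-dim composition (H/E/C/X) plus 2L
   dual-PWM scores over predicted secondary structure;
3. **solvent-accessibility block** — 3-dim composition (exposed/buried/X)
   plus 2L dual-PWM scores; a residue is *exposed* when its relative
   solvent accessibility is strictly greater than 0.25;
4. **hydropathy entropy** — Shannon entropy (bits) of the window over a
   6-class Kyte–Doolittle partition plus X (q = 7);
5. **charge entropy** — entropy over positive {H,K,R} / negative {D,E} /
   neutral / X (q = 4);
6. **correlation block** — gap-order pair-group occupancies (below), 10
   dims per selected gap order;
7. **propensity block** — the central residue's binding and non-binding
   propensity factors (2 dims).

Total dimension 30 + 6L + 10·|orders| + 2 (e.g. 118 at L = 11 with two
orders). The classifier is a gradient-boosting machine (additive stagewise
ensemble of depth-limited regression trees); its four tuned
hyperparameters are the number of trees {100,150,…,500}, interaction depth
{3,5,7,9}, shrinkage {0.01,0.1} and minimum terminal-node size
{10,20,30,40,50}. Class imbalance is deliberately left untouched — no
resampling or reweighting — and predicted probabilities are thresholded at
0.5.

### Dual PWMs and pseudocounts

For alphabet size q and N training windows, the per-position symbol
probability is smoothed with a square-root pseudocount,

    p_ij = (n_ij + √N/q) / (N + √N),     m_ij = ln(p_ij / p0_j),

with uniform background p0 = 1/q (natural log). Two matrices are fitted —
one on positive, one on negative training windows — and a window is scored
by both, giving 2L features per alphabet. The same pseudocount smooths the
category probabilities inside the entropies (log base 2), which therefore
reach exactly log₂ q for a composition uniform over all q categories. X is
its own category everywhere, fixing q = 21 (amino acids), 4 (secondary
structure), 3 (accessibility), 7 (hydropathy), 4 (charge).

### Gap correlation features

Binding residues of one spatial site cluster in sequence. For each chain
the gaps d between consecutive binding residues are counted (d = number of
residues strictly between; d = 0 means adjacent), pooled over chains into
an empirical distribution p(d), and the orders with p(d) > 0.10 are
selected per ligand (falling back to the single most probable order if
none clears the threshold). For each selected order d, the 400 ordered
amino-acid pairs (row-major over ACDEFGHIKLMNPQRSTVWY) are counted at
window offset d+1 in positive and negative fragment sets separately; pairs
touching X are skipped while their slots still count in the denominator,
so a frequency vector sums to 1 only for X-free windows. The D-value of a
pair is its positive-set frequency minus its negative-set frequency; pairs
are ranked by |D| descending (ties broken by the fixed pair order for
determinism), the top 100 are split into 10 consecutive rank groups of 10,
and a fragment's feature for group g is the fraction of its offset-(d+1)
slots occupied by group-g pairs. Whether these group features should be
counts or indicators was an open choice; normalised counts retain more
information at no extra dimension.

### Propensity factors

With residue-level counts n_ij (residue i in class j ∈ {binding,
non-binding}), N_i = n_i·, N_j = n·_j, N_t = n··, the propensity factor is

    F_ij = (n_ij / N_i) / (N_j / N_t),

i.e. how strongly residue type i is over-represented in class j (F > 1 ⇒
preference). It satisfies Σ_i (N_i/N_t)·F_ij = 1 per class, which the test
suite checks to 1e-9. Only the central residue's two factors enter the
feature vector, matching the 2-dim block; a central X (a mapped
non-standard residue) gets (0, 0).

## Evaluation protocol

Stratified 5-fold cross-validation at the fragment level with a fixed
seed. Pair screens, propensity tables and PWMs are refitted inside each
training fold to avoid label leakage; gap-order selection is a per-ligand
chain-level statistic and is computed once on the full chain set. Folds
that would lack positives are re-drawn with the next seed. Confusion
counts are pooled over folds and Sn, Sp, Acc and MCC computed from the
pooled counts (per-fold metrics are also reported); AUROC is computed on
the pooled out-of-fold scores, with per-fold AUROCs retained for
hyperparameter selection. MCC is defined as 0 when any factor of its
denominator is zero (e.g. the all-negative predictor). Fragment-level
splitting mirrors the fragment-dataset framing of the protocol it
reproduces; it does not guard against homologous fragments of one chain
straddling folds, which on real data would flatter the estimates.

Window sweep picks L ∈ {5,…,17} maximising pooled MCC (ties: higher Sn,
then smaller L). Grid search over the four hyperparameter grids selects by
mean per-fold AUROC (ties: fewer trees, then shallower depth). The random
forest baseline (500 trees) runs under the identical CV protocol.

## Synthetic data generator

The generator emulates exactly the three statistics the features exploit,
and nothing else:

* **prevalence** π = 0.02 by default (the per-chain binder count is
  Binomial(length, π)); realistic benchmark prevalences run ~0.5–3%;
* **binder identity preference** — binder positions redraw their residue
  from the background composition (Robinson–Robinson frequencies)
  multiplied by boosts C×6, D×8, E×5, H×10, echoing the observed
  preference of metal sites for C/D/E/H with H strongest;
* **gap clustering** — gaps between consecutive binders are i.i.d. from a
  planted law p(0)=0.30, p(1)=0.18, p(2)=0.07, p(3)=0.05, p(4)=0.04,
  p(5)=p(6)=0.03, remaining mass in a geometric tail (rate 0.05) over
  d ≥ 7. The binder run is placed uniformly in the chain, re-drawing the
  gap vector up to 20 times if it overflows the chain and trimming the
  largest gaps as a last resort, so the realised gap distribution matches
  the planted law up to a small truncation bias (empirically within
  sampling error at 10⁴ pairs).

Chain lengths are uniform on [50, 250]. Secondary structure is i.i.d.
(H/E/C at 0.32/0.21/0.47); RSA values are Beta(2,3) for background and
Beta(3,2) at binder positions (binders lean exposed). The null generator
switches every planted effect off (uniform binder placement, background
identities) and is used to calibrate screens, propensities and classifier
AUROC against no-signal data.

What the generator does **not** model: residue autocorrelation and real
secondary-structure segments, homology between chains, composition biases
beyond the binder boosts, any coupling between structure and sequence.
Passing tests therefore demonstrate that the pipeline recovers planted
statistics and ranks feature sets correctly under its own assumptions —
not that the reported real-benchmark performance is reproduced.

## Numerical and design choices

* Pseudocount form: the √N form above is adopted as the standard smoothing
  consistent with the symbols in the source formulas; background is
  uniform 1/q, keeping positive and negative matrices directly comparable.
* Ordered pairs (AH ≠ HA); ties in |D| broken by the fixed pair order;
  composition/entropy/PWM computations are exact sums, no tolerance knobs.
* Annotation positions are 1-based sequence indices; multiple sites of one
  ligand on a chain are merged by union of positions.
* Non-standard residues (B, J, O, U, Z) map to X rather than being
  dropped, preserving the fragment-count = chain-length identity.
* Degenerate inputs: chains shorter than the half-window are fully padded;
  an empty gap table raises; a screen on fragments shorter than d+2 yields
  a zero block with a warning; residues absent from a training fold get
  propensity 0 with a warning.
* Problem sizes in the test suite and acceptance script (30–150 chains of
  100–200 residues, 100-tree GBMs, ~10⁴ gap pairs) are the package's
  chosen desk scale: large enough that planted-signal recovery is a
  multi-sigma event, small enough to iterate on a laptop core.

## Known limitations

* Secondary structure and accessibility are *inputs* (predicted upstream);
  the package neither predicts them nor models their errors.
* Real-benchmark results depend on a curated binding-annotation dataset
  (resolution/identity filtering) that is out of scope here; no claim
  about real-data Sn/MCC is made by the synthetic evaluation.
* Probabilities from the boosted classifier are not calibrated; the 0.5
  threshold is a convention, not an optimum.
* Per-chain vs pooled normalisation of the gap table is a genuine
  ambiguity; gaps are pooled over all chains here, so chains with many
  sites weigh more.
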