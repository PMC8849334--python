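# Methods

## Model formalism

The engine integrates logic-based ODEs over a signaling network. Each
species has a maximal activity `Y_max` (default 1), a relaxation time
constant `tau` in hours, and an initial activity `y0` (default 0). Every
reaction is a conjunction of signed sources driving one target with a
weight `w in [0, 1]`, a half-maximal input `EC50 in (0, 1)`, and a Hill
coefficient `n > 0`. The activation function is the normalized Hill curve

    f(x) = B x^n / (K^n + x^n),  B = (EC50^n - 1)/(2 EC50^n - 1),  K^n = B - 1,

fixed by the anchors f(0) = 0, f(EC50) = 0.5, f(1) = 1. The
parameterization is singular when `2 EC50^n = 1`; the loader and the
function itself reject parameters within 1e-9 of that surface. Gate
algebra: NOT is `1 - f`, AND multiplies term activations (and the
reaction weight), OR across reactions targeting one node is the
probabilistic sum `a + b - a b` (equivalently `1 - prod(1 - d_i)`), which
is associative and commutative with absorbing element 1. A node targeted
by no reaction decays to zero; an input reaction contributes a constant
drive equal to the stimulus weight.

Node dynamics are `dy_i/dt = (Y_max,i^eff * F_i(y) - y_i)/tau_i`.
Perturbations modify `Y_max` per protocol stage (set for
knockdown/overexpression, add/subtract for graded drug effects) and apply
instantaneously at stage start; a perturbation driving effective `Y_max`
non-positive is an error.

### Clamping convention

Hill inputs are not clamped: under overexpression (`Y_max = 5`) upstream
activities exceed 1 and `f` saturates at its ceiling `B`. Reaction drives
*are* clamped into [0, 1] immediately before the OR fold, because the
probabilistic-sum algebra is only meaningful on that interval; this keeps
the 0-1 normalized-activity semantics downstream while letting
overexpressed nodes saturate their targets. The clamp is a switch on
`SolverConfig` (`clamp_drives`) so the unclamped variant remains
reachable; negative solver noise in source activities is floored at 0
before exponentiation in either mode.

## Integration and steady states

Protocols are ordered stages of (input weights, perturbations, duration in
hours); unspecified inputs inherit the previous stage or the global basal
default 0.1. The integrator is SciPy's LSODA (stiff-capable; `tau` spans
two orders of magnitude) with rtol 1e-6 / atol 1e-8; convergence is
declared when max |dy/dt| < 1e-5 at the stage end. Steady states are
integration-based rather than root-finding so that multistable or slowly
converging configurations are reported honestly via the `converged` flag.
Standard protocol numbers: 80 h basal at inputs 0.1, then 240 h of
stimulus (weight 0.8) or perturbation, long enough for transcription-level
species (`tau` = 10 h) to settle. Steady states are independent of the
`tau` values (verified to 1e-6 under 25x rescaling); an explicit-Euler
oracle at dt = 1e-3 h (enforced dt <= min(tau)/10) agrees with the
adaptive solver to better than 1e-4 on random cyclic fixtures.

## Analysis layers

**Qualitative validation.** The protocol mirrors in-vitro experiments on
tissue-culture plastic: all inputs 0.1 with tension 0.4 for 80 h, one
stimulus raised to 0.8 for 240 h (tension stays at 0.4 unless tension is
itself the stimulus). The change in each measured node is binned at an
inclusive absolute threshold of 0.05 on the normalized activity scale
(increase / decrease / no change) and compared with the observed
direction; accuracy is reported with numerator and denominator, split by
output vs intermediate nodes, and swept over thresholds 0.01-0.10
(simulations run once and are re-binned). The threshold is absolute, not
relative to baseline, because activities are already normalized. Tension
is held at 0.4 during biochemical stimulation on the reading that it is
the culture-substrate surrogate, constant through the experiment.

**Mechano-chemo interaction (AUC) analysis.** For each biochemical input
and each tension level, steady states are computed on a dose grid (0 to 1
in 0.01 steps by default), every dose independently from a shared 80 h
basal state with tension held at its level throughout. Curves are
baseline-subtracted at dose 0 and integrated by the trapezoid rule on the
exact grid (no interpolation refinement); the signed area preserves
inhibitory responses as negative AUC. The interaction category compares
basal tension (0.1) to an elevated level with threshold 0.05 in AUC
units: *reversed* takes precedence (opposite AUC signs and |dAUC| >=
threshold); otherwise *amplified*/*dampened* is decided by whether the
response magnitude |AUC| grew or shrank — so an inhibitory response that
deepens counts as amplified, which a raw-dAUC-sign rule would
misclassify. The raw-sign variant remains selectable (`mode="raw_delta"`)
since published category counts could follow either convention. Summary
fractions default to all model nodes as the denominator, with a
`non_input` alternative and explicit counts reported so either convention
is checkable. Distribution shifts between tension levels (0.2 vs 0.5,
0.2 vs 0.9, 0.5 vs 0.9 per input) use the asymptotic two-sided two-sample
Kolmogorov-Smirnov test (standard at ~100 nodes per vector) with
Benjamini-Hochberg adjustment across all tests jointly.

**Knockdown influence/sensitivity.** At each tension level (0.25, 0.5,
0.75), every node is knocked down (`Y_max = 0.1`) for 240 h from a shared
80 h basal state; ΔActivity is measured against the unperturbed steady
state continued for the same duration. Influence is the row sum of |Δ|
(effects caused), sensitivity the column sum (effects felt); the self
term is excluded by default (switchable, since heatmap-style summaries
may include it). Ranks are dense on raw scores, ties broken
alphabetically only for display; cross-tension tables report the first
tension at which a node enters the top 10.

**Drug protocols.** ARB-class drugs subtract from the AT1R node's
`Y_max`, NEPi-class drugs add to the NP node's `Y_max`; combinations
apply both. Dose grids are geometric between a protocol's minimum and
maximum modifiers (the ranges span up to two orders of magnitude, so
geometric spacing matches pharmacological dilution series). Fold changes
divide treated by reference steady-state activity with an epsilon floor
of 1e-6 on the reference (flagged in the output) to keep near-zero
readouts from exploding. The reference is either the unstimulated control
(all inputs 0.1) or the stimulated positive control, per protocol.
Zone-resolved comparisons hold the cytokine milieu fixed (weights are
user-supplied config — in-vivo interpolated levels are out of scope) and
vary only the tension weight between remote (0.1) and infarct (0.6)
zones.

**Mechano-adaptive screen.** Perturbations enumerate all single-node
knockdowns/overexpressions (2N) and all double combinations (4·C(N,2):
KD-KD, OE-OE, and both mixed assignments). Per perturbation and tension
(0.1 remote, 0.6 infarct), the matrix content change is

    MCC = sum(dActivity_matrix) - sum(dActivity_MMP) + sum(dActivity_inhibitor)

over the standard output groups (matrix: proCI, proCIII, fibronectin,
periostin, osteopontin; MMP: proMMPs 1, 2, 3, 8, 9, 12, 14; inhibitor:
TIMP1, TIMP2, PAI1). Candidates with MCC < 0 at low tension and MCC > 0
at high tension are retained, ranked ascending on low-tension MCC and
descending on high-tension MCC (1-based competition ranks, ties share the
minimum), and scored `N_retained - 2*(rank_low + rank_high)`. That quoted
formula can go negative even though a zero floor is sometimes described;
`zero_based` (0-based ranks, shifting every score by +4) and `clamped`
(floor at 0) conventions are selectable, and all three agree on the
ordering. The baseline steady state is computed once per tension and
reused; each completed (perturbation, tension) row can be appended to a
TSV cache so a tens-of-thousands-run screen is resumable, and per-row
solver failures are recorded without aborting the screen.

## Synthetic data

`make_fixture` builds seeded chain, star, feedback-loop, and random
(acyclic or cyclic) networks with configurable inhibitor and AND-gate
fractions; chains and stars carry closed-form steady states (compositions
of `f`) used as exact oracles. `make_validation_fixture` constructs
observation tables in which a chosen number of records match the model's
own predictions, giving a known ground-truth accuracy.
`make_demo_network` is a hand-authored, mid-size (54-node, 81-reaction)
fibroblast-like network: nine cytokine inputs plus tension, receptor /
kinase / transcription-factor layers, an autocrine latent-TGFB feedback
loop (weight 0.8), tension crosstalk through AT1R, ROS, Rho/MRTF and
smad3, and the full standard output panel. Its wiring is chosen for
plausibility and code-path coverage, not curated from literature: passing
tests on it demonstrate that the machinery computes the right quantities
on a network of realistic shape, not that any specific biological claim
holds. Published statistics for the curated 109-node network therefore
verify only when that model (distributed with its original publication)
is dropped under `data/curated/`.

## Problem sizes

The default test suite and the acceptance script run on the fixtures and
the demo network: dose sweeps use a 0.02 grid over nine inputs and four
tension levels, knockdown screens cover all 54 demo nodes at three
tensions, and the adaptive screen enumerates all single and double
perturbations of the 27 signaling-layer nodes (1,458 perturbations x 2
tensions). These sizes keep a full pipeline run to a few minutes while
exercising every code path; all grids and node sets scale up by argument
for larger models.

## Known limitations

- Steady states are obtained by finite-horizon integration; oscillatory
  networks report `converged=False` rather than a limit-cycle summary.
- No stochasticity, delays, or parameter fitting; reaction parameters are
  conventions, not data-driven estimates.
- The Excel reader targets species/reactions-sheet workbooks and
  tolerates Excel's formula-escaping of `=> X` input rules, but the
  canonical interchange format is the TSV pair.
- Fold changes on near-zero references are floored and flagged, not
  suppressed; downstream consumers should check the flag.
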