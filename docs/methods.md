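# Methods

This note records the models implemented in `proppinlab`, the defaults
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the design decisions taken where the underlying
science leaves the implementation open.

## Two-step membrane-binding kinetics

The kinetic model is a linear three-state system over the fractions of
unbound (U), membrane-bound (B) and membrane-bound oligomeric (O)
protein, with accessible lipid L held constant (pseudo-first-order
approximation):

    dU/dt = -k_on·L·U + k_off·B
    dB/dt =  k_on·L·U - k_off·B - k_oli·B + k_dis·O
    dO/dt =  k_oli·B - k_dis·O

Parameters, with units and defaults used by the generators:

| parameter | meaning | units | default |
|---|---|---|---|
| `k_on` | association rate constant | mM⁻¹·s⁻¹ | 0.85 |
| `k_off` | dissociation of the binding step | s⁻¹ | 0.66 |
| `k_oli` | oligomerization of bound protein | s⁻¹ | 0 |
| `k_dis` | oligomer disassembly | s⁻¹ | 0 |
| accessible fraction | share of total vesicle lipid reachable by protein | — | 0.6 |

The default rate pair is the S448C reporter / Texas Red condition of the
reference kinetic measurements; the single-step defaults (`k_oli` =
`k_dis` = 0) make the relaxation exactly mono-exponential with rate
`k_on·L + k_off`. The apparent dissociation rate of the full scheme is
`k_off,app = k_off + k_oli + k_dis` (valid when the binding step
equilibrates faster than oligomerization).

`simulate_trace` integrates the system with LSODA at rtol 1e-10 /
atol 1e-13, which keeps it within 1e-6 relative of the matrix-exponential
closed form (the test suite checks this against an independently coded
`expm` oracle over random parameter draws) and conserves U+B+O = 1 to
1e-9. The fluorescence readout is linear in the state fractions. The
model itself does not fix how FRET weights bound versus oligomeric
protein; because acceptor-labelled lipids sense any membrane-proximal
protein, the default sets `coeff_bound = coeff_oligomer = 1` and
`coeff_unbound = 0` on a zero baseline, and all four coefficients are
configurable. Aggregation drift is phenomenological: additive slow
exponentials, not a liposome-aggregation ODE.

Noise is i.i.d. Gaussian per point. The generator default
`noise_sd = 0.01` is 1% of the full-scale bound-state signal (1 a.u.) —
a realistic signal-to-noise for averaged stopped-flow traces; real
instruments add correlated noise and mixing dead time, which are not
modelled, so recovery tests demonstrate estimator correctness, not
instrument robustness. Default problem sizes are 500 points over 10 s
per trace and 5 replicates at 5 accessible-lipid concentrations spanning
0.1–0.6 mM — the concentration span of the reference titrations; the
exact grid is not published, so a uniform grid is used.

### Multi-exponential fitting

`fit_multiexponential` minimizes the least-squares objective of
`F₀ + Σ Aᵢ·e^(−kᵢt)` (1–3 phases) via Levenberg–Marquardt (lmfit).
Initialization: rates log-spaced inside the resolvable band
[1/duration, n_points/duration], equal split of the observed signal
change as amplitude guesses, final value as F₀. Single-phase fits are
well conditioned and restart (up to 5 perturbed multistarts, internal
fixed-seed jitter) only on failure; multi-phase objectives have local
minima, so all 5 multistarts are evaluated and the lowest-RSS converged
solution wins. Rates are bounded positive (1e-12); a fit that never
converges returns `converged=False` — never silent garbage — and
downstream selection refuses it. Standard errors come from the local
curvature (covariance) at the optimum. Phases are reported sorted by
descending rate.

`select_kobs1` keeps the fastest phase by default, because in this assay
the slower phases track aggregation, which develops later than binding;
a `largest_amplitude` rule is available as an alternative. The
pseudo-first-order regression weights points by 1/SE²; if any point has
a zero or non-finite SE (noiseless fixtures) the whole fit falls back to
ordinary least squares so the weights stay comparable. Negative fitted
intercepts are flagged and returned, never clamped. Pseudo-first-order
validity is not enforced; a warning is emitted when accessible lipid is
below 100× the protein concentration. Donor-quench values are ΔF/F
(`(F_with − F_without)/F_without`); normalization to F_max would change
only the scale, not the ranking the readout is used for.

## BS3 cross-link mass accounting

Digestion is strict trypsin (`cleave after K/R unless before P`,
pyteomics' cleavage iterator with this rule) with configurable missed
cleavages and length window; peptide coordinates honour a numbering
offset so tag residues can keep non-positive site labels (plain offset
arithmetic, including 0 when the range crosses it). Peptide masses are
neutral monoisotopic sums over the standard residue table plus water;
oxidation (M, +15.994915 Da) and carbamidomethylation (C, +57.021464 Da)
are variable modifications (a fixed-Cys switch is a matter of passing the
modification for every C).

Adduct arithmetic uses the bookkeeping constants DOPE = 743.36 Da and
BS3 bridge = 140.074 Da, giving the 881.42 Da lipid-adduct delta; these
are configuration, not code, because the formula-derived monoisotopic
DOPE mass (~743.55 Da for C41H78NO8P) differs from the bookkeeping value
and either accounting can be selected. Site rules: K/S/T/Y side chains
and the protein N-terminal α-amine react; a linked lysine blocks tryptic
cleavage, so a peptide's C-terminal K is not a valid site unless it ends
the protein; S/T/Y links are assumed not to affect cleavage. Di-peptide
candidates are unordered pairs, including self-pairs (homodimer links).

Matching is precursor-level only (spectral scoring, FDR and
retention-time modelling are out of scope): observed neutral masses are
matched within a ppm tolerance via a sorted-array window, every match
within tolerance reported, sorted by |ppm| then lower candidate mass.
Classification of same-protein di-peptide links: identical or
overlapping peptides ⇒ intermolecular (one protein copy cannot supply
both); disjoint peptides ⇒ ambiguous, since intra- and intermolecular
links of a homo-oligomer are indistinguishable at precursor level.
Fragment annotation covers b/y ions with the linked partner (lipid
adduct, or intact partner chain + linker − 2 protons) carried as a fixed
delta on the linked residue.

## Native-MS deconvolution

Peak picking takes local maxima above 1% of the base peak (configurable)
with 3-point parabolic apex refinement, so assignment error is not
limited by the m/z grid. Each picked peak is assigned to the (n, z) pair
minimizing |ppm| within tolerance, proton the only adduct. Exact m/z
degeneracies (n/z ratios equal, e.g. dimer z=12 vs trimer z=18) are
resolved toward the smallest n — parsimony — and merged degenerate peaks
therefore bias the smaller order's intensity slightly upward (≈1–2
percentage points under the default charge envelope). If only even
orders are assigned, the result is flagged ambiguous because a monomer
of mass 2M would fit equally well. When the monomer mass is given as a
search window, a 2001-point grid maximizes total assigned intensity and
the mass is refined as the intensity-weighted mean of per-peak
estimates. Relative intensities are percentages of the monomer (the most
abundant species in the reference spectra); if no monomer is assigned,
the most abundant order becomes the reference and a warning is raised.

The spectrum generator places Gaussian peaks (default sd 2 Th) at exact
charge-series positions for integer charges within ±2 charge-spreads of
the envelope centre (defaults 15 ± 1.5 ⇒ z = 12–18), heights following a
Gaussian charge envelope scaled by per-order abundance, with
multiplicative peak-height noise (default 2%) and optional additive
baseline noise. It does not simulate isotope envelopes, salt adducts,
peak-width dependence on m/z, or collision-energy effects, so recovery
tests validate the assignment and summation logic, not desolvation-level
realism. The intensity-conservation invariant (assigned + unassigned =
total) is defined over picked peaks; grid points below the picking floor
are baseline.

## Synthetic cross-link datasets

`gen_xl_dataset` draws true candidates uniformly from the enumerated
lipid-adduct and di-peptide candidate sets, perturbs their masses with
Gaussian ppm error (default 3 ppm, typical high-resolution precursor
accuracy; at a 10 ppm matching tolerance a 3σ excursion is still inside
the window) and adds uniform decoy masses over the candidate mass range —
sufficient for matcher testing, with no intensity or retention realism
claimed. Random test proteins draw residues uniformly with a combined
K/R frequency floor of 8% so digests always produce peptides.

## Problem sizes and determinism

Default analysis sizes (25 traces of 500 points for a kinetic recovery,
~26 picked peaks for a native spectrum, a 300-residue protein giving a
few thousand cross-link candidates) run in seconds on one core and were
chosen as the smallest sizes at which the estimators' uncertainties are
clearly smaller than the effects being recovered. Every stochastic
routine takes an explicit seed, spawns per-trace/per-draw sub-seeds
deterministically, and records the seed in the serialized truth; reruns
are bit-identical.

## Known limitations

- The pseudo-first-order treatment keeps L constant; ligand depletion at
  low lipid excess is warned about, not modelled.
- `k_off,app = k_off + k_oli + k_dis` assumes fast pre-equilibration of
  the binding step; when oligomerization is faster than binding the
  observed rate saturates and the linear analysis under-determines the
  rates.
- Precursor-level matching cannot separate intra- from intermolecular
  links of disjoint peptides, and reports them as ambiguous rather than
  guessing.
- Native-MS intensities are summed apex heights, a good proxy only while
  peak widths are comparable across orders, as they are in the
  generator.
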