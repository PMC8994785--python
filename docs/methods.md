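# Methods note

## Model

Two radicals, each an electron spin-1/2 coupled to its own set of
nuclear spins (1/2 or 1); no inter-radical coupling (exchange and
dipolar interactions neglected). Per-radical Hamiltonian

```
H_i = Σ_j Ŝ_i · A_ij · Î_ij + ω · Ŝ_i ,   ω = −γ_e B ,
```

with anisotropic hyperfine tensors `A_ij` and the electronic Zeeman
term; nuclear Zeeman interactions are neglected (three orders of
magnitude smaller at geomagnetic field strengths). The pair starts in
the electronic singlet with maximally mixed nuclei,
`ρ(0) = P_S / Tr[P_S]`, and recombines with symmetric rates
`k_S = k_T = k` (Haberkorn), so
`ρ(t) = e^{−kt} U(t) ρ(0) U(t)†` exactly and `Tr ρ(t) = e^{−kt}`.

## Units and default parameters

Hyperfine tensors are supplied in MHz (frequency convention) and
converted to angular frequency (rad/µs) at a single site when the
Hamiltonian is built. Magnetic field in µT, time in µs, rate constant in
µs⁻¹. `γ_e = −2π · 28.024951×10⁻³ rad µs⁻¹ µT⁻¹`, giving a Larmor
frequency of 1.4012 MHz at the default `B₀ = 50 µT`. Default lifetime
`k = 1 µs⁻¹`. These defaults are the study conditions used throughout
the analysis drivers and the acceptance script.

## Singlet probability via spin correlation tensors

Because the radicals are uncoupled, the singlet probability factorizes
into per-radical 3×3 spin correlation tensors

```
R_ab^{(i)}(t) = Tr[ S_a e^{−iH_i t} S_b e^{iH_i t} ] / Z_i ,
```

normalized so `R_ab(0) = δ_ab / 2` (`Z_i` is the nuclear-space
dimension). The tensor is provably real (trace of a product of two
Hermitian operators); it is stored as a real array after an explicit
imaginary-part check (tolerance 1e-9). Then

```
p_S(t) = 1/4 + Σ_ab R_ab^{(A)} R_ab^{(B)} ,
```

and the two-electron reduced density matrix, renormalized by `e^{kt}`,
is reconstructed from the same tensors. Both identities are verified in
the test suite against dense full-Hilbert-space propagation (scipy
`expm`) to 1e-9. Rotating a radical's tensors by `R` is implemented via
the exact shortcut `SCT(R A Rᵀ, f) = R · SCT(A, Rᵀ f) · Rᵀ`.

Propagation uses exact diagonalization (`scipy.linalg.eigh`) of each
radical Hamiltonian; cost is per-radical, never the pair product space,
except in the spectral yield below where only eigenvalues/eigenvectors
are combined.

## Yields

Time-domain yield: `Y_S = k ∫₀^∞ p_S(t) e^{−kt} dt`, evaluated by
composite Simpson quadrature on a uniform grid of 8193 points over
`[0, 20/k]` (truncation error `e^{−20} ≈ 2×10⁻⁹`). The grid is odd (as
Simpson requires) and fine enough to resolve ~50 MHz hyperfine
oscillations so the time route tracks the spectral route below 1e-6;
with 4097 points the worst benchmark deviation was 1.02e-6, hence the
8193-point default.

Spectral yield: in the joint product eigenbasis,

```
Y_S = (1/M) Σ_jk |⟨j|P_S|k⟩|² k² / (k² + ω_jk²) ,
```

with `M = Z_A Z_B`. The projector matrix elements are assembled from
per-radical eigenvector transforms of the electron spin operators
(`P_S = 1/4 − Σ_a S_a^A ⊗ S_a^B`), avoiding any pair-space
diagonalization. A Monte-Carlo estimator samples index pairs `(j,k)`
uniformly with replacement and reports value ± standard error; it falls
back to the exhaustive sum when the sample budget exceeds the number of
terms. Calibration (50 seeded replicates of 10⁴ samples on the 288-dim
benchmark) shows the estimator unbiased within sampling error.

## Coherence measures

Electronic measures act on the renormalized 4×4 electronic density
matrix: relative entropy of coherence `C_r = S[ρ_diag] − S[ρ]` and l1
coherence `Σ_{n≠m}|ρ_nm|`, each in the up/down product basis and the
singlet–triplet basis; a singlet–triplet dephasing measure
`C_st = S[P_S ρ P_S + P_T ρ P_T] − S[ρ]`; and a basis-independent
measure `ln d − S[ρ]`. Entropies are in nats; eigenvalues are floored at
1e-14 before logarithms. Every instantaneous measure is folded into a
lifetime-weighted coherence yield `C̄ = k ∫ C(t) e^{−kt} dt` with the
same Simpson grid. Because measures are evaluated on the renormalized
state, the decay factor cancels and the yields match the `k = 0`
trajectory weighted explicitly — this renormalization rule is tested.

The global (electron + nuclear) coherence yield is the coherent part of
the spectral yield sum: terms with `|ω_jk|` below a degeneracy tolerance
of 1e-7 rad/µs are classified as populations and excluded. This ω-mask
is numerically identical to the convention of diagonalizing `P_S` within
degenerate eigenspaces (the Frobenius norm of each degenerate block is
invariant under the within-block rotation and the Lorentzian factor is 1
there). Its zero-field variant `C_y^G|_{B=0}` is the primary coherence
predictor.

Quadrature caveat: the relative-entropy series of physical trajectories
is not smooth (eigenvalues of the electronic state touch zero), which
degrades Simpson's convergence order; self-convergence of coherence
yields is verified at 1e-5 on physical series and at 1e-8 on an analytic
smooth integrand with a closed-form value.

## Direction and orientation sampling

Field directions come from subdivided-icosahedron grids (`10·4ⁿ + 2`
vertices, order n ≤ 7; order 5 gives 10,242 directions = 5,121 unique
axes, since `Y_S(n) = Y_S(−n)` exactly — an anti-unitary time-reversal
symmetry verified in tests). Relative radical orientations use either a
ZYZ Euler grid (3° steps give `120·120·61 = 878,400` orientations; both
β endpoints included, α and γ exclude 360°) or seeded uniform random
rotations (uniform α, γ; cos β uniform).

## Synthetic data

All benchmark systems are generated, seeded and documented in
`synthetic_data`. Random hyperfine tensors are `a·I + η·s·W` with `W`
symmetric traceless unit-norm, scale `s = 10 MHz` and anisotropy
`η = 0.5`, matching the order of magnitude of organic-radical proton
couplings. The "flavin-like" nitrogen tensors, `diag(−2.6, −2.6, 49.2)`
and `diag(−0.4, −0.4, 16.9)` MHz for the two nitrogens, are synthetic
axial stand-ins of literature magnitude for a flavin anion radical —
they are not fitted to any specific molecule. The 5-nucleus
`flavinlike_random` benchmark (two nitrogens on radical A, three random
protons on radical B, 288-dim pair space) is the workhorse of the
orientation scans.

## Problem sizes and limitations

The shipped analyses run at desk scale on one CPU: 200 random
orientations, icosphere order 1 (42 directions) for per-orientation
yield maps, 5 nuclei. The production-scale grids (3° Euler grid,
order-5 icosphere) are implemented and size-checked but the full-scale
correlation study over them — and over realistic 15–20-nucleus
cryptochrome pairs — is outside this repository's compute envelope; the
correlations reported in `results/correlations.json` are the scaled-down
analogues. Further limitations: symmetric recombination only (no
asymmetric `k_S ≠ k_T`), no exchange/dipolar coupling, no spin
relaxation beyond recombination, nuclear spins limited to 1/2 and 1, and
the discrete direction grid slightly underestimates true extrema of the
yield surface (so `Δ_S` is grid-resolution dependent; comparisons always
use a fixed grid).
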