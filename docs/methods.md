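# Methods

## Model

A polymer threading a nanopore is reduced to one dimension: the reaction
coordinate x is the contour length that has passed through the pore,
x ∈ [0, L], L = N·l_aa. The dynamics are overdamped diffusion with constant
diffusion coefficient D in a potential U(x) measured in k_BT:

    dx = −D U′(x) dt + √(2D) dW.

Arrival at x = 0 is retraction, at x = L translocation; both boundaries are
absorbing for a free polymer. A tethered polymer cannot translocate, so x = L
becomes reflecting and only the mean escape time to x = 0 is defined. The
reported observables are the zeroth and first moments of the exit-time
distributions: splitting probabilities π₀ and π_L, conditional mean
first-passage times τ₀ and τ_L, and τ = π₀τ₀ + π_Lτ_L.

Position dependence of D is deliberately out of scope; D is a single
effective constant (typically 0.1–10 µm²/s for polypeptides in biological
pores).

## Potential construction

**Charge model.** Each residue i carries an integer charge z_i (D, E: −1;
H, K, R: +1; X: −2; others 0), with +1 added at the chemical N-terminus and
−1 at the C-terminus. The sequence direction flag selects which terminus sits
at x = 0; internally the sequence is stored so residue 1 is nearest x = 0 and
the terminal corrections follow the chemistry, so flipping the direction
mirrors the charge profile about L/2.

**Native density.** Residue charges are smeared with a Gaussian of standard
deviation σ_p = L_p/2.355 (FWHM equal to the pore length), centered at
(i − ½)·l_aa. Each residue Gaussian is normalized by its *trapezoidal
integral on the working grid*, not by the analytic Gaussian norm. This makes
total-charge conservation exact on the grid for any combination of pore
width, contour length and grid spacing — including the deliberately coarse
dsDNA surrogate grid (34 nm per residue, σ_p = 1 nm), where analytic
normalization would misstate the integrated charge several-fold. Edge
truncation is handled by the same rule automatically.

**EOF correction.** σ(x) = m_EOF σ_n(x) + b_EOF. Defaults m_EOF = 0.654 and
b_EOF = −0.21 e⁻/nm correspond to published estimates for VDAC with
α-synuclein; solid-state pores can need very different slopes (the dsDNA
benchmark uses 9.35).

**Electrokinetic term.** U_E(x) = (V/V_T)·∫₀ˣ σ dx′, cumulative trapezoid on
the grid. Voltages are in mV; V_T = k_BT/e defaults to 25.693 mV (25 °C) and
is configurable, since nanopore experiments quote mV rather than k_BT.

**Free-chain entropy.** U_S = ν[ln(x/L) + ln(1 − x/L)], ν = 0.59. The
logarithmic end divergences are regularized by assigning the endpoint values
at half a grid spacing inside the domain; e^{±U_S} then remain integrable
(e^{−U_S} is an integrable x^{−ν} singularity whose trapezoid estimates
converge as O(h^{1−ν}); this slow-but-convergent behaviour is tested as
such).

**Tethered entropy.** The non-self-avoiding Gaussian-chain expression with
Kuhn length b (default 0.6 nm), tether distance l_t, shell half-width
δ = 10⁻³ nm, valid for nC = (x − L_p/2)/b > 0 and nT = (L − x − L_p/2)/b > 0.
It is evaluated entirely in logarithms (with expm1 for the difference of
Gaussian factors), shifted so its minimum over the valid range is zero (it is
only defined up to an additive constant, and all observables are invariant to
constants — tested), and clamped outside the valid range to the nearest valid
value plus 25 k_BT, an effectively reflecting wall for a region the chain
cannot reach. A tether at l_t = 0 degenerates the expression (the two
Gaussian factors coincide for any δ), so l_t is floored at δ, which realizes
the documented δ → 0 limiting behaviour at a finite value.

**Auxiliary terms.** F·x (F in k_BT/nm; a pN input converts via
1 k_BT = 4.114 pN·nm), Gaussian E_G exp(−(x−x_G)²/2σ_G²), and barrier
E_B erf((x−x_B)/σ_B√2). Opposite-sign barrier pairs build smoothed box
potentials.

All terms share one grid of spacing l_aa/2 and sum pointwise.

## First-passage quadratures

With Φ(x) = ∫₀ˣ e^U dy, Ψ(x) = ∫ₓ^L e^U dy and N = Φ(L):

    π_L = Φ(x₀)/N,  π₀ = Ψ(x₀)/N,

and the boundary-resolved time moments follow from the backward-equation
Green's function G(x, y) = Φ(min)Ψ(max)/N:

    π_L τ_L = (1/DN²)[ Ψ(x₀) ∫₀^{x₀} Φ² e^{−U} + Φ(x₀) ∫_{x₀}^L ΦΨ e^{−U} ],
    π₀ τ₀ = (1/DN²)[ Ψ(x₀) ∫₀^{x₀} ΦΨ e^{−U} + Φ(x₀) ∫_{x₀}^L Ψ² e^{−U} ].

For the tethered (reflecting-at-L) case,
τ = (1/D) ∫₀^{x₀} e^{U(y)} ∫_y^L e^{−U(z)} dz dy.

Every integrand above is positive, so all integrals are evaluated as
*logarithms of trapezoid sums* accumulated with logaddexp. Ψ is computed as
its own reverse accumulation rather than as N − Φ, so no subtraction of
near-equal large exponentials ever occurs. This makes the engine exact up to
quadrature for potential ranges far beyond double-precision e^U limits
(verified at 2000 k_BT of tilt), and renders every observable invariant to
additive shifts of U to ~10⁻¹⁰ relative (tested). The injection point is the
grid minimum of U within the user range (ties to smallest x; a degenerate
range [a, a] forces the grid point nearest a) and is treated as a delta
function, not a distribution.

On the standard l_aa/2 grid the engine reproduces the zero-potential closed
forms to better than 1% over injection fractions 0.05–0.95 (for U = 0 the
composite trapezoid errors of the paired integrands cancel, so the agreement
is at machine precision; generic smooth potentials converge at O(h²)).
Sharply varying potentials that change by many k_BT per grid cell are
resolution-limited — refine l_aa if that matters.

## Langevin oracle

An independent Euler–Maruyama simulator (`simulate_langevin`) provides
brute-force checks: single-threaded, numba-compiled, seeded and bit
reproducible. The force is the derivative of a cubic spline of U sampled on
an 8× finer grid (a piecewise-linear central-difference force measurably
biases escape times of sharp potentials at the 10⁴-trajectory precision
level). Steps use dx = −D U′ dt + √(2D dt)·ξ with RMS step 0.4 grid spacings
by default (an RMS step exceeding the grid spacing is rejected). Unobserved
intra-step boundary crossings are recovered with Brownian-bridge crossing
probabilities, removing the O(√dt) first-passage bias; reflection at L uses
the mirror rule (exact for the flat-potential cases it is tested on).
Trajectories hitting the step cap are excluded with a warning and reported.

In tests, the engine and the oracle agree within 3 standard errors for
π₀, π_L and τ on 20 seeded random potentials (≤ 3 Gaussian/barrier terms,
range rescaled to ≤ 3 k_BT within a |U| ≤ 5 k_BT cap) on a 5 nm domain with
51 grid points, D = 1 nm²/s, 10⁴ trajectories each — sizes chosen to keep
the full comparison around a minute of CPU.

## Configuration and IO

Configurations are versioned JSON (schema_version 1) with explicit
validation and documented defaults (l_aa 0.4 nm, b 0.6 nm, ν 0.59,
m_EOF 0.654, b_EOF −0.21 e⁻/nm, δ 10⁻³ nm, L_p 2.355 nm, V_T 25.693 mV);
floats serialize via repr so save → load → save is byte-identical. Results,
charge densities and potentials export as TSV at %.17g, and a results file
re-imports losslessly. Experimental escape-time tables are plain 2- or
3-column text with `#` comments; mixed column counts and non-numeric cells
are rejected with line numbers.

## Limitations

* No pKa/pH-dependent fractional charges; only the integer charge alphabet
  plus the X code.
* The tethered entropy uses a non-self-avoiding Gaussian chain; its absolute
  offset is arbitrary (observables are unaffected).
* Only the zeroth and first moments of the escape-time distributions are
  computed, not full distributions.
* The synthetic benchmark configurations exercise charge smoothing, entropy
  and the quadrature engine, but not pore-specific physics (wall
  interactions beyond the linear EOF model, position-dependent D);
  agreement there does not by itself validate predictions for a particular
  experimental pore.
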