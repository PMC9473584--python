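# Methods

## The model

`phasefus` implements an associative-polymer (sticker-and-spacer) mean-field
theory of liquid-liquid phase separation in solutions of a multivalent
protein modelled on FUS, together with a reduced-scale coarse-grained (CG)
Langevin slab simulator for the dynamics of chain exchange.

The solution is an incompressible lattice mixture: protein chains of N₁
sites (default 526), solvent chains of N₂ sites, and optionally single-site
ATP molecules. Each protein carries m₁ Tyr and m₂ Arg stickers (default
34 + 34); the remaining residues are spacers contributing only mixing
entropy. All energies are in k_BT (β = 1); free energies are dimensionless
densities per lattice site.

The reference (bond-free) free energy is Flory–Huggins:

    f_ref(φ) = (φ/N₁) ln φ + ((1−φ)/N₂) ln(1−φ)

with φ the protein volume fraction. A solvent chain length N₂ > 1 is the
standard way to encode the protein's limited aqueous solubility; N₂ = 65 is
the value that maps the dilute branch at βε₁ = −2 onto the experimental
≈5 µM saturation concentration (see *Units*).

### Association free energy

Stickers form reversible bonds: Tyr–Arg (one-to-one, energy βε₁ per bond)
and ATP–Arg (one ATP binds up to L Arg, L ∈ {1,2,3}, energy βε₂ per bond).
The association free energy is −(v/V) ln Z with the bond-counting partition
function

    Z = Σ_{k,b} C(n_p m₁, k) · C(n_ATP L, b) · C(n_p m₂, k+b) · (k+b)!
        · (v/V)^{k+b} · e^{−kβε₁ − bβε₂},

where k and b count Tyr–Arg and ATP–Arg bonds and v is the lattice site
volume (the bond-proximity volume is taken equal to v). A saddle-point
(Stirling) evaluation in (k, b) gives, with p = k/(n_p m₁) the bonded Tyr
fraction, q = b/(n_ATP L) the occupied-ATP-site fraction, and
λ = n_ATP/(n_p N₁):

    f_bind = (m₁φ/N₁)[p ln p + (1−p) ln(1−p)]
           + Lλφ [q ln q + (1−q) ln(1−q)]
           + (m₂φ/N₁) σ ln σ
           − p(m₁φ/N₁) ln[(m₂φ/N₁) e^{−1−βε₁}]
           − qLλφ      ln[(m₂φ/N₁) e^{−1−βε₂}],

with σ = 1 − p m₁/m₂ − q L λ N₁/m₂ the free-Arg fraction. Note the e^{−1}
inside the attachment logarithms: it falls out of the Stirling evaluation
of C(M₂, k+b)(k+b)! and is required for agreement with the exact
enumeration of Z, which the package ships as
`exact_association_oracle` (direct log-sum-exp summation over all (k, b),
no Stirling). The test suite checks that the saddle-point free energy
converges to the enumeration as the composition is scaled up at fixed φ
and λ (relative gap ~3×10⁻⁴ at n_p = 2 down to ~2×10⁻⁶ at n_p = 250).
Stationarity in p and q gives the shared-pool mass-action laws

    p/[(1−p)σ] = (m₂φ/N₁) e^{−βε₁},   q/[(1−q)σ] = (m₂φ/N₁) e^{−βε₂},

closed by the scalar Arg balance for σ (monotone, hence a unique root).

### Semi-grand ATP ensemble

ATP exchanges with a reservoir (a binary ATP/solvent mixture at volume
fraction φ̄) at fixed chemical potential

    μ_ATP = ln φ̄ − ln(1−φ̄)/N₂ − 1/N₂ + 1 + χ(1−2φ̄),

with χ = −1.2 the ATP–solvent Flory parameter (ATP as a hydration
mediator). The reference free energy gains ATP translational entropy, the
χ term, and −λφ·μ_ATP. The ATP loading λ at fixed φ is the root of

    ln(λφ) + 1 − (ln ψ + 1)/N₂ + χ(1−φ−2λφ) + L ln(1−q) = μ_ATP,

ψ = 1−φ−λφ, i.e. the local free-ATP chemical potential (with the binding
factor (1−q)^L) equals the reservoir value. The solver brackets this on a
geometric λ grid; if several stationary points exist the lowest-free-energy
one is kept, and if the local potential stays below the reservoir value
everywhere the optimum is taken at the packing boundary λ → (1−φ)/φ (this
occurs only at extreme reservoir levels, ≳0.1 M).

### Chemical potential and coexistence

Phase coexistence requires equal protein exchange chemical potential
μ = df/dφ and equal osmotic pressure Π = φμ − f. By the envelope theorem
μ is the partial φ-derivative at the inner (p, q, λ) optimum, and it is
evaluated analytically. One numerical subtlety: at fixed reservoir, λ
diverges like 1/φ in the dilute limit while λφ stays finite, and the naive
term-by-term envelope expression cancels catastrophically (observed ~10⁴¹
roundoff at φ = 10⁻⁶⁰). The implementation substitutes the λ-stationarity
identity analytically before evaluation, leaving

    μ = μ_pure-like(φ, p) − χλφ + L(λq) ln σ,

whose factors are all O(1); it matches central differences of f to better
than 10⁻⁸ at moderate φ.

The binodal solver is a nested bracketed search: the spinodal (sign
changes of d²f/dφ² on a geometric φ grid, refined by Brent) brackets the
unstable region; for a trial μ, μ(φ) is inverted on the dilute branch (in
ln φ, since strong ATP cross-linking can push the dilute branch tens of
decades down) and on the dense branch; the pressure mismatch is monotone
in μ (dΠ/dμ = φ), so Brent on μ closes the 2×2 system. Tie-line residuals
are at machine precision (~10⁻¹⁷), and every reported tie-line is verified
against the common-tangent construction in the tests. Scan rows are solved
independently of one another (no continuation): the solver needs no
initial guesses, and independence makes rows trivially reproducible.

Critical points / loop closures along a scan axis (βε₁ or reservoir ATP
concentration) are located by bisection on the existence of a concave
region (minimum curvature < 0, with local refinement), which coincides
with binodal closure. Dissolution is defined as loop closure, searched by
log-space bisection between a coexisting and a non-coexisting reservoir
concentration (relative tolerance 10⁻³, search capped at 0.1 M — a
distinct ATP-rich instability reappears near ~0.3 M, far outside the
regime of interest).

## Units

The lattice site volume is set by the hydration size of an amino acid,
0.65 nm, interpreted as a hydration **radius**: v = (4/3)π(0.65 nm)³ =
1.1503 nm³. Chain molarity is φ/(N₁ v N_A) and ATP molarity φ̄/(v N_A).
The spherical reading is deliberate: it is the one under which the model's
two independent concentration anchors — the 5 µM saturation concentration
at βε₁ = −2, N₂ = 65, and the ~10 mM divalent-ATP dissolution point —
both come out right, whereas a cubic site of edge 0.65 nm misses both by
exactly 4π/3.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| N₁, m₁, m₂ | 526, 34, 34 | FUS chain length and Tyr/Arg counts (`fus2022` profile) |
| N₂ | 65 | solvent chain length, fitted to the 5 µM saturation concentration |
| βε₁ | −2.0 | Tyr–Arg bond free energy (quantum-chemistry input) |
| βε₂ | per L: −12 / −8 / −6 | ATP–Arg per-bond free energy for L = 1/2/3 |
| L | 2 | ATP valence (max Arg per ATP; trivalent at most) |
| χ | −1.2 | ATP–solvent interaction |

The per-valence βε₂ defaults deserve comment. The quantum-chemistry input
behind the model gives the ATP–Arg bond as roughly four times the Tyr–Arg
strength (≈ −8 k_BT), weakening as more Arg crowd one ATP and strengthening
for an isolated Arg on the triphosphate; the exact per-valence averages are
not available as printed numbers. We therefore keep −8 for L = 2 (the
FUS-relevant case, matching the ×4 anchor) and calibrate the L = 1 and
L = 3 values once against the reported dissolution concentrations
(≈10⁻³ mM and ≈15 mM), giving −12 and −6 k_BT. The L = 3 closure is
remarkably insensitive to this choice (15.1–15.4 mM across βε₂ ∈
[−6.2, −5.8]). All values are per-run configurable.

Asymmetric-sticker profiles `asym_hiY` (m₁ = 34, m₂ = 11) and `asym_hiR`
(m₁ = 11, m₂ = 34) cover the prion-like-protein cases: neither phase
separates without ATP; with trivalent ATP both show closed-loop phase
diagrams, the Arg-rich loop being much larger because each ATP finds more
Arg to bind. Loop areas are reported in (log₁₀ c, log₁₀ ρ) coordinates
(loops span decades; the linear-coordinate area is also computed).

## Coarse-grained slab simulator

Bead-spring chains (harmonic bonds, k = 20ε₀/r_b², r_b = 4.5 nm) carry
Tyr/Arg sticker beads and phantom spacer beads; ATP is a single bead.
Tyr–Arg and ATP–Arg pairs attract via U₀(1 + cos πr/r₀), r₀ = 2 nm, with
U₀ = −20ε₀ and −75ε₀. A softened, truncated LJ (λ = 0.68, σ = 3.5 nm,
r_c = 5 nm; ε = 0.621ε₀ Tyr, 0.15ε₀ Arg) acts between beads of the *same*
type only — it is there to prevent same-type pile-up; a repulsion between
cross pairs at any combined scale would exceed the −40ε₀ contact
attraction and forbid sticker binding altogether. The repulsion is shifted
by −U_r(r_c) so the energy is continuous at the cutoff (forces unchanged;
the constant is ≈0.28ε per unit ε). ATP–ATP repulsion uses the Arg scale
(0.15ε₀, not stated in the source model). Spacers and all other cross
pairs are non-interacting.

Dynamics: BAOAB Langevin, bead mass 1, friction 1/τ, minimum-image
periodic boundaries, O(N²) pair loop (numba-compiled when available, with
a pure-python/numpy fallback of identical structure). Temperature is given
in ε₀; the default mapping is k_BT = 10ε₀, chosen so the CG contact wells
(2 k_BT Tyr–Arg, 7.5 k_BT ATP–Arg) sit on the same per-contact scale as
the mean-field energies, making sticker bonds reversible on desk-scale
runs. Trajectories are bit-reproducible per seed.

Slab protocol: chains grown as random walks inside a central slab of an
elongated periodic box, ATP spread uniformly; the density profile along
the long axis is time-averaged, the condensate is the contiguous
half-plateau region, and a chain counts as "inside" when at least half its
beads are within the bounds (1 nm hysteresis, 5-frame dwell threshold for
exchange events).

### Reduced scale: what it does and does not show

Desk-scale runs use ~15 chains of 30 beads (sticker fraction 0.2 so each
chain still carries 6+6 stickers) in a 25×25×100 nm box for ~10⁴ steps —
roughly 10⁴× smaller than the production-scale simulations the model
derives from (50 chains × 526 beads, ~10⁸ steps). At this scale the slab
stays condensed without ATP, chains visibly exchange with the dilute
phase, and a moderate ATP dose (ATP ≈ 13% of Arg) reproducibly densifies
the condensate by bridging Arg beads — the dynamic counterpart of the
dense-branch rise at low ATP.

The *reentrant* branch — exchange promoted and the condensate loosened
again at high ATP — does **not** reproduce at this scale: excess ATP
remains a dilute gas and bridging never reverses. Mechanistically, the
pairwise CG model has no Arg-saturation analogue of the mean-field
one-bond-per-Arg constraint (an ATP-bound Arg still attracts Tyr, and
nothing caps how many partners a sticker engages), so the dissolution seen
in production-scale runs must rely on collective crowding that a
15-chain slab cannot develop. A sensitivity scan over the k_BT/ε₀ mapping
(1–10), ATP:Arg ratio (0.13–6.7) and ATP–ATP repulsion scale (0.15–2.0 ε₀)
did not recover it. The corresponding ordered-medians tests are kept in
the suite as the statement of the expected full-scale behaviour and fail
honestly at reduced scale.

More generally, the CG component here establishes orderings and
invariants, not rates: the ε₀↔k_BT mapping and friction are not fixed by
the source model, so absolute exchange counts are not comparable.

## Numerical choices

- Mass-action p for the pure solution: closed-form stable quadratic root;
  residual < 10⁻¹² enforced in tests.
- σ root: Brent on [0, 1] with xtol 10⁻¹⁶; λ root: Brent on a 48-point
  geometric bracket grid.
- Curvature d²f/dφ² by central differences of the analytic μ (relative
  step 10⁻⁵); spinodal grid: 160–200 geometric points on [10⁻⁶, 0.9].
- Boundary limits (φ → 0 or 1, p → 0) return exact limit values; x ln x
  is extended continuously to 0.
- Degenerate near-critical tie-lines: when the attainable trial-μ window
  closes, the row is reported as non-coexisting rather than refined.
- The φ-to-concentration conversion uses scipy's CODATA Avogadro number.

## Limitations

- Mean-field: no composition fluctuations, no explicit electrostatics or
  salt, no temperature dependence beyond the implicit k_BT scaling, no
  three-phase equilibria, single protein species.
- The dilute branch deep inside the ATP-stabilised loop can fall to
  physically meaningless concentrations (< 10⁻²⁰ M); these tie-lines are
  mathematically exact for the model but should not be read as predictions.
- CG: reduced scale only (see above); no pressure coupling, implicit
  solvent, no production-scale (10⁸-step) runs.
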