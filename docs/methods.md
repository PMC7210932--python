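# Methods

## Scope

`smbcfd` simulates four-zone simulated-moving-bed (SMB) chromatography
with a 4th-order compact finite difference spatial discretization.  The
package has three layers: the spatial operators (`operators`), an
analytic verification problem (`benchmark`), and the process model
(`isotherms`, `column`, `smb`).  Units are fixed throughout: cm, min,
mL/min, g/L, cm²/min.

## Column model

Each column follows the transport-dispersive model with a linear
driving force (LDF) for interphase mass transfer.  For each component,

    ∂c/∂t + v ∂c/∂x = Da ∂²c/∂x² − φ k_e (q* − q),
    ∂q/∂t = k_e (q* − q),        φ = (1 − ε_b)/ε_b,

with liquid concentration c, solid loading q, interstitial velocity
v = Q/(ε_b π d²/4), apparent axial dispersion Da, bed porosity ε_b and
LDF coefficient k_e.  Boundary conditions are of Danckwerts type: at
the inlet ∂c/∂x = (v/Da)(c − c_in) with c_in the (continuously
updated) node concentration, and ∂c/∂x = 0 at the outlet.  Components
couple only through the competitive isotherm q*(c_A, c_B); two
families are built in:

* `linear_coupled` (glucose/fructose on ion-exchange resin):
  q*_A = 0.675 c_A, q*_B = 0.32 c_B + 0.000457 c_A c_B;
* `bi_langmuir` (1,1'-bi-2-naphthol enantiomers on cellulose
  triacetate): two shared competitive Langmuir sites,
  q*_i = a1_i c_i/(1 + b1_A c_A + b1_B c_B) + a2_i c_i/(1 + b2_A c_A + b2_B c_B).

Component A is the more-retained species, collected at the extract.
Small negative concentrations produced by spatial undershoot are
clipped to zero inside the isotherm evaluation only, never on the
state itself, so the integrator's error control stays honest.

## Spatial discretization

Writing the spatial operator as −Da c'' + v c' = f, the compact scheme
satisfies, at interior nodes,

    [−(Da + h²v²/(12 Da)) δ²  + v δ¹ ] c = [ (h²/12) δ² − (h²v/(12 Da)) δ¹ + 1 ] f,

with the standard 3-point central differences δ¹, δ² — a 4th-order
relation on a 3-point stencil, obtained by folding the governing
equation into the truncation terms.  With f containing −∂c/∂t this is
a mass-matrix ODE system A c'(t) = B c(t) + g(t).  The boundary rows
close the system in one of two ways, neither of which requires the
boundary data to be a differentiable function of time (an SMB inlet
concentration is only known pointwise from the running solution):

* **direct**: one-sided 2nd-order stencils substituted into the
  boundary derivative relation, with the 3rd/4th derivative expressed
  through the governing equation;
* **pseudo grid point** (default): a fictitious exterior node lets the
  boundary node use the interior compact relation; the fictitious
  value is then eliminated through the Neumann condition.  The
  elimination is singular when h·v = 3·Da at the outlet; assembly
  rejects that combination with a diagnostic.

The right-boundary load coefficient of the pseudo closure is
−(6Da/h + h v²/(2Da) − 3v)·g2: it follows from the fictitious-point
elimination and is the mirror image (x → L − x, v → −v) of the inlet
coefficient −(6Da/h + h v²/(2Da) + 3v)·g1.  Unit tests rebuild every
boundary row from the defining one-sided-stencil relations and check
the mirror identity.

A classical 2nd-order central scheme (`cds`) with identity mass matrix
and ghost-point Neumann closure is provided as a convergence baseline
and as an independent cross-check of the SMB fixed point.

The mass matrix is constant, so it is LU-factorized once per operator
and reused for every right-hand-side evaluation; the grids are small
(n ≤ 513) and the matrices are stored dense.

## Analytic benchmark

A unit Gaussian pulse centred at x = 0.2 on [0, 1] with exact solution
c(x,t) = (4t+1)^{−1/2} exp[−(x − 0.2 − vt)²/(Da(4t+1))] is advanced to
t = 1 with exact Neumann data at both ends.  Runs are parameterized by
(v, Pe) with Da = vL/Pe.  The semi-discrete system is integrated with
LSODA at rtol = atol = 1e-11, with the constant matrix A⁻¹B supplied
as the exact Jacobian; at these tolerances the spatial error (down to
~2.6e-8 at Pe = 10, h = 1/256) dominates the temporal one, which the
suite verifies by halving the tolerance.

The error is measured as max over grid points of |numeric − exact| at
t_end.  For the compact scheme the maximum sits at x = 0.5 (also
recorded separately); the central baseline's error peaks slightly
upstream of the pulse centre and its x = 0.5 value is non-monotone in
h, so convergence orders are fitted by least squares on log(max error)
vs log(h).  The fitted orders at Pe = 100 over h = 1/2⁶..1/2⁹ are
4.00 (pseudo) and 2.01 (cds).

The direct closure is mildly unstable at coarse grids when the cell
Peclet number v h/Da grows beyond ≈ 1.5 (e.g. Pe = 100 at h = 1/64);
the pseudo closure is robust there and is the default everywhere.

Neither closure is unconditionally stable once the Danckwerts inlet is
folded into the first row: for isolated (h, v, Da) combinations a
boundary mode of A⁻¹B crosses into the right half-plane (for the sugar
zone-I parameters the pseudo operator is stable at 65 and 257 points
per column but has an eigenvalue with Re ≈ +144 min⁻¹ at 129).
`ColumnOperator.spectral_abscissa()` computes the largest real part so
a grid can be certified before a long run; the test suite certifies
every packaged operating grid.

## SMB process loop

The ring of 8 columns (2/2/2/2) is held in the *port-fixed* frame:
position 0 is always the first column of zone I (desorbent → extract),
positions 4–5 are zone III (feed → raffinate).  Node balances assume
instantaneous mixing and no dead volumes: within a zone a column is
fed its upstream effluent unchanged; the desorbent node dilutes the
recycle by Q_IV/Q_I; the feed node mixes Q_II·c_out + Q_F·c_feed into
Q_III; draws change flow, not composition.  A port switch advances all
ports one column downstream, implemented as rotating the fields one
position upstream.

One switching period integrates all columns, both components, both
phases (plus four cumulative port-mass states used by the solute
audit) with RK45 at rtol = atol = 1e-8 — two orders below the CSS
threshold.  Four operators are pre-built, one per zone, and columns
pick theirs by position; effluents are recorded at 201 uniformly
spaced times and port averages use the trapezoid rule.

**Cyclic steady state.**  The run starts from clean columns
(c = q = 0).  After each period the post-shift simulated state is
compared with the state the period started from; CSS is declared when
the maximum liquid-phase difference drops below 1e-4 of the largest
feed concentration (strict inequality).  Without acceleration the
period's initial state *is* the previous post-shift simulated state,
so this is exactly the classical two-consecutive-iterations test; with
acceleration it additionally requires the extrapolated CSS guess to be
self-consistent, which is the natural stopping rule for a
predictor-based iteration.  Switch counts at the packaged operating
points: sugar 90 (θ = 0) and 49 (θ = 0.8); bi-naphthol 79 (θ = 0) and
45 (θ = 0.7).  These counts are convention-sensitive at the level of a
few switches (when the prediction memory starts, whether solid-phase
differences are included, strict vs non-strict thresholds); the
implemented convention is the one stated above, applied uniformly.

**Continuous prediction.**  With acceleration factor θ ∈ [0, 1), the
next period starts from u + θ(u − u_prev), where u is the post-shift
simulated state and u_prev the previous prediction (initialized to the
empty state); negative extrapolated values are floored at zero before
they can reach the isotherm.  The extrapolation changes the path to
CSS, not the fixed point: the θ = 0 and θ = 0.8 sugar runs agree to
within 10× the CSS tolerance.

**Performance accounting.**  After convergence one clean period is
integrated for the product record.  With time-averaged port
concentrations ⟨c⟩, purity at the extract is 100·⟨c_A⟩/(⟨c_A⟩+⟨c_B⟩)
and recovery is 100·Q_ext·⟨c_A⟩/(Q_F·c_A,feed); the raffinate
analogues use component B.

## Grid sizes and a resolution caveat

The packaged operating grids are h = L/64 (sugar, 65 points/column)
and h = L/40 (bi-naphthol, 41 points/column).  Neither is fully
resolved, and the reported performance numbers are tied to the
operating grid.  For sugar (zone Pe ≈ 344, cell Peclet ≈ 5) the
h = L/64 run gives extract/raffinate purities 88.7/98.3 % and
recoveries 98.7/85.7 %; on refinement to h = L/256 these drift by
1–2.5 points (to 90.4/97.7 and 98.1/88.1) because the pointwise CSS
profiles at the steep zone-III front carry up to ≈ 4 % of the feed
concentration at h = L/64, and purity is sensitive to the small
minor-component concentration at a port.  At matched fine resolution
(h = L/256) the compact and central discretizations agree pointwise to
0.5 % of feed — the scheme-independence check — and to a fraction of a
point in the port quantities.  The bi-naphthol zones run at Pe ≈ 1000, i.e. cell Peclet
≈ 25 at h = L/40: the B-component desorption front in zone II is then
under-resolved and spurious spreading leaks B into the extract,
depressing the computed extract purity to ≈ 82 %.  A grid study
(41 → 81 → 161 points) shows the performance numbers converging to
extract/raffinate purities ≈ 93.4/96.8 % and recoveries
≈ 96.7/93.2 %; the resolved values, not the h = L/40 values, are the
physically meaningful performance of this operating point, and the
suite asserts them on the 161-point grid while keeping the stated
41-point grid for the switch-count studies.

## Solute conservation audit

Each period logs a mass-balance residual: (holdup change, by Simpson
quadrature of both phases over all columns) minus (feed input − port
withdrawals, the latter integrated exactly as ODE states).  The
collocation scheme is not discretely conservative, so this residual is
limited by the O(h⁴) flux-consistency error of the discretization, not
by the integrator: at the sugar operating grid it settles near 3e-6 of
the feed mass per period at CSS and is insensitive to the integrator
tolerance.  The audit therefore checks a spatial-accuracy bound
(< 1e-5 of feed at CSS) rather than an integrator-tolerance bound.

## What the simulator does and does not model

No extra-column dead volumes, pump or valve dynamics, temperature
effects, pore-diffusion/general-rate kinetics, or isotherm fitting.
Agreement of the packaged case studies with published plant data
therefore validates the transport-dispersive LDF description at these
operating points, not those neglected effects.  Nonuniform grids,
2-D/3-D operators, periodic boundaries and formal von Neumann
stability analysis are out of scope; stability at the packaged
operating points is established empirically by the bounded-solution
and scheme-agreement tests.
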