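"""Unit and property tests for the compact spatial operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smbcfd.operators import (
    BoundaryMethod,
    Coupling,
    GridSpec,
    TransportParams,
    _direct_left,
    _direct_right,
    _interior_residual,
    _pseudo_left,
    _pseudo_right,
    assemble_operator,
    one_sided_stencil,
    truncation_order,
)

METHODS = [BoundaryMethod.DIRECT, BoundaryMethod.PSEUDO, BoundaryMethod.CDS]
COUPLINGS = [Coupling.SMB_INLET, Coupling.EXPLICIT_NEUMANN]

# strategy covering the physical regimes of the case studies while keeping
# the pseudo closure away from its h*v = 3*Da singularity
params_st = st.tuples(
    st.floats(0.1, 30.0),  # v
    st.floats(0.05, 2.0),  # Da
    st.integers(9, 65),  # n
    st.floats(0.5, 60.0),  # L
).filter(lambda t: abs(t[3] / (t[2] - 1) * t[0] - 3 * t[1]) > 1e-3)


class TestGridAndParams:
    def test_grid_step_and_points(self):
        g = GridSpec(n=65, L=52.07)
        assert g.h == pytest.approx(52.07 / 64)
        assert g.x[0] == 0.0 and g.x[-1] == pytest.approx(52.07)
        assert np.allclose(np.diff(g.x), g.h)

    @pytest.mark.parametrize("n,L", [(4, 1.0), (2, 1.0), (10, -1.0)])
    def test_invalid_grid_rejected(self, n, L):
        with pytest.raises(ValueError):
            GridSpec(n=n, L=L)

    @pytest.mark.parametrize("v,Da", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_degenerate_transport_rejected(self, v, Da):
        with pytest.raises(ValueError):
            TransportParams(v=v, Da=Da)

    def test_peclet(self):
        assert TransportParams(v=0.3, Da=0.003).peclet(1.0) == pytest.approx(100.0)


class TestOneSidedStencils:
    @pytest.mark.parametrize(
        "key,weights,offsets,denom",
        [
            (("forward", 2, 1), (-3, 4, -1), (0, 1, 2), 2.0),
            (("backward", 2, 2), (-1, 4, -5, 2), (-3, -2, -1, 0), 1.0),
            (("forward", 1, 1), (-1, 1), (0, 1), 1.0),
            (("backward", 2, 1), (1, -4, 3), (-2, -1, 0), 2.0),
        ],
    )
    def test_tabulated_weights(self, key, weights, offsets, denom):
        h = 0.37
        power = key[2]
        w, off = one_sided_stencil(*key, h)
        assert np.allclose(w, np.array(weights) / (denom * h**power))
        assert list(off) == list(offsets)

    @pytest.mark.parametrize("kind", ["forward", "backward"])
    @pytest.mark.parametrize("accuracy,derivative", [(1, 1), (2, 1), (1, 2), (2, 2)])
    def test_stencils_differentiate_polynomials_exactly(self, kind, accuracy, derivative):
        # a stencil of order j for the i-th derivative is exact on degree i+j-1
        h = 0.15
        w, off = one_sided_stencil(kind, accuracy, derivative, h)
        x0 = 2.0
        deg = derivative + accuracy - 1
        coeffs = np.array([0.7, -1.3, 0.4, 2.1])[: deg + 1]
        poly = np.polynomial.Polynomial(coeffs)
        vals = poly(x0 + off * h)
        expected = poly.deriv(derivative)(x0)
        assert np.dot(w, vals) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError):
            one_sided_stencil("forward", 3, 1, 0.1)
        with pytest.raises(ValueError):
            one_sided_stencil("central", 2, 1, 0.1)
        with pytest.raises(ValueError):
            one_sided_stencil("forward", 2, 1, 0.0)


class TestAssembly:
    def setup_method(self):
        self.grid = GridSpec(n=9, L=1.0)
        self.params = TransportParams(v=1.7, Da=0.4)

    def test_interior_rows_match_printed_band(self):
        h, v, Da = self.grid.h, self.params.v, self.params.Da
        for method in (BoundaryMethod.DIRECT, BoundaryMethod.PSEUDO):
            op = assemble_operator(self.grid, self.params, method, Coupling.SMB_INLET)
            a_row = [1 / 12 + h * v / (24 * Da), 5 / 6, 1 / 12 - h * v / (24 * Da)]
            b_row = [
                Da / h**2 + v / (2 * h) + v**2 / (12 * Da),
                -2 * Da / h**2 - v**2 / (6 * Da),
                Da / h**2 - v / (2 * h) + v**2 / (12 * Da),
            ]
            for i in range(1, self.grid.n - 1):
                assert np.allclose(op.A[i, i - 1 : i + 2], a_row)
                assert np.allclose(op.B[i, i - 1 : i + 2], b_row)
                assert op.B[i].sum() == pytest.approx(0.0, abs=1e-9)

    def test_direct_first_mass_row(self):
        h, v, Da = self.grid.h, self.params.v, self.params.Da
        op = assemble_operator(self.grid, self.params, "direct", "smb_inlet")
        expected = [-1 / 4 - h * v / (4 * Da), 1 / 6 + h * v / (4 * Da), 1 / 12]
        assert np.allclose(op.A[0, :3], expected)
        assert np.all(op.A[0, 3:] == 0.0)

    def test_pseudo_inlet_load_coefficient(self):
        h, v, Da = self.grid.h, self.params.v, self.params.Da
        op = assemble_operator(self.grid, self.params, "pseudo", "smb_inlet")
        ((row, coef),) = op.load_coefs
        assert row == 0
        assert coef == pytest.approx(6 * v / h + h * v**3 / (2 * Da**2) + 3 * v**2 / Da)

    def test_direct_neumann_load_pattern(self):
        h, Da = self.grid.h, self.params.Da
        op = assemble_operator(self.grid, self.params, "direct", "explicit_neumann")
        g = op.load((2.0, -3.0))
        expected = np.zeros(self.grid.n)
        expected[0] = Da * 2.0 / h
        expected[-1] = Da * -3.0 / h
        assert np.allclose(g, expected)

    def test_zero_inlet_gives_zero_load(self):
        for method in METHODS:
            op = assemble_operator(self.grid, self.params, method, "smb_inlet")
            assert np.all(op.load(0.0) == 0.0)

    def test_cds_diffusion_only_rows(self):
        # with the advection terms analytically cancelled, the interior row
        # reduces to the plain second-difference; checked via v -> small
        grid = GridSpec(n=9, L=1.0)
        params = TransportParams(v=1e-12, Da=0.4)
        op = assemble_operator(grid, params, "direct", "explicit_neumann")
        h, Da = grid.h, params.Da
        assert np.allclose(op.A[4, 3:6], [1 / 12, 5 / 6, 1 / 12])
        assert np.allclose(op.B[4, 3:6], np.array([1.0, -2.0, 1.0]) * Da / h**2)

    def test_pseudo_singularity_rejected(self):
        # h*v = 3*Da on the nose
        grid = GridSpec(n=11, L=1.0)
        params = TransportParams(v=3.0 * 0.5 / grid.h, Da=0.5)
        with pytest.raises(ValueError, match="6\\*Da\\*h"):
            assemble_operator(grid, params, "pseudo", "smb_inlet")

    def test_band_structure(self):
        op = assemble_operator(self.grid, self.params, "direct", "smb_inlet")
        n = self.grid.n
        assert np.all(op.B[0, 4:] == 0.0) and np.all(op.B[-1, : n - 4] == 0.0)
        for i in range(1, n - 1):
            mask = np.ones(n, bool)
            mask[i - 1 : i + 2] = False
            assert np.all(op.B[i, mask] == 0.0)
            assert np.all(op.A[i, mask] == 0.0)

    def test_mass_matrix_nonsingular_in_paper_regimes(self):
        # zone operators of both case studies plus the benchmark grids
        cases = [
            (GridSpec(65, 52.07), TransportParams(7.30, 1.105)),
            (GridSpec(41, 10.5), TransportParams(26.76, 0.281)),
            (GridSpec(257, 1.0), TransportParams(0.3, 0.03)),
            (GridSpec(257, 1.0), TransportParams(0.3, 0.0003)),
        ]
        for grid, params in cases:
            for method in (BoundaryMethod.DIRECT, BoundaryMethod.PSEUDO):
                op = assemble_operator(grid, params, method, Coupling.SMB_INLET)
                assert np.linalg.cond(op.A) < 1e8


class TestTranscriptionInvariants:
    """Row-sum / annihilation identities that hold for all admissible h, v, Da."""

    @settings(max_examples=60, deadline=None)
    @given(params_st)
    def test_uniform_state_annihilation_smb_inlet(self, tup):
        v, Da, n, L = tup
        grid = GridSpec(n=n, L=L)
        params = TransportParams(v=v, Da=Da)
        kappa = 3.7
        for method in METHODS:
            op = assemble_operator(grid, params, method, Coupling.SMB_INLET)
            r = op.B @ np.full(n, kappa) + op.load(kappa)
            # inlet row annihilates a uniform state fed at the same level;
            # outlet row annihilates any uniform state
            assert r[0] == pytest.approx(0.0, abs=1e-7 * kappa * abs(op.B[0, 0]))
            assert r[-1] == pytest.approx(0.0, abs=1e-7 * kappa * abs(op.B[-1, -1]))

    @settings(max_examples=60, deadline=None)
    @given(params_st)
    def test_uniform_state_steady_explicit_neumann(self, tup):
        v, Da, n, L = tup
        grid = GridSpec(n=n, L=L)
        params = TransportParams(v=v, Da=Da)
        for method in METHODS:
            op = assemble_operator(grid, params, method, Coupling.EXPLICIT_NEUMANN)
            r = op.B @ np.ones(n)
            scale = np.abs(op.B).max()
            assert np.max(np.abs(r)) < 1e-9 * scale

    def test_mirror_symmetry_of_boundary_rows(self):
        # x -> L - x with v -> -v maps the left closure onto the right one:
        # rows negate and reverse, load coefficients map directly
        h, v, Da = 0.11, 2.3, 0.7
        for left, right in ((_direct_left, _direct_right), (_pseudo_left, _pseudo_right)):
            a_l, b_l, g_l = left(h, -v, Da)
            a_r, b_r, g_r = right(h, v, Da)
            assert np.allclose(a_r, -a_l[::-1])
            assert np.allclose(b_r, -b_l[::-1])
            assert g_r == pytest.approx(g_l)

    def test_direct_left_row_from_one_sided_stencils(self):
        # rebuild the direct left-boundary row from its defining relation:
        # (D21 + h^2 v/(3Da) D22 + h^3 v^2/(4Da^2) D12) c
        #   = (h^2/Da)(1/3 D21 + hv/(4Da) D11 + h/4 D12) f + g1,  f = -c'
        h, v, Da = 0.21, 1.4, 0.55
        s = Da / h  # row scaling used by the printed matrices
        d21, o21 = one_sided_stencil("forward", 2, 1, h)
        d22, o22 = one_sided_stencil("forward", 2, 2, h)
        d12, o12 = one_sided_stencil("forward", 1, 2, h)
        d11, o11 = one_sided_stencil("forward", 1, 1, h)

        lhs = np.zeros(4)
        for w, off in ((d21, o21), (h**2 * v / (3 * Da) * d22, o22),
                       (h**3 * v**2 / (4 * Da**2) * d12, o12)):
            np.add.at(lhs, off, w)
        rhs = np.zeros(4)
        for w, off in ((d21 / 3, o21), (h * v / (4 * Da) * d11, o11), (h / 4 * d12, o12)):
            np.add.at(rhs, off, h**2 / Da * w)

        a_l, b_l, g_l = _direct_left(h, v, Da)
        assert np.allclose(s * rhs[:3], a_l)  # A row (coefficient of c')
        assert np.allclose(-s * lhs, b_l)  # B row
        assert g_l == pytest.approx(s)

    def test_pseudo_left_row_from_elimination_formula(self):
        # the pseudo left row is the fictitious-point elimination result
        # scaled by (3Da + hv)/Da; rebuild it from that formula
        h, v, Da = 0.21, 1.4, 0.55
        s = (3 * Da + h * v) / Da
        K = (h**2 * v**2 - 12 * Da**2) / (6 * Da * h + 2 * h**2 * v)
        M = (12 * Da**2 + h**2 * v**2 + 6 * Da * h * v) / (6 * Da * h + 2 * h**2 * v)
        d11, o11 = one_sided_stencil("forward", 1, 1, h)
        d21, o21 = one_sided_stencil("forward", 2, 1, h)
        d22, o22 = one_sided_stencil("forward", 2, 2, h)

        lhs = np.zeros(4)
        np.add.at(lhs, o11, K * d11)
        rhs = np.zeros(4)
        rhs[0] += 1.0
        np.add.at(rhs, o22, h**2 / 12 * d22)
        np.add.at(rhs, o21, (4 * Da * h + h**2 * v) / (12 * Da + 4 * h * v) * d21)

        a_l, b_l, g_l = _pseudo_left(h, v, Da)
        assert np.allclose(s * rhs, a_l)
        assert np.allclose((-s * lhs)[:2], b_l)
        assert np.all(np.abs((s * lhs)[2:]) < 1e-12)
        assert g_l == pytest.approx(-s * M)


class TestTruncationOrder:
    def test_cubic_polynomials_exact(self):
        params = TransportParams(v=1.3, Da=0.6)
        poly = np.polynomial.Polynomial([0.2, -1.0, 0.8, 0.5])
        d1, d2 = poly.deriv(1), poly.deriv(2)

        def f(x):
            return -params.Da * d2(x) + params.v * d1(x)

        res = _interior_residual(GridSpec(33, 1.0), params, BoundaryMethod.PSEUDO, poly, f)
        assert res < 1e-11

    def test_exp_field_orders(self):
        params = TransportParams(v=1.0, Da=0.5)

        def c(x):
            return np.exp(x)

        def f(x):
            return (-params.Da + params.v) * np.exp(x)

        slope_cfds = truncation_order(params, "pseudo", c, f)
        slope_cds = truncation_order(params, "cds", c, f)
        assert slope_cfds == pytest.approx(4.0, abs=0.2)
        assert slope_cfds >= 3.8
        assert slope_cds == pytest.approx(2.0, abs=0.1)

    def test_too_few_refinements_rejected(self):
        params = TransportParams(v=1.0, Da=0.5)
        with pytest.raises(ValueError):
            truncation_order(params, "pseudo", np.exp, np.exp, n_values=(33, 65))


class TestLoadsAndDump:
    def test_wrong_boundary_data_shape_rejected(self):
        op = assemble_operator(GridSpec(9, 1.0), TransportParams(1.0, 0.5), "direct", "smb_inlet")
        with pytest.raises(ValueError):
            op.load((1.0, 2.0))
        op2 = assemble_operator(
            GridSpec(9, 1.0), TransportParams(1.0, 0.5), "direct", "explicit_neumann"
        )
        with pytest.raises(ValueError):
            op2.load(1.0)

    def test_dump_roundtrip(self, tmp_path):
        op = assemble_operator(GridSpec(7, 1.0), TransportParams(1.0, 0.5), "pseudo", "smb_inlet")
        path = tmp_path / "op.tsv"
        op.dump(path)
        rows = path.read_text().strip().split("\n")
        assert rows[0] == "matrix\trow\tcol\tvalue"
        entries = [r.split("\t") for r in rows[1:]]
        a_entries = {(int(r[1]), int(r[2])): float(r[3]) for r in entries if r[0] == "A"}
        assert a_entries[(0, 0)] == pytest.approx(op.A[0, 0])
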