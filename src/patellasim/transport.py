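"""Scalar transport operators on the quad mesh: diffusion and chemotaxis.

Galerkin bilinear-quad discretization with a lumped mass matrix.  Diffusion
is integrated with implicit Euler (unconditionally stable, positivity
preserving on the near-rectangular knee meshes); the chemotactic flux is
treated explicitly, so cell-density steps obey a CFL-style bound checked at
every call.  With no Dirichlet sources both operators have zero column
sums, which makes the total lumped mass an exact discrete invariant — the
basis of the conservation tests.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import QuadMesh, _GP, _shape_derivatives

__all__ = ["TransportSolver", "StabilityError", "PositivityError"]


class StabilityError(RuntimeError):
    """Time step violates the explicit-transport stability bound."""


class PositivityError(RuntimeError):
    """A field went negative beyond the clamping tolerance."""


def _shape_values(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array(
        [
            (1 - xi) * (1 - eta),
            (1 + xi) * (1 - eta),
            (1 + xi) * (1 + eta),
            (1 - xi) * (1 + eta),
        ]
    )


class TransportSolver:
    """Precomputed FE quadrature data and operator assembly for one mesh."""

    #: negative nodal values above this (absolute) are clamped to zero
    CLAMP_TOL = 1e-11
    #: negative values beyond this fraction of the field maximum raise
    #: :class:`PositivityError`; smaller undershoots (bilinear quads on the
    #: curved wrap are not exactly monotone near Dirichlet jumps) clamp to 0
    NEGATIVE_TOL = 1e-4

    def __init__(self, mesh: QuadMesh):
        self.mesh = mesh
        E = mesh.n_elements
        G = 4
        self.conn = mesh.elements
        self.dndx = np.zeros((E, G, 2, 4))
        self.w = np.zeros((E, G))
        self.N = np.zeros((G, 4))
        g = 0
        for xi in _GP:
            for eta in _GP:
                self.N[g] = _shape_values(xi, eta)
                dN = _shape_derivatives(xi, eta)
                for e in range(E):
                    coords = mesh.nodes[self.conn[e]]
                    J = dN @ coords
                    self.w[e, g] = np.linalg.det(J)
                    self.dndx[e, g] = np.linalg.solve(J, dN)
                g += 1
        # lumped mass: row-sum of the consistent mass matrix
        self.mass = np.zeros(mesh.n_nodes)
        me = np.einsum("eg,gi->ei", self.w, self.N)
        np.add.at(self.mass, self.conn, me)
        # unscaled per-element stiffness blocks
        self.ke_unit = np.einsum("egki,egkj,eg->eij", self.dndx, self.dndx, self.w)
        self._rows = np.repeat(self.conn, 4, axis=1).ravel()
        self._cols = np.tile(self.conn, (1, 4)).ravel()
        self._factor_cache: dict = {}
        self.min_edge = self._min_edge_length()

    def _min_edge_length(self) -> float:
        p = self.mesh.nodes[self.conn]
        d = np.linalg.norm(p - np.roll(p, -1, axis=1), axis=2)
        return float(d.min())

    # -- operators ----------------------------------------------------------

    def stiffness(self, diffusivity: np.ndarray | float) -> sp.csr_matrix:
        """K with per-element diffusivity; zero row and column sums."""
        d = np.broadcast_to(np.asarray(diffusivity, dtype=float), (self.mesh.n_elements,))
        data = (self.ke_unit * d[:, None, None]).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsr()

    def chemo_matrix(
        self,
        attractant: np.ndarray,
        chi: np.ndarray | float,
        upwind: bool = True,
    ) -> sp.csr_matrix:
        """Chemotactic transfer operator C with (C b)_i the discrete flux
        of b up the attractant gradient; zero column sums (conservative).

        With ``upwind`` (default) the Galerkin operator is stabilized by
        discrete upwinding: symmetric artificial diffusion
        d_ij = max(0, -c_ij, -c_ji) is added so all off-diagonal entries
        become nonnegative, which keeps cell densities positive at sharp
        fronts without destroying conservation."""
        c = np.broadcast_to(np.asarray(chi, dtype=float), (self.mesh.n_elements,))
        s_el = attractant[self.conn]  # (E, 4)
        grad_s = np.einsum("egki,ei->egk", self.dndx, s_el)  # (E, G, 2)
        adv = np.einsum("egki,egk->egi", self.dndx, grad_s)  # grad(phi_i).grad(s)
        ce = np.einsum("eg,egi,gj->eij", self.w, adv, self.N) * c[:, None, None]
        n = self.mesh.n_nodes
        C = sp.coo_matrix(
            (ce.ravel(), (self._rows, self._cols)), shape=(n, n)
        ).tocsr()
        if not upwind:
            return C
        # symmetric artificial diffusion with zero row/column sums
        neg = C.minimum(C.T).minimum(0.0)  # min(0, c_ij, c_ji), elementwise
        D = (-neg).tolil()
        D.setdiag(0.0)
        D = D.tocsr()
        D = D - sp.diags(np.asarray(D.sum(axis=1)).ravel())
        return (C + D).tocsr()

    def max_step(self, operator: sp.csr_matrix) -> float:
        """Largest dt keeping the explicit update b + dt M^-1 L b
        nonnegative for nonnegative b (positivity/CFL bound)."""
        diag = operator.diagonal()
        rate = np.maximum(-diag, 0.0) / self.mass
        peak = rate.max()
        return np.inf if peak == 0.0 else float(1.0 / peak)

    # -- time stepping ------------------------------------------------------

    def _system(self, dt: float, diffusivity, dirichlet_nodes) -> sp.csc_matrix:
        A = sp.diags(self.mass) + dt * self.stiffness(diffusivity)
        if dirichlet_nodes is not None and len(dirichlet_nodes):
            A = A.tolil()
            A[dirichlet_nodes, :] = 0.0
            A[dirichlet_nodes, dirichlet_nodes] = 1.0
        return A.tocsc()

    def factorized_system(self, key, dt, diffusivity, dirichlet_nodes):
        """LU factorization cached under ``key`` (caller invalidates by
        changing the key when diffusivities or source sets change)."""
        if key not in self._factor_cache:
            self._factor_cache[key] = spla.splu(
                self._system(dt, diffusivity, dirichlet_nodes)
            )
        return self._factor_cache[key]

    def clear_cache(self) -> None:
        self._factor_cache.clear()

    def implicit_step(
        self,
        values: np.ndarray,
        dt: float,
        diffusivity,
        dirichlet_nodes: np.ndarray | None = None,
        dirichlet_values: np.ndarray | float | None = None,
        explicit_rhs: np.ndarray | None = None,
        cache_key=None,
    ) -> np.ndarray:
        """One implicit-Euler diffusion step, optionally with an explicit
        source/advection term (units of d(mass)/dt) and Dirichlet nodes."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        rhs = self.mass * values
        if explicit_rhs is not None:
            rhs = rhs + dt * explicit_rhs
        if dirichlet_nodes is not None and len(dirichlet_nodes):
            rhs[dirichlet_nodes] = dirichlet_values
        if cache_key is not None:
            lu = self.factorized_system(cache_key, dt, diffusivity, dirichlet_nodes)
            out = lu.solve(rhs)
        else:
            A = self._system(dt, diffusivity, dirichlet_nodes)
            out = spla.spsolve(A, rhs)
        return self.clamp(out)

    def clamp(self, values: np.ndarray) -> np.ndarray:
        worst = values.min()
        scale = max(float(values.max()), 1.0)
        if worst < -self.NEGATIVE_TOL * scale:
            raise PositivityError(
                f"field reached {worst:.3e} < -{self.NEGATIVE_TOL * scale:.1e}"
            )
        if worst < 0.0:
            values = np.where(values < 0.0, 0.0, values)
        return values

    def check_cfl(self, dt: float, dt_max: float) -> None:
        if dt > dt_max:
            raise StabilityError(
                f"dt={dt:g} exceeds the explicit-transport positivity bound "
                f"{dt_max:g}; reduce the step"
            )

    def total_mass(self, values: np.ndarray) -> float:
        return float(self.mass @ values)

    def element_average(self, values: np.ndarray) -> np.ndarray:
        """Per-element mean of the four nodal values."""
        return values[self.conn].mean(axis=1)
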