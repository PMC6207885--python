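"""Vectorized numerics for the conductance-based microcircuit network.

Everything here is batched over a leading axis so that the finite-difference
sensitivities needed by the variational scheme can be evaluated as one stacked
LAPACK call instead of a Python loop.  States are ordered
``(source, population, state)`` with populations (SS, SP, II, DP) and states
(V, g_AMPA, g_GABAA, g_NMDA); one source contributes 16 states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microcircuit import (
    C_MEMBRANE,
    G_LEAK,
    PRIOR_TAU_MS,
    REVERSAL,
    V_LEAK,
    V_THRESH,
    FiringParams,
    MgBlockParams,
    SourceParams,
    PopulationKind as P,
    ReceptorKind as R,
)
from .network import NetworkModel, FORWARD_TARGETS, BACKWARD_TARGETS
from .params import ParamSpec

__all__ = ["ModelConfig", "CMCEngine", "StabilityError"]

_E = np.array([REVERSAL[R.AMPA], REVERSAL[R.GABAA], REVERSAL[R.NMDA]])


class StabilityError(RuntimeError):
    """Raised when the delay-adjusted Jacobian has eigenvalues in Re >= 0."""

    def __init__(self, max_real: float):
        super().__init__(
            f"linearization unstable: max eigenvalue real part {max_real:.4g} >= 0"
        )
        self.max_real = max_real


#: Designed stationary potentials (mV) of (SS, SP, II, DP) at prior means,
#: used to balance the inhibitory weights; chosen so that every population
#: sits on an informative part of its firing sigmoid.
_V_DESIGN = np.array([-52.0, -46.0, -40.0, -46.0])
_BACKGROUND0 = 24.0
_FIRING_VARIANCE0 = 16.0  # mV^2 -> sigmoid slope 4 mV


def _intrinsic_bases() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline intrinsic coupling templates (target population x source
    population), before per-source log-scale gains are applied.

    AMPA wiring: stellates drive superficial pyramidals; superficial
    pyramidals drive interneurons and deep pyramidals; stellates and deep
    pyramidals weakly drive interneurons.  NMDA wiring: a strong slow
    excitatory drive onto superficial/deep pyramidals (from stellates /
    superficial pyramidals) and onto interneurons (from superficial
    pyramidals), so that tonic NMDA current sets the operating point of
    both excitatory cells and interneurons.  GABA_A weights (interneurons
    onto every population) are solved analytically so that the designed
    stationary potentials are an exact current balance of the isolated
    source at prior means.
    """
    exc = np.zeros((4, 4))
    exc[P.SP, P.SS] = 2.0
    exc[P.II, P.SS] = 0.5
    exc[P.II, P.SP] = 3.0
    exc[P.II, P.DP] = 0.25
    exc[P.DP, P.SP] = 2.0
    nmda = np.zeros((4, 4))
    nmda[P.SP, P.SS] = 3.0
    nmda[P.DP, P.SP] = 1.5
    nmda[P.II, P.SP] = 4.0
    nmda[P.II, P.SS] = 4.0 / 3.0
    # solve GABA_A weights from the stationarity condition at the design point
    V = _V_DESIGN
    s = np.sqrt(_FIRING_VARIANCE0)
    F = 0.5 * (1.0 + np.tanh(0.5 * (V - V_THRESH) / s))
    m = 1.5 / (1.0 + 0.33 * np.exp(-0.06 * V))
    inh = np.zeros((4, 4))
    for p in range(4):
        gA = float(exc[p] @ F)
        gN = float(nmda[p] @ F)
        balance = (
            (V_LEAK - V[p]) + _BACKGROUND0
            + gA * (_E[R.AMPA] - V[p])
            + gN * m[p] * (_E[R.NMDA] - V[p])
        )
        inh[p, P.II] = balance / (F[P.II] * (V[p] - _E[R.GABAA]))
    return exc, inh, nmda


@dataclass
class ModelConfig:
    """Fixed structural constants of the generative model (not fitted)."""

    inter_source_delay_ms: float = 8.0
    lateral_weight: float = 0.25       # fixed SP->SP interhemispheric gain
    forward_base: tuple = (0.5, 0.25)  # onto (SS, DP) of the target
    backward_base: tuple = (0.25, 0.25)  # onto (SP, II) of the target
    sp_to_ss_base: float = 1.0         # NMDA weight of the variant connection
    exc_base: np.ndarray = field(default_factory=lambda: _intrinsic_bases()[0])
    inh_base: np.ndarray = field(default_factory=lambda: _intrinsic_bases()[1])
    nmda_base: np.ndarray = field(default_factory=lambda: _intrinsic_bases()[2])
    background0: float = _BACKGROUND0
    delay0_ms: float = 3.0
    firing_variance0: float = _FIRING_VARIANCE0
    capacitance: float = C_MEMBRANE    # membrane capacitance (tau_m = C/gL)
    mg0: MgBlockParams = field(default_factory=MgBlockParams)


class CMCEngine:
    """Batched evaluation of the network vector field and its linearization."""

    def __init__(self, net: NetworkModel, config: ModelConfig | None = None):
        self.net = net
        self.config = config or ModelConfig()
        self.spec: ParamSpec = net.param_spec()
        self.S = net.n_sources
        self.n = net.n_states
        sp = self.spec
        S = self.S
        # index slices into the neuronal lambda vector
        self._ix_kappa = np.stack(
            [sp.indices(f"kappa_{rec}.") for rec in ("AMPA", "GABAA", "NMDA")],
            axis=1,
        )  # (S, 3)
        self._ix_gain = np.stack(
            [sp.indices(f"{g}.") for g in
             ("g_AMPA", "g_GABAA", "g_NMDA_exc", "g_NMDA_inh")],
            axis=1,
        )  # (S, 4)
        self._ix_fwd = sp.indices("ext_forward.")
        self._ix_bwd = sp.indices("ext_backward.")
        self._ix_var = sp.index("firing_variance")
        self._ix_bg = sp.index("background")
        self._ix_mg = np.array(
            [sp.index("mg_alpha"), sp.index("mg_beta"), sp.index("mg_gamma")]
        )
        self._ix_delay = sp.indices("delay.")
        assert self._ix_kappa.shape == (S, 3)
        assert self._ix_delay.size == S
        self.C = self.config.capacitance
        self._kappa0 = 1000.0 / np.array(
            [PRIOR_TAU_MS[R.AMPA], PRIOR_TAU_MS[R.GABAA], PRIOR_TAU_MS[R.NMDA]]
        )  # s^-1

    # ------------------------------------------------------------------ #
    # parameter materialization
    # ------------------------------------------------------------------ #
    def materialize(self, lam: np.ndarray) -> dict:
        """Natural-unit parameter arrays from a batch of log-scale vectors.

        ``lam`` is (B, n_params); every returned array has leading axis B.
        """
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        c = self.config
        nat = {
            "kappa": self._kappa0 * np.exp(lam[:, self._ix_kappa]),  # (B,S,3)
            "gain": np.exp(lam[:, self._ix_gain]),                   # (B,S,4)
            "w_fwd": np.exp(lam[:, self._ix_fwd]),                   # (B,Ef)
            "w_bwd": np.exp(lam[:, self._ix_bwd]),                   # (B,Eb)
            "slope": np.sqrt(c.firing_variance0) * np.exp(0.5 * lam[:, self._ix_var]),
            "bg": c.background0 * np.exp(lam[:, self._ix_bg]),
            "mg_alpha": c.mg0.alpha * np.exp(lam[:, self._ix_mg[0]]),
            "mg_beta": c.mg0.beta * np.exp(lam[:, self._ix_mg[1]]),
            "mg_gamma": c.mg0.gamma * np.exp(lam[:, self._ix_mg[2]]),
            "delay_s": c.delay0_ms * 1e-3 * np.exp(lam[:, self._ix_delay]),  # (B,S)
        }
        nat["W"] = self._connection_tensor(nat)
        return nat

    def _connection_tensor(self, nat: dict) -> np.ndarray:
        """Full coupling tensor W[b, s_t, p_t, r, s_s, p_s].

        ``drive[s,p,r] = sum_{s',q} W[s,p,r,s',q] * F[s',q]`` where F is the
        presynaptic firing of population q in source s'.
        """
        c = self.config
        net = self.net
        B = nat["gain"].shape[0]
        S = self.S
        W = np.zeros((B, S, 4, 3, S, 4))
        gain = nat["gain"]  # (B, S, 4): AMPA, GABAA, NMDA_exc, NMDA_inh
        # intrinsic couplings
        for s in range(S):
            W[:, s, :, R.AMPA, s, :] = c.exc_base * gain[:, s, 0, None, None]
            W[:, s, :, R.GABAA, s, :] = c.inh_base * gain[:, s, 1, None, None]
            nm = np.broadcast_to(c.nmda_base, (B, 4, 4)).copy()
            if net.include_sp_to_ss:
                nm[:, P.SS, P.SP] = c.sp_to_ss_base
            nmda_gain = np.where(
                np.arange(4)[None, :] == P.II,
                gain[:, s, 3, None],   # onto inhibitory interneurons
                gain[:, s, 2, None],   # onto excitatory populations
            )  # (B, 4) per target population
            W[:, s, :, R.NMDA, s, :] = nm * nmda_gain[:, :, None]
        # extrinsic couplings (AMPA drive)
        for k, e in enumerate(net.forward):
            a, b = net.node_index(e.source), net.node_index(e.target)
            for pt, base in zip(FORWARD_TARGETS, c.forward_base):
                W[:, b, pt, R.AMPA, a, P.SP] += base * nat["w_fwd"][:, k]
        for k, e in enumerate(net.backward):
            a, b = net.node_index(e.source), net.node_index(e.target)
            for pt, base in zip(BACKWARD_TARGETS, c.backward_base):
                W[:, b, pt, R.AMPA, a, P.DP] += base * nat["w_bwd"][:, k]
        for e in net.lateral:
            a, b = net.node_index(e.source), net.node_index(e.target)
            W[:, b, P.SP, R.AMPA, a, P.SP] += c.lateral_weight
        return W

    # ------------------------------------------------------------------ #
    # vector field and Jacobian
    # ------------------------------------------------------------------ #
    @staticmethod
    def _sigmoid(V, thresh, slope):
        return 0.5 * (1.0 + np.tanh(0.5 * (V - thresh) / slope))

    def _firing(self, V, nat):
        s = nat["slope"][:, None, None]
        F = self._sigmoid(V, V_THRESH, s)
        dF = F * (1.0 - F) / s
        return F, dF

    def _mg(self, V, nat):
        a = nat["mg_alpha"][:, None, None]
        b = nat["mg_beta"][:, None, None]
        g = nat["mg_gamma"][:, None, None]
        m = a / (1.0 + b * np.exp(-g * V))
        dm = g * m * (1.0 - m / a)
        return m, dm

    def f(self, x: np.ndarray, nat: dict, drive_extra: np.ndarray | None = None
          ) -> np.ndarray:
        """Vector field; x is (B, n) flattened, returns (B, n) in units /s."""
        B = x.shape[0]
        xs = x.reshape(B, self.S, 4, 4)
        V = xs[..., 0]        # (B,S,4)
        g = xs[..., 1:]       # (B,S,4,3)
        F, _ = self._firing(V, nat)
        drive = np.einsum("btprsq,bsq->btpr", nat["W"], F)
        if drive_extra is not None:
            drive = drive + drive_extra
        m, _ = self._mg(V, nat)
        gate = np.stack([np.ones_like(m), np.ones_like(m), m], axis=-1)
        current = (
            G_LEAK * (V_LEAK - V)
            + nat["bg"][:, None, None]
            + np.einsum("btpr,btpr->btp", g * gate, _E - V[..., None])
        )
        dV = current / self.C
        dg = nat["kappa"][:, :, None, :] * (drive - g)
        out = np.empty_like(xs)
        out[..., 0] = dV
        out[..., 1:] = dg
        return out.reshape(B, self.n)

    def jac(self, x: np.ndarray, nat: dict) -> np.ndarray:
        """Analytic Jacobian of :meth:`f`; returns (B, n, n)."""
        B = x.shape[0]
        S = self.S
        xs = x.reshape(B, S, 4, 4)
        V = xs[..., 0]
        g = xs[..., 1:]
        F, dF = self._firing(V, nat)
        m, dm = self._mg(V, nat)
        kap = nat["kappa"]  # (B,S,3)

        J = np.zeros((B, S, 4, 4, S, 4, 4))
        # dVdot/dV (diagonal in source & population)
        gA, gG, gN = g[..., 0], g[..., 1], g[..., 2]
        dVdV = (
            -G_LEAK - gA - gG + gN * (dm * (_E[2] - V) - m)
        ) / self.C
        # dVdot/dg_r
        gate = np.stack([np.ones_like(m), np.ones_like(m), m], axis=-1)
        dVdg = gate * (_E - V[..., None]) / self.C  # (B,S,4,3)
        # dgdot_r/dV_{s'q} = kappa_r * W * F'(V_{s'q})
        T = (
            kap[:, :, None, :, None, None]
            * nat["W"]
            * dF[:, None, None, None, :, :]
        )  # (B,S,4,3,S,4)

        bi = np.arange(B)[:, None, None]
        si = np.arange(S)[None, :, None]
        pi = np.arange(4)[None, None, :]
        J[bi, si, pi, 0, si, pi, 0] = dVdV
        for r in range(3):
            J[bi, si, pi, 0, si, pi, 1 + r] = dVdg[..., r]
            J[:, :, :, 1 + r, :, :, 0] = T[:, :, :, r, :, :]
            J[bi, si, pi, 1 + r, si, pi, 1 + r] = np.broadcast_to(
                -kap[:, :, None, r], (B, S, 4)
            )
        return J.reshape(B, self.n, self.n)

    # ------------------------------------------------------------------ #
    # fixed point
    # ------------------------------------------------------------------ #
    def initial_state(self, B: int) -> np.ndarray:
        x0 = np.zeros((B, self.S, 4, 4))
        x0[..., 0] = -60.0
        return x0.reshape(B, self.n)

    def fixed_point(self, nat: dict, x0: np.ndarray | None = None,
                    tol: float = 1e-8, max_iter: int = 60,
                    relax_steps: int = 400) -> tuple[np.ndarray, np.ndarray]:
        """Solve f(x*) = 0 by (optionally relaxed) Newton iteration.

        Returns ``(x, ok)`` where ok flags batch elements with
        ``||f(x)||_inf <= tol`` (state units per second scaled by the
        membrane time constant, i.e. tolerance applies to C*f for voltages).
        """
        B = nat["kappa"].shape[0]
        if x0 is None:
            x = self.initial_state(B)
            # short forward relaxation to land in the Newton basin
            dt = 2e-4
            for _ in range(relax_steps):
                x = x + dt * np.clip(self.f(x, nat), -1e6, 1e6)
        else:
            x = np.array(x0, dtype=float)
            if x.ndim == 1:
                x = np.broadcast_to(x, (B, self.n)).copy()
        ok = np.zeros(B, dtype=bool)
        for _ in range(max_iter):
            fx = self.f(x, nat)
            res = np.abs(fx).max(axis=1) * self.C  # scale-free residual
            ok = res <= tol
            if ok.all():
                break
            J = self.jac(x, nat)
            try:
                step = np.linalg.solve(J, -fx[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(
                    J.reshape(-1, self.n, self.n)[0], -fx[0], rcond=None
                )[0][None, :]
            # cap huge steps to keep iterates finite
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = np.where(norm > 200.0, step * (200.0 / norm), step)
            x = x + np.where(ok[:, None], 0.0, step)
        fx = self.f(x, nat)
        ok = (np.abs(fx).max(axis=1) * self.C) <= tol
        return x, ok

    # ------------------------------------------------------------------ #
    # delays and linearization
    # ------------------------------------------------------------------ #
    def delay_matrix(self, nat: dict) -> np.ndarray:
        """Pairwise state-to-state delays (B, n, n) in seconds.

        Delays apply to synaptic transmission: couplings from a presynaptic
        voltage state onto a conductance state carry the intra-source delay
        (free, one per source) or the fixed inter-source delay.  Couplings
        within one population's own states (membrane integration) are
        undelayed.
        """
        B = nat["delay_s"].shape[0]
        S = self.S
        D = np.zeros((B, S, 4, 4, S, 4, 4))
        inter = self.config.inter_source_delay_ms * 1e-3
        # synaptic mask: target state is a conductance, source state is V
        blk = np.zeros((4, 4, 4, 4))
        blk[:, 1:, :, 0] = 1.0  # blk[p, g-state, q, V-state]
        for st in range(S):
            for ss in range(S):
                d = nat["delay_s"][:, st] if st == ss else inter
                D[:, st, :, :, ss, :, :] = np.multiply.outer(
                    np.broadcast_to(d, (B,)), blk
                )
        return D.reshape(B, self.n, self.n)

    def delayed_jacobian(self, J: np.ndarray, nat: dict) -> np.ndarray:
        """First-order delay compensation: J_d = (I + D o J)^-1 J."""
        D = self.delay_matrix(nat)
        eye = np.eye(self.n)
        return np.linalg.solve(eye + D * J, J)

    def linearize(self, lam: np.ndarray, x0=None):
        """Fixed point + delay-adjusted Jacobian for a batch of parameters.

        Returns dict with x (B,n), ok (B,), J (B,n,n), Jd (B,n,n).
        """
        nat = self.materialize(lam)
        x, ok = self.fixed_point(nat, x0=x0)
        J = self.jac(x, nat)
        Jd = self.delayed_jacobian(J, nat)
        return {"nat": nat, "x": x, "ok": ok, "J": J, "Jd": Jd}

    # ------------------------------------------------------------------ #
    # input / output matrices
    # ------------------------------------------------------------------ #
    def input_matrix(self, nat: dict) -> np.ndarray:
        """(B, n, S): innovations drive the AMPA conductance of the spiny
        stellate population of each source (scaled by the AMPA rate
        constant, as any presynaptic drive is)."""
        B = nat["kappa"].shape[0]
        Bm = np.zeros((B, self.S, 4, 4, self.S))
        for s in range(self.S):
            Bm[:, s, P.SS, 1 + R.AMPA, s] = nat["kappa"][:, s, R.AMPA]
        return Bm.reshape(B, self.n, self.S)

    def output_matrix(self, weights: np.ndarray) -> np.ndarray:
        """(S, n): population-weighted sum of voltage states per source."""
        O = np.zeros((self.S, self.S, 4, 4))
        for s in range(self.S):
            O[s, s, :, 0] = weights
        return O.reshape(self.S, self.n)

    def population_output_matrix(self, population: P) -> np.ndarray:
        """(S, n): selects one population's voltage state per source."""
        O = np.zeros((self.S, self.S, 4, 4))
        for s in range(self.S):
            O[s, s, int(population), 0] = 1.0
        return O.reshape(self.S, self.n)

    # ------------------------------------------------------------------ #
    # transfer functions
    # ------------------------------------------------------------------ #
    def transfer(self, Jd: np.ndarray, Bm: np.ndarray, Out: np.ndarray,
                 freqs: np.ndarray, check_stability: bool = True):
        """H(w) = Out (i w I - Jd)^-1 Bm on a frequency grid (Hz).

        Uses the eigen-decomposition of Jd so that stability (all eigenvalue
        real parts < 0) comes for free.  Returns (H, eigvals) with H of
        shape (B, n_freq, n_out, n_in).
        """
        freqs = np.asarray(freqs, dtype=float)
        w, U = np.linalg.eig(Jd)
        if check_stability:
            max_real = w.real.max()
            if max_real >= 0:
                raise StabilityError(float(max_real))
        UinvB = np.linalg.solve(U, Bm.astype(complex))
        OU = np.einsum("on,bnm->bom", Out.astype(complex), U)
        iw = 2j * np.pi * freqs  # (F,)
        Rsp = 1.0 / (iw[None, :, None] - w[:, None, :])  # (B,F,n)
        H = np.einsum("bom,bfm,bmk->bfok", OU, Rsp, UinvB,
                      optimize=True)
        return H, w
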