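"""Conductance-based neural-mass network model (canonical microcircuit).

Each network node is a cortical source modelled as four interacting neural
populations — spiny stellate cells (ss), superficial pyramidal cells (sp),
inhibitory interneurons (ii) and deep pyramidal cells (dp).  Population
dynamics follow a Morris-Lecar-type conductance model: the membrane
potential integrates leak, excitatory (AMPA-like) and inhibitory
(GABA-A-like) currents,

    C dV/dt = g_L (V_L - V) + g_E (V_E - V) + g_I (V_I - V) + u,

while each synaptic conductance relaxes towards a target set by presynaptic
firing rates (a logistic function of presynaptic potential) at the channel's
rate constant.

Between sources, directed extrinsic connections are typed by the
populations they target: feedforward connections project from superficial
pyramidal cells to spiny stellate cells of the target, feedback connections
from deep pyramidal cells to the target's inhibitory interneurons and
superficial pyramidal cells, and lateral (interhemispheric) connections
carry both patterns.  Connection strengths are expressed as log-scaling
deviations from defaults, and condition-specific modulations (the B matrix)
multiply edge strengths by exp(b).

The model is used in two ways: analytically, by linearizing around the
stable fixed point and propagating parameterized innovation spectra through
the transfer function to predict cross-spectral densities; and
generatively, by stochastic integration to produce synthetic source
timecourses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import CrossSpectrum, FrequencyGrid

__all__ = [
    "POPULATIONS",
    "Edge",
    "NetworkArchitecture",
    "MicrocircuitParams",
    "NetworkModel",
    "build_default_network",
    "build_sfg_top_network",
    "build_chain_network",
    "load_architecture",
    "save_architecture",
    "morris_lecar_rhs",
    "fixed_point",
    "linearize",
    "predicted_csd",
    "simulate_timecourses",
    "stability_check",
]

POPULATIONS = ("ss", "sp", "ii", "dp")
SS, SP, II, DP = 0, 1, 2, 3

FEEDFORWARD = "feedforward"
FEEDBACK = "feedback"
LATERAL = "lateral"
EDGE_KINDS = (FEEDFORWARD, FEEDBACK, LATERAL)


@dataclass(frozen=True, order=True)
class Edge:
    source: str
    target: str
    kind: str

    def __post_init__(self):
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")

    def __str__(self):  # e.g. "EVC_contra->IPS_contra (feedforward)"
        return f"{self.source}->{self.target} ({self.kind})"


@dataclass(frozen=True)
class NetworkArchitecture:
    """Node set with a functional hierarchy and typed directed edges.

    Feedforward edges must ascend the hierarchy, feedback edges descend it,
    and lateral edges connect nodes of equal rank.  ``b_mask`` lists the
    edges whose strength is subject to condition-specific modulation.
    """

    nodes: tuple[str, ...]
    hierarchy: dict[str, int]
    edges: tuple[Edge, ...]
    b_mask: tuple[Edge, ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        for e in self.edges:
            if e.source not in self.hierarchy or e.target not in self.hierarchy:
                raise ValueError(f"edge {e} references unknown node")
            ds = self.hierarchy[e.target] - self.hierarchy[e.source]
            if e.kind == FEEDFORWARD and ds <= 0:
                raise ValueError(f"feedforward edge {e} does not ascend hierarchy")
            if e.kind == FEEDBACK and ds >= 0:
                raise ValueError(f"feedback edge {e} does not descend hierarchy")
            if e.kind == LATERAL and ds != 0:
                raise ValueError(f"lateral edge {e} links unequal ranks")
        if not set(self.b_mask) <= set(self.edges):
            raise ValueError("b_mask must be a subset of edges")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def edges_of_kind(self, kind: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.kind == kind)

    def edge_counts(self) -> dict[str, int]:
        return {k: len(self.edges_of_kind(k)) for k in EDGE_KINDS}

    def drop_edge(self, edge: Edge) -> "NetworkArchitecture":
        return NetworkArchitecture(
            self.nodes,
            dict(self.hierarchy),
            tuple(e for e in self.edges if e != edge),
            tuple(e for e in self.b_mask if e != edge),
        )


def _hierarchy_edges(
    nodes_by_rank: list[tuple[str, int]], hemispheres: dict[str, str | None]
) -> list[Edge]:
    """All within-hemisphere ascending pairs as feedforward plus reverses.

    Midline nodes (hemisphere None) participate in both hemispheric chains.
    """
    ff = []
    for a, ra in nodes_by_rank:
        for b, rb in nodes_by_rank:
            if rb <= ra:
                continue
            ha, hb = hemispheres[a], hemispheres[b]
            if ha is None or hb is None or ha == hb:
                ff.append(Edge(a, b, FEEDFORWARD))
    fb = [Edge(e.target, e.source, FEEDBACK) for e in ff]
    return ff + fb


def _seven_node_network(ranks: dict[str, int]) -> NetworkArchitecture:
    nodes = (
        "EVC_contra",
        "EVC_ipsi",
        "IPS_contra",
        "IPS_ipsi",
        "MFG_contra",
        "MFG_ipsi",
        "SFG",
    )
    hemis = {n: ("contra" if n.endswith("contra") else "ipsi") for n in nodes}
    hemis["SFG"] = None
    hier = {n: ranks[n.split("_")[0]] for n in nodes}
    edges = _hierarchy_edges([(n, hier[n]) for n in nodes], hemis)
    for roi in ("EVC", "IPS", "MFG"):
        edges.append(Edge(f"{roi}_contra", f"{roi}_ipsi", LATERAL))
        edges.append(Edge(f"{roi}_ipsi", f"{roi}_contra", LATERAL))
    edges = tuple(edges)
    return NetworkArchitecture(nodes, hier, edges, edges)


def build_default_network() -> NetworkArchitecture:
    """Default 7-node working-memory network.

    Hierarchy EVC(1) < IPS(2) < SFG(3) < MFG(4); within each hemisphere
    every lower-rank node projects feedforward to every higher-rank node
    (the midline SFG participates in both hemispheric chains), feedback
    edges are the reverses, and the three homologous contra/ipsi pairs are
    linked laterally in both directions: 12 feedforward, 12 feedback and 6
    lateral edges, all condition-modulable.
    """
    return _seven_node_network({"EVC": 1, "IPS": 2, "SFG": 3, "MFG": 4})


def build_sfg_top_network() -> NetworkArchitecture:
    """Alternative hierarchy preset with SFG above MFG."""
    return _seven_node_network({"EVC": 1, "IPS": 2, "MFG": 3, "SFG": 4})


def build_chain_network(n_nodes: int = 3) -> NetworkArchitecture:
    """A small hierarchical chain (testing/reduced-scale architecture).

    Nodes n1 < n2 < ... are linked by nearest-neighbour feedforward edges
    and their feedback reverses; no lateral edges.  All edges modulable.
    """
    nodes = tuple(f"n{i + 1}" for i in range(n_nodes))
    hier = {n: i + 1 for i, n in enumerate(nodes)}
    edges = []
    for i in range(n_nodes - 1):
        edges.append(Edge(nodes[i], nodes[i + 1], FEEDFORWARD))
        edges.append(Edge(nodes[i + 1], nodes[i], FEEDBACK))
    edges = tuple(edges)
    return NetworkArchitecture(nodes, hier, edges, edges)


def save_architecture(arch: NetworkArchitecture, path) -> None:
    payload = {
        "nodes": list(arch.nodes),
        "hierarchy": arch.hierarchy,
        "edges": [[e.source, e.target, e.kind] for e in arch.edges],
        "b_mask": [[e.source, e.target, e.kind] for e in arch.b_mask],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_architecture(path) -> NetworkArchitecture:
    with open(path) as fh:
        payload = json.load(fh)
    return NetworkArchitecture(
        tuple(payload["nodes"]),
        {k: int(v) for k, v in payload["hierarchy"].items()},
        tuple(Edge(*e) for e in payload["edges"]),
        tuple(Edge(*e) for e in payload["b_mask"]),
    )


def save_params(params: "MicrocircuitParams", path) -> None:
    """Write parameters to a YAML config (arrays as lists)."""
    import yaml
    from dataclasses import asdict

    payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in asdict(params).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_params(path) -> "MicrocircuitParams":
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kwargs = {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
        for k, v in payload.items()
    }
    return MicrocircuitParams(**kwargs)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class MicrocircuitParams:
    """Population constants, coupling strengths and spectral parameters.

    Units: potentials in mV, time in seconds (rate constants in 1/s),
    conductances normalised to the leak conductance.  The defaults are a
    documented reference set chosen so that the default network is stable
    and spectrally active across the 2-100 Hz analysis band; they make no
    claim of numerical equality with any other implementation.

    Intrinsic wiring (per source): excitatory connections couple ss and sp
    in both directions and sp to dp; all three excitatory populations are
    reciprocally connected with the interlaminar inhibitory population; and
    every population carries an inhibitory self-connection modelling
    synaptic gain.
    """

    # membrane constants, per population (ss, sp, ii, dp)
    capacitance: np.ndarray = field(
        default_factory=lambda: np.array([0.010, 0.010, 0.005, 0.010])
    )
    g_leak: np.ndarray = field(default_factory=lambda: np.ones(4))
    v_leak: float = -70.0
    v_exc: float = 60.0
    v_inh: float = -90.0
    # channel rate constants (1/s): AMPA ~ 4 ms, GABA-A ~ 16 ms
    kappa_exc: np.ndarray = field(default_factory=lambda: np.full(4, 250.0))
    kappa_inh: np.ndarray = field(default_factory=lambda: np.full(4, 62.5))
    # firing-rate sigmoid
    sigmoid_threshold: float = -54.0
    sigmoid_slope: float = 6.0  # mV per unit of sigmoid argument
    # tonic background excitatory conductance drive, per population
    background_drive: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.05)
    )
    # intrinsic excitatory weights (post <- pre), conductance per unit rate
    w_ss_sp: float = 0.40  # ss <- sp
    w_sp_ss: float = 0.60  # sp <- ss
    w_dp_sp: float = 0.50  # dp <- sp
    w_ii_exc: np.ndarray = field(  # ii <- (ss, sp, dp)
        default_factory=lambda: np.array([0.40, 0.40, 0.20])
    )
    # inhibitory weights: from ii onto each population, and self-inhibition
    w_from_ii: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0, 0.0, 1.0])
    )
    w_self_inh: np.ndarray = field(
        default_factory=lambda: np.array([0.20, 0.20, 0.40, 0.20])
    )
    # extrinsic base weights per edge kind; lateral edges apply both the
    # feedforward and feedback patterns, mixed equally by default
    w_feedforward: float = 0.10
    w_feedback: float = 0.08
    w_lateral: float = 0.08
    lateral_mix: float = 0.5
    # innovations spectrum per node: amp * f^(-exponent) + floor, in
    # (input units)^2/Hz; frequencies below f_clamp are clamped
    innovations_amp: float = 1.0
    innovations_exponent: float = 1.0
    innovations_floor: float = 0.25
    innovations_f_clamp: float = 1.0
    # observation model: y = gain * (V_sp - V_sp*) + white noise
    obs_gain: float = 1.0
    obs_noise_psd: float = 1e-4

    def copy(self) -> "MicrocircuitParams":
        return replace(
            self,
            capacitance=self.capacitance.copy(),
            g_leak=self.g_leak.copy(),
            kappa_exc=self.kappa_exc.copy(),
            kappa_inh=self.kappa_inh.copy(),
            background_drive=self.background_drive.copy(),
            w_ii_exc=self.w_ii_exc.copy(),
            w_from_ii=self.w_from_ii.copy(),
            w_self_inh=self.w_self_inh.copy(),
        )

    def validate(self) -> None:
        for name in ("capacitance", "g_leak", "kappa_exc", "kappa_inh"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid slope must be positive")
        if not (self.v_inh < self.v_leak < self.v_exc):
            raise ValueError("need v_inh < v_leak < v_exc")


# ---------------------------------------------------------------------------
# compiled network model


class NetworkModel:
    """A network architecture bound to parameters and log-scaling deviations.

    Parameters
    ----------
    architecture : NetworkArchitecture
    params : MicrocircuitParams
    a_log : dict Edge -> float
        Log-scaling deviations of extrinsic edge strengths (the A-matrix
        parameters); missing edges default to 0.
    b : dict Edge -> float
        Condition-specific log-scaling modulations (the B-matrix entries);
        only edges in the architecture's b_mask may appear.  Effective edge
        strength is ``base * exp(a_log) * exp(b)``.
    intrinsic_log : per-node log-scaling of the self-inhibition gain
        (dict node name -> float); innovations/observation scalings are
        taken from ``params``.

    The state vector stacks (V, g_E, g_I) for each population of each node:
    shape (n_nodes, 4, 3), flattened C-order.
    """

    def __init__(
        self,
        architecture: NetworkArchitecture,
        params: MicrocircuitParams | None = None,
        a_log: dict[Edge, float] | None = None,
        b: dict[Edge, float] | None = None,
        intrinsic_log: dict[str, float] | None = None,
    ):
        self.architecture = architecture
        self.params = params or MicrocircuitParams()
        self.params.validate()
        self.a_log = dict(a_log or {})
        self.b = dict(b or {})
        self.intrinsic_log = dict(intrinsic_log or {})
        for e in self.a_log:
            if e not in architecture.edges:
                raise ValueError(f"a_log references unknown edge {e}")
        for e in self.b:
            if e not in architecture.b_mask:
                raise ValueError(f"modulated edge {e} not in b_mask")
        self._compile()

    # -- construction ------------------------------------------------------

    def _compile(self) -> None:
        arch, p = self.architecture, self.params
        n = arch.n_nodes
        self.n_nodes = n
        self.n_states = n * 4 * 3

        # intrinsic excitatory coupling (post <- pre), shared across nodes
        w = np.zeros((4, 4))
        w[SS, SP] = p.w_ss_sp
        w[SP, SS] = p.w_sp_ss
        w[DP, SP] = p.w_dp_sp
        w[II, SS], w[II, SP], w[II, DP] = p.w_ii_exc
        self._w_exc_intrinsic = w

        # extrinsic coupling tensors: contribution of presynaptic sp/dp
        # rates to each (node, population) excitatory conductance target
        m_sp = np.zeros((n, 4, n))
        m_dp = np.zeros((n, 4, n))
        for e in arch.edges:
            s, t = arch.node_index(e.source), arch.node_index(e.target)
            weight = {
                FEEDFORWARD: p.w_feedforward,
                FEEDBACK: p.w_feedback,
                LATERAL: p.w_lateral,
            }[e.kind]
            weight *= np.exp(self.a_log.get(e, 0.0) + self.b.get(e, 0.0))
            if e.kind == FEEDFORWARD:
                m_sp[t, SS, s] += weight
            elif e.kind == FEEDBACK:
                m_dp[t, II, s] += weight
                m_dp[t, SP, s] += weight
            else:  # lateral: both patterns
                m_sp[t, SS, s] += p.lateral_mix * weight
                m_dp[t, II, s] += (1 - p.lateral_mix) * weight
                m_dp[t, SP, s] += (1 - p.lateral_mix) * weight
        self._m_sp, self._m_dp = m_sp, m_dp

        self._w_self = np.array(
            [
                p.w_self_inh * np.exp(self.intrinsic_log.get(node, 0.0))
                for node in arch.nodes
            ]
        )  # (n, 4)

    # -- dynamics ----------------------------------------------------------

    def rate(self, v: np.ndarray) -> np.ndarray:
        """Population firing rate: logistic sigmoid of membrane potential."""
        p = self.params
        return 1.0 / (1.0 + np.exp(-(v - p.sigmoid_threshold) / p.sigmoid_slope))

    def _rate_deriv(self, v: np.ndarray) -> np.ndarray:
        r = self.rate(v)
        return r * (1.0 - r) / self.params.sigmoid_slope

    def _conductance_targets(
        self, rates: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        ge = (
            p.background_drive[None, :]
            + rates @ self._w_exc_intrinsic.T
            + np.einsum("tps,s->tp", self._m_sp, rates[:, SP])
            + np.einsum("tps,s->tp", self._m_dp, rates[:, DP])
        )
        gi = p.w_from_ii[None, :] * rates[:, II][:, None] + self._w_self * rates
        return ge, gi

    def rhs(self, x: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
        """Deterministic state derivative.

        ``x`` is the flat state vector; ``u`` an optional per-node input
        current applied to the spiny stellate population.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite state")
        p = self.params
        s = x.reshape(self.n_nodes, 4, 3)
        v, ge, gi = s[..., 0], s[..., 1], s[..., 2]
        rates = self.rate(v)
        ge_t, gi_t = self._conductance_targets(rates)
        current = (
            p.g_leak * (p.v_leak - v)
            + ge * (p.v_exc - v)
            + gi * (p.v_inh - v)
        )
        if u is not None:
            current = current.copy()
            current[:, SS] += np.asarray(u, dtype=float)
        out = np.empty_like(s)
        out[..., 0] = current / p.capacitance
        out[..., 1] = p.kappa_exc * (ge_t - ge)
        out[..., 2] = p.kappa_inh * (gi_t - gi)
        return out.ravel()

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (no input) at state ``x``."""
        p = self.params
        n = self.n_nodes
        s = np.asarray(x, dtype=float).reshape(n, 4, 3)
        v, ge, gi = s[..., 0], s[..., 1], s[..., 2]
        rp = self._rate_deriv(v)  # (n, 4)

        nn = self.n_states
        jac = np.zeros((nn, nn))

        def idx(node, pop, comp):
            return (node * 4 + pop) * 3 + comp

        node_i, pop_i = np.meshgrid(range(n), range(4), indexing="ij")
        iv = ((node_i * 4 + pop_i) * 3).ravel()

        # dV'/dV, dV'/dgE, dV'/dgI (diagonal blocks)
        c = p.capacitance[None, :]
        jac[iv, iv] = (-(p.g_leak + ge + gi) / c).ravel()
        jac[iv, iv + 1] = ((p.v_exc - v) / c).ravel()
        jac[iv, iv + 2] = ((p.v_inh - v) / c).ravel()

        # conductance relaxation
        ke = np.broadcast_to(p.kappa_exc, (n, 4)).ravel()
        ki = np.broadcast_to(p.kappa_inh, (n, 4)).ravel()
        jac[iv + 1, iv + 1] = -ke
        jac[iv + 2, iv + 2] = -ki

        # dgE'/dV_pre via excitatory targets
        for t in range(n):
            for pp in range(4):
                row = idx(t, pp, 1)
                kap = p.kappa_exc[pp]
                for pre in range(4):  # intrinsic
                    wgt = self._w_exc_intrinsic[pp, pre]
                    if wgt:
                        jac[row, idx(t, pre, 0)] += kap * wgt * rp[t, pre]
                for src in range(n):  # extrinsic
                    if self._m_sp[t, pp, src]:
                        jac[row, idx(src, SP, 0)] += (
                            kap * self._m_sp[t, pp, src] * rp[src, SP]
                        )
                    if self._m_dp[t, pp, src]:
                        jac[row, idx(src, DP, 0)] += (
                            kap * self._m_dp[t, pp, src] * rp[src, DP]
                        )

        # dgI'/dV via inhibitory targets (ii input + self-inhibition)
        for t in range(n):
            for pp in range(4):
                row = idx(t, pp, 2)
                kap = p.kappa_inh[pp]
                if p.w_from_ii[pp]:
                    jac[row, idx(t, II, 0)] += kap * p.w_from_ii[pp] * rp[t, II]
                if self._w_self[t, pp]:
                    jac[row, idx(t, pp, 0)] += kap * self._w_self[t, pp] * rp[t, pp]
        return jac

    # -- fixed point and linearization ------------------------------------

    def resting_state(self) -> np.ndarray:
        """Heuristic initial state: leak potential, target conductances."""
        n = self.n_nodes
        v = np.full((n, 4), self.params.v_leak)
        ge_t, gi_t = self._conductance_targets(self.rate(v))
        x = np.stack([v, ge_t, gi_t], axis=-1)
        return x.ravel()

    def fixed_point(
        self, x0: np.ndarray | None = None, tol: float = 1e-9, max_iter: int = 200
    ) -> np.ndarray:
        """Damped-Newton solution of rhs(x*) = 0."""
        x = self.resting_state() if x0 is None else np.asarray(x0, dtype=float)
        # scale residuals so the fast voltage rows (mV/s) and the slower
        # conductance rows (1/s) are comparable in the line-search norm
        scale = np.ones((self.n_nodes, 4, 3))
        scale[..., 0] = 1.0 / self.params.capacitance[None, :]
        scale = scale.ravel()

        def resid_norm(f):
            return np.abs(f / scale).max()

        f = self.rhs(x)
        for _ in range(max_iter):
            if np.abs(f).max() < tol:
                return x
            norm = resid_norm(f)
            step = np.linalg.solve(self.jacobian(x), -f)
            lam = 1.0
            for _ in range(60):
                x_new = x + lam * step
                try:
                    f_new = self.rhs(x_new)
                except FloatingPointError:
                    lam *= 0.5
                    continue
                if resid_norm(f_new) < norm:
                    break
                lam *= 0.5
            else:
                break
            x, f = x_new, f_new
        if np.abs(f).max() < tol:
            return x
        worst = int(np.argmax(np.abs(f)) // 12)
        raise RuntimeError(
            f"fixed point not found (residual {np.abs(f).max():.3g}, "
            f"worst node {self.architecture.nodes[worst]})"
        )

    def linearize(
        self, x_star: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Jacobian, input and output matrices at the fixed point.

        Returns ``(J, B_in, C_out, x_star)``: innovations enter as input
        current to each node's spiny stellate population; the observed
        signal is the superficial pyramidal potential scaled by the
        observation gain.
        """
        if x_star is None:
            x_star = self.fixed_point()
        jac = self.jacobian(x_star)
        n = self.n_nodes
        b_in = np.zeros((self.n_states, n))
        c_out = np.zeros((n, self.n_states))
        for node in range(n):
            b_in[(node * 4 + SS) * 3, node] = 1.0 / self.params.capacitance[SS]
            c_out[node, (node * 4 + SP) * 3] = self.params.obs_gain
        return jac, b_in, c_out, x_star

    def stability(self) -> tuple[bool, float]:
        """(stable?, spectral abscissa) of the Jacobian at the fixed point."""
        try:
            jac = self.jacobian(self.fixed_point())
        except RuntimeError:
            return False, np.inf
        abscissa = float(np.max(np.linalg.eigvals(jac).real))
        return abscissa < 0, abscissa

    # -- spectra -----------------------------------------------------------

    def innovations_psd(self, freqs: np.ndarray) -> np.ndarray:
        """One-sided innovation-current PSD per node, shape (n_f, n_nodes)."""
        p = self.params
        f = np.maximum(np.asarray(freqs, dtype=float), p.innovations_f_clamp)
        gu = p.innovations_amp * f ** (-p.innovations_exponent) + (
            p.innovations_amp * p.innovations_floor
        )
        return np.broadcast_to(gu[:, None], (f.size, self.n_nodes)).copy()

    def predicted_csd(
        self, grid: FrequencyGrid | np.ndarray | None = None
    ) -> CrossSpectrum:
        """Analytic cross-spectral density of the linearized model.

        S(f) = M(f) diag(G_u(f)) M(f)* + S_noise, with M the transfer
        function from innovation currents to observed signals.  Raises if
        the linearization is unstable.
        """
        if grid is None:
            grid = FrequencyGrid()
        freqs = grid.frequencies if isinstance(grid, FrequencyGrid) else np.asarray(grid)
        jac, b_in, c_out, _ = self.linearize()
        eig = np.linalg.eigvals(jac)
        if np.max(eig.real) >= 0:
            raise RuntimeError(
                f"unstable linearization (spectral abscissa {np.max(eig.real):.3g})"
            )
        gu = self.innovations_psd(freqs)
        n = self.n_nodes
        values = np.empty((freqs.size, n, n), dtype=complex)
        eye = np.eye(self.n_states)
        for i, f in enumerate(freqs):
            m = c_out @ np.linalg.solve(2j * np.pi * f * eye - jac, b_in)
            values[i] = (m * gu[i][None, :]) @ m.conj().T
        values += np.eye(n)[None, :, :] * self.params.obs_noise_psd
        values = 0.5 * (values + values.conj().transpose(0, 2, 1))
        return CrossSpectrum(freqs, values, {"kind": "analytic"})

    # -- simulation --------------------------------------------------------

    def _shaped_innovations(
        self, n_samples: int, fs: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Per-node innovation currents with one-sided PSD G_u, (n, T)."""
        white = rng.standard_normal((self.n_nodes, n_samples))
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(n_samples, 1.0 / fs)
        gu = self.innovations_psd(f)[:, 0]  # identical across nodes
        scale = np.sqrt(gu * fs / 2.0)
        scale[0] = 0.0  # no DC drive
        return np.fft.irfft(spec * scale[None, :], n=n_samples, axis=-1)

    def simulate_timecourses(
        self,
        duration_s: float,
        fs: float = 1000.0,
        seed: int | np.random.Generator = 0,
        burn_in_s: float = 2.0,
        return_states: bool = False,
    ) -> np.ndarray:
        """Stochastic realization of the observed node signals.

        Heun integration at the sampling step, driven by spectrally shaped
        innovation currents (zero-order hold within a step); white
        observation noise is added per the observation model and the
        burn-in transient is discarded.  Returns (n_nodes, n_samples).
        """
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        dt = 1.0 / fs
        n_total = int(round((duration_s + burn_in_s) * fs))
        n_burn = int(round(burn_in_s * fs))
        u = self._shaped_innovations(n_total, fs, rng)
        x_star = self.fixed_point()
        sp_slice = slice((SP * 3), None, 12)  # V_sp rows of the flat state

        x = x_star.copy()
        v_sp_star = x_star.reshape(self.n_nodes, 4, 3)[:, SP, 0]
        out = np.empty((self.n_nodes, n_total - n_burn))
        for t in range(n_total):
            try:
                k1 = self.rhs(x, u[:, t])
                k2 = self.rhs(x + dt * k1, u[:, t])
            except FloatingPointError:
                raise RuntimeError(f"numerical blow-up at sample {t}")
            x = x + 0.5 * dt * (k1 + k2)
            if np.abs(x.reshape(-1, 3)[:, 0]).max() > 500.0:
                raise RuntimeError(f"numerical blow-up at sample {t}")
            if t >= n_burn:
                v_sp = x.reshape(self.n_nodes, 4, 3)[:, SP, 0]
                out[:, t - n_burn] = self.params.obs_gain * (v_sp - v_sp_star)
        noise_sd = np.sqrt(self.params.obs_noise_psd * fs / 2.0)
        out += noise_sd * rng.standard_normal(out.shape)
        if return_states:
            return out, x
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def morris_lecar_rhs(
    model: NetworkModel, x: np.ndarray, u: np.ndarray | None = None
) -> np.ndarray:
    """State derivative of the deterministic neuronal dynamics."""
    return model.rhs(x, u)


def fixed_point(model: NetworkModel, **kwargs) -> np.ndarray:
    return model.fixed_point(**kwargs)


def linearize(model: NetworkModel, **kwargs):
    return model.linearize(**kwargs)


def predicted_csd(model: NetworkModel, grid=None) -> CrossSpectrum:
    return model.predicted_csd(grid)


def simulate_timecourses(model: NetworkModel, duration_s, **kwargs) -> np.ndarray:
    return model.simulate_timecourses(duration_s, **kwargs)


def stability_check(model: NetworkModel) -> tuple[bool, float]:
    return model.stability()


def numerical_jacobian(
    model: NetworkModel, x: np.ndarray, h: float = 1e-6
) -> np.ndarray:
    """Central finite-difference Jacobian of the rhs (testing oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    jac = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h * max(1.0, abs(x[j]))
        jac[:, j] = (model.rhs(x + e) - model.rhs(x - e)) / (2 * e[j])
    return jac
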