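"""Kinetic models for smFRET systems and their analytic properties.

A kinetic model is a continuous-time Markov chain over conformational
states, each with a characteristic FRET efficiency.  Off-diagonal entries
of ``rates`` are transition rate constants ``k_ij`` (s^-1) from state ``i``
to state ``j``; the diagonal is zero by convention.  The generator matrix
``Q`` (with diagonal ``-sum_j k_ij``) governs the process; its stationary
distribution gives long-run state occupancies.

For models with three or more states the chain need not satisfy detailed
balance: a non-zero net cycle flux corresponds to a free-energy drop per
cycle, ``delta_g = -ln(reverse product / forward product)`` in units of
k_B*T, negative for counter-clockwise net flow around the cycle as listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.linalg import null_space
from scipy.sparse.csgraph import connected_components


class ModelValidationError(ValueError):
    """A kinetic model violates a structural invariant."""


@dataclass(frozen=True)
class KineticModel:
    """A continuous-time kinetic model with per-state FRET efficiencies.

    Parameters
    ----------
    rates
        Square array, ``rates[i, j]`` = k_ij in s^-1 for i != j.
        Diagonal entries are ignored and stored as zero.
    fret
        Per-state FRET efficiency, each in [0, 1].
    state_labels
        Optional ordered identifiers; defaults to "S1", "S2", ...
    """

    rates: np.ndarray
    fret: np.ndarray
    state_labels: tuple[str, ...] = ()

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float).copy()
        fret = np.atleast_1d(np.asarray(self.fret, dtype=float))
        if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
            raise ModelValidationError(f"rate matrix must be square, got shape {rates.shape}")
        if fret.shape[0] != rates.shape[0]:
            raise ModelValidationError(
                f"{fret.shape[0]} FRET efficiencies for {rates.shape[0]} states"
            )
        np.fill_diagonal(rates, 0.0)
        rates.setflags(write=False)
        fret.setflags(write=False)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "fret", fret)
        labels = tuple(self.state_labels) or tuple(f"S{i + 1}" for i in range(rates.shape[0]))
        if len(labels) != rates.shape[0]:
            raise ModelValidationError("state_labels length does not match n_states")
        object.__setattr__(self, "state_labels", labels)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state, sum_j k_ij."""
        return self.rates.sum(axis=1)

    def generator(self) -> np.ndarray:
        """Generator matrix Q: off-diagonal k_ij, diagonal -sum_j k_ij."""
        q = self.rates.copy()
        np.fill_diagonal(q, -self.exit_rates)
        return q

    def permuted(self, order: np.ndarray) -> "KineticModel":
        """Return the model with states reordered by ``order``."""
        order = np.asarray(order)
        return KineticModel(
            rates=self.rates[np.ix_(order, order)],
            fret=self.fret[order],
            state_labels=tuple(self.state_labels[i] for i in order),
        )


@dataclass(frozen=True)
class FlowResult:
    """Cycle free-energy drop in k_B*T units.

    ``delta_g`` is zero exactly when the product of rate constants around
    the cycle equals the product in the reverse direction (detailed
    balance on that cycle); negative values flag net counter-clockwise
    flow, i.e. net flux against the listed cycle orientation.
    """

    delta_g: float
    cycle: tuple[int, ...]
    direction_convention: str = (
        "delta_g = -ln(prod reverse / prod forward) for the listed cycle; "
        "negative = net counter-clockwise flow (against the listed orientation)"
    )


def validate_model(model: KineticModel) -> KineticModel:
    """Validate invariants and return the model in canonical state order.

    Canonical order is ascending FRET efficiency; ties (degenerate FRET
    states, i.e. kinetic heterogeneity) are broken by larger total exit
    rate first.  Raises :class:`ModelValidationError` on negative rates,
    FRET outside [0, 1], or an absorbing state in a multi-state model.
    """
    off = model.rates[~np.eye(model.n_states, dtype=bool)]
    if np.any(off < 0):
        raise ModelValidationError("negative off-diagonal rate constant")
    if np.any((model.fret < 0) | (model.fret > 1)):
        raise ModelValidationError(f"FRET efficiencies outside [0, 1]: {model.fret}")
    if model.n_states > 1 and np.any(model.exit_rates == 0):
        dead = [model.state_labels[i] for i in np.flatnonzero(model.exit_rates == 0)]
        raise ModelValidationError(f"absorbing state(s) with no outgoing rate: {dead}")
    order = np.lexsort((-model.exit_rates, model.fret))
    if np.array_equal(order, np.arange(model.n_states)):
        return model
    return model.permuted(order)


def stationary_distribution(model: KineticModel, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi solving pi Q = 0, normalised to sum 1.

    Computed as the null space of Q^T.  Raises for reducible chains
    (states that cannot reach each other), naming the disconnected
    groups.
    """
    if model.n_states == 1:
        return np.array([1.0])
    n_comp, labels = connected_components(model.rates > 0, directed=True, connection="strong")
    if n_comp > 1:
        groups = [
            [model.state_labels[i] for i in np.flatnonzero(labels == c)] for c in range(n_comp)
        ]
        raise ModelValidationError(f"rate matrix is reducible; strongly connected groups: {groups}")
    ns = null_space(model.generator().T)
    if ns.shape[1] != 1:  # pragma: no cover - excluded by irreducibility
        raise ModelValidationError("generator null space is not one-dimensional")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.abs(pi @ model.generator()).max()
    if resid > tol * max(1.0, np.abs(model.rates).max()):
        raise ModelValidationError(f"stationary solve residual {resid:.3g} exceeds tolerance")
    return pi


def equilibrium_constant(k12: float, k21: float) -> float:
    """Equilibrium constant K = k21 / k12 of a two-state exchange."""
    if k12 == 0:
        raise ZeroDivisionError("equilibrium constant undefined: k12 = 0")
    return k21 / k12


def cycle_flow_free_energy(model: KineticModel, cycle: tuple[int, ...]) -> FlowResult:
    """Free-energy drop per traversal of ``cycle``, in k_B*T units.

    For cycle (0, 1, 2): ``delta_g = -ln[(k21 k32 k13) / (k12 k23 k31)]``
    (1-based subscripts).  Every edge of the cycle must have both forward
    and reverse rate constants > 0, otherwise the flow is undefined.
    """
    cycle = tuple(int(c) for c in cycle)
    if len(cycle) < 3:
        raise ValueError("a cycle needs at least three states")
    if len(set(cycle)) != len(cycle):
        raise ValueError(f"cycle revisits a state: {cycle}")
    forward = 1.0
    reverse = 1.0
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        kf, kr = model.rates[a, b], model.rates[b, a]
        if kf <= 0 or kr <= 0:
            raise ValueError(
                f"flow undefined: zero rate on cycle edge "
                f"{model.state_labels[a]}<->{model.state_labels[b]}"
            )
        forward *= kf
        reverse *= kr
    return FlowResult(delta_g=-float(np.log(reverse / forward)), cycle=cycle)


def is_detailed_balanced(model: KineticModel, tol: float = 1e-10) -> bool:
    """Kolmogorov criterion: zero free-energy drop on every independent cycle.

    A pair with k_ij > 0 but k_ji = 0 breaks detailed balance outright.
    Models whose connectivity graph has no cycle are balanced trivially.
    """
    asym = (model.rates > 0) != (model.rates.T > 0)
    if np.any(asym):
        return False
    g = nx.Graph((int(i), int(j)) for i, j in zip(*np.nonzero(model.rates)))
    for cyc in nx.cycle_basis(g):
        if abs(cycle_flow_free_energy(model, tuple(cyc)).delta_g) > tol:
            return False
    return True
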