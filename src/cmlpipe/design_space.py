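"""Automated model selection over candidate feedback architectures.

Each of the five regulated quantities (p0, p1, q1, eta1, eta2) may be
unregulated, or regulated positively or negatively by exactly one of
the four cell populations: 9 options each, 9^5 = 59,049 candidate
models.  A candidate is screened by decomposing it into dominant
power-law subsystems (S-systems): per ODE keep one dominant production
and one dominant loss term, plus a regime branch per Hill factor.  An
S-system survives if its log-linear equilibrium exists, every dominance
and regime inequality holds strictly at that equilibrium for some
positive parameter choice, and the equilibrium is stable.  A model with
at least one surviving S-system is accepted.

Feasibility over free positive parameters is certified by sampled
witnesses: a parameter sample satisfying all inequalities with a stable
equilibrium proves acceptance; rejection is the absence of a witness
(backed by cheap structural necessities — singular balances, a
non-Hurwitz determinant sign — that hold for every parameter choice).

Hill branches reduce to power laws: a negatively regulated factor
``max/(1 + g X)`` contributes a constant branch (``g X << 1``) and a
``(max/g) X^-1`` branch (``g X >> 1``); positive regulation mirrors
this with a linear ``(max g) X`` branch and a saturating constant
branch.  Constant branches carry no structural constraint because their
gain appears nowhere else, so they are equivalent to the unregulated
factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import NormalParameterSet
from .lineage import analytic_equilibrium, _rhs_closed

__all__ = [
    "Regulation",
    "RegulationScheme",
    "SSystem",
    "ModelVerdict",
    "enumerate_schemes",
    "count_schemes",
    "build_ssystems",
    "solve_ssystem",
    "check_consistency_and_stability",
    "filter_models",
    "map_design_space",
    "FIG_ARCHITECTURE",
]

POPS = ("S", "P", "TDl", "TDm")
QUANTITIES = ("p0", "p1", "q1", "eta1", "eta2")

#: parameter symbols: one max level per quantity, one gain per regulated
#: quantity, two terminal death rates
_MAX_PARAM = {
    "p0": "p0_max",
    "p1": "p1_max",
    "q1": "q1_max",
    "eta1": "eta1_max",
    "eta2": "eta2_max",
}
_GAIN_PARAM = {q: f"g_{q}" for q in QUANTITIES}
PARAM_NAMES = tuple(_MAX_PARAM.values()) + tuple(_GAIN_PARAM.values()) + ("d_l", "d_m")


@dataclass(frozen=True)
class Regulation:
    """Regulation entry for one quantity: none, or (source, sign)."""

    source: str | None = None
    sign: int = 0

    def __post_init__(self) -> None:
        if self.source is None:
            if self.sign != 0:
                raise ValueError("unregulated entry must have sign 0")
        else:
            if self.source not in POPS:
                raise ValueError(f"unknown source {self.source!r}")
            if self.sign not in (-1, 1):
                raise ValueError("sign must be -1 or +1")

    @property
    def code(self) -> int:
        """0 for none, 1..8 for (source, sign) combinations."""
        if self.source is None:
            return 0
        return 1 + 2 * POPS.index(self.source) + (self.sign > 0)

    @classmethod
    def from_code(cls, code: int) -> "Regulation":
        if code == 0:
            return cls()
        code -= 1
        return cls(source=POPS[code // 2], sign=+1 if code % 2 else -1)


@dataclass(frozen=True)
class RegulationScheme:
    """One candidate architecture: a regulation entry per quantity."""

    p0: Regulation = Regulation()
    p1: Regulation = Regulation()
    q1: Regulation = Regulation()
    eta1: Regulation = Regulation()
    eta2: Regulation = Regulation()

    def __getitem__(self, quantity: str) -> Regulation:
        return getattr(self, quantity)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(self[q].code for q in QUANTITIES)

    def encode(self) -> str:
        return "-".join(str(c) for c in self.codes)

    @classmethod
    def decode(cls, text: str) -> "RegulationScheme":
        codes = [int(c) for c in text.split("-")]
        if len(codes) != 5:
            raise ValueError("scheme encoding needs 5 codes")
        return cls(**{q: Regulation.from_code(c) for q, c in zip(QUANTITIES, codes)})


#: the architecture selected by the screening plus the perturbation
#: experiments: negative feedback P -> p0, TDm -> p1, TDm -> q1 and
#: negative feedforward/feedback S -> eta1, S -> eta2
FIG_ARCHITECTURE = RegulationScheme(
    p0=Regulation("P", -1),
    p1=Regulation("TDm", -1),
    q1=Regulation("TDm", -1),
    eta1=Regulation("S", -1),
    eta2=Regulation("S", -1),
)


def enumerate_schemes(
    constraints: Mapping[str, Iterable[Regulation]] | None = None,
) -> Iterator[RegulationScheme]:
    """Yield every scheme consistent with the constraints.

    ``constraints`` maps quantity names to the allowed Regulation
    entries for that quantity; unconstrained quantities range over all
    nine options.
    """
    options: list[list[Regulation]] = []
    constraints = dict(constraints or {})
    for q in QUANTITIES:
        if q in constraints:
            allowed = list(constraints.pop(q))
            if not allowed:
                raise ValueError(f"contradictory constraints: no options for {q}")
            if len({r.code for r in allowed}) != len(allowed):
                raise ValueError(f"duplicate constraint options for {q}")
            options.append(allowed)
        else:
            options.append([Regulation.from_code(c) for c in range(9)])
    if constraints:
        raise ValueError(f"unknown quantities in constraints: {sorted(constraints)}")
    for combo in itertools.product(*options):
        yield RegulationScheme(**dict(zip(QUANTITIES, combo)))


def count_schemes(
    constraints: Mapping[str, Iterable[Regulation]] | None = None,
) -> int:
    """Number of schemes the same constraints would enumerate."""
    n = 1
    constraints = dict(constraints or {})
    for q in QUANTITIES:
        n *= len(list(constraints[q])) if q in constraints else 9
    return n


def negative_regulations(source: str | None = None) -> list[Regulation]:
    """Helper: the negative-regulation options (for one source or all four)."""
    if source is not None:
        return [Regulation(source, -1)]
    return [Regulation(p, -1) for p in POPS]


# ---------------------------------------------------------------------------
# power-law structure


@dataclass(frozen=True)
class _Branch:
    """One regime branch of a regulated factor, as a power law."""

    quantity: str
    kind: str  # "const" | "hi" (negative, g X >> 1) | "lin" (positive, g X << 1)
    pop: int | None  # population index carrying the exponent / condition
    exponent: int  # 0, -1 or +1
    # parameter exponents of the branch coefficient
    coef: tuple[tuple[str, int], ...]
    # regime condition: (pop, gain, ">" | "<") or None
    condition: tuple[int, str, str] | None

    @property
    def key(self) -> tuple:
        # structural identity: const branches collapse regardless of origin
        if self.exponent == 0:
            return (self.quantity, "const")
        return (self.quantity, self.kind, self.pop)


def _branches(quantity: str, reg: Regulation) -> list[_Branch]:
    maxp = _MAX_PARAM[quantity]
    gain = _GAIN_PARAM[quantity]
    if reg.source is None:
        return [_Branch(quantity, "const", None, 0, ((maxp, 1),), None)]
    j = POPS.index(reg.source)
    if reg.sign < 0:
        return [
            # g X << 1: factor ~ max, gain otherwise unused -> condition free
            _Branch(quantity, "const", None, 0, ((maxp, 1),), None),
            # g X >> 1: factor ~ (max/g) X^-1
            _Branch(quantity, "hi", j, -1, ((maxp, 1), (gain, -1)), (j, gain, ">")),
        ]
    return [
        # g X >> 1: factor saturates at max, gain otherwise unused
        _Branch(quantity, "const", None, 0, ((maxp, 1),), None),
        # g X << 1: factor ~ (max g) X
        _Branch(quantity, "lin", j, +1, ((maxp, 1), (gain, 1)), (j, gain, "<")),
    ]


@dataclass(frozen=True)
class _Term:
    """A signed monomial flux: number * params^exps * populations^exps."""

    label: str
    lognum: float
    pexp: tuple[tuple[str, int], ...]
    xexp: tuple[int, int, int, int]

    def with_branches(self, factors: Sequence[_Branch]) -> "_Term":
        pexp = dict(self.pexp)
        xexp = list(self.xexp)
        for br in factors:
            for name, e in br.coef:
                pexp[name] = pexp.get(name, 0) + e
            if br.pop is not None and br.exponent != 0:
                xexp[br.pop] += br.exponent
        return _Term(self.label, self.lognum, tuple(sorted(pexp.items())), tuple(xexp))

    def log_value(self, logp: Mapping[str, np.ndarray], x: np.ndarray) -> np.ndarray:
        """log flux for parameter samples ``logp`` at log-populations ``x``
        (x has shape (4,) or (4, K))."""
        out = self.lognum
        for name, e in self.pexp:
            out = out + e * logp[name]
        for j, e in enumerate(self.xexp):
            if e:
                out = out + e * x[j]
        return out


_LN2 = float(np.log(2.0))

#: factor usage per equation term, as (lognum, factor-quantities, state pop)
_EQ_STRUCTURE: list[dict] = [
    {  # S' = 2 p0 eta1 S - eta1 S
        "sources": [("2*p0*eta1*S", _LN2, ("p0", "eta1"), 0)],
        "sinks": [("eta1*S", 0.0, ("eta1",), 0)],
        "state": 0,
    },
    {  # P' = 2 eta1 S + 2 p1 eta2 P - 2 p0 eta1 S - eta2 P
        "sources": [
            ("2*eta1*S", _LN2, ("eta1",), 0),
            ("2*p1*eta2*P", _LN2, ("p1", "eta2"), 1),
        ],
        "sinks": [
            ("2*p0*eta1*S", _LN2, ("p0", "eta1"), 0),
            ("eta2*P", 0.0, ("eta2",), 1),
        ],
        "state": 1,
    },
    {  # TDl' = 2 q1 eta2 P - d_l TDl
        "sources": [("2*q1*eta2*P", _LN2, ("q1", "eta2"), 1)],
        "sinks": [("d_l*TDl", 0.0, (), 2, ("d_l", 1))],
        "state": 2,
    },
    {  # TDm' = 2 eta2 P - 2 p1 eta2 P - 2 q1 eta2 P - d_m TDm
        "sources": [("2*eta2*P", _LN2, ("eta2",), 1)],
        "sinks": [
            ("2*p1*eta2*P", _LN2, ("p1", "eta2"), 1),
            ("2*q1*eta2*P", _LN2, ("q1", "eta2"), 1),
            ("d_m*TDm", 0.0, (), 3, ("d_m", 1)),
        ],
        "state": 3,
    },
]


def _base_term(spec: tuple, branch_map: Mapping[str, _Branch]) -> _Term:
    label, lognum, quantities, state = spec[0], spec[1], spec[2], spec[3]
    pexp: dict[str, int] = {}
    if len(spec) > 4:
        name, e = spec[4]
        pexp[name] = e
    xexp = [0, 0, 0, 0]
    xexp[state] += 1
    term = _Term(label, lognum, tuple(sorted(pexp.items())), tuple(xexp))
    return term.with_branches([branch_map[q] for q in quantities])


@dataclass(frozen=True)
class SSystem:
    """One dominant subsystem: per equation a dominant source and sink,
    the non-dominant terms (for the dominance inequalities), and the
    Hill regime conditions."""

    scheme: RegulationScheme
    branches: tuple[_Branch, ...]  # one per quantity, QUANTITIES order
    dominant: tuple[tuple[_Term, _Term], ...]  # per equation (src, snk)
    others: tuple[tuple[tuple[_Term, ...], tuple[_Term, ...]], ...]
    conditions: tuple[tuple[int, str, str], ...]

    @property
    def key(self) -> tuple:
        return (
            tuple(br.key for br in self.branches),
            tuple((s.label, k.label) for s, k in self.dominant),
        )

    @property
    def exponent_matrix(self) -> np.ndarray:
        """Rows: source-minus-sink population exponents per equation."""
        A = np.zeros((4, 4))
        for i, (src, snk) in enumerate(self.dominant):
            A[i] = np.array(src.xexp) - np.array(snk.xexp)
        return A

    def n_conditions(self) -> int:
        n_dom = sum(len(s) + len(k) for s, k in self.others)
        return n_dom + len(self.conditions)


def build_ssystems(scheme: RegulationScheme) -> list[SSystem]:
    """Every (dominant source, dominant sink, regime branch) combination."""
    branch_options = [_branches(q, scheme[q]) for q in QUANTITIES]
    out: list[SSystem] = []
    for combo in itertools.product(*branch_options):
        branch_map = dict(zip(QUANTITIES, combo))
        conditions = tuple(br.condition for br in combo if br.condition is not None)
        eq_terms = []
        for eq in _EQ_STRUCTURE:
            sources = [_base_term(s, branch_map) for s in eq["sources"]]
            sinks = [_base_term(s, branch_map) for s in eq["sinks"]]
            eq_terms.append((sources, sinks))
        for dom_combo in itertools.product(
            *[
                itertools.product(range(len(srcs)), range(len(snks)))
                for srcs, snks in eq_terms
            ]
        ):
            dominant = []
            others = []
            for (srcs, snks), (i_src, i_snk) in zip(eq_terms, dom_combo):
                dominant.append((srcs[i_src], snks[i_snk]))
                others.append(
                    (
                        tuple(t for j, t in enumerate(srcs) if j != i_src),
                        tuple(t for j, t in enumerate(snks) if j != i_snk),
                    )
                )
            out.append(
                SSystem(
                    scheme=scheme,
                    branches=combo,
                    dominant=tuple(dominant),
                    others=tuple(others),
                    conditions=conditions,
                )
            )
    return out


# ---------------------------------------------------------------------------
# solving and checking


def _log_params(params: Mapping[str, float]) -> dict[str, float]:
    return {k: float(np.log(v)) for k, v in params.items()}


def solve_ssystem(
    ssys: SSystem, params: Mapping[str, float]
) -> np.ndarray | None:
    """Positive equilibrium of the dominant balance for numeric params.

    Solves ``log(dominant source) = log(dominant sink)`` per equation in
    log-population space; returns ``None`` when the exponent matrix is
    singular (no isolated equilibrium).
    """
    logp = _log_params(params)
    A = ssys.exponent_matrix
    if abs(np.linalg.det(A)) < 1e-12:
        return None
    b = np.empty(4)
    zeros = np.zeros(4)
    for i, (src, snk) in enumerate(ssys.dominant):
        b[i] = snk.log_value(logp, zeros) - src.log_value(logp, zeros)
    x = np.linalg.solve(A, b)
    if not np.all(np.isfinite(x)):
        return None
    return np.exp(x)


def check_consistency_and_stability(
    ssys: SSystem, eq: np.ndarray, params: Mapping[str, float]
) -> tuple[bool, bool]:
    """Evaluate the dominance/regime inequalities and the Jacobian at a
    positive equilibrium ``eq`` of ``ssys`` under numeric parameters."""
    eq = np.asarray(eq, dtype=float)
    if np.any(eq <= 0) or not np.all(np.isfinite(eq)):
        raise ValueError("eq must be a positive finite state")
    logp = _log_params(params)
    x = np.log(eq)

    consistent = True
    for (src, snk), (osrcs, osnks) in zip(ssys.dominant, ssys.others):
        s_dom = src.log_value(logp, x)
        k_dom = snk.log_value(logp, x)
        for t in osrcs:
            if not s_dom > t.log_value(logp, x):
                consistent = False
        for t in osnks:
            if not k_dom > t.log_value(logp, x):
                consistent = False
    for j, gain, op in ssys.conditions:
        lhs = logp[gain] + x[j]
        if op == ">" and not lhs > 0:
            consistent = False
        if op == "<" and not lhs < 0:
            consistent = False

    stable = bool(np.all(np.real(_ssystem_eigvals(ssys, eq, logp)) < 0))
    return consistent, stable


def _ssystem_eigvals(
    ssys: SSystem, eq: np.ndarray, logp: Mapping[str, float]
) -> np.ndarray:
    x = np.log(eq)
    J = np.zeros((4, 4))
    for i, (src, snk) in enumerate(ssys.dominant):
        phi = float(np.exp(src.log_value(logp, x)))
        diff = np.array(src.xexp) - np.array(snk.xexp)
        J[i] = phi * diff / eq
    return np.linalg.eigvals(J)


# ---------------------------------------------------------------------------
# scheme screening over sampled parameter witnesses


def _sample_log_params(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Broad log-uniform parameter samples (witness candidates)."""
    out: dict[str, np.ndarray] = {}
    out["p0_max"] = np.log(rng.uniform(0.55, 0.99, n))
    # progenitor fractions respect the branching simplex p1 + q1 <= 1
    p1 = rng.uniform(0.02, 0.93, n)
    out["p1_max"] = np.log(p1)
    out["q1_max"] = np.log(rng.uniform(0.02, 0.98, n) * (1.0 - p1))
    for name in ("eta1_max", "eta2_max"):
        out[name] = np.log(rng.uniform(0.05, 0.95, n))
    for name in _GAIN_PARAM.values():
        out[name] = rng.uniform(np.log(1e-8), np.log(1e2), n)
    for name in ("d_l", "d_m"):
        out[name] = rng.uniform(np.log(1e-3), np.log(1e1), n)
    return out


def _full_model_rates(
    scheme: RegulationScheme, prm: Mapping[str, float], X: np.ndarray
) -> dict[str, float]:
    """Effective rates of the full Hill model at state ``X``.

    Negative regulation: ``max / (1 + g x)``; positive regulation:
    ``max g x / (1 + g x)`` (zero basal level); none: ``max``.
    """
    rates = {}
    for q in QUANTITIES:
        reg = scheme[q]
        maxv = prm[_MAX_PARAM[q]]
        if reg.source is None:
            rates[q] = maxv
            continue
        gx = prm[_GAIN_PARAM[q]] * X[POPS.index(reg.source)]
        if not np.isfinite(gx):
            rates[q] = 0.0 if reg.sign < 0 else maxv
        else:
            rates[q] = maxv / (1.0 + gx) if reg.sign < 0 else maxv * gx / (1.0 + gx)
    return rates


def _full_model_rhs(
    scheme: RegulationScheme, prm: Mapping[str, float], y: np.ndarray
) -> np.ndarray:
    X = np.maximum(y, 0.0)
    r = _full_model_rates(scheme, prm, X)
    S, P, L, M = X
    return np.array(
        [
            (2.0 * r["p0"] - 1.0) * r["eta1"] * S,
            2.0 * (1.0 - r["p0"]) * r["eta1"] * S + (2.0 * r["p1"] - 1.0) * r["eta2"] * P,
            2.0 * r["q1"] * r["eta2"] * P - prm["d_l"] * L,
            2.0 * (1.0 - r["p1"] - r["q1"]) * r["eta2"] * P - prm["d_m"] * M,
        ]
    )


def _full_model_confirms(
    scheme: RegulationScheme, prm: Mapping[str, float], eq_guess: np.ndarray
) -> bool:
    """Does the full Hill model have a stable strictly positive
    equilibrium near the S-system prediction?

    Dominant-branch equilibria can be self-consistent within their
    power-law approximation yet correspond to no positive equilibrium
    of the full model (the approximation shifts the balance into a
    different regime).  Confirming against the full model removes those
    artifacts; regime conditions are deliberately NOT re-imposed here
    because the approximation is loose near regime boundaries.
    """
    from scipy.optimize import root

    # solve in log space to keep the iterate positive
    guess = np.log(np.maximum(eq_guess, 1e-300))

    def f(logy):
        return _full_model_rhs(scheme, prm, np.exp(np.clip(logy, -500, 500)))

    sol = root(f, guess, method="hybr")
    if not sol.success:
        return False
    eq = np.exp(np.clip(sol.x, -500, 500))
    if not np.all(np.isfinite(eq)) or np.max(eq) > 1e30:
        return False
    if np.min(eq) < 1e-12 * np.max(eq):
        return False  # collapsed onto a boundary plane
    resid = _full_model_rhs(scheme, prm, eq)
    if np.max(np.abs(resid) / (1.0 + eq)) > 1e-8:
        return False
    J = np.zeros((4, 4))
    f0 = _full_model_rhs(scheme, prm, eq)
    for j in range(4):
        h = 1e-7 * max(eq[j], 1e-30)
        y = eq.copy()
        y[j] += h
        J[:, j] = (_full_model_rhs(scheme, prm, y) - f0) / h
    eig = np.linalg.eigvals(J)
    scale = np.max(np.abs(eig))
    if scale == 0:
        return False
    if not np.max(np.real(eig)) < -1e-9 * scale:
        return False
    return _establishes_from_seed(scheme, prm, eq)


def _establishes_from_seed(
    scheme: RegulationScheme,
    prm: Mapping[str, float],
    eq: np.ndarray,
    rel_tol: float = 0.05,
    max_time: float = 2.0e5,
) -> bool:
    """Can the architecture build the equilibrium from a small stem seed?

    Physiological homeostasis must be reachable from an initial state
    containing only a few stem cells.  Architectures whose regulated
    quantities vanish with their regulators (e.g. stem self-renewal
    positively driven by a population that starts empty) collapse or
    lock compartments at zero instead, and are rejected.
    """
    from scipy.integrate import solve_ivp

    y = np.array([1e-3 * eq[0], 0.0, 0.0, 0.0])
    t, chunk = 0.0, 500.0
    while t < max_time:
        sol = solve_ivp(
            lambda _t, yy: _full_model_rhs(scheme, prm, yy),
            (0.0, chunk),
            y,
            method="LSODA",
            rtol=1e-7,
            atol=1e-9 * max(1.0, np.max(eq)),
        )
        if not sol.success:
            return False
        y = np.maximum(sol.y[:, -1], 0.0)
        if not np.all(np.isfinite(y)) or np.max(y) > 1e3 * (1.0 + np.max(eq)):
            return False  # diverging away from the candidate equilibrium
        t += chunk
        rel = np.max(np.abs(y - eq) / (1.0 + np.abs(eq)))
        if rel < rel_tol:
            return True
        dy = _full_model_rhs(scheme, prm, y)
        if np.max(np.abs(dy) / (1.0 + np.abs(y))) < 1e-10:
            # settled somewhere else (extinction or a locked boundary)
            return False
        chunk = min(chunk * 2.0, max_time / 4.0)
    return False


#: per-equation dominance choices: (source index, sink index) per eq;
#: the canonical combo (stem-derived influx balancing progenitor
#: division, terminal death as myeloid sink) is listed first
_DOM_COMBOS = sorted(
    itertools.product(
        itertools.product((0,), (0,)),
        itertools.product((0, 1), (0, 1)),
        itertools.product((0,), (0,)),
        itertools.product((0,), (0, 1, 2)),
    ),
    key=lambda combo: (combo[1] != ((0, 1)), combo[3] != ((0, 2))),
)


def build_ssystem(
    scheme: RegulationScheme,
    branch_map: Mapping[str, _Branch],
    dom_combo: Sequence[tuple[int, int]],
) -> SSystem:
    """Assemble a single S-system from explicit branch and dominance
    choices."""
    conditions = tuple(
        br.condition for br in branch_map.values() if br.condition is not None
    )
    dominant = []
    others = []
    for eq, (i_src, i_snk) in zip(_EQ_STRUCTURE, dom_combo):
        sources = [_base_term(s, branch_map) for s in eq["sources"]]
        sinks = [_base_term(s, branch_map) for s in eq["sinks"]]
        dominant.append((sources[i_src], sinks[i_snk]))
        others.append(
            (
                tuple(t for j, t in enumerate(sources) if j != i_src),
                tuple(t for j, t in enumerate(sinks) if j != i_snk),
            )
        )
    return SSystem(
        scheme=scheme,
        branches=tuple(branch_map[q] for q in QUANTITIES),
        dominant=tuple(dominant),
        others=tuple(others),
        conditions=conditions,
    )


class _ComboEvaluator:
    """Two-layer S-system screening against shared parameter samples.

    Layer 1 (cached by structural key, scheme-independent): solve the
    log-linear balance for all samples, apply the dominance and regime
    inequalities, and keep the witnesses whose S-system Jacobian is
    stable.  Layer 2 (per scheme): confirm witnesses against the full
    Hill model; the S-system passes for a scheme when a majority of the
    attempted witnesses are confirmed — viability must be the rule
    across the consistent domain, not an exception at one parameter
    corner.
    """

    def __init__(self, n_samples: int = 96, seed: int = 0, confirm: bool = True,
                 max_confirm: int = 8):
        rng = np.random.default_rng(seed)
        self.logp = _sample_log_params(n_samples, rng)
        self.n = n_samples
        self.confirm = confirm
        self.max_confirm = max_confirm
        self.cache: dict[tuple, tuple | None] = {}

    def stable_witnesses(self, ssys: SSystem) -> tuple | None:
        """Indices of samples that are consistent with stable S-system
        equilibria, or ``None`` when the S-system is structurally or
        empirically unviable.  Cached by structural key."""
        key = ssys.key
        if key in self.cache:
            return self.cache[key]
        result = self._witnesses(ssys)
        self.cache[key] = result
        return result

    def _witnesses(self, ssys: SSystem) -> tuple | None:
        A = ssys.exponent_matrix
        det = np.linalg.det(A)
        if abs(det) < 1e-12:
            return None
        # det(J) = prod(phi_i / X_i) * det(A): Hurwitz 4x4 needs det > 0
        if det < 0:
            return None
        # trace(J) = sum r_i A_ii with r_i > 0: an all-nonnegative
        # diagonal cannot be Hurwitz
        if np.all(np.diag(A) >= 0):
            return None

        logp = self.logp
        b = np.empty((4, self.n))
        zeros = np.zeros(4)
        for i, (src, snk) in enumerate(ssys.dominant):
            b[i] = snk.log_value(logp, zeros) - src.log_value(logp, zeros)
        x = np.linalg.solve(A, b)  # (4, n)

        ok = np.ones(self.n, dtype=bool)
        for (src, snk), (osrcs, osnks) in zip(ssys.dominant, ssys.others):
            if not ok.any():
                return None
            s_dom = src.log_value(logp, x)
            k_dom = snk.log_value(logp, x)
            for t in osrcs:
                ok &= s_dom > t.log_value(logp, x)
            for t in osnks:
                ok &= k_dom > t.log_value(logp, x)
        for j, gain, op in ssys.conditions:
            lhs = logp[gain] + x[j]
            ok &= lhs > 0 if op == ">" else lhs < 0
        if not ok.any():
            return None

        stable = []
        for idx in np.nonzero(ok)[0]:
            eq = np.exp(x[:, idx])
            logp_i = {k: v[idx] for k, v in logp.items()}
            eig = _ssystem_eigvals(ssys, eq, logp_i)
            if np.all(np.real(eig) < 0):
                stable.append((int(idx), tuple(eq)))
        return tuple(stable) if stable else None

    #: minimum number of stable sampled witnesses for a "robust" domain;
    #: S-systems viable only in a sliver of parameter space are rejected
    MIN_WITNESSES = 5

    def passes(self, ssys: SSystem) -> bool:
        witnesses = self.stable_witnesses(ssys)
        if witnesses is None:
            return False
        if not self.confirm:
            return True
        if len(witnesses) < self.MIN_WITNESSES:
            return False
        key = ("confirm",) + ssys.key
        hit = self.cache.get(key)
        if hit is not None:
            return bool(hit[0])
        # regime-faithful confirmation: the S-system approximates a
        # specific asymptotic regime, so the Hill model to confirm
        # against keeps the ACTIVE branches' regulations and holds
        # constant-branch factors at their maximal level (their gains
        # are free and structurally unused).  Viability must hold for
        # most witnesses, not at a single parameter corner.
        reduced = RegulationScheme(
            **{
                br.quantity: (
                    ssys.scheme[br.quantity] if br.kind != "const" else Regulation()
                )
                for br in ssys.branches
            }
        )
        n_attempted = 0
        n_confirmed = 0
        for idx, eq in witnesses[: self.max_confirm]:
            prm = {k: float(np.exp(v[idx])) for k, v in self.logp.items()}
            n_attempted += 1
            if _full_model_confirms(reduced, prm, np.asarray(eq)):
                n_confirmed += 1
        result = n_confirmed >= 0.75 * n_attempted and n_confirmed > 0
        self.cache[key] = (result,)
        return result

    # kept for compatibility with older call sites
    def _evaluate(self, ssys: SSystem) -> bool:
        return self.passes(ssys)


@dataclass(frozen=True)
class ModelVerdict:
    scheme: RegulationScheme
    accepted: bool
    p0_class: str | None  # source of negative p0 regulation, when present
    n_checked: int

    @property
    def class_label(self) -> str | None:
        return self.p0_class if self.accepted else None


def _scheme_verdict(scheme: RegulationScheme, ev: _ComboEvaluator) -> ModelVerdict:
    reg = scheme.p0
    p0_class = reg.source if (reg.source is not None and reg.sign < 0) else None
    n_checked = 0
    accepted = False
    branch_options = []
    for q in QUANTITIES:
        opts = _branches(q, scheme[q])
        if q == "p0":
            # exponent-0 stem branches make the stem balance structurally
            # singular (log(2 p0_max) = 0 has no generic solution): only
            # branches with a population exponent can balance it
            opts = [br for br in opts if br.exponent != 0]
            if not opts:
                return ModelVerdict(scheme, False, p0_class, 0)
        else:
            # try the plain (constant) branch first: accepted schemes
            # usually pass on it, which maximizes memo reuse
            opts = sorted(opts, key=lambda br: br.exponent != 0)
        branch_options.append(opts)
    for combo in itertools.product(*branch_options):
        branch_map = dict(zip(QUANTITIES, combo))
        branch_key = tuple(br.key for br in combo)
        for dom_combo in _DOM_COMBOS:
            key = (branch_key, dom_combo)
            hit = ev.cache.get(key, "miss")
            n_checked += 1
            if hit is None:
                continue
            ssys = build_ssystem(scheme, branch_map, dom_combo)
            if ev.passes(ssys):
                accepted = True
                break
        if accepted:
            break
    return ModelVerdict(scheme, accepted, p0_class, n_checked)


def filter_models(
    schemes: Iterable[RegulationScheme],
    n_samples: int = 96,
    seed: int = 0,
    evaluator: _ComboEvaluator | None = None,
) -> tuple[list[ModelVerdict], pd.DataFrame]:
    """Screen schemes; returns verdicts plus a per-class summary.

    Classes partition the accepted models by the source of negative
    stem-self-renewal regulation (``None`` marks acceptances outside
    that pattern, which the screening is expected to leave empty).
    """
    ev = evaluator or _ComboEvaluator(n_samples=n_samples, seed=seed)
    verdicts = [_scheme_verdict(s, ev) for s in schemes]
    accepted = [v for v in verdicts if v.accepted]
    counts: dict[str, int] = {}
    for v in accepted:
        label = v.p0_class if v.p0_class is not None else "other"
        counts[label] = counts.get(label, 0) + 1
    summary = pd.DataFrame(
        sorted(counts.items()), columns=["p0_class", "n_accepted"]
    )
    return verdicts, summary


# ---------------------------------------------------------------------------
# design-space map for the selected architecture


def map_design_space(
    base_params: NormalParameterSet,
    gamma1_grid: Sequence[float],
    gamma3_grid: Sequence[float],
    boundary_tol: float = 1e-3,
) -> pd.DataFrame:
    """Label each (gamma1, gamma3) grid point by the dominant S-system
    signature of the full model at its equilibrium and by the
    equilibrium type (node vs spiral).

    The signature records, per equation, which source/sink term is
    largest at the equilibrium, and per Hill factor whether it is in
    its saturated (``g X < 1``) or power-law (``g X > 1``) regime.
    Points where any comparison is within ``boundary_tol`` (relative,
    log scale) are labeled ``boundary``.
    """
    records = []
    region_ids: dict[tuple, int] = {}
    for g1 in gamma1_grid:
        for g3 in gamma3_grid:
            if g1 <= 0 or g3 <= 0:
                raise ValueError("grid gains must be positive")
            ps = base_params.replace(gamma1=g1, gamma3=g3)
            eq = analytic_equilibrium(ps)
            if eq is None:
                records.append(
                    {
                        "gamma1": g1,
                        "gamma3": g3,
                        "region": -1,
                        "signature": "no-equilibrium",
                        "kind": "none",
                    }
                )
                continue
            sig, on_boundary = _dominance_signature(ps, eq, boundary_tol)
            kind = _equilibrium_kind(ps, eq)
            if on_boundary:
                label, region = "boundary", 0
            else:
                region = region_ids.setdefault(sig, len(region_ids) + 1)
                label = "|".join(sig)
            records.append(
                {
                    "gamma1": g1,
                    "gamma3": g3,
                    "region": region,
                    "signature": label,
                    "kind": kind,
                }
            )
    return pd.DataFrame.from_records(records)


def _dominance_signature(
    ps: NormalParameterSet, eq: np.ndarray, tol: float
) -> tuple[tuple[str, ...], bool]:
    S, P, L, M = eq
    p0 = ps.p0_max / (1.0 + ps.gamma1 * P)
    p1 = ps.p1_max / (1.0 + ps.gamma3 * M)
    q1 = ps.q1_max / (1.0 + ps.gamma4 * M)
    e1 = ps.eta1_max / (1.0 + ps.gamma2 * S)
    e2 = ps.eta2_max / (1.0 + ps.gamma5 * S)

    terms = {
        "P_src": [2.0 * e1 * S, 2.0 * p1 * e2 * P],
        "P_snk": [2.0 * p0 * e1 * S, e2 * P],
        "M_snk": [2.0 * p1 * e2 * P, 2.0 * q1 * e2 * P, ps.d_m * M],
    }
    regimes = {
        "g1P": ps.gamma1 * P,
        "g2S": ps.gamma2 * S,
        "g3M": ps.gamma3 * M,
        "g4M": ps.gamma4 * M,
        "g5S": ps.gamma5 * S,
    }
    sig = []
    on_boundary = False
    for name, values in terms.items():
        order = np.argsort(values)[::-1]
        lead, second = values[order[0]], values[order[1]]
        if abs(np.log(lead) - np.log(second)) < tol:
            on_boundary = True
        sig.append(f"{name}={order[0]}")
    for name, value in regimes.items():
        if abs(np.log(value)) < tol:
            on_boundary = True
        sig.append(f"{name}{'>' if value > 1 else '<'}1")
    return tuple(sig), on_boundary


def _equilibrium_kind(ps: NormalParameterSet, eq: np.ndarray) -> str:
    J = _numeric_jacobian(ps, eq)
    eig = np.linalg.eigvals(J)
    if np.any(np.real(eig) > 0):
        return "unstable"
    return "spiral" if np.any(np.abs(np.imag(eig)) > 1e-12) else "node"


def _numeric_jacobian(
    ps: NormalParameterSet, state: np.ndarray, rel_step: float = 1e-6
) -> np.ndarray:
    J = np.zeros((4, 4))
    f0 = _rhs_closed(0.0, state, ps, 0.0)
    for j in range(4):
        h = rel_step * max(abs(state[j]), 1.0)
        y = state.copy()
        y[j] += h
        J[:, j] = (_rhs_closed(0.0, y, ps, 0.0) - f0) / h
    return J
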