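"""Mass-action reaction networks.

A :class:`ReactionNetwork` is an ordered list of species plus an ordered list
of elementary reactions with mass-action rate constants.  The species order
fixes the state-vector index mapping used everywhere else in the package.
State is in molecules per cell (clamped modulator species may use other units,
e.g. µM for cytosolic calcium; the rate constants carry the conversion).

The module compiles a network into a derivative evaluator ``f(t, y) = S·v(y)``
with ``v_j = k_j · Π reactant amounts`` (with multiplicity), plus the analytic
Jacobian, for use with stiff ODE integrators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ValidationIssue",
    "NetworkValidationError",
    "validate_network",
    "stoichiometry_matrix",
    "build_rate_function",
    "build_jacobian_function",
    "conserved_moieties",
    "read_network",
    "write_network",
]


@dataclass(frozen=True)
class Species:
    """One chemical species.

    ``initial_amount`` is the default initial condition in molecules per cell
    (or the species' native unit for clamped modulators).  ``compartment`` is a
    free label (cytosolic, mitochondrial, ...) carried through serialization.
    """

    name: str
    initial_amount: float = 0.0
    compartment: str = "cytosolic"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    Reactants and products are tuples of species names; multiplicity is
    expressed by repetition (``("A", "A")`` for 2A).  Zeroth-order reactions
    have an empty reactant tuple and rate equal to the bare rate constant.
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float

    @staticmethod
    def parse(label: str, reactants: str, products: str, rate_constant: float) -> "Reaction":
        """Build a reaction from ``"A + B"``-style side strings (empty = ∅)."""
        return Reaction(label, _parse_side(reactants), _parse_side(products), rate_constant)

    def reactant_side(self) -> str:
        return _format_side(self.reactants)

    def product_side(self) -> str:
        return _format_side(self.products)


def _parse_side(side: str) -> tuple[str, ...]:
    side = side.strip()
    if side in ("", "0", "∅", "-"):
        return ()
    names: list[str] = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ValueError(f"malformed reaction side: {side!r}")
        # allow "2 A" shorthand for "A + A"
        parts = term.split()
        if len(parts) == 2 and parts[0].isdigit():
            names.extend([parts[1]] * int(parts[0]))
        else:
            names.append(term)
    return tuple(names)


def _format_side(names: Sequence[str]) -> str:
    return " + ".join(names) if names else "∅"


@dataclass
class ReactionNetwork:
    """Ordered species + reactions; the mathematical object the solver uses."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_state(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        """Default initial state vector, with per-species overrides applied."""
        y0 = np.array([s.initial_amount for s in self.species], dtype=float)
        if overrides:
            idx = self.index
            for name, amount in overrides.items():
                if name not in idx:
                    raise KeyError(f"override for unknown species {name!r}")
                y0[idx[name]] = amount
        return y0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # duplicate-species | dangling-reference | negative-rate | negative-initial | empty-reaction
    where: str
    message: str


class NetworkValidationError(ValueError):
    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__("; ".join(f"[{i.kind}] {i.where}: {i.message}" for i in issues))


def validate_network(network: ReactionNetwork) -> list[ValidationIssue]:
    """Report structural problems; an empty report means the network is well-formed."""
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for sp in network.species:
        if sp.name in seen:
            issues.append(ValidationIssue("duplicate-species", sp.name, "declared more than once"))
        seen.add(sp.name)
        if sp.initial_amount < 0:
            issues.append(
                ValidationIssue("negative-initial", sp.name, f"initial amount {sp.initial_amount}")
            )
    for rxn in network.reactions:
        if not rxn.reactants and not rxn.products:
            issues.append(ValidationIssue("empty-reaction", rxn.label, "no reactants or products"))
        if rxn.rate_constant < 0:
            issues.append(
                ValidationIssue("negative-rate", rxn.label, f"rate constant {rxn.rate_constant}")
            )
        for name in (*rxn.reactants, *rxn.products):
            if name not in seen:
                issues.append(
                    ValidationIssue("dangling-reference", rxn.label, f"unknown species {name!r}")
                )
    return issues


def _require_valid(network: ReactionNetwork) -> None:
    issues = validate_network(network)
    if issues:
        raise NetworkValidationError(issues)


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer matrix S (species × reactions); S[i, j] = net production of i by j."""
    _require_valid(network)
    idx = network.index
    S = np.zeros((len(network.species), len(network.reactions)), dtype=np.int64)
    for j, rxn in enumerate(network.reactions):
        for name in rxn.reactants:
            S[idx[name], j] -= 1
        for name in rxn.products:
            S[idx[name], j] += 1
    return S


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array form of a network for fast rate/Jacobian evaluation."""

    S: np.ndarray  # float (ns, nr)
    k: np.ndarray  # (nr,)
    entry_rxn: np.ndarray  # reactant occurrences, reaction index per occurrence
    entry_sp: np.ndarray  # species index per occurrence
    # unique (reaction, species, multiplicity) triples for the Jacobian
    jac_rxn: np.ndarray
    jac_sp: np.ndarray
    jac_mult: np.ndarray
    n_species: int
    n_reactions: int


def compile_network(network: ReactionNetwork) -> CompiledNetwork:
    _require_valid(network)
    idx = network.index
    S = stoichiometry_matrix(network).astype(float)
    k = np.array([r.rate_constant for r in network.reactions], dtype=float)
    entry_rxn: list[int] = []
    entry_sp: list[int] = []
    jac_rxn: list[int] = []
    jac_sp: list[int] = []
    jac_mult: list[int] = []
    for j, rxn in enumerate(network.reactions):
        counts: dict[int, int] = {}
        for name in rxn.reactants:
            i = idx[name]
            entry_rxn.append(j)
            entry_sp.append(i)
            counts[i] = counts.get(i, 0) + 1
        for i, m in counts.items():
            jac_rxn.append(j)
            jac_sp.append(i)
            jac_mult.append(m)
    return CompiledNetwork(
        S=S,
        k=k,
        entry_rxn=np.asarray(entry_rxn, dtype=np.int64),
        entry_sp=np.asarray(entry_sp, dtype=np.int64),
        jac_rxn=np.asarray(jac_rxn, dtype=np.int64),
        jac_sp=np.asarray(jac_sp, dtype=np.int64),
        jac_mult=np.asarray(jac_mult, dtype=np.int64),
        n_species=len(network.species),
        n_reactions=len(network.reactions),
    )


def rate_vector(compiled: CompiledNetwork, y: np.ndarray) -> np.ndarray:
    """v(y): per-reaction mass-action rates (no clamping of negative state)."""
    v = compiled.k.copy()
    np.multiply.at(v, compiled.entry_rxn, y[compiled.entry_sp])
    return v


def build_rate_function(
    network: ReactionNetwork | CompiledNetwork,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Derivative evaluator ``f(t, y) = S · v(y)`` for ODE integration."""
    c = network if isinstance(network, CompiledNetwork) else compile_network(network)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return c.S @ rate_vector(c, y)

    return rhs


def build_jacobian_function(
    network: ReactionNetwork | CompiledNetwork,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic Jacobian ``J[i, l] = Σ_j S[i, j] ∂v_j/∂y_l`` of the rate function."""
    c = network if isinstance(network, CompiledNetwork) else compile_network(network)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        v = rate_vector(c, y)
        dV = np.zeros((c.n_reactions, c.n_species))
        for j, l, m in zip(c.jac_rxn, c.jac_sp, c.jac_mult):
            yl = y[l]
            if yl != 0.0:
                dV[j, l] += m * v[j] / yl
            else:
                # recompute the product without the vanishing factor
                prod = c.k[j]
                skip = m - 1  # one power of y_l removed
                used = 0
                for jj, ll in zip(c.entry_rxn, c.entry_sp):
                    if jj != j:
                        continue
                    if ll == l and used < 1:
                        used += 1
                        continue
                    prod *= y[ll]
                dV[j, l] += m * prod if skip == 0 else 0.0
        return c.S @ dV

    return jac


def conserved_moieties(network: ReactionNetwork) -> list[np.ndarray]:
    """Non-negative integer vectors c with cᵀS = 0 (conserved pools).

    Computes a rational basis of the left null space of S exactly, scales each
    basis vector to coprime integers, and greedily combines basis vectors to
    remove negative entries.  Vectors that cannot be made non-negative are
    dropped, so the result is a (possibly incomplete) set of conservation laws
    — sufficient for integration-accuracy checks, not a full cone enumeration.
    """
    S = stoichiometry_matrix(network)
    basis = _left_nullspace_rational(S)
    out: list[np.ndarray] = []
    for vec in basis:
        fixed = _make_nonnegative(vec, basis)
        if fixed is not None and np.any(fixed):
            fixed = fixed // np.gcd.reduce(fixed[fixed != 0])
            if not any(np.array_equal(fixed, o) for o in out):
                out.append(fixed)
    return out


def _left_nullspace_rational(S: np.ndarray) -> list[np.ndarray]:
    """Exact integer basis of {c : cᵀS = 0} via fraction-free RREF of Sᵀ."""
    ns = S.shape[0]
    M = [[Fraction(int(x)) for x in row] for row in S.T.tolist()]
    nrows = len(M)
    pivots: list[int] = []
    r = 0
    for col in range(ns):
        piv = next((i for i in range(r, nrows) if M[i][col] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        pv = M[r][col]
        M[r] = [x / pv for x in M[r]]
        for i in range(nrows):
            if i != r and M[i][col] != 0:
                f = M[i][col]
                M[i] = [a - f * b for a, b in zip(M[i], M[r])]
        pivots.append(col)
        r += 1
        if r == nrows:
            break
    free = [c for c in range(ns) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * ns
        vec[fc] = Fraction(1)
        for ri, pc in enumerate(pivots):
            vec[pc] = -M[ri][fc]
        denom = 1
        for x in vec:
            denom = denom * x.denominator // np.gcd(denom, x.denominator)
        ivec = np.array([int(x * denom) for x in vec], dtype=np.int64)
        g = np.gcd.reduce(np.abs(ivec[ivec != 0])) if np.any(ivec) else 1
        basis.append(ivec // g)
    return basis


def _make_nonnegative(vec: np.ndarray, basis: list[np.ndarray]) -> np.ndarray | None:
    if np.all(vec >= 0):
        return vec.copy()
    if np.all(vec <= 0):
        return -vec
    cur = vec.copy()
    for _ in range(8):  # a few greedy repair passes
        neg = cur < 0
        if not neg.any():
            return cur
        progressed = False
        for other in basis:
            if other is vec:
                continue
            for cand in (cur + other, cur - other):
                if int((cand < 0).sum()) < int(neg.sum()) and np.any(cand):
                    cur = cand
                    progressed = True
                    break
            if progressed:
                break
        if not progressed:
            return None
    return cur if np.all(cur >= 0) else None


# ---------------------------------------------------------------------------
# Serialization: two delimited UTF-8 tables with header rows.
# species table: name, compartment, initial_amount
# reactions table: label, reactants, products, rate_constant
# ---------------------------------------------------------------------------

def read_network(species_path: str | Path, reactions_path: str | Path) -> ReactionNetwork:
    """Load a network from the two-table text dialect (TSV or CSV by extension)."""
    import pandas as pd

    sp_df = _read_table(species_path)
    rx_df = _read_table(reactions_path)
    _expect_columns(sp_df, ("name", "compartment", "initial_amount"), species_path)
    _expect_columns(rx_df, ("label", "reactants", "products", "rate_constant"), reactions_path)
    species = [
        Species(str(r["name"]), float(r["initial_amount"]), str(r["compartment"]))
        for _, r in sp_df.iterrows()
    ]
    reactions = [
        Reaction.parse(str(r["label"]), str(r["reactants"]) if not _isna(r["reactants"]) else "",
                       str(r["products"]) if not _isna(r["products"]) else "",
                       float(r["rate_constant"]))
        for _, r in rx_df.iterrows()
    ]
    return ReactionNetwork(species=species, reactions=reactions)


def write_network(
    network: ReactionNetwork, species_path: str | Path, reactions_path: str | Path
) -> None:
    """Round-trip writer for the same dialect read by :func:`read_network`."""
    import pandas as pd

    sp_df = pd.DataFrame(
        {
            "name": [s.name for s in network.species],
            "compartment": [s.compartment for s in network.species],
            "initial_amount": [repr(s.initial_amount) for s in network.species],
        }
    )
    rx_df = pd.DataFrame(
        {
            "label": [r.label for r in network.reactions],
            "reactants": [" + ".join(r.reactants) for r in network.reactions],
            "products": [" + ".join(r.products) for r in network.reactions],
            "rate_constant": [repr(r.rate_constant) for r in network.reactions],
        }
    )
    sep_s = "\t" if str(species_path).endswith(".tsv") else ","
    sep_r = "\t" if str(reactions_path).endswith(".tsv") else ","
    sp_df.to_csv(species_path, sep=sep_s, index=False)
    rx_df.to_csv(reactions_path, sep=sep_r, index=False)


def _read_table(path: str | Path):
    import pandas as pd

    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""


def _expect_columns(df, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
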