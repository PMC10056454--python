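"""Stoichiometric reaction network for syngas acetogenesis, chain
elongation and solventogenesis.

Reactions are coefficient maps over registry compounds (negative =
substrate).  Every reaction must balance in C, H and O, which for
C/H/O species implies electron balance as well; both are checked
independently.  The default network:

    R1  homoacetogenesis        2 CO2 + 4 H2        -> acetate + 2 H2O
    R2  CO acetogenesis         4 CO  + 2 H2O       -> acetate + 2 CO2
    R3  ethanol from H2/CO2     2 CO2 + 6 H2        -> ethanol + 3 H2O
    R4  ethanol from CO         6 CO  + 3 H2O       -> ethanol + 4 CO2
    R5  acetate reduction       acetate + 2 H2      -> ethanol + H2O
    R6  elongation to butyrate  5 ethanol + 3 acetate -> 4 butyrate + 2 H2 + 3 H2O
    R7  elongation to caproate  ethanol + butyrate  -> caproate + H2O
    R8  butyrate reduction      butyrate + 2 H2     -> butanol + H2O
    R9  ethanol oxidation       ethanol + H2O       -> acetate + 2 H2

R6 is the classic 5:3 reverse beta-oxidation of ethanol and acetate;
per mole of ethanol it releases 0.4 H2, whereas caproate formation (R7)
releases none — chain elongation to caproate is the more H2-sparing
sink for ethanol electrons.  Note two exact linear dependencies over
the measured (non-water) compounds: R3 = R1 + R5, and R9 = -R5; extent
fitting over sub-networks containing either pair is reported as
rank-deficient rather than silently resolved.

Reaction extents (mmol of reaction events) map a network onto a batch:
final = initial + S @ xi.  The inverse problem — recover extents from a
measured net-production vector — is solved by non-negative least
squares, which is exact for noiseless data whenever the measured
stoichiometric matrix has full column rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.linalg import null_space
from scipy.optimize import nnls

from .compounds import CompoundRegistry, default_registry

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "BalanceReport",
    "UnbalancedReactionError",
    "InfeasibleExtentError",
    "RankDeficiencyWarning",
    "check_balance",
    "apply_extents",
    "estimate_extents",
    "default_network",
    "CAPROATE_RBO_VARIANT",
]

_ELEMENTS = ("C", "H", "O", "N")


class UnbalancedReactionError(ValueError):
    """A reaction fails element or electron balance."""


class InfeasibleExtentError(ValueError):
    """An extent vector would drive some amount negative."""


class RankDeficiencyWarning(UserWarning):
    """The measured stoichiometric matrix has dependent columns."""


@dataclass(frozen=True)
class Reaction:
    """A named reaction as a compound -> signed coefficient map."""

    name: str
    coefficients: Mapping[str, Fraction | int | float]

    def __post_init__(self) -> None:
        coeffs = {c: Fraction(v).limit_denominator(10**6) for c, v in self.coefficients.items()}
        if not coeffs or all(v == 0 for v in coeffs.values()):
            raise ValueError(f"reaction {self.name!r} has no non-zero coefficients")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {c: -v for c, v in self.coefficients.items() if v < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {c: v for c, v in self.coefficients.items() if v > 0}


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and electron residuals of one reaction (products minus
    substrates); ``balanced`` iff every residual is zero."""

    reaction: str
    element_residuals: dict[str, Fraction]
    electron_residual: Fraction

    @property
    def balanced(self) -> bool:
        return self.electron_residual == 0 and all(
            v == 0 for v in self.element_residuals.values()
        )


def check_balance(reaction: Reaction, registry: CompoundRegistry | None = None) -> BalanceReport:
    """Element (C,H,O,N) and electron residuals of a reaction."""
    registry = registry if registry is not None else default_registry()
    el = {e: Fraction(0) for e in _ELEMENTS}
    e_res = Fraction(0)
    for name, nu in reaction.coefficients.items():
        c = registry[name]
        for e in _ELEMENTS:
            el[e] += nu * getattr(c.formula, e)
        e_res += nu * c.e_per_mol
    return BalanceReport(reaction=reaction.name, element_residuals=el, electron_residual=e_res)


class ReactionNetwork:
    """Ordered reactions sharing a compound space.

    The stoichiometric matrix ``S`` has one row per compound and one
    column per reaction.  ``measured_compounds`` (default: everything
    except water) defines the sub-matrix used for extent estimation.
    Each reaction is balance-verified on construction.
    """

    def __init__(
        self,
        reactions: Sequence[Reaction],
        registry: CompoundRegistry | None = None,
        measured_compounds: Sequence[str] | None = None,
    ):
        self.registry = registry if registry is not None else default_registry()
        self.reactions = list(reactions)
        if not self.reactions:
            raise ValueError("network needs at least one reaction")
        for rxn in self.reactions:
            report = check_balance(rxn, self.registry)
            if not report.balanced:
                raise UnbalancedReactionError(
                    f"reaction {rxn.name!r} unbalanced: elements "
                    f"{ {k: str(v) for k, v in report.element_residuals.items() if v} }, "
                    f"electrons {report.electron_residual}"
                )
        names: list[str] = []
        for rxn in self.reactions:
            for c in rxn.coefficients:
                canonical = self.registry[c].name
                if canonical not in names:
                    names.append(canonical)
        self.compounds: list[str] = names
        if measured_compounds is None:
            measured_compounds = [c for c in names if c != "H2O"]
        self.measured_compounds = [self.registry[c].name for c in measured_compounds]

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix, compounds x reactions."""
        S = np.zeros((len(self.compounds), len(self.reactions)))
        row = {c: i for i, c in enumerate(self.compounds)}
        for j, rxn in enumerate(self.reactions):
            for c, nu in rxn.coefficients.items():
                S[row[self.registry[c].name], j] = float(nu)
        return S

    @property
    def S_measured(self) -> np.ndarray:
        S = self.S
        row = {c: i for i, c in enumerate(self.compounds)}
        return S[[row[c] for c in self.measured_compounds], :]

    def measured_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.S_measured))

    def is_identifiable(self) -> bool:
        return self.measured_rank() == len(self.reactions)

    def subnetwork(self, reaction_names: Sequence[str]) -> "ReactionNetwork":
        wanted = set(reaction_names)
        missing = wanted - set(self.reaction_names)
        if missing:
            raise KeyError(f"unknown reactions: {sorted(missing)}")
        return ReactionNetwork(
            [r for r in self.reactions if r.name in wanted],
            registry=self.registry,
        )

    # ---- serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            r.name: {c: (int(v) if v.denominator == 1 else float(v)) for c, v in r.coefficients.items()}
            for r in self.reactions
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(
        cls, path: str | Path, registry: CompoundRegistry | None = None
    ) -> "ReactionNetwork":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            [Reaction(name=k, coefficients=v) for k, v in data.items()], registry=registry
        )


def apply_extents(
    network: ReactionNetwork,
    extents: Mapping[str, float] | Sequence[float] | np.ndarray,
    initial_mmol: Mapping[str, float],
) -> dict[str, float]:
    """Advance amounts by reaction extents: final = initial + S @ xi.

    ``extents`` in mmol of reaction events, non-negative.  Raises
    :class:`InfeasibleExtentError` naming the first exhausted compound
    if any final amount would go negative (beyond 1e-9 mmol).
    """
    xi = _extent_array(network, extents)
    if np.any(xi < 0):
        raise ValueError("extents must be non-negative")
    final_vec = network.S @ xi
    final = {c: initial_mmol.get(c, 0.0) for c in set(initial_mmol) | set(network.compounds)}
    for i, c in enumerate(network.compounds):
        final[c] = final.get(c, 0.0) + final_vec[i]
    for c, v in final.items():
        if v < -1e-9:
            raise InfeasibleExtentError(
                f"extents exhaust {c!r}: final amount {v:.6g} mmol < 0"
            )
        final[c] = max(v, 0.0)
    return final


def _extent_array(network: ReactionNetwork, extents) -> np.ndarray:
    if isinstance(extents, Mapping):
        unknown = set(extents) - set(network.reaction_names)
        if unknown:
            raise KeyError(f"unknown reactions in extent map: {sorted(unknown)}")
        return np.array([float(extents.get(r, 0.0)) for r in network.reaction_names])
    xi = np.asarray(extents, dtype=float)
    if xi.shape != (len(network.reactions),):
        raise ValueError(f"expected {len(network.reactions)} extents, got shape {xi.shape}")
    return xi


@dataclass(frozen=True)
class ExtentFit:
    """Non-negative least-squares extent estimate."""

    extents: dict[str, float]
    residual_norm: float
    rank: int
    identifiable: bool
    null_space_basis: np.ndarray | None = None

    def as_array(self, network: ReactionNetwork) -> np.ndarray:
        return np.array([self.extents[r] for r in network.reaction_names])


def estimate_extents(
    network: ReactionNetwork, net_changes_mmol: Mapping[str, float]
) -> ExtentFit:
    """Recover reaction extents from a measured net-production vector.

    Solves ``min || S_m xi - delta ||_2  s.t.  xi >= 0`` over the
    measured compounds.  When ``S_m`` is rank-deficient the solution is
    not unique; a :class:`RankDeficiencyWarning` is emitted carrying the
    null-space basis (combinations of reactions indistinguishable from
    start/end data).
    """
    S_m = network.S_measured
    delta = np.array(
        [float(net_changes_mmol.get(c, 0.0)) for c in network.measured_compounds]
    )
    rank = int(np.linalg.matrix_rank(S_m))
    identifiable = rank == len(network.reactions)
    basis = None
    if not identifiable:
        basis = null_space(S_m)
        combos = []
        for k in range(basis.shape[1]):
            terms = [
                f"{basis[j, k]:+.3f} {network.reaction_names[j]}"
                for j in range(basis.shape[0])
                if abs(basis[j, k]) > 1e-9
            ]
            combos.append(" ".join(terms))
        warnings.warn(
            "measured stoichiometric matrix is rank-deficient "
            f"(rank {rank} < {len(network.reactions)} reactions); "
            "unidentifiable combinations: " + "; ".join(combos),
            RankDeficiencyWarning,
            stacklevel=2,
        )
    xi, rnorm = nnls(S_m, delta)
    return ExtentFit(
        extents=dict(zip(network.reaction_names, xi.tolist())),
        residual_norm=float(rnorm),
        rank=rank,
        identifiable=identifiable,
        null_space_basis=basis,
    )


_DEFAULT_REACTIONS: list[tuple[str, dict[str, int]]] = [
    ("R1_homoacetogenesis", {"CO2": -2, "H2": -4, "acetic acid": 1, "H2O": 2}),
    ("R2_co_acetogenesis", {"CO": -4, "H2O": -2, "acetic acid": 1, "CO2": 2}),
    ("R3_ethanol_from_h2_co2", {"CO2": -2, "H2": -6, "ethanol": 1, "H2O": 3}),
    ("R4_ethanol_from_co", {"CO": -6, "H2O": -3, "ethanol": 1, "CO2": 4}),
    ("R5_acetate_reduction", {"acetic acid": -1, "H2": -2, "ethanol": 1, "H2O": 1}),
    (
        "R6_elongation_butyrate",
        {"ethanol": -5, "acetic acid": -3, "butyric acid": 4, "H2": 2, "H2O": 3},
    ),
    ("R7_elongation_caproate", {"ethanol": -1, "butyric acid": -1, "caproic acid": 1, "H2O": 1}),
    ("R8_butyrate_reduction", {"butyric acid": -1, "H2": -2, "butanol": 1, "H2O": 1}),
    ("R9_ethanol_oxidation", {"ethanol": -1, "H2O": -1, "acetic acid": 1, "H2": 2}),
]

# Optional reverse-beta-oxidation variant of caproate formation that
# releases acetate and H2, for users preferring a 5:4 stoichiometry over
# the minimal 1:1 condensation R7.
CAPROATE_RBO_VARIANT = Reaction(
    "R7alt_elongation_caproate_rbo",
    {
        "ethanol": -5,
        "butyric acid": -4,
        "caproic acid": 4,
        "acetic acid": 1,
        "H2": 2,
        "H2O": 3,
    },
)


def default_network(registry: CompoundRegistry | None = None) -> ReactionNetwork:
    """The nine-reaction acetogenesis / chain-elongation / solventogenesis
    network (balance-verified on construction)."""
    return ReactionNetwork(
        [Reaction(name, coeffs) for name, coeffs in _DEFAULT_REACTIONS], registry=registry
    )
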