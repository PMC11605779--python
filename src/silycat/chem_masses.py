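"""Formula arithmetic, adduct m/z, and the reaction mass-delta library.

Flavonolignan catabolites produced by gut microbiota are recognised by the
mass shift of their [M+H]+ ion relative to the parent flavonolignan ion at
m/z 483.129.  Small shifts correspond to simple biotransformations
(demethylation −CH2, hydrogenation +H2, dehydroxylation −O) or short
combinations of them; this module enumerates those combinations and matches
an observed shift against the library within a configurable tolerance.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "ElementCounts",
    "ReactionDelta",
    "MassMatch",
    "PROTON_MASS",
    "REFERENCE_MZ",
    "DEFAULT_TOLERANCE_DA",
    "LEGACY_LOOSE_TOLERANCE_DA",
    "PRIMITIVE_REACTIONS",
    "OPTIONAL_REACTIONS",
    "parse_formula",
    "render_formula",
    "monoisotopic_mass",
    "average_mass",
    "protonated_mz",
    "delta_mz",
    "match_reactions",
]

# element symbol -> (monoisotopic mass of lightest isotope, standard atomic weight)
_ELEMENTS: dict[str, tuple[float, float]] = {
    "C": (12.0, 12.011),
    "H": (1.00782503, 1.008),
    "O": (15.99491462, 15.999),
    "N": (14.00307401, 14.007),
    "S": (31.97207117, 32.06),
    "P": (30.97376200, 30.974),
    "Na": (22.98976928, 22.990),
    "K": (38.96370649, 39.098),
    "Cl": (34.96885268, 35.45),
}

#: mass of a proton, Da — added to the neutral mass for the [M+H]+ ion
PROTON_MASS = 1.007276

#: [M+H]+ of the C25H22O10 flavonolignan isomers; all catabolite deltas are
#: computed against this reference
REFERENCE_MZ = 483.129

#: default absolute matching tolerance (≈10 ppm at m/z 480)
DEFAULT_TOLERANCE_DA = 0.005

#: loose preset that additionally accepts the −16.03 Da shifts historically
#: labelled "dehydroxylation" (nominal −O is −15.9949, 37 mDa away)
LEGACY_LOOSE_TOLERANCE_DA = 0.040

ElementCounts = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a molecular formula like ``"C24H20O10"`` into element counts.

    Repeated element symbols accumulate.  Raises ``ValueError`` on unknown
    symbols or malformed counts (zero, negative, stray characters).
    """
    counts: ElementCounts = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return counts


def render_formula(counts: ElementCounts) -> str:
    """Render counts as a canonical Hill-order string (C, H, then alphabetical)."""
    order = [s for s in ("C", "H") if s in counts]
    order += sorted(s for s in counts if s not in ("C", "H"))
    parts = []
    for sym in order:
        n = counts[sym]
        if n <= 0:
            raise ValueError(f"non-positive count for {sym}")
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Exact mass from lightest-isotope masses.  Empty composition -> 0.0."""
    total = 0.0
    for sym, n in counts.items():
        if sym not in _ELEMENTS:
            raise ValueError(f"no isotope mass for element {sym!r}")
        total += n * _ELEMENTS[sym][0]
    return total


def average_mass(counts: ElementCounts) -> float:
    """Average (chemical) mass from standard atomic weights."""
    total = 0.0
    for sym, n in counts.items():
        if sym not in _ELEMENTS:
            raise ValueError(f"no atomic weight for element {sym!r}")
        total += n * _ELEMENTS[sym][1]
    return total


def protonated_mz(neutral_mass: float) -> float:
    """m/z of the [M+H]+ ion of a neutral of the given monoisotopic mass."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    return neutral_mass + PROTON_MASS


def delta_mz(observed_mz: float, reference_mz: float = REFERENCE_MZ) -> float:
    """Signed mass shift of an observed ion relative to the parent reference."""
    return observed_mz - reference_mz


@dataclass(frozen=True)
class ReactionDelta:
    """A (possibly combined) biotransformation and its net mass shift."""

    name: str
    loss: ElementCounts = field(default_factory=dict)
    gain: ElementCounts = field(default_factory=dict)
    steps: int = 1

    @property
    def shift(self) -> float:
        return monoisotopic_mass(self.gain) - monoisotopic_mass(self.loss)

    def combine(self, other: "ReactionDelta") -> "ReactionDelta":
        loss = dict(self.loss)
        for s, n in other.loss.items():
            loss[s] = loss.get(s, 0) + n
        gain = dict(self.gain)
        for s, n in other.gain.items():
            gain[s] = gain.get(s, 0) + n
        return ReactionDelta(
            name=f"{self.name}; {other.name}",
            loss=loss,
            gain=gain,
            steps=self.steps + other.steps,
        )


#: single-step biotransformations observed in flavonolignan catabolism.
#: Catabolites are seen as [M+H]+, so a net loss of CH2 appears in the table
#: as "loss CH3 / addition H": the neutral loses CH2.
PRIMITIVE_REACTIONS: tuple[ReactionDelta, ...] = (
    ReactionDelta("demethylation", loss={"C": 1, "H": 2}),
    ReactionDelta("hydrogenation", gain={"H": 2}),
    ReactionDelta("dehydroxylation", loss={"O": 1}),
)

#: available but off by default (a +2 OH transformation mentioned once in the
#: literature; likely a slip for dehydroxylation)
OPTIONAL_REACTIONS: tuple[ReactionDelta, ...] = (
    ReactionDelta("dihydroxylation", gain={"H": 2, "O": 2}),
)


@dataclass(frozen=True)
class MassMatch:
    """A reaction (or combination) whose theoretical shift matches an observed one."""

    reaction: ReactionDelta
    observed_delta: float
    error_da: float
    error_ppm: float


def match_reactions(
    delta: float,
    max_steps: int = 2,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    reactions: tuple[ReactionDelta, ...] = PRIMITIVE_REACTIONS,
    reference_mz: float = REFERENCE_MZ,
) -> list[MassMatch]:
    """Match an observed mass shift against multisets of primitive reactions.

    Enumerates every multiset of the primitive library of size 1..max_steps
    (a primitive may repeat, e.g. double demethylation) and returns the
    combinations whose net theoretical shift lies within ``tolerance_da`` of
    ``delta``, sorted by absolute error.  An empty list means the shift is
    unexplained at this tolerance.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    if not reactions:
        raise ValueError("empty reaction library")
    matches = []
    for k in range(1, max_steps + 1):
        for combo in itertools.combinations_with_replacement(reactions, k):
            rxn = combo[0]
            for extra in combo[1:]:
                rxn = rxn.combine(extra)
            err = delta - rxn.shift
            if abs(err) <= tolerance_da:
                matches.append(
                    MassMatch(
                        reaction=rxn,
                        observed_delta=delta,
                        error_da=err,
                        error_ppm=err / reference_mz * 1e6,
                    )
                )
    matches.sort(key=lambda m: abs(m.error_da))
    return matches
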